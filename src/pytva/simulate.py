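"""Seeded generators emulating the CombiTVA and CPT designs.

The generators draw trial-level data with exactly the statistical structure
the analysis assumes, so every pipeline stage can be exercised and checked
against ground truth without any behavioural recordings:

* CombiTVA sessions come from the capacity-limited exponential race itself
  (a capacity drawn from pK per trial, race rates from the attentional
  weights) plus a small lapse/guessing rate that appends one non-displayed
  letter, producing the non-zero error counts real sessions show;
* CPT sessions come from an equal-variance Gaussian SDT observer with
  half-specific sensitivity (to inject d'-change effects), a fixed response
  criterion, and truncated-lognormal response times inside the 1 s window;
* cohorts attach COMT / DBH genotype labels carrying programmable additive
  effects plus between-subject Gaussian variation, and emit a truth table
  of every participant's generating parameters for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import lognorm

from . import cpt as cpt_mod
from .core import (
    ALPHABET,
    DISPLAY_TYPES,
    DisplaySpec,
    EXPOSURES_MS,
    K_VALUES,
    TVAParams,
    TrialRecord,
    attentional_weights,
    effective_exposure,
    processing_rates,
)
from .cpt import CPTTrial, DISTRACTOR_SUBTYPES, RESPONSE_WINDOW_MS

__all__ = [
    "CombiTVADesign",
    "CPTDesign",
    "LognormalRT",
    "CohortConfig",
    "Participant",
    "Cohort",
    "generate_combitva_session",
    "generate_cpt_session",
    "generate_cohort",
]


@dataclass(frozen=True)
class CombiTVADesign:
    """The CombiTVA session design: 9 blocks x 36 trials, full 3 x 6 crossing.

    Display types and exposures are crossed with 18 repetitions each and
    shuffled, which honours the stated properties (random order, durations
    equally distributed).  The placeholder circle radius is display metadata
    only.
    """

    n_blocks: int = 9
    trials_per_block: int = 36
    display_types: tuple[str, ...] = DISPLAY_TYPES
    exposures_ms: tuple[float, ...] = EXPOSURES_MS
    alphabet: str = ALPHABET
    circle_radius_deg: float = 7.5

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def condition_list(self) -> list[tuple[str, float]]:
        cells = [(t, e) for t in self.display_types for e in self.exposures_ms]
        reps, rem = divmod(self.n_trials, len(cells))
        if rem:
            raise ValueError("trial count must be a multiple of the 3x6 crossing")
        return cells * reps


@dataclass(frozen=True)
class CPTDesign:
    """A 180-trial CPT session; target share 1/3 (SA) or 2/3 (GNG)."""

    n_trials: int = 180
    target_share: float = 1.0 / 3.0
    stimulus_duration_ms: float = 150.0
    isi_range_ms: tuple[float, float] = (1000.0, 5000.0)

    @classmethod
    def sa(cls) -> "CPTDesign":
        return cls(target_share=1.0 / 3.0)

    @classmethod
    def gng(cls) -> "CPTDesign":
        return cls(target_share=2.0 / 3.0)

    @property
    def n_targets(self) -> int:
        return round(self.n_trials * self.target_share)

    @property
    def n_distractors(self) -> int:
        return self.n_trials - self.n_targets


@dataclass(frozen=True)
class LognormalRT:
    """Hit-RT model: lognormal (median ``median_ms``, log-SD ``sigma``),
    truncated to the response window via inverse-CDF sampling."""

    median_ms: float = 450.0
    sigma: float = 0.25

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        dist = lognorm(s=self.sigma, scale=self.median_ms)
        u_max = dist.cdf(RESPONSE_WINDOW_MS)
        u = rng.uniform(0.0, u_max, size=n)
        return np.minimum(dist.ppf(u), RESPONSE_WINDOW_MS)


def generate_combitva_session(
    params: TVAParams,
    design: Optional[CombiTVADesign] = None,
    guess_rate: float = 0.05,
    seed: int | np.random.Generator = 0,
    participant_id: str = "P000",
) -> list[TrialRecord]:
    """Simulate one CombiTVA session from the race model.

    Per trial: draw the condition (pre-shuffled full crossing), sample
    letters without replacement, draw a capacity k ~ pK, race the displayed
    items, and report the encoded targets.  With probability ``guess_rate``
    one uniformly-random non-displayed letter is appended, emulating
    imperfect compliance with the no-guessing instruction (these guesses are
    never correct, so the score counts the fit consumes are unaffected).
    """
    if design is None:
        design = CombiTVADesign()
    if not (0.0 <= guess_rate <= 0.2):
        raise ValueError("guess_rate must be in [0, 0.2]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conditions = design.condition_list()
    order = rng.permutation(len(conditions))
    alphabet = list(design.alphabet)
    k_vals = np.asarray(K_VALUES)
    pK = np.asarray(params.pK)
    trials: list[TrialRecord] = []
    for t_idx, ci in enumerate(order):
        dtype, exposure = conditions[ci]
        display = DisplaySpec.of_type(dtype, exposure)
        disp = list(display.displayed)
        letters: list[Optional[str]] = [None] * 6
        drawn = rng.choice(len(alphabet), size=len(disp), replace=False)
        for slot, li in zip(disp, drawn):
            letters[slot] = alphabet[li]
        k = int(rng.choice(k_vals, p=pK))
        tau = effective_exposure(exposure, params.t0)
        weights = attentional_weights(display, params.w_index, params.alpha)[disp]
        rates = processing_rates(weights, params.C)
        # race: exponential finishing times, first min(k, #finishers) encoded
        times = np.full(len(disp), np.inf)
        pos = rates > 0
        times[pos] = rng.exponential(1.0 / rates[pos])
        finish_order = np.argsort(times)
        encoded = [
            disp[j]
            for rank, j in enumerate(finish_order)
            if times[j] <= tau and rank < k
        ]
        reported = "".join(
            letters[i] for i in encoded if display.roles[i] == "T"
        )
        if guess_rate > 0 and rng.random() < guess_rate:
            shown = {l for l in letters if l is not None}  # noqa: E741
            pool = [a for a in alphabet if a not in shown and a not in reported]
            reported += pool[rng.integers(len(pool))]
        trials.append(
            TrialRecord(
                participant_id=participant_id,
                block=1 + t_idx // design.trials_per_block,
                trial=1 + t_idx,
                display=display,
                letters=tuple(letters),
                reported=reported,
            )
        )
    return trials


def generate_cpt_session(
    d_prime_half1: float,
    d_prime_half2: float,
    criterion: float = 1.0,
    rt_model: Optional[LognormalRT] = None,
    design: Optional[CPTDesign] = None,
    seed: int | np.random.Generator = 0,
) -> list[CPTTrial]:
    """Simulate one CPT session from an equal-variance Gaussian SDT observer.

    Target evidence ~ N(d'_half, 1), distractor evidence ~ N(0, 1); the
    observer responds when evidence exceeds ``criterion``.  Response times
    come from the truncated-lognormal model.  Distractor subtypes are
    balanced.
    """
    if d_prime_half1 < 0 or d_prime_half2 < 0:
        raise ValueError("d' values must be >= 0")
    if design is None:
        design = CPTDesign.sa()
    if rt_model is None:
        rt_model = LognormalRT()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = design.n_trials
    is_target = np.zeros(n, dtype=bool)
    is_target[rng.permutation(n)[: design.n_targets]] = True
    # balanced subtype cycle, shuffled over distractor slots
    n_d = design.n_distractors
    subtype_cycle = (DISTRACTOR_SUBTYPES * (n_d // len(DISTRACTOR_SUBTYPES) + 1))[:n_d]
    subtypes = list(np.array(subtype_cycle)[rng.permutation(n_d)])
    half = n // 2
    d_by_trial = np.where(np.arange(n) < half, d_prime_half1, d_prime_half2)
    evidence = rng.normal(0.0, 1.0, size=n) + np.where(is_target, d_by_trial, 0.0)
    responded = evidence > criterion
    rts = rt_model.draw(int(responded.sum()), rng)
    trials: list[CPTTrial] = []
    ri = 0
    di = 0
    for i in range(n):
        rt = float(rts[ri]) if responded[i] else None
        if responded[i]:
            ri += 1
        sub = None
        if not is_target[i]:
            sub = subtypes[di]
            di += 1
        trials.append(
            CPTTrial(
                index=i + 1,
                stimulus="target" if is_target[i] else "distractor",
                responded=bool(responded[i]),
                rt_ms=rt,
                subtype=sub,
            )
        )
    return trials


# ---------------------------------------------------------------------------
# Cohorts with genotype structure
# ---------------------------------------------------------------------------

COMT_GROUPS = ("Val/Val", "Val/Met", "Met/Met")  # Val dose 2, 1, 0
DBH_GROUPS = ("A/A", "G/A", "G/G")  # G dose 0, 1, 2

COMT_VAL_DOSE = {"Val/Val": 2, "Val/Met": 1, "Met/Met": 0}
DBH_G_DOSE = {"A/A": 0, "G/A": 1, "G/G": 2}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort structure, base parameters, genotype effects and noise SDs.

    Group sizes default to the studied cohort (DBH A/A 42, G/A 36, G/G 47;
    COMT Val/Val 42, Val/Met 40, Met/Met 43; n = 125 total, genotypes paired
    by an independent seeded shuffle).  Effects are additive on the natural
    scale and clipped to the parameter bounds; all effect defaults are zero
    (a null cohort).
    """

    comt_sizes: tuple[int, int, int] = (42, 40, 43)  # Val/Val, Val/Met, Met/Met
    dbh_sizes: tuple[int, int, int] = (42, 36, 47)  # A/A, G/A, G/G
    # base attentional parameters
    base_expected_K: float = 3.5
    base_C: float = 50.0
    base_t0: float = 16.0
    base_w_index: float = 0.5
    base_alpha: float = 0.4
    # base CPT observer
    base_d_prime: float = 2.0
    criterion: float = 1.0
    # genotype effects (additive deltas; defaults = null cohort)
    t0_per_val_allele_ms: float = 0.0
    dbh_het_dprime_gain_pct: float = 0.0  # half-2 d' gain (%) for G/A carriers
    # between-subject SDs
    sd_expected_K: float = 0.5
    sd_C: float = 8.0
    sd_t0: float = 8.0
    sd_w_index: float = 0.03
    sd_alpha: float = 0.10
    sd_d_prime: float = 0.25
    guess_rate: float = 0.05
    master_seed: int = 0

    @property
    def n_participants(self) -> int:
        n = sum(self.comt_sizes)
        if n != sum(self.dbh_sizes):
            raise ValueError("COMT and DBH group sizes must total equally")
        return n

    @classmethod
    def with_effects(cls, **kw) -> "CohortConfig":
        """The injected-effect scenario: a linear Val-dose decrease in t0 and
        a heterozygote-advantage gain in second-half sensitivity."""
        kw.setdefault("t0_per_val_allele_ms", -2.5)
        kw.setdefault("dbh_het_dprime_gain_pct", 20.0)
        return cls(**kw)


@dataclass(frozen=True)
class Participant:
    """One simulated participant: genotypes, generating parameters, seeds."""

    participant_id: str
    comt_group: str
    dbh_group: str
    tva_params: TVAParams
    d_prime_half1: float
    d_prime_half2: float
    criterion: float
    seed: int

    @property
    def comt_dose(self) -> int:
        return COMT_VAL_DOSE[self.comt_group]

    @property
    def dbh_dose(self) -> int:
        return DBH_G_DOSE[self.dbh_group]


@dataclass
class Cohort:
    """A generated cohort: participants, their sessions, and the truth table."""

    config: CohortConfig
    participants: list[Participant]
    combitva: dict[str, list[TrialRecord]]
    cpt_sa: dict[str, list[CPTTrial]]
    cpt_gng: dict[str, list[CPTTrial]]

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            rows.append(
                dict(
                    participant_id=p.participant_id,
                    comt_group=p.comt_group,
                    comt_dose=p.comt_dose,
                    dbh_group=p.dbh_group,
                    dbh_dose=p.dbh_dose,
                    expected_K=p.tva_params.expected_K,
                    C=p.tva_params.C,
                    t0=p.tva_params.t0,
                    w_index=p.tva_params.w_index,
                    alpha=p.tva_params.alpha,
                    d_prime_half1=p.d_prime_half1,
                    d_prime_half2=p.d_prime_half2,
                    criterion=p.criterion,
                    seed=p.seed,
                )
            )
        return pd.DataFrame(rows)

    def measure_table(self) -> pd.DataFrame:
        """Per-participant row of the 8 attention measures + genotype codes.

        CPT-derived measures (d'-change, RT-SD, FA rate) are computed from
        the generated sessions with :mod:`pytva.cpt`; the attentional
        parameters are taken from the generating truth (their estimation
        error is covered separately by the fit's recovery suite).
        """
        rows = []
        for p in self.participants:
            sa = self.cpt_sa.get(p.participant_id)
            gng = self.cpt_gng.get(p.participant_id)
            row = dict(
                participant_id=p.participant_id,
                comt_dose=p.comt_dose,
                dbh_code=p.dbh_group,
                dbh_dose=p.dbh_dose,
                d_change=float("nan"),
                rt_sd=float("nan"),
                fa_rate=float("nan"),
                d_prime_half1=float("nan"),
                d_prime_half2=float("nan"),
                vstm_K=p.tva_params.expected_K,
                t0=p.tva_params.t0,
                C=p.tva_params.C,
                alpha=p.tva_params.alpha,
                w_index=p.tva_params.w_index,
            )
            if sa is not None:
                halves = cpt_mod._split_halves(sa)
                row["d_change"] = cpt_mod.d_prime_change(sa)
                row["rt_sd"] = cpt_mod.rt_sd(sa)
                row["d_prime_half1"] = cpt_mod.d_prime(
                    cpt_mod.classify_responses(halves[0])
                )
                row["d_prime_half2"] = cpt_mod.d_prime(
                    cpt_mod.classify_responses(halves[1])
                )
            if gng is not None:
                row["fa_rate"] = cpt_mod.false_alarm_rate(gng)
            rows.append(row)
        return pd.DataFrame(rows)


def _clip(x: float, lo: float, hi: float) -> float:
    return float(min(max(x, lo), hi))


def generate_cohort(
    config: Optional[CohortConfig] = None,
    tasks: Sequence[str] = ("combitva", "cpt_sa", "cpt_gng"),
) -> Cohort:
    """Generate a full cohort: genotypes, per-participant parameters, sessions.

    Individual parameters = base + genotype deltas + between-subject Gaussian
    noise, clipped to bounds.  Child seeds derive deterministically from the
    master seed, so the same configuration is byte-identical on re-run.
    ``tasks`` restricts which sessions are generated (the statistical-stage
    simulation suites only need the CPT streams).
    """
    if config is None:
        config = CohortConfig()
    n = config.n_participants
    rng = np.random.default_rng(config.master_seed)
    comt_labels = [
        g for g, size in zip(COMT_GROUPS, config.comt_sizes) for _ in range(size)
    ]
    dbh_labels = [
        g for g, size in zip(DBH_GROUPS, config.dbh_sizes) for _ in range(size)
    ]
    dbh_labels = list(np.array(dbh_labels)[rng.permutation(n)])
    participants: list[Participant] = []
    combitva: dict[str, list[TrialRecord]] = {}
    cpt_sa: dict[str, list[CPTTrial]] = {}
    cpt_gng: dict[str, list[CPTTrial]] = {}
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    for i in range(n):
        pid = f"P{i:03d}"
        comt, dbh = comt_labels[i], dbh_labels[i]
        prng = np.random.default_rng(int(child_seeds[i]))
        ek = _clip(config.base_expected_K + prng.normal(0, config.sd_expected_K), 1.0, 6.0)
        C = max(config.base_C + prng.normal(0, config.sd_C), 5.0)
        t0 = _clip(
            config.base_t0
            + COMT_VAL_DOSE[comt] * config.t0_per_val_allele_ms
            + prng.normal(0, config.sd_t0),
            0.0,
            100.0,
        )
        w = _clip(config.base_w_index + prng.normal(0, config.sd_w_index), 0.02, 0.98)
        alpha = _clip(config.base_alpha + prng.normal(0, config.sd_alpha), 0.0, 1.0)
        params = TVAParams.from_expected_K(ek, C, t0, w, alpha)
        d1 = max(config.base_d_prime + prng.normal(0, config.sd_d_prime), 0.2)
        gain = config.dbh_het_dprime_gain_pct if dbh == "G/A" else 0.0
        d2 = max(d1 * (1.0 + gain / 100.0), 0.0)
        p = Participant(
            participant_id=pid,
            comt_group=comt,
            dbh_group=dbh,
            tva_params=params,
            d_prime_half1=d1,
            d_prime_half2=d2,
            criterion=config.criterion,
            seed=int(child_seeds[i]),
        )
        participants.append(p)
        if "combitva" in tasks:
            combitva[pid] = generate_combitva_session(
                params,
                guess_rate=config.guess_rate,
                seed=np.random.default_rng(int(child_seeds[i]) ^ 0x1),
                participant_id=pid,
            )
        if "cpt_sa" in tasks:
            cpt_sa[pid] = generate_cpt_session(
                d1, d2, p.criterion,
                design=CPTDesign.sa(),
                seed=np.random.default_rng(int(child_seeds[i]) ^ 0x2),
            )
        if "cpt_gng" in tasks:
            cpt_gng[pid] = generate_cpt_session(
                d1, d2, p.criterion,
                design=CPTDesign.gng(),
                seed=np.random.default_rng(int(child_seeds[i]) ^ 0x3),
            )
    return Cohort(
        config=config,
        participants=participants,
        combitva=combitva,
        cpt_sa=cpt_sa,
        cpt_gng=cpt_gng,
    )
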