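"""Capacity-limited exponential race model of visual attention (TVA).

Visual items race in parallel for encoding into a visual short-term memory
(VSTM) store that can hold at most ``K`` items.  Each displayed item ``x``
finishes at an independent exponential time with rate

    v_x = C * w_x / sum_z w_z,

where ``C`` is the total processing rate (letters/second) and the attentional
weights ``w`` encode spatial bias (``w_index``, the left-hemifield share of
the total weight) and top-down selectivity (``alpha``, the distractor-to-
target weight ratio).  Items encoded on a trial are the first
``min(K, #finishers)`` items to finish within the effective exposure
``max(0, duration - t0)``, where ``t0`` is the perceptual threshold below
which nothing is encoded.  ``K`` itself varies from trial to trial with a
probability distribution ``pK`` over {1, ..., 6}.

This module computes the exact probability distribution over encoded item
sets and over report scores, and provides a seeded Monte-Carlo race
simulator used as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ALPHABET",
    "EXPOSURES_MS",
    "K_VALUES",
    "TVAParams",
    "DisplaySpec",
    "TrialRecord",
    "EncodingDistribution",
    "InvalidParameterError",
    "DegenerateDisplayError",
    "effective_exposure",
    "attentional_weights",
    "processing_rates",
    "spatial_bias_index",
    "selectivity_index",
    "encoding_set_distribution",
    "score_distribution",
    "simulate_race",
    "simulate_races",
]

#: The 20-letter CombiTVA stimulus alphabet.
ALPHABET = "ABDEFGHJKLMNOPRSTVXZ"

#: Exposure durations (ms) used by the CombiTVA design.
EXPOSURES_MS = (10, 20, 50, 80, 140, 200)

#: Support of the trial-to-trial VSTM capacity distribution.
K_VALUES = (1, 2, 3, 4, 5, 6)

N_POSITIONS = 6

DISPLAY_TYPES = ("WR2", "WR6", "PR")


class InvalidParameterError(ValueError):
    """A model parameter is outside its admissible range."""


class DegenerateDisplayError(ValueError):
    """A display carries zero total attentional weight (nothing can race)."""


@dataclass(frozen=True)
class TVAParams:
    """The five fitted attentional parameters (9 free degrees of freedom).

    Parameters
    ----------
    pK : tuple of 6 floats
        Probability that VSTM capacity equals 1..6 on a given trial
        (5 free df; must sum to 1).
    C : float
        Total processing rate, letters/second (> 0).
    t0 : float
        Perceptual threshold, ms (within ``t0_bounds``).
    w_index : float
        Left-hemifield share of the total attentional weight, in [0, 1];
        0.5 means symmetric weighting.
    alpha : float
        Distractor-to-target weight ratio, in [0, alpha_max];
        0 means perfect top-down selectivity.
    """

    pK: tuple[float, ...]
    C: float
    t0: float
    w_index: float
    alpha: float
    t0_bounds: tuple[float, float] = (0.0, 100.0)
    alpha_max: float = 1.0

    def __post_init__(self) -> None:
        pK = tuple(float(p) for p in self.pK)
        if len(pK) != len(K_VALUES):
            raise InvalidParameterError(
                f"pK must have {len(K_VALUES)} entries, got {len(pK)}"
            )
        if min(pK) < -1e-12:
            raise InvalidParameterError(f"pK entries must be >= 0, got {pK}")
        if abs(sum(pK) - 1.0) > 1e-9:
            raise InvalidParameterError(f"pK must sum to 1, got {sum(pK)!r}")
        object.__setattr__(self, "pK", pK)
        if not self.C > 0:
            raise InvalidParameterError(f"C must be > 0, got {self.C}")
        lo, hi = self.t0_bounds
        if not (lo - 1e-9 <= self.t0 <= hi + 1e-9):
            raise InvalidParameterError(
                f"t0={self.t0} outside bounds [{lo}, {hi}]"
            )
        if not (0.0 <= self.w_index <= 1.0):
            raise InvalidParameterError(f"w_index must be in [0,1], got {self.w_index}")
        if not (0.0 <= self.alpha <= self.alpha_max + 1e-12):
            raise InvalidParameterError(
                f"alpha must be in [0, {self.alpha_max}], got {self.alpha}"
            )

    @property
    def expected_K(self) -> float:
        """E[K] = sum_k k * pK(k), in letters."""
        return float(np.dot(K_VALUES, self.pK))

    @staticmethod
    def n_free_parameters() -> int:
        """Free degrees of freedom of the fitted model: 5 (pK) + C + t0 + w_index + alpha."""
        return (len(K_VALUES) - 1) + 4

    @classmethod
    def from_expected_K(
        cls,
        expected_K: float,
        C: float,
        t0: float,
        w_index: float,
        alpha: float,
        **kw,
    ) -> "TVAParams":
        """Build params with a binomial-shaped pK whose mean is ``expected_K``.

        ``K = 1 + Binomial(5, (expected_K - 1)/5)`` keeps support on {1..6}
        with the requested mean; a convenient one-parameter family for
        simulation defaults.
        """
        from scipy.stats import binom

        if not (1.0 <= expected_K <= 6.0):
            raise InvalidParameterError("expected_K must be in [1, 6]")
        p = (expected_K - 1.0) / 5.0
        pK = tuple(float(binom.pmf(k - 1, 5, p)) for k in K_VALUES)
        s = sum(pK)
        pK = tuple(x / s for x in pK)
        return cls(pK=pK, C=C, t0=t0, w_index=w_index, alpha=alpha, **kw)


@dataclass(frozen=True)
class DisplaySpec:
    """Geometry of one CombiTVA display plus its exposure duration.

    Six placeholders on an invisible circle, three per hemifield.  Roles per
    slot are 'T' (red target), 'D' (blue distractor) or 'E' (empty).
    """

    display_type: str
    exposure_ms: float
    roles: tuple[str, ...]
    sides: tuple[str, ...] = ("L", "L", "L", "R", "R", "R")

    def __post_init__(self) -> None:
        if self.display_type not in DISPLAY_TYPES:
            raise ValueError(f"unknown display type {self.display_type!r}")
        if len(self.roles) != N_POSITIONS or len(self.sides) != N_POSITIONS:
            raise ValueError("displays have exactly six placeholder slots")
        if any(r not in "TDE" for r in self.roles):
            raise ValueError(f"roles must be T/D/E, got {self.roles}")
        if self.sides.count("L") != 3 or self.sides.count("R") != 3:
            raise ValueError("exactly three placeholders per hemifield")
        if self.exposure_ms < 0:
            raise ValueError("exposure duration must be >= 0")
        n_t = self.roles.count("T")
        n_d = self.roles.count("D")
        expect = {"WR6": (6, 0), "WR2": (2, 0), "PR": (2, 4)}[self.display_type]
        if (n_t, n_d) != expect:
            raise ValueError(
                f"{self.display_type} requires {expect[0]} targets and "
                f"{expect[1]} distractors, got ({n_t}, {n_d})"
            )

    @property
    def n_targets(self) -> int:
        return self.roles.count("T")

    @property
    def displayed(self) -> tuple[int, ...]:
        """Indices of non-empty slots."""
        return tuple(i for i, r in enumerate(self.roles) if r != "E")

    @classmethod
    def whole_report_6(cls, exposure_ms: float) -> "DisplaySpec":
        return cls("WR6", exposure_ms, ("T",) * 6)

    @classmethod
    def whole_report_2(cls, exposure_ms: float) -> "DisplaySpec":
        # one target per hemifield (balanced default placement)
        return cls("WR2", exposure_ms, ("T", "E", "E", "T", "E", "E"))

    @classmethod
    def partial_report(cls, exposure_ms: float) -> "DisplaySpec":
        return cls("PR", exposure_ms, ("T", "D", "D", "T", "D", "D"))

    @classmethod
    def of_type(cls, display_type: str, exposure_ms: float) -> "DisplaySpec":
        return {
            "WR6": cls.whole_report_6,
            "WR2": cls.whole_report_2,
            "PR": cls.partial_report,
        }[display_type](exposure_ms)


@dataclass(frozen=True)
class TrialRecord:
    """One CombiTVA trial: the display, the letters shown, and the report."""

    participant_id: str
    block: int
    trial: int
    display: DisplaySpec
    letters: tuple[Optional[str], ...]  # per slot; None for empty slots
    reported: str

    @property
    def target_letters(self) -> tuple[str, ...]:
        return tuple(
            l  # noqa: E741
            for l, r in zip(self.letters, self.display.roles)
            if r == "T" and l is not None
        )

    @property
    def n_correct(self) -> int:
        targets = set(self.target_letters)
        return len(targets.intersection(self.reported))

    def _side_targets(self, side: str) -> set[str]:
        return {
            l  # noqa: E741
            for i, l in enumerate(self.letters)  # noqa: E741
            if self.display.roles[i] == "T"
            and self.display.sides[i] == side
            and l is not None
        }

    @property
    def n_correct_left(self) -> int:
        return len(self._side_targets("L").intersection(self.reported))

    @property
    def n_correct_right(self) -> int:
        return len(self._side_targets("R").intersection(self.reported))


def effective_exposure(duration_ms: float, t0_ms: float) -> float:
    """Effective exposure in seconds: max(0, duration - t0) / 1000.

    Exposures at or below the perceptual threshold yield zero effective
    exposure — nothing can be encoded.
    """
    if duration_ms < 0:
        raise InvalidParameterError(f"negative exposure duration {duration_ms}")
    return max(0.0, duration_ms - t0_ms) / 1000.0


def attentional_weights(
    display: DisplaySpec, w_index: float, alpha: float
) -> np.ndarray:
    """Per-slot attentional weights for a display.

    The left hemifield carries a total weight share ``w_index`` and the right
    ``1 - w_index``, split equally among the displayed items of that side;
    distractors are further down-weighted by ``alpha``.  Empty slots get 0.
    Only ratios matter downstream.  An all-zero weight vector (possible when
    a side holds no items or alpha = 0 removes everything) is returned as is
    and flagged by :func:`processing_rates`.
    """
    if not (0.0 <= w_index <= 1.0):
        raise InvalidParameterError(f"w_index must be in [0,1], got {w_index}")
    if alpha < 0:
        raise InvalidParameterError(f"alpha must be >= 0, got {alpha}")
    w = np.zeros(N_POSITIONS)
    for side, share in (("L", w_index), ("R", 1.0 - w_index)):
        idx = [
            i
            for i in range(N_POSITIONS)
            if display.sides[i] == side and display.roles[i] != "E"
        ]
        if not idx:
            continue
        for i in idx:
            role_factor = 1.0 if display.roles[i] == "T" else alpha
            w[i] = (share / len(idx)) * role_factor
    return w


def spatial_bias_index(display: DisplaySpec, weights: np.ndarray) -> float:
    """Left-to-total weight ratio recomputed over the display's targets."""
    left = sum(
        weights[i]
        for i in range(N_POSITIONS)
        if display.roles[i] == "T" and display.sides[i] == "L"
    )
    total = sum(weights[i] for i in range(N_POSITIONS) if display.roles[i] == "T")
    if total == 0:
        raise DegenerateDisplayError("no target weight; spatial bias undefined")
    return float(left / total)


def selectivity_index(display: DisplaySpec, weights: np.ndarray) -> float:
    """Mean-distractor to mean-target weight ratio (alpha) recomputed from weights."""
    t_idx = [i for i in range(N_POSITIONS) if display.roles[i] == "T"]
    d_idx = [i for i in range(N_POSITIONS) if display.roles[i] == "D"]
    if not t_idx or not d_idx:
        raise ValueError("selectivity requires both targets and distractors")
    mean_t = float(np.mean([weights[i] for i in t_idx]))
    mean_d = float(np.mean([weights[i] for i in d_idx]))
    if mean_t == 0:
        raise DegenerateDisplayError("zero target weight; selectivity undefined")
    return mean_d / mean_t


def processing_rates(weights: np.ndarray, C: float) -> np.ndarray:
    """Race rates v_x = C * w_x / sum(w); the rates sum to C."""
    if C <= 0:
        raise InvalidParameterError(f"C must be > 0, got {C}")
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise DegenerateDisplayError("all attentional weights are zero")
    return C * w / total


# ---------------------------------------------------------------------------
# Exact set probabilities for the capacity-limited race
# ---------------------------------------------------------------------------
#
# For items with rates v and capacity k, the encoded set after effective
# exposure tau is the first min(k, #finishers) finishers.  Two event classes:
#
#   |S| < k : exactly the items of S finish by tau
#             P = prod_{x in S}(1 - e^{-v_x tau}) prod_{y not in S} e^{-v_y tau}
#   |S| = k : the first k finishers are S and the k-th finishes by tau.
#             Conditioning on the minimum U ~ Exp(R_out) of the outside items
#             and expanding the CDF of max_S by inclusion-exclusion gives the
#             closed form
#             P = sum_{non-empty B subseteq S} (-1)^{|B|+1}
#                 V_B/(V_B + R_out) (1 - e^{-(V_B + R_out) tau}),
#             with V_B = sum_{x in B} v_x and R_out = sum_{y not in S} v_y.
#
# The two classes partition the outcome space, so the probabilities sum to 1.


@lru_cache(maxsize=16)
def _subset_structure(n: int):
    """Bitmask machinery for n racing items (n <= 8 is plenty here)."""
    n_sets = 1 << n
    masks = np.zeros((n_sets, n), dtype=bool)
    for s in range(n_sets):
        for i in range(n):
            masks[s, i] = bool(s >> i & 1)
    sizes = masks.sum(axis=1)
    # (S, B) pairs with non-empty B a subset of S, for the boundary formula
    s_idx, b_masks, signs = [], [], []
    for s in range(n_sets):
        sub = s
        while sub:
            s_idx.append(s)
            b_masks.append([bool(sub >> i & 1) for i in range(n)])
            signs.append(-1.0 if bin(sub).count("1") % 2 == 0 else 1.0)
            sub = (sub - 1) & s
    s_idx = np.array(s_idx, dtype=np.intp)
    b_masks = np.array(b_masks, dtype=bool)
    signs = np.array(signs)
    seg = np.zeros((n_sets, len(s_idx)))
    seg[s_idx, np.arange(len(s_idx))] = 1.0
    return masks, sizes, s_idx, b_masks, signs, seg


def _race_components(rates: np.ndarray, taus: np.ndarray):
    """P_all[S, t] and boundary T[S, t] for all subsets of the rate vector.

    P_all is the probability that exactly S finishes by tau; T is the
    probability that the first |S| finishers are S with the last by tau.
    """
    rates = np.asarray(rates, dtype=float)
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    n = len(rates)
    masks, sizes, s_idx, b_masks, signs, seg = _subset_structure(n)
    q = np.exp(-np.outer(rates, taus))  # (n, T): P(item not finished)
    p = 1.0 - q
    n_sets = 1 << n
    p_all = np.ones((n_sets, len(taus)))
    for i in range(n):
        p_all *= np.where(masks[:, i, None], p[i], q[i])
    v_s = masks @ rates
    r_out = rates.sum() - v_s
    v_b = b_masks @ rates
    rs = v_b + r_out[s_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.where(rs > 0, v_b / np.where(rs > 0, rs, 1.0), 0.0)
    terms = (signs * coef)[:, None] * (1.0 - np.exp(-np.outer(rs, taus)))
    boundary = seg @ terms
    return p_all, boundary, sizes


def _capacity_set_probs(rates: np.ndarray, k: int, taus) -> np.ndarray:
    """Exact P(encoded set = S) over all 2^n subsets, for capacity k."""
    p_all, boundary, sizes = _race_components(rates, np.atleast_1d(taus))
    below = (sizes < k)[:, None] * p_all
    at = (sizes == k)[:, None] * boundary
    return below + at


@dataclass(frozen=True)
class EncodingDistribution:
    """Exact probability of each encoded item subset for one display/exposure.

    ``items`` are the racing items' indices (display slots); ``probs`` is
    indexed by bitmask over positions *within* ``items``.
    """

    items: tuple[int, ...]
    probs: np.ndarray = field(repr=False)

    def prob(self, subset: Iterable[int]) -> float:
        subset = set(subset)
        if not subset.issubset(self.items):
            return 0.0
        mask = 0
        for j, item in enumerate(self.items):
            if item in subset:
                mask |= 1 << j
        return float(self.probs[mask])

    def as_dict(self) -> Mapping[frozenset, float]:
        out = {}
        for mask in range(len(self.probs)):
            s = frozenset(
                self.items[j] for j in range(len(self.items)) if mask >> j & 1
            )
            out[s] = float(self.probs[mask])
        return out

    def total(self) -> float:
        return float(self.probs.sum())


def encoding_set_distribution(
    rates: Sequence[float],
    pK: Sequence[float],
    tau_eff_seconds: float,
    items: Optional[Sequence[int]] = None,
) -> EncodingDistribution:
    """Exact encoded-set distribution, mixed over the capacity distribution pK.

    ``rates`` are per-item race rates (items/second); zero-rate items can
    never be encoded and are excluded exactly.  ``tau_eff_seconds = 0`` puts
    all mass on the empty set.
    """
    rates = np.asarray(rates, dtype=float)
    if tau_eff_seconds < 0:
        raise InvalidParameterError("effective exposure must be >= 0")
    if np.any(rates < 0):
        raise InvalidParameterError("rates must be >= 0")
    pK = np.asarray(pK, dtype=float)
    if items is None:
        items = tuple(range(len(rates)))
    items = tuple(items)
    active = np.flatnonzero(rates > 0)
    n_all = len(rates)
    probs_all = np.zeros(1 << n_all)
    if len(active) == 0 or tau_eff_seconds == 0.0:
        probs_all[0] = 1.0
        return EncodingDistribution(items=items, probs=probs_all)
    sub_rates = rates[active]
    mix = np.zeros(1 << len(active))
    for k, pk in zip(K_VALUES, pK):
        if pk == 0.0:
            continue
        mix += pk * _capacity_set_probs(sub_rates, k, tau_eff_seconds)[:, 0]
    # embed the active-item subsets back into the full item index space
    for mask in range(len(mix)):
        full = 0
        for j, i in enumerate(active):
            if mask >> j & 1:
                full |= 1 << int(i)
        probs_all[full] = mix[mask]
    return EncodingDistribution(items=items, probs=probs_all)


def score_distribution(params: TVAParams, display: DisplaySpec) -> np.ndarray:
    """Exact P(#correctly reportable targets = j), j = 0..T, for one display.

    Distractors occupy VSTM capacity when encoded but are never reported;
    the score counts encoded targets only.
    """
    tau = effective_exposure(display.exposure_ms, params.t0)
    targets = display.n_targets
    weights = attentional_weights(display, params.w_index, params.alpha)
    disp = list(display.displayed)
    w = weights[disp]
    if w.sum() <= 0:
        raise DegenerateDisplayError("display carries zero attentional weight")
    rates = processing_rates(w, params.C)
    out = np.zeros(targets + 1)
    if tau == 0.0:
        out[0] = 1.0
        return out
    active = np.flatnonzero(rates > 0)
    if len(active) == 0:
        out[0] = 1.0
        return out
    sub_rates = rates[active]
    target_flags = np.array([display.roles[disp[i]] == "T" for i in active])
    masks, _, _, _, _, _ = _subset_structure(len(active))
    scores = masks @ target_flags.astype(int)
    for k, pk in zip(K_VALUES, params.pK):
        if pk == 0.0:
            continue
        set_probs = _capacity_set_probs(sub_rates, k, tau)[:, 0]
        np.add.at(out, scores, pk * set_probs)
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo race oracle
# ---------------------------------------------------------------------------


def simulate_races(
    rates: Sequence[float],
    k: int,
    tau_eff_seconds: float,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised race draws; returns encoded-set bitmasks, shape (n_draws,).

    Each item finishes at an independent Exp(rate) time (never, for rate 0);
    the encoded set is the first min(k, #finishers-by-tau) finishers.
    """
    rates = np.asarray(rates, dtype=float)
    n = len(rates)
    times = np.full((n_draws, n), np.inf)
    pos = rates > 0
    if pos.any():
        times[:, pos] = rng.exponential(1.0 / rates[pos], size=(n_draws, int(pos.sum())))
    order = np.argsort(times, axis=1)
    sorted_times = np.take_along_axis(times, order, axis=1)
    finished = sorted_times <= tau_eff_seconds
    take = np.minimum(finished.sum(axis=1), k)
    ranks = np.arange(n)[None, :]
    chosen = ranks < take[:, None]
    masks = np.zeros(n_draws, dtype=np.int64)
    sel = np.where(chosen, order, -1)
    for j in range(n):
        col = sel[:, j]
        valid = col >= 0
        masks[valid] |= np.int64(1) << col[valid].astype(np.int64)
    return masks


def simulate_race(
    rates: Sequence[float],
    k: int,
    tau_eff_seconds: float,
    seed_or_rng,
) -> frozenset:
    """One seeded race draw; returns the encoded item-index set."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    mask = int(simulate_races(rates, k, tau_eff_seconds, 1, rng)[0])
    return frozenset(i for i in range(len(rates)) if mask >> i & 1)
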