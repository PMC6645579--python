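"""Maximum-likelihood estimation of the 9-df attentional model.

The likelihood of a CombiTVA session factorises over trials; because every
trial of a given (display type, exposure) condition shares one display
geometry, the per-condition counts of the report score are a sufficient
statistic.  The score is kept resolved by hemifield — the joint
(#correct-left, #correct-right) — because the total-score distribution of a
left/right-balanced display is invariant under mirroring the spatial bias
(w_index vs 1 - w_index), which would leave w_index unidentified.  The fit
minimises the multinomial negative log-likelihood of those counts over an
unconstrained
reparameterisation of the 9 free degrees of freedom (softmax for the
capacity distribution pK on the simplex, log for C, scaled logits for t0,
w_index and alpha within their bounds), from a deterministic multi-start
grid.

Goodness of fit follows the usual report for this paradigm: per-participant
RMSE over the 18 condition means, the Pearson correlation between observed
and predicted mean scores, and its square (``r_squared``); the
variance-accounted-for variant 1 - SS_res/SS_tot is exposed alongside as
``r_squared_vaf``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .core import (
    ALPHABET,
    DisplaySpec,
    InvalidParameterError,
    K_VALUES,
    TVAParams,
    TrialRecord,
    _race_components,
    _subset_structure,
    attentional_weights,
    processing_rates,
)

__all__ = [
    "ScoreCountTable",
    "FitConfig",
    "FitResult",
    "aggregate_counts",
    "negative_log_likelihood",
    "fit_participant",
    "predicted_mean_scores",
    "observed_mean_scores",
    "goodness_of_fit",
    "expected_K",
]

PROB_FLOOR = 1e-12


def expected_K(pK: Sequence[float]) -> float:
    """E[K] = sum_k k * pK(k) over the capacity support {1..6}."""
    pK = np.asarray(pK, dtype=float)
    if len(pK) != len(K_VALUES) or np.any(pK < -1e-12) or abs(pK.sum() - 1) > 1e-9:
        raise InvalidParameterError("pK must be a length-6 probability vector")
    return float(np.dot(K_VALUES, pK))


def _side_target_counts(display_type: str) -> tuple[int, int]:
    d = DisplaySpec.of_type(display_type, 0.0)
    tl = sum(1 for r, s in zip(d.roles, d.sides) if r == "T" and s == "L")
    tr = sum(1 for r, s in zip(d.roles, d.sides) if r == "T" and s == "R")
    return tl, tr


@dataclass
class ScoreCountTable:
    """Counts of trials per (display_type, exposure_ms) cell, resolved by
    the joint (#correct-left, #correct-right) score.

    ``counts[(type, duration)]`` is a matrix of shape (TL+1, TR+1) with TL
    and TR the target counts per hemifield; the total-score marginal is
    available via :meth:`score_marginal`.
    """

    counts: dict[tuple[str, float], np.ndarray] = field(default_factory=dict)

    def add(
        self, display_type: str, exposure_ms: float, n_left: int, n_right: int
    ) -> None:
        tl, tr = _side_target_counts(display_type)
        key = (display_type, float(exposure_ms))
        if key not in self.counts:
            self.counts[key] = np.zeros((tl + 1, tr + 1), dtype=np.int64)
        self.counts[key][min(n_left, tl), min(n_right, tr)] += 1

    def score_marginal(self, key: tuple[str, float]) -> np.ndarray:
        """Counts of the total score 0..T for one condition cell."""
        mat = self.counts[key]
        tl, tr = mat.shape[0] - 1, mat.shape[1] - 1
        out = np.zeros(tl + tr + 1, dtype=np.int64)
        for jl in range(tl + 1):
            for jr in range(tr + 1):
                out[jl + jr] += mat[jl, jr]
        return out

    def scale(self, factor: int) -> "ScoreCountTable":
        return ScoreCountTable({k: v * factor for k, v in self.counts.items()})

    @property
    def n_trials(self) -> int:
        return int(sum(v.sum() for v in self.counts.values()))

    def conditions(self) -> list[tuple[str, float]]:
        return sorted(self.counts.keys())


def aggregate_counts(trials: Iterable[TrialRecord]) -> ScoreCountTable:
    """Tabulate per-hemifield correct-report counts per condition cell.

    A trial's correct reports are the intersection of the reported letters
    with the displayed target letters (clipped at the per-side target
    count); aggregation is invariant to trial order.
    """
    table = ScoreCountTable()
    for t in trials:
        for ch in t.reported:
            if ch not in ALPHABET:
                raise ValueError(
                    f"reported letter {ch!r} outside the session alphabet"
                )
        table.add(
            t.display.display_type,
            t.display.exposure_ms,
            t.n_correct_left,
            t.n_correct_right,
        )
    return table


class _LikelihoodMachine:
    """Precompiled per-display-type structures for fast NLL evaluation.

    For each display type present in the data this caches the subset bitmask
    machinery and, for every capacity k, the (score x subset) indicator
    matrices splitting the below-capacity and at-capacity event classes, so
    one NLL evaluation is a handful of small matrix products.
    """

    def __init__(self, table: ScoreCountTable):
        self.blocks = []
        by_type: dict[str, list[tuple[float, np.ndarray]]] = {}
        for (dtype, dur), counts in sorted(table.counts.items()):
            by_type.setdefault(dtype, []).append((dur, counts))
        for dtype, cells in by_type.items():
            display = DisplaySpec.of_type(dtype, cells[0][0])
            disp = list(display.displayed)
            n = len(disp)
            masks, sizes, *_ = _subset_structure(n)
            left_t = np.array(
                [display.roles[i] == "T" and display.sides[i] == "L" for i in disp],
                dtype=int,
            )
            right_t = np.array(
                [display.roles[i] == "T" and display.sides[i] == "R" for i in disp],
                dtype=int,
            )
            tl, tr = int(left_t.sum()), int(right_t.sum())
            # joint (left, right) score cell per subset, flattened row-major
            cell = (masks @ left_t) * (tr + 1) + (masks @ right_t)
            n_cells = (tl + 1) * (tr + 1)
            a_stack = np.zeros((len(K_VALUES), n_cells, 1 << n))
            b_stack = np.zeros_like(a_stack)
            for ki, k in enumerate(K_VALUES):
                for s in range(1 << n):
                    if sizes[s] < k:
                        a_stack[ki, cell[s], s] = 1.0
                    elif sizes[s] == k:
                        b_stack[ki, cell[s], s] = 1.0
            durations = np.array([c[0] for c in cells])
            count_mat = np.stack(
                [c[1].reshape(-1) for c in cells], axis=1
            )  # (n_cells, n_dur)
            self.blocks.append(
                dict(
                    display=display,
                    disp=disp,
                    durations=durations,
                    counts=count_mat,
                    a_stack=a_stack,
                    b_stack=b_stack,
                    shape=(tl + 1, tr + 1),
                )
            )

    def _cell_probs(self, blk: dict, params: TVAParams) -> np.ndarray:
        """P(joint score cell | duration) for one display type, (n_cells, n_dur)."""
        display: DisplaySpec = blk["display"]
        pK = np.asarray(params.pK)
        weights = attentional_weights(display, params.w_index, params.alpha)
        rates = processing_rates(weights[blk["disp"]], params.C)
        taus = np.maximum(0.0, blk["durations"] - params.t0) / 1000.0
        p_all, boundary, _ = _race_components(rates, taus)
        m1 = np.einsum("k,kjs->js", pK, blk["a_stack"])
        m2 = np.einsum("k,kjs->js", pK, blk["b_stack"])
        return m1 @ p_all + m2 @ boundary

    def condition_probs(
        self, params: TVAParams
    ) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """Per display type: (type, durations, P(joint cell | duration))."""
        return [
            (blk["display"].display_type, blk["durations"], self._cell_probs(blk, params))
            for blk in self.blocks
        ]

    def nll(self, params: TVAParams) -> float:
        total = 0.0
        for blk in self.blocks:
            probs = self._cell_probs(blk, params)
            total -= float(
                np.sum(blk["counts"] * np.log(np.maximum(probs, PROB_FLOOR)))
            )
        return total


def negative_log_likelihood(params: TVAParams, table: ScoreCountTable) -> float:
    """Multinomial NLL of the score counts under the race model.

    Probabilities are floored at 1e-12 inside the log so data the model
    assigns ~zero probability (e.g. guess-inflated scores) stay finite.
    """
    if not isinstance(params, TVAParams):
        raise InvalidParameterError("params must be a TVAParams instance")
    return _LikelihoodMachine(table).nll(params)


# --- unconstrained reparameterisation ---------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def _theta_to_params(theta: np.ndarray, config: "FitConfig") -> TVAParams:
    logits = np.concatenate([theta[:5], [0.0]])
    logits -= logits.max()
    e = np.exp(logits)
    pK = tuple(e / e.sum())
    C = float(np.exp(theta[5]))
    lo, hi = config.t0_bounds
    t0 = lo + (hi - lo) * float(_sigmoid(theta[6]))
    w = float(_sigmoid(theta[7]))
    alpha = config.alpha_max * float(_sigmoid(theta[8]))
    return TVAParams(
        pK=pK, C=C, t0=t0, w_index=w, alpha=alpha,
        t0_bounds=config.t0_bounds, alpha_max=config.alpha_max,
    )


def _params_to_theta(p: TVAParams, config: "FitConfig") -> np.ndarray:
    pK = np.maximum(np.asarray(p.pK), 1e-9)
    logits = np.log(pK[:5]) - np.log(pK[5])
    lo, hi = config.t0_bounds
    return np.array(
        [
            *logits,
            np.log(p.C),
            _logit((p.t0 - lo) / (hi - lo)),
            _logit(p.w_index),
            _logit(p.alpha / config.alpha_max),
        ]
    )


@dataclass(frozen=True)
class FitConfig:
    """Fitter settings: bounds, multi-start grid size, tolerances."""

    t0_bounds: tuple[float, float] = (0.0, 100.0)
    alpha_max: float = 1.0
    n_starts: int = 10
    max_evals_per_start: int = 2000
    ftol: float = 1e-8
    start_jitter_sd: float = 0.05

    def start_points(self) -> list[tuple[float, float, float, float, float]]:
        """Deterministic Latin-style grid over (E[K], C, t0, w_index, alpha)."""
        grid = [
            (3.5, 50.0, 20.0, 0.50, 0.50),
            (2.5, 30.0, 10.0, 0.50, 0.30),
            (4.5, 80.0, 30.0, 0.50, 0.70),
            (3.0, 60.0, 15.0, 0.40, 0.20),
            (4.0, 40.0, 25.0, 0.60, 0.80),
            (2.0, 70.0, 5.0, 0.50, 0.50),
            (5.0, 35.0, 40.0, 0.50, 0.40),
            (3.5, 90.0, 10.0, 0.45, 0.60),
            (2.8, 45.0, 35.0, 0.55, 0.25),
            (4.2, 55.0, 18.0, 0.50, 0.90),
        ]
        reps = -(-self.n_starts // len(grid))
        return (grid * reps)[: self.n_starts]


@dataclass(frozen=True)
class FitResult:
    """Best multi-start ML fit plus the standard diagnostics."""

    params: TVAParams
    nll: float
    converged: bool
    n_starts: int
    seed: int
    diagnostics: Mapping[str, float]

    @property
    def expected_K(self) -> float:
        return self.params.expected_K


def fit_participant(
    table: ScoreCountTable,
    config: Optional[FitConfig] = None,
    seed: int = 0,
) -> FitResult:
    """Maximum-likelihood fit of the 9-df model to one participant's counts.

    Runs L-BFGS-B from each point of a fixed start grid (small seeded jitter
    on every start after the first) and keeps the lowest NLL.  Deterministic
    given (data, config, seed).  If no start converges the best incumbent is
    still returned with ``converged=False``.
    """
    if config is None:
        config = FitConfig()
    if not table.counts:
        raise ValueError("empty score-count table")
    machine = _LikelihoodMachine(table)

    def objective(theta: np.ndarray) -> float:
        try:
            return machine.nll(_theta_to_params(theta, config))
        except (InvalidParameterError, FloatingPointError, OverflowError):
            return 1e12

    rng = np.random.default_rng(seed)
    best = None
    any_converged = False
    for i, (ek, C, t0, w, a) in enumerate(config.start_points()):
        p0 = TVAParams.from_expected_K(
            ek, C, t0, w, a, t0_bounds=config.t0_bounds, alpha_max=config.alpha_max
        )
        theta0 = _params_to_theta(p0, config)
        if i > 0 and config.start_jitter_sd > 0:
            theta0 = theta0 + rng.normal(0.0, config.start_jitter_sd, size=theta0.shape)
        res = minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            options=dict(maxfun=config.max_evals_per_start, ftol=config.ftol),
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params = _theta_to_params(best.x, config)
    obs = observed_mean_scores(table)
    pred = predicted_mean_scores(params, table.conditions())
    diag = goodness_of_fit(
        np.array([obs[c] for c in table.conditions()]),
        np.array([pred[c] for c in table.conditions()]),
    )
    return FitResult(
        params=params,
        nll=float(best.fun),
        converged=any_converged,
        n_starts=config.n_starts,
        seed=seed,
        diagnostics=diag,
    )


def predicted_mean_scores(
    params: TVAParams, conditions: Sequence[tuple[str, float]]
) -> dict[tuple[str, float], float]:
    """Model-expected mean #correct per (display type, exposure) condition."""
    from .core import score_distribution

    out = {}
    for dtype, dur in conditions:
        display = DisplaySpec.of_type(dtype, dur)
        dist = score_distribution(params, display)
        out[(dtype, float(dur))] = float(np.dot(np.arange(len(dist)), dist))
    return out


def observed_mean_scores(table: ScoreCountTable) -> dict[tuple[str, float], float]:
    """Observed mean total #correct per condition from a score-count table."""
    out = {}
    for key in table.counts:
        counts = table.score_marginal(key)
        n = counts.sum()
        if n == 0:
            raise ValueError(f"condition {key} has zero trials")
        out[key] = float(np.dot(np.arange(len(counts)), counts) / n)
    return out


def goodness_of_fit(
    observed: Sequence[float], predicted: Sequence[float]
) -> dict[str, float]:
    """RMSE over conditions, Pearson r, squared correlation, and VAF R².

    rmse = sqrt( sum_c (obs_c - pred_c)^2 / #conditions ).  ``r_squared`` is
    the squared Pearson correlation; ``r_squared_vaf`` is 1 - SS_res/SS_tot.
    Zero variance in either vector leaves the correlation undefined (NaN).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if np.std(obs) == 0 or np.std(pred) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(obs, pred)[0, 1])
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    vaf = float("nan") if ss_tot == 0 else 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot
    return {
        "rmse": rmse,
        "pearson_r": r,
        "r_squared": r * r,
        "r_squared_vaf": vaf,
    }
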