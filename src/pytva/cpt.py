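"""Signal-detection and stability indices for continuous performance tasks.

A CPT session is a stream of target/distractor trials with present/absent
responses and reaction times inside a 1 s response window.  The indices:

* d' — equal-variance SDT sensitivity, Phi^{-1}(H) - Phi^{-1}(FA), with a
  log-linear correction by default so extreme rates stay finite;
* d'-change — percentage change of d' from the first to the second half of
  the session (positive = improvement), the time-on-task index;
* RT-SD — standard deviation of hit reaction times over the whole session;
* false-alarm rate — responses to distractors / distractor trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "RESPONSE_WINDOW_MS",
    "CPTTrial",
    "SDTCounts",
    "classify_responses",
    "d_prime",
    "d_prime_change",
    "rt_sd",
    "false_alarm_rate",
    "session_metrics",
]

#: Responses later than this (ms) count as no-response.
RESPONSE_WINDOW_MS = 1000.0

DISTRACTOR_SUBTYPES = ("colour_similar", "shape_similar", "unrelated")


@dataclass(frozen=True)
class CPTTrial:
    """One CPT trial: 1-based index, stimulus class, response and RT."""

    index: int
    stimulus: str  # 'target' or 'distractor'
    responded: bool
    rt_ms: Optional[float] = None
    subtype: Optional[str] = None  # distractor subtype

    def __post_init__(self) -> None:
        if self.stimulus not in ("target", "distractor"):
            raise ValueError(f"unknown stimulus class {self.stimulus!r}")
        if self.responded and self.rt_ms is None:
            raise ValueError("a response must carry a reaction time")
        if not self.responded and self.rt_ms is not None:
            raise ValueError("rt present without a response")
        if self.rt_ms is not None and self.rt_ms <= 0:
            raise ValueError("reaction times must be positive")

    @property
    def in_window(self) -> bool:
        """True when the response fell inside the 1 s window."""
        return self.responded and self.rt_ms is not None and self.rt_ms <= RESPONSE_WINDOW_MS


@dataclass(frozen=True)
class SDTCounts:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    @property
    def n_targets(self) -> int:
        return self.hits + self.misses

    @property
    def n_distractors(self) -> int:
        return self.false_alarms + self.correct_rejections


def classify_responses(trials: Iterable[CPTTrial]) -> SDTCounts:
    """Tabulate hits/misses/false alarms/correct rejections.

    Responses after the 1,000 ms window count as no-response.
    """
    h = m = fa = cr = 0
    for t in trials:
        responded = t.in_window
        if t.stimulus == "target":
            if responded:
                h += 1
            else:
                m += 1
        else:
            if responded:
                fa += 1
            else:
                cr += 1
    return SDTCounts(h, m, fa, cr)


def _rates(counts: SDTCounts, correction: str) -> tuple[float, float]:
    if counts.n_targets == 0 or counts.n_distractors == 0:
        raise ValueError("d' requires both target and distractor trials")
    if correction == "loglinear":
        hit = (counts.hits + 0.5) / (counts.n_targets + 1.0)
        fa = (counts.false_alarms + 0.5) / (counts.n_distractors + 1.0)
    elif correction == "none":
        hit = counts.hits / counts.n_targets
        fa = counts.false_alarms / counts.n_distractors
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return hit, fa


def d_prime(counts: SDTCounts, correction: str = "loglinear") -> float:
    """Sensitivity d' = Phi^{-1}(H) - Phi^{-1}(FA).

    The default log-linear correction adds 0.5 to each count and 1 to each
    denominator, keeping d' finite at ceiling/floor rates.
    """
    hit, fa = _rates(counts, correction)
    return float(norm.ppf(hit) - norm.ppf(fa))


def _split_halves(trials: Sequence[CPTTrial]) -> tuple[list[CPTTrial], list[CPTTrial]]:
    trials = sorted(trials, key=lambda t: t.index)
    half = len(trials) // 2
    return list(trials[:half]), list(trials[half:])


def d_prime_change(
    trials: Sequence[CPTTrial], correction: str = "loglinear"
) -> float:
    """Percentage change of d' between task halves: 100 (d'_2 - d'_1)/d'_1.

    The session splits at the midpoint by trial index (90/90 in the standard
    180-trial design); positive values mean sensitivity improved over time.
    """
    if len(trials) < 2:
        raise ValueError("d'-change needs at least two trials")
    first, second = _split_halves(trials)
    d1 = d_prime(classify_responses(first), correction)
    d2 = d_prime(classify_responses(second), correction)
    if d1 == 0:
        raise ZeroDivisionError("first-half d' is zero; d'-change undefined")
    return 100.0 * (d2 - d1) / d1


def rt_sd(trials: Iterable[CPTTrial]) -> float:
    """Sample SD (ms) of hit reaction times across the whole session."""
    rts = [t.rt_ms for t in trials if t.stimulus == "target" and t.in_window]
    if len(rts) < 2:
        raise ValueError("RT-SD needs at least two hit reaction times")
    return float(np.std(rts, ddof=1))


def false_alarm_rate(trials: Iterable[CPTTrial]) -> float:
    """False alarms as a proportion of distractor trials."""
    trials = list(trials)
    n_d = sum(1 for t in trials if t.stimulus == "distractor")
    if n_d == 0:
        raise ValueError("no distractor trials; false-alarm rate undefined")
    fa = sum(1 for t in trials if t.stimulus == "distractor" and t.in_window)
    return fa / n_d


def session_metrics(
    trials: Sequence[CPTTrial], correction: str = "loglinear"
) -> dict[str, float]:
    """One session's metrics row: overall and per-half d', d'-change, RT-SD, FA rate."""
    first, second = _split_halves(trials)
    d1 = d_prime(classify_responses(first), correction)
    d2 = d_prime(classify_responses(second), correction)
    return {
        "d_prime_overall": d_prime(classify_responses(trials), correction),
        "d_prime_half1": d1,
        "d_prime_half2": d2,
        "d_change_pct": 100.0 * (d2 - d1) / d1 if d1 != 0 else float("nan"),
        "rt_sd_ms": rt_sd(trials),
        "fa_rate": false_alarm_rate(trials),
    }
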