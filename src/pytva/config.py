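"""Run configuration: every open design default in one overridable place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .fit import FitConfig

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All tunable pipeline settings with their defaults.

    Surfaces every open design choice: parameter bounds, the fitter's
    multi-start budget and tolerances, the d' extreme-rate correction, the
    t-test variance assumption, and the genotype coding.
    """

    seed: int = 0
    # bounds / model
    t0_bounds: tuple[float, float] = (0.0, 100.0)
    alpha_max: float = 1.0
    # fitter
    n_starts: int = 10
    max_evals_per_start: int = 2000
    ftol: float = 1e-8
    # generator
    guess_rate: float = 0.05
    # corrections / statistical choices
    d_prime_correction: str = "loglinear"  # or "none"
    t_test_equal_var: bool = True  # pooled by default; False = Welch
    genotype_coding: str = "dose"  # numeric allele dose 0/1/2

    def fit_config(self) -> FitConfig:
        return FitConfig(
            t0_bounds=tuple(self.t0_bounds),
            alpha_max=self.alpha_max,
            n_starts=self.n_starts,
            max_evals_per_start=self.max_evals_per_start,
            ftol=self.ftol,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["t0_bounds"] = list(d["t0_bounds"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "t0_bounds" in d:
            d = dict(d, t0_bounds=tuple(d["t0_bounds"]))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        """Stable hash of the configuration, logged with every run."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
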