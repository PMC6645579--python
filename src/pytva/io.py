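"""CSV/JSON schemas binding the pipeline stages together.

All files are plain UTF-8, comma-delimited, with a mandatory header row and
a leading ``# pytva-schema: <name> v1`` comment line.  Empty placeholder
positions use a ``.`` sentinel; indices (trial, block) are 1-based;
durations are stored in milliseconds.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import ALPHABET, DisplaySpec, TrialRecord
from .cpt import CPTTrial
from .fit import FitResult

__all__ = [
    "write_combitva_csv",
    "read_combitva_csv",
    "write_cpt_csv",
    "read_cpt_csv",
    "write_measures_csv",
    "read_measures_csv",
    "write_fit_json",
    "read_fit_json",
    "SchemaError",
]

SCHEMA_LINES = {
    "combitva": "# pytva-schema: combitva v1",
    "cpt": "# pytva-schema: cpt v1",
    "measures": "# pytva-schema: measures v1",
}

MEASURE_COLUMNS = [
    "participant_id",
    "comt_dose",
    "dbh_code",
    "dbh_dose",
    "d_change",
    "rt_sd",
    "fa_rate",
    "vstm_K",
    "t0",
    "C",
    "alpha",
    "w_index",
]


class SchemaError(ValueError):
    """A file does not satisfy its declared schema."""


def _write_with_header(df: pd.DataFrame, path: Path, schema: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(SCHEMA_LINES[schema] + "\n")
        df.to_csv(fh, index=False)


def _read_checked(path: Path, schema: str, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", keep_default_na=False, na_values=[])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing {schema} columns {missing} (header line 2)")
    return df


# --- CombiTVA trials --------------------------------------------------------


def write_combitva_csv(trials: Iterable[TrialRecord], path) -> None:
    rows = []
    for t in trials:
        row = dict(
            participant_id=t.participant_id,
            block=t.block,
            trial=t.trial,
            display_type=t.display.display_type,
            exposure_ms=t.display.exposure_ms,
        )
        for i in range(6):
            row[f"pos{i + 1}"] = t.letters[i] if t.letters[i] is not None else "."
            row[f"role{i + 1}"] = t.display.roles[i]
        row["reported"] = t.reported
        rows.append(row)
    _write_with_header(pd.DataFrame(rows), Path(path), "combitva")


def read_combitva_csv(path) -> list[TrialRecord]:
    required = (
        ["participant_id", "block", "trial", "display_type", "exposure_ms"]
        + [f"pos{i}" for i in range(1, 7)]
        + [f"role{i}" for i in range(1, 7)]
        + ["reported"]
    )
    df = _read_checked(Path(path), "combitva", required)
    trials = []
    for line, row in enumerate(df.itertuples(index=False), start=3):
        roles = tuple(str(getattr(row, f"role{i}")) for i in range(1, 7))
        letters = []
        for i in range(1, 7):
            v = str(getattr(row, f"pos{i}"))
            if v == ".":
                letters.append(None)
            elif v in ALPHABET:
                letters.append(v)
            else:
                raise SchemaError(f"{path}:{line}: letter {v!r} outside alphabet")
        reported = str(row.reported)
        bad = [c for c in reported if c not in ALPHABET]
        if bad:
            raise SchemaError(f"{path}:{line}: reported letters {bad} outside alphabet")
        try:
            display = DisplaySpec(
                display_type=str(row.display_type),
                exposure_ms=float(row.exposure_ms),
                roles=roles,
            )
        except ValueError as e:
            raise SchemaError(f"{path}:{line}: {e}") from e
        trials.append(
            TrialRecord(
                participant_id=str(row.participant_id),
                block=int(row.block),
                trial=int(row.trial),
                display=display,
                letters=tuple(letters),
                reported=reported,
            )
        )
    return trials


# --- CPT trials -------------------------------------------------------------


def write_cpt_csv(trials: Iterable[CPTTrial], path, participant_id: str = "P000") -> None:
    rows = []
    for t in trials:
        rows.append(
            dict(
                participant_id=participant_id,
                trial=t.index,
                stimulus_class=t.stimulus,
                stimulus_subtype=t.subtype if t.subtype is not None else "",
                responded=int(t.responded),
                rt_ms="" if t.rt_ms is None else repr(float(t.rt_ms)),
            )
        )
    _write_with_header(pd.DataFrame(rows), Path(path), "cpt")


def read_cpt_csv(path) -> list[CPTTrial]:
    required = [
        "participant_id",
        "trial",
        "stimulus_class",
        "stimulus_subtype",
        "responded",
        "rt_ms",
    ]
    df = _read_checked(Path(path), "cpt", required)
    trials = []
    for line, row in enumerate(df.itertuples(index=False), start=3):
        rt_raw = str(row.rt_ms)
        rt = None if rt_raw == "" else float(rt_raw)
        try:
            trials.append(
                CPTTrial(
                    index=int(row.trial),
                    stimulus=str(row.stimulus_class),
                    responded=bool(int(row.responded)),
                    rt_ms=rt,
                    subtype=str(row.stimulus_subtype) or None,
                )
            )
        except ValueError as e:
            raise SchemaError(f"{path}:{line}: {e}") from e
    return trials


# --- measure table ----------------------------------------------------------


def write_measures_csv(table: pd.DataFrame, path) -> None:
    missing = [c for c in MEASURE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"measure table missing columns {missing}")
    _write_with_header(table[MEASURE_COLUMNS], Path(path), "measures")


def read_measures_csv(path) -> pd.DataFrame:
    return _read_checked(Path(path), "measures", MEASURE_COLUMNS)


# --- fit result -------------------------------------------------------------


def write_fit_json(result: FitResult, path) -> None:
    payload = dict(
        pK=list(result.params.pK),
        C=result.params.C,
        t0=result.params.t0,
        w_index=result.params.w_index,
        alpha=result.params.alpha,
        expected_K=result.expected_K,
        nll=result.nll,
        converged=bool(result.converged),
        n_starts=result.n_starts,
        seed=result.seed,
        **{k: float(v) for k, v in result.diagnostics.items()},
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_fit_json(path) -> dict:
    payload = json.loads(Path(path).read_text())
    required = {"pK", "C", "t0", "w_index", "alpha", "expected_K", "nll", "converged"}
    missing = required - payload.keys()
    if missing:
        raise SchemaError(f"{path}: missing fit keys {sorted(missing)}")
    return payload
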