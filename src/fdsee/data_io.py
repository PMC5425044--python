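"""Reading, validation, filtering and summarisation of sleeping energy
expenditure (SEE) cohorts.

A cohort is a collection of subjects, each carrying a minute-by-minute SEE
trace (kcal/min) recorded in a room respiration calorimeter during nighttime
sleep, together with the anthropometric covariates (weight, height, age, sex)
and the obesity group label used downstream.

Minutes are indexed 1-based from sleep onset.  Before windowing a subject's
minute index may contain gaps (awakenings are excluded upstream); after
:func:`filter_and_window` all retained subjects share the contiguous grid
``1..min_length``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EEProfile",
    "Cohort",
    "SchemaError",
    "IntegrityError",
    "CohortValidationError",
    "EmptyCohortError",
    "read_ee_dataset",
    "write_ee_dataset",
    "filter_and_window",
    "summarize_cohort",
]


class SchemaError(ValueError):
    """A mandatory column is missing or the schema config is malformed."""


class IntegrityError(ValueError):
    """Duplicate (subject, minute) rows or otherwise inconsistent input."""


class CohortValidationError(ValueError):
    """A value violates a physical or structural constraint."""


class EmptyCohortError(ValueError):
    """An operation removed every subject from the cohort."""


#: default column mapping used when a schema config omits ``columns``
DEFAULT_COLUMNS = {
    "id": "subject_id",
    "minute": "minute",
    "see": "see",
    "group": "group",
    "weight": "weight",
    "height": "height",
    "age": "age",
    "sex": "sex",
}

_COVARIATES = ("group", "weight", "height", "age", "sex")


@dataclass
class EEProfile:
    """One subject's sleep-aligned SEE series plus covariates.

    ``time`` holds integer minutes since sleep onset (strictly increasing,
    starting at 1); ``see`` the matching kcal/min values (finite, > 0).
    ``n_invalid`` counts source minutes dropped because the SEE value was
    missing or non-numeric — recorded, never silently discarded.
    """

    subject_id: str
    group: str
    weight: float
    height: float
    age: float
    sex: int
    time: np.ndarray
    see: np.ndarray
    n_invalid: int = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=int)
        self.see = np.asarray(self.see, dtype=float)
        if self.time.shape != self.see.shape or self.time.ndim != 1:
            raise CohortValidationError(
                f"subject {self.subject_id}: time and see must be 1-d arrays "
                f"of equal length"
            )
        if self.time.size and (np.diff(self.time) <= 0).any():
            raise CohortValidationError(
                f"subject {self.subject_id}: minutes must be strictly increasing"
            )
        if self.time.size and self.time[0] < 1:
            raise CohortValidationError(
                f"subject {self.subject_id}: minute index starts at 1"
            )
        if not np.all(np.isfinite(self.see)) or (self.see <= 0).any():
            raise CohortValidationError(
                f"subject {self.subject_id}: SEE values must be finite and > 0"
            )
        for name in ("weight", "height", "age"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise CohortValidationError(
                    f"subject {self.subject_id}: {name} must be positive, got {v!r}"
                )

    @property
    def n_minutes(self) -> int:
        return int(self.time.size)

    @property
    def mean_see(self) -> float:
        return float(self.see.mean())


@dataclass
class Cohort:
    """An ordered collection of :class:`EEProfile` with a provenance log."""

    profiles: list[EEProfile]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.subject_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise IntegrityError("duplicate subject_id in cohort")

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    @property
    def subject_ids(self) -> list[str]:
        return [p.subject_id for p in self.profiles]

    @property
    def groups(self) -> np.ndarray:
        return np.array([p.group for p in self.profiles])

    @property
    def weights(self) -> np.ndarray:
        return np.array([p.weight for p in self.profiles], dtype=float)

    def common_grid(self) -> np.ndarray | None:
        """The shared minute grid, or None if subjects differ."""
        if not self.profiles:
            return None
        t0 = self.profiles[0].time
        for p in self.profiles[1:]:
            if p.time.shape != t0.shape or not np.array_equal(p.time, t0):
                return None
        return t0.copy()

    def see_matrix(self) -> np.ndarray:
        """n x T matrix of SEE values; requires a common grid."""
        if self.common_grid() is None:
            raise CohortValidationError(
                "profiles do not share a common time grid; window the cohort first"
            )
        return np.vstack([p.see for p in self.profiles])

    def covariates(self) -> pd.DataFrame:
        rows = {
            "subject_id": self.subject_ids,
            "group": [p.group for p in self.profiles],
            "weight": [p.weight for p in self.profiles],
            "height": [p.height for p in self.profiles],
            "age": [p.age for p in self.profiles],
            "sex": [p.sex for p in self.profiles],
        }
        return pd.DataFrame(rows)

    def to_long_frame(self, columns: Mapping[str, str] = DEFAULT_COLUMNS) -> pd.DataFrame:
        frames = []
        for p in self.profiles:
            frames.append(
                pd.DataFrame(
                    {
                        columns["id"]: p.subject_id,
                        columns["minute"]: p.time,
                        columns["see"]: p.see,
                        columns["group"]: p.group,
                        columns["weight"]: p.weight,
                        columns["height"]: p.height,
                        columns["age"]: p.age,
                        columns["sex"]: p.sex,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def provenance_json(self) -> str:
        return json.dumps({"provenance": self.provenance}, indent=2)


def _load_schema(schema_config) -> dict:
    if schema_config is None:
        return {}
    if isinstance(schema_config, (str, Path)):
        import yaml

        with open(schema_config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(schema_config)


def _coerce_sex(value, sex_codes: Mapping | None) -> int:
    if sex_codes and value in sex_codes:
        return int(sex_codes[value])
    if isinstance(value, str):
        low = value.strip().lower()
        if low in ("f", "female", "0"):
            return 0
        if low in ("m", "male", "1"):
            return 1
        raise CohortValidationError(f"unrecognised sex code {value!r}")
    return int(value)


def read_ee_dataset(path, schema_config=None) -> Cohort:
    """Read a subject-level SEE table into a :class:`Cohort`.

    Two layouts are supported, selected by ``format`` in the schema config:

    * ``long`` (default): one row per (subject, minute) with covariate
      columns repeated per row;
    * ``wide``: one row per subject with minute columns named
      ``<minute_prefix><m>`` (default prefix ``"min_"``).

    Minutes with missing or non-numeric SEE are dropped from the series but
    counted per subject (``EEProfile.n_invalid``) and in the provenance log.
    """
    schema = _load_schema(schema_config)
    fmt = schema.get("format", "long")
    cols = {**DEFAULT_COLUMNS, **schema.get("columns", {})}
    sex_codes = schema.get("sex_codes")

    # round_trip parsing keeps write->read bitwise faithful
    df = pd.read_csv(
        path, sep=schema.get("delimiter", ","), float_precision="round_trip"
    )

    if fmt == "long":
        mandatory = [cols["id"], cols["minute"], cols["see"], cols["group"], cols["weight"]]
    elif fmt == "wide":
        mandatory = [cols["id"], cols["group"], cols["weight"]]
    else:
        raise SchemaError(f"unknown format {fmt!r}; expected 'long' or 'wide'")
    for c in mandatory:
        if c not in df.columns:
            raise SchemaError(f"mandatory column {c!r} missing from {path}")

    profiles: list[EEProfile] = []
    n_invalid_total = 0

    def _covs(sub: pd.DataFrame | pd.Series) -> dict:
        row = sub.iloc[0] if isinstance(sub, pd.DataFrame) else sub
        weight = float(row[cols["weight"]])
        if not np.isfinite(weight) or weight <= 0:
            raise CohortValidationError(
                f"subject {row[cols['id']]}: non-positive weight {weight}"
            )
        return {
            "group": str(row[cols["group"]]),
            "weight": weight,
            "height": float(row.get(cols["height"], np.nan)),
            "age": float(row.get(cols["age"], np.nan)),
            "sex": _coerce_sex(row.get(cols["sex"], 0), sex_codes),
        }

    if fmt == "long":
        if df.duplicated([cols["id"], cols["minute"]]).any():
            dup = df[df.duplicated([cols["id"], cols["minute"]])].iloc[0]
            raise IntegrityError(
                f"duplicate (subject, minute) row: "
                f"({dup[cols['id']]!r}, {dup[cols['minute']]!r})"
            )
        for sid, sub in df.groupby(cols["id"], sort=False):
            sub = sub.sort_values(cols["minute"])
            see = pd.to_numeric(sub[cols["see"]], errors="coerce").to_numpy()
            valid = np.isfinite(see)
            n_invalid = int((~valid).sum())
            n_invalid_total += n_invalid
            profiles.append(
                EEProfile(
                    subject_id=str(sid),
                    time=sub[cols["minute"]].to_numpy()[valid],
                    see=see[valid],
                    n_invalid=n_invalid,
                    **_covs(sub),
                )
            )
    else:  # wide
        prefix = schema.get("minute_prefix", "min_")
        minute_cols = [c for c in df.columns if c.startswith(prefix)]
        if not minute_cols:
            raise SchemaError(f"no minute columns with prefix {prefix!r} found")
        minutes = np.array([int(c[len(prefix):]) for c in minute_cols])
        order = np.argsort(minutes)
        minutes = minutes[order]
        minute_cols = [minute_cols[i] for i in order]
        if df[cols["id"]].duplicated().any():
            raise IntegrityError("duplicate subject rows in wide-format table")
        for _, row in df.iterrows():
            see = pd.to_numeric(row[minute_cols], errors="coerce").to_numpy(dtype=float)
            valid = np.isfinite(see)
            n_invalid = int((~valid).sum())
            n_invalid_total += n_invalid
            profiles.append(
                EEProfile(
                    subject_id=str(row[cols["id"]]),
                    time=minutes[valid],
                    see=see[valid],
                    n_invalid=n_invalid,
                    **_covs(row),
                )
            )

    cohort = Cohort(profiles)
    cohort.log(
        f"read {len(profiles)} subjects from {path} ({fmt} format); "
        f"{n_invalid_total} invalid SEE minutes recorded"
    )
    return cohort


def write_ee_dataset(cohort: Cohort, path, layout: str = "long") -> None:
    """Write a cohort to CSV in the same schema :func:`read_ee_dataset` ingests."""
    if layout == "long":
        cohort.to_long_frame().to_csv(path, index=False)
    elif layout == "wide":
        grid = cohort.common_grid()
        if grid is None:
            raise CohortValidationError("wide layout requires a common time grid")
        cov = cohort.covariates()
        see = pd.DataFrame(
            cohort.see_matrix(), columns=[f"min_{t}" for t in grid]
        )
        pd.concat([cov, see], axis=1).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def filter_and_window(cohort: Cohort, min_length: int = 405) -> Cohort:
    """Drop subjects with fewer than ``min_length`` usable minutes and window
    the rest to a common contiguous grid ``1..min_length``.

    The window keeps each retained subject's first ``min_length`` observed
    minutes and re-indexes them onto the common grid, so subjects with interior
    gaps (excluded awakenings) remain comparable.  Idempotent.
    """
    if not cohort.profiles:
        raise EmptyCohortError("cannot window an empty cohort")
    kept: list[EEProfile] = []
    removed: list[str] = []
    for p in cohort.profiles:
        if p.n_minutes < min_length:
            removed.append(p.subject_id)
            continue
        kept.append(
            replace(
                p,
                time=np.arange(1, min_length + 1),
                see=p.see[:min_length].copy(),
            )
        )
    if not kept:
        raise EmptyCohortError(
            f"no subject has >= {min_length} usable minutes"
        )
    out = Cohort(kept, provenance=list(cohort.provenance))
    out.log(
        f"filter_and_window(min_length={min_length}): kept {len(kept)}, "
        f"removed {len(removed)} subjects {removed if removed else ''}".rstrip()
    )
    return out


def summarize_cohort(cohort: Cohort, weight_exponent: float | None = None) -> pd.DataFrame:
    """Per-group and overall summary statistics (mean and SD).

    SEE is summarised as the mean of per-subject means — each subject
    contributes one number (their average over observed minutes) because
    subjects, not minutes, are the sampling unit.  If ``weight_exponent`` is
    given, the SEE summary is computed on ``see / weight**exponent``.
    """
    cov = cohort.covariates()
    exp = 0.0 if weight_exponent is None else float(weight_exponent)
    cov["mean_see"] = [
        p.mean_see / p.weight**exp for p in cohort.profiles
    ]

    def _block(sub: pd.DataFrame, label: str) -> dict:
        out = {"group": label, "n": len(sub)}
        for var in ("age", "weight", "height", "mean_see"):
            out[f"{var}_mean"] = sub[var].mean()
            out[f"{var}_sd"] = sub[var].std(ddof=1) if len(sub) > 1 else np.nan
        return out

    rows = [
        _block(sub, str(g)) for g, sub in cov.groupby("group", sort=True)
    ]
    rows.append(_block(cov, "all"))
    return pd.DataFrame(rows).set_index("group")
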