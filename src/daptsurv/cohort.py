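"""Cohort data model: feature schema, survival records, discrete time grid, CSV I/O.

A cohort is one row per patient: an identifier, categorical covariates
(sex, race/ethnicity, comorbidity and medication flags), numeric covariates
(age), follow-up time in days from the index procedure, and a binary event
indicator for one endpoint (ischemic or bleeding).  Follow-up starts at day 8
post-procedure; events during the index hospitalization are excluded upstream,
so records with ``time_days <= grid start`` are dropped at load time.

Time is always stored in days as reals; horizons use a 30/180/365-day
month convention on a configurable grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reserved category label for values unseen when the schema was fitted.
UNKNOWN_CATEGORY = "__unknown__"

#: Default interval boundaries (days): prediction starts on day 8; horizons are
#: 1/2/3/6/12 months with 1 month = 30 days, 6 months = 180, 12 months = 365.
DEFAULT_BOUNDARIES = (8.0, 30.0, 60.0, 90.0, 180.0, 365.0)


class CohortError(ValueError):
    """Raised for schema or record validation failures."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered covariate schema with standardization constants.

    ``categorical`` maps feature name -> ordered tuple of category codes
    (strings); every categorical feature additionally owns a reserved
    unknown-category slot that absorbs codes unseen at fit time.
    ``numeric`` maps feature name -> (mean, sd) used to standardize raw
    values to z-scores; the sd uses the sample (n-1) convention, recorded in
    ``sd_convention`` for reproducibility.
    """

    categorical: dict[str, tuple[str, ...]]
    numeric: dict[str, tuple[float, float]]
    sd_convention: str = "sample"

    def __post_init__(self) -> None:
        for name, vocab in self.categorical.items():
            if len(vocab) == 0:
                raise CohortError(f"empty vocabulary for categorical feature {name!r}")
            if len(set(vocab)) != len(vocab):
                raise CohortError(f"duplicate categories in feature {name!r}")
        for name, (_, sd) in self.numeric.items():
            if not sd > 0:
                raise CohortError(f"non-positive sd for numeric feature {name!r}: {sd}")
        overlap = set(self.categorical) & set(self.numeric)
        if overlap:
            raise CohortError(f"features both categorical and numeric: {sorted(overlap)}")

    @property
    def feature_names(self) -> tuple[str, ...]:
        """All features, categoricals first, in insertion order."""
        return tuple(self.categorical) + tuple(self.numeric)

    @property
    def n_features(self) -> int:
        """M, the number of covariates (one embedding row per feature)."""
        return len(self.categorical) + len(self.numeric)

    def category_index(self, feature: str, code: str) -> int:
        """Index of ``code`` in the feature's lookup table; unseen -> unknown slot."""
        vocab = self.categorical[feature]
        try:
            return vocab.index(str(code))
        except ValueError:
            return len(vocab)  # reserved unknown slot

    def standardize(self, feature: str, raw: float) -> float:
        mean, sd = self.numeric[feature]
        return (float(raw) - mean) / sd

    def to_dict(self) -> dict:
        return {
            "categorical": {k: list(v) for k, v in self.categorical.items()},
            "numeric": {k: [float(m), float(s)] for k, (m, s) in self.numeric.items()},
            "sd_convention": self.sd_convention,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureSchema":
        return cls(
            categorical={k: tuple(str(c) for c in v) for k, v in d["categorical"].items()},
            numeric={k: (float(v[0]), float(v[1])) for k, v in d["numeric"].items()},
            sd_convention=d.get("sd_convention", "sample"),
        )


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient: covariate values, follow-up time t_i (days) and event d_i."""

    patient_id: str
    categorical_values: dict[str, str]
    numeric_values: dict[str, float]
    time_days: float
    event: int

    def __post_init__(self) -> None:
        if not self.time_days > 0:
            raise CohortError(f"{self.patient_id}: non-positive time {self.time_days}")
        if self.event not in (0, 1):
            raise CohortError(f"{self.patient_id}: event must be 0/1, got {self.event}")


@dataclass
class Cohort:
    """A validated table of survival records with its schema.

    Backed by a pandas DataFrame (one column per feature plus ``patient_id``,
    ``time_days``, ``event``) so vectorized paths stay cheap; ``records``
    materializes :class:`SurvivalRecord` views on demand.
    """

    schema: FeatureSchema
    frame: pd.DataFrame
    endpoint_name: str = "event"

    def __post_init__(self) -> None:
        if len(self.frame) == 0:
            raise CohortError("cohort has no records")
        ids = self.frame["patient_id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].unique()[:5]
            raise CohortError(f"duplicate patient ids: {list(dups)}")
        missing = [c for c in self.schema.feature_names if c not in self.frame.columns]
        if missing:
            raise CohortError(f"cohort frame missing feature columns: {missing}")
        bad_t = self.frame.index[~(self.frame["time_days"] > 0)]
        if len(bad_t):
            raise CohortError(f"non-positive time_days on rows {list(bad_t[:5])}")
        bad_d = self.frame.index[~self.frame["event"].isin([0, 1])]
        if len(bad_d):
            raise CohortError(f"event not in {{0,1}} on rows {list(bad_d[:5])}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def patient_ids(self) -> list[str]:
        return self.frame["patient_id"].astype(str).tolist()

    @property
    def times(self) -> np.ndarray:
        return self.frame["time_days"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.frame["event"].to_numpy(dtype=int)

    @property
    def records(self) -> Iterator[SurvivalRecord]:
        cat_names = list(self.schema.categorical)
        num_names = list(self.schema.numeric)
        for row in self.frame.itertuples(index=False):
            d = row._asdict()
            yield SurvivalRecord(
                patient_id=str(d["patient_id"]),
                categorical_values={k: str(d[k]) for k in cat_names},
                numeric_values={k: float(d[k]) for k in num_names},
                time_days=float(d["time_days"]),
                event=int(d["event"]),
            )

    def subset(self, ids: Sequence[str]) -> "Cohort":
        idset = set(ids)
        mask = self.frame["patient_id"].astype(str).isin(idset)
        return Cohort(self.schema, self.frame[mask].copy(), self.endpoint_name)

    def encode(self) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized model inputs.

        Returns ``(cat_idx, num_z)``: integer category indices of shape
        (n, n_categorical) (unseen codes mapped to the unknown slot) and
        standardized numeric values of shape (n, n_numeric).
        """
        n = len(self.frame)
        cat_names = list(self.schema.categorical)
        num_names = list(self.schema.numeric)
        cat_idx = np.zeros((n, len(cat_names)), dtype=np.int64)
        for j, name in enumerate(cat_names):
            vocab = self.schema.categorical[name]
            lut = {c: i for i, c in enumerate(vocab)}
            col = self.frame[name].astype(str)
            cat_idx[:, j] = col.map(lambda c: lut.get(c, len(vocab))).to_numpy()
        num_z = np.zeros((n, len(num_names)), dtype=float)
        for j, name in enumerate(num_names):
            mean, sd = self.schema.numeric[name]
            num_z[:, j] = (self.frame[name].to_numpy(dtype=float) - mean) / sd
        return cat_idx, num_z


@dataclass(frozen=True)
class TimeGrid:
    """Ordered interval boundaries s_0 < s_1 < ... < s_J (days).

    Intervals are left-open/right-closed, (s_{j-1}, s_j], so an event exactly
    at a horizon counts inside that horizon.  ``durations`` are
    rho_j = s_j - s_{j-1}.
    """

    boundaries: tuple[float, ...] = DEFAULT_BOUNDARIES

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or len(b) < 2:
            raise CohortError("grid needs at least two boundaries")
        if not np.all(np.diff(b) > 0):
            raise CohortError(f"boundaries must be strictly increasing: {self.boundaries}")
        object.__setattr__(self, "boundaries", tuple(float(x) for x in b))

    @property
    def start(self) -> float:
        return self.boundaries[0]

    @property
    def end(self) -> float:
        return self.boundaries[-1]

    @property
    def n_intervals(self) -> int:
        return len(self.boundaries) - 1

    @property
    def durations(self) -> np.ndarray:
        b = np.asarray(self.boundaries)
        return np.diff(b)

    def interval_index(self, t) -> np.ndarray | int:
        """kappa(t): 1-based index j of the unique interval with s_{j-1} < t <= s_j."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr <= self.start) or np.any(t_arr > self.end):
            bad = t_arr[(t_arr <= self.start) | (t_arr > self.end)]
            raise CohortError(
                f"time(s) {bad[:5].tolist()} outside grid ({self.start}, {self.end}]"
            )
        # side='left' makes boundary values land in the interval they close
        kappa = np.searchsorted(np.asarray(self.boundaries), t_arr, side="left")
        return int(kappa[0]) if np.isscalar(t) or np.ndim(t) == 0 else kappa

    def overlaps(self, t: float) -> np.ndarray:
        """Length of (s_0, t] falling inside each interval, shape (J,)."""
        if not (self.start < t <= self.end):
            raise CohortError(f"horizon {t} outside grid ({self.start}, {self.end}]")
        b = np.asarray(self.boundaries)
        lo, hi = b[:-1], b[1:]
        return np.clip(np.minimum(hi, t) - lo, 0.0, None)

    def to_dict(self) -> dict:
        return {"boundaries": list(self.boundaries)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "TimeGrid":
        return cls(tuple(float(x) for x in d["boundaries"]))


def interval_index(grid: TimeGrid, t) -> np.ndarray | int:
    """Module-level alias for :meth:`TimeGrid.interval_index`."""
    return grid.interval_index(t)


def fit_schema(
    cohort_frame: pd.DataFrame,
    categorical_features: Sequence[str],
    numeric_features: Sequence[str],
    training_ids: Sequence[str] | None = None,
) -> FeatureSchema:
    """Fit a schema (vocabularies, standardization constants) on the training subset.

    Numeric means/sds are computed on training rows only so that standardizing
    the training data yields mean 0 and sd 1; categorical vocabularies are the
    sorted training-set codes, plus the reserved unknown slot applied at
    transform time.  Sample (n-1) sd convention.
    """
    df = cohort_frame
    if training_ids is not None:
        idset = set(str(i) for i in training_ids)
        if not idset:
            raise CohortError("training_ids is empty")
        mask = df["patient_id"].astype(str).isin(idset)
        if not mask.any():
            raise CohortError("training_ids do not match any cohort rows")
        df = df[mask]
    categorical = {}
    for name in categorical_features:
        codes = sorted(df[name].astype(str).unique().tolist())
        categorical[name] = tuple(codes)
    numeric = {}
    for name in numeric_features:
        # sorted so the result is bit-for-bit invariant to record order
        vals = np.sort(df[name].to_numpy(dtype=float))
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        if not sd > 0:
            raise CohortError(f"numeric feature {name!r} constant on training subset")
        numeric[name] = (mean, sd)
    return FeatureSchema(categorical=categorical, numeric=numeric)


def load_cohort(
    path,
    schema: FeatureSchema,
    endpoint_name: str = "event",
    min_time: float | None = None,
) -> Cohort:
    """Load and validate a cohort CSV (header row; ``patient_id``, one column per
    feature, ``time_days``, ``event``; no missing values).

    Rows with follow-up at or before ``min_time`` (default: day 8, the start of
    the prediction window) are excluded, mirroring the exclusion of in-hospital
    endpoint events; exclusion counts are logged.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = ["patient_id", "time_days", "event", *schema.feature_names]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing required columns {missing}")
    if df.isna().any().any():
        bad_rows = df.index[df.isna().any(axis=1)].tolist()[:10]
        raise CohortError(f"{path}: missing values on rows {bad_rows}")
    bad_t = df.index[~(df["time_days"].astype(float) > 0)].tolist()
    if bad_t:
        raise CohortError(f"{path}: non-positive time_days on rows {bad_t[:10]}")
    bad_d = df.index[~df["event"].astype(float).isin([0.0, 1.0])].tolist()
    if bad_d:
        raise CohortError(f"{path}: event not in {{0,1}} on rows {bad_d[:10]}")
    df["time_days"] = df["time_days"].astype(float)
    df["event"] = df["event"].astype(int)
    cutoff = DEFAULT_BOUNDARIES[0] if min_time is None else float(min_time)
    early = df["time_days"] <= cutoff
    if early.any():
        logger.info(
            "excluding %d/%d records with follow-up <= day %g", int(early.sum()), len(df), cutoff
        )
        df = df[~early]
    if len(df) == 0:
        raise CohortError(f"{path}: no records remain after day-{cutoff} exclusion")
    return Cohort(schema=schema, frame=df.reset_index(drop=True), endpoint_name=endpoint_name)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort back to CSV in the canonical column order."""
    cols = ["patient_id", *cohort.schema.feature_names, "time_days", "event"]
    cohort.frame.to_csv(path, columns=cols, index=False)
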