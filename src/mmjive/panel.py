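"""Data model and IO for two-domain repeated-measures feature panels.

A panel is a long-format table keyed by ``(subject, day)`` holding one block
of physical-activity (PA) features and one block of gait features.  This
module provides reading/writing, validation, valid-day filtering, column
z-scoring (with two scoping conventions) and day-averaging to per-subject
means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, ValidationError

logger = logging.getLogger(__name__)

SUBJECT_COL = "subject"
DAY_COL = "day"
WEAR_COL = "wear_hours"

#: float formatting used by every writer (12 significant digits)
FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------

@dataclass
class FeaturePanel:
    """Long-format repeated-measures table of two feature blocks.

    ``data`` has columns ``subject``, ``day``, optionally ``wear_hours``,
    then the feature columns.  Rows are sorted by (subject, day).
    """

    data: pd.DataFrame
    pa_features: list[str]
    gait_features: list[str]

    def __post_init__(self) -> None:
        self.validate()

    # -- shape accessors ----------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        return list(self.pa_features) + list(self.gait_features)

    @property
    def P(self) -> int:
        return len(self.pa_features)

    @property
    def Q(self) -> int:
        return len(self.gait_features)

    @property
    def subjects(self) -> list:
        return list(dict.fromkeys(self.data[SUBJECT_COL]))

    @property
    def n_subjects(self) -> int:
        return self.data[SUBJECT_COL].nunique()

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def days_per_subject(self) -> pd.Series:
        return self.data.groupby(SUBJECT_COL, sort=True).size()

    # -- matrix views -------------------------------------------------------
    def x(self) -> np.ndarray:
        """N x P matrix of PA feature values."""
        return self.data[self.pa_features].to_numpy(dtype=float)

    def y(self) -> np.ndarray:
        """N x Q matrix of gait feature values."""
        return self.data[self.gait_features].to_numpy(dtype=float)

    def values(self) -> np.ndarray:
        """N x (P+Q) matrix, PA columns first."""
        return self.data[self.feature_names].to_numpy(dtype=float)

    def subject_index(self) -> np.ndarray:
        """Integer codes mapping each row to its subject (sorted order)."""
        return pd.Categorical(
            self.data[SUBJECT_COL], categories=self.subjects
        ).codes.astype(int)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        for col in (SUBJECT_COL, DAY_COL):
            if col not in df.columns:
                raise InputError(f"panel is missing required column {col!r}")
        if not self.pa_features and not self.gait_features:
            raise ValidationError("panel has no feature columns")
        if len(self.pa_features) < 1 or len(self.gait_features) < 1:
            raise ValidationError("both feature blocks must be non-empty")
        overlap = set(self.pa_features) & set(self.gait_features)
        if overlap:
            raise ValidationError(f"features assigned to both blocks: {sorted(overlap)}")
        missing = [f for f in self.feature_names if f not in df.columns]
        if missing:
            raise ValidationError(f"feature columns absent from table: {missing}")
        dup = df.duplicated(subset=[SUBJECT_COL, DAY_COL])
        if dup.any():
            pairs = df.loc[dup, [SUBJECT_COL, DAY_COL]].values.tolist()
            raise ValidationError(f"duplicate (subject, day) pairs: {pairs[:5]}")
        vals = df[self.feature_names].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            bad = [f for f in self.feature_names
                   if not np.all(np.isfinite(df[f].to_numpy(dtype=float)))]
            raise ValidationError(f"non-finite values in features: {bad}")
        if (df[DAY_COL].to_numpy() < 1).any():
            raise ValidationError("day indices must be >= 1")
        # keep rows sorted deterministically
        self.data = df.sort_values([SUBJECT_COL, DAY_COL], kind="mergesort").reset_index(drop=True)


@dataclass
class ScaledPanel:
    """A panel together with the z-scoring that produced it.

    ``scaling_scope`` is ``"daily_rows"`` (statistics computed over all N
    daily rows) or ``"subject_means"`` (statistics computed over the n
    per-subject day-averages, then applied to the daily rows so that the
    subject means of the scaled panel are exactly z-scored).
    """

    panel: FeaturePanel
    column_means: pd.Series
    column_sds: pd.Series
    scaling_scope: str

    def inverse(self) -> FeaturePanel:
        """Undo the scaling, reproducing the original panel."""
        df = self.panel.data.copy()
        feats = self.panel.feature_names
        df[feats] = df[feats] * self.column_sds[feats] + self.column_means[feats]
        return FeaturePanel(df, list(self.panel.pa_features), list(self.panel.gait_features))


@dataclass
class SubjectMeansMatrix:
    """Per-subject day-averages of every feature (one row per subject)."""

    values: pd.DataFrame  # n x (P+Q), indexed by subject, PA columns first
    pa_features: list[str]
    gait_features: list[str]

    @property
    def subject_ids(self) -> list:
        return list(self.values.index)

    @property
    def n(self) -> int:
        return len(self.values)

    def x(self) -> np.ndarray:
        return self.values[self.pa_features].to_numpy(dtype=float)

    def y(self) -> np.ndarray:
        return self.values[self.gait_features].to_numpy(dtype=float)

    def all_values(self) -> np.ndarray:
        return self.values[list(self.pa_features) + list(self.gait_features)].to_numpy(dtype=float)


@dataclass
class FilterReport:
    """Outcome of valid-day filtering."""

    valid_days: pd.DataFrame          # subject, n_valid
    dropped_subjects: list = field(default_factory=list)
    n_rows_removed: int = 0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def read_domain_map(path) -> dict[str, str]:
    """Read a two-column ``feature,domain`` CSV into a mapping."""
    df = pd.read_csv(path)
    for col in ("feature", "domain"):
        if col not in df.columns:
            raise InputError(f"domain map is missing required column {col!r}")
    bad = sorted(set(df["domain"]) - {"PA", "gait"})
    if bad:
        raise ValidationError(f"unknown domain labels in map: {bad} (expected PA/gait)")
    return dict(zip(df["feature"], df["domain"]))


def read_panel(path, domain_map: dict[str, str]) -> FeaturePanel:
    """Read a long-format panel CSV and validate it against a domain map.

    The file must carry ``subject`` and ``day`` columns; every other column
    except an optional ``wear_hours`` is a feature and must appear in
    ``domain_map``.  Rows with any missing feature value are dropped (with a
    logged count); there is no imputation.
    """
    df = pd.read_csv(path)
    for col in (SUBJECT_COL, DAY_COL):
        if col not in df.columns:
            raise InputError(f"input file is missing required column {col!r}")
    feature_cols = [c for c in df.columns if c not in (SUBJECT_COL, DAY_COL, WEAR_COL)]
    if len(feature_cols) < 2:
        raise InputError("input file must have at least two feature columns")
    unmapped = [c for c in feature_cols if c not in domain_map]
    if unmapped:
        raise ValidationError(f"features absent from domain map: {unmapped}")
    pa = [c for c in feature_cols if domain_map[c] == "PA"]
    gait = [c for c in feature_cols if domain_map[c] == "gait"]

    n_before = len(df)
    df = df.dropna(subset=feature_cols)
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.warning("dropped %d rows with missing feature values", n_dropped)

    panel = FeaturePanel(df.reset_index(drop=True), pa, gait)
    logger.info(
        "read panel: %d subjects, %d rows, P=%d PA features, Q=%d gait features",
        panel.n_subjects, panel.n_rows, panel.P, panel.Q,
    )
    return panel


def write_panel(panel: FeaturePanel, path) -> None:
    """Write a panel to CSV deterministically (fixed order, 12-digit repr)."""
    cols = [SUBJECT_COL, DAY_COL]
    if WEAR_COL in panel.data.columns:
        cols.append(WEAR_COL)
    cols += panel.feature_names
    panel.data[cols].to_csv(path, index=False, float_format=FLOAT_FMT)


def filter_valid_days(
    panel: FeaturePanel, min_wear_hours: float = 10.0
) -> tuple[FeaturePanel, FilterReport]:
    """Keep only rows with wear time >= ``min_wear_hours`` (rule is >=).

    Subjects left with zero valid days are removed and listed in the report.
    """
    if WEAR_COL not in panel.data.columns:
        raise ConfigError(
            "panel has no wear_hours column; skip the valid-day filter for this input"
        )
    df = panel.data
    kept = df[df[WEAR_COL] >= min_wear_hours].reset_index(drop=True)
    before_subjects = panel.subjects
    after_subjects = set(kept[SUBJECT_COL])
    dropped = [s for s in before_subjects if s not in after_subjects]
    if dropped:
        logger.warning("subjects removed (no valid days): %s", dropped)
    counts = (
        kept.groupby(SUBJECT_COL, sort=True).size().rename("n_valid").reset_index()
    )
    report = FilterReport(
        valid_days=counts,
        dropped_subjects=dropped,
        n_rows_removed=len(df) - len(kept),
    )
    out = FeaturePanel(kept, list(panel.pa_features), list(panel.gait_features))
    return out, report


def subject_means(panel: FeaturePanel) -> SubjectMeansMatrix:
    """Unweighted arithmetic mean of each subject's daily rows."""
    means = (
        panel.data.groupby(SUBJECT_COL, sort=True)[panel.feature_names].mean()
    )
    return SubjectMeansMatrix(means, list(panel.pa_features), list(panel.gait_features))


def scale_panel(panel: FeaturePanel, scope: str = "daily_rows") -> ScaledPanel:
    """Column-wise z-scoring (sample sd) over the rows of the stated scope.

    scope="daily_rows": statistics over the N daily rows; each scaled column
    then has mean 0 and sample sd 1 across daily rows.  This is the input to
    the multilevel analyses.

    scope="subject_means": statistics over the n subject means; the scaled
    panel's *subject means* are exactly z-scored, which is what the one-level
    analyses consume.  Note that under this scope the daily rows themselves
    are not unit-sd.
    """
    if scope not in ("daily_rows", "subject_means"):
        raise ConfigError(f"unknown scaling scope {scope!r}")
    feats = panel.feature_names
    if scope == "daily_rows":
        ref = panel.data[feats]
    else:
        ref = subject_means(panel).values[feats]
    nun = ref.nunique()
    constant = [f for f in feats if nun[f] < 2]
    if constant:
        raise ValidationError(
            f"zero-variance feature(s) within scaling scope: {constant}"
        )
    mu = ref.mean()
    sd = ref.std(ddof=1)
    df = panel.data.copy()
    df[feats] = (df[feats] - mu) / sd
    scaled = FeaturePanel(df, list(panel.pa_features), list(panel.gait_features))
    return ScaledPanel(scaled, mu, sd, scope)
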