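"""Morphometric similarity networks (MSNs).

Each subject contributes seven regional morphometric features (cortical
thickness, surface area, mean and Gaussian curvature, folding and curvature
indices, grey-matter volume). Features are z-scaled across regions per
subject, and the MSN is the region-by-region correlation matrix of the
resulting 7-component feature vectors. Regional morphometric-similarity (MS)
strength is the signed sum of a region's correlations to all other regions:
high strength marks cortex architectonically similar to much of the rest
("de-differentiated"), negative strength marks differentiated cortex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

FEATURE_NAMES: tuple[str, ...] = ("CT", "SA", "MC", "GC", "FI", "CI", "GM")
#: physical units per feature, in FEATURE_NAMES order
FEATURE_UNITS: tuple[str, ...] = ("mm", "mm^2", "1/mm", "1/mm^2", "", "", "mm^3")

SUBJECT_COLUMNS = ("subject_id", "group", "age", "sex", "tiv", "attendance")
GROUPS = ("user", "control")


def validate_subjects(subjects: pd.DataFrame) -> pd.DataFrame:
    """Validate a subject-covariate table (one row per subject).

    Required columns: subject_id, group ('user'/'control'), age (>0),
    sex ('F'/'M'); optional: tiv, attendance (>=0 where present).
    """
    for col in ("subject_id", "group", "age", "sex"):
        if col not in subjects.columns:
            raise ValueError(f"subjects table missing required column {col!r}")
    if subjects["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id")
    if not set(subjects["group"]) <= set(GROUPS):
        raise ValueError(f"group must be one of {GROUPS}")
    if not set(subjects["sex"]) <= {"F", "M"}:
        raise ValueError("sex must be 'F' or 'M'")
    if (subjects["age"] <= 0).any():
        raise ValueError("age must be positive")
    if "attendance" in subjects.columns:
        att = subjects["attendance"].dropna()
        if (att < 0).any():
            raise ValueError("attendance must be non-negative")
    return subjects.reset_index(drop=True)


@dataclass
class MorphometryTable:
    """Per-subject regional morphometry: subjects x regions x 7 features.

    ``values`` holds physical-scale units unless ``standardized`` is True,
    in which case every (subject, feature) slice has mean 0 / SD 1 across
    regions. ``subjects`` is one row per subject in values order.
    """

    values: np.ndarray
    subjects: pd.DataFrame
    feature_names: tuple[str, ...] = FEATURE_NAMES
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be subjects x regions x features")
        if tuple(self.feature_names) != FEATURE_NAMES:
            raise ValueError(f"feature_names must be {FEATURE_NAMES}")
        if self.values.shape[2] != len(FEATURE_NAMES):
            raise ValueError("exactly 7 morphometric features are required")
        if np.isnan(self.values).any():
            raise ValueError("missing values must be handled before construction")
        self.subjects = validate_subjects(self.subjects)
        if len(self.subjects) != self.values.shape[0]:
            raise ValueError("subjects table does not match values' first axis")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def subject_index(self, subject_id: str) -> int:
        pos = np.flatnonzero(self.subjects["subject_id"].to_numpy() == subject_id)
        if pos.size == 0:
            raise KeyError(f"unknown subject_id {subject_id!r}")
        return int(pos[0])


@dataclass
class MSNMatrix:
    """One subject's region x region morphometric similarity matrix.

    Symmetric, off-diagonal entries in [-1, 1], diagonal stored as 0
    (self-similarity excluded by convention; a constant diagonal would shift
    all strengths equally and cancel in group contrasts).
    """

    matrix: np.ndarray
    method: str
    subject_id: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("MSN matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("MSN matrix must be symmetric to 1e-12")
        if np.any(np.abs(np.diag(m)) > 0):
            raise ValueError("MSN diagonal must be stored as 0")
        off = m[~np.eye(m.shape[0], dtype=bool)]
        if np.any(off < -1 - 1e-12) or np.any(off > 1 + 1e-12):
            raise ValueError("off-diagonal entries must lie in [-1, 1]")
        if self.method not in ("pearson", "spearman"):
            raise ValueError("method must be 'pearson' or 'spearman'")
        self.matrix = m


@dataclass
class RegionalMS:
    """Signed regional MS strength (sum of one region's MSN row)."""

    strength: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        self.strength = np.asarray(self.strength, dtype=float)
        if self.strength.ndim != 1:
            raise ValueError("strength must be a vector")


def zscore_features(table: MorphometryTable) -> MorphometryTable:
    """Z-scale each feature across regions, independently per subject.

    Controls for inter-feature variability (features live on wildly
    different physical scales) so the MSN correlations weight all seven
    features equally.
    """
    v = table.values
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=0, keepdims=True)
    tol = 1e-12 * (1.0 + np.abs(v).max(axis=1, keepdims=True))
    bad = np.argwhere((sd <= tol)[:, 0, :])
    if bad.size:
        s, f = bad[0]
        sid = table.subjects["subject_id"].iloc[int(s)]
        raise ValueError(
            f"zero-variance feature {table.feature_names[int(f)]!r} for subject {sid!r}"
        )
    return MorphometryTable(
        values=(v - mean) / sd,
        subjects=table.subjects.copy(),
        feature_names=table.feature_names,
        standardized=True,
    )


def build_msn(table: MorphometryTable, subject_id: str, method: str = "pearson") -> MSNMatrix:
    """Correlate every pair of regions' z-scored 7-feature vectors.

    ``method='spearman'`` ranks the 7 features within each region's vector
    (average ranks on ties) and correlates the ranks. The diagonal is set
    to 0. No thresholding or binarisation is applied.
    """
    if not table.standardized:
        raise ValueError("build_msn requires a z-scored table (run zscore_features first)")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    X = table.values[table.subject_index(subject_id)]  # regions x 7
    if method == "spearman":
        X = rankdata(X, axis=1)
    sd = X.std(axis=1)
    const = np.flatnonzero(sd <= 1e-12 * (1.0 + np.abs(X).max(axis=1)))
    if const.size:
        raise ValueError(
            f"constant feature vector for region {int(const[0])}: correlation undefined"
        )
    m = np.corrcoef(X)
    np.fill_diagonal(m, 0.0)
    m = (m + m.T) / 2.0  # enforce exact symmetry against rounding
    return MSNMatrix(matrix=m, method=method, subject_id=subject_id)


def regional_strength(msn: MSNMatrix) -> RegionalMS:
    """Signed sum of each region's correlations to all other regions."""
    return RegionalMS(strength=msn.matrix.sum(axis=1), subject_id=msn.subject_id)


def cohort_strengths(table: MorphometryTable, method: str = "pearson") -> pd.DataFrame:
    """Regional MS strength for every subject: subjects x regions DataFrame.

    Rows are indexed by subject_id; ``df.attrs['kind'] == 'ms'`` tags the
    response type for the downstream contrast schema check.
    """
    std = table if table.standardized else zscore_features(table)
    rows = []
    for sid in std.subjects["subject_id"]:
        rows.append(regional_strength(build_msn(std, sid, method)).strength)
    df = pd.DataFrame(
        np.asarray(rows),
        index=pd.Index(std.subjects["subject_id"], name="subject_id"),
        columns=pd.RangeIndex(std.n_regions, name="region_id"),
    )
    df.attrs["kind"] = "ms"
    return df


def group_mean_strength(
    strengths: pd.DataFrame, subjects: pd.DataFrame, group: str
) -> np.ndarray:
    """Mean regional MS over one group's subjects."""
    subjects = validate_subjects(subjects)
    ids = subjects.loc[subjects["group"] == group, "subject_id"]
    if len(ids) == 0:
        raise ValueError(f"no subjects in group {group!r}")
    return strengths.loc[ids].to_numpy().mean(axis=0)


def regional_feature_table(table: MorphometryTable, feature: str) -> pd.DataFrame:
    """Subjects x regions table of one raw feature (e.g. 'CT'), tagged for
    the contrast schema check."""
    f = table.feature_names.index(feature)
    df = pd.DataFrame(
        table.values[:, :, f],
        index=pd.Index(table.subjects["subject_id"], name="subject_id"),
        columns=pd.RangeIndex(table.n_regions, name="region_id"),
    )
    df.attrs["kind"] = feature.lower()
    return df
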