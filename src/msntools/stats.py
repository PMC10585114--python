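"""Case-control inference on regional MS (and cortical thickness).

Per region, an ordinary-least-squares model

    response ~ intercept + group + age_c + sex + age_c:sex (+ TIV) (+ mean CT)

is fitted and the two-tailed Wald t for the group coefficient (contrast
user - control) extracted, with Benjamini-Hochberg FDR across regions. Age
is mean-centred before forming the interaction so the interaction column is
decorrelated from the main effects; sex is coded F=0 / M=1. All regions
share one design matrix, so the mass-univariate fit is a single
normal-equations solve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .msn import validate_subjects
from .parcellation import Parcellation

T_CAP = 1e6  # |t| clamp for perfect-fit degenerate responses


@dataclass
class RegionalStatMap:
    """Group-contrast statistics per region (t is user - control)."""

    t: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray
    significant: np.ndarray
    model_terms: list[str]
    df_resid: int

    @property
    def n_regions(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": np.arange(self.n_regions),
                "t": self.t,
                "p": self.p,
                "p_fdr": self.p_fdr,
                "significant": self.significant,
            }
        )


def bh_fdr(p: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags.

    Returns ``(p_fdr, significant)`` with ``significant = p_fdr < alpha``.
    """
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_fdr, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_fdr, p_fdr < alpha


def _design_matrix(
    subjects: pd.DataFrame,
    extra_covariates: tuple[str, ...] = (),
    mean_ct: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    subjects = validate_subjects(subjects)
    group = (subjects["group"] == "user").to_numpy(float)
    age_c = subjects["age"].to_numpy(float)
    age_c = age_c - age_c.mean()
    sex = (subjects["sex"] == "M").to_numpy(float)
    cols = [np.ones(len(subjects)), group, age_c, sex, age_c * sex]
    terms = ["intercept", "group", "age_c", "sex", "age_c:sex"]
    for cov in extra_covariates:
        if cov != "tiv":
            raise ValueError(f"unsupported extra covariate {cov!r}")
        tiv = subjects["tiv"].to_numpy(float)
        if np.isnan(tiv).any():
            raise ValueError("tiv requested as covariate but missing for some subjects")
        cols.append(tiv - tiv.mean())
        terms.append("tiv")
    if mean_ct is not None:
        mct = np.asarray(mean_ct, dtype=float)
        if mct.shape != (len(subjects),):
            raise ValueError("mean_ct must be one value per subject")
        cols.append(mct - mct.mean())
        terms.append("mean_ct")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns via near-zero diagonal of R in QR
        _, Rq = np.linalg.qr(X)
        bad = [terms[j] for j in range(X.shape[1]) if abs(Rq[j, j]) < 1e-8 * X.shape[0]]
        raise ValueError(f"rank-deficient design matrix; collinear columns: {bad}")
    return X, terms


def fit_regional_contrast(
    values: pd.DataFrame,
    subjects: pd.DataFrame,
    extra_covariates: tuple[str, ...] = (),
    response: str = "ms",
    mean_ct: np.ndarray | None = None,
    alpha: float = 0.05,
) -> RegionalStatMap:
    """Mass-univariate group contrast across regions.

    Parameters
    ----------
    values : subjects x regions DataFrame (rows in ``subjects`` order). If
        the frame carries ``attrs['kind']`` it must match ``response``.
    response : 'ms' for regional MS strength, 'ct' for cortical thickness.
        The CT model additionally requires ``mean_ct`` (per-subject mean
        cross-hemispheric CT) as a nuisance covariate.
    extra_covariates : subset of {'tiv'}.
    """
    if response not in ("ms", "ct"):
        raise ValueError("response must be 'ms' or 'ct'")
    kind = getattr(values, "attrs", {}).get("kind")
    if kind is not None and kind != response:
        raise ValueError(
            f"response schema mismatch: values are tagged {kind!r} but response={response!r}"
        )
    if response == "ct" and mean_ct is None:
        raise ValueError("response='ct' requires mean_ct (mean cross-hemispheric CT)")
    if response == "ms" and mean_ct is not None:
        raise ValueError("mean_ct is a CT-model covariate; not valid with response='ms'")

    subjects = validate_subjects(subjects)
    counts = subjects["group"].value_counts()
    if counts.get("user", 0) < 2 or counts.get("control", 0) < 2:
        raise ValueError("each group needs at least 2 subjects")

    X, terms = _design_matrix(subjects, extra_covariates, mean_ct)
    Y = values.to_numpy(dtype=float) if hasattr(values, "to_numpy") else np.asarray(values)
    n, k = X.shape
    if n <= k:
        raise ValueError("not enough subjects for the requested model")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    g = terms.index("group")
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[g, g], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[g] / se
    degenerate = ~np.isfinite(t) | (np.abs(t) > T_CAP)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} region(s) had a (near-)perfect fit; |t| capped at {T_CAP:g}",
            RuntimeWarning,
            stacklevel=2,
        )
        t = np.where(degenerate, np.sign(beta[g]) * T_CAP, t)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p_fdr, significant = bh_fdr(p, alpha)
    return RegionalStatMap(
        t=t, p=p, p_fdr=p_fdr, significant=significant, model_terms=terms, df_resid=df
    )


def compare_global_ms(
    strengths: pd.DataFrame, subjects: pd.DataFrame, mode: str = "subject_mean"
) -> dict:
    """Global group comparison of MS.

    A Welch two-sample t-test on per-subject mean strength (or on pooled
    regional values with ``mode='pooled'``), plus a two-sample
    Kolmogorov-Smirnov test on the two groups' pooled regional-strength
    distributions. t is signed user - control.
    """
    subjects = validate_subjects(subjects)
    S = strengths.to_numpy(dtype=float)
    grp = (subjects["group"] == "user").to_numpy()
    if grp.sum() < 2 or (~grp).sum() < 2:
        raise ValueError("each group needs at least 2 subjects for the t-test")
    if mode == "subject_mean":
        a, b = S[grp].mean(axis=1), S[~grp].mean(axis=1)
    elif mode == "pooled":
        a, b = S[grp].ravel(), S[~grp].ravel()
    else:
        raise ValueError("mode must be 'subject_mean' or 'pooled'")
    t_res = sps.ttest_ind(a, b, equal_var=False)
    ks_res = sps.ks_2samp(S[grp].ravel(), S[~grp].ravel())
    return {
        "t": float(t_res.statistic),
        "p_t": float(t_res.pvalue),
        "ks_statistic": float(ks_res.statistic),
        "p_ks": float(ks_res.pvalue),
    }


def network_contrast(
    strengths: pd.DataFrame,
    subjects: pd.DataFrame,
    parcellation: Parcellation,
    atlas: str = "yeo7",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group contrast at the network level.

    Each subject's strength is averaged over every region carrying a given
    label, then the same linear model as the regional contrast is fitted to
    the aggregated values, with BH-FDR across the atlas's labels (7 tests).
    """
    labels = {"yeo7": parcellation.yeo, "von_economo": parcellation.von_economo}.get(atlas)
    if labels is None:
        raise ValueError("atlas must be 'yeo7' or 'von_economo'")
    uniq = list(dict.fromkeys(labels))  # stable order of appearance
    S = strengths.to_numpy(dtype=float)
    agg = np.empty((S.shape[0], len(uniq)))
    for j, lab in enumerate(uniq):
        mask = np.asarray(labels) == lab
        if not mask.any():
            raise ValueError(f"label {lab!r} has zero regions")
        agg[:, j] = S[:, mask].mean(axis=1)
    agg_df = pd.DataFrame(agg, index=strengths.index)
    agg_df.attrs["kind"] = "ms"
    sm = fit_regional_contrast(agg_df, subjects, alpha=alpha)
    return pd.DataFrame(
        {
            "label": uniq,
            "t": sm.t,
            "p": sm.p,
            "p_fdr": sm.p_fdr,
            "significant": sm.significant,
            "atlas": atlas,
        }
    )


def frequency_correlation(
    strengths: pd.DataFrame, subjects: pd.DataFrame, stat_map: RegionalStatMap
) -> pd.DataFrame:
    """Spearman correlation of ceremony attendance with mean flagged MS.

    For each FDR-flagged region set (significantly positive t, negative t,
    and all significant), each user subject's mean strength over the set is
    correlated (two-tailed Spearman) with their attendance count. Empty
    sets are skipped with a warning.
    """
    subjects = validate_subjects(subjects)
    users = subjects["group"] == "user"
    att = subjects.loc[users, "attendance"].to_numpy(float)
    if np.isnan(att).any():
        raise ValueError("attendance must be present for all user subjects")
    if np.unique(att).size < 2:
        raise ValueError("attendance is constant across users; rho undefined")
    S = strengths.to_numpy(dtype=float)[users.to_numpy()]
    sets = {
        "positive": stat_map.significant & (stat_map.t > 0),
        "negative": stat_map.significant & (stat_map.t < 0),
        "all": stat_map.significant,
    }
    rows = []
    for name, mask in sets.items():
        if not mask.any():
            warnings.warn(f"flag set {name!r} is empty; skipped", stacklevel=2)
            continue
        mean_ms = S[:, mask].mean(axis=1)
        rho, p = sps.spearmanr(mean_ms, att)
        rows.append({"set": name, "n_regions": int(mask.sum()), "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows, columns=["set", "n_regions", "rho", "p"])


def jaccard_flags(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard similarity |a AND b| / |a OR b| of two boolean flag vectors.

    Defined as 1.0 when both sets are empty. Used to compare main and
    replication significance maps.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("flag vectors must have equal length")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
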