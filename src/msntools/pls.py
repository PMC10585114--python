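"""Rank-1 partial least squares between a case-control map and gene maps.

With a univariate response (the left-hemisphere case-control t-map) the
first PLS component has a closed form: the weight vector is the normalised
gene-by-response cross-covariance, w = X'y / ||X'y||, and the regional
scores are X w. Variance explained is the squared Pearson correlation
between scores and response (the R^2 of the rank-1 regression of y on the
scores). Significance of the variance explained comes from permuting the
response across regions; gene contributions are ranked by bootstrap Z =
weight / bootstrap SE over region resamples, thresholded at the two-tailed
99% confidence level and additionally screened by BH-FDR across genes,
with each stage's survivors reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .spin import SpinEnsemble, SpinTestResult, spin_test
from .synthetic import ExpressionMatrix
from .parcellation import Parcellation

logger = logging.getLogger(__name__)

Z_99 = float(sps.norm.ppf(0.995))  # two-tailed 99% confidence threshold


@dataclass
class PLSResult:
    """PLS1 fit plus its permutation, spatial and bootstrap assessments."""

    weights: np.ndarray
    scores: np.ndarray
    varexp: float
    p_perm: float | None = None
    r_spatial: float | None = None
    p_spin_spatial: float | None = None
    boot_z: np.ndarray | None = None
    sig_pos: list[str] = field(default_factory=list)
    sig_neg: list[str] = field(default_factory=list)
    sig_pos_z_only: list[str] = field(default_factory=list)
    sig_neg_z_only: list[str] = field(default_factory=list)
    gene_symbols: list[str] = field(default_factory=list)


def _check_alignment(X: ExpressionMatrix, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape != (X.values.shape[0],):
        raise ValueError("response length must equal the expression region count")
    if y.std() == 0:
        raise ValueError("zero response variance: PLS undefined")
    return y


def _fit_raw(values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    yc = y - y.mean()
    w = values.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        # response orthogonal to every gene: no direction, zero variance
        return np.zeros(values.shape[1]), np.zeros(values.shape[0]), 0.0
    w = w / norm
    scores = values @ w
    if scores.std() == 0:
        return w, scores, 0.0
    r = float(np.corrcoef(scores, y)[0, 1])
    if r < 0:  # sign convention: positive spatial alignment with y
        w, scores, r = -w, -scores, -r
    return w, scores, r**2


def fit_pls1(
    X: ExpressionMatrix, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Closed-form rank-1 PLS of a univariate response on gene maps.

    Returns ``(weights, scores, varexp)`` with weights the unit-norm
    cross-covariance direction X'y_c, scores = X @ weights, and varexp the
    squared Pearson correlation between scores and y. Weights are oriented
    so that corr(scores, y) >= 0.
    """
    y = _check_alignment(X, y)
    return _fit_raw(X.values, y)


def permutation_test_varexp(
    X: ExpressionMatrix, y: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> float:
    """Permutation p-value for PLS1 variance explained.

    The response's region labels are randomly permuted ``n_perm`` times and
    PLS1 refitted; p = (count(null varexp >= observed) + 1) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    y = _check_alignment(X, y)
    _, _, obs = fit_pls1(X, y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        _, _, ve = _fit_raw(X.values, rng.permutation(y))
        if ve >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)


def bootstrap_gene_z(
    X: ExpressionMatrix,
    y: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    alpha_fdr: float = 0.05,
) -> tuple[np.ndarray, list[str], list[str], list[str], list[str]]:
    """Bootstrap Z-scores and significant gene sets for the PLS1 weights.

    Regions are resampled with replacement ``n_boot`` times, PLS1 refitted,
    and each bootstrap weight vector sign-aligned to the original (flipped
    when their dot product is negative). ``boot_z = weight / SD(aligned
    bootstrap weights)``. Genes pass the confidence stage when
    ``|boot_z| >= z_0.995`` (two-tailed 99%), and the FDR stage when BH
    across genes on the normal two-tailed p of boot_z is below
    ``alpha_fdr``; the reported ``sig_pos``/``sig_neg`` require both.

    Returns ``(boot_z, sig_pos, sig_neg, sig_pos_z_only, sig_neg_z_only)``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    y = _check_alignment(X, y)
    w0, _, _ = fit_pls1(X, y)
    R = X.values.shape[0]
    rng = np.random.default_rng(seed)
    W = np.empty((n_boot, X.n_genes))
    b = 0
    while b < n_boot:
        idx = rng.integers(0, R, size=R)
        yb = y[idx]
        if yb.std() == 0:
            logger.info("bootstrap resample with zero response variance; redrawn")
            continue
        wb, _, _ = _fit_raw(X.values[idx], yb)
        if wb @ w0 < 0:
            wb = -wb
        W[b] = wb
        b += 1
    se = W.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot_z = np.where(se > 0, w0 / se, 0.0)
    p = 2.0 * sps.norm.sf(np.abs(boot_z))
    from .stats import bh_fdr

    _, fdr_sig = bh_fdr(p, alpha_fdr)
    z_pos = boot_z >= Z_99
    z_neg = boot_z <= -Z_99
    syms = np.asarray(X.gene_symbols)
    return (
        boot_z,
        list(syms[z_pos & fdr_sig]),
        list(syms[z_neg & fdr_sig]),
        list(syms[z_pos]),
        list(syms[z_neg]),
    )


def pls_spatial_anchor(
    scores: np.ndarray,
    y: np.ndarray,
    parcellation: Parcellation,
    ensemble: SpinEnsemble,
) -> SpinTestResult:
    """Spin-test the spatial correlation of PLS1 scores with the response.

    Delegates to :func:`msntools.spin.spin_test` on a left-only ensemble
    matching the transcriptomic region support.
    """
    if not ensemble.left_only:
        raise ValueError("pls_spatial_anchor requires a left-only spin ensemble")
    if ensemble.n_regions != parcellation.n_left:
        raise ValueError("ensemble support does not match the parcellation's left hemisphere")
    return spin_test(np.asarray(scores, float), np.asarray(y, float), ensemble)


def run_pls_analysis(
    X: ExpressionMatrix,
    y: np.ndarray,
    parcellation: Parcellation,
    ensemble: SpinEnsemble | None = None,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
) -> PLSResult:
    """Full PLS1 assessment: fit, permutation p, spin anchor, bootstrap Z."""
    w, scores, varexp = fit_pls1(X, y)
    p_perm = permutation_test_varexp(X, y, n_perm=n_perm, seed=seed)
    boot_z, sig_pos, sig_neg, zp, zn = bootstrap_gene_z(X, y, n_boot=n_boot, seed=seed + 1)
    r_spatial = p_spin = None
    if ensemble is not None:
        spin_res = pls_spatial_anchor(scores, y, parcellation, ensemble)
        r_spatial, p_spin = spin_res.r_observed, spin_res.p_spin
    return PLSResult(
        weights=w,
        scores=scores,
        varexp=varexp,
        p_perm=p_perm,
        r_spatial=r_spatial,
        p_spin_spatial=p_spin,
        boot_z=boot_z,
        sig_pos=sig_pos,
        sig_neg=sig_neg,
        sig_pos_z_only=zp,
        sig_neg_z_only=zn,
        gene_symbols=list(X.gene_symbols),
    )
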