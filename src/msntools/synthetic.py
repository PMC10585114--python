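"""Synthetic cohorts with known ground truth.

Emulates the statistical structure the MSN analysis assumes: two groups of
24 subjects with age/sex (optionally TIV and ceremony-attendance)
covariates, 308 cortical regions with seven morphometric features whose
regional profiles are smooth over the cortical sphere, and spatially
autocorrelated gene-expression maps over the 152 left-hemisphere regions.

Planted group effects act on the feature COVARIANCE structure, not feature
means: regional MS is a correlation statistic, and a mean shift would be
removed by the per-subject z-scaling and plant nothing. The sign of
``effect_map[r]`` gives the direction of the planted MS change in the
"user" group, and the mechanism realising it is chosen per region: extra
independent feature-decorrelating noise pulls a region's MS toward zero
(used when the requested direction opposes the baseline-strength sign),
while shrinkage of the subject's feature vector toward the shared profile
homogenises the region and amplifies its baseline MS (used when it
matches).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msn import FEATURE_NAMES, MorphometryTable
from .parcellation import Parcellation, great_circle_distance

#: physical-scale location and spread per feature (CT mm, SA mm^2, MC 1/mm,
#: GC 1/mm^2, FI, CI, GM mm^3) — plausible parcel-level magnitudes. Spreads
#: are ~3% of the mean per profile z-unit so values stay physically positive
#: even at the tails of the amplitude (gain) field; the MSN itself is
#: invariant to these per-feature affine scales.
FEATURE_MEANS = np.array([2.5, 500.0, 0.13, 0.15, 0.55, 0.35, 1200.0])
FEATURE_SDS = np.array([0.08, 16.0, 0.004, 0.005, 0.017, 0.011, 38.0])

#: loading of each feature on the shared latent gradient; induces moderate
#: inter-feature correlation in the regional profile matrix.
_COMMON_LOADING = 0.6

#: share of profile variance carried by the cytoarchitectonic class of a
#: region (regions of one von Economo class share a morphometric signature
#: wherever they sit on the cortex — the premise of MSN analysis); the
#: remainder is a distance-local smooth field.
_CLASS_WEIGHT = 0.5

#: SD of the smooth log-gain field scaling profile amplitude per region.
#: Regional heteroscedasticity is what gives MS strength its wide, balanced
#: spread: z-scoring forces strengths to sum to ~0, and only variance
#: differences between regions let individual strengths move far from 0.
_GAIN_LOG_SD = 0.7

#: lognormal parameters matching mean 563 / SD 650 ceremony attendances
_ATTENDANCE_MU = 5.91
_ATTENDANCE_SIGMA = 0.92

DEFAULT_PROFILE_LENGTH_SCALE = 0.2  # radians, great-circle
DEFAULT_NOISE_SD = 0.55  # subject noise, relative to regional amplitude


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: per-region effect map and planted gene sets."""

    effect_map: np.ndarray
    affected_regions: np.ndarray
    planted_genes_pos: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    planted_genes_neg: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    seed: int = 0

    def __post_init__(self) -> None:
        e = np.asarray(self.effect_map, dtype=float)
        aff = np.asarray(self.affected_regions, dtype=int)
        nonzero = np.flatnonzero(e != 0)
        if not np.array_equal(np.sort(nonzero), np.sort(aff)):
            raise ValueError("effect_map must be zero exactly outside affected_regions")
        if np.intersect1d(self.planted_genes_pos, self.planted_genes_neg).size:
            raise ValueError("planted gene sets must be disjoint")


@dataclass
class ExpressionMatrix:
    """Regions x genes expression, z-scored per gene across regions.

    Left-hemisphere regions only, mirroring atlas-style transcriptomic data
    where right-hemisphere sampling is too sparse to use.
    """

    values: np.ndarray
    gene_symbols: list[str]
    region_ids: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(self.gene_symbols):
            raise ValueError("values must be regions x genes matching gene_symbols")
        if v.shape[0] != np.asarray(self.region_ids).size:
            raise ValueError("region_ids must match the row count")
        if not np.allclose(v.mean(axis=0), 0.0, atol=1e-9):
            raise ValueError("each gene column must have mean 0")
        if not np.allclose(v.std(axis=0), 1.0, atol=1e-9):
            raise ValueError("each gene column must have SD 1")
        self.values = v
        self.region_ids = np.asarray(self.region_ids, dtype=int)

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def exponential_kernel_cholesky(
    centroids: np.ndarray, length_scale: float, jitter: float = 1e-8
) -> np.ndarray:
    """Cholesky factor of exp(-d/ell) over great-circle distances d."""
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    K = np.exp(-great_circle_distance(centroids, centroids) / length_scale)
    K[np.diag_indices_from(K)] += jitter
    return np.linalg.cholesky(K)


#: share of whole-cortex field variance carried by the mirror-symmetric
#: (homotopic) component; the rest is independent per hemisphere
_HOMOTOPIC_WEIGHT = 0.5


def cortical_kernel_cholesky(
    parcellation: Parcellation,
    length_scale: float,
    homotopic_weight: float = _HOMOTOPIC_WEIGHT,
    jitter: float = 1e-8,
) -> np.ndarray:
    """Cholesky of a whole-cortex field covariance over both hemispheres.

    Each hemisphere lives on its own unit sphere, so a single kernel over
    all centroids would couple regions across hemispheres by accidental
    coordinate proximity. Instead the covariance is a positive-definite sum
    of (i) a mirror-symmetric component — right-hemisphere centroids are
    x-mirrored into left-sphere coordinates, giving homotopic regions
    correlated values — and (ii) an independent smooth component per
    hemisphere. This is the structure the hemisphere-mirrored spin
    permutations preserve.
    """
    c = parcellation.centroids.copy()
    right = np.asarray(parcellation.hemisphere) == "R"
    c[right, 0] *= -1.0  # mirror into left-sphere coordinates
    K_sym = np.exp(-great_circle_distance(c, c) / length_scale)
    K_hemi = K_sym.copy()
    K_hemi[np.ix_(right, ~right)] = 0.0
    K_hemi[np.ix_(~right, right)] = 0.0
    K = homotopic_weight * K_sym + (1.0 - homotopic_weight) * K_hemi
    K[np.diag_indices_from(K)] += jitter
    return np.linalg.cholesky(K)


def smooth_field(chol: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One z-scored draw of a Gaussian random field with the given Cholesky."""
    f = chol @ rng.standard_normal(chol.shape[0])
    return (f - f.mean()) / f.std()


@dataclass(frozen=True)
class RegionalProfile:
    """The cohort's shared regional profile in z-units, plus its gain field
    and the baseline MS strength it implies (noiseless MSN row sums)."""

    z: np.ndarray
    gain: np.ndarray
    baseline_strength: np.ndarray


def draw_regional_profile(
    parcellation: Parcellation,
    seed: int,
    profile_length_scale: float = DEFAULT_PROFILE_LENGTH_SCALE,
    gain_log_sd: float = _GAIN_LOG_SD,
) -> RegionalProfile:
    """Draw the shared regions x 7 profile all subjects are noisy copies of.

    Per feature the profile is a cytoarchitectonic class signature (shared
    by all regions of one von Economo class) plus a distance-local smooth
    field, coupled across features by a common latent gradient, and scaled
    by a smooth regional log-gain field. The gain heteroscedasticity is
    what gives MS strength its wide, balanced spread: z-scoring forces
    strengths to sum to ~0, and only variance differences between regions
    let individual strengths move far from zero.
    """
    rng = np.random.default_rng(seed)
    R = parcellation.n_regions
    chol = cortical_kernel_cholesky(parcellation, profile_length_scale)
    classes = np.asarray(parcellation.von_economo)
    class_levels = list(dict.fromkeys(classes))
    class_idx = np.asarray([class_levels.index(c) for c in classes])
    class_sig = rng.standard_normal((len(class_levels), len(FEATURE_NAMES)))
    g0 = smooth_field(chol, rng)
    profile = np.empty((R, len(FEATURE_NAMES)))
    for f in range(len(FEATURE_NAMES)):
        gf = (
            np.sqrt(_CLASS_WEIGHT) * class_sig[class_idx, f]
            + np.sqrt(1 - _CLASS_WEIGHT) * smooth_field(chol, rng)
        )
        profile[:, f] = _COMMON_LOADING * g0 + np.sqrt(1 - _COMMON_LOADING**2) * gf
    gain = np.exp(gain_log_sd * smooth_field(chol, rng))
    profile *= gain[:, None]

    z = (profile - profile.mean(axis=0)) / profile.std(axis=0)
    msn = np.corrcoef(z)
    np.fill_diagonal(msn, 0.0)
    return RegionalProfile(z=profile, gain=gain, baseline_strength=msn.sum(axis=1))


def make_effect_map(
    parcellation: Parcellation,
    n_affected: int,
    seed: int,
    magnitude: float = 1.0,
    frac_negative: float = 0.5,
    left_only: bool = False,
    profile: RegionalProfile | None = None,
) -> np.ndarray:
    """Plant a signed per-region MS effect at ``n_affected`` regions.

    Negative entries drive regional MS down in users, positive entries up.
    Without a profile, regions are chosen uniformly at random and signs
    split per ``frac_negative``. With a profile, regions are sampled from
    the ~1.25 * n_affected regions of largest baseline |MS strength| and
    each effect is signed toward zero (``-sign(baseline)``): effects can
    only express themselves where baseline similarity exists, and real
    case-control t-maps concentrate on high-|MS| cortex (the strong
    negative mean-MS-versus-t spatial correlation).

    ``left_only`` restricts affected regions to the left hemisphere
    (useful when the downstream target is the transcriptomic association).
    """
    rng = np.random.default_rng(seed)
    pool = parcellation.left_ids if left_only else np.asarray(parcellation.region_id)
    effect = np.zeros(parcellation.n_regions)
    if profile is None:
        affected = rng.choice(pool, size=n_affected, replace=False)
        n_neg = int(round(frac_negative * n_affected))
        signs = np.array([-1.0] * n_neg + [1.0] * (n_affected - n_neg))
        rng.shuffle(signs)
        effect[affected] = signs * magnitude
    else:
        b = profile.baseline_strength[pool]
        pool_size = max(n_affected, int(round(1.25 * n_affected)))
        top = pool[np.argsort(-np.abs(b))[:pool_size]]
        affected = rng.choice(top, size=n_affected, replace=False)
        effect[affected] = -np.sign(profile.baseline_strength[affected]) * magnitude
    return effect


def _draw_subjects(
    n_per_group: int, covariate_model: dict, rng: np.random.Generator
) -> pd.DataFrame:
    cm = {"age_mean": 55.0, "age_sd": 11.0, "tiv": False, **(covariate_model or {})}
    rows = []
    for group in ("user", "control"):
        ages = np.clip(
            rng.normal(cm["age_mean"], cm["age_sd"], size=n_per_group), 20.0, 85.0
        )
        sexes = np.array(["F", "M"] * (n_per_group // 2 + 1))[:n_per_group]
        for i in range(n_per_group):
            att = (
                float(np.round(rng.lognormal(_ATTENDANCE_MU, _ATTENDANCE_SIGMA)))
                if group == "user"
                else np.nan
            )
            rows.append(
                {
                    "subject_id": f"{group[:4]}-{i:03d}",
                    "group": group,
                    "age": float(ages[i]),
                    "sex": sexes[i],
                    "tiv": np.nan,
                    "attendance": att,
                }
            )
    return pd.DataFrame(rows)


def simulate_morphometry(
    parcellation: Parcellation,
    n_per_group: int = 24,
    effect_map: np.ndarray | None = None,
    effect_scale: float = 0.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    covariate_model: dict | None = None,
    seed: int = 0,
    profile_length_scale: float = DEFAULT_PROFILE_LENGTH_SCALE,
    gain_log_sd: float = _GAIN_LOG_SD,
    profile: RegionalProfile | None = None,
) -> tuple[MorphometryTable, GroundTruth]:
    """Simulate a two-group cohort of regional morphometry tables.

    Every subject's regions x 7 matrix is the shared regional profile (see
    :func:`draw_regional_profile`; drawn here from ``seed`` unless one is
    passed in) plus independent subject-level noise. Noise is
    multiplicative in the regional amplitude — SD ``noise_sd * gain[r]``
    in profile z-units — so between-subject variability scales with how
    variable a region's morphometry is, and the variance heterogeneity
    that carries MS strength survives at every noise level. Group "user"
    additionally receives the planted covariance effect: ``effect_map[r]``
    gives the signed direction of the planted MS change at region r, and
    the mechanism is chosen so the change goes that way — extra
    feature-decorrelating noise of SD
    ``effect_scale * |effect_map[r]| * gain[r]`` (pulling the region's MS
    toward zero) when the requested direction opposes the region's baseline
    strength sign, and shrinkage of the subject's feature vector toward the
    shared profile by ``exp(-effect_scale * |effect_map[r]|)`` (homogenising
    the region, amplifying its baseline MS) when it matches. Hemispheres
    are simulated symmetrically with independent noise. Features are
    returned on physical scales (not pre-z-scored).
    """
    if n_per_group < 3:
        raise ValueError("n_per_group must be at least 3 (covariate model unidentifiable)")
    if effect_scale < 0:
        raise ValueError("effect_scale must be non-negative")
    R = parcellation.n_regions
    effect = np.zeros(R) if effect_map is None else np.asarray(effect_map, dtype=float)
    if effect.shape != (R,):
        raise ValueError(f"effect_map must have length {R}")

    rng = np.random.default_rng(seed)
    subjects = _draw_subjects(n_per_group, covariate_model or {}, rng)

    if profile is None:
        profile = draw_regional_profile(
            parcellation,
            seed=int(rng.integers(2**31)),
            profile_length_scale=profile_length_scale,
            gain_log_sd=gain_log_sd,
        )
    P, gain = profile.z, profile.gain

    # decorrelate where the requested change opposes the baseline-strength
    # sign (MS can only move toward zero by losing correlation), homogenise
    # where it matches (less subject noise amplifies the baseline MS)
    active = effect != 0
    decorr = active & (effect * profile.baseline_strength <= 0)
    homog = active & ~decorr
    shrink = np.where(homog, np.exp(-effect_scale * np.abs(effect)), 1.0)
    # decorrelating noise scales with the region's profile amplitude so the
    # attenuation (hence the MS change) is uniform across gain levels
    decorr_sd = effect_scale * np.abs(effect[decorr]) * gain[decorr]

    values = np.empty((len(subjects), R, len(FEATURE_NAMES)))
    noise_amp = noise_sd * gain[:, None]
    for s, group in enumerate(subjects["group"]):
        z = P + noise_amp * rng.standard_normal((R, len(FEATURE_NAMES)))
        if group == "user" and effect_scale > 0:
            z[decorr] += decorr_sd[:, None] * rng.standard_normal(
                (int(decorr.sum()), len(FEATURE_NAMES))
            )
            z[homog] = P[homog] + shrink[homog, None] * (z[homog] - P[homog])
        values[s] = FEATURE_MEANS + FEATURE_SDS * z

    cm = covariate_model or {}
    if cm.get("tiv", False):
        gm_total = values[:, :, FEATURE_NAMES.index("GM")].sum(axis=1)
        # TIV correlated with total parcel GM volume; measurement noise
        # scaled to the cohort's GM spread so the correlation is scale-free
        noise = 1.5 * max(float(gm_total.std()), 1e-9)
        tiv = 2.5 * gm_total + rng.normal(0.0, noise, size=len(subjects))
        subjects["tiv"] = tiv

    table = MorphometryTable(values=values, subjects=subjects)
    truth = GroundTruth(
        effect_map=effect,
        affected_regions=np.flatnonzero(effect != 0),
        seed=seed,
    )
    return table, truth


#: default symbols: receptor/transporter and plasticity targets named in the
#: psychoplastogen literature, padded with synthetic placeholders to 66.
_NAMED_GENES = [
    "HTR1A", "HTR2A", "HTR2C", "SIGMAR1", "MAOA", "MAOB",
    "GRIN1", "GRIN2A", "GRIN2B", "BDNF", "FOS", "ARC", "JUNB", "EGR1",
]


def default_gene_symbols(n_genes: int) -> list[str]:
    syms = list(_NAMED_GENES[:n_genes])
    syms += [f"SYN{i:03d}" for i in range(len(syms), n_genes)]
    return syms


def simulate_expression(
    parcellation: Parcellation,
    n_genes: int = 66,
    autocorr_length: float = 0.5,
    effect_map: np.ndarray | None = None,
    planted_pos: np.ndarray | tuple = (),
    planted_neg: np.ndarray | tuple = (),
    association_strength: float = 0.0,
    seed: int = 0,
    gene_symbols: list[str] | None = None,
) -> ExpressionMatrix:
    """Simulate left-hemisphere gene-expression maps.

    Unplanted genes are independent Gaussian random fields over the left
    centroids (exponential kernel, length scale ``autocorr_length`` in
    radians), z-scored across regions. A planted gene mixes the normalised
    effect map (sign + for ``planted_pos``, - for ``planted_neg``) with an
    autocorrelated noise field:

        a * (+/- effect_z) + sqrt(1 - a^2) * field,   a = association_strength

    then is z-scored, so ``association_strength`` is the construction-scale
    spatial correlation between the planted gene and the effect map.
    """
    if not 0.0 <= association_strength <= 1.0:
        raise ValueError("association_strength must lie in [0, 1]")
    planted_pos = np.asarray(planted_pos, dtype=int)
    planted_neg = np.asarray(planted_neg, dtype=int)
    if np.intersect1d(planted_pos, planted_neg).size:
        raise ValueError("planted gene sets must be disjoint")
    planted = np.concatenate([planted_pos, planted_neg])
    if planted.size and (planted.min() < 0 or planted.max() >= n_genes):
        raise ValueError("planted gene indices must lie in 0..n_genes-1")

    left = parcellation.left_mask
    L = int(left.sum())
    rng = np.random.default_rng(seed)
    chol = exponential_kernel_cholesky(parcellation.centroids[left], autocorr_length)

    target = None
    if planted.size:
        e = (np.zeros(parcellation.n_regions) if effect_map is None else np.asarray(effect_map))[left]
        if e.std() == 0:
            raise ValueError("effect_map has no left-hemisphere variation to plant against")
        target = (e - e.mean()) / e.std()

    a = association_strength
    values = np.empty((L, n_genes))
    for g in range(n_genes):
        noise = smooth_field(chol, rng)
        if g in planted_pos:
            col = a * target + np.sqrt(1 - a**2) * noise
        elif g in planted_neg:
            col = a * (-target) + np.sqrt(1 - a**2) * noise
        else:
            col = noise
        values[:, g] = (col - col.mean()) / col.std()

    symbols = gene_symbols if gene_symbols is not None else default_gene_symbols(n_genes)
    if len(symbols) != n_genes:
        raise ValueError("gene_symbols length must equal n_genes")
    return ExpressionMatrix(
        values=values,
        gene_symbols=list(symbols),
        region_ids=parcellation.left_ids,
    )
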