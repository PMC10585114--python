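"""Cortical parcellation metadata: centroids on the sphere plus network labels.

A parcellation here is parcel-level only: each region carries a unit-vector
centroid on its hemisphere's spherical projection (FreeSurfer-style, one unit
sphere per hemisphere), a Yeo-7 resting-state-network label and a von Economo
cytoarchitectonic class. The spherical centroids anchor the spin-permutation
null models; the labels anchor network-level aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

YEO7_LABELS: tuple[str, ...] = ("VIS", "SMN", "DAN", "VAN", "LIM", "FPN", "DMN")
VON_ECONOMO_LABELS: tuple[str, ...] = (
    "primary_motor",
    "association_1",
    "association_2",
    "primary_sensory",
    "secondary_sensory",
    "limbic",
    "insular",
)


@dataclass(frozen=True)
class Parcellation:
    """Region metadata for a two-hemisphere cortical parcellation.

    Attributes
    ----------
    region_id : (R,) int array, contiguous 0..R-1; left-hemisphere regions
        occupy the leading block.
    name : list of region names.
    hemisphere : (R,) array of 'L'/'R'.
    centroids : (R, 3) float array, each row a unit vector on its
        hemisphere's sphere.
    yeo : (R,) array of Yeo-7 labels.
    von_economo : (R,) array of von Economo class labels.
    """

    region_id: np.ndarray
    name: list[str]
    hemisphere: np.ndarray
    centroids: np.ndarray
    yeo: np.ndarray
    von_economo: np.ndarray

    def __post_init__(self) -> None:
        rid = np.asarray(self.region_id)
        if rid.ndim != 1 or not np.array_equal(np.sort(rid), np.arange(rid.size)):
            raise ValueError("region_id must be unique and contiguous 0..R-1")
        norms = np.linalg.norm(self.centroids, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("centroids must lie on the unit sphere")
        if not set(np.unique(self.hemisphere)) <= {"L", "R"}:
            raise ValueError("hemisphere labels must be 'L' or 'R'")
        if not set(np.unique(self.yeo)) <= set(YEO7_LABELS):
            raise ValueError("unknown Yeo-7 label")
        if not set(np.unique(self.von_economo)) <= set(VON_ECONOMO_LABELS):
            raise ValueError("unknown von Economo label")

    @property
    def n_regions(self) -> int:
        return int(np.asarray(self.region_id).size)

    @property
    def left_mask(self) -> np.ndarray:
        return np.asarray(self.hemisphere) == "L"

    @property
    def right_mask(self) -> np.ndarray:
        return np.asarray(self.hemisphere) == "R"

    @property
    def left_ids(self) -> np.ndarray:
        return np.asarray(self.region_id)[self.left_mask]

    @property
    def n_left(self) -> int:
        return int(self.left_mask.sum())


def great_circle_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distance (radians) between unit vectors.

    Parameters are (n, 3) and (m, 3); returns (n, m).
    """
    cosang = np.clip(np.asarray(a) @ np.asarray(b).T, -1.0, 1.0)
    return np.arccos(cosang)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # golden-angle increments
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.stats import special_ortho_group

    return special_ortho_group.rvs(3, random_state=rng)


def _farthest_point_labels(
    centroids: np.ndarray, labels: tuple[str, ...], rng: np.random.Generator
) -> np.ndarray:
    """Assign labels by Voronoi patches around farthest-point-sampled seeds.

    Seeds are k centroids chosen by farthest-point sampling (first at random),
    then every region takes the label of its nearest seed, which yields
    spatially contiguous, autocorrelated label patches with every label
    present at least once (each seed claims itself).
    """
    k = len(labels)
    n = centroids.shape[0]
    seeds = [int(rng.integers(n))]
    d = great_circle_distance(centroids, centroids[seeds])
    mind = d[:, 0]
    for _ in range(k - 1):
        seeds.append(int(np.argmax(mind)))
        mind = np.minimum(mind, great_circle_distance(centroids, centroids[[seeds[-1]]])[:, 0])
    seed_pts = centroids[seeds]
    nearest = np.argmin(great_circle_distance(centroids, seed_pts), axis=1)
    order = rng.permutation(k)  # random seed->label pairing
    return np.asarray([labels[order[j]] for j in nearest])


def make_parcellation(n_regions: int, n_left: int, seed: int) -> Parcellation:
    """Build a synthetic two-hemisphere parcellation.

    Centroids are quasi-uniform on each hemisphere's unit sphere (Fibonacci
    lattice under a seeded random rotation); Yeo-7 and von Economo labels are
    assigned by spatially contiguous Voronoi clustering of the centroids so
    label maps are autocorrelated rather than independent per region.

    Parameters
    ----------
    n_regions : total region count (study-scale configuration: 308).
    n_left : left-hemisphere region count (study-scale: 152); the remainder
        is the right hemisphere.
    seed : seed for the centroid rotation and label seeding.
    """
    if n_left > n_regions:
        raise ValueError(f"n_left ({n_left}) cannot exceed n_regions ({n_regions})")
    n_right = n_regions - n_left
    if n_left < 7 or n_right < 7:
        raise ValueError("each hemisphere needs at least 7 regions (one per label)")
    rng = np.random.default_rng(seed)

    blocks = []
    for n_hemi in (n_left, n_right):
        pts = _fibonacci_sphere(n_hemi) @ _random_rotation(rng).T
        blocks.append(pts)
    centroids = np.vstack(blocks)
    hemisphere = np.asarray(["L"] * n_left + ["R"] * n_right)

    yeo = np.empty(n_regions, dtype=object)
    veco = np.empty(n_regions, dtype=object)
    for mask in (hemisphere == "L", hemisphere == "R"):
        yeo[mask] = _farthest_point_labels(centroids[mask], YEO7_LABELS, rng)
        veco[mask] = _farthest_point_labels(centroids[mask], VON_ECONOMO_LABELS, rng)

    names = [f"{h}_{i:03d}" for i, h in enumerate(hemisphere)]
    return Parcellation(
        region_id=np.arange(n_regions),
        name=names,
        hemisphere=hemisphere,
        centroids=centroids,
        yeo=yeo.astype(str),
        von_economo=veco.astype(str),
    )
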