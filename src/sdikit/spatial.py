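"""Spin-test spatial permutations and map-to-map association.

The spin test builds a spatial-autocorrelation-preserving null by rotating
parcel centroids on the sphere and reassigning each parcel to its nearest
rotated neighbour (hemispheres rotated with mirrored rotations and
reassigned within hemisphere).  Associations between region-indexed maps
are Spearman correlations with a Fisher z transform, tested against the
spin null with the add-one permutation p convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import cdist

from .synth import Parcellation

__all__ = [
    "SpinNull",
    "AssociationResult",
    "spin_rotations",
    "shuffle_null",
    "spatial_association",
    "decode_term_maps",
    "split_tmap_directions",
]

#: |rho| = 1 maps to atanh(1 - this) instead of infinity.
_FISHER_CAP = 1e-12


@dataclass
class AssociationResult:
    """Spearman association between two maps with a permutation p value."""

    rho: float
    fisher_z: float
    p: float
    n_perm: int
    threshold: float  # 1/n_corr significance threshold
    significant: bool
    label: str = ""


@dataclass
class SpinNull:
    """A bank of spatial permutations from random sphere rotations.

    ``permutations[k, i]`` is the source region whose value region ``i``
    receives under spin ``k``.  Nearest-centroid reassignment need not be
    a bijection: a source region may be used more than once.
    """

    permutations: np.ndarray  # (n_perm, n) int
    seed: int
    n_regions: int

    @property
    def n_perm(self) -> int:
        return self.permutations.shape[0]

    def apply(self, values: np.ndarray, k: int) -> np.ndarray:
        return np.asarray(values)[self.permutations[k]]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation: QR-orthonormalized Gaussian, det forced to +1."""
    M = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))  # make unique/uniform
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _reassign(centroids: np.ndarray, rotated: np.ndarray) -> np.ndarray:
    """Map each region to the nearest rotated centroid."""
    return np.argmin(cdist(centroids, rotated), axis=1)


def spin_rotations(parcellation: Parcellation, n_perm: int, seed: int = 0) -> SpinNull:
    """Build a spin null from ``n_perm`` random rotations of the sphere.

    The left hemisphere is rotated by a uniform random rotation and the
    right by its x-mirrored twin, preserving the brain's mirror symmetry;
    reassignment is within hemisphere.  Permutations that reproduce the
    identity are redrawn: the identity belongs to the observed statistic,
    not the null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cent = parcellation.centroid
    if np.any(np.abs(np.linalg.norm(cent, axis=1) - 1.0) > 1e-9):
        raise ValueError("centroids must lie on the unit sphere")
    rng = np.random.default_rng(seed)
    n = parcellation.n_regions
    mirror = np.diag([-1.0, 1.0, 1.0])
    hemis = parcellation.hemisphere
    idx_by_hemi = {h: np.flatnonzero(hemis == h) for h in ("L", "R")}
    identity = np.arange(n)
    perms = np.empty((n_perm, n), dtype=int)
    for k in range(n_perm):
        for _ in range(100):
            rot = _random_rotation(rng)
            rot_r = mirror @ rot @ mirror
            perm = np.empty(n, dtype=int)
            for h, R in (("L", rot), ("R", rot_r)):
                idx = idx_by_hemi[h]
                if len(idx) == 0:
                    continue
                sub = _reassign(cent[idx], cent[idx] @ R.T)
                perm[idx] = idx[sub]
            if not np.array_equal(perm, identity):
                break
        else:
            raise RuntimeError("could not draw a non-identity spin permutation")
        perms[k] = perm
    return SpinNull(permutations=perms, seed=seed, n_regions=n)


def shuffle_null(n_regions: int, n_perm: int, seed: int = 0) -> SpinNull:
    """Spatially naive label-shuffle null (sensitivity alternative to the spin)."""
    rng = np.random.default_rng(seed)
    identity = np.arange(n_regions)
    perms = np.empty((n_perm, n_regions), dtype=int)
    for k in range(n_perm):
        while True:
            perm = rng.permutation(n_regions)
            if not np.array_equal(perm, identity):
                break
        perms[k] = perm
    return SpinNull(permutations=perms, seed=seed, n_regions=n_regions)


def _fisher_z(rho: float) -> float:
    return float(np.arctanh(np.clip(rho, -1 + _FISHER_CAP, 1 - _FISHER_CAP)))


def _spearman(a: np.ndarray, b: np.ndarray, strict: bool = True) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return np.nan
    aa, bb = a[ok], b[ok]
    if np.all(aa == aa[0]) or np.all(bb == bb[0]):
        if strict:
            raise ValueError("constant map; Spearman correlation undefined")
        return np.nan  # degenerate null draw (e.g. spun-in repeats)
    return float(sps.spearmanr(aa, bb).statistic)


def spatial_association(
    map_a: np.ndarray,
    map_b: np.ndarray,
    null: SpinNull,
    n_corr: int = 1,
    label: str = "",
) -> AssociationResult:
    """Spearman association of two maps against a spin-permutation null.

    ``map_a`` is permuted by each spin; the two-sided permutation p
    compares |Fisher z| of the null draws with the observed value using
    the add-one convention ``p = (1 + #{|z_null| >= |z_obs|}) / (n_perm + 1)``,
    so p is never zero.  Regions that are NaN in either map (e.g. the
    excluded direction of a split t-map, or excluded regions spun into
    view) are dropped pairwise.

    Significance applies the 1/N rule with ``n_corr`` correlations in the
    battery.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("maps must be one-dimensional and of equal length")
    if len(a) != null.n_regions:
        raise ValueError("null was built for a different parcellation size")
    rho = _spearman(a, b)
    z_obs = _fisher_z(rho)
    count = 0
    for k in range(null.n_perm):
        rho_k = _spearman(null.apply(a, k), b, strict=False)
        if np.isnan(rho_k):
            count += 1  # undersized overlap counts as extreme (conservative)
            continue
        if abs(_fisher_z(rho_k)) >= abs(z_obs):
            count += 1
    p = (1 + count) / (null.n_perm + 1)
    threshold = 1.0 / n_corr
    return AssociationResult(
        rho=rho,
        fisher_z=z_obs,
        p=p,
        n_perm=null.n_perm,
        threshold=threshold,
        significant=p < threshold,
        label=label,
    )


def split_tmap_directions(t: np.ndarray, mask: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Split a t-map into positive and negative direction maps.

    The complementary direction's regions are set to NaN (excluded from
    correlations, not kept as zeros).  An optional significance mask
    restricts each direction to masked regions.
    """
    t = np.asarray(t, dtype=float)
    keep = np.ones(len(t), dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    pos = np.where(keep & (t > 0), t, np.nan)
    neg = np.where(keep & (t < 0), t, np.nan)
    return {"positive": pos, "negative": neg}


def decode_term_maps(
    direction_map: np.ndarray, term_maps: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Rank meta-analytic term maps by Spearman correlation with a direction map.

    Descriptive (no p values), mirroring word-cloud style decoding:
    returns a table of (term, rho) sorted by descending rho.
    """
    if len(term_maps) == 0:
        raise ValueError("need at least one term map")
    d = np.asarray(direction_map, dtype=float)
    rows = []
    for term, m in term_maps.items():
        m = np.asarray(m, dtype=float)
        if m.shape != d.shape:
            raise ValueError(f"term map '{term}' length {len(m)} != map length {len(d)}")
        rows.append({"term": term, "rho": _spearman(d, m)})
    return pd.DataFrame(rows).sort_values("rho", ascending=False).reset_index(drop=True)
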