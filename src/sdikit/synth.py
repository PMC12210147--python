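"""Synthetic parcellations, connectomes, cohorts, expression and annotation maps.

Every generator is a pure function of its arguments and a seed, and plants
a known ground truth so each downstream stage of the pipeline has a
recovery test: connectomes are connected weighted graphs on spherical
centroids, regional time series are band-projected mixtures of structural
harmonics with per-region low/high spectral gains, cohorts carry planted
group effects and severity links, expression matrices carry planted
spatial components, and annotation maps are smooth Gaussian fields
optionally correlated with a target map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist

from . import structural
from .structural import HarmonicBasis

__all__ = [
    "Parcellation",
    "CohortSpec",
    "Cohort",
    "gen_parcellation",
    "gen_structural_connectome",
    "gen_subject_timeseries",
    "gen_cohort",
    "gen_expression",
    "gen_annotation_map",
]


@dataclass
class Parcellation:
    """A set of cortical parcels with spherical centroids.

    Centroids live on the unit sphere (needed by the spin test); volumes
    are voxel-count surrogates used for edge normalization.
    """

    region_id: np.ndarray  # (n,) int, contiguous from 1
    name: list[str]
    hemisphere: np.ndarray  # (n,) '<U1', 'L' or 'R'
    centroid: np.ndarray  # (n, 3) unit-norm rows
    volume: np.ndarray  # (n,) positive

    def __post_init__(self) -> None:
        n = len(self.region_id)
        if not np.array_equal(np.sort(self.region_id), np.arange(1, n + 1)):
            raise ValueError("region_ids must be unique and contiguous from 1")
        norms = np.linalg.norm(self.centroid, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("centroids must have unit norm")
        if np.any(self.volume <= 0):
            raise ValueError("volumes must be positive")

    @property
    def n_regions(self) -> int:
        return len(self.region_id)


@dataclass
class CohortSpec:
    """Study-design parameters for a synthetic two-group cohort."""

    n_regions: int = 100
    n_timepoints: int = 230
    n_per_group: tuple[int, int] = (40, 40)  # (patients, controls)
    effect_regions: tuple[int, ...] = ()
    effect_size: float = 1.0  # multiplicative gain on decoupled energy
    severity_link_regions: tuple[int, ...] = ()
    severity_rho: float = 0.0
    base_high_gain: float = 1.0  # decoupled-band gain shared by all subjects
    effect_baseline: float = 1 / 8  # baseline gain dip at effect regions (both groups)
    cutoff_fraction: float = 0.2  # fraction of harmonics in the coupled band
    seed: int = 0

    def validate(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if not -1.0 < self.severity_rho < 1.0:
            raise ValueError("severity_rho must lie strictly inside (-1, 1)")
        ids = set(range(1, self.n_regions + 1))
        for label, regs in [
            ("effect_regions", self.effect_regions),
            ("severity_link_regions", self.severity_link_regions),
        ]:
            if not set(regs) <= ids:
                raise ValueError(f"{label} must be a subset of region ids 1..{self.n_regions}")
        if self.n_timepoints < self.n_regions:
            warnings.warn(
                f"n_timepoints ({self.n_timepoints}) below n_regions "
                f"({self.n_regions}); spectral estimates will be noisy",
                stacklevel=2,
            )


@dataclass
class Cohort:
    """Generated subjects with their signals, connectomes and ground truth."""

    spec: CohortSpec
    parcellation: Parcellation
    subject_id: list[str]
    group: np.ndarray  # (s,) int, patient=1 / control=0
    gender: np.ndarray  # (s,) int {0, 1}
    mean_fd: np.ndarray  # (s,) mm
    severity: np.ndarray  # (s,) float, NaN for controls
    timeseries: list[np.ndarray]  # each (n, T)
    connectome: list[np.ndarray]  # each (n, n)
    basis: HarmonicBasis  # shared generating basis (planted cutoff set)
    truth_high_gain: np.ndarray  # (s, n) per-subject decoupled-band gains

    @property
    def n_subjects(self) -> int:
        return len(self.subject_id)


def gen_parcellation(n: int, seed: int = 0) -> Parcellation:
    """Fibonacci-lattice parcellation of the unit sphere.

    Hemispheres are assigned by the sign of the centroid x coordinate;
    volumes are log-normal with median 1.
    """
    if n < 8:
        raise ValueError(f"need at least 8 regions, got {n}")
    rng = np.random.default_rng(seed)
    i = np.arange(n)
    golden = (1 + np.sqrt(5)) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.clip(1 - z**2, 0.0, None))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    hemi = np.where(pts[:, 0] < 0, "L", "R")
    volume = np.exp(rng.normal(0.0, 0.3, size=n))
    names = [f"{h}_region_{k + 1:03d}" for k, h in enumerate(hemi)]
    return Parcellation(
        region_id=np.arange(1, n + 1),
        name=names,
        hemisphere=hemi,
        centroid=pts,
        volume=volume,
    )


def gen_structural_connectome(
    parcellation: Parcellation, density: float = 0.2, seed: int = 0
) -> np.ndarray:
    """Connected weighted graph with distance-decaying edge weights.

    Edges are kept with probability decreasing in great-circle distance
    until the target density is reached; weights are distance-decaying
    with multiplicative log-normal noise.  If the sampled graph is
    disconnected, minimum-spanning-tree edges over the distance matrix are
    added so the result is always a single component.
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    rng = np.random.default_rng(seed)
    n = parcellation.n_regions
    dist = squareform(pdist(parcellation.centroid))
    scale = np.median(dist[dist > 0])
    base = np.exp(-dist / scale)
    noise = np.exp(rng.normal(0.0, 0.25, size=(n, n)))
    noise = np.triu(noise, 1)
    noise = noise + noise.T
    weights = base * noise
    np.fill_diagonal(weights, 0.0)

    iu = np.triu_indices(n, 1)
    n_edges = max(1, int(round(density * len(iu[0]))))
    if density < 1.0:
        # keep the highest-scoring edges under a noisy distance-decay score
        score = base[iu] * np.exp(rng.normal(0.0, 0.5, size=len(iu[0])))
        keep = np.argsort(score)[::-1][:n_edges]
        mask = np.zeros((n, n), dtype=bool)
        mask[iu[0][keep], iu[1][keep]] = True
        mask |= mask.T
        weights = np.where(mask, weights, 0.0)

    n_comp, _ = connected_components(weights > 0, directed=False)
    if n_comp > 1:
        mst = minimum_spanning_tree(dist).toarray()
        added = (mst > 0) & (weights == 0)
        added |= added.T
        weights[added] = base[added]
    return structural.validate_connectome(weights)


def gen_subject_timeseries(
    basis: HarmonicBasis,
    low_gain: np.ndarray | float,
    high_gain: np.ndarray | float,
    T: int,
    seed: int = 0,
) -> np.ndarray:
    """Band-projected harmonic mixture with per-region spectral gains.

    The signal is ``x = P_L diag(g_low) U_L e_L + P_H diag(g_high) U_H e_H``
    where ``U_L``/``U_H`` are the harmonics below/above the basis cutoff,
    ``e`` are i.i.d. standard-normal spectral coefficients and ``P_L``/``P_H``
    project back onto each band.  The projection keeps the two parts exactly
    band-limited, so a subject's expected SDI is monotone in the per-region
    high/low gain ratio and identically zero when ``high_gain`` is zero.
    With band-wise uniform gains this reduces to plain spectral scaling
    ``x = U (g * e)``.
    """
    if basis.cutoff is None:
        raise ValueError("basis needs a cutoff to define the low/high bands")
    if T < 10:
        raise ValueError(f"need T >= 10 timepoints, got {T}")
    n = basis.n_regions
    C = basis.cutoff
    g_low = np.broadcast_to(np.asarray(low_gain, dtype=float), (n,)).copy()
    g_high = np.broadcast_to(np.asarray(high_gain, dtype=float), (n,)).copy()
    if np.any(g_low <= 0):
        raise ValueError("low_gain must be strictly positive")
    if np.any(g_high < 0):
        raise ValueError("high_gain must be nonnegative")
    rng = np.random.default_rng(seed)
    U = basis.eigenvectors
    U_low, U_high = U[:, :C], U[:, C:]
    eps_low = rng.standard_normal((C, T))
    eps_high = rng.standard_normal((n - C, T))
    raw_low = g_low[:, None] * (U_low @ eps_low)
    raw_high = g_high[:, None] * (U_high @ eps_high)
    x = U_low @ (U_low.T @ raw_low) + U_high @ (U_high.T @ raw_high)
    return x


def gen_cohort(spec: CohortSpec, parcellation: Parcellation) -> Cohort:
    """Two-group cohort with planted decoupling effects and covariates.

    Patients receive ``effect_size`` multiplied onto the decoupled-band
    gain in ``effect_regions``.  Severity (a HAMD-like score, patients
    only) is a noisy linear readout of each patient's mean gain over
    ``severity_link_regions``, mixed to hit ``severity_rho`` in
    expectation.  Gender and head motion are drawn with a mild group
    imbalance so covariate adjustment is consequential.
    """
    spec.validate()
    if parcellation.n_regions != spec.n_regions:
        raise ValueError("parcellation size does not match spec.n_regions")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_regions
    n_pat, n_con = spec.n_per_group

    sc = gen_structural_connectome(parcellation, density=0.2, seed=spec.seed)
    sc_norm = structural.volume_normalize(sc, parcellation.volume)
    A, _ = structural.symmetric_normalize(sc_norm)
    basis = structural.harmonics(A, source="synthetic").with_cutoff(
        max(1, int(round(spec.cutoff_fraction * n)))
    )

    groups = np.array([1] * n_pat + [0] * n_con)
    subject_id = [f"sub-{k + 1:03d}" for k in range(len(groups))]

    # mild, intentional covariate imbalance (<= 15 percentage points)
    p_female = np.where(groups == 1, 0.58, 0.45)
    gender = (rng.random(len(groups)) < p_female).astype(int)
    mean_fd = np.exp(rng.normal(np.where(groups == 1, -2.1, -2.25), 0.3))

    timeseries: list[np.ndarray] = []
    connectomes: list[np.ndarray] = []
    truth = np.zeros((len(groups), n))
    effect_idx = np.array(sorted(spec.effect_regions), dtype=int) - 1
    # Baseline decoupled gain is dipped at the effect regions in BOTH
    # groups, so the patient-only boost stays small as a share of regional
    # variance: a large variance bump at a few regions would bleed into
    # their graph neighbours through the band filters and the per-region
    # z-scoring, faking group effects where none were planted.
    base_high = np.full(n, spec.base_high_gain)
    if len(effect_idx):
        base_high[effect_idx] *= spec.effect_baseline
    # balance expected energy across the two bands so the estimated
    # median-energy cutoff coincides with the generating band boundary
    q = basis.cutoff / n
    base_low = np.sqrt((1 - q) * np.mean(base_high**2) / q)
    for s, g in enumerate(groups):
        high = base_high.copy()
        if g == 1 and len(effect_idx):
            high[effect_idx] *= spec.effect_size
        truth[s] = high
        ts = gen_subject_timeseries(
            basis, base_low, high, spec.n_timepoints, seed=int(rng.integers(2**31))
        )
        timeseries.append(ts)
        # per-subject connectome: group connectome with subject-level edge noise
        jitter = np.exp(rng.normal(0.0, 0.1, size=sc.shape))
        jitter = np.triu(jitter, 1)
        jitter = jitter + jitter.T
        connectomes.append(sc * jitter)

    severity = np.full(len(groups), np.nan)
    pat = groups == 1
    if n_pat:
        link_idx = (
            np.array(sorted(spec.severity_link_regions), dtype=int) - 1
            if spec.severity_link_regions
            else np.arange(n)
        )
        # link severity to each patient's realized decoupling at the linked
        # regions (their effective gain): planted gains are identical across
        # patients, so the subject-level variation that severity can track
        # is the realized spectral energy ratio
        C = basis.cutoff
        U = basis.eigenvectors
        signal = np.empty(n_pat)
        for k, s in enumerate(np.flatnonzero(pat)):
            coeff = U.T @ timeseries[s]
            low = U[:, :C] @ coeff[:C]
            high = U[:, C:] @ coeff[C:]
            ratio = np.linalg.norm(high[link_idx], axis=1) / np.linalg.norm(
                low[link_idx], axis=1
            )
            signal[k] = ratio.mean()
        sd = signal.std(ddof=1)
        z_sig = (signal - signal.mean()) / sd if sd > 0 else np.zeros(n_pat)
        rho = spec.severity_rho
        z = rho * z_sig + np.sqrt(1 - rho**2) * rng.standard_normal(n_pat)
        severity[pat] = 24.0 + 5.0 * z  # HAMD-21-like location/scale

    return Cohort(
        spec=spec,
        parcellation=parcellation,
        subject_id=subject_id,
        group=groups,
        gender=gender,
        mean_fd=mean_fd,
        severity=severity,
        timeseries=timeseries,
        connectome=connectomes,
        basis=basis,
        truth_high_gain=truth,
    )


def _smooth_field(centroids: np.ndarray, length_scale: float, rng: np.random.Generator,
                  size: int = 1) -> np.ndarray:
    """Spatially autocorrelated Gaussian field(s) on spherical centroids."""
    dist = squareform(pdist(centroids))
    K = np.exp(-((dist / length_scale) ** 2) / 2)
    # squared-exponential kernels are numerically rank-deficient; sample
    # through the eigendecomposition with negative eigenvalues clipped
    w, V = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    Lc = V * np.sqrt(w)
    out = Lc @ rng.standard_normal((len(centroids), size))
    return out[:, 0] if size == 1 else out


def gen_expression(
    parcellation: Parcellation,
    n_genes: int,
    planted: np.ndarray | None = None,
    n_planted: int = 0,
    noise_sd: float = 1.0,
    seed: int = 0,
    planted_loadings: np.ndarray | None = None,
    length_scale: float = 0.5,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Region x gene expression matrix with a planted spatial component.

    The first ``n_planted`` genes are ``planted_map * loading + noise``;
    the rest are independent smooth spatial noise.  Columns are
    standardized (mean 0, sample sd 1).

    Returns the matrix, gene symbols, and the loading of each gene on the
    planted map (zero for pure-noise genes).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if n_planted > n_genes:
        raise ValueError("n_planted cannot exceed n_genes")
    if n_planted > 0 and planted is None:
        raise ValueError("a planted map is required when n_planted > 0")
    rng = np.random.default_rng(seed)
    n = parcellation.n_regions
    X = np.empty((n, n_genes))
    loadings = np.zeros(n_genes)
    if n_planted:
        planted = np.asarray(planted, dtype=float)
        pm = (planted - planted.mean()) / planted.std(ddof=1)
        if planted_loadings is None:
            lam = rng.uniform(0.5, 1.5, size=n_planted)
        else:
            lam = np.asarray(planted_loadings, dtype=float)
            if lam.shape != (n_planted,):
                raise ValueError("planted_loadings must have length n_planted")
        loadings[:n_planted] = lam
        X[:, :n_planted] = pm[:, None] * lam[None, :] + noise_sd * rng.standard_normal(
            (n, n_planted)
        )
    if n_genes > n_planted:
        X[:, n_planted:] = _smooth_field(
            parcellation.centroid, length_scale, rng, size=n_genes - n_planted
        )
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    symbols = [f"GENE{k + 1:05d}" for k in range(n_genes)]
    return X, symbols, loadings


def gen_annotation_map(
    parcellation: Parcellation,
    smoothness: float = 0.5,
    link: tuple[np.ndarray, float] | None = None,
    seed: int = 0,
    label: str = "synthetic",
) -> np.ndarray:
    """Smooth Gaussian annotation map, optionally correlated with a target.

    With ``link=(target, rho)`` the field is mixed with the standardized
    target so the Spearman correlation is approximately ``rho`` in
    expectation.
    """
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    rng = np.random.default_rng(seed)
    fieldvals = _smooth_field(parcellation.centroid, smoothness, rng)
    fieldvals = (fieldvals - fieldvals.mean()) / fieldvals.std(ddof=1)
    if link is None:
        return fieldvals
    target, rho = link
    if not -1.0 < rho < 1.0:
        raise ValueError("link correlation must lie strictly inside (-1, 1)")
    target = np.asarray(target, dtype=float)
    t = (target - target.mean()) / target.std(ddof=1)
    return rho * t + np.sqrt(1 - rho**2) * fieldvals
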