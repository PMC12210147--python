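"""Graph Fourier analysis of regional signals and the structural-decoupling index.

A regional time series ``x`` (regions x timepoints) is projected onto the
structural harmonics, ``x_hat = U^T x``, split with an ideal low/high-pass
filter at a cutoff harmonic, and reconstructed into a structure-coupled
part ``x_C`` and a structure-decoupled part ``x_D``.  The per-region SDI
is the energy ratio ``||x_D[r, :]|| / ||x_C[r, :]||`` pooled over time.

The cutoff follows the median-energy rule: the smallest harmonic index at
which the cumulative group-average energy spectral density reaches half
the total, never splitting a degenerate-eigenvalue block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structural import DEGENERACY_TOL, HarmonicBasis

__all__ = [
    "SpectralCoefficients",
    "zscore",
    "gft",
    "igft",
    "energy_spectral_density",
    "median_energy_cutoff",
    "split_filter",
    "sdi",
    "sdi_pipeline",
]


@dataclass
class SpectralCoefficients:
    """Harmonic-domain representation of one subject's signals.

    ``values[k, t]`` is the coefficient of harmonic ``k`` at timepoint
    ``t``; Parseval's identity ties its Frobenius norm to the signal's.
    """

    values: np.ndarray
    basis: HarmonicBasis
    subject_id: str = ""


def zscore(ts: np.ndarray) -> np.ndarray:
    """Standardize each region's signal across time (mean 0, sample sd 1).

    Uses the n-1 (sample) standard deviation.  A constant regional signal
    has no variance to standardize and is rejected by name.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError(f"expected a regions x timepoints matrix, got shape {ts.shape}")
    if ts.shape[1] < 2:
        raise ValueError("need at least 2 timepoints to z-score")
    sd = ts.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"region index {bad} has a constant signal; cannot z-score")
    return (ts - ts.mean(axis=1, keepdims=True)) / sd[:, None]


def gft(ts: np.ndarray, basis: HarmonicBasis, subject_id: str = "") -> SpectralCoefficients:
    """Graph Fourier transform: project signals onto the harmonic basis."""
    ts = np.asarray(ts, dtype=float)
    n = basis.n_regions
    if ts.shape[0] != n:
        raise ValueError(f"signal has {ts.shape[0]} regions but basis has {n}")
    return SpectralCoefficients(basis.eigenvectors.T @ ts, basis, subject_id)


def igft(coeffs: SpectralCoefficients) -> np.ndarray:
    """Inverse graph Fourier transform back to region space."""
    return coeffs.basis.eigenvectors @ coeffs.values


def energy_spectral_density(coeffs_by_subject: list[SpectralCoefficients]) -> np.ndarray:
    """Group-average energy per harmonic: mean over subjects and timepoints of x_hat^2."""
    if len(coeffs_by_subject) == 0:
        raise ValueError("need at least one subject")
    return np.mean([np.mean(c.values**2, axis=1) for c in coeffs_by_subject], axis=0)


def median_energy_cutoff(coeffs_by_subject: list[SpectralCoefficients]) -> int:
    """Cutoff harmonic index splitting the group energy spectrum in half.

    Returns the smallest ``C`` with ``sum(ESD[:C]) >= 0.5 * sum(ESD)``,
    promoted (never demoted) to the end of any degenerate-eigenvalue block
    it would otherwise split -- the SDI is only rotation-invariant within
    a degenerate block if the block sits entirely on one side of the cut.
    """
    esd = energy_spectral_density(coeffs_by_subject)
    # subjects may sit on different (e.g. per-group) bases; one shared
    # cutoff keeps SDI comparable across all of them, so the degenerate
    # block promotion must respect every basis's spectrum
    bases: list[HarmonicBasis] = []
    for c in coeffs_by_subject:
        if not any(b is c.basis or np.array_equal(b.eigenvalues, c.basis.eigenvalues)
                   for b in bases):
            bases.append(c.basis)
    total = esd.sum()
    cum = np.cumsum(esd)
    C = int(np.searchsorted(cum, 0.5 * total) + 1)
    C = min(C, len(esd) - 1)
    changed = True
    while changed:
        changed = False
        for b in bases:
            lam = b.eigenvalues
            while C < len(esd) - 1 and lam[C] - lam[C - 1] < DEGENERACY_TOL:
                C += 1
                changed = True
    return C


def split_filter(coeffs: SpectralCoefficients, cutoff: int) -> tuple[np.ndarray, np.ndarray]:
    """Ideal low/high-pass split at ``cutoff`` low harmonics.

    Returns the structure-coupled reconstruction ``x_C`` (harmonics
    1..cutoff) and the decoupled one ``x_D`` (the rest); they sum to the
    original signal.
    """
    n = coeffs.basis.n_regions
    if not 1 <= cutoff <= n - 1:
        raise ValueError(f"cutoff must be in [1, {n - 1}], got {cutoff}")
    U = coeffs.basis.eigenvectors
    low = coeffs.values.copy()
    low[cutoff:, :] = 0.0
    high = coeffs.values.copy()
    high[:cutoff, :] = 0.0
    return U @ low, U @ high


def sdi(x_coupled: np.ndarray, x_decoupled: np.ndarray, *, log2: bool = False) -> np.ndarray:
    """Structural-decoupling index per region.

    ``SDI_r = ||x_D[r, :]||_2 / ||x_C[r, :]||_2`` with norms pooled over
    all timepoints.  A region with zero coupled energy has no defined
    ratio and is rejected by name.
    """
    x_coupled = np.asarray(x_coupled, dtype=float)
    x_decoupled = np.asarray(x_decoupled, dtype=float)
    if x_coupled.shape != x_decoupled.shape:
        raise ValueError("coupled and decoupled parts must have matching shapes")
    nc = np.linalg.norm(x_coupled, axis=1)
    nd = np.linalg.norm(x_decoupled, axis=1)
    if np.any(nc == 0):
        bad = int(np.flatnonzero(nc == 0)[0])
        raise ValueError(
            f"region index {bad} has zero structure-coupled energy; SDI undefined"
        )
    ratio = nd / nc
    if log2:
        return np.log2(ratio)
    return ratio


def sdi_pipeline(
    timeseries: list[np.ndarray],
    basis: HarmonicBasis,
    *,
    cutoff: int | None = None,
    already_zscored: bool = False,
) -> tuple[np.ndarray, int]:
    """Full SDI computation for a group of subjects sharing one basis.

    z-scores each subject's signals, projects them onto the harmonics,
    estimates the median-energy cutoff from the group spectrum (unless
    ``cutoff`` is given), and returns a subjects x regions SDI matrix with
    the cutoff used.
    """
    coeffs = []
    for ts in timeseries:
        x = np.asarray(ts, dtype=float) if already_zscored else zscore(ts)
        coeffs.append(gft(x, basis))
    if cutoff is None:
        cutoff = median_energy_cutoff(coeffs)
    maps = []
    for c in coeffs:
        x_c, x_d = split_filter(c, cutoff)
        maps.append(sdi(x_c, x_d))
    return np.array(maps), cutoff
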