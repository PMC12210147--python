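"""Structural connectome preparation and Laplacian harmonics.

Turns raw structural connectivity matrices (fractional anisotropy x
streamline count, or any symmetric nonnegative weighting) into a
normalized group connectome and its harmonic basis -- the eigenvectors of
the symmetric normalized Laplacian ``L = I - D^{-1/2} A_u D^{-1/2}`` --
which serve as the graph Fourier basis for all downstream spectral
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HarmonicBasis",
    "validate_connectome",
    "volume_normalize",
    "group_average",
    "symmetric_normalize",
    "harmonics",
    "nodal_degree",
]

#: Eigenvalues closer than this are treated as a degenerate block.
DEGENERACY_TOL = 1e-8


@dataclass
class HarmonicBasis:
    """Orthonormal graph Fourier basis of a normalized Laplacian.

    Attributes
    ----------
    eigenvectors : (n, n) ndarray
        Structural harmonics as columns, sorted by ascending graph
        frequency and sign-fixed (largest-magnitude entry positive).
    eigenvalues : (n,) ndarray
        Graph frequencies, ascending, in [0, 2].
    cutoff : int or None
        Number of low-frequency harmonics in the "coupled" band; set by
        :func:`sdikit.gsp.median_energy_cutoff` or by a generator.
    source : str
        Label of the group connectome the basis was built from.
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    cutoff: int | None = None
    source: str = ""

    @property
    def n_regions(self) -> int:
        return self.eigenvectors.shape[0]

    def with_cutoff(self, cutoff: int) -> "HarmonicBasis":
        if not 1 <= cutoff <= self.n_regions - 1:
            raise ValueError(f"cutoff must be in [1, {self.n_regions - 1}], got {cutoff}")
        return HarmonicBasis(self.eigenvectors, self.eigenvalues, cutoff, self.source)


def validate_connectome(sc: np.ndarray, *, tol: float = 1e-10) -> np.ndarray:
    """Check that ``sc`` is a square symmetric hollow nonnegative matrix."""
    sc = np.asarray(sc, dtype=float)
    if sc.ndim != 2 or sc.shape[0] != sc.shape[1]:
        raise ValueError(f"connectome must be square, got shape {sc.shape}")
    if not np.allclose(sc, sc.T, atol=tol, rtol=0):
        raise ValueError("connectome is not symmetric")
    if np.any(np.abs(np.diag(sc)) > tol):
        raise ValueError("connectome diagonal is not zero")
    if np.any(sc < -tol):
        raise ValueError("connectome has negative weights")
    return sc


def volume_normalize(sc: np.ndarray, volumes: np.ndarray) -> np.ndarray:
    """Divide each edge weight by the summed volume of its two endpoint regions.

    ``out[i, j] = sc[i, j] / (volumes[i] + volumes[j])`` -- corrects for
    larger parcels accumulating more streamlines.
    """
    sc = validate_connectome(sc)
    volumes = np.asarray(volumes, dtype=float)
    if volumes.shape != (sc.shape[0],):
        raise ValueError(f"expected {sc.shape[0]} volumes, got shape {volumes.shape}")
    if np.any(volumes <= 0):
        bad = int(np.flatnonzero(volumes <= 0)[0])
        raise ValueError(f"region volume must be positive; region index {bad} has {volumes[bad]}")
    denom = volumes[:, None] + volumes[None, :]
    out = sc / denom
    np.fill_diagonal(out, 0.0)
    return out


def group_average(scs: list[np.ndarray]) -> np.ndarray:
    """Entrywise mean of a list of same-shape connectomes (the group connectome A_u)."""
    if len(scs) == 0:
        raise ValueError("need at least one connectome to average")
    first = np.asarray(scs[0], dtype=float)
    for k, m in enumerate(scs):
        if np.asarray(m).shape != first.shape:
            raise ValueError(
                f"connectome {k} has shape {np.asarray(m).shape}, expected {first.shape}"
            )
    return np.mean([np.asarray(m, dtype=float) for m in scs], axis=0)


def symmetric_normalize(sc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetrically normalize a connectome: ``A = D^{-1/2} sc D^{-1/2}``.

    ``D`` is the diagonal of weighted degrees (row sums).  The spectrum of
    A lies in [-1, 1], so the Laplacian ``I - A`` has spectrum in [0, 2].

    Returns
    -------
    A : (n, n) ndarray
    degrees : (n,) ndarray
        The weighted degrees used for normalization.

    Raises
    ------
    ValueError
        If any region is isolated (zero strength).  Isolated nodes are a
        hard error: silently regularizing them would perturb the harmonics
        unpredictably.
    """
    sc = validate_connectome(sc)
    degrees = sc.sum(axis=1)
    if np.any(degrees <= 0):
        bad = np.flatnonzero(degrees <= 0)
        raise ValueError(
            f"isolated region(s) with zero strength at index {bad.tolist()}; "
            "cannot symmetrically normalize"
        )
    d_isqrt = 1.0 / np.sqrt(degrees)
    A = sc * d_isqrt[:, None] * d_isqrt[None, :]
    return A, degrees


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Make each eigenvector's largest-magnitude entry positive (ties: lowest index)."""
    U = U.copy()
    for k in range(U.shape[1]):
        col = U[:, k]
        # argmax returns the first maximizer, which resolves |entry| ties
        # at the lowest region index
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            U[:, k] = -col
    return U


def _order_degenerate_blocks(lam: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Return column order with lexicographic ordering inside degenerate blocks."""
    order = np.arange(len(lam))
    start = 0
    while start < len(lam):
        stop = start + 1
        while stop < len(lam) and lam[stop] - lam[start] < DEGENERACY_TOL:
            stop += 1
        if stop - start > 1:
            block = order[start:stop]
            block = sorted(block, key=lambda k: tuple(np.round(U[:, k], 12)))
            order[start:stop] = block
        start = stop
    return order


def harmonics(A: np.ndarray, *, source: str = "") -> HarmonicBasis:
    """Eigendecompose ``L = I - A`` into a deterministic harmonic basis.

    Eigenpairs are sorted by ascending eigenvalue; each eigenvector is
    sign-fixed (largest-magnitude entry positive) and degenerate blocks are
    ordered lexicographically so the basis is reproducible bit-for-bit.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.allclose(A, A.T, atol=1e-10, rtol=0):
        raise ValueError("adjacency is not symmetric")
    L = np.eye(A.shape[0]) - A
    lam, U = np.linalg.eigh(L)
    U = _fix_signs(U)
    order = _order_degenerate_blocks(lam, U)
    return HarmonicBasis(eigenvectors=U[:, order], eigenvalues=lam[order], source=source)


def nodal_degree(sc: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Binary degree: count of off-diagonal weights strictly above ``threshold``."""
    sc = validate_connectome(sc)
    above = sc > threshold
    np.fill_diagonal(above, False)
    return above.sum(axis=1).astype(int)
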