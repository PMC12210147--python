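"""Transcriptome association of a group-difference map by partial least squares.

A region-indexed response (the signed t-map of SDI alteration) is
regressed on a region x gene expression matrix with PLS; component
significance is assessed by refitting under spin permutations of the
response, and per-gene bootstrap Z-scores (weight / bootstrap SE over
region resamples) define the PLS1+ (Z > 2.58) and PLS1- (Z < -2.58) gene
lists.  Weights of named disorder gene sets can be compared by label
permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spatial import SpinNull

__all__ = [
    "PLSModel",
    "pls_fit",
    "component_spin_test",
    "bootstrap_gene_z",
    "gene_set_weight_comparison",
    "Z_CRITICAL",
]

#: two-sided 1% normal quantile used for gene-list membership
Z_CRITICAL = 2.58


@dataclass
class PLSModel:
    """Fitted PLS regression of a regional response on gene expression.

    ``weights[:, k]`` is the unit-norm gene weight vector of component k;
    ``scores[:, k]`` the regional gene scores; ``explained_variance`` the
    percentage of response variance captured incrementally by each
    component (components in fit order).
    """

    weights: np.ndarray  # (genes, K), unit-norm columns
    scores: np.ndarray  # (regions, K)
    explained_variance: np.ndarray  # (K,) percent of y variance
    y_loadings: np.ndarray  # (K,)
    genes: list[str] = field(default_factory=list)
    spin_p: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """Explicit NIPALS deflation sequence for a univariate response.

    Each component's weight maximizes covariance between the X-score and
    the current (deflated) response; X and y are deflated by the fitted
    score after each component.
    """
    Xk = X.copy()
    yk = y.copy()
    n, p = X.shape
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    Q = np.zeros(n_components)
    for k in range(n_components):
        w = Xk.T @ yk
        nw = np.linalg.norm(w)
        if nw == 0:
            # response fully explained; remaining components are null
            break
        w /= nw
        t = Xk @ w
        tt = t @ t
        if tt == 0:
            break
        p_load = Xk.T @ t / tt
        q = yk @ t / tt
        Xk -= np.outer(t, p_load)
        yk = yk - q * t
        W[:, k], T[:, k], Q[k] = w, t, q
    return W, T, Q


def pls_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 5,
    genes: list[str] | None = None,
) -> PLSModel:
    """Fit PLS of a regional response on a standardized expression matrix.

    ``X`` is regions x genes (columns standardized); ``y`` is the signed
    regional response, centered internally.  Explained variance per
    component is the incremental R-squared of ``y`` on the cumulative
    scores, in percent.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError(f"response length {len(y)} != {n} regions")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if n < n_components + 2:
        raise ValueError(f"need at least {n_components + 2} regions for {n_components} components")
    if np.std(y) == 0:
        raise ValueError("constant response; PLS undefined")
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    W, T, Q = _nipals_pls1(Xc, yc, n_components)
    ss_tot = yc @ yc
    ev = np.zeros(n_components)
    prev = 0.0
    for k in range(n_components):
        Tk = T[:, : k + 1]
        coef, *_ = np.linalg.lstsq(Tk, yc, rcond=None)
        r2 = 1 - np.sum((yc - Tk @ coef) ** 2) / ss_tot
        ev[k] = 100 * (r2 - prev)
        prev = r2
    return PLSModel(
        weights=W,
        scores=T,
        explained_variance=ev,
        y_loadings=Q,
        genes=list(genes) if genes is not None else [],
    )


def component_spin_test(
    X: np.ndarray, y: np.ndarray, null: SpinNull, n_components: int = 5
) -> np.ndarray:
    """Spin-permutation p value for each component's explained variance.

    The response is spun, the PLS refitted, and each component's explained
    variance compared with the observed one:
    ``p_k = (1 + #{EV_perm_k >= EV_obs_k}) / (n_perm + 1)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != null.n_regions:
        raise ValueError("null was built for a different parcellation size")
    obs = pls_fit(X, y, n_components).explained_variance
    count = np.zeros(n_components)
    for k in range(null.n_perm):
        ev = pls_fit(X, null.apply(y, k), n_components).explained_variance
        count += ev >= obs
    return (1 + count) / (null.n_perm + 1)


def bootstrap_gene_z(
    X: np.ndarray,
    y: np.ndarray,
    genes: list[str],
    component: int = 0,
    n_boot: int = 1000,
    seed: int = 0,
    n_components: int | None = None,
) -> pd.DataFrame:
    """Bootstrap Z-score of each gene's weight on one PLS component.

    Regions (observations) are resampled with replacement; each bootstrap
    weight vector is sign-aligned to the original (flipped if its
    correlation with the original weights is negative); Z is the original
    weight divided by the bootstrap standard error.  Genes enter the
    ``PLS1+`` list when Z > 2.58 and ``PLS1-`` when Z < -2.58.

    Returns a table (gene, weight, bootstrap_se, z, list) plus the number
    of redrawn degenerate resamples in ``.attrs['n_redrawn']``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    K = component + 1 if n_components is None else n_components
    model = pls_fit(X, y, K, genes=genes)
    w_orig = model.weights[:, component]
    rng = np.random.default_rng(seed)
    n = len(y)
    boots = np.empty((n_boot, len(w_orig)))
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.std(y[idx]) > 0:
                break
            n_redrawn += 1
        wb = pls_fit(X[idx], y[idx], K).weights[:, component]
        if wb @ w_orig < 0:
            wb = -wb
        boots[b] = wb
    se = boots.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, w_orig / se, 0.0)
    membership = np.where(z > Z_CRITICAL, "PLS1+", np.where(z < -Z_CRITICAL, "PLS1-", "none"))
    out = pd.DataFrame(
        {"gene": genes, "weight": w_orig, "bootstrap_se": se, "z": z, "list": membership}
    )
    out.attrs["n_redrawn"] = n_redrawn
    out.attrs["component"] = component
    return out


def gene_set_weight_comparison(
    table: pd.DataFrame,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation comparison of mean PLS weights between named gene sets.

    For every pair of sets, the statistic is the difference in mean weight;
    the null shuffles set labels over the union of the two sets' genes.
    Two-sided p with the add-one convention.
    """
    weights = dict(zip(table["gene"], table["weight"]))
    resolved: dict[str, np.ndarray] = {}
    for name, members in sets.items():
        vals = np.array([weights[g] for g in members if g in weights])
        if len(vals) == 0:
            raise ValueError(f"gene set '{name}' has no genes in the expression universe")
        resolved[name] = vals
    rng = np.random.default_rng(seed)
    rows = []
    names = list(resolved)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = resolved[names[i]], resolved[names[j]]
            obs = a.mean() - b.mean()
            pool = np.concatenate([a, b])
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(pool)
                stat = perm[: len(a)].mean() - perm[len(a):].mean()
                if abs(stat) >= abs(obs):
                    count += 1
            rows.append(
                {
                    "set_a": names[i],
                    "set_b": names[j],
                    "mean_diff": obs,
                    "p": (1 + count) / (n_perm + 1),
                }
            )
    return pd.DataFrame(rows)
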