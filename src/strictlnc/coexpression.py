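"""Signed co-expression networks with biweight midcorrelation.

The pipeline mirrors the weighted-network workflow standard in the
field: variance-stabilized counts -> robust pairwise correlation
(biweight midcorrelation, tuning constant 9, Pearson fallback when the
MAD vanishes) -> signed adjacency a_ij = ((1 + cor_ij)/2)^beta ->
topological overlap (TOM) similarity -> average-linkage clustering with
a height cut honoring a minimum module size -> module eigengenes (first
right-singular vector of the standardized module expression).

The count normalization is a variance-stabilizing substitute for the
full regularized transform: median-of-ratios size factors followed by
log2(count/size_factor + 1).  Downstream correlations are rank-robust
to this choice; it is echoed in output metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .annotation_io import ValidationError


@dataclass
class NetworkConfig:
    beta: float = 12.0
    network_type: str = "signed"
    correlation: str = "bicor"
    bicor_c: float = 9.0
    min_module_size: int = 50
    #: static cut height as a fraction of the tallest merge in the tree
    cut_height_fraction: float = 0.99
    cut_height: float | None = None
    merge_modules: bool = False  # modules are reported unmerged

    def __post_init__(self):
        if self.beta < 1:
            raise ValidationError("beta must be >= 1")
        if self.min_module_size < 2:
            raise ValidationError("min_module_size must be >= 2")


@dataclass
class ModuleAssignment:
    labels: pd.Series  # gene_id -> module index; 0 = unassigned
    sizes: dict[int, int]

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    @property
    def n_modules(self) -> int:
        return len([m for m in self.sizes if m != 0])


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios size factors, then log2(count/size_factor + 1)."""
    if (counts < 0).any().any():
        raise ValidationError("counts must be non-negative")
    if (counts.sum(axis=0) == 0).any():
        bad = counts.columns[counts.sum(axis=0) == 0].tolist()
        raise ValidationError(f"sample(s) with all-zero counts: {bad}")
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValidationError("no gene with all-positive counts for size factors")
    log_geomean = np.log(positive).mean(axis=1)
    size_factors = np.exp(
        (np.log(positive).sub(log_geomean, axis=0)).median(axis=0)
    )
    return np.log2(counts.div(size_factors, axis=1) + 1.0)


def _bicor_prepare(x: np.ndarray, c: float = 9.0) -> np.ndarray:
    """Median/MAD-weighted, centered copy of x; Pearson-style (mean-centered,
    unit weights) when the MAD is zero."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x - x.mean()
    u = (x - med) / (c * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1)
    return (x - med) * w


def bicor(x, y, c: float = 9.0) -> float:
    """Biweight midcorrelation of two equal-length vectors, in [-1, 1].

    NaN when both vectors are degenerate (zero variance under both the
    robust and the Pearson fallback weighting).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("bicor: length mismatch")
    if x.size < 3:
        raise ValidationError("bicor needs vectors of length >= 3")
    xt = _bicor_prepare(x, c)
    yt = _bicor_prepare(y, c)
    nx = np.sqrt((xt**2).sum())
    ny = np.sqrt((yt**2).sum())
    if nx == 0 or ny == 0:
        return float("nan")
    return float(np.clip((xt * yt).sum() / (nx * ny), -1.0, 1.0))


def bicor_matrix(X: pd.DataFrame | np.ndarray, c: float = 9.0) -> np.ndarray:
    """Pairwise bicor between the rows of X (genes x samples)."""
    A = np.asarray(X, dtype=float)
    T = np.empty_like(A)
    for i in range(A.shape[0]):
        T[i] = _bicor_prepare(A[i], c)
    norms = np.sqrt((T**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        Tn = T / norms[:, None]
    corr = np.clip(Tn @ Tn.T, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def signed_adjacency(corr: np.ndarray, beta: float) -> np.ndarray:
    """a_ij = ((1 + cor_ij)/2)^beta with unit diagonal."""
    adj = ((1.0 + np.asarray(corr)) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (l_ij + a_ij)/(min(k_i,k_j)+1-a_ij)."""
    A = np.asarray(adj, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A
    k = A.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    tom = (L + A) / (kmin + 1.0 - A)
    np.fill_diagonal(tom, 1.0)
    return tom


def scale_free_fit(
    corr: np.ndarray,
    beta_grid: list[float] | None = None,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Scale-free topology fit table over a grid of soft powers.

    For each beta: connectivity k_i = sum_{j!=i} a_ij, binned; log10
    frequency regressed on log10 mean k per bin.  The reported R^2 is
    signed (negated when the slope is positive) and NaN when degenerate.
    """
    if corr.shape[0] < 50:
        warnings.warn("scale_free_fit on < 50 genes is unreliable")
    if beta_grid is None:
        beta_grid = list(range(1, 21))
    rows = []
    for beta in beta_grid:
        adj = signed_adjacency(corr, beta)
        np.fill_diagonal(adj, 0.0)
        k = adj.sum(axis=1)
        mean_k = float(k.mean())
        if np.allclose(k, k[0]):
            rows.append({"beta": beta, "r_squared": np.nan, "mean_connectivity": mean_k})
            continue
        edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
        idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
        freq = np.bincount(idx, minlength=n_bins).astype(float)
        centers = np.array(
            [k[idx == b].mean() if freq[b] else np.nan for b in range(n_bins)]
        )
        ok = (freq > 0) & (centers > 0)
        if ok.sum() < 3:
            rows.append({"beta": beta, "r_squared": np.nan, "mean_connectivity": mean_k})
            continue
        lx = np.log10(centers[ok])
        ly = np.log10(freq[ok])
        slope, intercept = np.polyfit(lx, ly, 1)
        pred = slope * lx + intercept
        ss_res = ((ly - pred) ** 2).sum()
        ss_tot = ((ly - ly.mean()) ** 2).sum()
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        if slope > 0:
            r2 = -r2
        rows.append({"beta": beta, "r_squared": r2, "mean_connectivity": mean_k})
    return pd.DataFrame(rows)


def detect_modules(
    normalized: pd.DataFrame, cfg: NetworkConfig | None = None
) -> ModuleAssignment:
    """Cluster the TOM dissimilarity and label modules by decreasing size.

    Genes in clusters below ``min_module_size`` (and zero-variance genes)
    go to module 0.  Modules are never merged by eigengene similarity.
    """
    cfg = cfg or NetworkConfig()
    genes = normalized.index
    if len(genes) < cfg.min_module_size:
        warnings.warn(
            f"{len(genes)} genes < min_module_size {cfg.min_module_size}; "
            "everything goes to module 0"
        )
        return ModuleAssignment(
            pd.Series(0, index=genes, name="module"), {0: len(genes)}
        )
    if normalized.shape[1] < 4:
        raise ValidationError("module detection needs >= 4 samples")

    variances = normalized.var(axis=1)
    active = genes[variances > 0]
    labels = pd.Series(0, index=genes, name="module")
    if len(active) >= cfg.min_module_size:
        X = normalized.loc[active]
        corr = bicor_matrix(X, cfg.bicor_c)
        adj = signed_adjacency(corr, cfg.beta)
        dissim = 1.0 - tom_similarity(adj)
        np.fill_diagonal(dissim, 0.0)
        Z = linkage(squareform(dissim, checks=False), method="average")
        cut = cfg.cut_height
        if cut is None:
            cut = cfg.cut_height_fraction * Z[:, 2].max()
        raw = fcluster(Z, t=cut, criterion="distance")
        counts = pd.Series(raw).value_counts()
        keep = counts[counts >= cfg.min_module_size].index
        # relabel by decreasing size, 1-based; the rest to 0
        ordered = sorted(keep, key=lambda m: (-counts[m], m))
        remap = {m: i + 1 for i, m in enumerate(ordered)}
        labels.loc[active] = [remap.get(m, 0) for m in raw]
    sizes = labels.value_counts().to_dict()
    return ModuleAssignment(labels, {int(k): int(v) for k, v in sizes.items()})


@dataclass
class ModuleEigengene:
    module: int
    vector: pd.Series  # unit-norm over samples
    variance_explained: float


def compute_eigengenes(
    normalized: pd.DataFrame, modules: ModuleAssignment
) -> tuple[dict[int, ModuleEigengene], pd.Series]:
    """Module eigengenes plus each gene's correlation with its eigengene.

    Gene rows are z-scored; the eigengene is the first right-singular
    vector, sign-oriented to correlate positively with the module's mean
    standardized profile.
    """
    eigengenes: dict[int, ModuleEigengene] = {}
    membership = pd.Series(np.nan, index=normalized.index, name="kME")
    for module in sorted(m for m in modules.sizes if m != 0):
        member_ids = modules.members(module)
        X = normalized.loc[member_ids]
        sd = X.std(axis=1, ddof=0)
        if (sd == 0).any():
            warnings.warn(
                f"module {module}: dropping {(sd == 0).sum()} zero-variance gene(s)"
            )
            X = X[sd > 0]
            sd = sd[sd > 0]
        if len(X) < 2:
            continue
        Z = X.sub(X.mean(axis=1), axis=0).div(sd, axis=0)
        _u, s, vt = np.linalg.svd(Z.values, full_matrices=False)
        eg = vt[0]
        mean_profile = Z.values.mean(axis=0)
        if np.corrcoef(eg, mean_profile)[0, 1] < 0:
            eg = -eg
        var_explained = float(s[0] ** 2 / (s**2).sum())
        vec = pd.Series(eg, index=normalized.columns, name=f"ME{module}")
        eigengenes[module] = ModuleEigengene(module, vec, var_explained)
        zc = Z.values - Z.values.mean(axis=1, keepdims=True)
        egc = eg - eg.mean()
        kme = (zc @ egc) / (
            np.sqrt((zc**2).sum(axis=1)) * np.sqrt((egc**2).sum())
        )
        membership.loc[Z.index] = kme
    return eigengenes, membership


def eigengene_frame(eigengenes: dict[int, ModuleEigengene]) -> pd.DataFrame:
    """Samples x modules matrix of eigengene values."""
    return pd.DataFrame({f"ME{m}": e.vector for m, e in sorted(eigengenes.items())})
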