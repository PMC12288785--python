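"""Signed weighted co-expression network construction and module analysis.

The network is built from family-adjusted log-scale expression of the
filtered genes:

1. biweight midcorrelation (bicor) between all gene pairs, with a
   ``maxPOutliers`` cap so no more than that fraction of samples per side
   can be zero-weighted as outliers;
2. signed adjacency a_ij = ((1 + cor_ij)/2)^beta, where the soft threshold
   beta is chosen as the smallest candidate reaching a signed scale-free
   topology fit R^2 of 0.85 (or fixed, e.g. at the conventional 14);
3. signed topological overlap TOM_ij, crediting shared neighbours;
4. average-linkage hierarchical clustering of 1 - TOM with a static cut,
   small clusters relegated to the unassigned label M0, and iterative
   merging of modules whose eigengenes correlate above ``merge_cor``.

Total connectivity kTotal_i = sum_j a_ij is the pleiotropy proxy used by
the permutation comparisons; kME is the correlation of any profile (gene or
exon) with a module eigengene, which is what the exon "atomization" of a
differentially spliced gene uses to place individual exons into modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

__all__ = [
    "NetworkConfig",
    "NetworkResult",
    "bicor_matrix",
    "bicor_transform",
    "pick_soft_threshold",
    "adjacency",
    "tom",
    "connectivity",
    "detect_modules",
    "kme",
    "atomize_gene",
    "extract_subnetwork",
    "build_network",
]

MAX_NETWORK_GENES = 6000


@dataclass
class NetworkConfig:
    correlation: str = "bicor"  # or "pearson"
    max_p_outliers: float = 0.10
    beta_candidates: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)
    beta: int | None = None  # fixed soft threshold; None = pick from candidates
    signed_r2_cut: float = 0.85
    cut_height: float = 0.99
    min_module_size: int = 20
    merge_cor: float = 0.75
    seed: int = 1234

    def validate(self) -> None:
        if not 0.0 <= self.max_p_outliers <= 0.5:
            raise ValueError("max_p_outliers must be in [0, 0.5]")
        if self.beta is not None and self.beta < 1:
            raise ValueError("beta must be >= 1")
        if any(b < 1 for b in self.beta_candidates):
            raise ValueError("beta candidates must be >= 1")
        if self.correlation not in ("bicor", "pearson"):
            raise ValueError(f"unknown correlation {self.correlation!r}")


@dataclass
class NetworkResult:
    """Module labels, connectivity and eigengenes of one network build."""

    gene_ids: list[str]
    sample_ids: list[str]
    labels: dict[str, str]  # gene -> "M0", "M1", ...
    k_total: pd.Series
    eigengenes: pd.DataFrame  # samples x modules
    soft_threshold_table: pd.DataFrame
    beta: int
    adjacency_matrix: np.ndarray = field(repr=False)
    expression: pd.DataFrame = field(repr=False)  # genes x samples used
    config: NetworkConfig = field(default_factory=NetworkConfig)

    def module_members(self, module: str) -> list[str]:
        return [g for g in self.gene_ids if self.labels[g] == module]

    def module_sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()


# ---------------------------------------------------------------------------
# correlation


def bicor_transform(x: np.ndarray, max_p_outliers: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise biweight transform used by bicor.

    Returns (xt, pearson_fallback): xt has rows (x - med) * w normalized to
    unit length; rows with zero MAD fall back to the centred/normalized
    (Pearson) transform and are flagged.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x, axis=1, keepdims=True)
    dev = x - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    fallback = (mad[:, 0] == 0) | ~np.isfinite(mad[:, 0])

    with np.errstate(divide="ignore", invalid="ignore"):
        u = dev / (9.0 * mad)
    u[fallback] = 0.0

    if max_p_outliers < 0.5:
        # cap each side so at most max_p_outliers of samples get zero weight
        q_lo = np.quantile(u, max_p_outliers, axis=1, keepdims=True)
        q_hi = np.quantile(u, 1.0 - max_p_outliers, axis=1, keepdims=True)
        scale_neg = np.maximum(1.0, -q_lo)
        scale_pos = np.maximum(1.0, q_hi)
        u = np.where(u < 0, u / scale_neg, u / scale_pos)

    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    xt = dev * w
    # Pearson fallback rows: plain centring
    if fallback.any():
        cen = x[fallback] - x[fallback].mean(axis=1, keepdims=True)
        xt[fallback] = cen
    norm = np.sqrt((xt**2).sum(axis=1, keepdims=True))
    zero = norm[:, 0] == 0
    norm[zero] = 1.0
    xt = xt / norm
    xt[zero] = np.nan
    return xt, fallback


def bicor_matrix(expr: np.ndarray, max_p_outliers: float = 0.10) -> np.ndarray:
    """Biweight midcorrelation between all rows of ``expr`` (genes x samples).

    Genes with zero median absolute deviation fall back to Pearson (a
    warning is emitted); constant genes yield NaN rows.
    """
    x = np.asarray(expr, dtype=float)
    if x.shape[1] < 4:
        raise ValueError("bicor needs at least 4 samples")
    xt, fallback = bicor_transform(x, max_p_outliers)
    if fallback.any():
        warnings.warn(
            f"{int(fallback.sum())} gene(s) with zero MAD fell back to Pearson",
            stacklevel=2,
        )
    c = xt @ xt.T
    np.clip(c, -1.0, 1.0, out=c)
    np.fill_diagonal(c, 1.0)
    c[np.isnan(xt[:, 0]), :] = np.nan
    c[:, np.isnan(xt[:, 0])] = np.nan
    return c


def _correlate(expr: np.ndarray, cfg: NetworkConfig) -> np.ndarray:
    if cfg.correlation == "bicor":
        return bicor_matrix(expr, cfg.max_p_outliers)
    c = np.corrcoef(expr)
    np.clip(c, -1.0, 1.0, out=c)
    return c


# ---------------------------------------------------------------------------
# adjacency / soft threshold / TOM


def adjacency(cor: np.ndarray, beta: float, signed: bool = True) -> np.ndarray:
    """Signed adjacency ((1+cor)/2)^beta (or |cor|^beta unsigned), zero diagonal."""
    if signed:
        a = ((1.0 + cor) / 2.0) ** beta
    else:
        a = np.abs(cor) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def connectivity(adj: np.ndarray) -> np.ndarray:
    """kTotal per gene: sum of adjacencies to all other genes."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    return a.sum(axis=1)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log regression of connectivity frequency.

    Bins k into ``n_bins`` equal-width bins, regresses log10(freq) on
    log10(mean k per bin) and returns -sign(slope) * R^2, so positive
    values indicate the decreasing power-law shape of a scale-free network.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 10:
        return np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        m = which == b
        if m.sum() == 0:
            continue
        xs.append(np.log10(k[m].mean()))
        ys.append(np.log10(m.sum() / k.size))
    if len(xs) < 3:
        return np.nan
    xs, ys = np.array(xs), np.array(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * xs + intercept
    ss_res = ((ys - pred) ** 2).sum()
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2)


def pick_soft_threshold(
    expr: np.ndarray,
    candidates=None,
    r2_cut: float = 0.85,
    cfg: NetworkConfig | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft threshold from the scale-free topology fit.

    Returns the smallest candidate whose signed R^2 reaches ``r2_cut``; if
    none does, the argmax candidate is returned and flagged in the table
    (column ``fallback``). The diagnostic table reports signed R^2 and mean
    connectivity for every candidate.
    """
    cfg = cfg or NetworkConfig()
    if candidates is None:
        candidates = cfg.beta_candidates
    if expr.shape[0] < 30:
        raise ValueError("soft-threshold fit needs at least 30 genes")
    cor = _correlate(expr, cfg)
    rows = []
    for b in candidates:
        a = adjacency(cor, b, signed=True)
        k = connectivity(a)
        rows.append(
            {
                "beta": b,
                "signed_r2": scale_free_fit(k),
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows)
    reach = table[table["signed_r2"] >= r2_cut]
    if len(reach):
        beta = int(reach["beta"].iloc[0])
        table["fallback"] = False
    else:
        beta = int(table.loc[table["signed_r2"].idxmax(), "beta"])
        table["fallback"] = True
        warnings.warn(
            f"no candidate reached signed R^2 {r2_cut}; using argmax beta={beta}",
            stacklevel=2,
        )
    return beta, table


def tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with unit diagonal. Input must be symmetric with values in [0, 1].
    """
    a = np.asarray(adj, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # with zero diagonal this is sum over u != i (and the
    # u = j term contributes a_ij * a_jj = 0, so third parties only)
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    t = num / den
    np.fill_diagonal(t, 1.0)
    return t


# ---------------------------------------------------------------------------
# modules


def _eigengene(expr_block: np.ndarray) -> np.ndarray:
    """First principal component of z-scored member expression (unit norm),
    sign-oriented so the mean correlation with members is positive."""
    z = expr_block - expr_block.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = z / sd
    # samples-dimension eigenvector of the gene covariance
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    e = e / np.linalg.norm(e)
    mean_cor = np.mean([np.corrcoef(e, row)[0, 1] for row in z])
    if mean_cor < 0:
        e = -e
    return e


def detect_modules(
    tom_matrix: np.ndarray,
    expr: np.ndarray,
    gene_ids: list[str],
    cut_height: float = 0.99,
    min_size: int = 20,
    merge_cor: float = 0.75,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Clusters below ``min_size`` go to M0; modules whose eigengenes correlate
    at or above ``merge_cor`` are merged iteratively (most correlated pair
    first); surviving modules are relabelled M1, M2, ... by decreasing size
    with ties broken by the lexicographically smallest member gene id.

    Returns (labels, eigengene table with samples as rows).
    """
    n = tom_matrix.shape[0]
    diss = 1.0 - tom_matrix
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    link = average(squareform(diss, checks=False))
    raw = fcluster(link, t=cut_height, criterion="distance")

    # order-independent grouping: collect clusters, filter by size
    clusters: dict[int, list[int]] = {}
    for i, c in enumerate(raw):
        clusters.setdefault(int(c), []).append(i)
    modules = [idx for idx in clusters.values() if len(idx) >= min_size]

    # iterative eigengene merging
    while len(modules) > 1:
        eigs = [_eigengene(expr[idx]) for idx in modules]
        m = len(modules)
        best, best_cor = None, merge_cor
        for i in range(m):
            for j in range(i + 1, m):
                c = float(np.corrcoef(eigs[i], eigs[j])[0, 1])
                if c >= best_cor:
                    best_cor, best = c, (i, j)
        if best is None:
            break
        i, j = best
        modules[i] = modules[i] + modules[j]
        del modules[j]

    # relabel by decreasing size; ties by smallest member gene id
    def sort_key(idx):
        return (-len(idx), min(gene_ids[i] for i in idx))

    modules.sort(key=sort_key)
    labels = {g: "M0" for g in gene_ids}
    eig_cols = {}
    for m, idx in enumerate(modules, start=1):
        name = f"M{m}"
        for i in idx:
            labels[gene_ids[i]] = name
        eig_cols[name] = _eigengene(expr[idx])
    eigengenes = pd.DataFrame(eig_cols)
    return labels, eigengenes


# ---------------------------------------------------------------------------
# kME / atomization / subnetworks


def kme(
    profiles: np.ndarray,
    eigengenes: pd.DataFrame,
    profile_ids: list[str],
    correlation: str = "bicor",
    max_p_outliers: float = 0.10,
) -> pd.DataFrame:
    """Correlation of each profile with each module eigengene.

    Uses the same correlation flavour as the network. Constant profiles get
    a NaN row.
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    e = eigengenes.to_numpy().T  # modules x samples
    if profiles.shape[1] != e.shape[1]:
        raise ValueError("profiles and eigengenes cover different samples")
    stacked = np.vstack([profiles, e])
    if correlation == "bicor":
        xt, _ = bicor_transform(stacked, max_p_outliers)
        c = xt @ xt.T
    else:
        sd = stacked.std(axis=1)
        cen = stacked - stacked.mean(axis=1, keepdims=True)
        norm = np.sqrt((cen**2).sum(axis=1, keepdims=True))
        norm[norm == 0] = np.nan
        z = cen / norm
        c = z @ z.T
    np.clip(c, -1.0, 1.0, out=c)
    k = profiles.shape[0]
    out = c[:k, k:]
    return pd.DataFrame(out, index=profile_ids, columns=list(eigengenes.columns))


def atomize_gene(
    gene_id: str,
    exon_profiles: pd.DataFrame,
    net: NetworkResult,
    min_kme: float = 0.5,
) -> pd.DataFrame:
    """Assign each exon of a gene to the module its profile best tracks.

    ``exon_profiles`` are the gene's exon expression profiles (log scale,
    family-adjusted, same samples as the network), rows indexed by exon id.
    Each exon goes to the module maximizing kME if that kME >= ``min_kme``,
    else M0. Returns the full kME table with ``assigned`` and ``best_kme``
    columns appended.
    """
    if exon_profiles.shape[0] == 0:
        raise ValueError(f"gene {gene_id!r} has no exon profiles")
    if list(exon_profiles.columns) != list(net.eigengenes.index):
        # eigengene rows are sample positions; require same count at least
        if exon_profiles.shape[1] != net.eigengenes.shape[0]:
            raise ValueError("exon profiles and network cover different samples")
    table = kme(
        exon_profiles.to_numpy(),
        net.eigengenes,
        list(exon_profiles.index),
        correlation=net.config.correlation,
        max_p_outliers=net.config.max_p_outliers,
    )
    if table.shape[1] == 0:
        table["assigned"] = "M0"
        table["best_kme"] = np.nan
        return table
    best = table.idxmax(axis=1)
    best_val = table.max(axis=1)
    assigned = np.where(best_val >= min_kme, best, "M0")
    out = table.copy()
    out["assigned"] = assigned
    out["best_kme"] = best_val
    return out


def extract_subnetwork(
    net: NetworkResult, focal: str, n: int = 10, mode: str | None = None
) -> pd.DataFrame:
    """Weighted edge list around a focal gene or within a module.

    Focal-gene mode: the ``n`` genes with largest adjacency to the focal
    gene, plus the focal gene. Module mode: the ``n`` highest-kTotal genes
    of the module (its hub genes). Edges are the pairwise adjacencies among
    the selected nodes.
    """
    if mode is None:
        mode = "module" if focal in set(net.labels.values()) else "gene"
    gi = {g: i for i, g in enumerate(net.gene_ids)}
    if mode == "gene":
        if focal not in gi:
            raise KeyError(f"gene {focal!r} not in network")
        row = net.adjacency_matrix[gi[focal]].copy()
        row[gi[focal]] = -np.inf
        order = np.argsort(row)[::-1][:n]
        nodes = [net.gene_ids[i] for i in order] + [focal]
    elif mode == "module":
        members = net.module_members(focal)
        if not members:
            raise KeyError(f"module {focal!r} has no members")
        if len(members) < n:
            warnings.warn(
                f"module {focal} has only {len(members)} genes (< {n})", stacklevel=2
            )
        ranked = sorted(members, key=lambda g: (-net.k_total[g], g))
        nodes = ranked[:n]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for i, gA in enumerate(nodes):
        for gB in nodes[i + 1 :]:
            rows.append(
                {"source": gA, "target": gB, "weight": float(net.adjacency_matrix[gi[gA], gi[gB]])}
            )
    return pd.DataFrame(rows, columns=["source", "target", "weight"])


# ---------------------------------------------------------------------------
# end-to-end build


def build_network(
    expr: pd.DataFrame, config: NetworkConfig | None = None
) -> NetworkResult:
    """Full network build from a genes x samples log-scale expression frame.

    Constant genes are excluded with a warning before correlation. Whole-
    matrix computation only: inputs above 6,000 genes are rejected.
    """
    cfg = config or NetworkConfig()
    cfg.validate()
    if expr.shape[0] > MAX_NETWORK_GENES:
        raise ValueError(
            f"{expr.shape[0]} genes exceed the whole-matrix cap of "
            f"{MAX_NETWORK_GENES}; reduce the input (no blockwise mode)"
        )
    x = expr.to_numpy(dtype=float)
    keep = x.std(axis=1) > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} constant gene(s) from the network",
            stacklevel=2,
        )
        expr = expr.loc[keep]
        x = x[keep]
    gene_ids = list(expr.index)

    if cfg.beta is not None:
        beta = cfg.beta
        _, table = pick_soft_threshold(x, cfg.beta_candidates, cfg.signed_r2_cut, cfg)
    else:
        beta, table = pick_soft_threshold(x, cfg.beta_candidates, cfg.signed_r2_cut, cfg)

    cor = _correlate(x, cfg)
    adj = adjacency(cor, beta, signed=True)
    t = tom(adj)
    labels, eigengenes = detect_modules(
        t, x, gene_ids, cfg.cut_height, cfg.min_module_size, cfg.merge_cor
    )
    k_total = pd.Series(connectivity(adj), index=gene_ids, name="k_total")
    return NetworkResult(
        gene_ids=gene_ids,
        sample_ids=list(expr.columns),
        labels=labels,
        k_total=k_total,
        eigengenes=eigengenes,
        soft_threshold_table=table,
        beta=beta,
        adjacency_matrix=adj,
        expression=expr,
        config=cfg,
    )
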