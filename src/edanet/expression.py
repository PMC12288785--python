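"""Library normalization, expression units, batch adjustment and MDS.

Normalization factors follow the trimmed-mean-of-M-values (TMM) scheme:
a reference sample is chosen by 75th-percentile CPM, per-sample log-ratios
(M) and average log-abundances (A) are doubly trimmed, and the factor is
two to the inverse-asymptotic-variance weighted mean of the surviving M
values, rescaled so the factors have geometric mean one.

The sample-distance routine reproduces the "leading log fold change"
distance: for each pair of samples, the root-mean-square of the largest
``top`` absolute log2 differences, with the gene selection made per pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneAnnotation, SampleTable

__all__ = [
    "NormalizedExpression",
    "tmm_factors",
    "to_units",
    "adjust_family",
    "leading_logfc_distance",
    "classical_mds",
]


@dataclass
class NormalizedExpression:
    """Normalized expression values plus the normalization bookkeeping."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # genes x samples
    library_sizes: np.ndarray
    factors: np.ndarray
    transform: str  # "CPM" | "TPM" | "log2CPM"

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")
        gm = np.exp(np.mean(np.log(self.factors)))
        if abs(gm - 1.0) > 1e-6:
            raise ValueError("factors must have geometric mean 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def copy_with(self, values: np.ndarray) -> "NormalizedExpression":
        return NormalizedExpression(
            list(self.gene_ids),
            list(self.sample_ids),
            values,
            self.library_sizes.copy(),
            self.factors.copy(),
            self.transform,
        )


def tmm_factors(
    cm: CountMatrix, trim_M: float = 0.30, trim_A: float = 0.05
) -> np.ndarray:
    """TMM normalization factors, geometric mean 1.

    Per non-reference sample, genes positive in both that sample and the
    reference contribute M (log2 CPM ratio) and A (mean log2 CPM); genes in
    the middle after trimming ``trim_M`` from each tail of M and ``trim_A``
    from each tail of A are combined by a weighted mean with the usual
    inverse binomial-variance weights.
    """
    counts = cm.counts.astype(float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = cm.sample_ids[int(np.argmax(lib == 0))]
        raise ValueError(f"sample {bad!r} has zero library size")
    if cm.n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    cpm = counts / lib * 1e6
    q75 = np.percentile(cpm, 75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    log_factors = np.zeros(cm.n_samples)
    yr = counts[:, ref]
    nr = lib[ref]
    for s in range(cm.n_samples):
        if s == ref:
            continue
        ys = counts[:, s]
        ns = lib[s]
        pos = (ys > 0) & (yr > 0)
        if not pos.any():
            continue
        ps, pr = ys[pos] / ns, yr[pos] / nr
        M = np.log2(ps / pr)
        A = 0.5 * np.log2(ps * pr)
        # asymptotic variance of M (delta method, binomial sampling)
        w = (ns - ys[pos]) / (ns * ys[pos]) + (nr - yr[pos]) / (nr * yr[pos])
        if np.allclose(M, 0.0, atol=1e-10):
            continue  # identical composition: factor 1
        keep = _double_trim(M, A, trim_M, trim_A)
        if not keep.any():
            continue
        log_factors[s] = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    factors = np.exp2(log_factors)
    return factors / np.exp(np.mean(np.log(factors)))


def _double_trim(M: np.ndarray, A: np.ndarray, trim_M: float, trim_A: float) -> np.ndarray:
    """Genes kept after trimming both tails of M and of A (rank-based)."""
    n = M.size
    keep = np.ones(n, dtype=bool)
    for vals, trim in ((M, trim_M), (A, trim_A)):
        lo = np.floor(n * trim) + 1
        hi = n + 1 - lo
        ranks = pd.Series(vals).rank().to_numpy()
        keep &= (ranks >= lo) & (ranks <= hi)
    return keep


def to_units(
    cm: CountMatrix,
    factors: np.ndarray | None = None,
    annotation: GeneAnnotation | None = None,
    units: str = "log2CPM",
    prior_count: float = 0.5,
) -> NormalizedExpression:
    """Convert counts to CPM, TPM or log2-CPM using effective library sizes.

    log2CPM uses a prior count: log2((y + prior) / (L f + 2 prior) * 1e6),
    so zeros stay finite. TPM requires gene lengths from ``annotation``.
    """
    counts = cm.counts.astype(float)
    lib = counts.sum(axis=0)
    if factors is None:
        factors = np.ones(cm.n_samples)
    factors = np.asarray(factors, dtype=float)
    eff = lib * factors
    if units == "CPM":
        vals = counts / eff * 1e6
    elif units == "log2CPM":
        vals = np.log2((counts + prior_count) / (eff + 2.0 * prior_count) * 1e6)
    elif units == "TPM":
        if annotation is None:
            raise ValueError("TPM requires a gene-length annotation")
        missing = [g for g in cm.gene_ids if g not in annotation.lengths]
        if missing:
            raise ValueError(f"no length for genes: {missing[:5]}")
        lengths = np.array([annotation.lengths[g] for g in cm.gene_ids])
        rate = counts / lengths[:, None]
        vals = rate / rate.sum(axis=0) * 1e6
    else:
        raise ValueError(f"unknown units {units!r}")
    return NormalizedExpression(
        list(cm.gene_ids), list(cm.sample_ids), vals, lib, factors, units
    )


def adjust_family(ne: NormalizedExpression, samples: SampleTable) -> NormalizedExpression:
    """Location-only family batch adjustment on a log-scale matrix.

    Per gene: subtract each family's mean and add back the grand mean.
    Families with a single sample are left uncentred (with a warning),
    since their mean is the observation itself.
    """
    if ne.transform not in ("log2CPM",):
        warnings.warn(
            f"family adjustment expects log-scale input, got {ne.transform}",
            stacklevel=2,
        )
    st = samples.aligned_to(ne.sample_ids)
    fam = st.frame["family"].to_numpy()
    vals = ne.values.copy()
    grand = vals.mean(axis=1, keepdims=True)
    for f in pd.unique(fam):
        cols = fam == f
        if cols.sum() < 2:
            warnings.warn(f"family {f!r} has one sample; left uncentred", stacklevel=2)
            continue
        vals[:, cols] += grand - vals[:, cols].mean(axis=1, keepdims=True)
    return ne.copy_with(vals)


def leading_logfc_distance(ne: NormalizedExpression, top: int = 500) -> np.ndarray:
    """Pairwise sample distance from the top ``top`` absolute log2 differences.

    For each pair the genes are re-selected, matching the "pairwise" gene
    selection of the leading-fold-change MDS.
    """
    x = ne.values
    n_genes, n = x.shape
    top = min(top, n_genes)
    d = np.zeros((n, n))
    for i in range(n):
        diffs = np.abs(x[:, i + 1 :] - x[:, [i]])  # genes x (n-i-1)
        if diffs.size == 0:
            continue
        if top < n_genes:
            part = np.partition(diffs, n_genes - top, axis=0)[n_genes - top :, :]
        else:
            part = diffs
        vals = np.sqrt(np.mean(part**2, axis=0))
        d[i, i + 1 :] = vals
        d[i + 1 :, i] = vals
    return d


def classical_mds(dist: np.ndarray, k: int = 2) -> np.ndarray:
    """Torgerson classical MDS: coordinates from double-centred -d^2/2.

    Returns an (n, k) array; axes are ordered by decreasing eigenvalue and
    scaled by sqrt(eigenvalue). A Euclidean distance matrix of rank <= k is
    reproduced exactly.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if k > n:
        raise ValueError("k exceeds the number of points")
    if (evals[:k] < -1e-8 * max(1.0, abs(evals[0]))).any():
        warnings.warn("negative eigenvalues: distances are not Euclidean", stacklevel=2)
    lam = np.clip(evals[:k], 0.0, None)
    return evecs[:, :k] * np.sqrt(lam)
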