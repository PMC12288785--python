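"""Permutation tests on gene sets, overlap tests and over-representation.

The median-comparison test mirrors the connectivity-as-pleiotropy
procedure: the observed statistic is the difference in medians of a
per-gene value (kTotal, TPM, ...) between two gene sets (or one set versus
the whole transcriptome); 10,000 random same-size sets are drawn and the
p-value is the fraction of permutations whose absolute median difference
is at least the observed one. A count of zero is reported with a floor
flag ("p < 1/B").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg
from .io import GeneSetCollection

__all__ = [
    "PermutationResult",
    "perm_median_diff",
    "perm_overlap",
    "ora",
    "crosstab_modules",
]


@dataclass
class PermutationResult:
    observed: float
    B: int
    exceed_count: int
    p: float
    floored: bool  # True when exceed_count == 0: report as "< 1/B"
    seed: int
    exact_p: float | None = None  # hypergeometric cross-check (overlap test)

    def __post_init__(self) -> None:
        if not 0 <= self.exceed_count <= self.B:
            raise ValueError("exceed count outside [0, B]")

    @property
    def display(self) -> str:
        return f"p < {1.0 / self.B:g}" if self.floored else f"p = {self.p:g}"


def _as_positions(ids, index: pd.Index, what: str) -> np.ndarray:
    pos = index.get_indexer(pd.Index(list(ids)))
    if (pos < 0).any():
        missing = [g for g, p in zip(ids, pos) if p < 0]
        raise ValueError(f"{what} contains genes without values: {missing[:5]}")
    return pos


def perm_median_diff(
    values: pd.Series,
    set_a,
    set_b=None,
    B: int = 10000,
    seed: int = 1234,
    plus_one: bool = False,
) -> PermutationResult:
    """Permutation test of the median difference between gene sets.

    ``values`` maps every gene in the universe to a number. With
    ``set_b=None`` the comparison is set A versus the whole universe (only
    A is re-drawn each iteration); otherwise two disjoint random sets of
    sizes |A| and |B| are drawn per iteration. ``plus_one`` switches to the
    (c+1)/(B+1) estimator.
    """
    values = values.astype(float)
    universe = values.index
    n = len(universe)
    pos_a = _as_positions(set_a, universe, "set A")
    if pos_a.size == 0:
        raise ValueError("set A is empty")
    if pos_a.size > n:
        raise ValueError("set A larger than the universe")
    vals = values.to_numpy()
    med_univ = float(np.median(vals))

    rng = np.random.default_rng(seed)
    two_set = set_b is not None
    if two_set:
        pos_b = _as_positions(set_b, universe, "set B")
        if pos_b.size == 0:
            raise ValueError("set B is empty")
        if pos_a.size + pos_b.size > n:
            raise ValueError("disjoint draws impossible: |A| + |B| > universe")
        observed = float(np.median(vals[pos_a]) - np.median(vals[pos_b]))
    else:
        observed = float(np.median(vals[pos_a]) - med_univ)

    na = pos_a.size
    c = 0
    for _ in range(B):
        if two_set:
            draw = rng.choice(n, size=na + pos_b.size, replace=False)
            d = np.median(vals[draw[:na]]) - np.median(vals[draw[na:]])
        else:
            d = np.median(vals[rng.choice(n, size=na, replace=False)]) - med_univ
        if abs(d) >= abs(observed):
            c += 1
    p = (c + 1) / (B + 1) if plus_one else c / B
    return PermutationResult(observed, B, c, p, floored=(c == 0), seed=seed)


def perm_overlap(
    universe_size: int,
    n1: int,
    n2: int,
    observed_overlap: int,
    B: int = 10000,
    seed: int = 1234,
    plus_one: bool = False,
) -> PermutationResult:
    """Permutation test of an overlap between two gene sets.

    Each iteration draws independent random sets of sizes n1 and n2 from a
    universe of ``universe_size`` genes and counts their intersection; the
    p-value is the fraction with overlap >= observed. The exact upper-tail
    hypergeometric probability is returned alongside as a cross-check.
    """
    if not (0 <= n1 <= universe_size and 0 <= n2 <= universe_size):
        raise ValueError("set sizes exceed the universe")
    if observed_overlap > min(n1, n2):
        raise ValueError("observed overlap exceeds the smaller set")
    rng = np.random.default_rng(seed)
    c = 0
    for _ in range(B):
        s1 = rng.choice(universe_size, size=n1, replace=False)
        s2 = rng.choice(universe_size, size=n2, replace=False)
        if np.intersect1d(s1, s2, assume_unique=True).size >= observed_overlap:
            c += 1
    p = (c + 1) / (B + 1) if plus_one else c / B
    exact = float(stats.hypergeom.sf(observed_overlap - 1, universe_size, n1, n2))
    return PermutationResult(
        float(observed_overlap), B, c, p, floored=(c == 0), seed=seed, exact_p=exact
    )


def ora(
    sets: GeneSetCollection,
    query,
    background,
    min_term: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation against an explicit background.

    The background is the filtered gene list of the run; terms are
    intersected with it, and terms with fewer than ``min_term`` background
    members are skipped. BH across the tested terms; ``enriched`` flags
    FDR < alpha.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    N, nq = len(background), len(query)
    rows = []
    for tid, (name, members) in sets.items():
        in_bg = members & background
        K = len(in_bg)
        if K < min_term:
            continue
        k = len(in_bg & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, nq))
        rows.append(
            {"term_id": tid, "term_name": name, "term_size": K, "overlap": k, "p": p}
        )
    table = pd.DataFrame(rows, columns=["term_id", "term_name", "term_size", "overlap", "p"])
    if len(table):
        table["fdr"] = benjamini_hochberg(table["p"].to_numpy())
        table["enriched"] = table["fdr"] < alpha
        table = table.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        table["fdr"] = pd.Series(dtype=float)
        table["enriched"] = pd.Series(dtype=bool)
    return table


def crosstab_modules(
    deg_set, dsg_set, labels: dict[str, str]
) -> pd.DataFrame:
    """Module x category table of DEG-only / DSG-only / both counts.

    Columns are every module containing at least one DEG or DSG (M0
    included when hit), ordered M0 first then by module number; rows are
    DSG-only, DEG-only, both, and the total genes per module.
    """
    deg_set, dsg_set = set(deg_set), set(dsg_set)
    missing = (deg_set | dsg_set) - set(labels)
    if missing:
        raise ValueError(f"genes without module labels: {sorted(missing)[:5]}")
    both = deg_set & dsg_set
    deg_only = deg_set - both
    dsg_only = dsg_set - both

    hit_modules = sorted(
        {labels[g] for g in deg_set | dsg_set},
        key=lambda m: (m != "M0", int(m[1:]) if m[1:].isdigit() else m),
    )
    totals = pd.Series(labels).value_counts()
    data = {}
    for m in hit_modules:
        data[m] = [
            sum(1 for g in dsg_only if labels[g] == m),
            sum(1 for g in deg_only if labels[g] == m),
            sum(1 for g in both if labels[g] == m),
            int(totals.get(m, 0)),
        ]
    return pd.DataFrame(
        data, index=["dsg_only", "deg_only", "both", "total_genes"]
    )
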