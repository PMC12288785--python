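"""Count-matrix containers, TSV/GMT readers and the low-expression filter.

Gene identifiers are opaque strings throughout; no genome coordinates are
needed downstream. All tables are plain TSV (tab-separated, UTF-8, header
row) so that every intermediate of the pipeline can be inspected with
standard command-line tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExonCountMatrix",
    "SampleTable",
    "GeneAnnotation",
    "GeneSetCollection",
    "read_counts",
    "write_counts",
    "read_samples",
    "read_gmt",
    "default_max_low_samples",
    "filter_low_expression",
    "filter_exons_by_genes",
]

GENOTYPES = ("CC", "CL", "LL")


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples), integer

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CountMatrix(
            [self.gene_ids[i] for i in idx], list(self.sample_ids), self.counts[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ExonCountMatrix:
    """Exon x sample counts with an exon -> gene grouping.

    ``exon_order`` gives each exon's 1-based position within its gene, which
    is how planted splicing effects and the usage tests refer to exons.
    """

    exon_ids: list[str]
    gene_of_exon: dict[str, str]
    exon_order: dict[str, int]
    sample_ids: list[str]
    counts: np.ndarray
    exon_lengths: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.exon_ids), len(self.sample_ids)):
            raise ValueError("exon count matrix shape inconsistent with ids")
        if (self.counts < 0).any():
            raise ValueError("negative exon count")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("exon counts must be integers")
            self.counts = self.counts.astype(np.int64)
        _check_unique(self.exon_ids, "exon")
        missing = [e for e in self.exon_ids if e not in self.gene_of_exon]
        if missing:
            raise ValueError(f"exons without gene mapping: {missing[:3]}")
        # exon order must be unique within each gene
        seen: dict[tuple[str, int], str] = {}
        for e in self.exon_ids:
            key = (self.gene_of_exon[e], self.exon_order[e])
            if key in seen:
                raise ValueError(
                    f"duplicate exon order {key[1]} within gene {key[0]!r}"
                )
            seen[key] = e

    @property
    def n_exons(self) -> int:
        return len(self.exon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def genes(self) -> list[str]:
        out: list[str] = []
        seen = set()
        for e in self.exon_ids:
            g = self.gene_of_exon[e]
            if g not in seen:
                seen.add(g)
                out.append(g)
        return out

    def exon_indices_of_gene(self, gene_id: str) -> np.ndarray:
        return np.array(
            [i for i, e in enumerate(self.exon_ids) if self.gene_of_exon[e] == gene_id],
            dtype=int,
        )

    def gene_totals(self) -> CountMatrix:
        """Sum exon counts within genes, preserving first-seen gene order."""
        genes = self.genes()
        pos = {g: i for i, g in enumerate(genes)}
        out = np.zeros((len(genes), self.n_samples), dtype=np.int64)
        for i, e in enumerate(self.exon_ids):
            out[pos[self.gene_of_exon[e]]] += self.counts[i]
        return CountMatrix(genes, list(self.sample_ids), out)


@dataclass
class SampleTable:
    """Per-sample design metadata: genotype, family, sex, tissue."""

    frame: pd.DataFrame  # index sample_id; columns genotype, family, sex, tissue

    def __post_init__(self) -> None:
        required = {"genotype", "family", "sex"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate sample ids in sample table")
        bad = set(self.frame["genotype"]) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotype levels: {sorted(bad)}")
        if "tissue" not in self.frame.columns:
            self.frame = self.frame.assign(tissue="tissue1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def aligned_to(self, sample_ids: list[str]) -> "SampleTable":
        return SampleTable(self.frame.loc[sample_ids].copy())


@dataclass
class GeneAnnotation:
    """Total exonic length (bp) per gene; needed only for TPM."""

    lengths: dict[str, float]

    def __post_init__(self) -> None:
        bad = [g for g, L in self.lengths.items() if not L > 0]
        if bad:
            raise ValueError(f"non-positive gene lengths: {bad[:3]}")


@dataclass
class GeneSetCollection:
    """term_id -> (name, member gene ids); a generic stand-in for GO."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {tid!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path, level: str = "gene"):
    """Read a TSV count table at gene or exon level.

    Gene level: first column ``gene_id``, remaining columns one per sample.
    Exon level: columns ``gene_id``, ``exon_id``, ``exon_order`` then samples.
    """
    if level not in ("gene", "exon"):
        raise ValueError(f"unknown level {level!r}")
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if level == "gene":
        gene_ids = df.iloc[:, 0].astype(str).tolist()
        sample_ids = [str(c) for c in df.columns[1:]]
        counts = _coerce_counts(df.iloc[:, 1:], df.iloc[:, 0], sample_ids, path)
        return CountMatrix(gene_ids, sample_ids, counts)
    expected = ["gene_id", "exon_id", "exon_order"]
    if list(df.columns[:3]) != expected:
        raise ValueError(
            f"exon-level table must start with columns {expected}, "
            f"got {list(df.columns[:3])}"
        )
    exon_ids = df["exon_id"].astype(str).tolist()
    gene_of_exon = dict(zip(exon_ids, df["gene_id"].astype(str)))
    exon_order = dict(zip(exon_ids, df["exon_order"].astype(int)))
    sample_ids = [str(c) for c in df.columns[3:]]
    counts = _coerce_counts(df.iloc[:, 3:], df["exon_id"], sample_ids, path)
    return ExonCountMatrix(exon_ids, gene_of_exon, exon_order, sample_ids, counts)


def _coerce_counts(block: pd.DataFrame, row_ids, sample_ids, path) -> np.ndarray:
    arr = block.to_numpy()
    flt = arr.astype(float)
    if np.isnan(flt).any():
        r, c = np.argwhere(np.isnan(flt))[0]
        raise ValueError(
            f"{path}: missing/non-numeric count at row {row_ids.iloc[r]!r}, "
            f"column {sample_ids[c]!r}"
        )
    if (flt < 0).any():
        r, c = np.argwhere(flt < 0)[0]
        raise ValueError(
            f"{path}: negative count at row {row_ids.iloc[r]!r}, "
            f"column {sample_ids[c]!r}"
        )
    if not np.all(np.equal(np.mod(flt, 1), 0)):
        r, c = np.argwhere(np.mod(flt, 1) != 0)[0]
        raise ValueError(
            f"{path}: non-integer count at row {row_ids.iloc[r]!r}, "
            f"column {sample_ids[c]!r}"
        )
    return flt.astype(np.int64)


def write_counts(obj, path) -> None:
    """Write a CountMatrix or ExonCountMatrix as TSV (inverse of read_counts)."""
    if isinstance(obj, CountMatrix):
        df = obj.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")
    elif isinstance(obj, ExonCountMatrix):
        head = pd.DataFrame(
            {
                "gene_id": [obj.gene_of_exon[e] for e in obj.exon_ids],
                "exon_id": obj.exon_ids,
                "exon_order": [obj.exon_order[e] for e in obj.exon_ids],
            }
        )
        body = pd.DataFrame(obj.counts, columns=obj.sample_ids)
        pd.concat([head, body], axis=1).to_csv(path, sep="\t", index=False)
    else:
        raise TypeError(type(obj))


def read_samples(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    return SampleTable(df)


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in the standard 3+-column GMT dialect."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has < 3 columns")
            tid, name, members = parts[0], parts[1], frozenset(p for p in parts[2:] if p)
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {tid!r} empty")
            sets[tid] = (name, members)
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# low-expression filter


def default_max_low_samples(n_samples: int) -> int:
    """Generalize the 11-of-35 / 12-of-36 drop thresholds as floor(n/3).

    floor(35/3) = 11 and floor(36/3) = 12, reproducing both published
    ratios exactly.
    """
    return n_samples // 3


def filter_low_expression(
    cm: CountMatrix, min_count: int = 10, max_low_samples: int | None = None
) -> CountMatrix:
    """Drop genes with fewer than ``min_count`` reads in too many samples.

    A gene is removed iff the number of samples where its count is below
    ``min_count`` is at least ``max_low_samples`` (default: the published
    11-of-35 ratio scaled to the actual sample count).
    """
    if max_low_samples is None:
        max_low_samples = default_max_low_samples(cm.n_samples)
    if max_low_samples > cm.n_samples:
        raise ValueError("max_low_samples exceeds the number of samples")
    n_low = (cm.counts < min_count).sum(axis=1)
    keep = n_low < max_low_samples
    if not keep.any():
        import warnings

        warnings.warn("low-expression filter removed every gene", stacklevel=2)
    return cm.subset_genes(keep)


def filter_exons_by_genes(ec: ExonCountMatrix, gene_ids) -> ExonCountMatrix:
    """Keep exons whose gene survived the gene-level filter."""
    keep = set(gene_ids)
    idx = [i for i, e in enumerate(ec.exon_ids) if ec.gene_of_exon[e] in keep]
    exon_ids = [ec.exon_ids[i] for i in idx]
    return ExonCountMatrix(
        exon_ids,
        {e: ec.gene_of_exon[e] for e in exon_ids},
        {e: ec.exon_order[e] for e in exon_ids},
        list(ec.sample_ids),
        ec.counts[idx],
        None
        if ec.exon_lengths is None
        else {e: ec.exon_lengths[e] for e in exon_ids},
    )
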