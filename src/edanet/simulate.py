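"""Synthetic RNA-seq count generator with planted, recorded effects.

The generator emulates the sibling-cross study design this package is built
around: three families, three *Eda* genotypes (CC/CL/LL), two sexes and a
configurable number of replicates per cell (36 samples at the defaults).
It plants, on a log2-CPM scale,

* per-gene baselines ``a_g ~ Normal(mu0, sd0)``,
* co-expression modules driven by latent per-sample factors with gene
  loadings drawn from a band (one orientation sign per module, so a signed
  network can recover the module as one cluster),
* family batch offsets ``gamma_{g,f} ~ Normal(0, family_sd)``,
* genotype expression effects ``delta_g`` on a chosen set of DEGs, applied
  through a recessive-L (default), additive or dominant-L genotype coding,
* exon-usage shifts ``delta_pi`` on one target exon of each planted DSG,
  active in samples where the genotype design value is 1.

Counts are negative binomial around softmax-composed expected counts, with
a mean-dispersion trend ``phi = b0 + b1/mu``; exon counts are multinomial
(optionally Dirichlet-multinomial) partitions of each gene's count, so exon
counts sum exactly to the gene count in every gene x sample cell.

Every planted quantity is recorded in a :class:`SyntheticTruth` ledger so
downstream recovery can be scored against ground truth.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import CountMatrix, ExonCountMatrix, GeneAnnotation, SampleTable

__all__ = ["SimulationConfig", "SyntheticTruth", "generate_dataset", "genotype_design_values"]

_GENOTYPE_CODES = {
    "recessive_L": {"CC": 0.0, "CL": 0.0, "LL": 1.0},
    "additive": {"CC": 0.0, "CL": 0.5, "LL": 1.0},
    "dominant_L": {"CC": 0.0, "CL": 1.0, "LL": 1.0},
}


@dataclass
class SimulationConfig:
    """Parameters of the planted-truth simulation.

    Defaults give a 3,000-gene, 36-sample dataset with 10 planted 100-gene
    modules, 200 DEGs (|log2FC| in 1..2), 100 DSGs (usage shift 0.2) and
    libraries of ~5e5 reads: small enough for minute-scale test runs while
    keeping per-gene counts in a realistic bulk RNA-seq range.
    """

    n_genes: int = 3000
    n_modules: int = 10
    module_size: int = 100
    samples_per_cell: int = 2  # replicates per family x genotype x sex cell
    families: tuple[str, ...] = ("A", "B", "C")
    genotypes: tuple[str, ...] = ("CC", "CL", "LL")
    sexes: tuple[str, ...] = ("F", "M")
    baseline_log2_mean_sd: tuple[float, float] = (5.0, 2.0)
    family_sd: float = 0.5
    module_loading_band: tuple[float, float] = (0.4, 0.8)
    n_deg: int = 200
    deg_effect_range: tuple[float, float] = (1.0, 2.0)
    genotype_model: str = "recessive_L"
    n_dsg: int = 100
    usage_shift: float = 0.2
    exons_per_gene_range: tuple[int, int] = (3, 8)
    dirichlet_alpha: float = float("inf")  # inf = plain multinomial
    dispersion_intercept: float = 0.05
    dispersion_slope: float = 2.0  # phi = b0 + b1 / mean
    library_size_mean: float = 5e5
    library_size_cv: float = 0.1
    tissue: str = "skin"
    seed: int = 1234

    def validate(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError(
                f"module overflow: {self.n_modules} x {self.module_size} "
                f"modules exceed {self.n_genes} genes"
            )
        if self.genotype_model not in _GENOTYPE_CODES:
            raise ValueError(f"unknown genotype_model {self.genotype_model!r}")
        if not 0.0 <= self.usage_shift < 1.0:
            raise ValueError("usage_shift must lie in [0, 1)")
        if self.n_deg + self.n_dsg > self.n_genes:
            raise ValueError("n_deg + n_dsg exceed the gene universe")
        lo, hi = self.exons_per_gene_range
        if lo < 2 and self.n_dsg > 0:
            raise ValueError("planted DSGs need genes with at least 2 exons")
        if self.dispersion_intercept < 0 or self.dispersion_slope < 0:
            raise ValueError("dispersion trend coefficients must be >= 0")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be positive")


@dataclass
class SyntheticTruth:
    """Ground-truth ledger of everything the generator planted."""

    deg_ids: list[str]
    deg_log2fc: dict[str, float]  # planted delta_g
    deg_realized_log2fc: dict[str, float]  # delta_g minus compositional shift
    dsg_ids: list[str]
    dsg_target_exon: dict[str, str]
    dsg_usage_shift: dict[str, float]
    module_membership: dict[str, str]  # gene -> M1..Mk or M0
    family_offsets: pd.DataFrame  # genes x families
    library_sizes: dict[str, float]
    dispersions: dict[str, float]
    compositional_log2_shift: float
    config: SimulationConfig

    def to_json(self, path) -> None:
        payload = {
            "deg_ids": self.deg_ids,
            "deg_log2fc": self.deg_log2fc,
            "deg_realized_log2fc": self.deg_realized_log2fc,
            "dsg_ids": self.dsg_ids,
            "dsg_target_exon": self.dsg_target_exon,
            "dsg_usage_shift": self.dsg_usage_shift,
            "module_membership": self.module_membership,
            "library_sizes": self.library_sizes,
            "dispersions": self.dispersions,
            "compositional_log2_shift": self.compositional_log2_shift,
            "config": asdict(self.config),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def genotype_design_values(model: str) -> dict[str, float]:
    """Design value x_k per genotype under the chosen inheritance model."""
    return dict(_GENOTYPE_CODES[model])


def _sample_table(cfg: SimulationConfig) -> SampleTable:
    rows = []
    for fam, gt, sex in itertools.product(cfg.families, cfg.genotypes, cfg.sexes):
        for rep in range(1, cfg.samples_per_cell + 1):
            rows.append(
                {
                    "sample_id": f"{fam}_{gt}_{sex}{rep}",
                    "genotype": gt,
                    "family": fam,
                    "sex": sex,
                    "tissue": cfg.tissue,
                }
            )
    frame = pd.DataFrame(rows).set_index("sample_id")
    return SampleTable(frame)


def generate_dataset(
    config: SimulationConfig,
) -> tuple[CountMatrix, ExonCountMatrix, SampleTable, GeneAnnotation, SyntheticTruth]:
    """Simulate gene- and exon-level counts with a recorded ground truth.

    Deterministic for a fixed ``config.seed``. Returns the gene count
    matrix, the exon count matrix (summing to the gene counts), the sample
    table, a gene-length annotation for TPM, and the truth ledger.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cfg = config

    samples = _sample_table(cfg)
    sample_ids = samples.sample_ids
    n_samp = len(sample_ids)
    gene_ids = [f"g{i:05d}" for i in range(1, cfg.n_genes + 1)]

    x_map = _GENOTYPE_CODES[cfg.genotype_model]
    x = np.array([x_map[g] for g in samples.frame["genotype"]])

    # --- per-gene structural parameters --------------------------------
    a = rng.normal(cfg.baseline_log2_mean_sd[0], cfg.baseline_log2_mean_sd[1], cfg.n_genes)

    membership = np.full(cfg.n_genes, "M0", dtype=object)
    loadings = np.zeros(cfg.n_genes)
    module_of = np.full(cfg.n_genes, -1)
    lo, hi = cfg.module_loading_band
    # module genes occupy a random subset so membership is not positional
    module_gene_idx = rng.choice(
        cfg.n_genes, size=cfg.n_modules * cfg.module_size, replace=False
    )
    orient = rng.choice([-1.0, 1.0], size=cfg.n_modules)
    for m in range(cfg.n_modules):
        idx = module_gene_idx[m * cfg.module_size : (m + 1) * cfg.module_size]
        membership[idx] = f"M{m + 1}"
        module_of[idx] = m
        loadings[idx] = orient[m] * rng.uniform(lo, hi, size=cfg.module_size)

    # family batch effect as one latent factor: per-gene loading times a
    # centred, unit-variance family score, so the family structure forms a
    # single gradient (the dominant-axis batch pattern bulk RNA-seq MDS
    # plots typically show) rather than spanning n_families - 1 dimensions
    n_fam = len(cfg.families)
    fam_scores = np.arange(n_fam, dtype=float)
    fam_scores -= fam_scores.mean()
    sd = fam_scores.std()
    if sd > 0:
        fam_scores /= sd
    fam_loading = rng.normal(0.0, cfg.family_sd, size=cfg.n_genes)
    gamma = fam_loading[:, None] * fam_scores[None, :]
    fam_index = {f: j for j, f in enumerate(cfg.families)}
    fam_of_sample = np.array([fam_index[f] for f in samples.frame["family"]])

    # planted DEG / DSG index sets, disjoint so splicing effects are pure
    effect_idx = rng.choice(cfg.n_genes, size=cfg.n_deg + cfg.n_dsg, replace=False)
    deg_idx = np.sort(effect_idx[: cfg.n_deg])
    dsg_idx = np.sort(effect_idx[cfg.n_deg :])
    delta = np.zeros(cfg.n_genes)
    if cfg.n_deg:
        mag = rng.uniform(*cfg.deg_effect_range, size=cfg.n_deg)
        sign = rng.choice([-1.0, 1.0], size=cfg.n_deg)
        delta[deg_idx] = mag * sign

    # --- log2 mean surface ----------------------------------------------
    z = rng.normal(0.0, 1.0, size=(cfg.n_modules, n_samp))
    if cfg.n_modules:
        module_term = np.where(
            module_of[:, None] >= 0,
            loadings[:, None] * z[np.maximum(module_of, 0), :],
            0.0,
        )
    else:
        module_term = 0.0
    log2_mu = (
        a[:, None]
        + module_term
        + gamma[:, fam_of_sample]
        + delta[:, None] * x[None, :]
    )

    # softmax composition: expected count share per sample
    w = np.exp2(log2_mu)
    p = w / w.sum(axis=0, keepdims=True)

    lib_mean = cfg.library_size_mean
    lib_sd = lib_mean * cfg.library_size_cv
    L = np.maximum(rng.normal(lib_mean, lib_sd, size=n_samp), lib_mean * 0.1)
    L = np.round(L)

    mu = p * L[None, :]

    # compositional correction: the softmax makes realized logFC differ from
    # delta_g by the log-ratio of totals between the x=1 and x=0 states
    # (evaluated at the deterministic part of the model, z = gamma = 0)
    t0 = np.exp2(a).sum()
    t1 = np.exp2(a + delta).sum()
    comp_shift = float(np.log2(t1 / t0))

    # --- NB gene counts ---------------------------------------------------
    mu_bar = mu.mean(axis=1)
    phi = cfg.dispersion_intercept + cfg.dispersion_slope / np.maximum(mu_bar, 1e-8)
    counts = _rnbinom(rng, mu, phi[:, None])

    # --- exon structure and multinomial partition -------------------------
    e_lo, e_hi = cfg.exons_per_gene_range
    n_exons = rng.integers(e_lo, e_hi + 1, size=cfg.n_genes)
    base_props = [rng.dirichlet(np.full(k, 5.0)) for k in n_exons]

    dsg_target = np.full(cfg.n_genes, -1)
    for gi in dsg_idx:
        props = base_props[gi]
        # target the exon closest to proportion 0.25 that still has headroom
        ok = np.flatnonzero(props + cfg.usage_shift < 0.95)
        if ok.size == 0:
            raise ValueError(
                f"usage_shift {cfg.usage_shift} pushes every exon proportion "
                f"of gene {gene_ids[gi]} outside (0,1)"
            )
        dsg_target[gi] = ok[np.argmin(np.abs(props[ok] - 0.25))]

    exon_ids: list[str] = []
    gene_of_exon: dict[str, str] = {}
    exon_order: dict[str, int] = {}
    exon_rows: list[np.ndarray] = []
    is_shifted = x == 1.0
    for gi, gid in enumerate(gene_ids):
        k = n_exons[gi]
        props = base_props[gi]
        ids = [f"{gid}:e{j + 1}" for j in range(k)]
        exon_ids.extend(ids)
        for j, eid in enumerate(ids):
            gene_of_exon[eid] = gid
            exon_order[eid] = j + 1
        block = np.zeros((k, n_samp), dtype=np.int64)
        for s in range(n_samp):
            pr = props
            if dsg_target[gi] >= 0 and is_shifted[s]:
                pr = _shift_usage(props, dsg_target[gi], cfg.usage_shift)
            if np.isfinite(cfg.dirichlet_alpha):
                pr = rng.dirichlet(cfg.dirichlet_alpha * pr)
            block[:, s] = rng.multinomial(counts[gi, s], pr)
        exon_rows.append(block)
    exon_counts = np.vstack(exon_rows)

    # gene lengths: 200 bp per exon plus jitter, for TPM support
    exon_len = rng.integers(80, 400, size=len(exon_ids)).astype(float)
    lengths: dict[str, float] = {}
    pos = 0
    for gi, gid in enumerate(gene_ids):
        k = n_exons[gi]
        lengths[gid] = float(exon_len[pos : pos + k].sum())
        pos += k
    exon_lengths = dict(zip(exon_ids, exon_len))

    cm = CountMatrix(gene_ids, sample_ids, counts)
    ec = ExonCountMatrix(
        exon_ids, gene_of_exon, exon_order, sample_ids, exon_counts, exon_lengths
    )
    ann = GeneAnnotation(lengths)

    truth = SyntheticTruth(
        deg_ids=[gene_ids[i] for i in deg_idx],
        deg_log2fc={gene_ids[i]: float(delta[i]) for i in deg_idx},
        deg_realized_log2fc={
            gene_ids[i]: float(delta[i] - comp_shift) for i in deg_idx
        },
        dsg_ids=[gene_ids[i] for i in dsg_idx],
        dsg_target_exon={
            gene_ids[i]: f"{gene_ids[i]}:e{dsg_target[i] + 1}" for i in dsg_idx
        },
        dsg_usage_shift={gene_ids[i]: cfg.usage_shift for i in dsg_idx},
        module_membership=dict(zip(gene_ids, membership)),
        family_offsets=pd.DataFrame(gamma, index=gene_ids, columns=list(cfg.families)),
        library_sizes=dict(zip(sample_ids, L.astype(float))),
        dispersions=dict(zip(gene_ids, phi)),
        compositional_log2_shift=comp_shift,
        config=cfg,
    )
    return cm, ec, samples, ann, truth


def _shift_usage(props: np.ndarray, target: int, shift: float) -> np.ndarray:
    """Raise the target exon's proportion by ``shift``, renormalizing the rest."""
    out = props.copy()
    pt = props[target]
    new_t = pt + shift
    if not 0.0 < new_t < 1.0:
        raise ValueError("usage shift leaves target proportion outside (0,1)")
    scale = (1.0 - new_t) / (1.0 - pt)
    out *= scale
    out[target] = new_t
    return out


def _rnbinom(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean mu, var mu + phi mu^2) via the gamma-Poisson mixture."""
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = phi <= 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    nb = ~poisson
    if nb.any():
        shape = 1.0 / phi[nb]
        lam = rng.gamma(shape, phi[nb] * mu[nb])
        out[nb] = rng.poisson(lam)
    return out
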