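"""End-to-end orchestration: simulate/load -> DE -> splicing -> network ->
permutation comparisons, with every table persisted as TSV and a JSON
summary whose numbers are all recomputable from those tables.

A fixed seed makes the whole output bundle byte-identical across runs; the
log file therefore carries no timestamps.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    CountMatrix,
    ExonCountMatrix,
    GeneAnnotation,
    SampleTable,
    filter_exons_by_genes,
    filter_low_expression,
    read_counts,
    read_samples,
    write_counts,
)
from .expression import (
    adjust_family,
    classical_mds,
    leading_logfc_distance,
    tmm_factors,
    to_units,
)
from .diffexpr import (
    CONTRASTS,
    build_design,
    call_degs,
    estimate_dispersions,
    fit_nb_glm,
    treat_test,
)
from .diffsplice import fit_exon_glm, run_differential_splicing
from .network import NetworkConfig, atomize_gene, build_network, extract_subnetwork
from .permstats import crosstab_modules, perm_median_diff, perm_overlap
from .simulate import SimulationConfig, generate_dataset

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulate`` (a SimulationConfig) or the input paths
    (``gene_counts``/``exon_counts``/``samples``) must be given. All
    thresholds default to the published analysis settings: min_count 10,
    tau 0.585, alpha 0.05, top 500 MDS genes, B 10,000 permutations,
    maxPOutliers 0.10, seed 1234; the soft threshold defaults to the
    scale-free scan (fix it via ``network.beta``, e.g. 14).
    """

    outdir: str | Path = "edanet_run"
    simulate: SimulationConfig | None = None
    gene_counts: str | None = None
    exon_counts: str | None = None
    samples: str | None = None

    min_count: int = 10
    max_low_samples: int | None = None
    tau: float = 0.585
    alpha: float = 0.05
    mds_top: int = 500
    prior_df: float = 10.0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    permutations: int = 10000
    seed: int = 1234
    atomize: tuple[str, ...] = ()  # gene ids to atomize into exons
    run_network: bool = True

    def validate(self) -> None:
        has_paths = self.gene_counts is not None
        if has_paths == (self.simulate is not None):
            raise ValueError("exactly one of input paths or a simulate block required")
        if has_paths:
            for p in (self.gene_counts, self.samples):
                if p is None or not Path(p).exists():
                    raise ValueError(f"missing input file: {p}")
            if self.exon_counts is not None and not Path(self.exon_counts).exists():
                raise ValueError(f"missing input file: {self.exon_counts}")


class _Log:
    def __init__(self, path: Path, echo: bool = True):
        self.fh = open(path, "w", encoding="utf-8")
        self.echo = echo

    def __call__(self, msg: str) -> None:
        self.fh.write(msg + "\n")
        if self.echo:
            print(msg, file=sys.stderr)

    def close(self) -> None:
        self.fh.close()


def run_pipeline(config: RunConfig, echo: bool = False) -> dict:
    """Execute the full analysis; returns the JSON summary as a dict.

    Stages, in order: load/simulate, low-expression filter, TMM, log2-CPM,
    leading-logFC MDS table, TREAT DE for the three genotype contrasts,
    differential exon usage with the union DSG call, family adjustment,
    network build (soft threshold, modules, kTotal, eigengenes), module
    cross-tabulation, permutation median comparisons of kTotal and TPM for
    DEG-only/DSG-only sets (both-category genes excluded), the DEG-DSG
    overlap test, optional exon atomization, and hub/neighbourhood edge
    lists. Any stage failure aborts with the stage name; tables written so
    far are left on disk.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run.log", echo=echo)
    summary: dict = {"version": __version__, "seed": config.seed}
    stage = "setup"
    try:
        # ------------------------------------------------ load / simulate
        stage = "load"
        if config.simulate is not None:
            log(f"stage=load simulate seed={config.simulate.seed}")
            cm, ec, samples, ann, truth = generate_dataset(config.simulate)
            write_counts(cm, out / "gene_counts.tsv")
            write_counts(ec, out / "exon_counts.tsv")
            samples.frame.to_csv(out / "samples.tsv", sep="\t")
            truth.to_json(out / "truth.json")
        else:
            log(f"stage=load from {config.gene_counts}")
            cm = read_counts(config.gene_counts, "gene")
            ec = (
                read_counts(config.exon_counts, "exon")
                if config.exon_counts
                else None
            )
            samples = read_samples(config.samples)
            ann, truth = None, None
        samples = samples.aligned_to(cm.sample_ids)

        # ------------------------------------------------ filter
        stage = "filter"
        n0 = cm.n_genes
        cm = filter_low_expression(cm, config.min_count, config.max_low_samples)
        if ec is not None:
            ec = filter_exons_by_genes(ec, cm.gene_ids)
        log(f"stage=filter kept {cm.n_genes}/{n0} genes")
        summary["n_genes_input"] = n0
        summary["n_genes_filtered"] = cm.n_genes

        # ------------------------------------------------ normalization
        stage = "normalize"
        factors = tmm_factors(cm)
        pd.DataFrame(
            {"sample_id": cm.sample_ids, "library_size": cm.library_sizes(), "tmm_factor": factors}
        ).to_csv(out / "normalization.tsv", sep="\t", index=False)
        logcpm = to_units(cm, factors, units="log2CPM")
        tpm = (
            to_units(cm, factors, annotation=ann, units="TPM") if ann is not None else None
        )
        log("stage=normalize TMM factors computed")

        # ------------------------------------------------ MDS
        stage = "mds"
        dist = leading_logfc_distance(logcpm, top=config.mds_top)
        coords = classical_mds(dist, k=2)
        mds_tab = samples.frame.copy()
        mds_tab["dim1"] = coords[:, 0]
        mds_tab["dim2"] = coords[:, 1]
        mds_tab.to_csv(out / "mds.tsv", sep="\t")
        log("stage=mds leading-logFC distances embedded")

        # ------------------------------------------------ DE (TREAT)
        stage = "diffexpr"
        design = build_design(samples)
        offsets = np.log(cm.library_sizes() * factors)
        disp = estimate_dispersions(cm, design, offsets, prior_df=config.prior_df)
        fit = fit_nb_glm(cm, design, offsets, disp)
        de_results = {}
        for contrast in CONTRASTS:
            res = treat_test(fit, contrast, tau=config.tau)
            de_results[contrast] = res
            res.table.to_csv(out / f"de_{contrast[0]}vs{contrast[1]}.tsv", sep="\t")
        deg_sets, deg_overlap = call_degs(de_results, alpha=config.alpha)
        deg_overlap.to_csv(out / "deg_overlap.tsv", sep="\t", index=False)
        summary["deg_counts"] = {
            "vs".join(c): len(s) for c, s in deg_sets.items()
        }
        n_excluded = int((~(fit.stable & fit.converged)).sum())
        log(
            "stage=diffexpr DEGs "
            + " ".join(f"{k}={v}" for k, v in summary["deg_counts"].items())
            + f" (excluded {n_excluded} unstable fits)"
        )

        # ------------------------------------------------ splicing
        stage = "diffsplice"
        dsg_sets: dict = {}
        if ec is not None:
            exon_offsets = np.log(ec.counts.sum(axis=0).astype(float) * factors)
            exon_fit = fit_exon_glm(ec, design, exon_offsets)
            for contrast in CONTRASTS:
                ds = run_differential_splicing(
                    ec, design, contrast, alpha=config.alpha, fit=exon_fit
                )
                tag = "vs".join(contrast)
                ds.exon_table.to_csv(out / f"splice_exons_{tag}.tsv", sep="\t", index=False)
                ds.gene_table.to_csv(out / f"splice_genes_{tag}.tsv", sep="\t")
                dsg_sets[contrast] = set(ds.dsgs())
            summary["dsg_counts"] = {"vs".join(c): len(s) for c, s in dsg_sets.items()}
            log(
                "stage=diffsplice DSGs "
                + " ".join(f"{k}={v}" for k, v in summary["dsg_counts"].items())
            )

        # ------------------------------------------------ network
        stage = "network"
        net = None
        if config.run_network:
            adj_expr = adjust_family(logcpm, samples)
            frame = pd.DataFrame(
                adj_expr.values, index=cm.gene_ids, columns=cm.sample_ids
            )
            net = build_network(frame, config.network)
            module_tab = pd.DataFrame(
                {
                    "gene_id": net.gene_ids,
                    "module": [net.labels[g] for g in net.gene_ids],
                    "k_total": net.k_total.to_numpy(),
                }
            )
            module_tab.to_csv(out / "modules.tsv", sep="\t", index=False)
            net.soft_threshold_table.to_csv(
                out / "soft_threshold.tsv", sep="\t", index=False
            )
            net.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t", index=False)
            summary["beta"] = net.beta
            summary["n_modules"] = int(
                len([m for m in set(net.labels.values()) if m != "M0"])
            )
            summary["median_k_total"] = float(net.k_total.median())
            log(f"stage=network beta={net.beta} modules={summary['n_modules']}")

        # ------------------------------------------------ set statistics
        stage = "geneset_stats"
        main = ("LL", "CC")
        if net is not None and main in deg_sets:
            degs = set(deg_sets[main])
            dsgs = set(dsg_sets.get(main, set()))
            both = degs & dsgs
            deg_only = sorted(degs - both)
            dsg_only = sorted(dsgs - both)
            summary["n_deg_dsg_both"] = len(both)

            ct = crosstab_modules(degs, dsgs, net.labels)
            ct.to_csv(out / "module_crosstab.tsv", sep="\t")

            perm_rows = []
            value_sets = {"k_total": net.k_total}
            if tpm is not None:
                mean_tpm = pd.Series(
                    tpm.values.mean(axis=1), index=cm.gene_ids, name="tpm"
                )
                value_sets["mean_tpm"] = mean_tpm
            for vname, vals in value_sets.items():
                vals = vals.reindex([g for g in cm.gene_ids if g in vals.index]).dropna()
                comparisons = {}
                if deg_only and dsg_only:
                    comparisons["deg_vs_dsg"] = (deg_only, dsg_only)
                if deg_only:
                    comparisons["deg_vs_all"] = (deg_only, None)
                if dsg_only:
                    comparisons["dsg_vs_all"] = (dsg_only, None)
                for cname, (sa, sb) in comparisons.items():
                    sa = [g for g in sa if g in vals.index]
                    sb = None if sb is None else [g for g in sb if g in vals.index]
                    if not sa or (sb is not None and not sb):
                        continue
                    pr = perm_median_diff(
                        vals, sa, sb, B=config.permutations, seed=config.seed
                    )
                    perm_rows.append(
                        {
                            "value": vname,
                            "comparison": cname,
                            "observed": pr.observed,
                            "B": pr.B,
                            "exceed_count": pr.exceed_count,
                            "p": pr.p,
                            "display": pr.display,
                        }
                    )
            perm_tab = pd.DataFrame(perm_rows)
            perm_tab.to_csv(out / "permutation_tests.tsv", sep="\t", index=False)
            summary["permutation_tests"] = perm_rows

            if degs and dsgs:
                ov = perm_overlap(
                    cm.n_genes, len(degs), len(dsgs), len(both),
                    B=config.permutations, seed=config.seed,
                )
                summary["deg_dsg_overlap"] = {
                    "observed": len(both),
                    "p": ov.p,
                    "display": ov.display,
                    "exact_hypergeom_p": ov.exact_p,
                }
            log("stage=geneset_stats permutation comparisons done")

        # ------------------------------------------------ atomization / hubs
        stage = "subnetworks"
        if net is not None:
            if config.atomize and ec is not None:
                adj_expr = adjust_family(
                    to_units(
                        CountMatrix(list(ec.exon_ids), list(ec.sample_ids), ec.counts),
                        factors,
                        units="log2CPM",
                    ),
                    samples,
                )
                exon_frame = pd.DataFrame(
                    adj_expr.values, index=ec.exon_ids, columns=ec.sample_ids
                )
                atom_tabs = []
                for gid in config.atomize:
                    idx = ec.exon_indices_of_gene(gid)
                    if idx.size == 0:
                        raise KeyError(f"gene {gid!r} absent from exon matrix")
                    tab = atomize_gene(gid, exon_frame.iloc[idx], net)
                    tab.insert(0, "gene_id", gid)
                    atom_tabs.append(tab)
                pd.concat(atom_tabs).to_csv(out / "atomization.tsv", sep="\t")
            hub_modules = [
                m for m in sorted(set(net.labels.values())) if m != "M0"
            ][:2]
            edges = []
            for m in hub_modules:
                e = extract_subnetwork(net, m, n=10)
                e.insert(0, "focal", m)
                edges.append(e)
            if edges:
                pd.concat(edges).to_csv(out / "hub_edges.tsv", sep="\t", index=False)
            log("stage=subnetworks hub edge lists written")

        # ------------------------------------------------ summary
        stage = "summary"
        summary["parameters"] = {
            "min_count": config.min_count,
            "tau": config.tau,
            "alpha": config.alpha,
            "mds_top": config.mds_top,
            "prior_df": config.prior_df,
            "permutations": config.permutations,
            "network": asdict(config.network),
        }
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True, default=_json_default)
        log("stage=summary bundle complete")
        return summary
    except Exception as exc:
        log(f"stage={stage} FAILED: {exc}")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        log.close()


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
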