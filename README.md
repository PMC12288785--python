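# edanet

Differential expression, differential exon usage and signed co-expression
network analysis for genotype-contrast RNA-seq designs — plus a seeded
synthetic-data generator with planted truth so the whole chain can be
exercised and calibrated end to end.

The design the package targets is a three-genotype (CC/CL/LL) study such
as an *Eda*-haplotype stickleback experiment: 3 families x 3 genotypes x
2 sexes x 2 replicates = 36 samples, with the L allele acting recessively
(CC ≈ CL, LL differs).

## What's inside

| Module | What it does |
| --- | --- |
| `edanet.simulate` | Synthetic counts with planted DEGs, spliced genes, co-expression modules, family batch factor and an NB dispersion trend; full truth ledger |
| `edanet.io` | Count/metadata/GMT readers and writers, the low-expression filter |
| `edanet.expression` | TMM normalization, CPM/TPM/log2-CPM, family adjustment, leading-logFC MDS |
| `edanet.diffexpr` | NB GLM with trended/shrunken dispersions and the TREAT fold-change-threshold test (default: 1.5-fold, i.e. 0.585 log2 units) |
| `edanet.diffsplice` | Exon-usage GLM, chi-square and Simes gene-level routes, union DSG call |
| `edanet.network` | bicor → signed adjacency (soft-threshold scan) → TOM → modules, kTotal, kME, exon atomization, hub subnetworks |
| `edanet.permstats` | Median-difference and overlap permutation tests, hypergeometric ORA, module crosstabs |
| `edanet.pipeline` / CLI | End-to-end orchestration with byte-deterministic output bundles |

## Worked example

Simulate a small study and test for differential expression beyond a
1.5-fold threshold:

```python
import numpy as np
from edanet import SimulationConfig, generate_dataset
from edanet.io import filter_low_expression
from edanet.expression import tmm_factors
from edanet.diffexpr import (
    CONTRASTS, build_design, call_degs,
    estimate_dispersions, fit_nb_glm, treat_test,
)

counts, exons, samples, lengths, truth = generate_dataset(
    SimulationConfig(n_genes=800, n_modules=4, module_size=80,
                     n_deg=60, n_dsg=30, seed=7)
)
counts = filter_low_expression(counts)          # drop low genes (10 in >= n/3)
factors = tmm_factors(counts)                   # TMM normalization
design = build_design(samples)                  # ~ genotype + family + sex
offsets = np.log(counts.library_sizes() * factors)

disp = estimate_dispersions(counts, design, offsets)
fit = fit_nb_glm(counts, design, offsets, disp)
results = {c: treat_test(fit, c, tau=0.585) for c in CONTRASTS}
deg_sets, overlap = call_degs(results, alpha=0.05)

for contrast, genes in deg_sets.items():
    print(f"{contrast[0]} vs {contrast[1]}: {len(genes)} DEGs at FDR 0.05")
print(overlap.to_string(index=False))
```

Output:

```
LL vs CC: 48 DEGs at FDR 0.05
CL vs CC: 0 DEGs at FDR 0.05
LL vs CL: 50 DEGs at FDR 0.05
contrast_a contrast_b  n_a  n_b  overlap
    LLvsCC     CLvsCC   48    0        0
    LLvsCC     LLvsCL   48   50       46
    CLvsCC     LLvsCL    0   50        0
```

The recessive pattern is exactly what the design plants: CLvsCC calls
nothing, while LLvsCC and LLvsCL call overlapping sets. Of the 48 LLvsCC
calls, all are planted genes (sensitivity 0.81, zero false discoveries on
this seed).

The `examples/` directory walks through the other capabilities as short
narrative scripts:

- `01_simulate_and_explore.py` — simulation, filtering, TMM, leading-logFC MDS
- `02_differential_expression.py` — the TREAT analysis above
- `03_differential_splicing.py` — exon usage, both aggregation routes, union call
- `04_network_and_connectivity.py` — network build, module recovery, kTotal permutation test, exon atomization

## Command line

```bash
# generate a dataset with planted truth
edanet simulate --outdir sim --seed 1234 --n-genes 1000

# run the full pipeline on it (or on your own TSVs)
edanet run --gene-counts sim/gene_counts.tsv --exon-counts sim/exon_counts.tsv \
           --samples sim/samples.tsv --outdir run1 --seed 1234

# or simulate-and-run in one step
edanet run --simulate --n-genes 1000 --outdir run2 --seed 1234
```

Every table the pipeline produces is a TSV under `--outdir`, together
with a `summary.json` whose numbers are all recomputable from the tables.
Two runs with the same seed produce byte-identical bundles.

## Testing

```bash
python -m pytest -q tests/
```

The suite contains unit and property tests for every module plus
`tests/test_acceptance.py`, which checks the package's six shipped
guarantees (threshold identity, oracle equivalence of core primitives,
null calibration, planted-effect recovery, permutation-test behaviour,
byte determinism).

## Documentation

`docs/methods.md` documents the statistical methods, every default
parameter with its rationale, and the limitations.
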