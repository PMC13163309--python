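# netprio

Network-guided prioritization of drug targets and candidate metabolites, built
as a tested, reusable pipeline. It covers the computational chain used in
integrative pharmacology studies of chemotherapy-induced stress adaptation:
two-condition RNA-seq differential expression, pathway over-representation, a
weighted composite gene-prioritization score, protein–protein interaction
(PPI) topology statistics, PLS-DA/VIP metabolite selection, docking-table
ligand ranking, and four-parameter-logistic (4PL) IC50 estimation from
microplate viability assays.

The package is aimed at computational biologists who want each of these steps
as an auditable function with explicit thresholds, plus seeded synthetic-data
generators with planted ground truth so the whole chain can be exercised and
benchmarked without access to the original raw data.

## The score at the core

Genes contributing to enriched pathways are ranked by a composite score

```
Score = 0.5 · [−log10(p.adjust)] + 0.3 · log2(FPKM + 1) + 0.2 · PathwayRelevance
```

where `p.adjust` is the Benjamini–Hochberg-adjusted enrichment p-value, FPKM
is expression abundance, and the relevance weight is 1.0 for genes in the top
five enriched pathways, 0.5 for genes in other significantly enriched
pathways. Downstream, targets must additionally satisfy |log2FC| ≥ 0.5,
FDR < 0.05, a top-20 composite rank, and a curated functional-annotation flag.

Other stage conventions, all exposed as parameters with these defaults:
DEG filter |log2FC| ≥ 0.5 (inclusive) and FDR < 0.05 (strict); PPI edges kept
at combined score ≥ 0.700; metabolites kept at VIP > 1.5, p < 0.05,
FDR < 0.05, fold change > 2.0; ligands ranked per target by docking score
(most negative first) with top-3 retained; viability fitted with
`y = bottom + (top − bottom) / (1 + (x/IC50)^hill)`.

## Worked example

The package ships two checksum-verified tables from the study it models: the
top-20 prioritized genes (with their score inputs) and the 50-row per-target
docking results. Fixture mode re-runs the analytical chain from those inputs:

```python
from netprio import reproduce_table1, run_all
from netprio.pipeline import PipelineConfig

cmp = reproduce_table1()
print(cmp.head(3).to_string(index=False))
report = run_all(PipelineConfig(mode="fixture", seed=1))
print("targets:", report["prioritize"]["targets"])
print("assay candidates:", sorted(set(report["dockrank"]["assay_candidates"].values())))
```

prints

```
 gene  computed_score  printed_score  abs_diff  mismatch
  APP           5.862          5.862       0.0     False
FGFR3           4.966          4.966       0.0     False
 BRAF           4.966          4.966       0.0     False
targets: ['BRAF', 'MAOB', 'PARP1', 'BACE1', 'GSK3β']
assay candidates: ['Amino(1H-indol-2-yl)acetic acid', 'Lactol', 'Quercetin 3-(6″-malonyl-glucoside)']
```

i.e. the recomputed composite scores match the published score column (19 of
20 rows to half a printing ulp; one row is printed truncated rather than
rounded — see `docs/methods.md`), the five-gene target set falls out of the
multi-criteria gate, and the per-target docking ranking plus the
molecular-dynamics pass list reproduce the three compounds taken into the
viability assay.

Synthetic mode generates every input with known truth and reports recovery:

```sh
netprio run --synthetic --seed 7 --out out/
netprio simulate --seed 7 --out sim/                # or stage by stage:
netprio ic50 --plate sim/plate.csv --out fits.tsv
```

A seed-7 run reports DE sensitivity 0.84 at empirical FDR 0.0, metabolite
selection sensitivity 1.0, and hub recall 1.0 against the planted truth.

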