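# mzt — maternal mRNA clearance analysis for the maternal-to-zygotic transition

During the maternal-to-zygotic transition (MZT), transcripts deposited in the
oocyte are cleared by two sequential pathways: **M-decay**, driven entirely by
maternal factors before zygotic genome activation (ZGA), and **Z-decay**,
which requires de novo zygotic transcription. In human embryos ZGA occurs at
the 8-cell stage, and failure of either clearance pathway is associated with
preimplantation developmental arrest in IVF embryos. `mzt` is a reusable,
tested implementation of the transcriptome analysis behind this biology, for
reproductive/developmental biologists working with stage-wise FPKM matrices,
single-embryo RNA-seq profiles, 3′-UTR annotations, and RT-qPCR Ct tables.

## What it computes

**Decay-cluster classification.** Maternal transcripts (mean GV-oocyte
FPKM > 2) are partitioned by their log-profiles E(s) = log₂(FPKM(s) + 1)
across GV → zygote → 8-cell with margin m = 1 (a 2-fold rule):

| Cluster | Rule | Interpretation |
|---|---|---|
| I | E(GV) > E(zyg)+m and E(zyg) ≤ E(8c)+m | degraded before fertilization (M-decay) |
| II | \|E(GV)−E(zyg)\| within m and E(zyg) > E(8c)+m | degraded after the zygote stage (Z-decay) |
| III | E(GV) > E(zyg)+m and E(zyg) > E(8c)+m | continuously degraded |
| IV | both transitions within m | stable through MZT |

Genes matching no rule (e.g. up-regulated) are UNCLASSIFIED; the predicates
are provably mutually exclusive. Cluster IV genes are optionally flagged as
degraded between the 8-cell and morula stages by the same 2-fold rule.

**ZGA-dependence calling.** For Cluster II/III genes that decay ≥2-fold in
control embryos ((FPKM(8c)+1)/(FPKM(zyg)+1) < 0.5), decay is called
ZGA-*dependent* when blocking RNA-polymerase-II transcription with
α-amanitin abolishes the drop (treated E(zyg) − E(8c) < 1 while the control
drop is ≥ 1), and ZGA-*independent* otherwise.

**3′-UTR features.** Exact strand-specific scans for the cytoplasmic
polyadenylation element (CPE: UUUUAU/UUUUAAU) and the polyadenylation signal
(PAS: AAUAAA/AUUAAA) in the DNA alphabet, counting every start position
(overlaps included); lengths and counts are compared between M-decay
(Cluster I) and Z-decay (Cluster II) transcripts by a two-tailed pooled
Student's *t*-test.

**Embryo QC and decay-defect diagnosis.** Pearson correlation and
prcomp-convention PCA on log₂(FPKM+1); pseudocounted fold-change tables at
2×/5×; upper-tail hypergeometric set-overlap enrichment; an M-decay defect
caller (≥4 of 6 panel markers accumulated with one-way ANOVA significance vs
control zygotes) and a Z-decay defect caller (Group A = transcripts normally
degraded zygote→8-cell but stable in an arrested 8-cell embryo, tested for
enrichment among the embryo's accumulated transcripts).

**qPCR quantification.** Relative levels 2^(Ct_ref − Ct_gene) against a
reference gene (GAPDH by convention), technical replicates averaged on the
Ct scale, with *t*-test/ANOVA group comparisons.

**Synthetic data.** Every input above can be generated with planted ground
truth (decay clusters, ZGA dependence, motif positions, defect labels) so the
full pipeline is testable offline; see `docs/methods.md` for the generative
model.

## Worked example

Simulate a 2,000-gene experiment end to end and summarize it:

```sh
mzt report --seed 7 --out report.json --n-genes 2000 --n-embryos 10
```

prints `{I: 676, II: 613, III: 285, IV: 426}` — the decay-cluster sizes
recovered from the simulated stage matrix (the generator plants the four
clusters in the proportions 2372:2259:1109:1531 observed in human embryos).
`report.json` additionally contains:

* `utr_length_comparison` — mean 3′-UTR length 526 nt for M-decay vs
  1052 nt for Z-decay transcripts (t = −32.7, p ≈ 4e−171): Z-decay UTRs are
  simulated twice as long, and the comparison recovers that design.
* `defect_calls` — per-embryo M-decay diagnoses for the simulated arrested
  cohort (here 7 of 10 embryos carry a planted defect and all are called
  `M_DECAY_DEFECT`; the rest are `NO_DEFECT`).

The same steps run from Python:

```python
from mzt import synthetic_data as synth, classify_decay, classify_morula_extension

matrix, truth = synth.generate_stage_matrix(n_genes=2000, seed=7)
classes = classify_morula_extension(matrix, classify_decay(matrix))
print(classes.counts())
(classes.table["cluster"] == truth.genes["expected_call"]).mean()  # ~0.99
```

Individual steps are exposed as subcommands: `mzt classify`, `mzt zga`,
`mzt utr`, `mzt qc`, `mzt defects`, `mzt qpcr`, `mzt simulate`. Every run
writes a `*.provenance.json` with the full configuration and seed; identical
configuration and seed reproduce outputs byte-identically.

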