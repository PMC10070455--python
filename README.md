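# rewire3d

Comparative multi-omics analysis of 3D genome rewiring between two related
samples — a primary state (PR) and a derived state (CR), such as a
chemotherapy-resistant subline of the same tumor.

Acquired drug resistance in cancer is accompanied by reorganization of the
three-dimensional genome: gains and losses of chromatin loops and
topologically associating domains (TADs), switching of megabase-scale A/B
compartments between active and inactive states, and copy-number
rearrangements that reshape both the contact map and expression. `rewire3d`
implements the full comparative pipeline for paired Hi-C, WGS-coverage,
structural-variant and expression data, and ships a synthetic-data
generator with recorded ground truth so every stage is testable end to end
without any sequencing download.

## What it computes

**Contact maps** (`rewire3d.contact_map`) — sparse-text I/O, VC/ICE
balancing, distance-decay curves and differential decay
`log2((a+pc)/(b+pc))`, power-law decay-exponent fits, the map-resolution
rule (≥ 80% of bins with > 1000 contacts), a stratum-adjusted correlation
for reproducibility, and classical MDS of `1 − scc` distances.

**A/B compartments** (`rewire3d.compartments`) — the compartment score is
the eigenvector of the O/E correlation matrix best correlated with gene
density, oriented so A (active) is positive. Saddle analysis bins the
genome into score quantiles and summarizes corner enrichments as the A–A,
B–B and A–B strengths and the compartmentalization score

```
score = log2( (A-A) · (B-B) / (A-B)² )
```

Differential compartments quantile-normalize the per-sample scores, test
each bin's between-condition difference with a Mahalanobis/chi-square
statistic against replicate variation, control FDR at 0.3, classify
switches (AA/AB/BA/BB), and count genes in switching regions.

**Loops and TADs** (`rewire3d.loops_tads`) — a donut-style local-enrichment
loop caller (Poisson upper tail, BH FDR < 0.05, non-maximum suppression),
common/condition-specific partition of loops and anchors with a one-bin
flank, aggregate peak analysis with center-to-corner ratios,
insulation-score TAD boundaries, CTCF motif annotation with
convergent/tandem/divergent loop classes, circular-permutation region
association, and loop-size statistics with rank-sum tests.

**Copy number and SVs** (`rewire3d.variants`) — coverage log2 ratios,
circular binary segmentation with permutation-calibrated splits, ≥ 5-read
support filtering, ≥ 2-caller consensus with 500 bp / 1 kb type-specific
windows, condition-specific SV intersection, and gene-level CNV classes
with genome-wide deleted/duplicated totals.

**Integration** (`rewire3d.integration`) — ranking metrics (signed
−log10 p, coverage-weighted, compartment delta), 1-SD-filtered Pearson
correlation between omics layers, pre-ranked GSEA, hypergeometric set
enrichment, the five-layer importance score (genes with ≥ 4 evidence flags
are prioritized), and the immunohistochemistry optical-density statistic
`OD = log10(255 / mean intensity)`.

**Synthetic data** (`rewire3d.synthetic_data`) — Poisson contact maps with
power-law decay, a ±1 compartment checkerboard, nested TADs, focal loops
and multiplicative CNVs; paired-condition rewiring (block flips, loop
gains/losses, TAD splits); coverage, per-caller SV call sets, coupled
expression tables, and gene/motif/GC annotation tracks — all against a
recorded `GroundTruth`.

## Worked example

```python
import numpy as np
from rewire3d import synthetic_data as sd, contact_map as cm
from rewire3d import compartments as comp, loops_tads as lt

rng = np.random.default_rng(0)
signs = sd.checkerboard_signs(800, 40)
loops = sd.random_loop_positions(10, 800, rng, boost=3.0, signs=signs)
spec = sd.SimulationSpec(n_bins=800, depth=5e5, compartment_effect=0.4,
                         loop_list=loops, seed=1)
rew = sd.RewiringSpec(flip_block_fraction=0.2, cnv_list=[(100, 160, 2.0)], seed=2)
map_pr, map_cr, truth = sd.simulate_condition_pair(spec, rew)

bal = cm.balance(map_pr, method="ICE")
genes, motifs, gc = sd.simulate_annotation_tracks(spec, truth, seed=3)
gd = sd.gene_density_track(genes, spec.n_bins, spec.resolution)
track = comp.call_compartments(bal, gd, gc)
valid = np.isfinite(track.scores)
agree = np.mean(np.sign(track.scores[valid]) == truth.signs_pr[valid])
saddle = comp.saddle_summary(bal, track, n_groups=20)
calls = lt.call_loops(map_pr)

print(f"compartment sign agreement: {agree:.3f}")
print(f"A-A strength: {saddle.aa_strength:.2f}  B-B: {saddle.bb_strength:.2f}  "
      f"A-B: {saddle.ab_strength:.2f}  score: {saddle.score:.2f}")
print(f"loops called at FDR<0.05: {len(calls)} (10 planted)")
```

prints

```
compartment sign agreement: 0.999
A-A strength: 1.17  B-B: 1.17  A-B: 0.61  score: 1.89
loops called at FDR<0.05: 11 (10 planted)
```

The eigenvector recovers 99.9% of the planted compartment signs; same-state
contacts are enriched (A–A and B–B strengths 1.17) while cross-state
contacts are depleted (0.61), giving a compartmentalization score of 1.89;
and the caller finds the ten planted loops (plus one near-duplicate pixel).
Reproducibility behaves as replicate structure demands: on this simulation
`scc` is 0.706 within condition and 0.097 between the rewired conditions,
and the fitted decay exponent is 1.010 ± 0.019 against a planted α = 1.

A thin CLI covers the pipeline entry points:

```sh
rewire3d simulate --spec spec.yaml --outdir sim/
rewire3d balance --in sim/pr.contacts.txt --out pr.bal.txt --n-bins 800 --method ice
rewire3d loops --in sim/pr.contacts.txt --out loops.tsv --n-bins 800 --fdr 0.05
```

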