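# bacpanel

Comparative genomics of signal-transduction-rich bacteria, packaged as a
testable pipeline. Social, pattern-forming soil bacteria such as
*Paenibacillus vortex* carry unusually many regulatory and environment-sensing
genes; quantifying that claim requires counting two-component system (TCS),
transcription factor (TF), transport and defense genes consistently across a
large panel of genomes, standardizing the counts, and asking where one genome
sits in the resulting distribution. `bacpanel` implements that analysis plus
the genome-project QC that surrounds it: assembly reconciliation between two
contig sets, coverage-window flagging and copy-number-by-coverage for
collapsed repeats, repeat catalogues, chromosomal organization of TCS genes,
and a neighbor-joining 16S tree with bootstrap support. Everything runs on
synthetic fixtures with known ground truth, so no external downloads are
needed to exercise or validate any stage.

Intended users: microbial genomicists who want reproducible category
inventories and panel statistics for their own genome sets, and developers
who need a reference implementation of these classic analyses with oracle
tests attached.

## The combined score

For genome *g* and category *c* ∈ {TCS, TF, transport, defense} with count
x₍g,c₎ over a panel of *n* genomes:

    z_{g,c} = (x_{g,c} − μ_c) / σ_c         (population sd, divisor n)
    S_g     = (1/4) Σ_c z_{g,c}

The size-normalized variant standardizes densities d₍g,c₎ = x₍g,c₎ / Mbp
instead of raw counts. Genomes are ranked by percentile (ties share the
lower rank) and flagged when they fall in a configurable upper tail.
Category membership is decided by editable rule lists: Pfam-style domain
accessions for TCS (receiver domain → response regulator, kinase-core
domains → histidine kinase, both → hybrid kinase) and TFs, COG ids and COG
category letters for transport and defense genes.

## Worked example

```python
from bacpanel import synthetic_data as sim
from bacpanel import build_inventory, combined_scores, rank_and_flag
from bacpanel import tcs_topology as tt

panel, truth = sim.gen_panel(seed=42)          # 500 genomes, 2-10 Mbp
scores = combined_scores(panel)
flags = rank_and_flag(scores, top_fraction=0.01)
top = scores.idxmax()
print("planted outlier:", truth["outlier_id"])
print("top combined score: %s (S = %.2f)" % (top, scores[top]))
print("genomes flagged in the upper 1%%: %d" % flags["flagged"].sum())

genome, _ = sim.gen_annotated_genome(seed=42)  # planted TCS architecture
inv = build_inventory(genome)
print("category counts:", inv.counts)
recs = tt.build_tcs_records(genome, inv.tcs_roles)
tt.organize_tcs(genome, recs)
print("TCS organization:", tt.organization_counts(recs))
```

prints

```
planted outlier: G0082
top combined score: G0082 (S = 2.98)
genomes flagged in the upper 1%: 5
category counts: {'tcs': 19, 'tf': 5, 'transport': 4, 'defense': 3}
TCS organization: {'paired': 10, 'orphan': 3, 'complex': 6}
```

The synthetic panel plants one genome at +3 panel-sd in all four categories;
the combined score ranks it first and the 1% flag catches it. The annotated
genome plants 5 adjacent HK–RR pairs (10 paired genes), 3 isolated TCS genes
(orphans) and 2 three-gene clusters (6 complex genes), which the
organization step recovers exactly.

A `bacpanel` console script exposes the same steps as verbs
(`simulate`, `inventory`, `classify`, `tcs-topology`, `panel-stats`,
`assembly-qc`, `repeats`, `phylo`, `report`); see `bacpanel --help`.

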