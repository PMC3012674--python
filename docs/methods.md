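# Methods

This note documents the models, parameter choices and numerical conventions
behind `bacpanel`, and what the synthetic fixtures do and do not establish
about behavior on real data.

## Genome model and coordinates

Genes live on named replicons with 0-based half-open coordinates
internally; every file format read or written (GFF3, the simple feature
TSV, BED/bedGraph follow their own native conventions) converts exactly
once at I/O time, so length arithmetic inside the package is always
`end − start`. Domain hits are read from hmmscan-style `--tblout` tables
and filtered at a configurable full-sequence e-value (default ≤ 1e-5); the
original study does not state its inclusion criteria, so this is a package
default, not a reproduction. Pfam accession versions are stripped
(`PF00072.25` → `PF00072`).

## Category rules

Classification is purely data-driven from rule lists (YAML, one section per
category with `pfam:`, `cog_id:`, `cog_cat:` keys). The shipped defaults
are labeled stand-ins: a receiver-domain set ({PF00072}) and a
kinase-core set (HisKA/HisKA_2/HisKA_3/HWE_HK/HATPase_c/H-kinase_dim) for
TCS, ten common bacterial DNA-binding regulator families for TFs, a list of
ABC-transporter/permease/MFS COGs for transport, and defense COGs plus COG
category V for defense. Users with curated lists substitute their own file.

TCS role logic: receiver only → RR, kinase core only → HK, both → hybrid.
A TCS gene is excluded from the TF count even when it carries a DNA-binding
output domain; this keeps the four scored categories non-overlapping for
TCS/TF and avoids double-weighting one gene in the combined score. RR
structural families are assigned from the best-scoring (bit score) output
domain present in a configurable domain→family map; genes with no mapped
output domain are "other".

## TCS organization and neighborhoods

TCS genes are walked in coordinate order; maximal runs with consecutive
inter-gene gaps ≤ `pair_gap_bp` (default 200 bp, strand-agnostic — typical
operon spacing; the classification scheme this follows states no threshold)
are formed. A two-gene run of one HK-like gene (HK or hybrid — hybrids
carry the kinase core, so they pair) and one RR is *paired*; runs of three
or more are *complex*; everything else is *orphan*. The three labels
partition the TCS set by construction, and the implementation is checked
against a brute-force run-enumeration oracle.

Neighborhood profiles collect every non-TCS gene within ±`window_genes`
(default 5) positions of any TCS gene, deduplicated across overlapping
windows, truncated at replicon edges. Each neighbor with COG annotation
maps through a configurable COG-letter→class table (defaults: G/E/P/U →
transport, K/T → regulatory, C → energy metabolism, otherwise "other");
fractions are over classified neighbors only. When a neighbor's letters map
to several classes, a fixed priority (transport > regulatory > energy
metabolism) breaks the tie deterministically.

Category loci (e.g. flagellar or biosynthetic gene clusters) use the same
run construction with `max_gap_bp` default 5,000 — kb-scale loci — and are
verified against a union-find oracle.

## Panel statistics

Standardization uses the population standard deviation (divisor n): the
panel is treated as the population of interest. A zero-variance category
yields all-zero z-scores with a warning rather than NaNs. The combined
score is the unweighted mean of the four category z-scores; "normalized to
genome size" divides counts by Mbp before standardizing. Percentile rank
counts strictly smaller values, so ties share the lower rank and flagging
is conservative. Count-vs-size regression is ordinary least squares on size
in Mbp (scipy `linregress`), reporting signed Pearson r. COG-profile
clustering computes the Pearson correlation matrix of per-genome COG
abundance vectors (zero-variance profiles get correlation 0, with a
warning) and orders genomes by average-linkage hierarchical clustering on
distance 1 − r; the linkage choice is a package decision, since the source
figure names none.

## Assembly reconciliation and coverage

Contigs are placed on scaffolds by k-mer seeding (default k = 31) with
full-length extension in both orientations, accepted when
mismatches/span ≤ `max_mismatch_frac` (default 0.01). When two distinct
candidate placements tie at the minimal mismatch count the contig is
reported unplaced as ambiguous: determinism over guessing. Signed
inter-contig distance is `next.start − prev.end` between consecutive
placements on one scaffold (negative = overlap); identity is base-weighted
across placements; coverage uses merged intervals.

Coverage windows are non-overlapping 5,000 bp tiles (the per-window
averaging reads most naturally as tiling; width is configurable), flagged
high/low outside mean ± n·sd (default n = 2) of the window means. Copy
number of a region is the ratio of its window-mean depth to the genome-wide
mean, plus a nearest-integer estimate.

Repeat definitions: *global* repeats are maximal non-nested intervals whose
sequence occurs at ≥ 2 distinct positions (seeded by repeated L_g-mers,
default L_g = 25, extended to pair-maximal matches); *local inverted*
repeats are maximal exact reverse-complement arm pairs (arm ≥ 10 bp) around
a loop ≤ 100 bp; *tandem* repeats are maximal runs of periods 1–6 with ≥ 3
copies, reported at their smallest period only. All three agree with
O(n²)–O(n³) brute-force oracles on sequences up to 300 bp. Scaffold-end
statistics take both 100 bp termini of every scaffold, search both strands
of every other end for the longest shared exact substring ≥ 20 bp, and
report the matched fraction (over all ends), mean match length and mean
number of ends matched (over matched ends). Whether both termini and both
strands should be counted is not specified by the source analysis; counting
both is this package's convention.

## Phylogenetics

Distances: `p` (mismatch fraction over pairwise-complete sites), `jc`
(−3/4 ln(1 − 4p/3), undefined at p ≥ 3/4, reported as an error naming the
pair), and `tn93_pooled` — Tamura–Nei 1993 with base frequencies pooled
over all sequences and per-pair transition/transversion proportions. The
pooled-TN93 form is an explicit stand-in for composite-likelihood
distances: on equal-frequency, equal-rate data it converges to the JC
distance (verified within 2% at p ≈ 0.1 on 10 kb), but exact equivalence to
any particular composite-likelihood implementation is not claimed.

Neighbor joining is the canonical Q-criterion agglomeration with
deterministic tie-breaking (lowest node-index pair) and negative branch
lengths clamped to zero; the three-taxon closed form is exact and additive
matrices are recovered perfectly (checked over 100 random 5–12 taxon
trees, and against an independent NJ implementation). Bootstrap resamples
columns with replacement from a seeded generator; support is the
percentage of replicate trees containing each internal bipartition of the
full-data tree. Saturated replicates (undefined distances) contribute no
support rather than aborting the run.

## Synthetic data

Generators fan one global seed into independent numpy streams (one fixed
stream id per generator), so regenerating one fixture never perturbs
another; everything is bit-reproducible given (config, seed) and returns
machine-readable ground truth.

* **Panel**: 500 genomes (default) with sizes uniform on 2–10 Mbp and
  counts `round(slope·Mbp + N(0, sd))` floored at 0. Default slopes/noise
  (TCS 8/Mbp ± 15, TF 26/Mbp ± 40, transport 50/Mbp ± 60, defense
  10/Mbp ± 8) put panel means and spreads in the range reported for large
  bacterial panels at the default size distribution. One genome is
  generated at mean + 3 panel-sd in all four categories; panel sd (not
  noise sd) is the right unit because between-genome spread is dominated by
  the size trend.
* **Annotated genome**: planted HK–RR pairs (50 bp internal gaps), isolated
  orphans and ≥ 3-gene clusters separated by 1,000 bp unit gaps (safely
  above the 200 bp pairing threshold), plus planted TF/transport/defense
  genes drawn from the default rule lists and COG-annotated filler genes.
  Gene length 900 bp, typical of bacterial CDSs.
* **Assembly**: a 50 kb random reference (uniform base composition)
  carrying one collapsed repeat unit; the scaffold equals the reference;
  contig sets fragment it with configurable signed junction offsets
  (default −5 bp overlap in one set, matching the magnitude of real
  inter-contig overlaps) and independent per-base substitution rates
  (default 0.002, i.e. 99.8% identity); the Poisson coverage track
  multiplies baseline depth (default 100×) by the copy number over the
  repeat locus. Substitution-only mutation keeps placements length-exact
  and identity analytically checkable; indels are out of scope.
* **Alignment**: i.i.d. Jukes–Cantor evolution along a random (or supplied)
  binary tree, branch lengths uniform on 0.02–0.15 substitutions/site.

What passing these tests shows — and does not. The fixtures establish
correctness of the arithmetic, the rule engine, the clustering/organization
logic, placement/reconciliation and the tree machinery under the stated
generative models. They do not establish that the default rule lists match
any curated domain list, that real assemblies satisfy the
substitution-only/unique-seed assumptions, or that real coverage tracks are
Poisson; headline counts from real genome panels depend on database
versions and scan parameters and are out of scope.

## Numerical conventions and degenerate inputs

Percentages print with round-half-away-from-zero to integers, recorded in
report metadata. Zero-variance columns/profiles are defined (0 with a
warning), not errors; single-genome panels, identical-size regressions,
empty length lists, saturated JC pairs, and sub-4-column alignments are
errors. Empty TCS sets give empty (not erroneous) neighborhood profiles.
Problem sizes in tests and the acceptance script (100-seed panels of 500,
50 kb assemblies, 300 bp oracle sequences, 500 bootstrap replicates) were
chosen so each check has clear statistical power while the whole suite runs
in seconds.

## Known limitations

* Default category rules are stand-ins; absolute counts on real genomes
  are rule-list-dependent by design.
* Placement assumes contigs embed fully within scaffolds (no split or
  partial placements) and has no indel handling.
* `tn93_pooled` is not a composite-likelihood implementation.
* The repeat finders are exact-match finders; diverged repeat copies are
  not detected.
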