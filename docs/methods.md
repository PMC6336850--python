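# Methods

This note records the models behind each pipeline stage, the defaults that
matter, the choices made where the design was genuinely open, and what the
synthetic studies do and do not demonstrate.

## Genome simulation and the ANI truth

Genomes are evolved along a user-supplied tree (taxa = genomes, branch
lengths = expected substitutions/site) from a uniform-random ancestor under
a Jukes–Cantor process: on a branch of length *t*, each site is replaced by
a uniformly random base (possibly the same) with probability 1 − e^(−4t/3).
This per-branch rule composes exactly to the JC transition matrix, so the
expected per-site identity between two leaves separated by path length *d*
is 1 − ¾(1 − e^(−4d/3)) — a closed form the ANI estimator must recover.
There are no indels by default; indel-free evolution is what makes the
truth exact. Sequences are single-contig; the ancestor must be at least
10× the ANI fragment length (15 kb at the 1500 bp default) so fragment
mapping is actually exercised. Completeness and contamination estimates are
drawn uniformly from (70, 100) % and (0, 4) % respectively — a clean bin
set; quality-gate behaviour is tested separately with explicit values.

All five generators draw from independent seed streams derived from
`(seed, stream-tag)`, so identical `(seed, spec)` pairs give identical
output and adding one stage never perturbs another.

## ANI estimation and dereplication

The estimator chops the query into non-overlapping 1500 bp fragments,
places each on the reference by exact 16-mer diagonal voting (most shared
k-mers wins; ties to the smallest offset), and scores the placement by
ungapped per-site identity. Fragments with no shared k-mer, or whose
placement covers < 80 % of the fragment, are unmapped and excluded from the
mean. ANI is the mean fragment identity × 100, computed in both directions
and averaged (fragment ANI is direction-dependent; the mean removes order
effects from grouping). A pair with no mapped fragment in either direction
is a distinct *no-estimate*, never 0. This is a deliberately simple
deterministic mapper, not a minimizer-based re-implementation; on indel-free
synthetic genomes it is unbiased by construction, and validation shows
agreement with the JC expectation to < 0.1 ANI points at 100 kb.

Redundancy groups at ≥ 98.5 % ANI are single-linkage connected components
of the thresholded graph by default — what a greedy pass over an all-vs-all
table produces; a clique mode (every within-group pair above threshold) is
available behind a flag since the published grouping semantics are
ambiguous. Representatives maximize completeness, then minimize
contamination; remaining ties go to the larger assembly, then the
lexicographically smaller id (recorded, invented tie-break).

## Relative root distance and subclade cutting

"Relative phylogenetic distance from the root" is not a standard quantity;
here depth(node) = branch-length sum root→node divided by the **mean**
root-to-leaf depth, so leaves average 1.0 and a threshold of 1.2 reads as
"20 % past the average tip". Max- and median-based normalizations are
available behind `--normalization`. A subclade is a maximal clade whose
stem crosses the threshold (MRCA depth ≥ t, parent depth < t); leaves whose
path never crosses become singleton *unplaced* labels rather than being
forced into a neighbor — matching how deep-branching genomes that fail the
subclade criteria are handled in practice.

A consequence of mean normalization worth stating: in a tree where every
leaf sits inside some dense clade, no clade MRCA can exceed relative depth
1 (each clade's tips are deeper than its MRCA, so the mean tip depth is
too). MRCAs pass 1.2 only when shallower lineages pull the mean down. The
planted-clade tree generator therefore includes short basal singleton
lineages alongside the deep-stemmed clades; its defaults (stem 1.0, tip
0.02, basal depth 0.1, one basal lineage per two clade tips) put every
clade MRCA above 1.4 and the basal tips below 0.3, so the production
threshold of 1.2 sits inside the planted gap.

AAI uses reciprocal best hits under BLOSUM62 local alignment (gap open −11,
extend −1), keeping pairs with ≥ 30 % identity over the alignment and
≥ 70 % coverage of the shorter protein (CompareM-style defaults, since only
"defaults" is on record); AAI is the mean percent identity over those
orthologs. Subclade support reports, per subclade, the fraction of
within-subclade pairs above 70 % ANI and 70 % AAI; "supported" requires
both fractions to reach a quorum (default 0.9 — the published criterion
says only that clustering of pairwise relationships supports the clades).

## Trait rules

The rhodopsin diagnostic positions (97, 108, 105) are columns of a bundled
240-residue reference numbering scaffold (a synthetic stand-in: only its
coordinate system matters). Query sequences are globally aligned to it
(BLOSUM62, open −10, extend −0.5) and the residues at the three columns are
read off; a gap leaves the field indeterminate. Proton pumping requires
D97 and K/E108; tuning is blue for Q105, green for M105, indeterminate
otherwise; a tuning residue without the pumping pair is flagged for review.
C-ring motifs are exact residue-class matches (`x` = any residue), first
occurrence wins, and a sequence matching both motifs yields a `conflict`
call rather than an exception. The peptidase rule is: bitscore ≥ 75 AND
(extracellular/outer-membrane localization OR unknown localization with a
signal peptide); missing localization rows mean "unknown". The flagellum
operon requires FlaH, FlaI, FlaJ and ≥ 1 flagellin on one contig within a
gene-index window of 10 (the syntenic region spans a handful of genes plus
1–3 flagellins; the window is a flag).

## Pangenome

Raw similarity is a BLOSUM62 local-alignment score with affine gaps over
pairs sharing a 5-mer seed — a bitscore proxy, sufficient because minbit
only needs a score with a meaningful self-normalization:
minbit(a,b) = score / min(self(a), self(b)), pruned below 0.5. Markov
clustering runs on the minbit-weighted graph with self-loops weighted by
each node's maximum incident edge, column normalization, expansion/
inflation (power 2) iterations, per-iteration pruning below 1e-10, and
convergence when the largest column change falls under 1e-8; clusters are
the connected components of the limit matrix's support, a partition
invariant to node order. Enrichment categories apply the 70/30/10
frequency criteria with precedence MGII-core > clade-core >
subclade-unique > none (relevant only at boundary frequencies, where the
most inclusive reading wins; such ties are logged). The criteria can be
applied to clusters directly or to functions aggregated over clusters —
both modes reduce to the same frequency classifier.

## Abundance

SAM records (text form, via pysam) yield identity = 1 − NM/alignment_length
and aligned fraction = alignment_length/read_length; a TSV dialect accepts
precomputed fields. Filtering keeps records with identity ≥ 0.95 AND
aligned fraction ≥ 0.75 — both inclusive, as every threshold written "≥"
in this package is — and retains one best-identity placement per read
(ties by contig id). Per-sample totals (reads R, bp B) come from a
manifest, never from the records, which only cover recruited reads.
RPKM = (r / (L/10³)) / (B/10⁶); relative fraction = r/R; samples are
"high" when the summed fraction over the genome set reaches 0.5 %.

The community generator draws counts as independent Poisson variables with
mean depth × community-share × relative abundance × (L/mean L), where
relative abundance ∝ exp(Σ coefficient × standardized covariate).
Below-detection-limit covariate values enter the response as 0 and missing
values as the variable mean (no effect); both are kept distinct in the
emitted metadata (the sentinel string `BDL` vs an empty cell). Poisson
rather than multinomial keeps genomes independent and variances simple;
totals are recorded, not constrained. Alignment-record identities and
fractions are quantized to integer-mismatch-over-integer-length values so
the planted pass/fail label and the value a SAM round-trip reconstructs
agree exactly.

## Ecology

Bray–Curtis d(x,y) = Σ|x−y| / Σ(x+y); an all-zero pair is defined as 0
with a warning. Average linkage is unweighted UPGMA with ties broken by the
lexicographically smallest leaf-label pair, making dendrograms invariant to
input order; cutting at height *h* returns the maximal subtrees with all
merge heights < *h*. Ecological clusters cross taxon clades (cut 0.8) with
sample clades (cut 0.7) and keep blocks whose median RPKM is at least 4×
the global median of nonzero RPKM — "elevated" is not quantified in the
published description, so the 4× default is this package's operational
definition, exposed as `--elevation-min` and validated by planted-block
recovery.

CCA follows the classical chi-square formulation: the standardized
abundance residual matrix Q = (P − rcᵀ)/√(rcᵀ) is projected onto the
row-weighted, z-standardized environmental space and the projection is
eigen-decomposed; axis fractions are eigenvalues over total constrained
inertia. Samples with any missing variable are dropped (complete-case),
collinear variables are dropped with a warning. The implementation
reproduces the reference R implementation's eigenvalues to 1e-8 on a fixed
matrix (frozen in the test suite).

PERMANOVA: SS_total = Σ_{i<j} d²/N, within-group SS analogously per group,
pseudo-F = (SS_between/(a−1))/(SS_within/(N−a)); p = (1 + #{F* ≥ F}) /
(1 + n_perm) under uniform unrestricted label permutation (9999
permutations by default, seed mandatory in the CLI). Pairwise tests permute
within each pair's subset and multiply p by the number of pairs
(Bonferroni, capped at 1). BH-FDR is the step-up adjustment with enforced
monotonicity. Environmental bins are exactly the printed intervals, closed
on their printed endpoints; values in the gaps between printed ranges
(e.g. oxygen 159–160) go to the nearer edge's bin, ties downward; BDL is
its own category for phosphate and nitrate. Welch's t is two-sided with
Satterthwaite degrees of freedom.

## Validation studies and their scale

The planted community study uses 40 samples in two thermal regimes (half
warm 22–28 °C, half cold 3–8 °C — the bimodal structure of mixed
tropical/temperate surveys, chosen because fixed-height dendrogram cuts
find *blocks*, which a smooth gradient does not produce), 10 genomes of
~20 kb with 2 temperature-responsive taxa (log-linear coefficient 3 on the
standardized covariate, roughly a 400-fold abundance ratio between
regimes), 10⁶ reads/sample at 1 % community share. Calibration and power
use 1000 null datasets and 200 replicates with 199 permutations each; the
ANI studies use 100 kb genomes at 0.5/1.5/3/5 % divergence; trait recovery
uses 600 planted labels. These sizes keep the full validation under two
minutes on one CPU.

What passing these studies shows: the estimators are unbiased and exact
where the model says they should be, the rules are implemented faithfully,
and the statistics are calibrated. What it does not show: robustness to
indels, rearrangements or contamination in real assemblies (the
substitution model has none), to misassembly or chimeric bins, to read-level
sequencing error (alignment records are generated above the read level), or
to the patchy, autocorrelated metadata of real ocean surveys.

## Known limitations

- The ANI mapper is ungapped; genomes with substantial indel divergence
  would lose fragments rather than score them, biasing ANI slightly high
  within groups and increasing no-estimates across them.
- The AAI and pangenome scorers use exact-k-mer prescreens; highly diverged
  homolog pairs sharing no seed are invisible to them.
- MCL is dense (O(n³) per iteration); it is comfortable at thousands of
  proteins but is not an sparse industrial implementation.
- The rhodopsin position map is only as good as the global alignment to the
  bundled scaffold; sequences with long insertions near the diagnostic
  columns should be checked manually (gaps are flagged).
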