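# mgiitools

Comparative genomics and community ecology of **Marine Group II (MGII)
Euryarchaeota** — the most abundant planktonic archaea in the surface
ocean — as a tested, reusable Python pipeline. The package covers the full
analysis chain used to delineate and profile MGII subclades from
metagenome-assembled genomes:

1. **Dereplication** (`mgii.derep`) — pairwise average nucleotide identity
   (ANI) by fragment mapping (1500 bp windows), grouping of redundant
   genomes at ≥ 98.5 % ANI, and selection of the best-quality representative
   (highest CheckM completeness, lowest contamination), after a strict
   quality gate (> 50 % complete, < 5 % contaminated).
2. **Subclade delineation** (`mgii.clades`) — a marker-count gate (≥ 60 of
   120 single-copy markers), cutting of the rooted phylogenomic tree at a
   *relative root distance* of 1.2 (branch-length depth normalized by the
   mean root-to-leaf depth), and support checks requiring within-subclade
   pairs to exceed 70 % ANI and ~70 % AAI.
3. **Trait classification** (`mgii.traits`) — deterministic rules for
   proteorhodopsin function and spectral tuning (D97 + K/E108 ⇒ proton
   pumping; Q105 ⇒ blue-tuned, M105 ⇒ green-tuned), the Na⁺-type
   ATP-synthase c-ring motifs (`LPESxxI` for MGIIa, `LPETIxL` for MGIIb),
   extracellular peptidases (HMM bitscore ≥ 75 plus
   localization/signal-peptide logic), the archaeal flagellum operon
   (co-localized FlaH/I/J + flagellin), and per-subclade occurrence
   matrices scaled 0–1.
4. **Pangenomics** (`mgii.pangenome`) — an all-vs-all protein similarity
   graph pruned with *minbit* ≥ 0.5 (score over the smaller self-score),
   Markov clustering (inflation 2) into protein clusters, and enrichment
   categories: MGII-core (≥ 70 % of both clades), clade-core (≥ 70 % in
   one, ≤ 30 % in the other), subclade-unique (≥ 70 % within, ≤ 10 %
   elsewhere).
5. **Read-recruitment abundance** (`mgii.abundance`) — alignment filtering
   at ≥ 95 % identity and ≥ 75 % aligned fraction, per-genome read counts,
   relative fraction r/R, RPKM = (r / (L/10³)) / (B/10⁶), and the
   high/low split at 0.5 % summed recruitment.
6. **Community ecology** (`mgii.ecology`) — Bray–Curtis distances, UPGMA
   dendrograms cut at 0.8 (taxa) and 0.7 (samples) to define ecological
   clusters with elevated RPKM, canonical correspondence analysis,
   one-way PERMANOVA (pseudo-F, 9999 permutations) with BH-FDR and
   Bonferroni corrections, fixed environmental bins (with a
   below-detection-limit category), and Welch's t-test.
7. **Synthetic data** (`mgii.simulate`) — first-class generators that plant
   ground truth for every stage: genomes evolved under Jukes–Cantor
   substitution along a known tree, Bernoulli gene-family matrices with
   known enrichment labels, proteins embedding the diagnostic residues and
   motifs, Poisson read counts driven by log-linear environmental
   responses, and alignment records with exact pass/fail labels.

## Worked example

Estimate ANI between two genomes simulated at 3 % divergence and recover
the closed-form expectation:

```python
from mgii import simulate as sim, derep

spec = sim.SimSpec(seed=11, tree=sim.two_taxon_tree(0.03),
                   ancestor_length=100_000)
genomes, truth = sim.simulate_genome_set(spec)
print(round(truth.expected_identity.loc["a", "b"], 2))  # 97.06
res = derep.estimate_ani(genomes["a"], genomes["b"])
print(round(res.ani, 2))                                # 97.07
```

The expected identity (97.06 %) comes from the Jukes–Cantor formula
1 − ¾(1 − e^(−4d/3)) at d = 0.03 substitutions/site; the fragment-mapping
estimator recovers it to within a tenth of an ANI point at 100 kb.

The same stages are available from the shell via the `mgii` command
(`mgii simulate`, `mgii derep`, `mgii clades`, `mgii traits`,
`mgii pangenome`, `mgii abundance`, `mgii ecology`); each subcommand reads
and writes plain FASTA/TSV/SAM/Newick files. See `mgii <cmd> --help`.

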