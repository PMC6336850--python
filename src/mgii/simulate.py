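"""Synthetic inputs with planted ground truth for every pipeline stage.

Real analyses of Marine Group II Euryarchaeota start from hundreds of
metagenome-assembled genomes and ocean metagenomes; none of that is needed
to exercise the pipeline.  This module generates each input with a known
answer attached:

* genome sets evolved along a given tree under a Jukes-Cantor substitution
  process (no indels by default), with the closed-form expected pairwise
  identity recorded — the truth the ANI estimator must recover;
* gene-family presence/absence matrices with per-clade Bernoulli occurrence
  frequencies whose implied enrichment category is planted per family;
* protein sets embedding the diagnostic rhodopsin residues, c-ring motifs,
  peptidase annotation combinations and flagellar operon layouts;
* read-recruitment counts driven by log-linear responses of genome
  abundance to environmental covariates (Poisson counts, so cross-genome
  independence holds and variances are simple);
* alignment-record tables with exact planted pass/fail labels under the
  identity/aligned-fraction filter (thresholds named ">=" are inclusive).

Identical (seed, spec) pairs reproduce byte-identical outputs; the five
generators draw from independent seed streams so adding one stage never
perturbs another.
"""
from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from skbio import TreeNode

from .derep import GenomeRecord, DEFAULT_FRAG_LEN
from . import pangenome as _pan
from . import traits as _traits

NUCLEOTIDES = np.frombuffer(b"ACGT", dtype=np.uint8)
AA = "ACDEFGHIKLMNPQRSTVWY"

# independent sub-stream tags per generator
_STREAM_GENOMES = 1
_STREAM_PRESENCE = 2
_STREAM_TRAITS = 3
_STREAM_COMMUNITY = 4
_STREAM_ALIGNMENTS = 5


@dataclass
class CommunityPlan:
    """Log-linear community layout: expected relative abundance of genome g
    in sample m is proportional to exp(sum_k coef_gk * z_km), z = covariates
    standardized across samples (below-detection-limit counts as 0 before
    standardization, missing as the variable mean, i.e. no effect)."""

    env: pd.DataFrame                      # samples x variables; NaN / "BDL" allowed
    coefficients: dict[str, dict[str, float]]  # genome -> variable -> coefficient
    depth: pd.Series                       # expected total reads per sample
    mgii_fraction: float = 0.01            # share of reads recruiting to the set


@dataclass
class AlignmentPlan:
    """Per-sample alignment-record distributions: a fraction ``p_pass`` of
    records is drawn from the passing identity/fraction ranges, the rest
    from the failing ranges."""

    n_records: int = 200
    p_pass: float = 0.6
    id_pass: tuple[float, float] = (0.95, 1.0)
    id_fail: tuple[float, float] = (0.80, 0.95)
    aln_pass: tuple[float, float] = (0.75, 1.0)
    aln_fail: tuple[float, float] = (0.40, 0.75)


@dataclass
class SimSpec:
    """Everything the generators need, with the planted truth parameters."""

    seed: int
    tree: TreeNode | str                   # taxa = genome ids; lengths = subs/site
    ancestor_length: int = 100_000
    n_families: int = 200
    family_freq_plan: dict[str, dict[str, float]] | None = None
    trait_plan: dict[str, list[dict]] = field(default_factory=dict)
    community_plan: CommunityPlan | None = None
    alignment_plan: AlignmentPlan = field(default_factory=AlignmentPlan)
    read_length: int = 100
    quality_range: tuple[float, float] = (70.0, 100.0)      # completeness draw
    contamination_range: tuple[float, float] = (0.0, 4.0)

    def __post_init__(self):
        if isinstance(self.tree, str):
            self.tree = TreeNode.read(StringIO(self.tree), convert_underscores=False)
        if self.ancestor_length <= 0:
            raise ValueError("ancestor_length must be positive")
        if self.ancestor_length < 10 * DEFAULT_FRAG_LEN:
            raise ValueError(
                f"ancestor_length must be >= {10 * DEFAULT_FRAG_LEN} bp so that "
                "fragment mapping is exercised")
        names = [t.name for t in self.tree.tips()]
        if any(n is None for n in names):
            raise ValueError("all tree taxa must be named")
        if len(set(names)) != len(names):
            raise ValueError("tree taxon names must be unique")
        for node in self.tree.traverse():
            if node.length is not None and node.length < 0:
                raise ValueError("branch lengths must be non-negative")
        if self.family_freq_plan is not None:
            for fam, per_clade in self.family_freq_plan.items():
                for clade, p in per_clade.items():
                    if not (0.0 <= p <= 1.0):
                        raise ValueError(
                            f"occurrence probability out of [0,1] for {fam}/{clade}: {p}")

    def taxa(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class TrueDivergence:
    """Tree-derived truth for pairwise genome relatedness."""

    path_length: pd.DataFrame        # substitutions/site along the tree path
    expected_identity: pd.DataFrame  # percent, Jukes-Cantor expectation


def jc_expected_identity(path_length: float) -> float:
    """Expected per-site identity after ``path_length`` substitutions/site of
    Jukes-Cantor evolution: 1 - (3/4)(1 - exp(-4 d / 3))."""
    return 1.0 - 0.75 * (1.0 - math.exp(-4.0 * path_length / 3.0))


def _evolve(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """One Jukes-Cantor branch: each site is replaced by a uniformly random
    base (possibly the same) with probability 1 - exp(-4t/3), which composes
    exactly to the JC transition matrix along paths."""
    if t <= 0:
        return seq.copy()
    out = seq.copy()
    mask = rng.random(len(seq)) < 1.0 - math.exp(-4.0 * t / 3.0)
    out[mask] = NUCLEOTIDES[rng.integers(0, 4, size=int(mask.sum()))]
    return out


def simulate_genome_set(spec: SimSpec) -> tuple[dict[str, GenomeRecord], TrueDivergence]:
    """Evolve one genome per tree taxon from a random ancestor.

    Returns the genomes (single-contig, with quality estimates drawn from
    the spec's ranges) and the tree-path divergence truth for every pair.
    """
    rng = spec.rng(_STREAM_GENOMES)
    ancestor = NUCLEOTIDES[rng.integers(0, 4, size=spec.ancestor_length)]
    seqs: dict[str, np.ndarray] = {}

    def descend(node, seq):
        for child in node.children:
            child_seq = _evolve(seq, child.length or 0.0, rng)
            if child.is_tip():
                seqs[child.name] = child_seq
            else:
                descend(child, child_seq)

    if spec.tree.is_tip():
        seqs[spec.tree.name] = ancestor
    else:
        descend(spec.tree, ancestor)
    taxa = spec.taxa()
    genomes = {}
    for name in taxa:
        comp = float(rng.uniform(*spec.quality_range))
        cont = float(rng.uniform(*spec.contamination_range))
        genomes[name] = GenomeRecord(
            id=name, contigs=[seqs[name].tobytes().decode("ascii")],
            completeness=comp, contamination=cont)
    dist = pd.DataFrame(0.0, index=taxa, columns=taxa)
    tip = {t.name: t for t in spec.tree.tips()}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            d = tip[a].distance(tip[b])
            dist.loc[a, b] = dist.loc[b, a] = d
    ident = dist.map(lambda d: 100.0 * jc_expected_identity(d))
    np.fill_diagonal(ident.values, 100.0)
    return genomes, TrueDivergence(path_length=dist, expected_identity=ident)


def simulate_presence_matrix(
    spec: SimSpec,
    clade_labels: dict[str, str],
    subclade_labels: dict[str, str] | None = None,
    freq_by: str = "clade",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Bernoulli gene-family presence/absence with planted enrichment labels.

    Each cell is Bernoulli with the probability the plan assigns to that
    genome's group — its clade by default, or its subclade with
    ``freq_by='subclade'`` (needed to plant subclade-unique families).  The
    planted label per family is what the enrichment criteria imply for the
    *expected* frequencies (not the sampled matrix), computed with the same
    classifier the pangenome module applies.
    """
    genomes = sorted(clade_labels)
    missing = [g for g in spec.taxa() if g not in clade_labels]
    if missing:
        raise ValueError(f"genomes without a clade label: {missing[:5]}")
    if subclade_labels is None:
        subclade_labels = dict(clade_labels)
    if freq_by == "clade":
        group_of = dict(clade_labels)
    elif freq_by == "subclade":
        group_of = dict(subclade_labels)
    else:
        raise ValueError("freq_by must be 'clade' or 'subclade'")
    plan = spec.family_freq_plan
    if plan is None:
        plan = default_family_plan(spec, sorted(set(group_of.values())))
    rng = spec.rng(_STREAM_PRESENCE)
    rows = {}
    planted: dict[str, str] = {}
    for fam in sorted(plan):
        per_clade = plan[fam]
        for group in set(group_of.values()):
            if group not in per_clade:
                raise ValueError(f"family {fam} has no frequency for group {group}")
            if not (0.0 <= per_clade[group] <= 1.0):
                raise ValueError(f"probability out of [0,1]: {fam}/{group}")
        probs = np.array([per_clade[group_of[g]] for g in genomes])
        rows[fam] = rng.random(len(genomes)) < probs
        by_clade: dict[str, list[str]] = {}
        by_sub: dict[str, list[str]] = {}
        for g in genomes:
            by_clade.setdefault(clade_labels[g], []).append(g)
            by_sub.setdefault(subclade_labels[g], []).append(g)
        p_of = {g: per_clade[group_of[g]] for g in genomes}
        clade_freq = {c: float(np.mean([p_of[g] for g in m])) for c, m in by_clade.items()}
        sub_freq = {s: float(np.mean([p_of[g] for g in m])) for s, m in by_sub.items()}
        other_freq = {
            s: float(np.mean([p_of[g] for g in genomes if subclade_labels[g] != s]))
            for s in by_sub
        }
        planted[fam] = _pan.classify_frequencies(clade_freq, sub_freq, other_freq, fam).category
    presence = pd.DataFrame(rows, index=genomes).T
    presence.index.name = "family"
    return presence, planted


def default_family_plan(spec: SimSpec, clades: list[str]) -> dict[str, dict[str, float]]:
    """A mixed plan: a third core families (high everywhere), a third
    clade-enriched, a third background noise."""
    rng = spec.rng(_STREAM_PRESENCE + 100)
    plan = {}
    for i in range(spec.n_families):
        fam = f"fam{i + 1:04d}"
        kind = i % 3
        if kind == 0:
            plan[fam] = {c: 0.9 for c in clades}
        elif kind == 1:
            lucky = clades[int(rng.integers(0, len(clades)))]
            plan[fam] = {c: (0.9 if c == lucky else 0.05) for c in clades}
        else:
            plan[fam] = {c: float(rng.uniform(0.3, 0.6)) for c in clades}
    return plan


_TRAIT_KINDS = {"rhodopsin", "cring", "peptidase", "operon"}


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, size=length))


def _make_rhodopsin(rng, r97: str, r108: str, r105: str) -> str:
    """Mutated copy of the reference scaffold carrying the requested
    diagnostic residues (5% substitutions elsewhere, no indels, so global
    alignment maps columns one-to-one)."""
    ref = _traits.REFERENCE_RHODOPSIN
    seq = list(ref)
    diag = {_traits.POS_PUMP_1 - 1, _traits.POS_PUMP_2 - 1, _traits.POS_TUNING - 1}
    for i in range(len(seq)):
        if i not in diag and rng.random() < 0.05:
            seq[i] = AA[int(rng.integers(0, 20))]
    seq[_traits.POS_PUMP_1 - 1] = r97
    seq[_traits.POS_PUMP_2 - 1] = r108
    seq[_traits.POS_TUNING - 1] = r105
    return "".join(seq)


def _make_cring(rng, clade: str, length: int = 80) -> str:
    """Random protein embedding exactly one c-ring motif instance."""
    core = ("LPES" + _random_protein(rng, 2) + "I") if clade == "MGIIa" \
        else ("LPETI" + _random_protein(rng, 1) + "L")
    while True:
        pos = int(rng.integers(5, length - 15))
        seq = _random_protein(rng, pos) + core + _random_protein(rng, length - pos - len(core))
        a = _traits.MOTIF_MGIIA.findall(seq)
        b = _traits.MOTIF_MGIIB.findall(seq)
        if (len(a), len(b)) == ((1, 0) if clade == "MGIIa" else (0, 1)):
            return seq


def simulate_trait_proteins(spec: SimSpec):
    """Emit proteins, gene coordinates and annotation tables realizing the
    planted trait plan.

    Returns (proteins, gene_coords, annotations, planted) where ``proteins``
    maps protein id -> sequence, ``gene_coords`` is the 1-based coordinate
    table, ``annotations`` is a dict of tables (hmm / localization / signal /
    ko) and ``planted`` is the per-genome expected classifier output.
    """
    rng = spec.rng(_STREAM_TRAITS)
    proteins: dict[str, str] = {}
    coord_rows, hmm_rows, loc_rows, sp_rows, ann_rows = [], [], [], [], []
    planted: list[dict] = []
    for genome in sorted(spec.trait_plan):
        plan = spec.trait_plan[genome]
        gene_index = 0
        for t_i, trait in enumerate(plan):
            kind = trait.get("kind")
            if kind not in _TRAIT_KINDS:
                raise ValueError(f"unknown trait kind: {kind!r}")
            pid = f"{genome}|p{t_i + 1:03d}"
            if kind == "rhodopsin":
                r97, r108, r105 = trait["r97"], trait["r108"], trait["r105"]
                proteins[pid] = _make_rhodopsin(rng, r97, r108, r105)
                pumping = r97 == "D" and r108 in ("K", "E")
                tuning = {"Q": "blue", "M": "green"}.get(r105, "indeterminate")
                planted.append({"genome": genome, "protein": pid, "kind": kind,
                                "expected": f"pumping={pumping},tuning={tuning}"})
            elif kind == "cring":
                clade = trait["clade"]
                if clade not in ("MGIIa", "MGIIb"):
                    raise ValueError(f"unknown c-ring clade: {clade!r}")
                proteins[pid] = _make_cring(rng, clade)
                planted.append({"genome": genome, "protein": pid, "kind": kind,
                                "expected": f"{clade}-type"})
            elif kind == "peptidase":
                score = float(trait.get("score", 90.0))
                loc = trait.get("localization", "extracellular")
                sp = bool(trait.get("signal_peptide", False))
                fam = trait.get("family", "M01")
                proteins[pid] = _random_protein(rng, 120)
                hmm_rows.append({"protein": pid, "family": fam, "score": score})
                loc_rows.append({"protein": pid, "localization": loc})
                sp_rows.append({"protein": pid, "has_signal_peptide": sp})
                expected = score >= _traits.PEPTIDASE_SCORE_MIN and (
                    loc in ("extracellular", "outer membrane")
                    or (loc == "unknown" and sp))
                planted.append({"genome": genome, "protein": pid, "kind": kind,
                                "expected": str(bool(expected))})
            elif kind == "operon":
                present = bool(trait.get("present", True))
                contig = f"{genome}_ctg1"
                comps = ["K07331", "K07332", "K07333", _traits.FLAGELLIN_ACC]
                if present:
                    start = gene_index + 1
                    idxs = list(range(start, start + 4))
                else:
                    layout = trait.get("absent_layout", "split_contig")
                    start = gene_index + 1
                    if layout == "split_contig":
                        idxs = [start, start + 1, start + 2, None]  # flagellin elsewhere
                    else:  # far apart on the same contig
                        idxs = [start, start + 1, start + 2,
                                start + 2 + _traits.DEFAULT_OPERON_WINDOW + 5]
                for comp, idx in zip(comps, idxs):
                    if idx is None:
                        ann_rows.append({"genome": genome, "contig": f"{genome}_ctg2",
                                         "gene_index": 1, "annotation": comp})
                    else:
                        ann_rows.append({"genome": genome, "contig": contig,
                                         "gene_index": idx, "annotation": comp})
                gene_index += 25
                planted.append({"genome": genome, "protein": "", "kind": kind,
                                "expected": str(present)})
                continue
            gene_index += 1
            start_bp = 1 + (gene_index - 1) * 1500
            coord_rows.append({"genome": genome, "contig": f"{genome}_ctg1",
                               "gene_index": gene_index, "start": start_bp,
                               "end": start_bp + 3 * len(proteins[pid]) - 1,
                               "strand": "+"})
    gene_coords = pd.DataFrame(coord_rows, columns=["genome", "contig", "gene_index",
                                                    "start", "end", "strand"])
    annotations = {
        "hmm": pd.DataFrame(hmm_rows, columns=["protein", "family", "score"]),
        "localization": pd.DataFrame(loc_rows, columns=["protein", "localization"]),
        "signal": pd.DataFrame(sp_rows, columns=["protein", "has_signal_peptide"]),
        "genes": pd.DataFrame(ann_rows, columns=["genome", "contig", "gene_index",
                                                 "annotation"]),
    }
    return proteins, gene_coords, annotations, pd.DataFrame(
        planted, columns=["genome", "protein", "kind", "expected"])


def _numeric_env(env: pd.DataFrame) -> pd.DataFrame:
    """Covariates for the log-linear response: BDL -> 0, missing -> column
    mean (no effect), then z-standardized across samples."""
    num = env.copy()
    for col in num.columns:
        num[col] = [0.0 if (isinstance(v, str) and v.strip().upper() == "BDL")
                    else float(v) for v in num[col]]
    num = num.astype(float)
    num = num.fillna(num.mean())
    std = num.std(ddof=0).replace(0, 1.0)
    return (num - num.mean()) / std


def simulate_community(spec: SimSpec, genomes: dict[str, GenomeRecord]):
    """Poisson read counts from the log-linear community plan.

    Returns (counts, env, manifest, truth) where ``truth`` carries the
    expected counts, relative fractions and RPKM implied by the plan.
    Counts are independent Poisson draws with mean
    depth * mgii_fraction * relabund_g * (L_g / mean L); per-sample totals
    (reads and bp) are recorded in the manifest, not constrained.
    """
    plan = spec.community_plan
    if plan is None:
        raise ValueError("spec has no community_plan")
    if (plan.depth < 0).any():
        raise ValueError("expected depth must be non-negative")
    rng = spec.rng(_STREAM_COMMUNITY)
    gids = sorted(genomes)
    samples = list(plan.env.index)
    z = _numeric_env(plan.env)
    lengths = pd.Series({g: genomes[g].total_length for g in gids})
    eta = np.zeros((len(gids), len(samples)))
    for i, g in enumerate(gids):
        for var, coef in plan.coefficients.get(g, {}).items():
            eta[i, :] += coef * z[var].values
    rel = np.exp(eta)
    rel = rel / rel.sum(axis=0, keepdims=True)
    len_share = (lengths / lengths.mean()).values[:, None]
    depth = plan.depth.reindex(samples).values[None, :]
    lam = depth * plan.mgii_fraction * rel * len_share
    counts = pd.DataFrame(rng.poisson(lam), index=gids, columns=samples)
    manifest = pd.DataFrame({
        "sample": samples,
        "total_reads": plan.depth.reindex(samples).astype(int).values,
        "total_bp": (plan.depth.reindex(samples) * spec.read_length).astype(int).values,
    })
    total_bp = manifest.set_index("sample")["total_bp"].astype(float)
    expected = pd.DataFrame(lam, index=gids, columns=samples)
    truth = {
        "expected_counts": expected,
        "relative_abundance": pd.DataFrame(rel, index=gids, columns=samples),
        "true_relative_fraction": expected / manifest.set_index("sample")["total_reads"],
        "true_rpkm": expected.div(lengths / 1000.0, axis=0).div(total_bp / 1e6, axis=1),
    }
    return counts, plan.env.copy(), manifest, truth


def simulate_alignment_records(spec: SimSpec, genome: GenomeRecord,
                               sample: str = "s1") -> pd.DataFrame:
    """Alignment records with exact planted pass/fail labels.

    Identity and aligned fraction are quantized to representable values
    (integer mismatch count over integer aligned length) so the planted
    label and the value a SAM round-trip reconstructs agree exactly.
    """
    plan = spec.alignment_plan
    rng = spec.rng(_STREAM_ALIGNMENTS)
    rlen = spec.read_length
    rows = []
    for i in range(plan.n_records):
        passing = rng.random() < plan.p_pass
        id_lo, id_hi = plan.id_pass if passing else plan.id_fail
        al_lo, al_hi = plan.aln_pass if passing else plan.aln_fail
        target_aln = rng.uniform(al_lo, al_hi)
        alen = max(1, round(target_aln * rlen))
        frac = alen / rlen
        target_id = rng.uniform(id_lo, id_hi)
        nm = round((1.0 - target_id) * alen)
        ident = 1.0 - nm / alen
        # quantization can push a draw across a threshold; the planted label
        # always follows the exact emitted values
        planted_pass = ident >= 0.95 and frac >= 0.75
        if not (0 <= ident <= 1 and 0 <= frac <= 1):
            raise ValueError("identity/fraction out of [0,1]")
        rows.append({"read_id": f"{sample}_r{i + 1:06d}", "contig": f"{genome.id}_c1",
                     "identity": ident, "aligned_fraction": frac,
                     "read_length": rlen, "nm": nm, "aligned_length": alen,
                     "planted_pass": planted_pass})
    return pd.DataFrame(rows)


def write_sam(records: pd.DataFrame, genome: GenomeRecord, path: str) -> None:
    """Minimal text SAM for the record table (NM tag + soft-clip CIGAR so
    identity and aligned fraction are derivable downstream)."""
    contig = f"{genome.id}_c1"
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{contig}\tLN:{genome.total_length}\n")
        for _, r in records.iterrows():
            rlen = int(r["read_length"])
            alen = int(r["aligned_length"])
            clip = rlen - alen
            cigar = f"{alen}M" + (f"{clip}S" if clip else "")
            seq = "A" * rlen
            fh.write("\t".join([
                str(r["read_id"]), "0", str(r["contig"]), "1", "60", cigar,
                "*", "0", "0", seq, "*", f"NM:i:{int(r['nm'])}",
            ]) + "\n")


def community_scenario(seed: int, n_samples: int = 40, n_taxa: int = 10,
                       n_responsive: int = 2, temperature_coef: float = 3.0,
                       depth: int = 1_000_000, mgii_fraction: float = 0.01,
                       ancestor_length: int = 20_000):
    """Canonical planted community study: a warm/cold two-regime survey.

    Half the samples come from warm surface water (22-28 C), half from cold
    water (3-8 C) — the bimodal structure typical of mixed tropical/temperate
    ocean surveys, and what gives ecological *blocks* rather than a smooth
    gradient.  ``n_responsive`` taxa respond to temperature with a strong
    log-linear coefficient; the rest are flat.  Oxygen is drawn independently
    (no effect) so constrained ordination has a null variable to ignore.

    Returns (spec, planted) where planted records the responsive taxa and
    the warm sample set — the block the ecology stage should recover.
    """
    rng = np.random.default_rng([seed, 77])
    samples = [f"s{i + 1:03d}" for i in range(n_samples)]
    n_warm = n_samples // 2
    temps = np.concatenate([rng.uniform(22, 28, n_warm),
                            rng.uniform(3, 8, n_samples - n_warm)])
    env = pd.DataFrame({
        "temperature": temps,
        "oxygen": rng.uniform(100, 250, n_samples),
    }, index=samples)
    taxa = [f"g{i + 1:02d}" for i in range(n_taxa)]
    responsive = taxa[:n_responsive]
    coefficients = {t: {"temperature": temperature_coef} for t in responsive}
    plan = CommunityPlan(env=env, coefficients=coefficients,
                         depth=pd.Series(float(depth), index=samples),
                         mgii_fraction=mgii_fraction)
    tips = ",".join(f"{t}:0.01" for t in taxa)
    spec = SimSpec(seed=seed, tree=f"({tips});", ancestor_length=ancestor_length,
                   community_plan=plan)
    planted = {"responsive_taxa": set(responsive),
               "warm_samples": set(samples[:n_warm])}
    return spec, planted


# ---------------------------------------------------------------------------
# tree builders for planted scenarios

def planted_clade_tree(clade_sizes: dict[str, int], stem: float = 1.0,
                       intra: float = 0.02, n_basal: int | None = None,
                       basal_depth: float = 0.1):
    """Tree with dense clades on deep stems plus shallow basal lineages.

    Because node depths are normalized by the *mean* root-to-leaf depth, a
    clade MRCA can only sit beyond relative depth 1 when shallower lineages
    pull the mean down — exactly the deep-branching singletons seen in real
    trees.  Defaults put every clade MRCA beyond relative depth 1.2 while
    the basal tips stay well under it, so any cut threshold in that gap
    recovers the planted clades (basal leaves become unplaced singletons).

    Returns (tree, truth) where truth maps each clade label to its taxa
    (clade tips are ``<clade>g<i>``, basal tips ``basal<i>``).
    """
    n_leaves = sum(clade_sizes.values())
    if n_basal is None:
        n_basal = math.ceil(n_leaves / 2)
    parts = []
    truth: dict[str, set[str]] = {}
    for clade, size in sorted(clade_sizes.items()):
        names = [f"{clade}g{i + 1}" for i in range(size)]
        truth[clade] = set(names)
        tips = ",".join(f"{n}:{intra}" for n in names)
        parts.append(f"({tips}):{stem}")
    parts += [f"basal{i + 1}:{basal_depth}" for i in range(n_basal)]
    tree = TreeNode.read(StringIO(f"({','.join(parts)});"))
    return tree, truth


def strain_tree(n_strains: int = 3, strain_divergence: float = 0.005,
                n_outgroups: int = 2, outgroup_divergence: float = 0.06) -> TreeNode:
    """One cluster of near-identical strains (pairwise path =
    ``strain_divergence``) plus deeply diverged outgroups — the planted
    answer for dereplication is one group of strains plus singleton
    outgroups."""
    half = strain_divergence / 2.0
    tips = ",".join(f"strain{i + 1}:{half}" for i in range(n_strains))
    outs = ",".join(f"outgroup{i + 1}:{outgroup_divergence}" for i in range(n_outgroups))
    return TreeNode.read(StringIO(f"(({tips}):0.0,{outs});"))


def two_taxon_tree(divergence: float) -> TreeNode:
    """Two genomes separated by a total path of ``divergence`` subs/site."""
    half = divergence / 2.0
    return TreeNode.read(StringIO(f"(a:{half},b:{half});"))
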