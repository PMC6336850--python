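"""Pangenome construction: protein clusters and enrichment categories.

Proteins from all genomes are compared all-vs-all with a local-alignment
bitscore proxy, the similarity graph is pruned with the *minbit* heuristic
(pair score divided by the smaller self-score, default cutoff 0.5), and
protein clusters are produced by Markov clustering (MCL, inflation 2).

Each cluster's genome presence profile is then classified against the
core/enrichment frequency criteria used for the Marine Group II pangenome:

* **MGII-core** — present in >= 70% of the genomes of *each* major clade;
* **clade-core** (MGIIa-core / MGIIb-core) — >= 70% within one clade and
  <= 30% in the other;
* **subclade-unique** — >= 70% within one subclade and <= 10% of all other
  genomes;
* **none** — anything else.

When several criteria fire at boundary frequencies the most inclusive
category wins (MGII-core > clade-core > subclade-unique).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

DEFAULT_MINBIT = 0.5
DEFAULT_INFLATION = 2.0
MCL_PRUNE = 1e-10
SEED_K = 5  # amino-acid k-mer length for the all-vs-all prescreen

CORE_MIN = 0.70        # "detected in >= 70%"
OTHER_CLADE_MAX = 0.30  # "<= 30% of the genomes in the other clade"
OTHER_GENOMES_MAX = 0.10  # "<= 10% of all other genomes"


@dataclass
class SimilarityGraph:
    """Weighted protein-similarity graph with self-scores.

    ``edges`` maps frozenset({a, b}) -> score; ``self_scores`` maps protein
    id -> its self-alignment score; ``genome_of`` maps protein -> genome.
    """

    nodes: list[str]
    genome_of: dict[str, str]
    edges: dict[frozenset, float]
    self_scores: dict[str, float]


@dataclass
class ProteinCluster:
    cluster_id: str
    member_ids: frozenset[str]

    def presence(self, genome_of: dict[str, str]) -> set[str]:
        return {genome_of[p] for p in self.member_ids}


@dataclass
class EnrichmentCall:
    cluster_id: str
    category: str  # 'MGII-core' | '<clade>-core' | 'subclade-unique(<label>)' | 'none'
    frequencies: dict[str, float]  # per-group occurrence fractions (audit trail)


def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


def score_pairs(proteins: dict[str, str], genome_of: dict[str, str],
                k: int = SEED_K) -> SimilarityGraph:
    """Local-alignment scores for every protein pair sharing a k-mer seed.

    Scores are BLOSUM62 local-alignment scores with affine gaps — a bitscore
    proxy sufficient for minbit normalization.  Self-scores are computed for
    every protein.  Pairs sharing no k-mer get no edge.
    """
    if any(len(s) == 0 for s in proteins.values()):
        raise ValueError("empty protein sequence")
    aligner = _protein_aligner()
    ids = sorted(proteins)
    kmers: dict[str, set[str]] = {
        pid: {proteins[pid][i:i + k] for i in range(len(proteins[pid]) - k + 1)}
        for pid in ids
    }
    self_scores = {pid: float(aligner.score(proteins[pid], proteins[pid])) for pid in ids}
    edges: dict[frozenset, float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if kmers[a] & kmers[b]:
                edges[frozenset((a, b))] = float(aligner.score(proteins[a], proteins[b]))
    return SimilarityGraph(nodes=ids, genome_of=dict(genome_of),
                           edges=edges, self_scores=self_scores)


def minbit_filter(graph: SimilarityGraph, minbit: float = DEFAULT_MINBIT) -> SimilarityGraph:
    """Prune edges with minbit = score / min(self_a, self_b) below the cutoff.

    Retained edges are re-weighted by their minbit value (in (0, 1]); edges
    touching a node with no self-score are dropped with a warning.
    """
    new_edges: dict[frozenset, float] = {}
    for pair, score in graph.edges.items():
        members = sorted(pair)
        a, b = (members[0], members[0]) if len(members) == 1 else members
        if a not in graph.self_scores or b not in graph.self_scores:
            logger.warning("edge %s-%s dropped: missing self-score", a, b)
            continue
        mb = score / min(graph.self_scores[a], graph.self_scores[b])
        if mb >= minbit:
            new_edges[pair] = mb
    return SimilarityGraph(nodes=list(graph.nodes), genome_of=dict(graph.genome_of),
                           edges=new_edges, self_scores=dict(graph.self_scores))


def markov_cluster(graph: SimilarityGraph, inflation: float = DEFAULT_INFLATION,
                   max_iter: int = 200, tol: float = 1e-8,
                   prune: float = MCL_PRUNE) -> list[ProteinCluster]:
    """Markov clustering of the (minbit-weighted) similarity graph.

    The adjacency matrix gets a self-loop per node weighted by its maximum
    incident edge (1.0 for isolated nodes), is column-normalized, then
    alternates expansion (matrix squaring) and inflation (elementwise power
    + column re-normalization), pruning entries below ``prune``, until the
    largest column change falls under ``tol``.  Clusters are the weakly
    connected components of the limit matrix's support — a partition of the
    nodes, deterministic in node order.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return []
    pos = {p: i for i, p in enumerate(nodes)}
    m = np.zeros((n, n))
    for pair, w in graph.edges.items():
        members = sorted(pair)
        if len(members) == 1:
            continue  # explicit self-edges are replaced by the loop rule below
        a, b = members
        m[pos[a], pos[b]] = m[pos[b], pos[a]] = w
    loop = m.max(axis=0)
    loop[loop == 0] = 1.0
    m[np.diag_indices(n)] = loop
    m = m / m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = m @ m
        m = np.power(m, inflation)
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations; interpreting current matrix",
                       max_iter)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(*np.nonzero(m)))
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    return [
        ProteinCluster(cluster_id=f"PC{idx + 1:05d}",
                       member_ids=frozenset(nodes[i] for i in comp))
        for idx, comp in enumerate(comps)
    ]


def presence_matrix(clusters: list[ProteinCluster], genome_of: dict[str, str],
                    genomes: list[str] | None = None):
    """Cluster x genome boolean presence frame."""
    import pandas as pd

    if genomes is None:
        genomes = sorted(set(genome_of.values()))
    data = {
        c.cluster_id: [g in c.presence(genome_of) for g in genomes] for c in clusters
    }
    return pd.DataFrame(data, index=genomes).T


def classify_frequencies(clade_freq: dict[str, float],
                         subclade_freq: dict[str, float],
                         other_freq: dict[str, float],
                         cluster_id: str = "") -> EnrichmentCall:
    """Apply the 70/30/10 enrichment criteria to occurrence frequencies.

    ``clade_freq``: occurrence fraction per major clade; ``subclade_freq``:
    per subclade; ``other_freq``: for each subclade, the occurrence fraction
    among all genomes *outside* it.  Precedence: MGII-core > clade-core >
    subclade-unique > none.
    """
    freqs = {f"clade:{c}": f for c, f in clade_freq.items()}
    freqs.update({f"subclade:{s}": f for s, f in subclade_freq.items()})
    clades = sorted(clade_freq)
    if clades and all(clade_freq[c] >= CORE_MIN for c in clades):
        return EnrichmentCall(cluster_id, "MGII-core", freqs)
    for c in clades:
        others = [clade_freq[o] for o in clades if o != c]
        if clade_freq[c] >= CORE_MIN and others and all(o <= OTHER_CLADE_MAX for o in others):
            return EnrichmentCall(cluster_id, f"{c}-core", freqs)
    fired = [s for s in sorted(subclade_freq)
             if subclade_freq[s] >= CORE_MIN and other_freq[s] <= OTHER_GENOMES_MAX]
    if fired:
        if len(fired) > 1:
            logger.warning("cluster %s unique to several subclades %s; keeping first",
                           cluster_id, fired)
        return EnrichmentCall(cluster_id, f"subclade-unique({fired[0]})", freqs)
    return EnrichmentCall(cluster_id, "none", freqs)


def classify_cluster(presence: dict[str, bool],
                     clade_labels: dict[str, str],
                     subclade_labels: dict[str, str],
                     cluster_id: str = "") -> EnrichmentCall:
    """Classify one cluster's genome presence profile.

    ``presence`` maps genome -> bool over the full analyzed genome set;
    every genome must carry a clade and subclade label.
    """
    genomes = sorted(presence)
    unlabeled = [g for g in genomes if g not in clade_labels or g not in subclade_labels]
    if unlabeled:
        raise ValueError(f"genomes without clade/subclade labels: {unlabeled[:5]}")

    def freq(members: list[str]) -> float:
        return float(np.mean([presence[g] for g in members])) if members else 0.0

    by_clade: dict[str, list[str]] = {}
    by_sub: dict[str, list[str]] = {}
    for g in genomes:
        by_clade.setdefault(clade_labels[g], []).append(g)
        by_sub.setdefault(subclade_labels[g], []).append(g)
    clade_freq = {c: freq(m) for c, m in by_clade.items()}
    subclade_freq = {s: freq(m) for s, m in by_sub.items()}
    other_freq = {
        s: freq([g for g in genomes if subclade_labels[g] != s]) for s in by_sub
    }
    return classify_frequencies(clade_freq, subclade_freq, other_freq, cluster_id)
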