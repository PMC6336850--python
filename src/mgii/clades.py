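"""Subclade delineation on a rooted phylogenomic tree.

Genomes are assigned to subclades by cutting the concatenated-marker tree at
a *relative root distance* threshold (default 1.2): node depths are summed
branch lengths from the root, normalized so the average root-to-leaf depth is
1.0, and a subclade is a maximal clade whose stem edge crosses the threshold.
Candidate genomes first pass a single-copy-marker count gate (>= 60 of the
120 GTDB markers), and recovered subclades are checked for support by
within-clade pairwise ANI and AAI.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from skbio import TreeNode
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

N_GTDB_MARKERS = 120
DEFAULT_MIN_MARKERS = 60
DEFAULT_DEPTH_THRESHOLD = 1.2
# CompareM-style ortholog cutoffs for AAI
AAI_MIN_IDENTITY = 30.0
AAI_MIN_COVERAGE = 0.7


def read_tree(source: str) -> TreeNode:
    """Read a Newick tree from a path or string; unrooted (trifurcating root)
    trees are midpoint rooted with a logged note."""
    if "(" in source:
        tree = TreeNode.read(StringIO(source), convert_underscores=False)
    else:
        tree = TreeNode.read(source, convert_underscores=False)
    if len(tree.children) > 2:
        logger.info("input tree has a multifurcating root; applying midpoint rooting")
        tree = tree.root_at_midpoint()
    return tree


@dataclass
class CladeAssignment:
    labels: dict[str, str]            # genome id -> subclade label
    mrca: dict[str, TreeNode]         # subclade label -> MRCA node
    mrca_depth: dict[str, float]      # subclade label -> relative MRCA depth

    def subclades(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gid, lab in self.labels.items():
            out.setdefault(lab, []).append(gid)
        return out


@dataclass
class AAIResult:
    a_id: str
    b_id: str
    aai: float | None  # percent; None = no reciprocal best hits
    n_orthologs: int = 0


def count_markers(hits: pd.DataFrame, marker_list: list[str]) -> dict[str, int]:
    """Distinct markers hit per genome.

    ``hits`` columns: genome, marker, (score ignored beyond presence).
    Hits to markers outside ``marker_list`` are warned about and dropped.
    """
    known = set(marker_list)
    unknown = set(hits["marker"]) - known
    if unknown:
        logger.warning("ignoring hits to %d unknown markers: %s",
                       len(unknown), sorted(unknown)[:5])
    valid = hits[hits["marker"].isin(known)]
    return valid.groupby("genome")["marker"].nunique().to_dict()


def marker_gate(counts: dict[str, int], min_markers: int = DEFAULT_MIN_MARKERS) -> set[str]:
    """Genomes with at least ``min_markers`` distinct single-copy markers."""
    return {g for g, c in counts.items() if c >= min_markers}


def relative_depths(tree: TreeNode, normalization: str = "mean") -> dict[int, float]:
    """Relative root distance for every node, keyed by ``id(node)``.

    Absolute depth is the branch-length sum root->node; depths are divided by
    the mean (default; alternatives: max / median) root-to-leaf depth so
    leaves average 1.0.  A tree of all-zero branch lengths gets all-zero
    depths.
    """
    abs_depth: dict[int, float] = {}
    for node in tree.preorder():
        if node.is_root():
            abs_depth[id(node)] = 0.0
        else:
            abs_depth[id(node)] = abs_depth[id(node.parent)] + (node.length or 0.0)
    leaf_depths = [abs_depth[id(t)] for t in tree.tips()]
    if normalization == "mean":
        norm = float(np.mean(leaf_depths))
    elif normalization == "max":
        norm = float(np.max(leaf_depths))
    elif normalization == "median":
        norm = float(np.median(leaf_depths))
    else:
        raise ValueError(f"unknown normalization: {normalization!r}")
    if norm == 0:
        return {k: 0.0 for k in abs_depth}
    return {k: d / norm for k, d in abs_depth.items()}


def cut_subclades(
    tree: TreeNode,
    threshold: float = DEFAULT_DEPTH_THRESHOLD,
    normalization: str = "mean",
    label_prefix: str = "subclade",
) -> CladeAssignment:
    """Cut the tree where stem edges cross the relative-depth threshold.

    A subclade is a maximal clade with MRCA depth >= threshold whose parent
    is shallower than the threshold.  Leaves shallower than the threshold
    (their path never crosses it) become singleton ``unplaced`` labels rather
    than being forced into a neighboring clade.  Subclades are numbered in
    preorder.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    depths = relative_depths(tree, normalization=normalization)
    if all(d == 0.0 for d in depths.values()):
        # degenerate star of zero branch lengths: one clade holding everything
        lab = f"{label_prefix}.1"
        return CladeAssignment(
            labels={t.name: lab for t in tree.tips()},
            mrca={lab: tree}, mrca_depth={lab: 0.0},
        )
    labels: dict[str, str] = {}
    mrca: dict[str, TreeNode] = {}
    mrca_depth: dict[str, float] = {}
    counter = 0
    unplaced = 0

    def visit(node):
        nonlocal counter, unplaced
        d = depths[id(node)]
        parent_d = depths[id(node.parent)] if node.parent is not None else 0.0
        if d >= threshold and (node.is_root() or parent_d < threshold):
            counter += 1
            lab = f"{label_prefix}.{counter}"
            mrca[lab] = node
            mrca_depth[lab] = d
            for tip in ([node] if node.is_tip() else node.tips()):
                labels[tip.name] = lab
            return
        if node.is_tip():
            unplaced += 1
            lab = f"unplaced.{unplaced}"
            labels[node.name] = lab
            mrca[lab] = node
            mrca_depth[lab] = d
            return
        for child in node.children:
            visit(child)

    visit(tree)
    return CladeAssignment(labels=labels, mrca=mrca, mrca_depth=mrca_depth)


_aligner = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11
        a.extend_gap_score = -1
        _aligner = a
    return _aligner


def _best_hits(qry: dict[str, str], ref: dict[str, str]):
    """Best local-alignment hit in ``ref`` for each query protein, with the
    hit's percent identity and coverage of the shorter protein."""
    aligner = _get_aligner()
    hits = {}
    for qid, qseq in qry.items():
        best = None
        for rid, rseq in ref.items():
            score = aligner.score(qseq, rseq)
            if best is None or score > best[1]:
                best = (rid, score)
        if best is None or best[1] <= 0:
            continue
        rid, score = best
        paths = aligner.align(qseq, ref[rid])
        try:
            aln = paths[0]
        except IndexError:
            continue
        c = aln.counts()
        cols = c.identities + c.mismatches + c.internal_gaps
        if cols == 0:
            continue
        pid = 100.0 * c.identities / cols
        cov = (c.identities + c.mismatches) / min(len(qseq), len(ref[rid]))
        hits[qid] = (rid, score, pid, cov)
    return hits


def estimate_aai(proteome_a: dict[str, str], proteome_b: dict[str, str],
                 min_identity: float = AAI_MIN_IDENTITY,
                 min_coverage: float = AAI_MIN_COVERAGE,
                 a_id: str = "a", b_id: str = "b") -> AAIResult:
    """Mean percent identity over reciprocal-best-hit ortholog pairs.

    Orthologs are reciprocal best local-alignment hits passing the identity
    and shorter-protein-coverage cutoffs.  With no qualifying pair the result
    is a distinct no-estimate (aai=None).
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    fwd = _best_hits(proteome_a, proteome_b)
    rev = _best_hits(proteome_b, proteome_a)
    idents = []
    for qid, (rid, _score, pid, cov) in fwd.items():
        if rev.get(rid, (None,))[0] != qid:
            continue
        if pid < min_identity or cov < min_coverage:
            continue
        idents.append(pid)
    if not idents:
        return AAIResult(a_id=a_id, b_id=b_id, aai=None, n_orthologs=0)
    return AAIResult(a_id=a_id, b_id=b_id, aai=float(np.mean(idents)),
                     n_orthologs=len(idents))


def support_check(
    assignment: CladeAssignment,
    ani: dict[frozenset, float],
    aai: dict[frozenset, float],
    ani_min: float = 70.0,
    aai_min: float = 70.0,
    quorum: float = 0.9,
) -> pd.DataFrame:
    """Fraction of within-subclade pairs exceeding the ANI and AAI cutoffs.

    A subclade is 'supported' when both fractions reach the quorum;
    singletons are trivially supported and flagged as such.  Pairs missing
    from a matrix count as failing that cutoff.
    """
    rows = []
    for lab, members in sorted(assignment.subclades().items()):
        if len(members) == 1:
            rows.append({"subclade": lab, "n_genomes": 1, "ani_support": 1.0,
                         "aai_support": 1.0, "supported": True, "singleton": True})
            continue
        pairs = [frozenset((a, b)) for i, a in enumerate(members)
                 for b in members[i + 1:]]
        ani_frac = np.mean([1.0 if ani.get(p, -np.inf) > ani_min else 0.0 for p in pairs])
        aai_frac = np.mean([1.0 if aai.get(p, -np.inf) > aai_min else 0.0 for p in pairs])
        rows.append({"subclade": lab, "n_genomes": len(members),
                     "ani_support": float(ani_frac), "aai_support": float(aai_frac),
                     "supported": bool(ani_frac >= quorum and aai_frac >= quorum),
                     "singleton": False})
    return pd.DataFrame(rows)


def neighbor_joining_tree(distance: pd.DataFrame) -> TreeNode:
    """Neighbor-joining tree from a distance matrix (test utility; the
    production tree is an external input built from concatenated markers)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(distance.values, ids=list(distance.index))
    return nj(dm)
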