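"""Rule-based trait classification from protein sequences and annotations.

Four traits central to the ecology of Marine Group II Euryarchaeota are
called with deterministic rules:

* **Proteorhodopsin** — proton pumping requires aspartate at alignment
  position 97 and lysine or glutamate at 108; spectral tuning is read from
  position 105 (glutamine -> blue-shifted, methionine -> green-shifted).
  Positions refer to columns of a bundled reference numbering scaffold; a
  novel sequence is mapped onto it by global alignment.
* **ATP-synthase c-ring motif** — the transmembrane-helix motif LPESxxI
  marks the MGIIa-type rotor ring and LPETIxL the MGIIb-type; both indicate
  putative Na+-coupled A-type ATP synthases.
* **Extracellular peptidases** — a MEROPS-family HMM hit of >= 75 bits on a
  protein localized extracellularly / to the outer membrane, or of unknown
  localization but carrying a translocation signal peptide.
* **Archaeal flagellum operon** — FlaH, FlaI, FlaJ (K07331-K07333) plus at
  least one archaeal flagellin (PF01917) co-localized on one contig within a
  bounded gene-index window.

Per-subclade trait occurrence is summarized as a fraction matrix in [0, 1].
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .clades import CladeAssignment

logger = logging.getLogger(__name__)

# Diagnostic alignment columns (1-based, reference numbering)
POS_PUMP_1 = 97    # aspartate required for proton pumping
POS_PUMP_2 = 108   # lysine / glutamate proton donor
POS_TUNING = 105   # spectral tuning switch (Q = blue, M = green)

MOTIF_MGIIA = re.compile(r"LPES..I")
MOTIF_MGIIB = re.compile(r"LPETI.L")

PEPTIDASE_SCORE_MIN = 75.0
FLA_KOS = {"K07331": "FlaH", "K07332": "FlaI", "K07333": "FlaJ"}
FLAGELLIN_ACC = "PF01917"
DEFAULT_OPERON_WINDOW = 10

# Synthetic reference numbering scaffold for the rhodopsin classifier: a
# fixed 240-residue sequence providing the coordinate system for the
# diagnostic columns (97/105/108).  It is a stand-in built for this package,
# not a natural proteorhodopsin; only its numbering matters, and query
# sequences are mapped onto it by global alignment.
_REF_RNG = np.random.default_rng(20180917)
_AA = "ACDEFGHIKLMNPQRSTVWY"
REFERENCE_RHODOPSIN = "".join(_AA[i] for i in _REF_RNG.integers(0, 20, size=240))
REFERENCE_RHODOPSIN = (
    REFERENCE_RHODOPSIN[: POS_PUMP_1 - 1] + "D"
    + REFERENCE_RHODOPSIN[POS_PUMP_1:POS_TUNING - 1] + "Q"
    + REFERENCE_RHODOPSIN[POS_TUNING:POS_PUMP_2 - 1] + "K"
    + REFERENCE_RHODOPSIN[POS_PUMP_2:]
)


@dataclass
class RhodopsinCall:
    protein_id: str
    residue_97: str       # '-' when the column is gapped
    residue_108: str
    residue_105: str
    is_proton_pumping: bool
    tuning: str           # 'blue' | 'green' | 'indeterminate'
    flagged: bool = False  # unusual residue combination worth manual review


@dataclass
class CRingMotifCall:
    protein_id: str
    motif_class: str      # 'MGIIa-type' | 'MGIIb-type' | 'none' | 'conflict'
    match_position: int | None  # 1-based position of first match


@dataclass
class PeptidaseCall:
    protein_id: str
    merops_family: str
    hmm_score: float
    localization: str
    has_signal_peptide: bool
    is_extracellular_call: bool


@dataclass
class OperonCall:
    genome_id: str
    contig: str | None
    span: tuple[int, int] | None   # gene-index span of the co-localized set
    components_found: frozenset[str]
    is_present: bool


_glob_aligner = None


def _global_aligner() -> Align.PairwiseAligner:
    global _glob_aligner
    if _glob_aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -10
        a.extend_gap_score = -0.5
        _glob_aligner = a
    return _glob_aligner


def map_to_reference(protein: str, reference: str = REFERENCE_RHODOPSIN) -> dict[int, str]:
    """Map reference columns (1-based) to query residues by global alignment.

    Columns where the query is gapped map to '-'.
    """
    aln = _global_aligner().align(protein, reference)[0]
    qidx, ridx = aln.indices  # -1 where gapped
    out: dict[int, str] = {}
    for q, r in zip(qidx, ridx):
        if r >= 0:
            out[int(r) + 1] = protein[q] if q >= 0 else "-"
    return out


def classify_rhodopsin(protein: str, protein_id: str = "",
                       positions: tuple[int, int, int] = (POS_PUMP_1, POS_PUMP_2, POS_TUNING),
                       aligned: bool = False) -> RhodopsinCall:
    """Call proton-pumping function and spectral tuning from the diagnostic
    residues.

    ``aligned=True`` treats the sequence as already laid out on the reference
    numbering (position i = residue i); otherwise it is globally aligned to
    the bundled reference first.  A gap at a diagnostic column leaves that
    field indeterminate (and the call not-pumping), logged.
    """
    p97, p108, p105 = positions
    if aligned:
        if len(protein) < max(positions):
            raise ValueError("aligned sequence shorter than the reference numbering map")
        colmap = {i + 1: protein[i] for i in range(len(protein))}
    else:
        colmap = map_to_reference(protein)
    r97 = colmap.get(p97, "-")
    r108 = colmap.get(p108, "-")
    r105 = colmap.get(p105, "-")
    if "-" in (r97, r108, r105):
        logger.warning("rhodopsin %s: gap at a diagnostic column (97=%s 108=%s 105=%s)",
                       protein_id, r97, r108, r105)
    pumping = r97 == "D" and r108 in ("K", "E")
    tuning = {"Q": "blue", "M": "green"}.get(r105, "indeterminate")
    # a tuning residue without the pumping pair is biologically odd; flag it
    flagged = (not pumping) and tuning != "indeterminate"
    return RhodopsinCall(protein_id=protein_id, residue_97=r97, residue_108=r108,
                         residue_105=r105, is_proton_pumping=pumping,
                         tuning=tuning, flagged=flagged)


def scan_cring_motif(protein: str, protein_id: str = "") -> CRingMotifCall:
    """Scan for the clade-diagnostic c-ring motifs; 'x' matches any residue.

    Both motifs present yields a 'conflict' call (never an exception); the
    reported position is the first occurrence, 1-based.
    """
    ma = MOTIF_MGIIA.search(protein)
    mb = MOTIF_MGIIB.search(protein)
    if ma and mb:
        first = min(ma.start(), mb.start())
        return CRingMotifCall(protein_id, "conflict", first + 1)
    if ma:
        return CRingMotifCall(protein_id, "MGIIa-type", ma.start() + 1)
    if mb:
        return CRingMotifCall(protein_id, "MGIIb-type", mb.start() + 1)
    return CRingMotifCall(protein_id, "none", None)


def call_extracellular_peptidases(
    hits: pd.DataFrame,
    localization: pd.DataFrame | None = None,
    signal: pd.DataFrame | None = None,
    score_min: float = PEPTIDASE_SCORE_MIN,
) -> list[PeptidaseCall]:
    """Apply the extracellular-peptidase rule to MEROPS-family HMM hits.

    ``hits`` columns: protein, family, score.  ``localization`` columns:
    protein, localization (missing proteins -> 'unknown').  ``signal``
    columns: protein, has_signal_peptide.  Duplicate (protein, family) rows
    keep the maximum score with a warning.  Every candidate is returned with
    its boolean so the filter is auditable.
    """
    if hits.duplicated(subset=["protein", "family"]).any():
        logger.warning("duplicate peptidase hit rows; keeping max score per protein+family")
        hits = hits.sort_values("score").drop_duplicates(
            subset=["protein", "family"], keep="last")
    loc_map = {}
    if localization is not None:
        loc_map = dict(zip(localization["protein"], localization["localization"]))
    sp_map = {}
    if signal is not None:
        sp_map = dict(zip(signal["protein"], signal["has_signal_peptide"].astype(bool)))
    calls = []
    for _, row in hits.iterrows():
        pid = row["protein"]
        loc = loc_map.get(pid, "unknown")
        sp = bool(sp_map.get(pid, False))
        ok = row["score"] >= score_min and (
            loc in ("extracellular", "outer membrane") or (loc == "unknown" and sp)
        )
        calls.append(PeptidaseCall(protein_id=pid, merops_family=row["family"],
                                   hmm_score=float(row["score"]), localization=loc,
                                   has_signal_peptide=sp, is_extracellular_call=bool(ok)))
    return calls


def detect_flagellum_operon(genes: pd.DataFrame,
                            window: int = DEFAULT_OPERON_WINDOW) -> list[OperonCall]:
    """Detect the archaeal flagellum operon per genome.

    ``genes`` columns: genome, contig, gene_index, annotation (KO id or Pfam
    accession; unannotated genes may be absent or carry any other value).
    The operon is present when one contig carries FlaH, FlaI and FlaJ plus at
    least one flagellin with max pairwise gene-index gap <= window.
    """
    calls = []
    for gid, gdf in genes.groupby("genome", sort=True):
        best: OperonCall | None = None
        found_all: set[str] = set()
        for contig, cdf in gdf.groupby("contig", sort=True):
            comp_pos: dict[str, list[int]] = {}
            for _, row in cdf.iterrows():
                ann = row["annotation"]
                name = FLA_KOS.get(ann, "flagellin" if ann == FLAGELLIN_ACC else None)
                if name:
                    comp_pos.setdefault(name, []).append(int(row["gene_index"]))
            found_all |= set(comp_pos)
            if not {"FlaH", "FlaI", "FlaJ", "flagellin"} <= set(comp_pos):
                continue
            # smallest window containing one of each required component
            candidates = []
            for h in comp_pos["FlaH"]:
                for i in comp_pos["FlaI"]:
                    for j in comp_pos["FlaJ"]:
                        for f in comp_pos["flagellin"]:
                            lo, hi = min(h, i, j, f), max(h, i, j, f)
                            candidates.append((hi - lo, lo, hi))
            gap, lo, hi = min(candidates)
            if gap <= window:
                best = OperonCall(genome_id=gid, contig=contig, span=(lo, hi),
                                  components_found=frozenset(comp_pos), is_present=True)
                break
        if best is None:
            best = OperonCall(genome_id=gid, contig=None, span=None,
                              components_found=frozenset(found_all), is_present=False)
        calls.append(best)
    return calls


def occurrence_matrix(trait_calls: pd.DataFrame,
                      assignment: CladeAssignment) -> pd.DataFrame:
    """Per-subclade trait occurrence fractions (rows: subclades, cols: traits).

    ``trait_calls``: genomes x traits boolean frame indexed by genome id.
    Cell = genomes in the subclade possessing the trait / subclade size, so
    1.0 means every genome in the subclade has the trait.
    """
    sub = assignment.subclades()
    for lab, members in sub.items():
        if not members:
            raise ValueError(f"subclade {lab} is empty")
    missing = set(trait_calls.index) - set(assignment.labels)
    if missing:
        raise ValueError(f"genomes without a subclade assignment: {sorted(missing)[:5]}")
    rows = {}
    for lab, members in sorted(sub.items()):
        # a genome absent from the call table simply lacks the trait
        block = trait_calls.reindex(members).fillna(False).astype(bool)
        rows[lab] = block.mean(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "subclade"
    return out.astype(float)
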