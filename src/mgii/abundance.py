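"""Read-recruitment abundance profiling.

Metagenomic read alignments are filtered at >= 95% sequence identity and
>= 75% aligned read fraction (both inclusive), counted per genome, and
normalized two ways:

* relative fraction = reads recruited to the genome / total reads in the
  sample;
* RPKM = (reads recruited / (genome length in bp / 1,000))
         / (total bp in the sample / 1,000,000).

Samples are split into high (summed recruited fraction >= 0.5%) and low
recruitment classes; only high samples feed the ecology statistics.

SAM input is read in text form via pysam; identity is derived as
1 - NM / alignment_length and the aligned fraction as
alignment_length / read_length.  A TSV dialect with precomputed fields is
accepted for tools that report them directly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_MIN_ALIGNED = 0.75
DEFAULT_HIGH_THRESHOLD = 0.005


@dataclass
class AlignmentRecord:
    read_id: str
    contig: str
    identity: float        # fraction in [0, 1]
    aligned_fraction: float  # fraction of the read aligned, in [0, 1]
    read_length: int = 0

    def __post_init__(self):
        if not (0 <= self.identity <= 1 and 0 <= self.aligned_fraction <= 1):
            raise ValueError(
                f"identity/aligned_fraction must lie in [0,1]: {self}")


@dataclass
class AbundanceMatrix:
    """Genome x sample recruited-read counts with the per-sample totals
    needed for normalization."""

    counts: pd.DataFrame          # genomes x samples, integer counts
    genome_lengths: pd.Series     # bp per genome
    total_reads: pd.Series        # reads per sample (R_m)
    total_bp: pd.Series           # bp per sample (B_m)

    def relative_fraction(self) -> pd.DataFrame:
        return relative_fraction(self.counts, self.total_reads)

    def rpkm(self) -> pd.DataFrame:
        return rpkm(self.counts, self.genome_lengths, self.total_bp)


def read_sam(path: str) -> list[AlignmentRecord]:
    """Parse a text SAM file into alignment records.

    Identity = 1 - NM/alignment_length; aligned fraction uses the full read
    length (soft-clipped bases included in the denominator).  Unmapped and
    secondary records are skipped.
    """
    import pysam

    records = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            alen = aln.query_alignment_length
            rlen = aln.infer_read_length() or aln.query_length or alen
            if alen == 0 or rlen == 0:
                continue
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            records.append(AlignmentRecord(
                read_id=aln.query_name, contig=aln.reference_name,
                identity=max(0.0, 1.0 - nm / alen),
                aligned_fraction=min(1.0, alen / rlen), read_length=rlen))
    return records


def read_alignment_tsv(path: str) -> list[AlignmentRecord]:
    """TSV dialect: read_id, contig, identity, aligned_fraction[, read_length]."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, r in df.iterrows():
        try:
            records.append(AlignmentRecord(
                read_id=str(r["read_id"]), contig=str(r["contig"]),
                identity=float(r["identity"]),
                aligned_fraction=float(r["aligned_fraction"]),
                read_length=int(r.get("read_length", 0) or 0)))
        except (ValueError, KeyError) as exc:
            logger.warning("skipping malformed alignment row: %s", exc)
    return records


def filter_alignments(records: list[AlignmentRecord],
                      min_id: float = DEFAULT_MIN_IDENTITY,
                      min_aln: float = DEFAULT_MIN_ALIGNED) -> list[AlignmentRecord]:
    """Keep records meeting both thresholds (inclusive); one record per read.

    When a read has several passing placements the single best-identity one
    is kept (ties broken by contig id, then input order).  Idempotent.
    """
    best: dict[str, AlignmentRecord] = {}
    for rec in records:
        if rec.identity >= min_id and rec.aligned_fraction >= min_aln:
            cur = best.get(rec.read_id)
            if cur is None or (rec.identity, ) > (cur.identity, ) or (
                    rec.identity == cur.identity and rec.contig < cur.contig):
                best[rec.read_id] = rec
    return [best[r] for r in best]


def count_reads(filtered: list[AlignmentRecord],
                contig_to_genome: dict[str, str],
                genomes: list[str] | None = None) -> pd.Series:
    """Recruited-read count per genome for one sample."""
    missing = sorted({r.contig for r in filtered} - set(contig_to_genome))
    if missing:
        raise KeyError(f"contigs not mapped to any genome: {missing[:10]}")
    if genomes is None:
        genomes = sorted(set(contig_to_genome.values()))
    counts = pd.Series(0, index=pd.Index(genomes, name="genome"), dtype=int)
    for rec in filtered:
        counts[contig_to_genome[rec.contig]] += 1
    return counts


def relative_fraction(counts: pd.DataFrame, total_reads: pd.Series) -> pd.DataFrame:
    """r_g / R_m per genome and sample; zero-read samples are flagged and
    yield NaN rather than a silent zero."""
    totals = total_reads.reindex(counts.columns)
    zero = totals[totals <= 0].index
    if len(zero):
        logger.warning("samples with zero total reads (fractions undefined): %s",
                       list(zero))
        totals = totals.replace(0, np.nan)
    return counts.div(totals, axis=1)


def rpkm(counts: pd.DataFrame, genome_lengths: pd.Series,
         total_bp: pd.Series) -> pd.DataFrame:
    """(r_g / (L_g/1000)) / (B_m/1e6) per genome and sample."""
    lengths = genome_lengths.reindex(counts.index)
    bp = total_bp.reindex(counts.columns)
    if (lengths <= 0).any():
        raise ValueError("all genome lengths must be positive")
    if (bp <= 0).any():
        raise ValueError("all per-sample total bp must be positive")
    per_kb = counts.div(lengths / 1_000.0, axis=0)
    return per_kb.div(bp / 1_000_000.0, axis=1)


def split_high_low(fractions: pd.DataFrame,
                   threshold: float = DEFAULT_HIGH_THRESHOLD) -> pd.Series:
    """Classify samples by summed recruited fraction over the genome set:
    'high' when >= threshold (inclusive), else 'low'."""
    summed = fractions.sum(axis=0, skipna=False)
    return pd.Series(np.where(summed >= threshold, "high", "low"),
                     index=fractions.columns, name="class")


def profile(sample_records: dict[str, list[AlignmentRecord]],
            contig_to_genome: dict[str, str],
            genome_lengths: pd.Series,
            manifest: pd.DataFrame,
            min_id: float = DEFAULT_MIN_IDENTITY,
            min_aln: float = DEFAULT_MIN_ALIGNED) -> AbundanceMatrix:
    """Filter + count every sample into one AbundanceMatrix.

    ``manifest`` columns: sample, total_reads, total_bp (totals come from the
    sequencing manifest — the alignment records only cover recruited reads).
    """
    manifest = manifest.set_index("sample") if "sample" in manifest.columns else manifest
    genomes = sorted(genome_lengths.index)
    cols = {}
    for sample, records in sample_records.items():
        filtered = filter_alignments(records, min_id=min_id, min_aln=min_aln)
        cols[sample] = count_reads(filtered, contig_to_genome, genomes=genomes)
    counts = pd.DataFrame(cols, index=pd.Index(genomes, name="genome")).fillna(0).astype(int)
    counts = counts[sorted(counts.columns)]
    return AbundanceMatrix(counts=counts,
                           genome_lengths=genome_lengths.reindex(genomes),
                           total_reads=manifest["total_reads"].reindex(counts.columns),
                           total_bp=manifest["total_bp"].reindex(counts.columns))
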