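"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything on disk is FASTA or TSV; binary formats are out of scope (SAM is
read in its text form through pysam).
"""
from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str) -> dict[str, str]:
    """Return {record id: uppercase sequence} for a FASTA file."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    SeqIO.write(records, path, "fasta")


def read_tsv(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_genome_dir(fasta_dir: str, quality_tsv: str | None = None):
    """Load one GenomeRecord per ``*.fasta``/``*.fa`` file in a directory.

    The quality table (columns: id, completeness, contamination) is optional;
    genomes missing from it get NaN estimates and are dropped (with a
    warning) by the quality gate downstream.
    """
    from .derep import GenomeRecord

    quality = {}
    if quality_tsv is not None:
        qdf = read_tsv(quality_tsv)
        quality = {
            str(r["id"]): (float(r["completeness"]), float(r["contamination"]))
            for _, r in qdf.iterrows()
        }
    genomes = []
    for fname in sorted(os.listdir(fasta_dir)):
        if not fname.endswith((".fasta", ".fa", ".fna")):
            continue
        gid = fname.rsplit(".", 1)[0]
        contigs = read_fasta(os.path.join(fasta_dir, fname))
        comp, cont = quality.get(gid, (float("nan"), float("nan")))
        genomes.append(
            GenomeRecord(
                id=gid,
                contigs=list(contigs.values()),
                completeness=comp,
                contamination=cont,
            )
        )
    return genomes


def iter_pairs(items: Iterable):
    """All unordered pairs, in stable order."""
    items = list(items)
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            yield items[i], items[j]
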