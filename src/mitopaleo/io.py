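"""Readers and writers for the formats the pipeline speaks.

FASTA via Biopython, a SAM dialect subset via pysam (single reference
sequence, match-only CIGARs; reads wrapping past the circular origin are
split into two records re-joined on read), FASTQ with truth labels in the
description, aligned-panel multi-FASTA, a TSV allele-frequency table,
Newick via dendropy, and the JSON run report.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clock import TipDatedSequence
from .contamination import ReferencePanel
from .reference import MT_LENGTH
from .simulate import ENDOGENOUS, SimulatedRead

_REF_NAME = "MT"
_TRUTH_TAG = "XC"  # truth label (endogenous/contaminant), validation only


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Sequences by record id, uppercased."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# SAM


def write_sam(reads: Sequence[SimulatedRead], path, reference_length: int = MT_LENGTH) -> None:
    """Write reads as SAM (text) against a single circular reference.

    A read running past the origin is emitted as two match-only records
    with the same query name; :func:`read_sam` re-joins them.  The truth
    label travels in the XC tag and is never consulted by estimators.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": _REF_NAME, "LN": reference_length}],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, read in enumerate(reads):
            qname = f"read{i:07d}"
            end = read.start + read.length
            parts = []
            if end <= reference_length:
                parts.append((read.start, read.bases))
            else:
                split = reference_length - read.start
                parts.append((read.start, read.bases[:split]))
                parts.append((0, read.bases[split:]))
            for pos, bases in parts:
                seg = pysam.AlignedSegment(header)
                seg.query_name = qname
                seg.flag = 16 if read.strand == "-" else 0
                seg.reference_id = 0
                seg.reference_start = pos
                seg.mapping_quality = 60
                seg.cigartuples = [(0, len(bases))]
                seg.query_sequence = bases
                seg.set_tag(_TRUTH_TAG, read.source, "Z")
                out.write(seg)


def read_sam(path) -> list[SimulatedRead]:
    """Read the SAM dialect subset back into aligned reads.

    Only match-type CIGAR operations (M/=/X) are supported; any other
    operation raises with the offending op named.  Consecutive records
    sharing a query name are re-joined as one origin-wrapping read.
    """
    by_name: dict[str, list[pysam.AlignedSegment]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            for op, _n in seg.cigartuples or []:
                if op not in (0, 7, 8):  # M, =, X
                    opname = "MIDNSHP=XB"[op]
                    raise ValueError(
                        f"unsupported CIGAR op {opname!r} in read {seg.query_name}"
                    )
            if seg.query_name not in by_name:
                order.append(seg.query_name)
            by_name.setdefault(seg.query_name, []).append(seg)

    reads = []
    for name in order:
        segs = by_name[name]
        first = segs[0]
        bases = "".join(s.query_sequence for s in segs)
        reads.append(
            SimulatedRead(
                start=int(first.reference_start),
                length=len(bases),
                strand="-" if first.is_reverse else "+",
                bases=bases,
                source=(
                    first.get_tag(_TRUTH_TAG)
                    if first.has_tag(_TRUTH_TAG)
                    else ENDOGENOUS
                ),
            )
        )
    return reads


# ---------------------------------------------------------------------------
# FASTQ


def write_fastq(reads: Sequence[SimulatedRead], path) -> None:
    """FASTQ with constant quality; alignment and truth in the description."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(
                f"@read{i:07d} start={read.start} strand={read.strand} "
                f"source={read.source}\n{read.bases}\n+\n{'I' * read.length}\n"
            )


def read_fastq(path) -> list[SimulatedRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        fields = dict(
            kv.split("=") for kv in rec.description.split()[1:] if "=" in kv
        )
        reads.append(
            SimulatedRead(
                start=int(fields["start"]),
                length=len(rec.seq),
                strand=fields.get("strand", "+"),
                bases=str(rec.seq).upper(),
                source=fields.get("source", ENDOGENOUS),
            )
        )
    if not reads:
        raise ValueError(f"no FASTQ records in {path}")
    return reads


# ---------------------------------------------------------------------------
# reference panel


def read_panel(path, n_genomes: int | None = None) -> ReferencePanel:
    """Panel from aligned multi-FASTA or from a TSV frequency table.

    TSV columns: position (1-based), A, C, G, T; ``n_genomes`` is then
    required since frequencies alone do not reveal it.
    """
    path = Path(path)
    if path.suffix.lower() in (".tsv", ".txt"):
        table = pd.read_csv(path, sep="\t", comment="#")
        if n_genomes is None:
            raise ValueError("n_genomes is required with a frequency-table panel")
        return ReferencePanel.from_frequency_table(table, n_genomes=n_genomes)
    return ReferencePanel.from_sequences(list(read_fasta(path).values()))


def write_panel_frequencies(panel: ReferencePanel, path) -> None:
    L = panel.frequencies.shape[0]
    df = pd.DataFrame(panel.frequencies, columns=list("ACGT"))
    df.insert(0, "position", np.arange(1, L + 1))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# tip-dated alignments and trees


def read_tip_dated(fasta_path, ages_path) -> list[TipDatedSequence]:
    """Aligned FASTA plus a sidecar TSV (id, age_BP) -> dated sequences."""
    seqs = read_fasta(fasta_path)
    ages = pd.read_csv(ages_path, sep="\t", comment="#")
    if not {"id", "age_BP"} <= set(ages.columns):
        raise ValueError("ages table needs columns: id, age_BP")
    age_of = dict(zip(ages["id"].astype(str), ages["age_BP"].astype(float)))
    missing = set(seqs) - set(age_of)
    if missing:
        raise ValueError(f"no age for sequences: {sorted(missing)}")
    return [
        TipDatedSequence(label=name, sequence=seq, age=age_of[name])
        for name, seq in seqs.items()
    ]


def write_tip_dated(tips: Sequence[TipDatedSequence], fasta_path, ages_path) -> None:
    write_fasta({t.label: t.sequence for t in tips}, fasta_path)
    pd.DataFrame(
        {"id": [t.label for t in tips], "age_BP": [t.age for t in tips]}
    ).to_csv(ages_path, sep="\t", index=False)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


# ---------------------------------------------------------------------------
# variants


def write_variants_tsv(variants, path) -> None:
    """Substitutions as a VCF-like TSV: position, ref, alt, label."""
    rows = [(v.position, v.ref, v.alt, v.label) for v in sorted(variants)]
    pd.DataFrame(rows, columns=["position", "ref", "alt", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_variants_tsv(path):
    from .variants import MtVariant

    table = pd.read_csv(path, sep="\t", comment="#")
    return sorted(
        MtVariant(position=int(r.position), ref=r.ref, alt=r.alt)
        for r in table.itertuples()
    )


# ---------------------------------------------------------------------------
# reports and traces


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_trace(trace: np.ndarray, columns: Sequence[str], path) -> None:
    pd.DataFrame(trace, columns=list(columns)).to_csv(path, sep="\t", index=False)
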