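"""File formats: FASTA/FASTQ, BED, TSV tables, and minimal SAM.

Conventions: in-memory coordinates are 0-based half-open; BED stays 0-based
half-open per its own convention; SAM positions are 1-based as required by
the format (written through pysam).  FASTA is wrapped at 70 columns.
Simulated FASTQ qualities are a constant placeholder ('I', Q40), since the
simulator has no per-base quality model.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import FragmentAlignment, ScoringScheme, sw_align_path
from .genome import CnvTruth, CnvTruthSegment, ReferenceGenome
from .simulate import SmurfRead, reverse_complement

__all__ = [
    "write_fasta", "read_fasta", "write_reads_fastq", "read_reads",
    "write_truth_bed", "read_truth_bed", "write_digest_bed",
    "write_fragment_truth_tsv", "read_fragment_truth_tsv",
    "write_fragments_tsv", "read_fragments_tsv",
    "write_sam", "read_fragments_sam",
]

FRAGMENT_COLUMNS = [
    "read_id", "read_start", "read_end", "chrom", "ref_start", "ref_end",
    "strand", "score", "unique",
]


def write_fasta(genome: ReferenceGenome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in zip(genome.chrom_names, genome.sequences)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(records)


def read_fasta(path: str | Path) -> ReferenceGenome:
    names, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return ReferenceGenome(names, seqs)


def write_reads_fastq(reads: list[SmurfRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def read_reads(path: str | Path) -> list[tuple[str, str]]:
    """(read_id, sequence) pairs from FASTA or FASTQ (sniffed by extension)."""
    p = str(path)
    fmt = "fastq" if p.endswith((".fq", ".fastq")) else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(p, fmt)]


def write_truth_bed(truth: CnvTruth, path: str | Path) -> None:
    """Copy-number truth as BED4: chrom, start, end, copy_number."""
    with open(path, "w") as fh:
        for seg in truth.segments:
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.copy_number}\n")


def read_truth_bed(path: str | Path) -> list[CnvTruthSegment]:
    segs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, cn = line.split()[:4]
            segs.append(CnvTruthSegment(chrom, int(start), int(end), int(cn)))
    return segs


def write_digest_bed(fragments: dict, path: str | Path) -> None:
    """Digest fragments as BED3."""
    with open(path, "w") as fh:
        for chrom, ivs in fragments.items():
            for s, e in ivs:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def write_fragment_truth_tsv(reads: list[SmurfRead], path: str | Path) -> None:
    rows = []
    for r in reads:
        for i, f in enumerate(r.fragments):
            rows.append(
                (r.read_id, i, f.source_chrom, f.source_start, f.source_end,
                 f.strand, f.read_start, f.read_end)
            )
    pd.DataFrame(
        rows,
        columns=["read_id", "frag_index", "chrom", "start", "end", "strand",
                 "read_start", "read_end"],
    ).to_csv(path, sep="\t", index=False)


def read_fragment_truth_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"read_id": str})


def write_fragments_tsv(
    fragments: list[FragmentAlignment], path: str | Path
) -> None:
    rows = [
        (f.read_id, f.read_start, f.read_end, f.chrom, f.ref_start, f.ref_end,
         f.strand, f.score, int(f.is_unique))
        for f in fragments
    ]
    pd.DataFrame(rows, columns=FRAGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fragments_tsv(path: str | Path) -> list[FragmentAlignment]:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str})
    return [
        FragmentAlignment(
            read_id=str(r.read_id), read_start=int(r.read_start),
            read_end=int(r.read_end), chrom=str(r.chrom),
            ref_start=int(r.ref_start), ref_end=int(r.ref_end),
            strand=str(r.strand), score=int(r.score),
            is_unique=bool(r.unique),
        )
        for r in df.itertuples()
    ]


def write_sam(
    fragments: list[FragmentAlignment],
    reads: list[SmurfRead],
    genome: ReferenceGenome,
    path: str | Path,
    scoring: ScoringScheme = ScoringScheme(),
) -> None:
    """Minimal SAM: one line per fragment, supplementary beyond the first.

    The CIGAR is recomputed by aligning the fragment's read substring to its
    reference interval; bases outside the fragment are soft-clipped.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [
                {"SN": c, "LN": len(s)}
                for c, s in zip(genome.chrom_names, genome.sequences)
            ],
        }
    )
    seq_by_id = {r.read_id: r.sequence for r in reads}
    by_read: dict[str, list[FragmentAlignment]] = {}
    for f in fragments:
        by_read.setdefault(f.read_id, []).append(f)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read_id, frags in by_read.items():
            seq = seq_by_id[read_id]
            L = len(seq)
            for i, f in enumerate(sorted(frags, key=lambda x: x.read_start)):
                sub = seq[f.read_start : f.read_end]
                if f.strand == "-":
                    sub = reverse_complement(sub)
                ref = genome[f.chrom][f.ref_start : f.ref_end]
                _, qs, qe, _, _, ops = sw_align_path(sub, ref, scoring)
                # the whole read is stored (strand-adjusted); the fragment's
                # aligned stretch is bracketed by soft clips
                stored = seq if f.strand == "+" else reverse_complement(seq)
                frag_off = f.read_start if f.strand == "+" else L - f.read_end
                lead = frag_off + qs
                cigar = _ops_to_cigar(ops, L, lead)
                a = pysam.AlignedSegment(header)
                a.query_name = read_id
                a.flag = (16 if f.strand == "-" else 0) | (2048 if i > 0 else 0)
                a.reference_id = genome.chrom_names.index(f.chrom)
                a.reference_start = f.ref_start
                a.mapping_quality = 60 if f.is_unique else 0
                a.cigarstring = cigar
                a.query_sequence = stored
                a.set_tag("AS", f.score)
                out.write(a)


def _ops_to_cigar(ops: list[str], qlen: int, lead: int) -> str:
    """Collapse an op path into CIGAR with soft clips around the aligned
    query stretch (``lead`` clipped bases before it)."""
    qcov = sum(1 for o in ops if o in "MXI")
    runs: list[tuple[str, int]] = []

    def push(op: str, n: int = 1) -> None:
        if n <= 0:
            return
        if runs and runs[-1][0] == op:
            runs[-1] = (op, runs[-1][1] + n)
        else:
            runs.append((op, n))

    push("S", lead)
    for o in ops:
        push({"M": "M", "X": "M", "I": "I", "D": "D"}[o])
    push("S", qlen - qcov - lead)
    return "".join(f"{n}{op}" for op, n in runs) or f"{qlen}S"


def read_fragments_sam(path: str | Path) -> list[FragmentAlignment]:
    """Fragment alignments from any SAM/BAM with split/supplementary lines.

    Read coordinates are reconstructed from soft/hard clips; uniqueness is
    taken as MAPQ > 0 (the usual convention for externally produced
    alignments).
    """
    out: list[FragmentAlignment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            qlen = rec.infer_read_length() or 0
            clip_start = 0
            cig = rec.cigartuples or []
            if cig and cig[0][0] in (4, 5):
                clip_start = cig[0][1]
            aligned = sum(n for op, n in cig if op in (0, 1, 7, 8))
            if rec.is_reverse:
                read_start = qlen - clip_start - aligned
            else:
                read_start = clip_start
            out.append(
                FragmentAlignment(
                    read_id=rec.query_name,
                    read_start=read_start,
                    read_end=read_start + aligned,
                    chrom=rec.reference_name,
                    ref_start=rec.reference_start,
                    ref_end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    score=int(rec.get_tag("AS")) if rec.has_tag("AS") else 0,
                    is_unique=rec.mapping_quality > 0,
                )
            )
    return out
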