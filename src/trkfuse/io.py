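"""File formats: SAM alignments, call/annotation reports, MSI profiles.

Alignments travel as genuine SAM text (written and parsed with pysam);
sequences are stored in reference orientation per the SAM convention and
converted back to read orientation on load. Reports are TSVs with 1-based
coordinates; internal coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
import pysam

from ._util import revcomp
from .svcall import AlignmentRecord, FusionCall

__all__ = [
    "write_sam",
    "read_sam",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_msi_profiles_tsv",
    "read_msi_profiles_tsv",
]


def write_sam(records: Iterable[AlignmentRecord], lengths: dict[str, int], path) -> None:
    """Write paired alignment records as SAM with an @SQ header."""
    chroms = sorted(lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": lengths[c]} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    by_id: dict[str, dict[bool, AlignmentRecord]] = {}
    for rec in records:
        by_id.setdefault(rec.read_id, {})[rec.is_first] = rec
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rid in by_id:
            mates = by_id[rid]
            for is_first, rec in sorted(mates.items(), reverse=True):
                mate = mates.get(not is_first)
                seg = pysam.AlignedSegment()
                seg.query_name = rec.read_id
                flag = 0x1 | (0x40 if rec.is_first else 0x80)
                if rec.strand == "-":
                    flag |= 0x10
                if mate is not None and mate.strand == "-":
                    flag |= 0x20
                seg.flag = flag
                seg.reference_id = tid[rec.chrom]
                seg.reference_start = rec.pos
                seg.mapping_quality = 60
                seq = rec.sequence if rec.strand == "+" else revcomp(rec.sequence)
                seg.query_sequence = seq
                seg.cigarstring = f"{len(seq)}M"
                seg.next_reference_id = tid[rec.mate_chrom]
                seg.next_reference_start = rec.mate_pos
                out.write(seg)


def read_sam(path) -> list[AlignmentRecord]:
    """Load paired records from SAM; sequences returned in read orientation."""
    records = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for seg in fh:
            if seg.is_unmapped or seg.mate_is_unmapped:
                continue
            seq = seg.query_sequence
            strand = "-" if seg.is_reverse else "+"
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    chrom=seg.reference_name,
                    pos=seg.reference_start,
                    strand=strand,
                    sequence=seq if strand == "+" else revcomp(seq),
                    mate_chrom=fh.get_reference_name(seg.next_reference_id),
                    mate_pos=seg.next_reference_start,
                    is_first=seg.is_read1,
                )
            )
    return records


_CALL_COLUMNS = [
    "chrom_a", "pos_a", "strand_a", "chrom_b", "pos_b", "strand_b",
    "unique_pairs", "confirmed", "contig",
]


def write_calls_tsv(calls: Sequence[FusionCall], path) -> None:
    """Emit calls as TSV with 1-based inclusive breakpoint positions."""
    rows = [
        {
            "chrom_a": c.chrom_a,
            "pos_a": c.pos_a + 1,
            "strand_a": c.strand_a,
            "chrom_b": c.chrom_b,
            "pos_b": c.pos_b + 1,
            "strand_b": c.strand_b,
            "unique_pairs": c.n_unique_support,
            "confirmed": int(c.confirmed),
            "contig": c.contig,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=_CALL_COLUMNS).to_csv(str(path), sep="\t", index=False)


def read_calls_tsv(path) -> list[FusionCall]:
    df = pd.read_csv(str(path), sep="\t")
    return [
        FusionCall(
            chrom_a=r.chrom_a,
            pos_a=int(r.pos_a) - 1,
            strand_a=r.strand_a,
            chrom_b=r.chrom_b,
            pos_b=int(r.pos_b) - 1,
            strand_b=r.strand_b,
            contig=r.contig,
            n_unique_support=int(r.unique_pairs),
            confirmed=bool(r.confirmed),
        )
        for r in df.itertuples()
    ]


def write_msi_profiles_tsv(profiles: dict[str, dict[int, int]], sample: str, path) -> None:
    """Allele-length profiles as TSV: locus_id, sample, allele_length, reads."""
    rows = [
        {"locus_id": locus, "sample": sample, "allele_length": length, "read_count": count}
        for locus, alleles in profiles.items()
        for length, count in sorted(alleles.items())
    ]
    pd.DataFrame(rows).to_csv(str(path), sep="\t", index=False)


def read_msi_profiles_tsv(path) -> dict[str, dict[str, dict[int, int]]]:
    """Returns {sample: {locus_id: {allele_length: read_count}}}."""
    df = pd.read_csv(str(path), sep="\t")
    out: dict[str, dict[str, dict[int, int]]] = {}
    for r in df.itertuples():
        out.setdefault(r.sample, {}).setdefault(r.locus_id, {})[int(r.allele_length)] = int(
            r.read_count
        )
    return out
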