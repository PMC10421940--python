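"""Synthetic inputs with known ground truth.

Everything the fusion pipeline consumes can be generated here: a toy
multi-chromosome reference, paired-end reads with planted rearrangement
breakpoints, tumor/normal microsatellite allele-length profiles with a
stated planted instability rate, and patient cohorts with configurable
fusion and MSI-H rates. All generators are deterministic for a fixed seed.

The read model is deliberately simple: fragments of fixed length span the
planted junction, and each read is anchored (recorded chromosome/position)
to the side of the fragment end it starts from — the soft-clipped-alignment
abstraction, without modeling CIGAR clips, base qualities, or sequencing
error. Background fragments follow a truncated normal insert distribution
and never satisfy the discordance predicate under the default insert model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._util import revcomp
from .cohort import CohortTable, load_table1
from .svcall import AlignmentRecord

__all__ = [
    "ToyReference",
    "PlantedFusion",
    "MicrosatelliteLocus",
    "MicrosatellitePanel",
    "MsiSimulation",
    "make_reference",
    "junction_sequence",
    "simulate_fusion_reads",
    "simulate_msi_profiles",
    "simulate_cohort",
    "make_panel",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ToyReference:
    """A small in-memory reference: chromosome name -> ACGT string."""

    sequences: dict[str, str]

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def write_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [SeqRecord(Seq(s), id=c, description="") for c, s in self.sequences.items()]
        seqio_write(records, str(path), "fasta")

    @classmethod
    def read_fasta(cls, path) -> "ToyReference":
        from Bio.SeqIO import parse

        return cls({rec.id: str(rec.seq).upper() for rec in parse(str(path), "fasta")})


@dataclass(frozen=True)
class PlantedFusion:
    """Ground truth for one planted rearrangement.

    Breakpoints are 0-based half-open: ``pos`` is the position one past the
    last retained base reading toward the junction on the '+' convention
    (for strand '-', the retained segment lies genomically right of ``pos``).
    """

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    strand_a: str = "+"
    strand_b: str = "+"
    n_support_pairs: int = 8
    read_length: int = 100
    median_insert: int = 300
    insert_sd: float = 30.0

    def __post_init__(self):
        if self.n_support_pairs < 0:
            raise ValueError("n_support_pairs must be >= 0")
        for s in (self.strand_a, self.strand_b):
            if s not in "+-":
                raise ValueError(f"invalid strand {s!r}")


def make_reference(
    n_chrom: int, length_bp: int, seed: int, names: tuple[str, ...] | None = None
) -> ToyReference:
    """Random ACGT reference with ``n_chrom`` chromosomes of equal length.

    At least two chromosomes are required so interchromosomal events can be
    planted. Base composition is uniform, so GC content is ~0.5. Chromosome
    names default to chr1..chrN; pass ``names`` to match a gene-model set.
    """
    if n_chrom < 2:
        raise ValueError("need >= 2 chromosomes to plant interchromosomal events")
    if length_bp < 10_000:
        raise ValueError("chromosome length must be >= 10 kb")
    if names is not None and len(names) != n_chrom:
        raise ValueError("names must match n_chrom")
    rng = np.random.default_rng(seed)
    seqs = {}
    for i in range(n_chrom):
        name = names[i] if names is not None else f"chr{i + 1}"
        arr = _ALPHABET[rng.integers(0, 4, size=length_bp)]
        seqs[name] = arr.tobytes().decode("ascii")
    return ToyReference(seqs)


def _five_prime_segment(ref: ToyReference, event: PlantedFusion, length: int) -> str:
    if event.strand_a == "+":
        return ref[event.chrom_a][event.pos_a - length : event.pos_a]
    return revcomp(ref[event.chrom_a][event.pos_a : event.pos_a + length])


def _three_prime_segment(ref: ToyReference, event: PlantedFusion, length: int) -> str:
    if event.strand_b == "+":
        return ref[event.chrom_b][event.pos_b : event.pos_b + length]
    return revcomp(ref[event.chrom_b][event.pos_b - length : event.pos_b])


def junction_sequence(ref: ToyReference, event: PlantedFusion, flank: int) -> str:
    """The true junction-spanning sequence, ``flank`` bases on each side."""
    return _five_prime_segment(ref, event, flank) + _three_prime_segment(ref, event, flank)


def simulate_fusion_reads(
    ref: ToyReference,
    event: PlantedFusion,
    background_pairs: int,
    seed: int,
    *,
    margin: int = 30,
    stagger: int = 10,
) -> list[AlignmentRecord]:
    """Paired-end reads: planted junction-spanning pairs plus concordant noise.

    Exactly ``event.n_support_pairs`` fragments of length ``median_insert``
    span the junction at unique, 10 bp-staggered offsets, so the pooled
    cluster reads tile across the junction (assembly can bridge it) while
    each recorded pair maps one end near the A-side breakpoint and the other
    near the B-side breakpoint. Background pairs are concordant with insert
    ~ Normal(median_insert, insert_sd) truncated to > 2*read_length.
    """
    rl = event.read_length
    frag = event.median_insert
    if frag < 2 * margin:
        raise ValueError("median_insert too small for junction staggering")
    capacity = (frag - 2 * margin) // stagger + 1
    if event.n_support_pairs > capacity:
        raise ValueError(
            f"cannot place {event.n_support_pairs} unique supporting pairs: "
            f"only {capacity} staggered starts fit within one fragment length"
        )
    _check_event_bounds(ref, event, frag)

    rng = np.random.default_rng(seed)
    records: list[AlignmentRecord] = []

    for i in range(event.n_support_pairs):
        left_len = margin + i * stagger
        right_len = frag - left_len
        fragment = _five_prime_segment(ref, event, left_len) + _three_prime_segment(
            ref, event, right_len
        )
        read1 = fragment[:rl]
        read2 = revcomp(fragment[-rl:])
        # anchor coordinates: read1 at the fragment's left end (A side),
        # read2 at the fragment's right end (B side)
        if event.strand_a == "+":
            pos1, strand1 = event.pos_a - left_len, "+"
        else:
            pos1, strand1 = event.pos_a, "-"
        if event.strand_b == "+":
            pos2, strand2 = event.pos_b + max(0, right_len - rl), "-"
        else:
            pos2, strand2 = event.pos_b - right_len, "+"
        rid = f"sup{i:05d}"
        records.append(
            AlignmentRecord(rid, event.chrom_a, pos1, strand1, read1, event.chrom_b, pos2, True)
        )
        records.append(
            AlignmentRecord(rid, event.chrom_b, pos2, strand2, read2, event.chrom_a, pos1, False)
        )

    chroms = sorted(ref.sequences)
    lengths = ref.lengths
    for j in range(background_pairs):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        insert = 0
        while insert <= 2 * rl:
            insert = int(round(rng.normal(event.median_insert, event.insert_sd)))
        start = int(rng.integers(0, lengths[chrom] - insert))
        seq = ref[chrom]
        pos2 = start + insert - rl
        rid = f"bg{j:06d}"
        records.append(
            AlignmentRecord(rid, chrom, start, "+", seq[start : start + rl], chrom, pos2, True)
        )
        records.append(
            AlignmentRecord(rid, chrom, pos2, "-", revcomp(seq[pos2 : pos2 + rl]), chrom, start, False)
        )
    return records


def _check_event_bounds(ref: ToyReference, event: PlantedFusion, frag: int) -> None:
    for chrom, pos in ((event.chrom_a, event.pos_a), (event.chrom_b, event.pos_b)):
        if chrom not in ref:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not frag <= pos <= len(ref[chrom]) - frag:
            raise ValueError(f"breakpoint {chrom}:{pos} too close to a contig edge")


# ---------------------------------------------------------------------------
# microsatellites
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MicrosatelliteLocus:
    locus_id: str
    chrom: str
    pos: int
    repeat_unit: str
    ref_repeats: int


@dataclass(frozen=True)
class MicrosatellitePanel:
    """The capture panel's microsatellite marker set (default 572 loci)."""

    loci: tuple[MicrosatelliteLocus, ...]

    def __post_init__(self):
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("locus ids must be unique")

    @property
    def size(self) -> int:
        return len(self.loci)


def make_panel(size: int = 572, seed: int = 0) -> MicrosatellitePanel:
    """A synthetic marker panel of mono/di-nucleotide repeat loci."""
    rng = np.random.default_rng(seed)
    units = ["A", "T", "AC", "AG", "AT", "CT"]
    loci = tuple(
        MicrosatelliteLocus(
            locus_id=f"MS{i:04d}",
            chrom=f"chr{1 + i % 2}",
            pos=1000 + 80 * i,
            repeat_unit=units[int(rng.integers(0, len(units)))],
            ref_repeats=int(rng.integers(10, 26)),
        )
        for i in range(size)
    )
    return MicrosatellitePanel(loci)


@dataclass(frozen=True)
class MsiSimulation:
    """Tumor/normal allele-length profiles plus the planted truth."""

    tumor: dict[str, dict[int, int]]
    normal: dict[str, dict[int, int]]
    planted_unstable: frozenset[str] = field(default_factory=frozenset)


def simulate_msi_profiles(
    panel: MicrosatellitePanel,
    unstable_fraction: float,
    depth: int = 100,
    seed: int = 0,
) -> MsiSimulation:
    """Plant a novel tumor allele at round(unstable_fraction * panel size) loci.

    Unstable loci receive a tumor allele length absent from the matched
    normal, carried by depth//4 (>= 3) reads; all remaining loci have
    identical tumor and normal length distributions.
    """
    if not 0.0 <= unstable_fraction <= 1.0:
        raise ValueError("unstable_fraction must be in [0, 1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    n_unstable = int(math.floor(unstable_fraction * panel.size + 0.5))
    unstable_idx = set(
        rng.choice(panel.size, size=n_unstable, replace=False).tolist() if n_unstable else []
    )
    novel_reads = max(3, depth // 4)
    tumor: dict[str, dict[int, int]] = {}
    normal: dict[str, dict[int, int]] = {}
    planted = []
    for i, locus in enumerate(panel.loci):
        base = {locus.ref_repeats: depth}
        normal[locus.locus_id] = dict(base)
        if i in unstable_idx:
            shift = int(rng.integers(1, 4)) * (1 if rng.random() < 0.5 else -1)
            tumor[locus.locus_id] = {
                locus.ref_repeats: depth - novel_reads,
                locus.ref_repeats + shift: novel_reads,
            }
            planted.append(locus.locus_id)
        else:
            tumor[locus.locus_id] = dict(base)
    return MsiSimulation(tumor, normal, frozenset(planted))


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def simulate_cohort(
    n_patients: int,
    fusion_rate: float,
    msih_rate_given_fusion: float,
    msih_rate_given_no_fusion: float,
    seed: int = 0,
) -> CohortTable:
    """Draw a cohort with the published tumor-type frequency structure.

    Fusion status is Bernoulli(fusion_rate) per patient; MSI status is drawn
    conditionally on fusion status. Tumor types follow the transcribed
    overall cohort frequency vector.
    """
    for r in (fusion_rate, msih_rate_given_fusion, msih_rate_given_no_fusion):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    t1 = load_table1()
    types = t1[t1.variable == "tumor_type"]
    labels = types.level.to_numpy()
    probs = types.overall.to_numpy(dtype=float)
    probs = probs / probs.sum()

    import pandas as pd

    fusion = rng.random(n_patients) < fusion_rate
    p_msih = np.where(fusion, msih_rate_given_fusion, msih_rate_given_no_fusion)
    msih = rng.random(n_patients) < p_msih
    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n_patients)],
            "tumor_type": rng.choice(labels, size=n_patients, p=probs),
            "fusion_positive": fusion,
            "msi_status": np.where(msih, "MSI-H", "MSS"),
        }
    )
    return CohortTable(patients=patients)
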