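"""Panel-level variant metrics: tumor mutational burden and MSI status.

TMB is the count of coding somatic SNVs and indels per megabase of the
panel's coding territory. The MSI call compares tumor and matched-normal
allele-length profiles at the panel's microsatellite markers: a locus is
unstable when the tumor carries an adequately supported allele length
absent from the normal, and the sample is MSI-high when strictly more
than 15% of evaluable loci are unstable.

The panel's genomic footprint is an input parameter, not a constant; the
per-locus instability rule (novel allele with >= 3 reads at >= 10x locus
depth) is this module's operationalization of "unstable versus matched
normal" and every threshold is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._util import round_half_up

__all__ = [
    "SomaticVariant",
    "MSIResult",
    "MSI_THRESHOLD",
    "compute_tmb",
    "score_locus_instability",
    "call_msi",
    "read_variants_vcf",
]

MSI_THRESHOLD = 0.15
VARIANT_CLASSES = frozenset({"SNV", "insertion", "deletion"})


@dataclass(frozen=True)
class SomaticVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str  # SNV | insertion | deletion
    coding: bool

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")


@dataclass(frozen=True)
class MSIResult:
    n_loci_evaluated: int
    n_unstable: int
    status: str  # MSI-H | MSS | Unknown

    def __post_init__(self):
        if not 0 <= self.n_unstable <= max(self.n_loci_evaluated, 0):
            raise ValueError("unstable count out of range")

    @property
    def unstable_fraction(self) -> float:
        if self.n_loci_evaluated == 0:
            return float("nan")
        return self.n_unstable / self.n_loci_evaluated


def compute_tmb(variants: Iterable[SomaticVariant], panel_coding_mb: float) -> float:
    """Coding SNVs and indels per megabase, reported to one decimal."""
    if panel_coding_mb <= 0:
        raise ValueError("panel size must be positive")
    n = sum(1 for v in variants if v.coding and v.variant_class in VARIANT_CLASSES)
    return round_half_up(n / panel_coding_mb, 1)


def score_locus_instability(
    tumor: Mapping[int, int],
    normal: Mapping[int, int],
    min_allele_reads: int = 3,
    min_locus_depth: int = 10,
) -> str:
    """'stable' | 'unstable' | 'uncovered' for one microsatellite locus.

    Profiles map allele length -> read count. The locus is uncovered when
    either sample is below ``min_locus_depth``; unstable when the tumor has
    an allele length with >= ``min_allele_reads`` reads that is absent from
    the normal.
    """
    for profile in (tumor, normal):
        if any(c < 0 for c in profile.values()):
            raise ValueError("negative read counts")
    if sum(tumor.values()) < min_locus_depth or sum(normal.values()) < min_locus_depth:
        return "uncovered"
    normal_lengths = {length for length, count in normal.items() if count > 0}
    for length, count in tumor.items():
        if count >= min_allele_reads and length not in normal_lengths:
            return "unstable"
    return "stable"


def call_msi(
    locus_statuses: Sequence[str],
    min_evaluated: int = 20,
    threshold: float = MSI_THRESHOLD,
) -> MSIResult:
    """Panel-level MSI status from per-locus instability calls.

    Uncovered loci are excluded from the denominator; the sample is MSI-H
    iff the unstable fraction strictly exceeds ``threshold``, Unknown when
    fewer than ``min_evaluated`` loci are evaluable, MSS otherwise.
    """
    evaluated = sum(1 for s in locus_statuses if s in ("stable", "unstable"))
    unstable = sum(1 for s in locus_statuses if s == "unstable")
    if evaluated < min_evaluated:
        return MSIResult(evaluated, unstable, "Unknown")
    status = "MSI-H" if unstable / evaluated > threshold else "MSS"
    return MSIResult(evaluated, unstable, status)


def read_variants_vcf(path) -> list[SomaticVariant]:
    """Read a minimal somatic VCF (INFO tags CLASS and CODING)."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            vclass = info.get("CLASS", "SNV")
            coding = bool(int(info.get("CODING", 0)))
            out.append(
                SomaticVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else ".",
                    variant_class=vclass,
                    coding=coding,
                )
            )
    return out
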