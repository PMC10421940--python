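"""Discordant-read-pair rearrangement caller.

The detection contract, with its published constants as defaults:

1. paired-end reads whose mates map to different chromosomes, or whose
   outer insert size strictly exceeds 2000 bp, are collected as discordant;
2. discordant pairs within 500 bp of each other on *both* sides of the
   candidate junction form single-linkage clusters;
3. each cluster's reads are assembled into a contig by greedy exact
   suffix-prefix overlap merging (a bundled stand-in for an external
   assembler);
4. breakpoints are confirmed by split realignment of the two contig flanks
   against the reference, strand-aware, allowing a small mismatch budget
   (a bundled stand-in for an external realigner);
5. calls with fewer than five unique supporting pairs — distinct
   (A-start, B-start) coordinate tuples after deduplication — are dropped.

Coordinates are 0-based half-open internally; report writers emit 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from ._util import revcomp

__all__ = [
    "AlignmentRecord",
    "DiscordantPair",
    "BreakpointCluster",
    "FusionCall",
    "AssemblyError",
    "collect_discordant",
    "cluster_discordant",
    "assemble_contig",
    "confirm_breakpoint",
    "filter_support",
    "call_pipeline",
]

logger = logging.getLogger(__name__)

DEFAULT_INSERT_THRESHOLD = 2000
DEFAULT_CLUSTER_DISTANCE = 500
DEFAULT_MIN_SUPPORT = 5
DEFAULT_MIN_OVERLAP = 20
DEFAULT_MAX_MISMATCH = 2
DEFAULT_MIN_FLANK = 25


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read end with mate information."""

    read_id: str
    chrom: str
    pos: int  # 0-based leftmost
    strand: str
    sequence: str
    mate_chrom: str
    mate_pos: int
    is_first: bool

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if not self.sequence:
            raise ValueError("sequence must be non-empty")

    @property
    def end(self) -> int:
        return self.pos + len(self.sequence)


@dataclass(frozen=True)
class DiscordantPair:
    """A discordant mate pair, canonically ordered so side A <= side B."""

    a: AlignmentRecord
    b: AlignmentRecord
    reason: str  # "interchromosomal" | "long-insert"
    insert_size: Optional[int]  # outer span; defined for same-chromosome pairs

    def __post_init__(self):
        inter = self.a.chrom != self.b.chrom
        if inter != (self.reason == "interchromosomal"):
            raise ValueError("discordance reason inconsistent with chromosomes")

    @property
    def key(self) -> tuple:
        """Orientation/chromosome signature used for cluster compatibility."""
        return (self.a.chrom, self.b.chrom, self.a.strand, self.b.strand)

    @property
    def start_tuple(self) -> tuple[int, int]:
        return (self.a.pos, self.b.pos)


@dataclass(frozen=True)
class BreakpointCluster:
    pairs: tuple[DiscordantPair, ...]
    chrom_a: str
    a_min: int
    a_max: int
    chrom_b: str
    b_min: int
    b_max: int
    unique_pair_count: int

    def __post_init__(self):
        if self.unique_pair_count > len(self.pairs):
            raise ValueError("unique pair count exceeds member count")


@dataclass(frozen=True)
class FusionCall:
    """A confirmed breakpoint pair with its assembled contig.

    ``strand_a == '+'`` means the retained A segment lies genomically left
    of ``pos_a`` and reads toward the junction on the forward strand;
    ``strand_b == '+'`` means the retained B segment lies right of
    ``pos_b``. Calls are canonicalized so (chrom_a, pos_a) <= (chrom_b,
    pos_b); side swapping flips both strands.
    """

    chrom_a: str
    pos_a: int
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    contig: str
    n_unique_support: int
    confirmed: bool

    def canonical(self) -> "FusionCall":
        if (self.chrom_b, self.pos_b) < (self.chrom_a, self.pos_a):
            flip = {"+": "-", "-": "+"}
            return FusionCall(
                self.chrom_b,
                self.pos_b,
                flip[self.strand_b],
                self.chrom_a,
                self.pos_a,
                flip[self.strand_a],
                revcomp(self.contig),
                self.n_unique_support,
                self.confirmed,
            )
        return self


class AssemblyError(RuntimeError):
    """No overlap of the required length anywhere in the cluster's reads."""


# ---------------------------------------------------------------------------
# 1. discordant pair collection
# ---------------------------------------------------------------------------


def collect_discordant(
    records: Iterable[AlignmentRecord],
    insert_threshold: int = DEFAULT_INSERT_THRESHOLD,
) -> list[DiscordantPair]:
    """Pair records by read id and keep inter-chromosomal or long-insert pairs.

    The outer insert is the span from the leftmost start to the rightmost end
    of the mate pair (SAM TLEN convention); a pair is long-insert discordant
    iff that span strictly exceeds ``insert_threshold``.
    """
    by_id: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        by_id.setdefault(rec.read_id, []).append(rec)

    out: list[DiscordantPair] = []
    for rid, recs in by_id.items():
        if len(recs) != 2:
            logger.warning("read id %s has %d records, expected 2; skipping", rid, len(recs))
            continue
        x, y = recs
        if x.mate_chrom is None or y.mate_chrom is None:
            logger.warning("read id %s missing mate coordinates; skipping", rid)
            continue
        a, b = sorted(recs, key=lambda r: (r.chrom, r.pos))
        if a.chrom != b.chrom:
            out.append(DiscordantPair(a, b, "interchromosomal", None))
        else:
            insert = max(a.end, b.end) - min(a.pos, b.pos)
            if insert > insert_threshold:
                out.append(DiscordantPair(a, b, "long-insert", insert))
    return out


# ---------------------------------------------------------------------------
# 2. clustering
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_discordant(
    pairs: Sequence[DiscordantPair],
    cluster_distance: int = DEFAULT_CLUSTER_DISTANCE,
) -> list[BreakpointCluster]:
    """Single-linkage clustering of compatible pairs on both junction sides.

    Two pairs are linked when they share (chromA, chromB, strand
    orientation) and both their A-side and B-side start positions differ by
    strictly less than ``cluster_distance``; clusters are the connected
    components of that link graph, so the result is independent of input
    order. Output is sorted by (chromA, min A position).
    """
    groups: dict[tuple, list[DiscordantPair]] = {}
    for p in pairs:
        groups.setdefault(p.key, []).append(p)

    clusters: list[BreakpointCluster] = []
    for members in groups.values():
        members = sorted(members, key=lambda p: p.start_tuple)
        uf = _UnionFind(len(members))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if members[j].a.pos - members[i].a.pos >= cluster_distance:
                    break  # sorted by A-side position
                if abs(members[i].b.pos - members[j].b.pos) < cluster_distance:
                    uf.union(i, j)
        comp: dict[int, list[DiscordantPair]] = {}
        for i, p in enumerate(members):
            comp.setdefault(uf.find(i), []).append(p)
        for group in comp.values():
            a_pos = [p.a.pos for p in group]
            b_pos = [p.b.pos for p in group]
            clusters.append(
                BreakpointCluster(
                    pairs=tuple(group),
                    chrom_a=group[0].a.chrom,
                    a_min=min(a_pos),
                    a_max=max(a_pos),
                    chrom_b=group[0].b.chrom,
                    b_min=min(b_pos),
                    b_max=max(b_pos),
                    unique_pair_count=len({p.start_tuple for p in group}),
                )
            )
    clusters.sort(key=lambda c: (c.chrom_a, c.a_min, c.chrom_b, c.b_min))
    return clusters


# ---------------------------------------------------------------------------
# 3. assembly
# ---------------------------------------------------------------------------


def _overlap_len(left: str, right: str, min_overlap: int) -> int:
    """Longest exact suffix(left)-prefix(right) overlap >= min_overlap."""
    best = 0
    max_k = min(len(left), len(right))
    for k in range(max_k, min_overlap - 1, -1):
        if left[-k:] == right[:k]:
            best = k
            break
    return best


def assemble_contigs(
    cluster_or_reads,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[str]:
    """Greedy overlap assembly of a cluster's read sequences.

    Repeatedly merges the pair of fragments (either orientation) with the
    longest exact suffix-prefix overlap of at least ``min_overlap`` bases,
    absorbing contained fragments, until nothing merges. Returns every
    resulting contig, longest first (a cluster's mate reads can tile two
    disjoint reference intervals, so more than one contig is normal).
    Raises :class:`AssemblyError` when nothing merges at all.
    """
    if isinstance(cluster_or_reads, BreakpointCluster):
        seqs = [r.sequence for p in cluster_or_reads.pairs for r in (p.a, p.b)]
    else:
        seqs = list(cluster_or_reads)
    if len(seqs) < 2:
        raise ValueError("assembly needs at least 2 reads")

    # collapse duplicates, keep deterministic order
    contigs: list[str] = sorted(set(seqs), key=lambda s: (len(s), s), reverse=True)
    merged_any = len(contigs) < len(seqs)  # identical reads count as a merge

    while len(contigs) > 1:
        best = None  # (overlap, i, j, oriented_j)
        for i in range(len(contigs)):
            for j in range(len(contigs)):
                if i == j:
                    continue
                for cand in (contigs[j], revcomp(contigs[j])):
                    if cand in contigs[i]:
                        k = len(cand)  # containment
                    else:
                        k = _overlap_len(contigs[i], cand, min_overlap)
                    if k and (best is None or k > best[0]):
                        best = (k, i, j, cand)
        if best is None:
            break
        k, i, j, cand = best
        merged = contigs[i] if cand in contigs[i] else contigs[i] + cand[k:]
        keep = [c for idx, c in enumerate(contigs) if idx not in (i, j)]
        contigs = sorted(keep + [merged], key=lambda s: (len(s), s), reverse=True)
        merged_any = True

    if not merged_any:
        raise AssemblyError(f"no overlap >= {min_overlap} bp among {len(seqs)} reads")
    return contigs


def assemble_contig(cluster_or_reads, min_overlap: int = DEFAULT_MIN_OVERLAP) -> str:
    """Longest contig from :func:`assemble_contigs`."""
    return assemble_contigs(cluster_or_reads, min_overlap)[0]


# ---------------------------------------------------------------------------
# 4. breakpoint confirmation by split realignment
# ---------------------------------------------------------------------------


_MISMATCH_PENALTY = 4  # alignment-endpoint scoring: match +1, mismatch -4


def _extend(query: str, win: str, start: int, seed_len: int, max_mismatch: int) -> int:
    """Extend a seeded match rightward; return the score-maximal end length.

    The endpoint maximizes (matches - 4*mismatches) within the mismatch
    budget, so a run of chance matches past the true alignment edge cannot
    drag the edge outward.
    """
    k_best, score_best = seed_len, seed_len
    score, mism = seed_len, 0
    k = seed_len
    limit = min(len(query), len(win) - start)
    while k < limit:
        if query[k] == win[start + k]:
            score += 1
        else:
            mism += 1
            if mism > max_mismatch:
                break
            score -= _MISMATCH_PENALTY
        k += 1
        if score > score_best:
            k_best, score_best = k, score
    return k_best


def _best_prefix_match(
    query: str, window: str, max_mismatch: int, seed_len: int
) -> tuple[int, int, str]:
    """Longest (score-maximal) prefix of ``query`` aligning inside ``window``.

    Returns (length, window_start, strand): '+' means query[:k] matches
    window[start:start+k] with <= max_mismatch mismatches; '-' means it
    matches the reverse complement of window[start:start+k]. Anchoring
    requires the first ``seed_len`` bases of the prefix to match exactly.
    """
    best = (0, -1, "+")
    seed = query[:seed_len]
    for strand, win in (("+", window), ("-", revcomp(window))):
        start = win.find(seed)
        while start != -1:
            k = _extend(query, win, start, seed_len, max_mismatch)
            if k > best[0]:
                if strand == "+":
                    best = (k, start, "+")
                else:
                    # map back onto forward window coordinates
                    best = (k, len(window) - start - k, "-")
            start = win.find(seed, start + 1)
    return best


def confirm_breakpoint(
    contig: str,
    ref,
    locus_a: tuple[str, int, int],
    locus_b: tuple[str, int, int],
    n_unique_support: int = 0,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_flank: int = DEFAULT_MIN_FLANK,
    pad: int = 1000,
) -> Optional[FusionCall]:
    """Split-realign the two contig flanks against the reference.

    The contig is confirmed when >= ``min_flank`` bases left of a junction
    offset align near locus A and the bases right of it align near locus B
    (strand-aware, reverse complement considered, <= ``max_mismatch``
    mismatches per flank) and the two flank alignments jointly cover the
    contig. The reported positions are the alignment edges at the junction.
    Returns None when either flank is unalignable.
    """
    if len(contig) <= 2 * min_flank:
        return None

    def window(locus):
        chrom, lo, hi = locus
        seq = ref[chrom]
        w_start = max(0, lo - pad)
        return chrom, w_start, seq[w_start : min(len(seq), hi + pad)]

    chrom_a, wa_start, win_a = window(locus_a)
    chrom_b, wb_start, win_b = window(locus_b)

    # the assembler's contig orientation is arbitrary and either contig end
    # may derive from either locus: try prefix<->A then prefix<->B (strand-
    # aware matching inside each window covers reverse-complement contigs)
    oriented = contig
    rc = revcomp(contig)
    for swapped in (False, True):
        wc_a, wc_b = (win_b, win_a) if swapped else (win_a, win_b)
        k, sa, str_a = _best_prefix_match(oriented, wc_a, max_mismatch, min_flank)
        m, sb, str_b_rc = _best_prefix_match(rc, wc_b, max_mismatch, min_flank)
        if k < min_flank or m < min_flank or k + m < len(oriented):
            continue
        # suffix-match strand is flipped relative to the rc-prefix match
        str_b = "-" if str_b_rc == "+" else "+"
        n = len(oriented)
        # The two flank alignments may overlap (junction microhomology or
        # chance agreement); any junction offset in [n-m, k] is equivalent.
        # Take the midpoint so a one-sided overrun biases the reported
        # coordinates by at most half its length.
        j = (k + (n - m) + 1) // 2
        # A-side breakpoint: the prefix alignment edge at the junction
        # ('-' means the contig prefix matched the window reverse strand,
        # so the junction-adjacent base maps near the segment's left end).
        if str_a == "+":
            pos_a, strand_a = sa + j, "+"
        else:
            pos_a, strand_a = sa + (k - j), "-"
        # B-side: the first retained base is contig index j, mapped through
        # the suffix alignment (contig[n-m:] <-> window[sb:sb+m]).
        if str_b == "+":
            pos_b, strand_b = sb + (j - (n - m)), "+"
        else:
            pos_b, strand_b = sb + (n - j), "-"
        off_a = wb_start if swapped else wa_start
        off_b = wa_start if swapped else wb_start
        call = FusionCall(
            chrom_a=chrom_b if swapped else chrom_a,
            pos_a=off_a + pos_a,
            strand_a=strand_a,
            chrom_b=chrom_a if swapped else chrom_b,
            pos_b=off_b + pos_b,
            strand_b=strand_b,
            contig=oriented,
            n_unique_support=n_unique_support,
            confirmed=True,
        )
        return call.canonical()
    logger.info("contig of %d bp failed split realignment", len(contig))
    return None


# ---------------------------------------------------------------------------
# 5. support filter and orchestration
# ---------------------------------------------------------------------------


def filter_support(
    calls: Sequence[FusionCall], min_pairs: int = DEFAULT_MIN_SUPPORT
) -> list[FusionCall]:
    """Retain calls with at least ``min_pairs`` unique supporting pairs."""
    return [c for c in calls if c.n_unique_support >= min_pairs]


def call_pipeline(
    records: Iterable[AlignmentRecord],
    ref,
    insert_threshold: int = DEFAULT_INSERT_THRESHOLD,
    cluster_distance: int = DEFAULT_CLUSTER_DISTANCE,
    min_support: int = DEFAULT_MIN_SUPPORT,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> list[FusionCall]:
    """End-to-end caller: collect, cluster, assemble, confirm, filter.

    Unique support is counted after coordinate deduplication and before
    assembly; clusters failing the support filter are never assembled.
    """
    pairs = collect_discordant(records, insert_threshold)
    clusters = cluster_discordant(pairs, cluster_distance)
    calls: list[FusionCall] = []
    for cluster in clusters:
        if cluster.unique_pair_count < min_support or len(cluster.pairs) < 2:
            continue
        try:
            contigs = assemble_contigs(cluster, min_overlap)
        except AssemblyError:
            logger.info(
                "cluster %s:%d-%d / %s:%d-%d dropped: assembly failed",
                cluster.chrom_a, cluster.a_min, cluster.a_max,
                cluster.chrom_b, cluster.b_min, cluster.b_max,
            )
            continue
        for contig in contigs:
            call = confirm_breakpoint(
                contig,
                ref,
                (cluster.chrom_a, cluster.a_min, cluster.a_max),
                (cluster.chrom_b, cluster.b_min, cluster.b_max),
                n_unique_support=cluster.unique_pair_count,
                max_mismatch=max_mismatch,
                min_flank=min_flank,
            )
            if call is not None:
                calls.append(call)
                break  # first confirming contig wins; the rest tile one side
    calls = filter_support(calls, min_support)
    calls.sort(key=lambda c: (c.chrom_a, c.pos_a, c.chrom_b, c.pos_b))
    return calls
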