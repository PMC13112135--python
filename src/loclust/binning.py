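"""Seeding of genomic bins and transcript-to-bin assignment.

A bin is an interval on one sequence of one genome collecting the ids of all
transcripts with an exon alignment overlapping it.  Bins can be seeded de
novo from the alignments themselves, or pre-seeded from reference exon
annotations (with alignments then assigned to the frozen annotation bins).

Bins are strandless by default: a single bin space per sequence, so
opposite-strand overlapping genes share bins.  ``stranded=True`` keeps a
separate bin space per strand.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import ExonPlacement, LoclustError

DENOVO = "denovo"
PRESEEDED = "preseeded"


@dataclass
class Bin:
    bin_id: int
    genome_id: str
    seq_id: str
    start: int  # 1-based inclusive
    end: int
    members: set[str] = field(default_factory=set)
    origin: str = DENOVO

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"bin {self.bin_id}: start > end")
        if self.origin not in (DENOVO, PRESEEDED):
            raise ValueError(f"invalid bin origin {self.origin!r}")


@dataclass
class BinIndex:
    """All bins across genomes plus the inverse transcript -> bins lookup."""

    bins: dict[int, Bin]
    by_transcript: dict[str, frozenset[int]]

    def bins_of(self, transcript_id: str) -> frozenset[int]:
        return self.by_transcript.get(transcript_id, frozenset())

    def transcript_ids(self) -> frozenset[str]:
        return frozenset(self.by_transcript)

    @property
    def n_bins(self) -> int:
        return len(self.bins)


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap length in bp for 1-based inclusive intervals (<= 0: none)."""
    return min(a_end, b_end) - max(a_start, b_start) + 1


def select_paths(
    placements: Iterable[ExonPlacement], multipath: bool = False
) -> list[ExonPlacement]:
    """Keep only the best path per (transcript, genome) unless ``multipath``."""
    if multipath:
        return list(placements)
    return [p for p in placements if p.path_rank == 1]


def _space_key(placement: ExonPlacement, stranded: bool):
    if stranded:
        return (placement.genome_id, placement.seq_id, placement.strand)
    return (placement.genome_id, placement.seq_id)


def _sweep_merge(
    blocks: Sequence[tuple[int, int, str]], min_overlap: int
) -> list[tuple[int, int, set[str]]]:
    """Merge (start, end, transcript_id) blocks into maximal intervals.

    A block joins the current growing interval when it overlaps the
    interval's extent by >= min_overlap bp.  With min_overlap = 1 this is the
    plain interval-union closure and is independent of input order.
    """
    merged: list[tuple[int, int, set[str]]] = []
    for start, end, tid in sorted(blocks, key=lambda b: (b[0], b[1], b[2])):
        if merged and _overlap(merged[-1][0], merged[-1][1], start, end) >= min_overlap:
            prev_start, prev_end, members = merged[-1]
            members.add(tid)
            merged[-1] = (prev_start, max(prev_end, end), members)
        else:
            merged.append((start, end, {tid}))
    return merged


def seed_bins_denovo(
    placements: Iterable[ExonPlacement],
    min_overlap: int = 1,
    stranded: bool = False,
) -> BinIndex:
    """Seed bins directly from alignment exon blocks.

    Every exon block either founds a new bin or joins (and extends) the bins
    it overlaps; bins that come to overlap are merged, so the result is the
    interval-union closure per (genome, sequence) and is deterministic
    regardless of input order.
    """
    if min_overlap < 1:
        raise LoclustError("min_overlap must be >= 1")
    spaces: dict[tuple, list[tuple[int, int, str]]] = {}
    for placement in placements:
        key = _space_key(placement, stranded)
        blocks = spaces.setdefault(key, [])
        for start, end in placement.blocks:
            blocks.append((start, end, placement.transcript_id))

    bins: dict[int, Bin] = {}
    bin_id = 0
    for key in sorted(spaces):
        genome_id, seq_id = key[0], key[1]
        for start, end, members in _sweep_merge(spaces[key], min_overlap):
            bin_id += 1
            bins[bin_id] = Bin(bin_id, genome_id, seq_id, start, end, members, DENOVO)
    return _index(bins)


def seed_bins_preseeded(
    annotation_placements: Iterable[ExonPlacement],
    transcript_placements: Iterable[ExonPlacement],
    min_overlap: int = 1,
    stranded: bool = False,
) -> BinIndex:
    """Seed bins from reference exon annotations, then assign alignments.

    Overlapping annotated exons are merged into frozen bins whose
    coordinates never change.  Each transcript exon block joins every frozen
    bin it overlaps by >= min_overlap bp; blocks overlapping no frozen bin
    found new de novo bins among themselves, so novel loci are not lost.
    Frozen bins with no assigned transcripts are dropped.
    """
    if min_overlap < 1:
        raise LoclustError("min_overlap must be >= 1")

    # 1. frozen annotation bins, memberless until assignment
    frozen_spaces: dict[tuple, list[tuple[int, int, str]]] = {}
    for placement in annotation_placements:
        key = _space_key(placement, stranded)
        blocks = frozen_spaces.setdefault(key, [])
        for start, end in placement.blocks:
            blocks.append((start, end, placement.transcript_id))

    frozen: dict[tuple, list[Bin]] = {}
    bin_id = 0
    for key in sorted(frozen_spaces):
        genome_id, seq_id = key[0], key[1]
        intervals = []
        for start, end, _members in _sweep_merge(frozen_spaces[key], min_overlap):
            bin_id += 1
            intervals.append(Bin(bin_id, genome_id, seq_id, start, end, set(), PRESEEDED))
        frozen[key] = intervals  # sorted by start by construction

    # 2. assign transcript blocks to frozen bins; collect leftovers
    leftovers: dict[tuple, list[tuple[int, int, str]]] = {}
    for placement in transcript_placements:
        key = _space_key(placement, stranded)
        intervals = frozen.get(key, [])
        starts = [b.start for b in intervals]
        for start, end in placement.blocks:
            hit = False
            # candidate frozen bins: those starting at or before `end`
            hi = bisect.bisect_right(starts, end)
            for b in intervals[:hi]:
                if _overlap(b.start, b.end, start, end) >= min_overlap:
                    b.members.add(placement.transcript_id)
                    hit = True
            if not hit:
                leftovers.setdefault(key, []).append(
                    (start, end, placement.transcript_id)
                )

    bins: dict[int, Bin] = {}
    for key in sorted(frozen):
        for b in frozen[key]:
            if b.members:
                bins[b.bin_id] = b

    # 3. leftover blocks seed de novo bins
    for key in sorted(leftovers):
        genome_id, seq_id = key[0], key[1]
        for start, end, members in _sweep_merge(leftovers[key], min_overlap):
            bin_id += 1
            bins[bin_id] = Bin(bin_id, genome_id, seq_id, start, end, members, DENOVO)

    return _index(bins)


def _index(bins: dict[int, Bin]) -> BinIndex:
    by_transcript: dict[str, set[int]] = {}
    for b in bins.values():
        for tid in b.members:
            by_transcript.setdefault(tid, set()).add(b.bin_id)
    return BinIndex(
        bins=bins,
        by_transcript={tid: frozenset(ids) for tid, ids in by_transcript.items()},
    )


def bins_of(index: BinIndex, transcript_id: str) -> frozenset[int]:
    return index.bins_of(transcript_id)


def unbinned_transcripts(
    index: BinIndex, all_transcripts: Iterable[str]
) -> frozenset[str]:
    """Transcripts with zero bin memberships (failed or filtered alignment)."""
    binned = index.transcript_ids()
    return frozenset(t for t in all_transcripts if t not in binned)
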