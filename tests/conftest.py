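from __future__ import annotations

import itertools

import pytest

from loclust.binning import Bin, BinIndex
from loclust.model import Clustering, TrueClustering, make_clustering


def index_from_layout(layout: dict[int, set[str]]) -> BinIndex:
    """Build a BinIndex from {bin_id: member set} with synthetic
    non-overlapping coordinates (the graph code only uses memberships)."""
    bins = {}
    for i, (bin_id, members) in enumerate(sorted(layout.items())):
        start = 1000 * (i + 1)
        bins[bin_id] = Bin(
            bin_id=bin_id,
            genome_id="g1",
            seq_id="chr1",
            start=start,
            end=start + 100,
            members=set(members),
        )
    by_transcript: dict[str, set[int]] = {}
    for bin_id, members in layout.items():
        for tid in members:
            by_transcript.setdefault(tid, set()).add(bin_id)
    return BinIndex(
        bins=bins,
        by_transcript={t: frozenset(v) for t, v in by_transcript.items()},
    )


def clustering_from_groups(groups: dict[str, set[str]], flag: str = "binned") -> Clustering:
    return make_clustering((cid, members, flag) for cid, members in groups.items())


def truth_from_groups(groups: dict[str, set[str]], provenance: str = "gff3_loci") -> TrueClustering:
    return TrueClustering(
        groups={k: frozenset(v) for k, v in groups.items()}, provenance=provenance
    )


def brute_force_edges(index: BinIndex, threshold: float) -> set[frozenset[str]]:
    """All-pairs evaluation of the edge rule — the independent oracle."""
    nodes = sorted(index.by_transcript)
    edges = set()
    for i, j in itertools.combinations(nodes, 2):
        bins_i, bins_j = index.bins_of(i), index.bins_of(j)
        shared = len(bins_i & bins_j)
        if shared == 0:
            continue
        if shared / len(bins_i) >= threshold or shared / len(bins_j) >= threshold:
            edges.add(frozenset((i, j)))
    return edges


def brute_force_pairs(
    test_groups: dict[str, set[str]], truth_groups: dict[str, set[str]]
) -> tuple[int, int, int, int]:
    """Exhaustive pair enumeration of (a, b, c, d) over common items."""
    test_assign = {t: c for c, members in test_groups.items() for t in members}
    truth_assign = {t: g for g, members in truth_groups.items() for t in members}
    common = sorted(set(test_assign) & set(truth_assign))
    a = b = c = d = 0
    for x, y in itertools.combinations(common, 2):
        same_test = test_assign[x] == test_assign[y]
        same_truth = truth_assign[x] == truth_assign[y]
        if same_test and same_truth:
            a += 1
        elif same_test:
            b += 1
        elif same_truth:
            c += 1
        else:
            d += 1
    return a, b, c, d


@pytest.fixture
def chimera_layout() -> dict[int, set[str]]:
    """The constructed seven-transcript two-locus layout: locus A transcripts
    span bins {1, 2}, locus B transcripts span bins {4, 5}, and the chimera X
    spans all four bins."""
    return {
        1: {"A1", "A2", "A3", "X"},
        2: {"A1", "A2", "A3", "X"},
        4: {"B1", "B2", "B3", "X"},
        5: {"B1", "B2", "B3", "X"},
    }
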