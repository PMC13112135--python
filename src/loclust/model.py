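"""Core domain types shared across the package.

Coordinate convention: all genomic coordinates are GFF3-style, 1-based and
inclusive at both ends.  No half-open conversions are exposed anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping


class LoclustError(Exception):
    """Base class for user-facing errors."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One input transcript (gene-model CDS or de novo assembly)."""

    transcript_id: str
    length: int
    species_tag: str = ""
    source: str = "de_novo"  # "gene_model" | "de_novo"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(
                f"transcript {self.transcript_id!r}: length must be >= 1, got {self.length}"
            )
        if self.source not in ("gene_model", "de_novo"):
            raise ValueError(f"invalid source {self.source!r}")


@dataclass(frozen=True)
class ExonPlacement:
    """One transcript's exon-level alignment blocks on one genome sequence.

    ``blocks`` are (start, end) pairs, 1-based inclusive, sorted by start and
    non-overlapping within the placement.  ``identity`` and ``coverage`` are
    fractions in [0, 1]; ``path_rank`` is 1 for the best path of a transcript
    on a genome, 2 for the next, and so on.
    """

    transcript_id: str
    genome_id: str
    seq_id: str
    blocks: tuple[tuple[int, int], ...]
    strand: str = "?"  # "+" | "-" | "?"
    identity: float = 1.0
    coverage: float = 1.0
    path_rank: int = 1

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"placement of {self.transcript_id!r} has no blocks")
        prev_end = None
        for start, end in self.blocks:
            if start > end:
                raise ValueError(
                    f"placement of {self.transcript_id!r}: block ({start}, {end}) has start > end"
                )
            if prev_end is not None and start <= prev_end:
                raise ValueError(
                    f"placement of {self.transcript_id!r}: blocks unsorted or overlapping"
                )
            prev_end = end
        if self.strand not in ("+", "-", "?"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.coverage <= 1.0):
            raise ValueError("identity/coverage must be fractions in [0, 1]")
        if self.path_rank < 1:
            raise ValueError("path_rank must be >= 1")

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


@dataclass(frozen=True)
class TrueClustering:
    """A reference partition: locus_id -> set of transcript ids."""

    groups: Mapping[str, frozenset[str]]
    provenance: str = "gff3_loci"  # "gff3_loci" | "ortholog_pairs"

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for locus, members in self.groups.items():
            if not members:
                raise ValueError(f"true group {locus!r} is empty")
            for member in members:
                if member in seen:
                    raise ValueError(
                        f"transcript {member!r} in both {seen[member]!r} and {locus!r}"
                    )
                seen[member] = locus
        if self.provenance not in ("gff3_loci", "ortholog_pairs"):
            raise ValueError(f"invalid provenance {self.provenance!r}")

    def assignment(self) -> dict[str, str]:
        """Flat transcript -> group id map."""
        return {t: g for g, members in self.groups.items() for t in members}

    def item_ids(self) -> frozenset[str]:
        return frozenset(self.assignment())

    @property
    def n_groups(self) -> int:
        return len(self.groups)


BINNED = "binned"
UNBINNED = "unbinned"
FRAGMENT = "fragment"
CHIMERA = "chimera"


@dataclass(frozen=True)
class Cluster:
    cluster_id: str
    members: frozenset[str]
    flag: str = BINNED  # "binned" | "unbinned"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id!r} is empty")
        if self.flag not in (BINNED, UNBINNED):
            raise ValueError(f"invalid cluster flag {self.flag!r}")


@dataclass(frozen=True)
class Clustering:
    """A partition of transcript ids into clusters plus a filtered report.

    ``filtered`` maps a removed transcript id to its removal reason
    ("fragment" or "chimera"); filtered transcripts never appear in any
    cluster.
    """

    clusters: tuple[Cluster, ...]
    filtered: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cluster in self.clusters:
            for member in cluster.members:
                if member in seen:
                    raise ValueError(
                        f"transcript {member!r} in clusters "
                        f"{seen[member]!r} and {cluster.cluster_id!r}"
                    )
                seen[member] = cluster.cluster_id
        for transcript_id, reason in self.filtered.items():
            if transcript_id in seen:
                raise ValueError(
                    f"filtered transcript {transcript_id!r} also appears in "
                    f"cluster {seen[transcript_id]!r}"
                )
            if reason not in (FRAGMENT, CHIMERA):
                raise ValueError(f"invalid filter reason {reason!r}")

    def __iter__(self) -> Iterator[Cluster]:
        return iter(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)

    def assignment(self) -> dict[str, str]:
        return {t: c.cluster_id for c in self.clusters for t in c.members}

    def member_ids(self) -> frozenset[str]:
        return frozenset(self.assignment())

    def groups(self) -> dict[str, frozenset[str]]:
        return {c.cluster_id: c.members for c in self.clusters}


def make_clustering(
    groups: Iterable[tuple[str, Iterable[str], str]],
    filtered: Mapping[str, str] | None = None,
) -> Clustering:
    """Build a Clustering from (cluster_id, members, flag) triples."""
    clusters = tuple(
        Cluster(cid, frozenset(members), flag) for cid, members, flag in groups
    )
    return Clustering(clusters=clusters, filtered=dict(filtered or {}))
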