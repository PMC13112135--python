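"""Fallback clustering for transcripts that aligned to no genome.

The internal algorithm is an incremental greedy scheme in the spirit of
CD-HIT: sequences are processed longest-first and each joins the first
cluster whose representative it matches at ``min_identity`` over the aligned
region with sufficient aligned-region coverage of both the shorter and the
longer sequence; otherwise it founds a new cluster.  Representatives are
therefore always the longest member.

Adapters for CD-HIT and MMseqs2 are provided for users who have those
binaries; nothing in this package (or its tests) requires them.
"""

from __future__ import annotations

import logging
import re
import shutil
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

from .model import UNBINNED, Cluster, Clustering, LoclustError, make_clustering

logger = logging.getLogger(__name__)

_VALID_NT = frozenset("ACGTN")

# banded-alignment engineering knobs (see GreedyParams docstring)
_KMER = 15
_BAND_PAD = 31
_MATCH, _MISMATCH, _GAP = 1, -1, -2


@dataclass(frozen=True)
class GreedyParams:
    """Acceptance thresholds for the internal greedy clusterer.

    Defaults are the plant/animal optimum (98% identity, 40% coverage of
    both sequences); the microbial preset raises both coverages to 80%.
    """

    min_identity: float = 0.98
    min_short_coverage: float = 0.4
    min_long_coverage: float = 0.4
    preset: str = "plant_animal"

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_short_coverage", "min_long_coverage"):
            value = getattr(self, name)
            if not (0.0 < value <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.preset not in ("plant_animal", "microbial"):
            raise ValueError(f"unknown preset {self.preset!r}")

    @classmethod
    def from_preset(cls, preset: str) -> "GreedyParams":
        if preset == "plant_animal":
            return cls(preset="plant_animal")
        if preset == "microbial":
            return cls(
                min_short_coverage=0.8, min_long_coverage=0.8, preset="microbial"
            )
        raise LoclustError(f"unknown preset {preset!r}")


# ---------------------------------------------------------------------------
# Banded local alignment

def _kmer_positions(seq: str, k: int = _KMER) -> dict[str, int]:
    positions: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer not in positions:
            positions[kmer] = i
    return positions


def _seed_diagonal(a: str, b: str, b_kmers: dict[str, int]) -> int | None:
    """Diagonal (a_pos - b_pos) of the first k-mer shared by a and b."""
    for i in range(len(a) - _KMER + 1):
        j = b_kmers.get(a[i : i + _KMER])
        if j is not None:
            return i - j
    return None


def banded_local_align(
    a: str, b: str, diagonal: int, half_width: int
) -> tuple[float, int, int] | None:
    """Smith-Waterman restricted to cells within ``half_width`` of
    ``diagonal`` (= i - j offset).

    Returns (identity over alignment columns, aligned length on a, aligned
    length on b), or None when no positive-scoring alignment exists.
    """
    n, m = len(a), len(b)
    best_score, best_cell = 0, None
    score: dict[tuple[int, int], int] = {}
    trace: dict[tuple[int, int], tuple[int, int]] = {}

    for i in range(1, n + 1):
        j_low = max(1, i - diagonal - half_width)
        j_high = min(m, i - diagonal + half_width)
        for j in range(j_low, j_high + 1):
            diag = score.get((i - 1, j - 1), 0) + (
                _MATCH if a[i - 1] == b[j - 1] else _MISMATCH
            )
            up = score.get((i - 1, j), 0) + _GAP
            left = score.get((i, j - 1), 0) + _GAP
            s = max(0, diag, up, left)
            if s == 0:
                continue
            score[(i, j)] = s
            if s == diag:
                trace[(i, j)] = (i - 1, j - 1)
            elif s == up:
                trace[(i, j)] = (i - 1, j)
            else:
                trace[(i, j)] = (i, j - 1)
            if s > best_score:
                best_score, best_cell = s, (i, j)

    if best_cell is None:
        return None
    matches = columns = 0
    i, j = best_cell
    end_i, end_j = i, j
    while (i, j) in trace and score.get((i, j), 0) > 0:
        pi, pj = trace[(i, j)]
        columns += 1
        if pi == i - 1 and pj == j - 1 and a[i - 1] == b[j - 1]:
            matches += 1
        i, j = pi, pj
    identity = matches / columns if columns else 0.0
    return identity, end_i - i, end_j - j


def _match_stats(a: str, b: str, b_kmers: dict[str, int]) -> tuple[float, float, float] | None:
    """(identity, coverage of a, coverage of b) for the best banded local
    alignment, or None when the k-mer prefilter finds no shared seed."""
    if min(len(a), len(b)) >= _KMER:
        diagonal = _seed_diagonal(a, b, b_kmers)
        if diagonal is None:
            return None
    else:
        diagonal = 0  # tiny sequences: centre band, no prefilter
    half_width = (2 * abs(len(a) - len(b)) + _BAND_PAD) // 2
    result = banded_local_align(a, b, diagonal, half_width)
    if result is None:
        return None
    identity, len_a, len_b = result
    return identity, len_a / len(a), len_b / len(b)


# ---------------------------------------------------------------------------
# Greedy clustering

def greedy_cluster(
    seqs: Mapping[str, str], params: GreedyParams | None = None
) -> Clustering:
    """Cluster sequences with the incremental greedy scheme.

    Sequences are processed longest-first (ties broken by identifier sort);
    each joins the first existing cluster whose representative satisfies all
    three thresholds, else founds a new cluster.  Deterministic given the
    input mapping; empty input yields an empty clustering.
    """
    params = params or GreedyParams()
    for tid, seq in seqs.items():
        if not seq:
            raise LoclustError(f"sequence {tid!r} is empty")
        bad = set(seq) - _VALID_NT
        if bad:
            raise LoclustError(
                f"sequence {tid!r} contains non-nucleotide symbol(s) {sorted(bad)}"
            )

    order = sorted(seqs, key=lambda tid: (-len(seqs[tid]), tid))
    reps: list[tuple[str, str, dict[str, int]]] = []  # (rep_id, seq, kmer index)
    members: list[list[str]] = []

    for tid in order:
        seq = seqs[tid]
        placed = False
        for idx, (rep_id, rep_seq, rep_kmers) in enumerate(reps):
            stats = _match_stats(seq, rep_seq, rep_kmers)
            if stats is None:
                continue
            identity, cov_new, cov_rep = stats
            # new sequence is never longer than the representative
            cov_short, cov_long = cov_new, cov_rep
            if (
                identity >= params.min_identity
                and cov_short >= params.min_short_coverage
                and cov_long >= params.min_long_coverage
            ):
                members[idx].append(tid)
                placed = True
                break
        if not placed:
            reps.append((tid, seq, _kmer_positions(seq)))
            members.append([tid])

    clusters = tuple(
        Cluster(f"unbinned-{i:06d}", frozenset(group), UNBINNED)
        for i, group in enumerate(members, 1)
    )
    return Clustering(clusters=clusters)


def representative_of(cluster: Cluster, seqs: Mapping[str, str]) -> str:
    """Longest member, ties broken by identifier sort."""
    return min(cluster.members, key=lambda tid: (-len(seqs[tid]), tid))


# ---------------------------------------------------------------------------
# Merging

def merge_clusterings(binned: Clustering, unbinned: Clustering) -> Clustering:
    """Concatenate the binned and unbinned clusterings with globally unique
    cluster ids; flags are preserved."""
    shared = binned.member_ids() & unbinned.member_ids()
    if shared:
        raise LoclustError(
            f"transcript(s) present in both clusterings: {sorted(shared)[:5]}"
        )
    shared_filtered = set(binned.filtered) | set(unbinned.filtered)
    merged_filtered = dict(binned.filtered)
    merged_filtered.update(unbinned.filtered)
    for tid in shared_filtered:
        if tid in binned.member_ids() or tid in unbinned.member_ids():
            raise LoclustError(f"filtered transcript {tid!r} also clustered")

    clusters = []
    counter = 0
    for source in (binned, unbinned):
        for cluster in sorted(source.clusters, key=lambda c: c.cluster_id):
            counter += 1
            clusters.append(replace(cluster, cluster_id=f"cluster-{counter:06d}"))
    return Clustering(clusters=tuple(clusters), filtered=merged_filtered)


# ---------------------------------------------------------------------------
# External tool adapters (interface only; binaries never required by tests)

_CLSTR_MEMBER_RE = re.compile(r">(\S+?)\.\.\.")


def parse_cdhit_clstr(text: str) -> Clustering:
    """Parse CD-HIT ``.clstr`` text into an unbinned Clustering."""
    groups: list[list[str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">Cluster"):
            groups.append([])
            continue
        match = _CLSTR_MEMBER_RE.search(line)
        if match is None:
            raise LoclustError(f"unparseable .clstr line: {line!r}")
        if not groups:
            raise LoclustError(".clstr member line before any cluster header")
        groups[-1].append(match.group(1))
    groups = [g for g in groups if g]
    return make_clustering(
        (f"unbinned-{i:06d}", group, UNBINNED) for i, group in enumerate(groups, 1)
    )


def parse_mmseqs_tsv(text: str) -> Clustering:
    """Parse MMseqs2 two-column (representative, member) cluster TSV."""
    groups: dict[str, list[str]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise LoclustError(f"expected 2 columns in MMseqs2 TSV, got {line!r}")
        rep, member = fields
        groups.setdefault(rep, []).append(member)
    return make_clustering(
        (f"unbinned-{i:06d}", group, UNBINNED)
        for i, (_, group) in enumerate(sorted(groups.items()), 1)
    )


def external_tool_adapter(
    tool: str,
    fasta_path: str | Path,
    params: GreedyParams | None = None,
    workdir: str | Path | None = None,
) -> Clustering:
    """Run CD-HIT or MMseqs2 on a FASTA and parse its clusters.

    Parameters map from :class:`GreedyParams` (CD-HIT ``-c/-aS/-aL/-G``;
    MMseqs2 ``--min-seq-id/-c``).  A missing binary raises an actionable
    error suggesting the internal algorithm.
    """
    import subprocess
    import tempfile

    params = params or GreedyParams()
    if tool not in ("cdhit", "mmseqs2"):
        raise LoclustError(f"unknown external tool {tool!r}")
    binary = {"cdhit": "cd-hit-est", "mmseqs2": "mmseqs"}[tool]
    if shutil.which(binary) is None:
        raise LoclustError(
            f"{binary!r} not found on PATH; use the internal greedy clusterer "
            f"(--unbinned-tool internal) or install {binary}"
        )
    workdir = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="loclust-"))
    workdir.mkdir(parents=True, exist_ok=True)
    if tool == "cdhit":
        out = workdir / "cdhit_out"
        global_mode = "1" if params.preset == "microbial" else "0"
        subprocess.run(
            [
                binary, "-i", str(fasta_path), "-o", str(out),
                "-c", str(params.min_identity),
                "-aS", str(params.min_short_coverage),
                "-aL", str(params.min_long_coverage),
                "-G", global_mode, "-d", "0",
            ],
            check=True,
            capture_output=True,
        )
        return parse_cdhit_clstr(Path(str(out) + ".clstr").read_text())
    db = workdir / "db"
    clu = workdir / "clu"
    tsv = workdir / "clusters.tsv"
    for args in (
        [binary, "createdb", str(fasta_path), str(db)],
        [
            binary, "cluster", str(db), str(clu), str(workdir / "tmp"),
            "--min-seq-id", str(params.min_identity),
            "-c", str(params.min_short_coverage),
        ],
        [binary, "createtsv", str(db), str(db), str(clu), str(tsv)],
    ):
        subprocess.run(args, check=True, capture_output=True)
    return parse_mmseqs_tsv(tsv.read_text())
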