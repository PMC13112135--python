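"""Partition-agreement metrics between a clustering and a reference.

Implements pair-counting (RI, ARI) and information-theoretic (NMI, AMI)
indices from the contingency table, with natural logarithms and the
arithmetic-mean normalisation for NMI/AMI.  Items absent from either
partition are excluded before computation, with counts logged.  Negative
ARI/AMI values are reported as computed, never clamped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .model import Cluster, Clustering, LoclustError, TrueClustering

logger = logging.getLogger(__name__)

_EPS = np.finfo(np.float64).eps


@dataclass(frozen=True)
class PartitionMetrics:
    ri: float
    ari: float
    nmi: float
    ami: float
    n_test_clusters: int
    n_true_groups: int
    n_items_compared: int


def _comb2(x: np.ndarray | int) -> np.ndarray | float:
    return x * (x - 1) / 2


def _contingency(
    test: Clustering, truth: TrueClustering
) -> tuple[np.ndarray, list[str]]:
    """Contingency table over the items present in both partitions.

    Rows are test clusters, columns true groups.  Items on one side only are
    dropped (counts logged).
    """
    test_assign = test.assignment()
    truth_assign = truth.assignment()
    common = sorted(set(test_assign) & set(truth_assign))
    dropped = (len(test_assign) - len(common), len(truth_assign) - len(common))
    if any(dropped):
        logger.info(
            "metric computation dropped %d test-only and %d truth-only item(s)",
            *dropped,
        )
    if len(common) < 2:
        raise LoclustError(
            f"need >= 2 items present in both partitions, got {len(common)}"
        )
    row_ids = sorted({test_assign[t] for t in common})
    col_ids = sorted({truth_assign[t] for t in common})
    row_index = {c: i for i, c in enumerate(row_ids)}
    col_index = {g: j for j, g in enumerate(col_ids)}
    table = np.zeros((len(row_ids), len(col_ids)), dtype=np.int64)
    for item in common:
        table[row_index[test_assign[item]], col_index[truth_assign[item]]] += 1
    return table, common


def pair_confusion(
    test: Clustering, truth: TrueClustering
) -> tuple[int, int, int, int]:
    """Pair counts (a, b, c, d) over items present in both partitions.

    a: together in both; b: together only in the test clustering; c:
    together only in the truth; d: apart in both.  a + b + c + d = C(n, 2).
    """
    table, common = _contingency(test, truth)
    n = len(common)
    a = int(_comb2(table).sum())
    ab = int(_comb2(table.sum(axis=1)).sum())  # together in test
    ac = int(_comb2(table.sum(axis=0)).sum())  # together in truth
    total = n * (n - 1) // 2
    b, c = ab - a, ac - a
    d = total - a - b - c
    return a, b, c, d


def _entropy(marginal: np.ndarray, n: int) -> float:
    p = marginal[marginal > 0] / n
    return float(-(p * np.log(p)).sum())


def _mutual_information(table: np.ndarray, n: int) -> float:
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    mi = 0.0
    nz = np.nonzero(table)
    for i, j in zip(*nz):
        nij = table[i, j]
        mi += nij / n * math.log(n * nij / (rows[i] * cols[j]))
    return max(mi, 0.0)  # guard tiny negative round-off


def expected_mutual_information(
    row_sums: Sequence[int], col_sums: Sequence[int], n: int
) -> float:
    """E[MI] between two random partitions with the given marginals under
    the hypergeometric (permutation) model."""
    emi = 0.0
    lg_n = gammaln(n + 1)
    for a in row_sums:
        for b in col_sums:
            lo = max(1, a + b - n)
            hi = min(a, b)
            for nij in range(lo, hi + 1):
                term = nij / n * math.log(n * nij / (a * b))
                log_prob = (
                    gammaln(a + 1)
                    + gammaln(b + 1)
                    + gammaln(n - a + 1)
                    + gammaln(n - b + 1)
                    - lg_n
                    - gammaln(nij + 1)
                    - gammaln(a - nij + 1)
                    - gammaln(b - nij + 1)
                    - gammaln(n - a - b + nij + 1)
                )
                emi += term * math.exp(log_prob)
    return emi


def compute_metrics(test: Clustering, truth: TrueClustering) -> PartitionMetrics:
    """RI, ARI, NMI, AMI between the clustering and the reference.

    Degenerate cases follow the usual 0/0 -> 0 convention except that two
    identical trivial partitions score 1 on every index.
    """
    table, common = _contingency(test, truth)
    n = len(common)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n_test, n_true = len(rows), len(cols)

    a, b, c, d = pair_confusion(test, truth)
    total = n * (n - 1) // 2
    ri = (a + d) / total

    # ARI from the contingency table (permutation-model adjustment)
    if b == 0 and c == 0:  # identical partitions, incl. degenerate ones
        ari = 1.0
    else:
        sum_ij = float(_comb2(table.astype(np.float64)).sum())
        sum_i = float(_comb2(rows.astype(np.float64)).sum())
        sum_j = float(_comb2(cols.astype(np.float64)).sum())
        expected = sum_i * sum_j / total
        max_index = (sum_i + sum_j) / 2
        ari = (sum_ij - expected) / (max_index - expected)

    h_test = _entropy(rows, n)
    h_true = _entropy(cols, n)
    mi = _mutual_information(table, n)
    mean_h = (h_test + h_true) / 2

    if n_test == n_true == 1:
        nmi = ami = 1.0
    else:
        nmi = 0.0 if mi == 0.0 else mi / max(mean_h, _EPS)
        emi = expected_mutual_information(rows.tolist(), cols.tolist(), n)
        denominator = mean_h - emi
        if denominator < 0:
            denominator = min(denominator, -_EPS)
        else:
            denominator = max(denominator, _EPS)
        ami = (mi - emi) / denominator

    return PartitionMetrics(
        ri=ri,
        ari=float(ari),
        nmi=float(nmi),
        ami=float(ami),
        n_test_clusters=n_test,
        n_true_groups=n_true,
        n_items_compared=n,
    )


# ---------------------------------------------------------------------------
# Per-species subsetting

def subset_by_species(
    clustering: Clustering,
    species_lookup: Mapping[str, str],
    species_tag: str,
) -> Clustering:
    """Restrict every cluster to one species' transcripts; empty
    intersections are dropped.  Unknown tags raise, listing the known ones."""
    known = sorted({tag for tag in species_lookup.values() if tag})
    if species_tag not in known:
        raise LoclustError(
            f"unknown species tag {species_tag!r}; known tags: {known}"
        )
    kept = []
    for cluster in clustering.clusters:
        members = frozenset(
            t for t in cluster.members if species_lookup.get(t) == species_tag
        )
        if members:
            kept.append(Cluster(cluster.cluster_id, members, cluster.flag))
    filtered = {
        t: reason
        for t, reason in clustering.filtered.items()
        if species_lookup.get(t) == species_tag
    }
    return Clustering(clusters=tuple(kept), filtered=filtered)


# ---------------------------------------------------------------------------
# Report

_REPORT_COLUMNS = (
    "species",
    "configuration",
    "n_items_compared",
    "n_test_clusters",
    "n_true_groups",
    "ri",
    "ari",
    "nmi",
    "ami",
)


def evaluation_report(
    entries: Sequence[tuple[str, str, PartitionMetrics]], path: str | Path
) -> None:
    """Write one TSV row per (species, configuration) pair."""
    lines = ["\t".join(_REPORT_COLUMNS)]
    for species, configuration, m in entries:
        lines.append(
            "\t".join(
                [
                    species,
                    configuration,
                    str(m.n_items_compared),
                    str(m.n_test_clusters),
                    str(m.n_true_groups),
                    f"{m.ri:.9f}",
                    f"{m.ari:.9f}",
                    f"{m.nmi:.9f}",
                    f"{m.ami:.9f}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def parse_evaluation_report(
    path: str | Path,
) -> list[tuple[str, str, PartitionMetrics]]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != "\t".join(_REPORT_COLUMNS):
        raise LoclustError(f"{path}: missing report header")
    entries = []
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("\t")
        species, configuration = fields[0], fields[1]
        n_items, n_test, n_true = (int(x) for x in fields[2:5])
        ri, ari, nmi, ami = (float(x) for x in fields[5:9])
        entries.append(
            (
                species,
                configuration,
                PartitionMetrics(ri, ari, nmi, ami, n_test, n_true, n_items),
            )
        )
    return entries
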