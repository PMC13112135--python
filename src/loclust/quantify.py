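"""Representative selection, transcript-to-cluster export, and locus-level
count aggregation.

Count matrices are pandas DataFrames with transcript ids as the index and
sample ids as columns; values may be fractional (estimated counts) and are
never rounded.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .model import Clustering, LoclustError

logger = logging.getLogger(__name__)


def select_representatives(
    clustering: Clustering, lengths: Mapping[str, int]
) -> dict[str, str]:
    """Longest member of each cluster; ties broken by lexicographically
    smallest identifier."""
    reps: dict[str, str] = {}
    for cluster in clustering.clusters:
        missing = [t for t in cluster.members if t not in lengths]
        if missing:
            raise LoclustError(
                f"cluster {cluster.cluster_id!r}: no length for {sorted(missing)[:5]}"
            )
        reps[cluster.cluster_id] = min(
            cluster.members, key=lambda t: (-lengths[t], t)
        )
    return reps


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a transcripts-by-samples count TSV (first column = ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise LoclustError(f"duplicate transcript row(s) in {path}: {dupes[:5]}")
    if df.columns.duplicated().any():
        raise LoclustError(f"duplicate sample column(s) in {path}")
    if (df.values < 0).any():
        raise LoclustError(f"negative counts in {path}")
    return df


def write_count_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.sort_index().to_csv(path, sep="\t", index_label="id")


def aggregate_counts(matrix: pd.DataFrame, clustering: Clustering) -> pd.DataFrame:
    """Sum member transcript counts per cluster per sample.

    Rows for filtered transcripts are dropped with a warning; a transcript
    that is neither clustered nor filtered is an error.  Per-sample totals
    are conserved up to the dropped rows.
    """
    assignment = clustering.assignment()
    unknown = [
        t
        for t in matrix.index
        if t not in assignment and t not in clustering.filtered
    ]
    if unknown:
        raise LoclustError(
            f"transcript(s) in count matrix but in no cluster and not "
            f"filtered: {sorted(unknown)[:5]}"
        )
    dropped = [t for t in matrix.index if t in clustering.filtered]
    if dropped:
        logger.warning(
            "dropping %d filtered transcript row(s) from count matrix", len(dropped)
        )
    kept = matrix.loc[[t for t in matrix.index if t in assignment]]
    grouped = kept.groupby(kept.index.map(assignment)).sum()
    grouped.index.name = "cluster_id"
    return grouped.sort_index()


def write_tx2gene(clustering: Clustering, path: str | Path) -> None:
    """Two-column TXNAME/GENEID map (GENEID = cluster id); filtered
    transcripts are absent.  Deterministic row order."""
    lines = ["TXNAME\tGENEID"]
    assignment = clustering.assignment()
    for transcript_id in sorted(assignment):
        lines.append(f"{transcript_id}\t{assignment[transcript_id]}")
    Path(path).write_text("\n".join(lines) + "\n")


_R_TEMPLATE = """\
# Locus-level count import (generated; do not edit)
# Loads transcript-level quantifications and aggregates them per cluster.
library(tximport)

tx2gene <- read.table("{tx2gene}", header = TRUE, sep = "\\t",
                      stringsAsFactors = FALSE)

samples <- c(
{sample_lines}
)
files <- file.path(samples, "quant.sf")
names(files) <- basename(samples)
stopifnot(all(file.exists(files)))

txi <- tximport(files, type = "salmon", tx2gene = tx2gene)
counts <- txi$counts
write.table(counts, file = "cluster_counts.tsv", sep = "\\t",
            quote = FALSE, col.names = NA)
"""


def emit_import_script(
    tx2gene_path: str | Path,
    quant_dirs: Sequence[str | Path],
    path: str | Path,
) -> str:
    """Write a pre-configured R/tximport count-import script and return its
    text.  Output is deterministic for fixed inputs."""
    sample_lines = ",\n".join(f'    "{d}"' for d in quant_dirs)
    text = _R_TEMPLATE.format(tx2gene=tx2gene_path, sample_lines=sample_lines)
    Path(path).write_text(text)
    return text
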