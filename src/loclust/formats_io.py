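"""Readers and writers for the external formats the tool touches.

Everything is normalised into the domain types of :mod:`loclust.model` on the
way in.  Coordinates are GFF3 1-based inclusive throughout.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import networkx as nx
from Bio import SeqIO

from .model import (
    BINNED,
    CHIMERA,
    FRAGMENT,
    UNBINNED,
    Cluster,
    Clustering,
    ExonPlacement,
    LoclustError,
    TranscriptRecord,
    TrueClustering,
)

logger = logging.getLogger(__name__)

#: Default spliced-alignment acceptance filters.  The aligner's own output is
#: unfiltered; these are applied on read and are configurable from the CLI.
DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MIN_COVERAGE = 0.70


# ---------------------------------------------------------------------------
# FASTA

def read_fasta_sequences(fasta_path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Raises on duplicate identifiers and on empty files.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in seqs:
            raise LoclustError(
                f"duplicate FASTA identifier {record.id!r} in {fasta_path}"
            )
        seqs[record.id] = str(record.seq).upper()
    if not seqs:
        raise LoclustError(f"no FASTA records found in {fasta_path}")
    return seqs


def load_species_map(path: str | Path) -> dict[str, str]:
    """Load a two-column ``transcript_id<TAB>species`` sidecar TSV."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise LoclustError(f"species map {path}: malformed line {line!r}")
        mapping[fields[0]] = fields[1]
    return mapping


def species_of(transcript_id: str, species_map: Mapping[str, str] | None) -> str:
    """Species tag for a transcript: sidecar map first, then the prefix
    before the first ``|`` in the identifier, else empty."""
    if species_map and transcript_id in species_map:
        return species_map[transcript_id]
    if "|" in transcript_id:
        return transcript_id.split("|", 1)[0]
    return ""


def read_transcripts(
    fasta_path: str | Path,
    species_map: Mapping[str, str] | None = None,
    source: str = "de_novo",
) -> list[TranscriptRecord]:
    """Read transcript FASTA into records (id, length, species tag)."""
    seqs = read_fasta_sequences(fasta_path)
    return [
        TranscriptRecord(
            transcript_id=tid,
            length=len(seq),
            species_tag=species_of(tid, species_map),
            source=source,
        )
        for tid, seq in seqs.items()
    ]


# ---------------------------------------------------------------------------
# GFF3 — spliced alignments (GMAP-style)

_ATTR_RE = re.compile(r"\s*([^=;]+)=([^;]*)")
_PATH_SUFFIX_RE = re.compile(r"\.(?:mrna|path)\d+$")


def _parse_attributes(text: str) -> dict[str, str]:
    return {m.group(1): m.group(2) for m in _ATTR_RE.finditer(text)}


def _as_fraction(value: str) -> float:
    """Identity/coverage attributes may be fractions or percentages."""
    x = float(value)
    return x / 100.0 if x > 1.0 else x


def _transcript_name(attrs: dict[str, str], feature_id: str) -> str:
    if "Name" in attrs:
        return attrs["Name"]
    return _PATH_SUFFIX_RE.sub("", feature_id)


def read_gmap_gff3(
    gff3_path: str | Path,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    genome_id: str | None = None,
) -> list[ExonPlacement]:
    """Parse spliced-alignment GFF3 into placements, applying identity and
    coverage filters.

    Both the ``mRNA``/``exon`` and the ``cDNA_match`` representations are
    accepted.  Identity/coverage attributes default to 1.0 when absent (with
    a warning) so hand-made files are valid.  ``path_rank`` follows input
    order per transcript.  Paths failing either filter are dropped and
    counted in the log; malformed features (end < start) are skipped with a
    warning.
    """
    if not (0.0 <= min_identity <= 1.0 and 0.0 <= min_coverage <= 1.0):
        raise LoclustError("alignment filters must be fractions in [0, 1]")
    gff3_path = Path(gff3_path)
    if genome_id is None:
        genome_id = gff3_path.stem

    # path key -> accumulated state; insertion order preserved
    paths: dict[str, dict] = {}
    missing_attr = 0

    with open(gff3_path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                logger.warning("%s:%d: not 9 columns, skipped", gff3_path, lineno)
                continue
            seq_id, _, ftype, start_s, end_s, _, strand, _, attr_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                logger.warning("%s:%d: non-integer coordinates, skipped", gff3_path, lineno)
                continue
            if end < start:
                logger.warning(
                    "%s:%d: malformed coordinates (end %d < start %d), skipped",
                    gff3_path, lineno, end, start,
                )
                continue
            attrs = _parse_attributes(attr_s)

            if ftype in ("mRNA", "transcript"):
                key = attrs.get("ID", f"_anon{lineno}")
                if "identity" not in attrs or "coverage" not in attrs:
                    missing_attr += 1
                paths[key] = {
                    "transcript_id": _transcript_name(attrs, key),
                    "seq_id": seq_id,
                    "strand": strand if strand in "+-" else "?",
                    "identity": _as_fraction(attrs.get("identity", "1.0")),
                    "coverage": _as_fraction(attrs.get("coverage", "1.0")),
                    "blocks": [],
                }
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None or parent not in paths:
                    logger.warning("%s:%d: exon with unknown Parent, skipped", gff3_path, lineno)
                    continue
                paths[parent]["blocks"].append((start, end))
            elif ftype == "cDNA_match":
                key = attrs.get("ID", f"_anon{lineno}")
                if key not in paths:
                    if "identity" not in attrs or "coverage" not in attrs:
                        missing_attr += 1
                    paths[key] = {
                        "transcript_id": _transcript_name(attrs, key),
                        "seq_id": seq_id,
                        "strand": strand if strand in "+-" else "?",
                        "identity": _as_fraction(attrs.get("identity", "1.0")),
                        "coverage": _as_fraction(attrs.get("coverage", "1.0")),
                        "blocks": [],
                    }
                paths[key]["blocks"].append((start, end))

    if missing_attr:
        logger.warning(
            "%s: %d path(s) lacked identity/coverage attributes; assumed 1.0",
            gff3_path, missing_attr,
        )

    placements: list[ExonPlacement] = []
    dropped = 0
    rank: dict[str, int] = {}
    for state in paths.values():
        if not state["blocks"]:
            logger.warning("path for %r has no exon blocks, skipped", state["transcript_id"])
            continue
        if state["identity"] < min_identity or state["coverage"] < min_coverage:
            dropped += 1
            continue
        tid = state["transcript_id"]
        rank[tid] = rank.get(tid, 0) + 1
        placements.append(
            ExonPlacement(
                transcript_id=tid,
                genome_id=genome_id,
                seq_id=state["seq_id"],
                blocks=tuple(sorted(state["blocks"])),
                strand=state["strand"],
                identity=state["identity"],
                coverage=state["coverage"],
                path_rank=rank[tid],
            )
        )
    if dropped:
        logger.info(
            "%s: dropped %d path(s) below identity %.2f / coverage %.2f",
            gff3_path, dropped, min_identity, min_coverage,
        )
    return placements


# ---------------------------------------------------------------------------
# GFF3 — reference annotations

def read_annotation_loci(
    gff3_path: str | Path,
    genome_id: str | None = None,
) -> tuple[TrueClustering, list[ExonPlacement]]:
    """Read a gene -> mRNA -> exon annotation.

    Returns the locus partition (each gene's mRNAs are one true group) and
    exon placements synthesised from the annotation (identity = coverage = 1)
    for bin pre-seeding.  Orphan mRNAs without a gene parent become their own
    locus, with a warning.
    """
    gff3_path = Path(gff3_path)
    if genome_id is None:
        genome_id = gff3_path.stem
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )

    groups: dict[str, frozenset[str]] = {}
    placements: list[ExonPlacement] = []
    claimed: set[str] = set()

    def _placement(mrna) -> ExonPlacement | None:
        blocks = sorted(
            (exon.start, exon.end) for exon in db.children(mrna, featuretype="exon")
        )
        if not blocks:
            return None
        merged: list[tuple[int, int]] = []
        for start, end in blocks:  # defensive merge; exons should be disjoint
            if merged and start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        return ExonPlacement(
            transcript_id=mrna.id,
            genome_id=genome_id,
            seq_id=mrna.seqid,
            blocks=tuple(merged),
            strand=mrna.strand if mrna.strand in "+-" else "?",
        )

    for gene in db.features_of_type("gene"):
        mrna_ids = []
        for mrna in db.children(gene, featuretype="mRNA"):
            placement = _placement(mrna)
            if placement is None:
                continue
            mrna_ids.append(mrna.id)
            claimed.add(mrna.id)
            placements.append(placement)
        if mrna_ids:
            groups[gene.id] = frozenset(mrna_ids)

    for mrna in db.features_of_type("mRNA"):
        if mrna.id in claimed:
            continue
        placement = _placement(mrna)
        if placement is None:
            continue
        logger.warning("mRNA %r has no gene parent; treated as its own locus", mrna.id)
        groups[f"orphan:{mrna.id}"] = frozenset([mrna.id])
        placements.append(placement)

    return TrueClustering(groups=groups, provenance="gff3_loci"), placements


# ---------------------------------------------------------------------------
# Ortholog pair tables

def read_ortholog_pairs(
    tsv_path: str | Path,
    species_filter: set[str] | None = None,
) -> TrueClustering:
    """Parse a one-to-one ortholog pair TSV (NCBI ``gene_orthologs`` layout:
    tax_id, GeneID, relationship, Other_tax_id, Other_GeneID).

    Connected components of the pair graph become true groups.  When
    ``species_filter`` is given, rows whose taxa are not all in the filter
    contribute only the in-filter gene (which may end up a singleton); rows
    with no in-filter gene are skipped and counted.
    """
    graph: nx.Graph = nx.Graph()
    skipped = 0
    for line in Path(tsv_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise LoclustError(f"{tsv_path}: expected >= 5 columns, got {line!r}")
        tax_a, gene_a, _rel, tax_b, gene_b = fields[:5]
        keep_a = species_filter is None or tax_a in species_filter
        keep_b = species_filter is None or tax_b in species_filter
        if keep_a:
            graph.add_node(gene_a)
        if keep_b:
            graph.add_node(gene_b)
        if keep_a and keep_b:
            graph.add_edge(gene_a, gene_b)
        elif not keep_a and not keep_b:
            skipped += 1
    if skipped:
        logger.info("%s: skipped %d row(s) with out-of-filter species", tsv_path, skipped)
    components = sorted(
        (sorted(component) for component in nx.connected_components(graph))
    )
    groups = {
        f"og{i:05d}": frozenset(component)
        for i, component in enumerate(components, 1)
    }
    return TrueClustering(groups=groups, provenance="ortholog_pairs")


# ---------------------------------------------------------------------------
# Cluster TSV round-trip

_CLUSTER_HEADER = "cluster_id\ttranscript_id\tbinned_flag"
_FILTERED_HEADER = "transcript_id\treason"


def filtered_report_path(cluster_path: str | Path) -> Path:
    p = Path(cluster_path)
    return p.with_name(p.stem + ".filtered" + (p.suffix or ".tsv"))


def write_clusters(clustering: Clustering, path: str | Path) -> None:
    """Write cluster TSV (cluster_id, transcript_id, binned_flag) plus the
    sibling filtered-transcript report.  Row order is deterministic."""
    lines = [_CLUSTER_HEADER]
    for cluster in sorted(clustering.clusters, key=lambda c: c.cluster_id):
        for member in sorted(cluster.members):
            lines.append(f"{cluster.cluster_id}\t{member}\t{cluster.flag}")
    Path(path).write_text("\n".join(lines) + "\n")

    flines = [_FILTERED_HEADER]
    for transcript_id in sorted(clustering.filtered):
        flines.append(f"{transcript_id}\t{clustering.filtered[transcript_id]}")
    filtered_report_path(path).write_text("\n".join(flines) + "\n")


def read_clusters(path: str | Path) -> Clustering:
    """Inverse of :func:`write_clusters`."""
    members: dict[str, set[str]] = {}
    flags: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _CLUSTER_HEADER:
        raise LoclustError(f"{path}: missing cluster header line")
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise LoclustError(f"{path}: malformed row {line!r}")
        cluster_id, transcript_id, flag = fields
        if flag not in (BINNED, UNBINNED):
            raise LoclustError(f"{path}: unknown binned_flag {flag!r}")
        if cluster_id in flags and flags[cluster_id] != flag:
            raise LoclustError(f"{path}: inconsistent flags for {cluster_id!r}")
        flags[cluster_id] = flag
        members.setdefault(cluster_id, set()).add(transcript_id)

    filtered: dict[str, str] = {}
    report = filtered_report_path(path)
    if report.exists():
        rlines = report.read_text().splitlines()
        for line in rlines[1:]:
            if not line.strip():
                continue
            transcript_id, reason = line.split("\t")
            if reason not in (FRAGMENT, CHIMERA):
                raise LoclustError(f"{report}: unknown filter reason {reason!r}")
            filtered[transcript_id] = reason

    clusters = tuple(
        Cluster(cid, frozenset(members[cid]), flags[cid]) for cid in sorted(members)
    )
    return Clustering(clusters=clusters, filtered=filtered)


# ---------------------------------------------------------------------------
# Debug dumps

def write_bins_bed(bins: Iterable, path: str | Path) -> None:
    """BED-like TSV dump of bins for genome-browser inspection (start is
    converted to 0-based here, and only here)."""
    lines = []
    for b in sorted(bins, key=lambda b: (b.genome_id, b.seq_id, b.start, b.bin_id)):
        lines.append(
            f"{b.seq_id}\t{b.start - 1}\t{b.end}\t{b.bin_id}\t{b.origin}\t{len(b.members)}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
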