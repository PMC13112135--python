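"""Seeded synthetic-data generator.

Produces genomes, annotations, transcripts, and spliced-alignment records
with planted loci, exon-skipping isoforms, fragments, chimeras, and
contaminants, plus a ground-truth manifest.  Alignment records are
synthesised directly (no aligner is ever run): exact on the home genome,
coordinate-jittered on additional genomes to emulate related species.

One RNG stream per bundle, keyed by the config seed; the same seed always
yields a byte-identical bundle.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ExonPlacement, LoclustError, TranscriptRecord, TrueClustering

_NT = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_loci: int = 10
    exons_per_locus: tuple[int, int] = (3, 3)
    isoforms_per_locus: tuple[int, int] = (3, 3)
    n_genomes: int = 1
    coordinate_jitter: int = 0
    fragment_rate: float = 0.0
    chimera_rate: float = 0.0
    contaminant_rate: float = 0.0
    exon_len: tuple[int, int] = (80, 200)
    intron_len: tuple[int, int] = (60, 120)
    locus_gap: int = 500
    species_tag: str = "spA"
    related_identity: float = 0.95
    max_seq_len: int = 50_000_000

    def __post_init__(self) -> None:
        for name in ("fragment_rate", "chimera_rate", "contaminant_rate"):
            value = getattr(self, name)
            if not (0.0 <= value < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {value}")
        for name in ("exons_per_locus", "isoforms_per_locus", "exon_len", "intron_len"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} range ({lo}, {hi}) invalid")
        if self.n_loci < 1 or self.n_genomes < 1:
            raise ValueError("n_loci and n_genomes must be >= 1")
        if self.coordinate_jitter < 0:
            raise ValueError("coordinate_jitter must be >= 0")


@dataclass
class SimBundle:
    """In-memory result of a simulation, plus file paths when written."""

    config: SimConfig
    sequences: dict[str, str]  # transcript_id -> sequence
    records: list[TranscriptRecord]
    placements: dict[str, list[ExonPlacement]]  # genome_id -> placements
    truth: TrueClustering
    manifest: dict
    genome_sequences: dict[str, dict[str, str]]  # genome -> {seq_id: seq}
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.sequences)


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=length)])


def _jitter_blocks(
    blocks: tuple[tuple[int, int], ...],
    rng: np.random.Generator,
    jitter: int,
) -> tuple[tuple[int, int], ...]:
    """Independently jitter each block boundary, then repair ordering so the
    result is a valid sorted non-overlapping block list."""
    out: list[tuple[int, int]] = []
    prev_end = 0
    for start, end in blocks:
        s = start + int(rng.integers(-jitter, jitter + 1))
        e = end + int(rng.integers(-jitter, jitter + 1))
        s = max(prev_end + 1, s, 1)
        e = max(e, s)
        out.append((s, e))
        prev_end = e
    return tuple(out)


def simulate(config: SimConfig, outdir: str | Path | None = None) -> SimBundle:
    """Generate a full synthetic bundle; optionally write it to ``outdir``.

    Loci are placed without exon overlap between loci.  Isoforms are made by
    skipping one internal exon (so any two isoforms of a locus share at
    least the first and last exon).  Fragments are single-exon truncations;
    chimeras concatenate the leading half of one locus with the trailing
    half of another and appear exactly once; contaminants are random
    sequences with no placements.
    """
    rng = np.random.default_rng(config.seed)
    sp = config.species_tag
    home_genome = "genome1"
    seq_id = "chr1"

    # --- plant loci on the home genome
    loci: list[dict] = []  # exon blocks + ids per locus
    cursor = 1_000
    for l in range(1, config.n_loci + 1):
        n_exons = int(rng.integers(config.exons_per_locus[0], config.exons_per_locus[1] + 1))
        blocks: list[tuple[int, int]] = []
        pos = cursor
        for e in range(n_exons):
            length = int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
            blocks.append((pos, pos + length - 1))
            pos += length
            if e < n_exons - 1:
                pos += int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
        loci.append({"locus_id": f"L{l:04d}", "blocks": tuple(blocks)})
        cursor = pos + config.locus_gap
    genome_len = cursor + 1_000
    if genome_len > config.max_seq_len:
        raise LoclustError(
            f"infeasible packing: {config.n_loci} loci need {genome_len} bp "
            f"> max_seq_len {config.max_seq_len}"
        )
    home_seq = _rand_seq(rng, genome_len)

    def exon_seq(start: int, end: int) -> str:
        return home_seq[start - 1 : end]

    # --- chimera donor loci are chosen up front: their isoforms keep the
    #     full exon structure so the chimera attaches to every isoform and
    #     is the sole articulation point (separability condition)
    n_chimeras = int(round(config.chimera_rate * config.n_loci))
    if 2 * n_chimeras > config.n_loci:
        raise LoclustError("chimera_rate too high: needs 2 distinct loci per chimera")
    chimera_pool = rng.choice(config.n_loci, size=2 * n_chimeras, replace=False)
    chimera_donors = set(chimera_pool.tolist())

    # --- isoforms
    sequences: dict[str, str] = {}
    home_placements: list[ExonPlacement] = []
    groups: dict[str, frozenset[str]] = {}
    manifest_loci: dict[str, list[str]] = {}
    for locus_idx, locus in enumerate(loci):
        blocks = locus["blocks"]
        n_exons = len(blocks)
        n_iso = int(
            rng.integers(config.isoforms_per_locus[0], config.isoforms_per_locus[1] + 1)
        )
        iso_ids = []
        for m in range(1, n_iso + 1):
            if m == 1 or n_exons < 3 or locus_idx in chimera_donors:
                iso_blocks = blocks
            else:
                skip = 1 + (m - 2) % (n_exons - 2)  # internal exon index
                iso_blocks = tuple(b for e, b in enumerate(blocks) if e != skip)
            tid = f"{sp}|{locus['locus_id']}.iso{m}"
            sequences[tid] = "".join(exon_seq(s, e) for s, e in iso_blocks)
            home_placements.append(
                ExonPlacement(
                    transcript_id=tid,
                    genome_id=home_genome,
                    seq_id=seq_id,
                    blocks=iso_blocks,
                    strand="+",
                    identity=1.0,
                    coverage=1.0,
                    path_rank=1,
                )
            )
            iso_ids.append(tid)
        groups[locus["locus_id"]] = frozenset(iso_ids)
        manifest_loci[locus["locus_id"]] = iso_ids

    # --- fragments: single-exon truncations (first exon, present in all isoforms)
    n_fragments = int(round(config.fragment_rate * config.n_loci))
    fragment_loci = sorted(
        rng.choice(config.n_loci, size=n_fragments, replace=False).tolist()
    )
    fragments: list[str] = []
    for idx in fragment_loci:
        locus = loci[idx]
        start, end = locus["blocks"][0]
        tid = f"{sp}|{locus['locus_id']}.frag"
        sequences[tid] = exon_seq(start, end)
        home_placements.append(
            ExonPlacement(
                transcript_id=tid,
                genome_id=home_genome,
                seq_id=seq_id,
                blocks=((start, end),),
                strand="+",
            )
        )
        fragments.append(tid)

    # --- chimeras: leading half of one locus + trailing half of another,
    #     each appearing exactly once
    chimeras: list[str] = []
    for c in range(n_chimeras):
        i, j = sorted(chimera_pool[2 * c : 2 * c + 2].tolist())
        left, right = loci[i], loci[j]
        n_left = math.ceil(len(left["blocks"]) / 2)
        n_right = math.ceil(len(right["blocks"]) / 2)
        blocks = tuple(left["blocks"][:n_left]) + tuple(right["blocks"][-n_right:])
        tid = f"{sp}|chim{c + 1:03d}.{left['locus_id']}-{right['locus_id']}"
        sequences[tid] = "".join(exon_seq(s, e) for s, e in blocks)
        home_placements.append(
            ExonPlacement(
                transcript_id=tid,
                genome_id=home_genome,
                seq_id=seq_id,
                blocks=blocks,
                strand="+",
            )
        )
        chimeras.append(tid)

    # --- contaminants: no placements anywhere
    n_contaminants = int(round(config.contaminant_rate * config.n_loci))
    contaminants: list[str] = []
    for c in range(n_contaminants):
        tid = f"{sp}|contam{c + 1:03d}"
        sequences[tid] = _rand_seq(rng, int(rng.integers(200, 501)))
        contaminants.append(tid)

    # --- additional (related) genomes: jittered copies of every placement
    placements: dict[str, list[ExonPlacement]] = {home_genome: home_placements}
    genome_sequences: dict[str, dict[str, str]] = {
        home_genome: {seq_id: home_seq}
    }
    for g in range(2, config.n_genomes + 1):
        genome_id = f"genome{g}"
        jittered: list[ExonPlacement] = []
        max_end = 0
        for placement in home_placements:
            blocks = (
                _jitter_blocks(placement.blocks, rng, config.coordinate_jitter)
                if config.coordinate_jitter
                else placement.blocks
            )
            max_end = max(max_end, blocks[-1][1])
            jittered.append(
                ExonPlacement(
                    transcript_id=placement.transcript_id,
                    genome_id=genome_id,
                    seq_id=seq_id,
                    blocks=blocks,
                    strand=placement.strand,
                    identity=config.related_identity,
                    coverage=1.0,
                    path_rank=1,
                )
            )
        placements[genome_id] = jittered
        genome_sequences[genome_id] = {seq_id: _rand_seq(rng, max_end + 100)}

    records = [
        TranscriptRecord(
            transcript_id=tid,
            length=len(seq),
            species_tag=sp,
            source="de_novo",
        )
        for tid, seq in sequences.items()
    ]
    truth = TrueClustering(groups=groups, provenance="gff3_loci")
    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "n_transcripts": len(sequences),
        "loci": manifest_loci,
        "fragments": fragments,
        "chimeras": chimeras,
        "contaminants": contaminants,
        "genomes": sorted(placements),
        "home_genome": home_genome,
    }

    bundle = SimBundle(
        config=config,
        sequences=sequences,
        records=records,
        placements=placements,
        truth=truth,
        manifest=manifest,
        genome_sequences=genome_sequences,
    )
    if outdir is not None:
        _write_bundle(bundle, Path(outdir), loci)
    return bundle


# ---------------------------------------------------------------------------
# Writers

def _wrap(seq: str, width: int = 80) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w") as handle:
        for name, seq in seqs.items():
            handle.write(f">{name}\n{_wrap(seq)}\n")


def _write_alignment_gff3(placements: list[ExonPlacement], path: Path) -> None:
    """GMAP-style mRNA/exon GFF3 with identity/coverage percentages."""
    lines = ["##gff-version 3"]
    for k, p in enumerate(placements, 1):
        path_id = f"{p.transcript_id}.path{p.path_rank}"
        span = p.span
        attrs = (
            f"ID={path_id};Name={p.transcript_id};"
            f"identity={p.identity * 100:.1f};coverage={p.coverage * 100:.1f}"
        )
        lines.append(
            f"{p.seq_id}\tsim\tmRNA\t{span[0]}\t{span[1]}\t.\t{p.strand}\t.\t{attrs}"
        )
        for start, end in p.blocks:
            lines.append(
                f"{p.seq_id}\tsim\texon\t{start}\t{end}\t.\t{p.strand}\t.\tParent={path_id}"
            )
    path.write_text("\n".join(lines) + "\n")


def _write_annotation_gff3(bundle: SimBundle, loci: list[dict], path: Path) -> None:
    lines = ["##gff-version 3"]
    home = bundle.manifest["home_genome"]
    by_tid = {
        p.transcript_id: p for p in bundle.placements[home]
    }
    for locus in loci:
        locus_id = locus["locus_id"]
        iso_ids = bundle.manifest["loci"][locus_id]
        placements = [by_tid[t] for t in iso_ids]
        start = min(p.span[0] for p in placements)
        end = max(p.span[1] for p in placements)
        seq = placements[0].seq_id
        lines.append(
            f"{seq}\tsim\tgene\t{start}\t{end}\t.\t+\t.\tID=gene:{locus_id}"
        )
        for p in placements:
            span = p.span
            lines.append(
                f"{seq}\tsim\tmRNA\t{span[0]}\t{span[1]}\t.\t+\t.\t"
                f"ID={p.transcript_id};Parent=gene:{locus_id}"
            )
            for start_, end_ in p.blocks:
                lines.append(
                    f"{seq}\tsim\texon\t{start_}\t{end_}\t.\t+\t.\t"
                    f"Parent={p.transcript_id}"
                )
    path.write_text("\n".join(lines) + "\n")


def write_truth_tsv(truth: TrueClustering, path: str | Path) -> None:
    lines = ["locus_id\ttranscript_id"]
    for locus_id in sorted(truth.groups):
        for tid in sorted(truth.groups[locus_id]):
            lines.append(f"{locus_id}\t{tid}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_tsv(path: str | Path) -> TrueClustering:
    groups: dict[str, set[str]] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        locus_id, tid = line.split("\t")
        groups.setdefault(locus_id, set()).add(tid)
    return TrueClustering(
        groups={k: frozenset(v) for k, v in groups.items()}, provenance="gff3_loci"
    )


def _write_bundle(bundle: SimBundle, outdir: Path, loci: list[dict]) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["transcripts"] = outdir / "transcripts.fasta"
    _write_fasta(bundle.sequences, paths["transcripts"])

    for genome_id, seqs in bundle.genome_sequences.items():
        key = f"genome_fasta:{genome_id}"
        paths[key] = outdir / f"{genome_id}.fasta"
        _write_fasta(seqs, paths[key])

    for genome_id, placements in bundle.placements.items():
        key = f"alignments:{genome_id}"
        paths[key] = outdir / f"alignments_{genome_id}.gff3"
        _write_alignment_gff3(placements, paths[key])

    paths["annotation"] = outdir / "annotation_genome1.gff3"
    _write_annotation_gff3(bundle, loci, paths["annotation"])

    paths["truth"] = outdir / "truth.tsv"
    write_truth_tsv(bundle.truth, paths["truth"])

    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n")

    bundle.paths = paths


# ---------------------------------------------------------------------------
# Counts

def simulate_counts(
    transcript_ids, n_samples: int, seed: int
) -> pd.DataFrame:
    """Negative-binomial integer counts per transcript per sample."""
    if hasattr(transcript_ids, "groups"):  # TrueClustering
        ids = sorted(transcript_ids.item_ids())
    else:
        ids = sorted(transcript_ids)
    rng = np.random.default_rng(seed)
    values = rng.negative_binomial(n=5, p=0.05, size=(len(ids), n_samples))
    columns = [f"sample{i:02d}" for i in range(1, n_samples + 1)]
    return pd.DataFrame(values, index=pd.Index(ids, name="id"), columns=columns)
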