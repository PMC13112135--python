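from __future__ import annotations

import random

import pytest

from loclust import formats_io
from loclust.model import LoclustError, make_clustering

from conftest import clustering_from_groups


# ---------------------------------------------------------------------------
# FASTA

def write(path, text):
    path.write_text(text)
    return path


def test_read_transcripts_lengths(tmp_path):
    fasta = write(tmp_path / "t.fasta", ">t1\n" + "A" * 300 + "\n>t2\n" + "C" * 150 + "\n")
    records = formats_io.read_transcripts(fasta)
    assert [(r.transcript_id, r.length) for r in records] == [("t1", 300), ("t2", 150)]


def test_read_transcripts_duplicate_header_errors(tmp_path):
    fasta = write(tmp_path / "t.fasta", ">dup\nACGT\n>dup\nACGT\n")
    with pytest.raises(LoclustError, match="dup"):
        formats_io.read_transcripts(fasta)


def test_read_transcripts_empty_file_errors(tmp_path):
    fasta = write(tmp_path / "t.fasta", "")
    with pytest.raises(LoclustError):
        formats_io.read_transcripts(fasta)


def test_species_from_prefix_and_sidecar(tmp_path):
    fasta = write(tmp_path / "t.fasta", ">spX|t1\nACGT\n>plain\nACGT\n")
    records = formats_io.read_transcripts(fasta)
    assert records[0].species_tag == "spX"
    assert records[1].species_tag == ""
    sidecar = write(tmp_path / "map.tsv", "plain\tspY\n")
    records = formats_io.read_transcripts(fasta, formats_io.load_species_map(sidecar))
    assert records[1].species_tag == "spY"


# ---------------------------------------------------------------------------
# Spliced-alignment GFF3

GMAP_TEMPLATE = """\
##gff-version 3
chr1\tgmap\tmRNA\t100\t900\t.\t+\t.\tID=t1.path1;Name=t1;identity={ident};coverage={cov}
chr1\tgmap\texon\t100\t200\t.\t+\t.\tParent=t1.path1
chr1\tgmap\texon\t400\t500\t.\t+\t.\tParent=t1.path1
chr1\tgmap\texon\t800\t900\t.\t+\t.\tParent=t1.path1
"""


def test_identity_filter_drops_path(tmp_path):
    gff = write(tmp_path / "a.gff3", GMAP_TEMPLATE.format(ident=85.0, cov=99.0))
    assert formats_io.read_gmap_gff3(gff, min_identity=0.90, min_coverage=0.70) == []


def test_three_exon_path_yields_three_ordered_blocks(tmp_path):
    gff = write(tmp_path / "a.gff3", GMAP_TEMPLATE.format(ident=99.0, cov=99.0))
    (placement,) = formats_io.read_gmap_gff3(gff)
    assert placement.transcript_id == "t1"
    assert placement.blocks == ((100, 200), (400, 500), (800, 900))
    assert placement.path_rank == 1


def test_planted_subthreshold_paths_counted(tmp_path):
    lines = ["##gff-version 3"]
    n_total, n_bad = 12, 5
    for i in range(n_total):
        ident = 50.0 if i < n_bad else 99.0
        lines.append(
            f"chr1\tgmap\tmRNA\t{100 * i + 1}\t{100 * i + 50}\t.\t+\t.\t"
            f"ID=t{i}.path1;Name=t{i};identity={ident};coverage=95.0"
        )
        lines.append(
            f"chr1\tgmap\texon\t{100 * i + 1}\t{100 * i + 50}\t.\t+\t.\tParent=t{i}.path1"
        )
    gff = write(tmp_path / "a.gff3", "\n".join(lines) + "\n")
    placements = formats_io.read_gmap_gff3(gff)
    assert len(placements) == n_total - n_bad


def test_malformed_coordinates_skipped(tmp_path, caplog):
    text = GMAP_TEMPLATE.format(ident=99.0, cov=99.0) + \
        "chr1\tgmap\texon\t900\t800\t.\t+\t.\tParent=t1.path1\n"
    gff = write(tmp_path / "a.gff3", text)
    (placement,) = formats_io.read_gmap_gff3(gff)
    assert len(placement.blocks) == 3


def test_cdna_match_dialect(tmp_path):
    text = (
        "chr1\tgmap\tcDNA_match\t100\t200\t.\t+\t.\tID=m1;Name=t9;identity=0.99;coverage=0.95\n"
        "chr1\tgmap\tcDNA_match\t400\t500\t.\t+\t.\tID=m1\n"
    )
    gff = write(tmp_path / "a.gff3", text)
    (placement,) = formats_io.read_gmap_gff3(gff)
    assert placement.transcript_id == "t9"
    assert placement.blocks == ((100, 200), (400, 500))


def test_missing_identity_defaults_to_one(tmp_path):
    text = (
        "chr1\tx\tmRNA\t10\t60\t.\t+\t.\tID=p1;Name=tA\n"
        "chr1\tx\texon\t10\t60\t.\t+\t.\tParent=p1\n"
    )
    gff = write(tmp_path / "a.gff3", text)
    (placement,) = formats_io.read_gmap_gff3(gff)
    assert placement.identity == 1.0 and placement.coverage == 1.0


def test_multipath_ranks_follow_input_order(tmp_path):
    text = (
        "chr1\tx\tmRNA\t10\t60\t.\t+\t.\tID=p1;Name=tA;identity=99;coverage=99\n"
        "chr1\tx\texon\t10\t60\t.\t+\t.\tParent=p1\n"
        "chr2\tx\tmRNA\t10\t60\t.\t+\t.\tID=p2;Name=tA;identity=98;coverage=98\n"
        "chr2\tx\texon\t10\t60\t.\t+\t.\tParent=p2\n"
    )
    gff = write(tmp_path / "a.gff3", text)
    placements = formats_io.read_gmap_gff3(gff)
    assert [p.path_rank for p in placements] == [1, 2]


# ---------------------------------------------------------------------------
# Annotation GFF3

ANNOTATION = """\
##gff-version 3
chr1\tann\tgene\t100\t900\t.\t+\t.\tID=G1
chr1\tann\tmRNA\t100\t900\t.\t+\t.\tID=m1;Parent=G1
chr1\tann\texon\t100\t200\t.\t+\t.\tParent=m1
chr1\tann\texon\t800\t900\t.\t+\t.\tParent=m1
chr1\tann\tmRNA\t100\t900\t.\t+\t.\tID=m2;Parent=G1
chr1\tann\texon\t100\t200\t.\t+\t.\tParent=m2
chr1\tann\tgene\t2000\t2900\t.\t-\t.\tID=G2
chr1\tann\tmRNA\t2000\t2900\t.\t-\t.\tID=m3;Parent=G2
chr1\tann\texon\t2000\t2100\t.\t-\t.\tParent=m3
chr1\tann\tmRNA\t2000\t2900\t.\t-\t.\tID=m4;Parent=G2
chr1\tann\texon\t2800\t2900\t.\t-\t.\tParent=m4
"""


def test_gene_groups_its_mrnas(tmp_path):
    gff = write(tmp_path / "ann.gff3", ANNOTATION)
    truth, placements = formats_io.read_annotation_loci(gff)
    assert truth.groups["G1"] == frozenset({"m1", "m2"})
    assert truth.n_groups == 2
    assert truth.groups["G2"] == frozenset({"m3", "m4"})
    by_id = {p.transcript_id: p for p in placements}
    assert by_id["m1"].blocks == ((100, 200), (800, 900))
    assert by_id["m1"].identity == 1.0 and by_id["m1"].path_rank == 1


def test_two_genes_two_isoforms_each(tmp_path):
    gff = write(tmp_path / "ann.gff3", ANNOTATION)
    truth, _ = formats_io.read_annotation_loci(gff)
    assert sorted(len(v) for v in truth.groups.values()) == [2, 2]


def test_orphan_mrna_becomes_own_locus(tmp_path):
    text = ANNOTATION + (
        "chr1\tann\tmRNA\t5000\t5100\t.\t+\t.\tID=m9\n"
        "chr1\tann\texon\t5000\t5100\t.\t+\t.\tParent=m9\n"
    )
    gff = write(tmp_path / "ann.gff3", text)
    truth, _ = formats_io.read_annotation_loci(gff)
    assert truth.groups["orphan:m9"] == frozenset({"m9"})


def test_group_count_equals_genes_with_mrna_children(tmp_path):
    # gene without any mRNA child must not form a group
    text = ANNOTATION + "chr1\tann\tgene\t9000\t9100\t.\t+\t.\tID=G_empty\n"
    gff = write(tmp_path / "ann.gff3", text)
    truth, _ = formats_io.read_annotation_loci(gff)
    assert truth.n_groups == 2


def test_fixture_gff3_locus_count(tmp_path):
    from loclust.fixtures import SimConfig, simulate

    bundle = simulate(SimConfig(seed=3, n_loci=10), outdir=tmp_path / "sim")
    truth, placements = formats_io.read_annotation_loci(bundle.paths["annotation"])
    assert truth.n_groups == 10
    assert {p.transcript_id for p in placements} == bundle.truth.item_ids()


# ---------------------------------------------------------------------------
# Ortholog pairs

def _pairs_file(tmp_path, pairs, taxa=("9606", "10090")):
    lines = ["#tax_id\tGeneID\trelationship\tOther_tax_id\tOther_GeneID"]
    for a, b in pairs:
        lines.append(f"{taxa[0]}\t{a}\tOrtholog\t{taxa[1]}\t{b}")
    return write(tmp_path / "orthologs.tsv", "\n".join(lines) + "\n")


def test_transitive_closure(tmp_path):
    path = _pairs_file(tmp_path, [("a", "b"), ("b", "c")])
    truth = formats_io.read_ortholog_pairs(path)
    assert set(truth.groups.values()) == {frozenset({"a", "b", "c"})}


def test_filtered_partner_leaves_singleton(tmp_path):
    path = _pairs_file(tmp_path, [("a", "b")])
    truth = formats_io.read_ortholog_pairs(path, species_filter={"9606"})
    assert set(truth.groups.values()) == {frozenset({"a"})}


def test_components_match_union_find_oracle(tmp_path):
    rng = random.Random(17)
    genes = [f"g{i}" for i in range(60)]
    pairs = [(rng.choice(genes), rng.choice(genes)) for _ in range(120)]
    pairs = [(a, b) for a, b in pairs if a != b]
    path = _pairs_file(tmp_path, pairs)
    truth = formats_io.read_ortholog_pairs(path)

    # independent union-find oracle
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    components: dict[str, set[str]] = {}
    for g in parent:
        components.setdefault(find(g), set()).add(g)
    assert set(truth.groups.values()) == {frozenset(c) for c in components.values()}


def test_four_planted_components(tmp_path):
    pairs = [("a", "b"), ("b", "c"), ("d", "e"), ("f", "g"), ("h", "i"), ("i", "j")]
    path = _pairs_file(tmp_path, pairs)
    truth = formats_io.read_ortholog_pairs(path)
    assert truth.n_groups == 4
    assert truth.provenance == "ortholog_pairs"


# ---------------------------------------------------------------------------
# Cluster TSV round-trip

def test_cluster_roundtrip(tmp_path):
    clustering = make_clustering(
        [
            ("c1", {"t1", "t2"}, "binned"),
            ("c2", {"t3"}, "unbinned"),
        ],
        filtered={"t4": "fragment", "t5": "chimera"},
    )
    path = tmp_path / "clusters.tsv"
    formats_io.write_clusters(clustering, path)
    back = formats_io.read_clusters(path)
    assert back.groups() == clustering.groups()
    assert dict(back.filtered) == dict(clustering.filtered)
    assert {c.cluster_id: c.flag for c in back} == {"c1": "binned", "c2": "unbinned"}


def test_empty_clustering_header_only(tmp_path):
    path = tmp_path / "clusters.tsv"
    formats_io.write_clusters(make_clustering([]), path)
    assert path.read_text().splitlines() == ["cluster_id\ttranscript_id\tbinned_flag"]
    assert len(formats_io.read_clusters(path)) == 0


def test_unknown_flag_errors(tmp_path):
    path = write(
        tmp_path / "clusters.tsv",
        "cluster_id\ttranscript_id\tbinned_flag\nc1\tt1\tbogus\n",
    )
    with pytest.raises(LoclustError, match="bogus"):
        formats_io.read_clusters(path)


def test_seven_cluster_fixture_roundtrip(tmp_path):
    groups = {f"c{i}": {f"t{i}a", f"t{i}b"} for i in range(7)}
    clustering = clustering_from_groups(groups)
    path = tmp_path / "clusters.tsv"
    formats_io.write_clusters(clustering, path)
    back = formats_io.read_clusters(path)
    assert len(back) == 7
    assert back.groups() == clustering.groups()
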