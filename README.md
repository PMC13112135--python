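# loclust

Locus-level clustering of transcripts from one or more species, based on
shared overlap of spliced alignments against one or more reference genomes.

Transcripts (gene-model CDS and/or de novo assemblies) are assigned to
genomic **bins** — intervals collecting every transcript with an exon
alignment overlapping them.  For each ordered transcript pair sharing a bin,
the **co-occurrence proportion** is the number of shared bins divided by the
first transcript's total bin count; an edge forms when either direction
reaches the threshold (default 0.66).  After removing probable **fragments**
(nodes whose relationships are one-sided against them in ≥ 50% of cases) and
**chimeras** (articulation points of a component), connected components are
emitted as *binned* locus clusters.  Transcripts with no retained genome
alignment are clustered by an internal greedy identity/coverage algorithm
(CD-HIT-like semantics; presets: plant/animal 0.98 identity, 0.4/0.4
coverage; microbial 0.98 / 0.8 / 0.8) and emitted as *unbinned* clusters.
The package also aggregates transcript-level counts to the cluster (locus)
level and scores clusterings against reference partitions with RI, ARI, NMI
and AMI.

## CLI

```sh
# generate a synthetic bundle with planted ground truth
loclust simulate --seed 7 --n-loci 20 --fragment-rate 0.2 --n-samples 3 --out-dir sim/

# cluster transcripts against one or more genomes
loclust cluster \
    --transcripts sim/transcripts.fasta \
    --alignments genome1=sim/alignments_genome1.gff3 \
    --out-dir run/
# optional: --preseed --annotation ann.gff3, --threshold, --stranded,
#           --multipath, --min-overlap, --preset microbial, --rescue-filtered

# score against a reference partition
loclust evaluate --clusters run/clusters.tsv --truth-tsv sim/truth.tsv --out report.tsv
# alternatives: --truth-gff3 annotation.gff3 | --truth-orthologs gene_orthologs.tsv
#               [--species TAG --species-map map.tsv]

# aggregate transcript counts to the locus level
loclust aggregate --clusters run/clusters.tsv --counts sim/counts.tsv --out agg.tsv
```

Outputs of `cluster`: `clusters.tsv` (cluster_id, transcript_id,
binned_flag), `clusters.filtered.tsv` (removed transcripts with reason
fragment/chimera), and `tx2gene.tsv` (TXNAME/GENEID for tximport).

## Input formats

- transcripts: FASTA; species tag from a `--species-map` sidecar TSV or from
  the identifier prefix before the first `|`.
- spliced alignments: GMAP-style GFF3 (`mRNA`/`exon` or `cDNA_match`
  features) with `identity`/`coverage` attributes (fractions or
  percentages; default 1.0 when absent).  Alignment acceptance filters
  default to identity ≥ 0.90, coverage ≥ 0.70.
- annotations: GFF3 with gene → mRNA → exon hierarchy (truth groups and bin
  pre-seeding).
- ortholog pairs: NCBI `gene_orthologs` layout; connected components become
  truth groups.

All coordinates are GFF3 1-based inclusive throughout.

## Notes and trade-offs

- Bins are strandless by default (one bin space per sequence); overlapping
  opposite-strand genes will share bins.  Use `--stranded` to split bin
  spaces per strand when alignments carry reliable strand information.
- Bins are per-genome by construction and never merge across genomes;
  transcripts aligned to several genomes are linked through co-occurrence,
  since their bin sets span all genomes.
- Only the best alignment path per transcript and genome is kept by default
  (`--multipath` keeps all retained paths); extra paths inflate a
  transcript's bin count and dilute its co-occurrence proportions.
- Chimera detection is single-pass: articulation points are collected once
  per component and removed simultaneously, without iterative re-detection.
- ARI/AMI may be negative for worse-than-chance clusterings and are
  reported as computed, never clamped.

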