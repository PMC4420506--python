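# kataclust

Detection and characterization of **clustered deaminase-induced mutations**
(kataegis-like events) in densely mutagenized genomes.

When an APOBEC/AID-family cytosine deaminase acts on a genome — for example
PmCDA1 expressed in diploid *ung1* yeast — it leaves showers of strand-
coordinated C→T and G→A substitutions concentrated near transcription start
sites. `kataclust` takes SNV call sets (VCF or TSV), a genome annotation
(GFF3 with UTRs), repeat masks (BED), the genome sequence (FASTA) and an
optional per-gene FPKM table, and provides:

- **Cluster detection** in three stages:
  1. per-chromosome UPGMA (average-linkage) hierarchical clustering of SNV
     coordinates, with flat clusters extracted by a cophenetic-distance
     criterion (default *t* = 1000 bp) — every SNV pair inside a cluster
     joins the tree below *t*;
  2. border adjustment of each cluster by re-clustering its members and
     splitting dendrogram links that are inconsistent with the links beneath
     them (threshold 0.8, depth 2);
  3. filtering: clusters touching masked regions are removed; clusters with
     more than one non-deaminase-like SNV (anything other than C→T/G→A) are
     removed, a lone one confined to a single sample is deleted; finally
     only clusters with **size ≥ 5** and **power ≥ 0.05** are kept, where

     power = size / median(consecutive inter-SNV distances)  [per bp]

- **Cluster statistics**: span, power, and *homogeneity*
  max(n_CT, n_GA)/(n_CT + n_GA) ∈ [0.5, 1] — 1 for a fully strand-polar
  cluster, 0.5 for an even C→T/G→A mixture — plus Fig-style summary grids
  and span histograms.
- **Modified rainfall plots**: log2 distance to the previous SNV against the
  chromosomal coordinate, class-colored, with mask/gap bands and guide
  lines at 10/100/500/1000 bp.
- **Genomic distribution analytics**: strand-resolved deamination
  assignment (which strand carried the deaminated C relative to
  transcription), metagene mutation-density profiles around the CDS start
  (5 bp bins) and a pre-5′-UTR / percent-normalized 5′-UTR / CDS tri-panel,
  the phi strand-bias coefficient per feature class with chi-square/Fisher
  p-values, GC-normalized sequence-context matrices around the deaminated
  cytosine, and the expression–mutation association (median FPKM by SNV
  load, rank-sum test).
- **A synthetic-data generator** producing genomes, annotations, masks,
  FPKM tables and pooled multi-clone SNV sets with planted, strand-biased,
  TSS-anchored clusters and ground truth, so the whole pipeline is testable
  end to end without external data.

## Worked example

Simulate a dataset and run the detection cascade at the default ("paper
mode") parameters:

```
$ kataclust simulate --seed 7 --out-dir sim
simulated 382 SNVs, 20 planted clusters

$ kataclust cluster --snv sim/sample1.vcf --snv sim/sample2.vcf \
    --snv sim/sample3.vcf --mask sim/masks.bed --out-prefix out/clusters
INFO kataclust: kept 18 / 185 candidate clusters

$ kataclust evaluate --clusters out/clusters.tsv --snv sim/sample1.vcf \
    --snv sim/sample2.vcf --snv sim/sample3.vcf --truth sim/truth.tsv \
    --out out/eval.tsv
precision=1.000 recall=0.950 merges=1
```

185 candidate clusters enter stage 3 (most are background singletons and
pairs); 18 survive the size ≥ 5 / power ≥ 0.05 filter. Of the 20 planted
clusters, 19 are recovered (one pair of clusters anchored to nearby genes is
found merged, which the evaluator flags), and every reported cluster
corresponds to a planted one. The first rows of `out/clusters.tsv`:

```
cluster_id    chrom start end  span size power   homogeneity majority_class
cluster_0001  chr1  6096  6192 96   12   2.4     0.6667      GA
cluster_0002  chr1  11495 11568 73  10   1.11111 0.9000      GA
```

Strand bias of the same dataset (`kataclust strand-bias ... --gff
sim/genes.gff3`): phi = 0.42 (p = 3·10⁻¹⁰) over all genic SNVs and 0.58 in
5′-UTRs — positive phi means C→T mutations concentrate in Watson-strand
genes, i.e. the deaminase hits the non-transcribed strand, strongest near
the transcription start, as planted by the generator.

The threshold sweep (`kataclust sweep`) reports how many clusters with ≥ 3
members each extraction threshold yields over 50–5000 bp; the count is flat
around *t* = 500–1000 bp (19–21 clusters) for this dataset, which is how
the 1000 bp default was chosen on real data.

Other subcommands: `rainfall`, `density` (CDS-start profile or TSS
tri-panel), `context`, `expression`. Every run writes a
`<name>.report.json` with parameters, input checksums and stage counts.

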