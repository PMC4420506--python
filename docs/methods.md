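# Methods

## Model and scope

`kataclust` analyses pooled sets of single-nucleotide variants from heavily
mutagenized genomes under a deamination readout model: in a uracil-glycosylase
deficient (*ung1*) background every cytosine deamination is fixed as a
substitution, so a C→T call marks a deaminated C on the Watson (reference)
strand and a G→A call marks one on the Crick strand. All other substitution
classes are treated as non-deaminase-like noise. The package consumes SNV
calls, annotation, masks and expression tables; it does not perform read
processing, alignment or variant calling.

Pooling clones mutagenized by the same enzyme raises cluster-detection
sensitivity at the cost of legal duplicate positions (the same site mutated
in two clones). Duplicates are kept as distinct records throughout; zero
inter-mutation distances are handled explicitly everywhere they can occur.

## Cluster detection

**Stage 1 — extraction.** SNV coordinates are clustered per chromosome with
UPGMA: the distance between clusters *u*, *v* is the mean over all cross
pairs, d(u,v) = Σᵢⱼ d(uᵢ,vⱼ)/(|u||v|). For disjoint 1-D clusters this mean
equals the difference of the cluster means, so the globally closest pair is
always adjacent in coordinate order; the implementation exploits this for an
O(n²) exact algorithm with a deterministic leftmost tie-break, emitting a
scipy-format linkage matrix. Flat clusters are extracted by a distance
criterion on the cophenetic distance (the height at which two SNVs first
share a subtree): the tree is cut at *t* = 1000 bp by default, so every
within-cluster pair joins below *t*. A unit-tested brute-force
implementation (naive O(n³) UPGMA over the full distance matrix, explicit
cophenetic matrix, union-find tree cut) reproduces the production partition
on 1000 random instances.

The extraction threshold is a tuning parameter; `threshold_sweep` counts
flat clusters with ≥ 3 members over a 50–5000 bp grid (50 bp steps) so the
plateau region can be inspected before committing to a cutoff.

**Stage 2 — border adjustment.** Each extracted cluster is re-clustered
from scratch and its fresh dendrogram walked from the root: a link is split
into its children when it is inconsistent with the links beneath it, and the
leaves of a consistent link are emitted as one subcluster. Clusters of one
or two SNVs pass through unchanged. Two link statistics are available:

- `relative` (default): the excess of the link height over the mean height
  of its descendant links within `depth` levels, as a fraction of the link
  height, (h − mean(H))/h ∈ [0, 1). At the default threshold 0.8 and depth
  2 a link splits only when it stands more than five-fold above the average
  of the links beneath it. This makes the stage a border adjustment in the
  strict sense: single-scale dense clusters (evenly spaced or uniformly
  scattered members) pass through whole, while stragglers glued on by the
  1000 bp cut and composites of well-separated blocks are cut apart.
- `standard`: the textbook inconsistency coefficient
  (h − mean(H))/sd(H) with H the heights of the link and its descendant
  links within `depth` levels (population sd; 0 when sd = 0). We do not use
  it by default because over the two or three heights a depth-2
  neighborhood contains it is scale-free — a link above two comparable
  children scores ≈ 1.0–1.41 whether the height jump is 1.5-fold or
  100-fold, and a caterpillar link scores ≈ 0.7–1.0 — so at any usable
  threshold it separates tree shapes rather than distance scales and
  fragments internally homogeneous clusters.

**Stage 3 — filtering.** (a) Clusters with any member inside a masked
(repeat/low-confidence) interval are removed. (b) In deaminase mode,
clusters with more than one non-deaminase-like SNV are removed as likely
call errors; a single such SNV confined to one sample is deleted and the
cluster kept; a single one recurring in several samples is treated
conservatively and the cluster removed (recurrence is unexplained by a
one-off call error). (c) Statistics are recomputed. (d) Clusters must have
size ≥ 5 and power ≥ 0.05 (both inclusive). (e) Per-sample SNV lists are
restored from everything surviving (a)–(b).

**Cluster statistics.** Power is size divided by the median inter-SNV
distance (per bp). The median is taken over consecutive gaps after sorting
by position — the same quantity rainfall plots display; an all-pairs option
exists behind `power_gap_mode="allpairs"`. Degenerate cases: a single-member
cluster uses a 1 bp denominator, and a zero median (duplicate positions) is
clamped to 1 bp so the filter stays meaningful. Homogeneity is
max(n_CT, n_GA)/(n_CT + n_GA), undefined when a cluster has no deaminase-like
member; non-deaminase SNVs are excluded so the statistic stays in [0.5, 1]
(at most one such member can survive deaminase-mode filtering).

## Distribution analytics

**Strand assignment.** A C→T SNV in a Watson-strand gene (or G→A in a
Crick-strand gene) is a deamination of the non-transcribed (coding) strand;
the converse pairs mark the transcribed strand. SNVs overlapping genes on
both strands, or no gene, are undefined.

**Metagene densities.** Profiles are fractions of the genome-wide SNV total
(not per-window totals), so duplicating records changes nothing and panels
from different gene sets are comparable. Offsets are measured on each
gene's own 5′→3′ axis (mirrored for Crick-strand genes), with offset 0 at
the first base of the start codon and half-open 5 bp bins [5k, 5(k+1)).
An SNV upstream of two divergent genes contributes to both windows —
consistent with the genome-wide normalization. The TSS tri-panel covers
genes with an annotated 5′-UTR of ≥ 10 bp: 5 bp bins over 300 bp upstream
of the UTR 5′-end, ten percent-of-UTR-length bins inside the UTR, and 5 bp
bins over the first 300 bp of CDS; in the pre-UTR and UTR panels SNVs that
hit a different annotated feature are excluded so the panels reflect the
promoter/UTR signal rather than neighboring genes.

**Strand bias.** Per feature class, the 2×2 table of mutation class
(C→T/G→A) against gene strand (+/−) is summarized by the phi coefficient
φ = (n₁₁n₂₂ − n₁₂n₂₁)/√(r₁r₂c₁c₂); φ > 0 means deamination prefers the
non-transcribed strand. The p-value is a 1-df chi-square test of
independence without continuity correction, replaced by Fisher's exact test
when any expected cell is below 5 (the test is not named in the source
analyses; chi-square/Fisher is the conventional pairing for 2×2 tables).

**Sequence context.** Windows of ±3 bp (configurable) around C→T/G→A sites
are oriented so the deaminated C is at offset 0 (G→A windows
reverse-complemented). Per-offset frequencies f(b) are normalized against a
background of GC fraction g (default 0.38, the yeast genome):
p(b) = (f(b)/bg(b)) / Σ f(b′)/bg(b′) with bg(C) = bg(G) = g/2. At g = 0.5
the normalization is the identity.

**Expression.** Per-gene SNV counts (gene body including UTRs) are joined
with an FPKM table (optional replicate averaging); medians are reported per
SNV-count stratum and mutated vs unmutated genes are compared with a
two-sided Wilcoxon–Mann–Whitney test. All-tied inputs are reported as
p = 1 rather than an undefined asymptotic value.

**Rainfall plots.** One point per SNV except the first per chromosome,
y = log2 of the distance to the previous SNV in the pooled set (a
per-sample mode is a matter of filtering inputs). Zero distances from
pooled duplicates are drawn at a fixed floor of −1 on the log2 axis.
Guide lines at 10/100/500/1000 bp; masks and assembly gaps as vertical
bands; optional zoom panels per highlighted region.

## Synthetic data

The generator emulates the structure the analyses assume, at a reduced
scale chosen so the full pipeline runs in seconds: one 1 Mb chromosome at
GC 0.38 with 300 non-overlapping genes (CDS 500–2000 bp, 5′-UTR 20–150 bp,
3′-UTR 20–100 bp, random strand), log-normal FPKM, ~2% of the genome
masked, 20 planted clusters and a 2·10⁻⁴/bp uniform background (~200 SNVs)
split across 3 clones — the same SNVs-per-Mb order as pooled deaminase
mutant genomes (hundreds to thousands of SNVs over ~12 Mb). Planted
clusters anchor to genes with probability proportional to FPKM (coupling
exponent 1), occupy a window of −100..0 bp relative to the CDS start, and
draw each member's strand as non-transcribed with probability p_nt = 0.8,
placing C→T only on reference C and G→A only on reference G of the window.
`sub1_mode` mimics loss of the Sub1 ssDNA-binding factor: half the clusters
move to a −250..−100 bp promoter window, the strand bias weakens
(p_nt = 0.6) and the background rate inside CDS halves.

What the generator does **not** model: chromatin, replication timing,
sequence-motif preferences beyond the deaminated C itself, per-clone
correlation structure, copy number, and calling artifacts other than a flat
OTHER-class fraction (5%). Passing recovery tests therefore demonstrate the
pipeline's correctness on data satisfying its own assumptions, not
performance on real sequencing data.

A detected cluster matches a planted one when ≥ 50% of the planted members
are among its members; precision and recall are reported over detections
and truth records respectively, and a detection matching several truths is
flagged as a merge.

## Determinism and numerical choices

Detection is fully deterministic given input order: UPGMA ties merge the
leftmost pair, candidate clusters are processed in coordinate order, and
output clusters are sorted and renumbered by (chromosome, start). The
generator drives all draws from one seeded numpy Generator in a fixed
documented order, so an identical config + seed reproduces every output
byte-identically. Test problem sizes (1 Mb genomes, ≤ 12-point oracle
instances, 10-seed recovery panels) were chosen to keep the default suite
in the tens of seconds while leaving the statistics well away from their
thresholds.

## Known limitations

- Chromosome name matching is exact; no "chrI"/"I" normalization is
  attempted by default.
- The GFF3 reader collapses multi-exon CDS features to their outer span;
  intron-aware metagene profiles are out of scope.
- Cluster detection assigns no p-values; the negative-binomial style of
  cluster calling is deliberately not implemented.
- The VCF writer emits minimal heterozygous single-sample records, which is
  all the downstream analyses consume.
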