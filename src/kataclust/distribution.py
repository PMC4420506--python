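"""Genome-wide distribution analytics for deaminase-induced SNVs.

Covers the strand-resolved assignment of deaminations (which DNA strand
carried the deaminated cytosine relative to transcription), metagene
mutation-density profiles anchored at the CDS start or at the 5'-UTR
(pre-UTR / percent-normalized UTR / CDS tri-panel), the phi strand-bias
statistic per feature class, GC-normalized sequence-context matrices, and the
expression-mutation association.

Density profiles are fractions of the genome-wide SNV total (not per-window
totals), so duplicating every record leaves the profile unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io import (FeatureAssignment, GeneModel, GenomeAnnotation, MutationClass,
                 SnvRecord, assign_feature, revcomp)

STRAND_LAYERS = ("all", "non_transcribed", "transcribed")


def deaminated_strand(mclass: MutationClass, gene_strand: str) -> str:
    """'non_transcribed' / 'transcribed' for a deamination in a gene.

    The deaminated C lies on the Watson strand for CT and on the Crick strand
    for GA; a +-strand gene transcribes from the Crick template, so its
    non-transcribed (coding) strand is Watson.
    """
    if mclass is MutationClass.CT:
        return "non_transcribed" if gene_strand == "+" else "transcribed"
    if mclass is MutationClass.GA:
        return "transcribed" if gene_strand == "+" else "non_transcribed"
    return "undefined"


def assign_deaminated_strand(snv: SnvRecord, annotation: GenomeAnnotation) -> str:
    """Strand assignment for an SNV overlapping exactly one gene; 'undefined'
    for OTHER-class SNVs, both-strand overlaps, or intergenic positions."""
    if snv.mclass is MutationClass.OTHER:
        return "undefined"
    genes = annotation.overlapping(snv.chrom, snv.pos)
    strands = {g.strand for g in genes}
    if len(strands) != 1:
        return "undefined"
    return deaminated_strand(snv.mclass, strands.pop())


# ---------------------------------------------------------------------------
# Density profiles
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Binned fractions of the genome-wide SNV total near an anchor."""

    anchor: str
    bin_edges: np.ndarray  # offsets (bp) or percent edges, length nbins+1
    values: np.ndarray     # fraction of all SNVs in the analyzed set
    strand_layer: str = "all"
    n_total: int = 0       # denominator (genome-wide SNV count)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start": self.bin_edges[:-1],
            "bin_end": self.bin_edges[1:],
            "fraction": self.values,
            "strand_layer": self.strand_layer,
        })

    @property
    def mass(self) -> float:
        return float(self.values.sum())


def _gene_offset(gene: GeneModel, pos: int, origin: int) -> int:
    """Gene-axis offset of `pos` from the genomic `origin` base (offset 0 at
    the origin, increasing 5'->3' of the gene)."""
    return pos - origin if gene.strand == "+" else origin - pos


def _anchor_origin(gene: GeneModel, anchor: str) -> Optional[int]:
    if anchor == "cds_start":
        return gene.cds_start if gene.strand == "+" else gene.cds_end
    if anchor == "tss":
        if gene.utr5 is None:
            return None
        return gene.utr5[0] if gene.strand == "+" else gene.utr5[1]
    raise ValueError(anchor)


def _window_tree(annotation: GenomeAnnotation, anchor: str, lo: int, hi: int,
                 genes: Optional[Sequence[GeneModel]] = None) -> dict[str, IntervalTree]:
    """Per-chromosome tree mapping genomic positions to (gene, origin) for the
    gene-axis offset window [lo, hi]."""
    trees: dict[str, IntervalTree] = {}
    for g in (genes if genes is not None else annotation.genes):
        origin = _anchor_origin(g, anchor)
        if origin is None:
            continue
        if g.strand == "+":
            gstart, gend = origin + lo, origin + hi
        else:
            gstart, gend = origin - hi, origin - lo
        if gend < 1:
            continue
        trees.setdefault(g.chrom, IntervalTree()).addi(
            max(0, gstart - 1), gend, (g, origin))
    return trees


def _bin_index(offset: float, lo: int, width: int) -> int:
    return int(math.floor((offset - lo) / width))


def density_around_cds_start(snvs: Iterable[SnvRecord], annotation: GenomeAnnotation,
                             window: tuple[int, int] = (-600, 600), bin_width: int = 5,
                             strand_layer: str = "all") -> DensityProfile:
    """Metagene SNV density around the start codon (offset 0 = first base of
    the CDS; half-open bins [k*w, (k+1)*w) on the gene's own 5'->3' axis).

    Every SNV contributes one count per overlapping gene window; values are
    fractions of the genome-wide SNV total. ``strand_layer`` restricts counts
    to deaminations of the chosen strand relative to the anchor gene.
    """
    lo, hi = window
    snvs = list(snvs)
    n_total = len(snvs)
    n_bins = (hi - lo) // bin_width
    edges = np.arange(lo, hi + bin_width, bin_width, dtype=float)
    counts = np.zeros(n_bins)
    coding = [g for g in annotation.genes if g.feature_kind == "protein_coding"]
    trees = _window_tree(annotation, "cds_start", lo, hi - 1, genes=coding)
    for snv in snvs:
        tree = trees.get(snv.chrom)
        if tree is None:
            continue
        for iv in tree.at(snv.pos - 1):
            gene, origin = iv.data
            if strand_layer != "all" and \
                    deaminated_strand(snv.mclass, gene.strand) != strand_layer:
                continue
            off = _gene_offset(gene, snv.pos, origin)
            if lo <= off < hi:
                counts[_bin_index(off, lo, bin_width)] += 1
    values = counts / n_total if n_total else counts
    return DensityProfile("cds_start", edges, values, strand_layer, n_total)


@dataclass
class TriPanelDensity:
    """Pre-5'-UTR / percent-normalized 5'-UTR / CDS-start density panels."""

    pre_utr: DensityProfile
    utr5: DensityProfile
    cds: DensityProfile
    n_genes: int = 0


def tss_tripanel_density(snvs: Iterable[SnvRecord], annotation: GenomeAnnotation,
                         pre_len: int = 300, cds_len: int = 300, bin_width: int = 5,
                         utr_bins: int = 10, strand_layer: str = "all",
                         ) -> TriPanelDensity:
    """Tri-panel metagene density for genes with an annotated 5'-UTR of at
    least 10 bp: bp bins upstream of the UTR 5'-end, percent-of-UTR-length
    bins inside the UTR, and bp bins over the first ``cds_len`` of the CDS.

    For the pre-UTR and UTR panels, SNVs that also hit a different annotated
    feature are excluded. All values are fractions of the genome-wide total.
    """
    snvs = list(snvs)
    n_total = len(snvs)
    eligible = [g for g in annotation.genes
                if g.feature_kind == "protein_coding" and g.utr5_length >= 10]
    pre_counts = np.zeros(pre_len // bin_width)
    utr_counts = np.zeros(utr_bins)
    cds_counts = np.zeros(cds_len // bin_width)

    pre_trees = _window_tree(annotation, "tss", -pre_len, -1, genes=eligible)
    cds_trees = _window_tree(annotation, "cds_start", 0, cds_len - 1, genes=eligible)
    utr_trees: dict[str, IntervalTree] = {}
    for g in eligible:
        utr_trees.setdefault(g.chrom, IntervalTree()).addi(
            g.utr5[0] - 1, g.utr5[1], g)

    def _other_feature_hit(snv: SnvRecord, own: GeneModel) -> bool:
        for g2 in annotation.overlapping(snv.chrom, snv.pos):
            if g2.gene_id != own.gene_id:
                return True
        return False

    def _layer_ok(snv: SnvRecord, gene: GeneModel) -> bool:
        return strand_layer == "all" or \
            deaminated_strand(snv.mclass, gene.strand) == strand_layer

    for snv in snvs:
        tree = pre_trees.get(snv.chrom)
        if tree is not None:
            for iv in tree.at(snv.pos - 1):
                gene, origin = iv.data
                off = _gene_offset(gene, snv.pos, origin)
                if -pre_len <= off <= -1 and not _other_feature_hit(snv, gene) \
                        and _layer_ok(snv, gene):
                    pre_counts[_bin_index(off, -pre_len, bin_width)] += 1
        tree = utr_trees.get(snv.chrom)
        if tree is not None:
            for iv in tree.at(snv.pos - 1):
                gene = iv.data
                if _other_feature_hit(snv, gene) or not _layer_ok(snv, gene):
                    continue
                start5 = gene.utr5[0] if gene.strand == "+" else gene.utr5[1]
                off = _gene_offset(gene, snv.pos, start5)
                pct = 100.0 * off / gene.utr5_length
                utr_counts[min(int(pct // (100 / utr_bins)), utr_bins - 1)] += 1
        tree = cds_trees.get(snv.chrom)
        if tree is not None:
            for iv in tree.at(snv.pos - 1):
                gene, origin = iv.data
                off = _gene_offset(gene, snv.pos, origin)
                if 0 <= off < cds_len and _layer_ok(snv, gene):
                    cds_counts[_bin_index(off, 0, bin_width)] += 1

    denom = n_total if n_total else 1
    pre = DensityProfile("pre_utr5", np.arange(-pre_len, 1, bin_width, dtype=float),
                         pre_counts / denom, strand_layer, n_total)
    utr = DensityProfile("utr5_percent", np.linspace(0, 100, utr_bins + 1),
                         utr_counts / denom, strand_layer, n_total)
    cds = DensityProfile("cds_from_start", np.arange(0, cds_len + 1, bin_width, dtype=float),
                         cds_counts / denom, strand_layer, n_total)
    return TriPanelDensity(pre, utr, cds, n_genes=len(eligible))


# ---------------------------------------------------------------------------
# Strand-bias phi
# ---------------------------------------------------------------------------

@dataclass
class StrandBiasResult:
    """2x2 contingency (CT/GA x gene strand +/-) with its phi coefficient.

    phi > 0 indicates C->T mutations preferentially hitting genes on the
    Watson strand, i.e. deamination of the non-transcribed strand.
    """

    feature_category: Optional[str]
    table: np.ndarray  # rows CT, GA; cols +, -
    phi: Optional[float]
    p_value: Optional[float]
    test: str = "chi2"

    @property
    def n(self) -> int:
        return int(self.table.sum())


def phi_coefficient(table: np.ndarray) -> Optional[float]:
    """phi = (n11*n22 - n12*n21) / sqrt(r1*r2*c1*c2); None on a zero margin."""
    t = np.asarray(table, dtype=float)
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    denom = r[0] * r[1] * c[0] * c[1]
    if denom == 0:
        return None
    return float((t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]) / math.sqrt(denom))


def _phi_p_value(table: np.ndarray) -> tuple[Optional[float], str]:
    t = np.asarray(table, dtype=float)
    n = t.sum()
    if n == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return None, "none"
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    if (expected < 5).any():
        _, p = stats.fisher_exact(t)
        return float(p), "fisher"
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(p), "chi2"


def strand_bias_phi(snvs: Iterable[SnvRecord], annotation: GenomeAnnotation,
                    category: Optional[str] = None) -> StrandBiasResult:
    """Strand-specificity of deaminations within a feature class.

    Rows of the table are the mutation class (CT, GA), columns the strand of
    the overlapping gene (+, -). SNVs with both-strand or no gene context are
    excluded, as are OTHER-class SNVs. ``category=None`` pools all genic
    categories.
    """
    table = np.zeros((2, 2))
    for snv in snvs:
        if snv.mclass is MutationClass.OTHER:
            continue
        fa = assign_feature(snv, annotation)
        if fa.gene_strand_context not in {"plus_only", "minus_only"}:
            continue
        if category is not None:
            if fa.category != category:
                continue
        elif fa.category == "intergenic":
            continue
        row = 0 if snv.mclass is MutationClass.CT else 1
        col = 0 if fa.gene_strand_context == "plus_only" else 1
        table[row, col] += 1
    phi = phi_coefficient(table)
    p, test = (None, "none") if phi is None else _phi_p_value(table)
    return StrandBiasResult(category, table, phi, p, test)


# ---------------------------------------------------------------------------
# Sequence-context matrix
# ---------------------------------------------------------------------------

_BASE_ORDER = ("A", "C", "G", "T")


@dataclass
class ContextMatrix:
    """Per-offset nucleotide composition around deaminated cytosines.

    All windows are oriented so the deaminated C sits at offset 0 (G->A
    records are reverse-complemented); probabilities are normalized against a
    background composition of the given GC fraction.
    """

    halfwidth: int
    gc: float
    counts: pd.DataFrame       # index A,C,G,T; columns offsets -w..w
    frequencies: pd.DataFrame
    probabilities: pd.DataFrame
    n_used: int = 0
    n_skipped: int = 0


def normalize_context(frequencies: pd.DataFrame, gc: float = 0.38) -> pd.DataFrame:
    """Background-normalized probabilities per offset:
    p(b) = (f(b)/bg(b)) / sum_b' f(b')/bg(b') with bg(C)=bg(G)=gc/2 and
    bg(A)=bg(T)=(1-gc)/2. At gc=0.5 this is the identity."""
    bg = pd.Series({"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2})
    ratio = frequencies.div(bg, axis=0)
    total = ratio.sum(axis=0)
    total = total.replace(0, np.nan)
    return ratio.div(total, axis=1).fillna(0.0)


def context_matrix(snvs: Iterable[SnvRecord], genome_fasta, halfwidth: int = 3,
                   gc: float = 0.38) -> ContextMatrix:
    """Oriented sequence-context matrix around CT/GA SNVs.

    ``genome_fasta`` is a pyfaidx.Fasta (or a path to a FASTA file). Records
    whose window runs past a contig end are skipped and counted.
    """
    if isinstance(genome_fasta, (str, bytes)) or hasattr(genome_fasta, "__fspath__"):
        from pyfaidx import Fasta

        genome_fasta = Fasta(str(genome_fasta))
    w = halfwidth
    offsets = list(range(-w, w + 1))
    counts = np.zeros((4, len(offsets)))
    n_used = n_skipped = 0
    for snv in snvs:
        if snv.mclass is MutationClass.OTHER:
            continue
        try:
            contig = genome_fasta[snv.chrom]
        except KeyError:
            n_skipped += 1
            continue
        lo = snv.pos - 1 - w
        hi = snv.pos + w
        if lo < 0 or hi > len(contig):
            n_skipped += 1
            continue
        seq = str(contig[lo:hi]).upper()
        if snv.mclass is MutationClass.GA:
            seq = revcomp(seq)
        if any(b not in "ACGT" for b in seq):
            n_skipped += 1
            continue
        for j, b in enumerate(seq):
            counts[_BASE_ORDER.index(b), j] += 1
        n_used += 1
    counts_df = pd.DataFrame(counts, index=list(_BASE_ORDER), columns=offsets)
    col_tot = counts_df.sum(axis=0).replace(0, np.nan)
    freqs = counts_df.div(col_tot, axis=1).fillna(0.0)
    probs = normalize_context(freqs, gc=gc)
    return ContextMatrix(w, gc, counts_df, freqs, probs, n_used, n_skipped)


# ---------------------------------------------------------------------------
# Expression association
# ---------------------------------------------------------------------------

@dataclass
class ExpressionAssociation:
    """Per-gene SNV load vs expression (FPKM)."""

    per_gene: pd.DataFrame         # gene_id, snv_count, fpkm
    median_by_count: pd.Series     # median FPKM per SNV-count stratum
    median_mutated: float
    median_unmutated: float
    statistic: float
    p_value: float
    n_missing_fpkm: int = 0


def read_fpkm_table(path, replicate_mean: bool = False) -> pd.Series:
    """Two-column TSV (gene_id, fpkm); with ``replicate_mean`` extra numeric
    columns are averaged per gene."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if replicate_mean and df.shape[1] > 2:
        return df.set_index(0).mean(axis=1).rename("fpkm")
    return df.set_index(0)[1].rename("fpkm")


def expression_association(snvs: Iterable[SnvRecord], annotation: GenomeAnnotation,
                           fpkm: pd.Series) -> ExpressionAssociation:
    """Median FPKM stratified by per-gene SNV count (gene body incl. UTRs)
    and a two-sided rank-sum test of mutated vs unmutated genes."""
    counts = {g.gene_id: 0 for g in annotation.genes}
    for snv in snvs:
        for g in annotation.overlapping(snv.chrom, snv.pos):
            counts[g.gene_id] += 1
    rows = []
    missing = 0
    for gid, cnt in counts.items():
        if gid in fpkm.index:
            rows.append((gid, cnt, float(fpkm[gid])))
        else:
            missing += 1
    if not rows:
        raise ValueError("no annotated gene has an FPKM value")
    df = pd.DataFrame(rows, columns=["gene_id", "snv_count", "fpkm"])
    med = df.groupby("snv_count")["fpkm"].median()
    mutated = df.loc[df.snv_count > 0, "fpkm"]
    unmutated = df.loc[df.snv_count == 0, "fpkm"]
    if len(mutated) == 0 or len(unmutated) == 0:
        stat, p = float("nan"), float("nan")
    elif mutated.nunique() == 1 and unmutated.nunique() == 1 \
            and mutated.iloc[0] == unmutated.iloc[0]:
        stat, p = len(mutated) * len(unmutated) / 2.0, 1.0
    else:
        stat, p = stats.mannwhitneyu(mutated, unmutated, alternative="two-sided")
    return ExpressionAssociation(
        per_gene=df, median_by_count=med,
        median_mutated=float(mutated.median()) if len(mutated) else float("nan"),
        median_unmutated=float(unmutated.median()) if len(unmutated) else float("nan"),
        statistic=float(stat), p_value=float(p), n_missing_fpkm=missing)
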