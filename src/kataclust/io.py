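"""Data model and I/O for dense SNV call sets and their genome annotation.

The objects here carry everything downstream analyses need: single-nucleotide
variants with their deamination class (C->T on the Watson strand, G->A on the
Crick strand, or anything else), pooled multi-clone variant sets, gene models
with UTRs, repeat/low-confidence masks, and the feature assignment of each SNV.

Coordinates are 1-based inclusive internally (the VCF/GFF3 convention); BED
output converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

import enum
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class MutationClass(str, enum.Enum):
    """Substitution class relative to the Watson (reference) strand.

    CT marks deamination of a cytosine on the Watson strand, GA deamination of
    a cytosine on the Crick strand (read as G->A on Watson). Everything else
    is OTHER (non-deaminase-like).
    """

    CT = "CT"
    GA = "GA"
    OTHER = "OTHER"


def classify_substitution(ref: str, alt: str) -> MutationClass:
    """Classify a single-base substitution as CT, GA or OTHER.

    Raises ValueError for non-ACGT bases or ref == alt.
    """
    ref = ref.upper()
    alt = alt.upper()
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"non-ACGT base in substitution {ref}->{alt}")
    if ref == alt:
        raise ValueError(f"ref equals alt ({ref})")
    if ref == "C" and alt == "T":
        return MutationClass.CT
    if ref == "G" and alt == "A":
        return MutationClass.GA
    return MutationClass.OTHER


@dataclass(frozen=True, slots=True)
class SnvRecord:
    """One substitution call: chromosome, 1-based position, ref/alt, sample."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str = "sample"

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        classify_substitution(self.ref, self.alt)  # validates bases

    @property
    def mclass(self) -> MutationClass:
        return classify_substitution(self.ref, self.alt)


def _sort_key(r: SnvRecord):
    return (r.chrom, r.pos)


@dataclass
class PooledVariantSet:
    """SNV records from one or more clones, sorted by (chrom, pos).

    Duplicate positions from different samples are retained as distinct
    records; zero inter-mutation distances are legal downstream.
    """

    label: str
    snvs: list[SnvRecord]
    sample_ids: set[str] = field(default_factory=set)
    n_skipped: int = 0

    @classmethod
    def from_records(cls, records: Iterable[SnvRecord], label: str = "pooled",
                     n_skipped: int = 0) -> "PooledVariantSet":
        snvs = sorted(records, key=_sort_key)
        return cls(label=label, snvs=snvs,
                   sample_ids={r.sample_id for r in snvs}, n_skipped=n_skipped)

    def __len__(self) -> int:
        return len(self.snvs)

    def __iter__(self):
        return iter(self.snvs)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.snvs:
            seen.setdefault(r.chrom, None)
        return list(seen)

    def by_chromosome(self) -> dict[str, list[SnvRecord]]:
        out: dict[str, list[SnvRecord]] = {}
        for r in self.snvs:
            out.setdefault(r.chrom, []).append(r)
        return out


def pool_samples(sample_sets: Sequence[PooledVariantSet], label: str) -> PooledVariantSet:
    """Union of several per-clone SNV sets (duplicates at the same position
    from different samples retained), sorted by (chrom, pos)."""
    if not sample_sets:
        raise ValueError("pool_samples requires at least one sample set")
    records: list[SnvRecord] = []
    for s in sample_sets:
        records.extend(s.snvs)
    pooled = PooledVariantSet.from_records(records, label=label)
    pooled.n_skipped = sum(s.n_skipped for s in sample_sets)
    return pooled


# ---------------------------------------------------------------------------
# SNV readers / writers
# ---------------------------------------------------------------------------

def read_snvs(path: str | os.PathLike, fmt: Optional[str] = None,
              sample_label: Optional[str] = None) -> PooledVariantSet:
    """Read a single-sample SNV set from VCF or the 5-column TSV dialect
    (chrom, pos 1-based, ref, alt, sample; '#' comments).

    Multi-allelic records and indels are skipped; the skip count is logged and
    stored on the returned set as ``n_skipped``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() in {".vcf", ".gz", ".bcf"} else "tsv"
    if fmt == "vcf":
        return _read_vcf(path, sample_label)
    if fmt == "tsv":
        return _read_tsv(path, sample_label)
    raise ValueError(f"unknown SNV format {fmt!r}")


def _read_vcf(path: Path, sample_label: Optional[str]) -> PooledVariantSet:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample_label is None:
        sample_label = vcf.samples[0] if vcf.samples else path.stem
    records: list[SnvRecord] = []
    skipped = 0
    for v in vcf:
        alts = v.ALT
        if len(alts) != 1 or len(v.REF) != 1 or len(alts[0]) != 1 \
                or v.REF.upper() not in _BASES or alts[0].upper() not in _BASES:
            skipped += 1
            continue
        records.append(SnvRecord(v.CHROM, v.POS, v.REF.upper(), alts[0].upper(),
                                 sample_id=sample_label))
    if skipped:
        log.info("read_snvs(%s): skipped %d non-SNV/multi-allelic records", path, skipped)
    return PooledVariantSet.from_records(records, label=sample_label, n_skipped=skipped)


def _read_tsv(path: Path, sample_label: Optional[str]) -> PooledVariantSet:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "pos", "ref", "alt", "sample"],
                     dtype={"chrom": str, "ref": str, "alt": str, "sample": str})
    records: list[SnvRecord] = []
    skipped = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            skipped += 1
            continue
        try:
            pos = int(row.pos)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: unparseable position on data line {i}") from exc
        sample = sample_label or (str(row.sample) if pd.notna(row.sample) else path.stem)
        records.append(SnvRecord(str(row.chrom), pos, ref, alt, sample_id=sample))
    if skipped:
        log.info("read_snvs(%s): skipped %d non-SNV rows", path, skipped)
    label = sample_label or (records[0].sample_id if records else path.stem)
    return PooledVariantSet.from_records(records, label=label, n_skipped=skipped)


def write_snvs_tsv(snvs: Iterable[SnvRecord], path: str | os.PathLike) -> None:
    """Write SNVs in the 5-column TSV dialect."""
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\tsample\n")
        for r in sorted(snvs, key=_sort_key):
            fh.write(f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.sample_id}\n")


# ---------------------------------------------------------------------------
# Genome annotation
# ---------------------------------------------------------------------------

Interval = tuple[int, int]  # 1-based inclusive


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand, CDS and optional UTR intervals (1-based inclusive).

    For ncRNA features the CDS interval holds the feature span.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' (Watson) or '-' (Crick)
    cds_start: int
    cds_end: int
    utr5: Optional[Interval] = None
    utr3: Optional[Interval] = None
    feature_kind: str = "protein_coding"

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.cds_end < self.cds_start:
            raise ValueError("empty CDS interval")

    @property
    def tx_start(self) -> int:
        lo = self.cds_start
        for iv in (self.utr5, self.utr3):
            if iv is not None:
                lo = min(lo, iv[0])
        return lo

    @property
    def tx_end(self) -> int:
        hi = self.cds_end
        for iv in (self.utr5, self.utr3):
            if iv is not None:
                hi = max(hi, iv[1])
        return hi

    @property
    def utr5_length(self) -> int:
        return 0 if self.utr5 is None else self.utr5[1] - self.utr5[0] + 1

    def contains(self, pos: int) -> bool:
        return self.tx_start <= pos <= self.tx_end


class GenomeAnnotation:
    """Interval-queryable collection of gene models."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        self._by_id: dict[str, GeneModel] = {}
        for g in self.genes:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            # half-open 0-based for the tree
            tree.addi(g.tx_start - 1, g.tx_end, g)
            self._by_id[g.gene_id] = g

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        """All genes whose body (incl. UTRs) covers 1-based position ``pos``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(pos - 1)), key=lambda g: g.gene_id)

    def overlapping_range(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose body overlaps the 1-based inclusive range [start, end]."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start - 1, end)),
                      key=lambda g: g.gene_id)


_NCRNA_TYPES = {"ncRNA", "ncRNA_gene", "tRNA", "rRNA", "snoRNA", "snRNA"}


def read_gff(path: str | os.PathLike) -> GenomeAnnotation:
    """Load gene models from GFF3 (gene/CDS/five_prime_UTR/three_prime_UTR
    plus top-level ncRNA features)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        gid = feat.id
        cds = [(c.start, c.end) for c in db.children(feat, featuretype="CDS")]
        utr5s = [(c.start, c.end) for c in db.children(feat, featuretype="five_prime_UTR")]
        utr3s = [(c.start, c.end) for c in db.children(feat, featuretype="three_prime_UTR")]
        if cds:
            cds_start = min(s for s, _ in cds)
            cds_end = max(e for _, e in cds)
        else:
            cds_start, cds_end = feat.start, feat.end
        genes.append(GeneModel(
            gene_id=gid, chrom=feat.seqid, strand=feat.strand,
            cds_start=cds_start, cds_end=cds_end,
            utr5=(min(s for s, _ in utr5s), max(e for _, e in utr5s)) if utr5s else None,
            utr3=(min(s for s, _ in utr3s), max(e for _, e in utr3s)) if utr3s else None,
        ))
    for nctype in sorted(_NCRNA_TYPES):
        try:
            feats = list(db.features_of_type(nctype))
        except Exception:
            feats = []
        for feat in feats:
            genes.append(GeneModel(gene_id=feat.id, chrom=feat.seqid,
                                   strand=feat.strand if feat.strand in "+-" else "+",
                                   cds_start=feat.start, cds_end=feat.end,
                                   feature_kind="ncRNA"))
    return GenomeAnnotation(genes)


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

class MaskSet:
    """Per-chromosome repeat / low-confidence intervals (0-based half-open)."""

    def __init__(self, intervals: Optional[dict[str, list[tuple[int, int]]]] = None):
        self._trees: dict[str, IntervalTree] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                self.add_many(chrom, ivs)

    def add_many(self, chrom: str, intervals: Iterable[tuple[int, int]]) -> None:
        tree = self._trees.setdefault(chrom, IntervalTree())
        for start, end in intervals:
            if end > start:
                tree.addi(start, end)

    def contains(self, chrom: str, pos: int) -> bool:
        """Is the 1-based position ``pos`` inside a masked interval?"""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.at(pos - 1))

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end) for iv in tree)

    def chromosomes(self) -> list[str]:
        return sorted(self._trees)

    @property
    def empty(self) -> bool:
        return all(len(t) == 0 for t in self._trees.values())


def read_bed_mask(path: str | os.PathLike) -> MaskSet:
    """Read BED3+ intervals into a MaskSet."""
    masks = MaskSet()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            masks.add_many(parts[0], [(int(parts[1]), int(parts[2]))])
    return masks


def write_bed_mask(masks: MaskSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in masks.chromosomes():
            for start, end in masks.intervals(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Feature assignment
# ---------------------------------------------------------------------------

#: category priority for the unique per-SNV assignment
CATEGORY_PRIORITY = ("CDS", "UTR5", "UTR3", "ncRNA", "intergenic")


@dataclass(frozen=True)
class FeatureAssignment:
    snv: SnvRecord
    category: str  # one of CATEGORY_PRIORITY
    gene_strand_context: str  # plus_only / minus_only / both / none


def _categories_for(gene: GeneModel, pos: int) -> list[str]:
    cats = []
    if gene.feature_kind == "ncRNA":
        if gene.cds_start <= pos <= gene.cds_end:
            cats.append("ncRNA")
        return cats
    if gene.cds_start <= pos <= gene.cds_end:
        cats.append("CDS")
    if gene.utr5 and gene.utr5[0] <= pos <= gene.utr5[1]:
        cats.append("UTR5")
    if gene.utr3 and gene.utr3[0] <= pos <= gene.utr3[1]:
        cats.append("UTR3")
    return cats


def assign_feature(snv: SnvRecord, annotation: GenomeAnnotation) -> FeatureAssignment:
    """Unique genomic-feature category for an SNV under the priority
    CDS > UTR5 > UTR3 > ncRNA > intergenic, plus the strand context of all
    overlapping gene bodies."""
    genes = annotation.overlapping(snv.chrom, snv.pos)
    cats: set[str] = set()
    strands: set[str] = set()
    for g in genes:
        cats.update(_categories_for(g, snv.pos))
        strands.add(g.strand)
    category = next((c for c in CATEGORY_PRIORITY if c in cats), "intergenic")
    if not strands:
        context = "none"
    elif strands == {"+"}:
        context = "plus_only"
    elif strands == {"-"}:
        context = "minus_only"
    else:
        context = "both"
    return FeatureAssignment(snv=snv, category=category, gene_strand_context=context)


# ---------------------------------------------------------------------------
# Cluster output
# ---------------------------------------------------------------------------

def write_clusters(clusters, out_prefix: str | os.PathLike) -> tuple[Path, Path]:
    """Write detected clusters as BED6 (0-based half-open, score =
    round(1000*power) capped at 1000) and a companion TSV with the cluster
    statistics. Returns the (bed_path, tsv_path) pair."""
    out_prefix = Path(out_prefix)
    bed_path = out_prefix.with_suffix(".bed")
    tsv_path = out_prefix.with_suffix(".tsv")
    with open(bed_path, "w") as bed:
        bed.write('track name="kataclust" description="mutation clusters"\n')
        for c in clusters:
            score = min(1000, int(round(1000 * c.power)))
            bed.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.cluster_id}\t{score}\t.\n")
    with open(tsv_path, "w") as tsv:
        tsv.write("cluster_id\tchrom\tstart\tend\tspan\tsize\tpower\thomogeneity"
                  "\tmajority_class\tn_CT\tn_GA\tn_OTHER\n")
        for c in clusters:
            n_ct = sum(1 for m in c.members if m.mclass is MutationClass.CT)
            n_ga = sum(1 for m in c.members if m.mclass is MutationClass.GA)
            n_other = c.size - n_ct - n_ga
            hom = "NA" if c.homogeneity is None else f"{c.homogeneity:.4f}"
            tsv.write(f"{c.cluster_id}\t{c.chrom}\t{c.start}\t{c.end}\t{c.span}"
                      f"\t{c.size}\t{c.power:.6g}\t{hom}\t{c.majority_class}"
                      f"\t{n_ct}\t{n_ga}\t{n_other}\n")
    return bed_path, tsv_path
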