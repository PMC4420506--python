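"""Synthetic genomes and SNV sets with planted mutation clusters.

The generator emulates the structure the analyses assume: a random genome at
yeast-like GC content, non-overlapping genes with 5'/3'-UTRs on both strands,
log-normal per-gene expression, repeat masks, and pooled diploid SNV sets
made of (i) strand-polar deamination clusters planted near transcription
starts of expression-weighted genes and (ii) a uniform background over the
unmasked genome. Every planted cluster is recorded as ground truth so
detection can be scored by precision/recall.

A single seeded numpy Generator drives all draws in a fixed order, so an
identical config + seed reproduces every output byte-identically.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import (GeneModel, GenomeAnnotation, MaskSet, MutationClass,
                 PooledVariantSet, SnvRecord, write_bed_mask)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults give one 1 Mb chromosome with 300 genes and ~300 SNVs (20
    planted clusters plus ~200 background), matching the per-genome mutation
    density scale of heavily deaminase-mutagenized yeast (hundreds to a few
    thousand SNVs over ~12 Mb).
    """

    # genome
    n_chromosomes: int = 1
    chrom_length: int = 1_000_000
    gc: float = 0.38
    # genes
    n_genes: int = 300
    cds_length: tuple[int, int] = (500, 2000)
    utr5_length: tuple[int, int] = (20, 150)
    utr3_length: tuple[int, int] = (20, 100)
    p_plus_strand: float = 0.5
    # expression
    fpkm_log_mean: float = 3.5
    fpkm_log_sd: float = 1.0
    # masks
    n_masks: int = 20
    mask_fraction: float = 0.02
    # mutation model
    background_rate: float = 2e-4  # per bp -> ~200 SNVs on 1 Mb
    other_fraction: float = 0.05
    n_clusters: int = 20
    cluster_size: tuple[int, int] = (5, 15)
    cluster_window: tuple[int, int] = (-100, 0)   # bp relative to CDS start
    sub1_window: tuple[int, int] = (-250, -100)
    p_nt: float = 0.8              # P(clustered deamination hits non-transcribed strand)
    sub1_p_nt: float = 0.6
    expression_coupling: float = 1.0
    sub1_mode: bool = False
    sub1_cds_rate_scale: float = 0.5
    n_samples: int = 3
    seed: int = 0

    def __post_init__(self):
        for p in (self.gc, self.p_plus_strand, self.p_nt, self.sub1_p_nt,
                  self.other_fraction, self.mask_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted cluster."""

    cluster_id: str
    chrom: str
    start: int
    end: int
    positions: tuple[int, ...]
    classes: tuple[str, ...]
    anchor_gene: str


@dataclass
class Reference:
    """In-memory synthetic reference: sequences, annotation, masks, FPKM."""

    sequences: dict[str, str]
    annotation: GenomeAnnotation
    masks: MaskSet
    fpkm: pd.Series

    def base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos - 1]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def generate_reference(config: SimulationConfig,
                       rng: Optional[np.random.Generator] = None) -> Reference:
    """Random genome + non-overlapping gene models + masks + FPKM table."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    masks = MaskSet()
    L = config.chrom_length
    genes_per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    genes_per_chrom[-1] += config.n_genes - sum(genes_per_chrom)
    gene_no = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        sequences[chrom] = _random_sequence(rng, L, config.gc)
        ng = genes_per_chrom[ci]
        if ng:
            cds = rng.integers(config.cds_length[0], config.cds_length[1] + 1, ng)
            u5 = rng.integers(config.utr5_length[0], config.utr5_length[1] + 1, ng)
            u3 = rng.integers(config.utr3_length[0], config.utr3_length[1] + 1, ng)
            totals = cds + u5 + u3
            slack = L - int(totals.sum())
            if slack < ng + 1:
                raise ValueError("genes cannot be placed without overlap at the "
                                 "requested density")
            gaps = rng.multinomial(slack, np.full(ng + 1, 1 / (ng + 1)))
            cursor = 1
            for gi in range(ng):
                cursor += int(gaps[gi])
                start = cursor
                end = start + int(totals[gi]) - 1
                strand = "+" if rng.random() < config.p_plus_strand else "-"
                gene_no += 1
                if strand == "+":
                    utr5 = (start, start + int(u5[gi]) - 1)
                    cds_iv = (utr5[1] + 1, utr5[1] + int(cds[gi]))
                    utr3 = (cds_iv[1] + 1, end)
                else:
                    utr3 = (start, start + int(u3[gi]) - 1)
                    cds_iv = (utr3[1] + 1, utr3[1] + int(cds[gi]))
                    utr5 = (cds_iv[1] + 1, end)
                genes.append(GeneModel(
                    gene_id=f"gene{gene_no:04d}", chrom=chrom, strand=strand,
                    cds_start=cds_iv[0], cds_end=cds_iv[1], utr5=utr5, utr3=utr3))
                cursor = end + 1
        # masks: uniform random intervals
        n_masks = config.n_masks // config.n_chromosomes or config.n_masks
        if config.mask_fraction > 0 and n_masks > 0:
            mlen = max(1, int(config.mask_fraction * L / n_masks))
            starts = rng.integers(0, L - mlen, n_masks)
            masks.add_many(chrom, [(int(s), int(s) + mlen) for s in starts])
    fpkm = pd.Series(rng.lognormal(config.fpkm_log_mean, config.fpkm_log_sd,
                                   len(genes)),
                     index=[g.gene_id for g in genes], name="fpkm")
    return Reference(sequences, GenomeAnnotation(genes), masks, fpkm)


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

def _class_for(target_strand: str, gene_strand: str) -> MutationClass:
    """Substitution class realizing a deamination of the given strand
    (non_transcribed / transcribed) in a gene of the given orientation."""
    if (target_strand == "non_transcribed") == (gene_strand == "+"):
        return MutationClass.CT  # deaminated C on Watson
    return MutationClass.GA


def _window_coords(gene: GeneModel, window: tuple[int, int]) -> tuple[int, int]:
    lo, hi = window
    if gene.strand == "+":
        return gene.cds_start + lo, gene.cds_start + hi
    return gene.cds_end - hi, gene.cds_end - lo


def generate_mutations(reference: Reference, config: SimulationConfig,
                       rng: Optional[np.random.Generator] = None,
                       ) -> tuple[dict[str, list[SnvRecord]], list[TruthRecord]]:
    """Plant strand-biased deamination clusters near CDS starts of
    expression-weighted genes plus uniform background SNVs, distributed
    across ``n_samples`` clones.

    Clustered deaminations only occur at C positions of the deaminated
    strand, so CT records always sit on a reference C and GA records on a G.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    sample_names = [f"sample{j + 1}" for j in range(config.n_samples)]
    samples: dict[str, list[SnvRecord]] = {s: [] for s in sample_names}
    truth: list[TruthRecord] = []

    coding = [g for g in reference.annotation.genes
              if g.feature_kind == "protein_coding"]
    weights = np.asarray([float(reference.fpkm[g.gene_id]) for g in coding])
    weights = weights ** config.expression_coupling
    weights = weights / weights.sum()
    p_nt = config.sub1_p_nt if config.sub1_mode else config.p_nt

    for k in range(config.n_clusters):
        placed = False
        for _attempt in range(200):
            gene = coding[int(rng.choice(len(coding), p=weights))]
            window = config.cluster_window
            if config.sub1_mode and rng.random() < 0.5:
                window = config.sub1_window
            wstart, wend = _window_coords(gene, window)
            L = len(reference.sequences[gene.chrom])
            if wstart < 2 or wend > L - 1:
                continue
            if any(reference.masks.contains(gene.chrom, p)
                   for p in (wstart, wend, (wstart + wend) // 2)):
                continue
            seq = reference.sequences[gene.chrom]
            c_sites = [p for p in range(wstart, wend + 1) if seq[p - 1] == "C"]
            g_sites = [p for p in range(wstart, wend + 1) if seq[p - 1] == "G"]
            size = int(rng.integers(config.cluster_size[0], config.cluster_size[1] + 1))
            members: list[tuple[int, MutationClass]] = []
            for _m in range(size):
                target = "non_transcribed" if rng.random() < p_nt else "transcribed"
                mc = _class_for(target, gene.strand)
                pool = c_sites if mc is MutationClass.CT else g_sites
                if not pool:
                    pool = g_sites if mc is MutationClass.CT else c_sites
                    mc = MutationClass.GA if mc is MutationClass.CT else MutationClass.CT
                if not pool:
                    break
                pos = pool.pop(int(rng.integers(len(pool))))
                members.append((pos, mc))
            if len(members) < size:
                continue
            members.sort()
            recs = []
            for pos, mc in members:
                ref, alt = ("C", "T") if mc is MutationClass.CT else ("G", "A")
                sample = sample_names[int(rng.integers(config.n_samples))]
                recs.append(SnvRecord(gene.chrom, pos, ref, alt, sample_id=sample))
            for r in recs:
                samples[r.sample_id].append(r)
            truth.append(TruthRecord(
                cluster_id=f"truth_{k + 1:03d}", chrom=gene.chrom,
                start=members[0][0], end=members[-1][0],
                positions=tuple(p for p, _ in members),
                classes=tuple(mc.value for _, mc in members),
                anchor_gene=gene.gene_id))
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place cluster {k}: no eligible "
                               "C/G sites after bounded retries")

    # background: uniform over the unmasked genome
    chroms = list(reference.sequences)
    lengths = np.asarray([len(reference.sequences[c]) for c in chroms], dtype=float)
    n_bg = int(rng.poisson(config.background_rate * lengths.sum()))
    placed_bg = 0
    attempts = 0
    while placed_bg < n_bg and attempts < 100 * n_bg + 1000:
        attempts += 1
        chrom = chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]
        pos = int(rng.integers(1, len(reference.sequences[chrom]) + 1))
        if reference.masks.contains(chrom, pos):
            continue
        if config.sub1_mode and config.sub1_cds_rate_scale < 1:
            in_cds = any(g.cds_start <= pos <= g.cds_end
                         for g in reference.annotation.overlapping(chrom, pos))
            if in_cds and rng.random() > config.sub1_cds_rate_scale:
                continue
        ref = reference.base(chrom, pos)
        if rng.random() < config.other_fraction:
            choices = [b for b in "ACGT"
                       if b != ref and (ref, b) not in {("C", "T"), ("G", "A")}]
            alt = choices[int(rng.integers(len(choices)))]
        elif ref == "C":
            alt = "T"
        elif ref == "G":
            alt = "A"
        else:
            continue  # deaminase-like background needs a C or G
        sample = sample_names[int(rng.integers(config.n_samples))]
        samples[sample].append(SnvRecord(chrom, pos, ref, alt, sample_id=sample))
        placed_bg += 1
    for s in samples.values():
        s.sort(key=lambda r: (r.chrom, r.pos))
    return samples, truth


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reference: Reference
    samples: dict[str, list[SnvRecord]]
    truth: list[TruthRecord]

    def pooled(self, label: str = "pooled") -> PooledVariantSet:
        records = [r for recs in self.samples.values() for r in recs]
        return PooledVariantSet.from_records(records, label=label)


def simulate_dataset(config: Optional[SimulationConfig] = None,
                     seed: Optional[int] = None, **overrides) -> SimulatedDataset:
    """Generate a full dataset from one seeded random stream."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    reference = generate_reference(config, rng)
    samples, truth = generate_mutations(reference, config, rng)
    return SimulatedDataset(config, reference, samples, truth)


# ---------------------------------------------------------------------------
# Detection scoring
# ---------------------------------------------------------------------------

@dataclass
class DetectionEvaluation:
    precision: Optional[float]
    recall: Optional[float]
    matches: pd.DataFrame  # truth_id, detected_id (or NA), overlap fraction
    merged_detections: list[str] = field(default_factory=list)


def evaluate_detection(detected: Sequence, truth: Sequence[TruthRecord],
                       min_overlap: float = 0.5) -> DetectionEvaluation:
    """Score detected clusters against planted truth.

    A detected cluster matches a truth record when at least ``min_overlap``
    of the truth members (by chrom+position) are among the detected members.
    Precision is the matched fraction of detections, recall the matched
    fraction of truth records; either is None when its denominator is empty.
    A detection matching several truth records is flagged as a merge.
    """
    det_positions = [
        (d, {(d.chrom, m.pos) for m in d.members}) for d in detected]
    rows = []
    matched_det: set[int] = set()
    det_hits: dict[int, int] = {}
    n_truth_matched = 0
    for t in truth:
        tset = {(t.chrom, p) for p in t.positions}
        best = None
        for i, (d, dset) in enumerate(det_positions):
            frac = len(tset & dset) / len(tset)
            if frac >= min_overlap and (best is None or frac > best[1]):
                best = (i, frac)
        if best is not None:
            i, frac = best
            matched_det.add(i)
            det_hits[i] = det_hits.get(i, 0) + 1
            n_truth_matched += 1
            rows.append((t.cluster_id, det_positions[i][0].cluster_id, frac))
        else:
            rows.append((t.cluster_id, None, 0.0))
    merged = [det_positions[i][0].cluster_id
              for i, n in sorted(det_hits.items()) if n > 1]
    precision = len(matched_det) / len(detected) if detected else None
    recall = n_truth_matched / len(truth) if truth else None
    matches = pd.DataFrame(rows, columns=["truth_id", "detected_id", "overlap"])
    return DetectionEvaluation(precision, recall, matches, merged)


# ---------------------------------------------------------------------------
# Writers (plain-text formats only)
# ---------------------------------------------------------------------------

def write_reference(reference: Reference, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write genome.fa / genes.gff3 / masks.bed / fpkm.tsv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"fasta": out / "genome.fa", "gff": out / "genes.gff3",
             "mask": out / "masks.bed", "fpkm": out / "fpkm.tsv"}
    with open(paths["fasta"], "w") as fh:
        for chrom, seq in reference.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, seq in reference.sequences.items():
            fh.write(f"##sequence-region {chrom} 1 {len(seq)}\n")
        for g in sorted(reference.annotation.genes,
                        key=lambda g: (g.chrom, g.tx_start)):
            gid = g.gene_id
            fh.write(f"{g.chrom}\tkataclust\tgene\t{g.tx_start}\t{g.tx_end}\t.\t"
                     f"{g.strand}\t.\tID={gid}\n")
            if g.utr5:
                fh.write(f"{g.chrom}\tkataclust\tfive_prime_UTR\t{g.utr5[0]}\t"
                         f"{g.utr5[1]}\t.\t{g.strand}\t.\tID={gid}.utr5;Parent={gid}\n")
            fh.write(f"{g.chrom}\tkataclust\tCDS\t{g.cds_start}\t{g.cds_end}\t.\t"
                     f"{g.strand}\t0\tID={gid}.cds;Parent={gid}\n")
            if g.utr3:
                fh.write(f"{g.chrom}\tkataclust\tthree_prime_UTR\t{g.utr3[0]}\t"
                         f"{g.utr3[1]}\t.\t{g.strand}\t.\tID={gid}.utr3;Parent={gid}\n")
    write_bed_mask(reference.masks, paths["mask"])
    with open(paths["fpkm"], "w") as fh:
        for gid, val in reference.fpkm.items():
            fh.write(f"{gid}\t{val:.4f}\n")
    return paths


def write_sample_vcfs(samples: dict[str, list[SnvRecord]], reference: Reference,
                      out_dir: str | os.PathLike) -> dict[str, Path]:
    """One minimal VCF 4.2 per sample (heterozygous diploid calls)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample, records in samples.items():
        path = out / f"{sample}.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom, length in reference.chrom_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     f"{sample}\n")
            for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
                fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                         "GT\t0/1\n")
        paths[sample] = path
    return paths


def write_truth(truth: Sequence[TruthRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#cluster_id\tchrom\tstart\tend\tpositions\tclasses\tanchor_gene\n")
        for t in truth:
            fh.write(f"{t.cluster_id}\t{t.chrom}\t{t.start}\t{t.end}\t"
                     f"{','.join(map(str, t.positions))}\t{','.join(t.classes)}\t"
                     f"{t.anchor_gene}\n")


def read_truth(path: str | os.PathLike) -> list[TruthRecord]:
    truth = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cid, chrom, start, end, positions, classes, anchor = \
                line.rstrip("\n").split("\t")
            truth.append(TruthRecord(
                cid, chrom, int(start), int(end),
                tuple(int(p) for p in positions.split(",")),
                tuple(classes.split(",")), anchor))
    return truth
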