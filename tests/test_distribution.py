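"""Strand assignment, metagene densities, phi, context and expression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import kataclust as kc
from kataclust.distribution import (deaminated_strand, normalize_context,
                                    phi_coefficient)
from kataclust.io import MutationClass


class TestDeaminatedStrand:
    @pytest.mark.parametrize("mclass,strand,expected", [
        (MutationClass.CT, "+", "non_transcribed"),
        (MutationClass.GA, "+", "transcribed"),
        (MutationClass.CT, "-", "transcribed"),
        (MutationClass.GA, "-", "non_transcribed"),
    ])
    def test_mapping(self, mclass, strand, expected):
        assert deaminated_strand(mclass, strand) == expected

    def test_involution_under_joint_flip(self):
        """Complementing the class while flipping the gene strand preserves
        the assignment."""
        flip = {MutationClass.CT: MutationClass.GA,
                MutationClass.GA: MutationClass.CT}
        for mc in (MutationClass.CT, MutationClass.GA):
            for s in "+-":
                assert deaminated_strand(mc, s) == \
                    deaminated_strand(flip[mc], "-" if s == "+" else "+")

    def test_ambiguous_contexts_undefined(self):
        plus = kc.GeneModel("gp", "chr1", "+", 1000, 2000)
        minus = kc.GeneModel("gm", "chr1", "-", 1500, 2500)
        ann = kc.GenomeAnnotation([plus, minus])
        assert kc.assign_deaminated_strand(
            kc.SnvRecord("chr1", 1700, "C", "T"), ann) == "undefined"
        assert kc.assign_deaminated_strand(
            kc.SnvRecord("chr1", 1200, "A", "G"), ann) == "undefined"
        assert kc.assign_deaminated_strand(
            kc.SnvRecord("chr1", 1200, "C", "T"), ann) == "non_transcribed"


def _one_gene_annotation(strand="+", chrom="chr1"):
    if strand == "+":
        g = kc.GeneModel("g1", chrom, "+", 2000, 3000, utr5=(1900, 1999),
                         utr3=(3001, 3100))
    else:
        g = kc.GeneModel("g1", chrom, "-", 2000, 3000, utr5=(3001, 3100),
                         utr3=(1900, 1999))
    return kc.GenomeAnnotation([g])


class TestCdsStartDensity:
    def test_upstream_only_snvs(self):
        ann = _one_gene_annotation("+")
        snvs = [kc.SnvRecord("chr1", 2000 + off, "C", "T")
                for off in range(-100, 0)]
        prof = kc.density_around_cds_start(snvs, ann)
        edges = prof.bin_edges
        in_cds = prof.values[edges[:-1] >= 0]
        assert in_cds.sum() == 0
        assert prof.mass == pytest.approx(1.0)

    def test_minus_strand_offsets_mirrored(self):
        ann = _one_gene_annotation("-")
        # gene 5'->3' offset -1 is one base downstream-in-reference: 3001
        prof = kc.density_around_cds_start(
            [kc.SnvRecord("chr1", 3001, "C", "T")], ann)
        i = int(np.argmax(prof.values))
        assert (prof.bin_edges[i], prof.bin_edges[i + 1]) == (-5, 0)

    def test_normalized_by_genomewide_total(self):
        ann = _one_gene_annotation("+")
        snvs = [kc.SnvRecord("chr1", 1990, "C", "T"),
                kc.SnvRecord("chr1", 500_000, "C", "T")]  # outside any window
        prof = kc.density_around_cds_start(snvs, ann)
        assert prof.mass == pytest.approx(0.5)

    def test_duplicating_records_leaves_fractions_unchanged(self, dataset):
        ann = dataset.reference.annotation
        snvs = list(dataset.pooled())
        a = kc.density_around_cds_start(snvs, ann)
        b = kc.density_around_cds_start(snvs + snvs, ann)
        assert np.allclose(a.values, b.values)

    def test_uniform_snvs_give_flat_profile(self):
        """Uniformly placed mutations show no anchor enrichment beyond
        binomial noise."""
        rng = np.random.default_rng(42)
        genes = [kc.GeneModel(f"g{i}", "chr1", "+", s, s + 999)
                 for i, s in enumerate(range(10_000, 400_000, 4000))]
        ann = kc.GenomeAnnotation(genes)
        n = 30_000
        snvs = [kc.SnvRecord("chr1", int(p), "C", "T")
                for p in rng.integers(5000, 405_000, n)]
        prof = kc.density_around_cds_start(snvs, ann)
        p_bin = prof.values.mean()  # expected per-bin fraction under uniformity
        se = np.sqrt(p_bin * (1 - p_bin) / n)
        assert np.all(np.abs(prof.values - p_bin) < 4 * se)


class TestTriPanel:
    def test_snv_at_tss_lands_in_first_utr_bin(self):
        ann = _one_gene_annotation("+")
        tri = kc.tss_tripanel_density([kc.SnvRecord("chr1", 1900, "C", "T")], ann)
        assert tri.utr5.values[0] == pytest.approx(1.0)
        assert tri.pre_utr.mass == 0

    def test_snv_just_upstream_in_last_pre_bin(self):
        ann = _one_gene_annotation("+")
        tri = kc.tss_tripanel_density([kc.SnvRecord("chr1", 1899, "C", "T")], ann)
        assert tri.pre_utr.values[-1] == pytest.approx(1.0)

    def test_percent_normalized_utr_bin(self):
        """UTR of length 100, SNV at internal offset 50 -> 50-60% bin."""
        ann = _one_gene_annotation("+")
        tri = kc.tss_tripanel_density([kc.SnvRecord("chr1", 1950, "C", "T")], ann)
        assert tri.utr5.values[5] == pytest.approx(1.0)

    def test_short_utrs_excluded(self):
        g = kc.GeneModel("g1", "chr1", "+", 2000, 3000, utr5=(1995, 1999))
        tri = kc.tss_tripanel_density([kc.SnvRecord("chr1", 1996, "C", "T")],
                                      kc.GenomeAnnotation([g]))
        assert tri.n_genes == 0
        assert tri.utr5.mass == 0

    def test_pre_utr_excludes_snvs_in_other_features(self):
        ann = kc.GenomeAnnotation([
            kc.GeneModel("g1", "chr1", "+", 2000, 3000, utr5=(1900, 1999)),
            kc.GeneModel("g2", "chr1", "-", 900, 1850, utr5=(1851, 1890)),
        ])
        # 40 bp upstream of g1's TSS but inside g2's UTR -> excluded
        tri = kc.tss_tripanel_density([kc.SnvRecord("chr1", 1860, "C", "T")], ann)
        assert tri.pre_utr.mass == 0


class TestPhi:
    @pytest.mark.parametrize("table,expected", [
        ([[40, 10], [10, 40]], 0.6),
        ([[25, 25], [25, 25]], 0.0),
        ([[50, 0], [0, 50]], 1.0),
    ])
    def test_direct_formula(self, table, expected):
        assert phi_coefficient(np.array(table)) == pytest.approx(expected)

    def test_zero_margin_undefined(self):
        assert phi_coefficient(np.array([[0, 0], [10, 5]])) is None

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 40)] * 4))
    def test_phi_equals_pearson_of_indicators(self, cells):
        n11, n12, n21, n22 = cells
        x = np.repeat([0, 0, 1, 1], [n11, n12, n21, n22])
        y = np.repeat([0, 1, 0, 1], [n11, n12, n21, n22])
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        r = stats.pearsonr(x, y).statistic
        assert phi_coefficient(np.array([[n11, n12], [n21, n22]])) == \
            pytest.approx(r)

    def test_strand_bias_direction(self):
        """CT in + genes / GA in - genes (non-transcribed deamination)
        gives phi > 0."""
        genes = [kc.GeneModel(f"gp{i}", "chr1", "+", 1000 + 5000 * i,
                              2000 + 5000 * i) for i in range(5)]
        genes += [kc.GeneModel(f"gm{i}", "chr1", "-", 100_000 + 5000 * i,
                               101_000 + 5000 * i) for i in range(5)]
        ann = kc.GenomeAnnotation(genes)
        snvs = []
        for g in genes:
            ref, alt = ("C", "T") if g.strand == "+" else ("G", "A")
            snvs += [kc.SnvRecord("chr1", g.cds_start + j, ref, alt)
                     for j in range(10)]
        res = kc.strand_bias_phi(snvs, ann)
        assert res.phi == pytest.approx(1.0)
        assert res.p_value < 1e-6

    def test_small_counts_use_fisher(self):
        g = kc.GeneModel("gp", "chr1", "+", 1000, 2000)
        g2 = kc.GeneModel("gm", "chr1", "-", 5000, 6000)
        ann = kc.GenomeAnnotation([g, g2])
        snvs = [kc.SnvRecord("chr1", 1001, "C", "T"),
                kc.SnvRecord("chr1", 1002, "G", "A"),
                kc.SnvRecord("chr1", 5001, "C", "T"),
                kc.SnvRecord("chr1", 5002, "G", "A")]
        res = kc.strand_bias_phi(snvs, ann)
        assert res.test == "fisher"


class TestContext:
    def test_closed_forms(self):
        freqs = pd.DataFrame(0.25, index=list("ACGT"), columns=[-1, 0, 1])
        # gc = 0.5: normalization is the identity
        assert np.allclose(normalize_context(freqs, gc=0.5), freqs)
        # uniform frequencies at gc = 0.38
        p = normalize_context(freqs, gc=0.38)
        assert p.loc["C", 0] == pytest.approx(0.31, abs=0.005)
        assert p.loc["A", 0] == pytest.approx(0.19, abs=0.005)

    def test_degenerate_offset(self):
        freqs = pd.DataFrame(0.0, index=list("ACGT"), columns=[0])
        freqs.loc["A", 0] = 1.0
        assert normalize_context(freqs, gc=0.38).loc["A", 0] == pytest.approx(1.0)

    def test_center_is_always_c_after_orientation(self, dataset, dataset_files):
        cm = kc.context_matrix(dataset.pooled(), dataset_files["fasta"])
        assert cm.probabilities.loc["C", 0] == pytest.approx(1.0)
        assert cm.n_used > 0
        # every offset's probabilities sum to 1
        assert np.allclose(cm.probabilities.sum(axis=0), 1.0)

    def test_ga_records_reverse_complemented(self, tmp_path):
        fa = tmp_path / "ref.fa"
        fa.write_text(">chr1\nAATTGACGGT\n")
        # G at 1-based pos 8; window pos 6..10 = ACGGT -> revcomp ACCGT
        cm = kc.context_matrix([kc.SnvRecord("chr1", 8, "G", "A")], fa,
                               halfwidth=2)
        assert cm.counts.loc["C", 0] == 1
        assert cm.counts.loc["C", -1] == 1
        assert cm.counts.loc["G", 1] == 1

    def test_contig_edge_skipped(self, tmp_path):
        fa = tmp_path / "ref.fa"
        fa.write_text(">chr1\nCCCCC\n")
        cm = kc.context_matrix([kc.SnvRecord("chr1", 1, "C", "T")], fa,
                               halfwidth=3)
        assert cm.n_used == 0 and cm.n_skipped == 1


class TestExpression:
    def test_separated_groups(self):
        genes = [kc.GeneModel(f"g{i}", "chr1", "+", 1000 + 2000 * i,
                              1999 + 2000 * i) for i in range(10)]
        ann = kc.GenomeAnnotation(genes)
        fpkm = pd.Series([100.0] * 5 + [10.0] * 5,
                         index=[g.gene_id for g in genes])
        snvs = [kc.SnvRecord("chr1", genes[i].cds_start + 5, "C", "T")
                for i in range(5)]
        res = kc.expression_association(snvs, ann, fpkm)
        assert res.median_mutated == 100.0
        assert res.median_unmutated == 10.0
        assert res.p_value < 0.05

    def test_identical_fpkm_gives_p_one(self):
        genes = [kc.GeneModel(f"g{i}", "chr1", "+", 1000 + 2000 * i,
                              1999 + 2000 * i) for i in range(6)]
        ann = kc.GenomeAnnotation(genes)
        fpkm = pd.Series(7.0, index=[g.gene_id for g in genes])
        snvs = [kc.SnvRecord("chr1", genes[0].cds_start, "C", "T")]
        res = kc.expression_association(snvs, ann, fpkm)
        assert res.median_mutated == res.median_unmutated
        assert res.p_value == 1.0

    def test_strata_cover_all_genes(self, dataset):
        res = kc.expression_association(dataset.pooled(),
                                        dataset.reference.annotation,
                                        dataset.reference.fpkm)
        strata_total = res.per_gene.groupby("snv_count").size().sum()
        assert strata_total == len(dataset.reference.annotation)

    def test_no_overlap_raises(self):
        ann = kc.GenomeAnnotation([kc.GeneModel("g1", "chr1", "+", 100, 200)])
        with pytest.raises(ValueError):
            kc.expression_association([], ann, pd.Series(dtype=float))
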