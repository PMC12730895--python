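"""Biomarker derivations: burden, entropy, flags, divergence, expression."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from motiscore import (
    GranthamMatrix,
    IntervalSet,
    build_panel,
    compute_tmb,
    cxcl_combined,
    detect_allele_loss,
    expression_markers,
    hed,
    neoantigen_burden,
    resistance_flag,
    response_flag,
    tcr_entropy,
)
from motiscore.biomarkers import cpm, groove_sequences_for
from motiscore.errors import (
    AlignmentError,
    ConfigurationError,
    DataConsistencyError,
    DataConsistencyError as _DCE,
    EvaluationError,
    IntegrityError,
)
from motiscore.types import CnvCall, HlaGenotype, NeoantigenCandidate, TcrClone

from conftest import make_variant


def homo_del(gene, clonality=0.9):
    return CnvCall("chr1", 0, 1000, copy_number=0, clonality=clonality,
                   loglikelihood=500.0, genes=(gene,))


class TestTmb:
    def test_simple_ratio(self, one_mb_region):
        region = IntervalSet.from_tuples([("chr1", 0, 10_000_000)])
        variants = [make_variant(pos=i + 1, impact="moderate") for i in range(30)]
        assert compute_tmb(variants, region) == pytest.approx(3.0)

    def test_region_mask(self, one_mb_region):
        inside = [make_variant(pos=i + 1) for i in range(3)]
        outside = [make_variant(chrom="chr9", pos=i + 1) for i in range(2)]
        assert compute_tmb(inside + outside, one_mb_region) == pytest.approx(3.0)

    def test_impact_classification(self, one_mb_region):
        variants = (
            [make_variant(pos=i + 1, impact="high") for i in range(4)]
            + [make_variant(pos=i + 10, impact="moderate") for i in range(3)]
            + [make_variant(pos=i + 20, impact="synonymous_or_lower") for i in range(3)]
            + [make_variant(pos=i + 30, impact="protein_altering") for i in range(2)]
        )
        # only strictly-more-severe-than-protein-altering counts: 4 + 3
        assert compute_tmb(variants, one_mb_region) == pytest.approx(7.0)

    def test_empty_region_undefined(self):
        with pytest.raises(EvaluationError):
            compute_tmb([], IntervalSet())

    @settings(derandomize=True, max_examples=25)
    @given(st.randoms(use_true_random=False))
    def test_permutation_invariant_and_additive_over_partition(self, rnd):
        variants = [
            make_variant(pos=p, impact="moderate")
            for p in range(1, 41)
        ]
        rnd.shuffle(variants)
        left = IntervalSet.from_tuples([("chr1", 0, 500_000)])
        right = IntervalSet.from_tuples([("chr1", 500_000, 1_000_000)])
        whole = IntervalSet.from_tuples([("chr1", 0, 1_000_000)])
        n_whole = compute_tmb(variants, whole) * 1.0  # per-Mb over 1 Mb = count
        n_parts = (
            compute_tmb(variants, left) * 0.5 + compute_tmb(variants, right) * 0.5
        )
        assert n_whole == pytest.approx(n_parts)


class TestNeoantigenBurden:
    def genotype(self, lost=None):
        return HlaGenotype(
            alleles={"A": ("A*01:01", "A*02:01"), "B": ("B*07:02", "B*08:01"),
                     "C": ("C*04:01", "C*07:01")},
            lost_allele=lost or {},
        )

    def cand(self, allele="A*01:01", affinity=100.0, rna=5):
        return NeoantigenCandidate("SIINFEKL", allele, affinity, rna)

    def test_strict_affinity_threshold(self):
        cands = [self.cand(affinity=a) for a in (100.0, 499.0, 500.0, 1000.0)]
        assert neoantigen_burden(cands, self.genotype()) == 2

    def test_rna_support_required(self):
        assert neoantigen_burden([self.cand(rna=0)], self.genotype()) == 0
        assert neoantigen_burden([self.cand(rna=1)], self.genotype()) == 1

    def test_allele_loss_restricts_to_retained(self):
        genotype = self.genotype(lost={"A": 0})  # A*01:01 lost
        lost_bound = self.cand("A*01:01")
        retained_bound = self.cand("A*02:01")
        other_locus = self.cand("B*07:02")
        assert neoantigen_burden([lost_bound], genotype) == 0
        assert neoantigen_burden([retained_bound], genotype) == 1
        assert neoantigen_burden([other_locus], genotype) == 1

    def test_loss_flag_never_increases_burden(self):
        cands = [self.cand("A*01:01"), self.cand("A*02:01"), self.cand("B*07:02")]
        without = neoantigen_burden(cands, self.genotype())
        with_loss = neoantigen_burden(cands, self.genotype(lost={"A": 0}))
        assert with_loss <= without

    def test_unknown_allele_is_data_error(self):
        with pytest.raises(DataConsistencyError):
            neoantigen_burden([self.cand("A*99:99")], self.genotype())


class TestTcrEntropy:
    def clones(self, counts, chain="alpha"):
        return [TcrClone(chain, f"CDR{i}", c) for i, c in enumerate(counts)]

    def test_uniform_counts(self):
        assert tcr_entropy(self.clones([2, 2, 2, 2])) == pytest.approx(math.log(4))

    def test_single_clone_zero(self):
        assert tcr_entropy(self.clones([10])) == 0.0

    def test_hand_computed_mixture(self):
        expected = -(0.5 * math.log(0.5) + 0.3 * math.log(0.3) + 0.2 * math.log(0.2))
        assert tcr_entropy(self.clones([5, 3, 2])) == pytest.approx(expected, abs=1e-4)

    def test_singletons_dropped(self):
        assert tcr_entropy(self.clones([1, 1, 7])) == 0.0

    def test_beta_chains_ignored(self):
        mixed = self.clones([5, 3, 2]) + self.clones([9, 9], chain="beta")
        assert tcr_entropy(mixed) == tcr_entropy(self.clones([5, 3, 2]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(2, 50), min_size=2, max_size=20))
    def test_bounded_by_log_clone_count(self, counts):
        h = tcr_entropy(self.clones(counts))
        assert -1e-12 <= h <= math.log(len(counts)) + 1e-12

    def test_maximum_at_uniform(self):
        assert tcr_entropy(self.clones([7] * 6)) == pytest.approx(math.log(6))


class TestResistanceFlag:
    def test_clonal_b2m_hit(self):
        v = make_variant(gene="B2M", impact="high", vaf=0.45, tumor_depth=100)
        assert resistance_flag([v], [], tumor_clonality=0.5) == -1  # 0.45 >= 0.4

    def test_subclonal_hit_ignored(self):
        v = make_variant(gene="B2M", impact="high", vaf=0.30, tumor_depth=100)
        assert resistance_flag([v], [], tumor_clonality=0.5) == 0

    def test_no_alterations(self):
        v = make_variant(gene="KRAS", impact="high", vaf=0.5)
        assert resistance_flag([v], [], tumor_clonality=0.5) == 0

    def test_cmc_annotation_suffices(self):
        v = make_variant(gene="TAP1", impact="moderate", vaf=0.5, cmc=True)
        assert resistance_flag([v], [], tumor_clonality=0.5) == -1

    def test_calx_alias_resolves_to_canx(self):
        v = make_variant(gene="CALX", impact="high", vaf=0.5)
        assert resistance_flag([v], [], tumor_clonality=0.5) == -1

    def test_homozygous_deletion_main_clone(self):
        assert resistance_flag([], [homo_del("B2M", clonality=0.9)], 0.5) == -1
        assert resistance_flag([], [homo_del("B2M", clonality=0.1)], 0.5) == 0

    def test_invalid_clonality(self):
        with pytest.raises(ConfigurationError):
            resistance_flag([], [], tumor_clonality=0.0)


class TestResponseFlag:
    def test_low_vaf_still_counts(self):
        v = make_variant(gene="LRP1B", impact="high", cmc=True, vaf=0.06,
                         tumor_depth=100, alt_reads=6)
        assert response_flag([v], []) == 1

    def test_unclear_significance_excluded(self):
        v = make_variant(gene="LRP1B", impact="moderate", cmc=False, vaf=0.5)
        assert response_flag([v], []) == 0
        # high impact without CMC is also insufficient
        v2 = make_variant(gene="LRP1B", impact="high", cmc=False, vaf=0.5)
        assert response_flag([v2], []) == 0

    def test_homozygous_deletion_any_clonality(self):
        assert response_flag([], [homo_del("LRP1B", clonality=0.05)]) == 1

    def test_no_events(self):
        assert response_flag([], []) == 0


class TestAlleleLoss:
    def genotype(self):
        return HlaGenotype(alleles={"A": ("A*01:01", "A*02:01")})

    def ratios(self, r1=1.0, r2=1.0):
        return {"A": (r1, r2)}

    def test_deleting_cnv_at_min_clonality(self):
        cnv = CnvCall("chr6", 0, 1000, copy_number=1, clonality=0.25,
                      loglikelihood=500.0, genes=("HLA-A",))
        loss = detect_allele_loss(self.genotype(), [cnv], self.ratios(0.9, 1.0))
        assert loss["A"] == 0  # smaller ratio allele lost

    def test_cnv_below_clonality_ignored(self):
        cnv = CnvCall("chr6", 0, 1000, copy_number=1, clonality=0.24,
                      loglikelihood=500.0, genes=("HLA-A",))
        assert detect_allele_loss(self.genotype(), [cnv], self.ratios())["A"] is None

    def test_ratio_deviation_triggers_loss(self):
        # |1.0 - 0.55| / 1.0 = 0.45 > 0.40
        loss = detect_allele_loss(self.genotype(), [], self.ratios(1.0, 0.55))
        assert loss["A"] == 1

    def test_small_deviation_no_loss(self):
        loss = detect_allele_loss(self.genotype(), [], self.ratios(1.0, 0.9))
        assert loss["A"] is None


class TestHed:
    def geno(self, a1="A*01:01", a2="A*02:01", seqs=None, lost=None):
        g = HlaGenotype(
            alleles={"A": (a1, a2)},
            lost_allele=lost or {},
            groove_seqs=seqs or {},
        )
        return g

    def test_homozygous_locus_zero(self):
        g = self.geno(a1="A*01:01", a2="A*01:01", seqs={"A": ("ACD", "ACD")})
        assert hed(g)["A"] == 0.0

    def test_loss_flag_zero(self):
        g = self.geno(seqs={"A": ("ACD", "AEF")}, lost={"A": 1})
        assert hed(g)["A"] == 0.0

    def test_single_substitution_normalized_by_length(self):
        g = self.geno(seqs={"A": ("ASD", "ALD")})  # Ser<->Leu at one of 3 sites
        matrix = GranthamMatrix()
        assert hed(g)["A"] == pytest.approx(matrix.distance("S", "L") / 3)

    def test_symmetric_in_allele_order(self):
        g1 = self.geno(seqs={"A": ("ASDW", "ALDC")})
        g2 = self.geno(a1="A*02:01", a2="A*01:01", seqs={"A": ("ALDC", "ASDW")})
        assert hed(g1)["A"] == pytest.approx(hed(g2)["A"])

    def test_zero_iff_identical_sequences(self):
        g = self.geno(seqs={"A": ("ACDEF", "ACDEF")})
        assert hed(g)["A"] == 0.0
        g2 = self.geno(seqs={"A": ("ACDEF", "ACDEW")})
        assert hed(g2)["A"] > 0.0

    def test_unequal_groove_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            self.geno(seqs={"A": ("ACD", "AC")})

    def test_packaged_groove_table_mean_over_loci(self):
        alleles = {"A": ("A*01:01", "A*02:01"), "B": ("B*07:02", "B*08:01"),
                   "C": ("C*04:01", "C*07:01")}
        g = HlaGenotype(alleles=alleles, groove_seqs=groove_sequences_for(alleles))
        result = hed(g)
        assert result["mean"] == pytest.approx(
            np.mean([result["A"], result["B"], result["C"]])
        )
        assert all(result[l] > 0 for l in "ABC")


@pytest.fixture
def counts():
    return pd.DataFrame(
        {
            "S1": [500, 4000, 100, 200, 50, 995150],
            "S2": [100, 2000, 50, 100, 25, 497725],
            "S3": [0, 1000, 200, 400, 100, 498300],
        },
        index=pd.Index(["CD274", "B2M", "CXCL9", "CXCL10", "CXCL11", "FILLER"], name="gene"),
    )


class TestExpression:
    def test_cpm_simple(self, counts):
        assert cpm(counts, "S1", "CD274") == pytest.approx(500.0)

    def test_cpm_zero_count(self, counts):
        assert cpm(counts, "S3", "CD274") == 0.0

    def test_pdl1_alias(self, counts):
        assert cpm(counts, "S1", "PDL1") == cpm(counts, "S1", "CD274")

    def test_markers_hand_computed(self, counts):
        pdl1, b2m = expression_markers(counts, "S2")
        total = counts["S2"].sum()
        assert pdl1 == pytest.approx(1e6 * 100 / total)
        assert b2m == pytest.approx(1e6 * 2000 / total)

    def test_cpm_sums_to_million(self, counts):
        total = sum(cpm(counts, "S1", g) for g in counts.index)
        assert total == pytest.approx(1e6)

    def test_zero_library_rejected(self, counts):
        counts = counts.copy()
        counts["S4"] = 0
        with pytest.raises(IntegrityError):
            cpm(counts, "S4", "B2M")


class TestCxclCombined:
    def make_counts(self, sample_factor):
        # cohort of 5 samples, equal library sizes; target sample scales the
        # three chemokine genes by the given per-gene factors
        base = {"CXCL9": 1000, "CXCL10": 2000, "CXCL11": 500}
        frame = {}
        for i in range(5):
            frame[f"S{i}"] = [base["CXCL9"], base["CXCL10"], base["CXCL11"], 996500]
        scaled = [
            int(base["CXCL9"] * sample_factor[0]),
            int(base["CXCL10"] * sample_factor[1]),
            int(base["CXCL11"] * sample_factor[2]),
        ]
        # equal library sizes so CPM fold changes equal count fold changes
        frame["T"] = scaled + [1_000_000 - sum(scaled)]
        return pd.DataFrame(
            frame, index=pd.Index(["CXCL9", "CXCL10", "CXCL11", "FILLER"], name="gene")
        )

    def test_at_cohort_median_is_zero(self):
        counts = self.make_counts((1, 1, 1))
        assert cxcl_combined(counts, "T") == pytest.approx(0.0, abs=1e-6)

    def test_twofold_everywhere_is_one(self):
        counts = self.make_counts((2, 2, 2))
        assert cxcl_combined(counts, "T") == pytest.approx(1.0, abs=5e-3)

    def test_mixed_fold_changes(self):
        counts = self.make_counts((4, 1, 1))
        assert cxcl_combined(counts, "T") == pytest.approx(2 / 3, abs=5e-3)

    def test_absent_gene_named(self):
        counts = self.make_counts((1, 1, 1)).drop(index=["CXCL10"])
        with pytest.raises(IntegrityError, match="CXCL10"):
            cxcl_combined(counts, "T")


class TestBuildPanel:
    def test_compositional_consistency(self, one_mb_region, counts):
        variants = [make_variant(pos=i + 1, impact="moderate") for i in range(5)]
        clones = [TcrClone("alpha", f"C{i}", 4) for i in range(4)]
        alleles = {"A": ("A*01:01", "A*02:01"), "B": ("B*07:02", "B*08:01"),
                   "C": ("C*04:01", "C*07:01")}
        genotype = HlaGenotype(alleles=alleles, groove_seqs=groove_sequences_for(alleles))
        cands = [NeoantigenCandidate("SIINFEKL", "A*01:01", 100.0, 3)]
        panel = build_panel(
            variants=variants, cnvs=[], region=one_mb_region, clones=clones,
            candidates=cands, genotype=genotype, counts=counts, sample="S1",
            tumor_clonality=0.6,
        )
        assert panel.tmb == pytest.approx(compute_tmb(variants, one_mb_region))
        assert panel.tcr_entropy == pytest.approx(tcr_entropy(clones))
        assert panel.neoantigen_burden == neoantigen_burden(cands, genotype)
        assert panel.hed == pytest.approx(hed(genotype)["mean"])
        assert panel.pdl1_cpm == pytest.approx(500.0)
        assert panel.missing == ()

    def test_missing_rna_inputs_marked(self, one_mb_region):
        variants = [make_variant(pos=1)]
        panel = build_panel(variants=variants, cnvs=[], region=one_mb_region,
                            tumor_clonality=0.5)
        assert {"tcr_entropy", "pdl1_cpm", "b2m_cpm", "cxcl_combined",
                "neoantigen_burden", "hed"} <= set(panel.missing)
        assert panel.tmb is not None and panel.response_flag is not None
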