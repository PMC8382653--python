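"""Alignment, wPRS scaling rule and ancestry-PC model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import multiprs as mp
from multiprs.types import EmptyTraitGroupError, ProjectionOverlapError, VariantWeight, WeightSet

from conftest import tiny_config, toy_genotypes, toy_weightset


class TestAlignment:
    def test_negative_beta_flipped_to_other_allele(self):
        ws = toy_weightset([-0.2])
        geno = toy_genotypes([[2.0], [1.0], [0.0]], ws)
        res = mp.align_weights(ws, geno)
        w = res.weights.weights[0]
        assert (w.effect_allele, w.other_allele, w.beta) == ("G", "A", 0.2)
        assert res.n_flipped == 1
        # the scorer reads the dosage as 2 - old through the allele annotation
        scores = mp.compute_wprs(res.genotypes, res.weights)
        np.testing.assert_allclose(scores.raw["raw_cvd"], [0.0, 0.2, 0.4])

    def test_positive_matching_weight_unchanged(self):
        ws = toy_weightset([0.3])
        geno = toy_genotypes([[1.0]], ws)
        res = mp.align_weights(ws, geno)
        assert res.weights.weights[0] == ws.weights[0]
        assert res.n_flipped == 0 and len(res.exclusions) == 0

    def test_allele_mismatch_excluded_with_reason(self):
        ws = WeightSet(
            weights=[
                VariantWeight("rs1", "1", 100, "A", "G", 0.2, "cvd"),
                VariantWeight("rs2", "1", 200, "C", "T", 0.2, "cvd"),
            ],
            groups=("cvd",),
        )
        geno = toy_genotypes([[1.0, 1.0]], toy_weightset([0.2, 0.2]))
        # rs2 in genotypes carries A/G alleles -> mismatch with C/T weight
        res = mp.align_weights(ws, geno)
        assert list(res.exclusions["variant_id"]) == ["rs2"]
        assert list(res.exclusions["reason"]) == ["allele mismatch"]

    def test_group_losing_all_variants_raises(self):
        ws = toy_weightset([0.2, 0.3], groups=["cvd", "lipids"])
        geno = toy_genotypes([[1.0, 1.0]], ws)
        lone = WeightSet(weights=[ws.weights[0],
                                  VariantWeight("rs99", "9", 999, "C", "T", 0.1, "lipids")],
                         groups=("cvd", "lipids"))
        with pytest.raises(EmptyTraitGroupError, match="lipids"):
            mp.align_weights(lone, geno)

    def test_alignment_is_involutive(self):
        ws = toy_weightset([-0.2, 0.5, -0.1])
        geno = toy_genotypes(np.random.default_rng(0).integers(0, 3, (20, 3)), ws)
        once = mp.align_weights(ws, geno)
        twice = mp.align_weights(once.weights, once.genotypes)
        assert twice.weights.weights == once.weights.weights
        np.testing.assert_allclose(twice.genotypes.dosage, once.genotypes.dosage)

    def test_strand_ambiguous_never_matches_positionally(self):
        amb = WeightSet(
            weights=[VariantWeight("rsX", "1", 100, "A", "T", 0.2, "cvd")], groups=("cvd",)
        )
        carrier = toy_weightset([0.2])  # genotype variant rs1 at 1:100 with A/G
        geno = toy_genotypes([[1.0]], carrier)
        with pytest.raises(EmptyTraitGroupError):
            mp.align_weights(amb, geno)


class TestWPRS:
    def test_hand_example(self):
        """beta (0.2, 0.3), dosages (2, 1): raw 0.7, scaled 0.7/0.5*2 = 2.8."""
        ws = toy_weightset([0.2, 0.3])
        geno = toy_genotypes([[2.0, 1.0]], ws)
        s = mp.compute_wprs(geno, ws)
        assert s.raw["raw_cvd"][0] == pytest.approx(0.7, abs=1e-15)
        assert s.scaled["wPRS_cvd"][0] == pytest.approx(2.8, abs=1e-12)

    @pytest.mark.parametrize("c, expected_factor", [(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)])
    def test_constant_dosage_identity(self, c, expected_factor):
        """Constant dosage c across a group gives scaled score exactly c*m_k."""
        ws = toy_weightset([0.11, 0.52, 0.37])
        geno = toy_genotypes(np.full((4, 3), c), ws)
        s = mp.compute_wprs(geno, ws)
        np.testing.assert_allclose(s.scaled["wPRS_cvd"], expected_factor * 3, atol=1e-12)

    def test_scale_invariance_of_scaled_score(self):
        rng = np.random.default_rng(7)
        betas = rng.uniform(0.05, 0.5, 5)
        dosage = rng.integers(0, 3, (30, 5)).astype(float)
        ws1 = toy_weightset(betas)
        ws2 = toy_weightset(betas * 17.3)
        s1 = mp.compute_wprs(toy_genotypes(dosage, ws1), ws1)
        s2 = mp.compute_wprs(toy_genotypes(dosage, ws2), ws2)
        np.testing.assert_allclose(
            s1.scaled["wPRS_cvd"], s2.scaled["wPRS_cvd"], rtol=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_brute_force_oracle_and_range(self, seed):
        """Vectorised scores equal a direct double loop; range within [0, 2 m_k]."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 6))
        betas = rng.uniform(1e-3, 1.0, m)
        dosage = rng.uniform(0, 2, (8, m))
        ws = toy_weightset(betas)
        s = mp.compute_wprs(toy_genotypes(dosage, ws), ws)
        for i in range(8):
            raw = 0.0
            for j in range(m):
                raw += dosage[i, j] * betas[j]
            scaled = raw / betas.sum() * m
            assert abs(s.raw["raw_cvd"][i] - raw) < 1e-12
            assert abs(s.scaled["wPRS_cvd"][i] - scaled) < 1e-12
            assert -1e-12 <= s.scaled["wPRS_cvd"][i] <= 2 * m + 1e-12

    def test_missing_dosages_mean_imputed_per_variant(self):
        ws = toy_weightset([0.4])
        geno = toy_genotypes([[0.0], [2.0], [np.nan]], ws)
        s = mp.compute_wprs(geno, ws)
        assert s.raw["raw_cvd"][2] == pytest.approx(0.4 * 1.0)

    def test_ten_group_default_yields_ten_score_columns(self, small_study):
        assert len(small_study.scores.groups) == 10
        assert list(small_study.scores.scaled.columns) == [
            f"wPRS_{g}" for g in mp.DEFAULT_GROUPS
        ]

    def test_unaligned_weights_rejected(self):
        ws = toy_weightset([-0.2])
        geno = toy_genotypes([[1.0]], ws)
        with pytest.raises(ValueError, match="aligned"):
            mp.compute_wprs(geno, ws)


class TestPCModel:
    def make_panel(self, seed=0, n=120, m=80, missing=0.0):
        cfg = tiny_config(seed=seed, n=n, n_pca_variants=m, missing_rate=missing)
        return mp.simulate_reference_genotypes(cfg)[0]

    def test_self_projection_identity(self):
        geno = self.make_panel()
        model, scores = mp.fit_pc_model(geno, n_components=5)
        proj = mp.project_pcs(model, geno)
        np.testing.assert_allclose(
            proj[model.component_columns()].to_numpy(),
            scores[model.component_columns()].to_numpy(),
            atol=1e-8,
        )

    def test_loadings_orthonormal(self):
        model, _ = mp.fit_pc_model(self.make_panel(), n_components=6)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)

    def test_monomorphic_variant_excluded_and_reported(self):
        geno = self.make_panel(n=50, m=20)
        geno.dosage[:, 3] = 2.0
        model, _ = mp.fit_pc_model(geno, n_components=4)
        assert geno.variant_ids[3] in model.excluded
        assert geno.variant_ids[3] not in model.variant_ids

    def test_pc1_separates_two_subpopulations(self):
        cfg = tiny_config(seed=9, n=500, n_pca_variants=2000, subpop_divergence=0.01)
        geno, truth = mp.simulate_reference_genotypes(cfg)
        _, scores = mp.fit_pc_model(geno, n_components=2)
        r = np.corrcoef(scores["pc1"], truth.subpop_labels)[0, 1]
        assert abs(r) > 0.9

    def test_projection_robust_to_dropped_variants(self):
        geno = self.make_panel(seed=4, n=300, m=400)
        model, _ = mp.fit_pc_model(geno, n_components=2)
        full = mp.project_pcs(model, geno)
        rng = np.random.default_rng(0)
        keep = rng.random(geno.n_variants) > 0.1  # drop ~10%
        from multiprs.types import GenotypeMatrix

        sub = GenotypeMatrix(
            individual_ids=geno.individual_ids,
            variant_ids=[v for v, k in zip(geno.variant_ids, keep) if k],
            dosage=geno.dosage[:, keep],
            effect_allele=[a for a, k in zip(geno.effect_allele, keep) if k],
            other_allele=[a for a, k in zip(geno.other_allele, keep) if k],
        )
        part = mp.project_pcs(model, sub)
        r = np.corrcoef(full["pc1"], part["pc1"])[0, 1]
        assert r > 0.95

    def test_zero_overlap_errors_with_fraction(self):
        geno = self.make_panel(n=30, m=10)
        model, _ = mp.fit_pc_model(geno, n_components=2)
        other = self.make_panel(seed=2, n=30, m=10)
        other.variant_ids = [f"x{v}" for v in other.variant_ids]
        with pytest.raises(ProjectionOverlapError):
            mp.project_pcs(model, other)
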