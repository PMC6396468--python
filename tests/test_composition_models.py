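import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modsplice import (
    Exon,
    Genome,
    ModuleDeltaScores,
    Variant,
    allelic_log_ratio,
    apply_variant,
    classify_sdv,
    clip_psi,
    delta_psi_from_dlogit,
    fit_effect_model,
    fit_pathogenicity,
    logit,
    module_delta_scores,
    predict_competition,
    predict_delta_psi,
    predict_pathogenicity,
    sigmoid,
)
from modsplice.composition_models import FEATURE_NAMES, cross_validate_pathogenicity


class TestTransforms:
    def test_sigmoid_midpoint_and_logit_zero(self):
        assert sigmoid(0.0) == 0.5
        assert logit(0.5) == 0.0

    def test_mutual_inverse(self):
        assert logit(sigmoid(1.7)) == pytest.approx(1.7, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=-15, max_value=15))
    def test_inverse_property(self, x):
        # 1 - sigmoid(x) underflows gradually for large x, so the
        # achievable round-trip accuracy degrades with saturation
        assert logit(sigmoid(x)) == pytest.approx(x, abs=1e-6)

    def test_logit_of_boundary_errors_without_clipping(self):
        with pytest.raises(ValueError):
            logit(0.0)
        with pytest.raises(ValueError):
            logit(1.0)

    def test_clip_psi_bounds(self):
        assert clip_psi(0.0) == 1e-5
        assert clip_psi(1.0) == 1 - 1e-5
        assert clip_psi(0.37) == 0.37


def _scores(**kw):
    base = dict(
        dS_intron3p=0.0, dS_acceptor=0.0, dS_exon=0.0, dS_donor=0.0,
        dS_intron5p=0.0, ind_exon_ss=0, ind_intron5p_donor=0,
        ind_intron3p_acceptor=0,
    )
    base.update(kw)
    return ModuleDeltaScores(**base)


@pytest.fixture(scope="module")
def scored_gene():
    rng = np.random.default_rng(11)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 800)])
    genome = Genome({"c": seq})
    exon = Exon("e1", "g", "c", "+", 300, 360)
    return genome, exon


class TestModuleDeltaScores:
    def test_identical_alleles_give_zero_deltas(self, scored_gene, module_set):
        genome, exon = scored_gene
        pos0 = exon.start + 30
        ref = genome.fetch("c", pos0, pos0 + 1)
        pair = apply_variant(genome, exon, Variant("c", pos0 + 1, ref, ref), la=100, ld=100)
        s = module_delta_scores(pair, module_set)
        assert (s.dS_intron3p, s.dS_acceptor, s.dS_exon, s.dS_donor, s.dS_intron5p) == (0,) * 5

    def test_mid_exon_snv_sets_no_indicators_but_moves_exon_score(self, scored_gene, module_set):
        genome, exon = scored_gene
        pos0 = exon.start + 30  # 30 nt from both splice sites
        ref = genome.fetch("c", pos0, pos0 + 1)
        alt = "A" if ref != "A" else "C"
        pair = apply_variant(genome, exon, Variant("c", pos0 + 1, ref, alt), la=100, ld=100)
        s = module_delta_scores(pair, module_set)
        assert (s.ind_exon_ss, s.ind_intron5p_donor, s.ind_intron3p_acceptor) == (0, 0, 0)
        assert s.dS_exon != 0.0
        assert s.dS_donor == 0.0  # outside the 18-nt donor window

    def test_intronic_snv_near_donor_sets_donor_overlap(self, scored_gene, module_set):
        genome, exon = scored_gene
        pos0 = exon.end + 3  # 4th intronic nucleotide downstream of the donor
        ref = genome.fetch("c", pos0, pos0 + 1)
        alt = "A" if ref != "A" else "C"
        pair = apply_variant(genome, exon, Variant("c", pos0 + 1, ref, alt), la=100, ld=100)
        s = module_delta_scores(pair, module_set)
        assert s.ind_intron5p_donor == 1
        assert s.ind_exon_ss == 0 and s.ind_intron3p_acceptor == 0
        assert s.dS_exon == 0.0

    def test_indicator_validation(self):
        with pytest.raises(ValueError):
            _scores(ind_exon_ss=2)
        with pytest.raises(ValueError):
            _scores(dS_exon=np.nan)


class TestEffectModelFit:
    BETA = np.array([0.3, -0.7, -1.1, -0.9, -1.4, -0.6, 0.5, 0.8, 0.4])

    @staticmethod
    def _rows(rng, n):
        rows = []
        for _ in range(n):
            rows.append(_scores(
                dS_intron3p=rng.normal(), dS_acceptor=rng.normal(),
                dS_exon=rng.normal(), dS_donor=rng.normal(), dS_intron5p=rng.normal(),
                ind_exon_ss=int(rng.random() < 0.2),
                ind_intron5p_donor=int(rng.random() < 0.2),
                ind_intron3p_acceptor=int(rng.random() < 0.2),
            ))
        return rows

    def test_model_has_nine_parameters(self, rng):
        rows = self._rows(rng, 50)
        X = np.stack([r.features() for r in rows])
        y = self.BETA[0] + X @ self.BETA[1:]
        model = fit_effect_model(rows, y)
        assert model.coef.size == 9
        assert len(model.feature_names) == 8

    def test_exact_recovery_without_noise(self, rng):
        rows = self._rows(rng, 200)
        X = np.stack([r.features() for r in rows])
        y = self.BETA[0] + X @ self.BETA[1:]
        model = fit_effect_model(rows, y)
        assert np.abs(model.coef - self.BETA) .max() < 1e-6

    def test_huber_resists_outliers_better_than_ols(self, rng):
        n = 2000
        rows = self._rows(rng, n)
        X = np.stack([r.features() for r in rows])
        y = self.BETA[0] + X @ self.BETA[1:] + rng.normal(0, 0.1, n)
        out = rng.random(n) < 0.05
        y[out] += rng.choice([-10.0, 10.0], size=out.sum())
        model = fit_effect_model(rows, y, huber_delta=1.0)
        assert np.abs(model.coef - self.BETA).max() < 0.05
        A = np.column_stack([np.ones(n), X])
        ols, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert np.abs(ols - self.BETA).max() > np.abs(model.coef - self.BETA).max()

    def test_underdetermined_rejected(self, rng):
        rows = self._rows(rng, 5)
        with pytest.raises(ValueError, match="cannot identify"):
            fit_effect_model(rows, np.zeros(5))

    def test_zero_variance_column_reported(self, rng):
        rows = [
            _scores(dS_exon=rng.normal(), dS_donor=rng.normal(),
                    dS_acceptor=rng.normal(), dS_intron3p=rng.normal(),
                    dS_intron5p=rng.normal())
            for _ in range(30)
        ]
        with pytest.warns(UserWarning, match="zero-variance"):
            fit_effect_model(rows, np.zeros(30))

    def test_json_round_trip(self, tmp_path, rng):
        from modsplice import EffectModel

        rows = self._rows(rng, 40)
        X = np.stack([r.features() for r in rows])
        model = fit_effect_model(rows, X @ self.BETA[1:] + self.BETA[0])
        path = tmp_path / "m.json"
        model.to_json(path)
        again = EffectModel.from_json(path)
        assert np.array_equal(again.coef, model.coef)
        assert again.feature_names == FEATURE_NAMES


class TestDeltaPsiPrediction:
    @staticmethod
    def _intercept_model(dlogit):
        from modsplice import EffectModel

        coef = np.zeros(9)
        coef[0] = dlogit
        return EffectModel("delta_logit_psi", coef, FEATURE_NAMES)

    def test_zero_dlogit_gives_zero_dpsi(self):
        model = self._intercept_model(0.0)
        dlogit, dpsi = predict_delta_psi(model, _scores(), 0.3)
        assert dlogit == 0.0 and dpsi == pytest.approx(0.0, abs=1e-15)

    def test_analytic_case(self):
        # logit(0.8) - logit(0.5) = log(4) = 1.3862944
        model = self._intercept_model(np.log(4))
        _, dpsi = predict_delta_psi(model, _scores(), 0.5)
        assert dpsi == pytest.approx(0.3, abs=1e-9)

    def test_boundary_psi_ref_stays_finite(self):
        model = self._intercept_model(2.0)
        dlogit, dpsi = predict_delta_psi(model, _scores(), 1.0)
        assert np.isfinite(dpsi) and -1 < dpsi < 1

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(min_value=1e-4, max_value=1 - 1e-4),
        st.floats(min_value=1e-4, max_value=1 - 1e-4),
    )
    def test_round_trip_recovers_psi_difference(self, p_ref, p_alt):
        dlogit = logit(p_alt) - logit(p_ref)
        assert delta_psi_from_dlogit(dlogit, p_ref) == pytest.approx(
            p_alt - p_ref, abs=1e-12
        )

    def test_monotone_in_dlogit(self):
        dls = np.linspace(-4, 4, 41)
        dpsis = delta_psi_from_dlogit(dls, 0.4)
        assert np.all(np.diff(dpsis) > 0)


class TestCompetition:
    def test_equal_effects_cancel(self):
        for genotype in ("hom_alt", "het"):
            assert predict_competition(1.3, 1.3, 0.7, genotype) == pytest.approx(0.0, abs=1e-15)

    def test_analytic_case(self):
        diff = logit(0.6) - logit(0.2)  # 1.7917595
        assert predict_competition(diff, 0.0, 0.2, "hom_alt") == pytest.approx(0.4, abs=1e-9)
        assert predict_competition(diff, 0.0, 0.2, "het") == pytest.approx(0.2, abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(min_value=-5, max_value=5),
        st.floats(min_value=-5, max_value=5),
        st.floats(min_value=0.01, max_value=0.99),
    )
    def test_het_is_half_hom(self, d1, d2, psi_ref):
        hom = predict_competition(d1, d2, psi_ref, "hom_alt")
        het = predict_competition(d1, d2, psi_ref, "het")
        assert het == pytest.approx(hom / 2, abs=1e-15)

    def test_monotone_in_each_exon_effect(self):
        base = predict_competition(0.5, 0.2, 0.3, "hom_alt")
        assert predict_competition(0.9, 0.2, 0.3, "hom_alt") > base
        assert predict_competition(0.5, 0.6, 0.3, "hom_alt") < base


class TestAllelicLogRatio:
    def test_balanced_counts_zero(self):
        assert allelic_log_ratio(10, 10, 10, 10) == 0.0

    def test_doubled_mutant_output_is_one(self):
        assert allelic_log_ratio(20, 10, 10, 10) == pytest.approx(1.0)

    def test_zero_count_without_pseudocount_errors(self):
        with pytest.raises(ValueError):
            allelic_log_ratio(10, 10, 10, 0)
        assert np.isfinite(allelic_log_ratio(10, 10, 10, 0, pseudocount=0.5))

    @settings(derandomize=True, max_examples=50)
    @given(*(st.integers(min_value=1, max_value=10_000) for _ in range(4)))
    def test_antisymmetry(self, mo, mi, wo, wi):
        assert allelic_log_ratio(mo, mi, wo, wi) == pytest.approx(
            -allelic_log_ratio(wo, wi, mo, mi), abs=1e-12
        )


class TestPathogenicity:
    def test_separable_labels_perfect_cv_auroc(self, rng):
        # a margin keeps held-out points away from the true hyperplane,
        # so cross-validated ranking is exactly perfect
        w = np.array([2.0, -1.0, 1.5, -2.0, 1.0, 0.5, -0.5, 1.0])
        rows = [r for r in TestEffectModelFit._rows(rng, 600)
                if abs(r.features() @ w) > 0.5][:300]
        X = np.stack([r.features() for r in rows])
        y = (X @ w > 0).astype(int)
        res = cross_validate_pathogenicity(rows, y, n_folds=5, seed=0)
        assert res["auroc_mean"] == pytest.approx(1.0, abs=1e-9)

    def test_null_labels_cv_auroc_near_half(self, rng):
        rows = TestEffectModelFit._rows(rng, 2000)
        y = (rng.random(2000) < 0.5).astype(int)
        res = cross_validate_pathogenicity(rows, y, n_folds=10, seed=0)
        assert 0.45 <= res["auroc_mean"] <= 0.55

    def test_zero_features_predict_sigmoid_intercept(self, rng):
        rows = TestEffectModelFit._rows(rng, 100)
        y = (rng.random(100) < 0.7).astype(int)
        model = fit_pathogenicity(rows, y)
        zeros = [_scores() for _ in range(5)]
        probs = predict_pathogenicity(model, zeros)
        assert np.allclose(probs, sigmoid(model.intercept))

    def test_single_class_rejected(self, rng):
        rows = TestEffectModelFit._rows(rng, 20)
        with pytest.raises(ValueError):
            fit_pathogenicity(rows, np.ones(20))

    def test_extended_feature_set_has_fourteen_parameters(self, rng):
        rows = []
        for _ in range(200):
            s = TestEffectModelFit._rows(rng, 1)[0]
            s.ref_scores = {k: rng.normal() for k in ("intron3p", "acceptor", "exon", "donor", "intron5p")}
            rows.append(s)
        y = (rng.random(200) < 0.5).astype(int)
        model = fit_pathogenicity(rows, y, feature_set="extended")
        assert model.coef.size == 14


class TestSdvClassification:
    def test_separable_effects_give_perfect_aupr(self, rng):
        from modsplice import metric

        dpsi = np.concatenate([rng.uniform(0.5, 0.9, 30) * rng.choice([-1, 1], 30),
                               rng.uniform(0.0, 0.1, 70) * rng.choice([-1, 1], 70)])
        labels = np.concatenate([np.ones(30), np.zeros(70)])
        calls = classify_sdv(dpsi).sort_values("index")
        assert metric("auPR", labels, calls["score"].to_numpy()) == pytest.approx(1.0)

    def test_ranking_is_by_absolute_effect(self):
        calls = classify_sdv(np.array([0.1, -0.8, 0.3]))
        assert list(calls["index"]) == [1, 2, 0]

    def test_threshold_makes_hard_calls(self):
        calls = classify_sdv(np.array([0.1, -0.8, 0.3]), threshold=0.25)
        assert list(calls.sort_values("index")["call"]) == [False, True, True]
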