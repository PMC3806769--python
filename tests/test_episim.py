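import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from epii.episim import (
    DEFAULT_HYBRID_POSITIONS,
    HybridModel,
    PenetranceModel,
    _conditional_joint,
    build_zero_marginal_model,
    heritability,
    hwe_probs,
    load_model_csv,
    marginal_penetrance,
    max_heritability,
    prevalence,
    save_model_csv,
    simulate_hybrid,
    simulate_pure,
    xor_model,
)


def model_of(f, maf=0.5):
    return PenetranceModel(f=np.asarray(f, float), maf_a=maf, maf_b=maf)


class TestHweProbs:
    def test_half(self):
        assert np.allclose(hwe_probs(0.5), [0.25, 0.5, 0.25])

    def test_point_four(self):
        assert np.allclose(hwe_probs(0.4), [0.16, 0.48, 0.36])

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.01, 0.5))
    def test_sums_to_one(self, maf):
        assert hwe_probs(maf).sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("maf", [0.0, -0.1, 0.6])
    def test_out_of_range(self, maf):
        with pytest.raises(ValueError, match="frequency"):
            hwe_probs(maf)


class TestPrevalence:
    def test_constant_table(self):
        assert prevalence(model_of(np.full((3, 3), 0.1), 0.3)) == pytest.approx(0.1)

    def test_diagonal(self):
        # oracle: direct summation over the diagonal cells
        m = model_of(np.eye(3), 0.5)
        probs = hwe_probs(0.5)[::-1]  # indexed by minor-allele count 0,1,2
        expected = sum(probs[i] * probs[i] for i in range(3))
        assert prevalence(m) == pytest.approx(expected, abs=1e-15)

    def test_bounded_by_penetrance_range(self, rng):
        for _ in range(10):
            f = rng.random((3, 3))
            m = model_of(f, float(rng.uniform(0.05, 0.5)))
            assert f.min() - 1e-12 <= prevalence(m) <= f.max() + 1e-12


class TestHeritability:
    def test_constant_is_zero(self):
        assert heritability(model_of(np.full((3, 3), 0.3))) == pytest.approx(0.0)

    def test_deterministic_xor_pattern(self):
        # f in {0,1} with K = 0.5: all variance explained
        f = np.array([[1, 0, 1], [0, 1, 0], [1, 0, 1]], float)
        m = model_of(f, 0.5)
        assert prevalence(m) == pytest.approx(0.5)
        assert heritability(m) == pytest.approx(1.0)

    def test_matches_nine_cell_enumeration(self, rng):
        f = rng.uniform(0.05, 0.95, (3, 3))
        maf = 0.35
        m = model_of(f, maf)
        probs = hwe_probs(maf)[::-1]
        k = sum(probs[i] * probs[j] * f[i, j] for i in range(3) for j in range(3))
        var = sum(
            probs[i] * probs[j] * (f[i, j] - k) ** 2
            for i in range(3)
            for j in range(3)
        )
        assert heritability(m) == pytest.approx(var / (k * (1 - k)), abs=1e-12)

    def test_degenerate_prevalence_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            heritability(model_of(np.zeros((3, 3))))


class TestMarginalPenetrance:
    def test_constant(self):
        m = model_of(np.full((3, 3), 0.2), 0.3)
        assert np.allclose(marginal_penetrance(m, "a"), 0.2)
        assert np.allclose(marginal_penetrance(m, "b"), 0.2)

    def test_total_probability(self, rng):
        m = model_of(rng.random((3, 3)), 0.25)
        probs = hwe_probs(0.25)[::-1]
        for locus in "ab":
            assert probs @ marginal_penetrance(m, locus) == pytest.approx(
                prevalence(m), abs=1e-12
            )

    def test_xor_model_flat_marginals(self):
        m = xor_model(0.4, 0.2)
        k = prevalence(m)
        for locus in "ab":
            assert np.abs(marginal_penetrance(m, locus) - k).max() < 1e-10


class TestBuildZeroMarginal:
    @pytest.mark.parametrize("maf,h2", [(0.4, 0.4), (0.25, 0.025)])
    def test_postconditions(self, maf, h2):
        m = build_zero_marginal_model(maf, h2, seed=5)
        k = prevalence(m)
        for locus in "ab":
            assert np.abs(marginal_penetrance(m, locus) - k).max() < 1e-8
        assert abs(heritability(m) - h2) < 1e-6

    def test_deterministic(self):
        m1 = build_zero_marginal_model(0.3, 0.1, seed=9)
        m2 = build_zero_marginal_model(0.3, 0.1, seed=9)
        assert (m1.f == m2.f).all()

    def test_distinct_seeds_distinct_tables(self):
        m1 = build_zero_marginal_model(0.3, 0.1, seed=1)
        m2 = build_zero_marginal_model(0.3, 0.1, seed=2)
        assert not (m1.f == m2.f).all()

    def test_hard_corner_uses_asymmetric_prevalence(self):
        # maf 0.2 cannot reach h2=0.4 at K=0.5; the grid search must solve it
        assert max_heritability(0.2, 0.5) < 0.4
        m = build_zero_marginal_model(0.2, 0.4, seed=0)
        assert abs(heritability(m) - 0.4) < 1e-6

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            build_zero_marginal_model(0.2, 0.4, seed=0, prevalence=0.5)

    def test_invalid_target(self):
        with pytest.raises(ValueError, match="heritability"):
            build_zero_marginal_model(0.4, 1.5, seed=0)


class TestModelCsv:
    def test_round_trip(self, tmp_path):
        m = build_zero_marginal_model(0.4, 0.1, seed=3)
        path = tmp_path / "model.csv"
        save_model_csv(path, m)
        back = load_model_csv(path, maf_a=0.4)
        assert np.allclose(back.f, m.f, atol=1e-15)


@pytest.fixture(scope="module")
def model():
    return build_zero_marginal_model(0.4, 0.4, seed=77)


@pytest.fixture(scope="module")
def hybrid():
    return HybridModel.uniform(0.4, 0.4, seed=21)


class TestSimulatePure:
    def test_class_counts_exact(self, model):
        ds = simulate_pure(model, n_cases=30, n_controls=50, n_snps=20, seed=1)
        assert ds.phenotype.n_cases == 30
        assert ds.phenotype.n_controls == 50
        assert ds.genotypes.n_snps == 20

    def test_truth_record(self, model):
        ds = simulate_pure(model, n_snps=50, positions=(3, 17), seed=1)
        assert ds.truth.pairs == ((3, 17),)
        assert ds.truth.model_hashes == (model.table_hash(),)

    def test_deterministic(self, model):
        d1 = simulate_pure(model, n_snps=30, seed=4)
        d2 = simulate_pure(model, n_snps=30, seed=4)
        assert (d1.genotypes.values == d2.genotypes.values).all()

    def test_distinct_seeds(self, model):
        d1 = simulate_pure(model, n_snps=30, seed=4)
        d2 = simulate_pure(model, n_snps=30, seed=5)
        assert not (d1.genotypes.values == d2.genotypes.values).all()

    def test_no_missing_by_default(self, model):
        ds = simulate_pure(model, n_snps=30, seed=4)
        assert (ds.genotypes.values < 3).all()

    def test_missing_rate_knob(self, model):
        ds = simulate_pure(model, n_snps=30, seed=4, missing_rate=0.2)
        frac = (ds.genotypes.values == 3).mean()
        assert 0.1 < frac < 0.3

    def test_positions_validated(self, model):
        with pytest.raises(ValueError, match="distinct"):
            simulate_pure(model, n_snps=10, positions=(2, 2))
        with pytest.raises(ValueError, match="out of range"):
            simulate_pure(model, n_snps=10, positions=(1, 11))

    def test_zero_penetrance_cases_rejected(self):
        m = model_of(np.zeros((3, 3)), 0.4)
        with pytest.raises(ValueError, match="zero probability to cases"):
            simulate_pure(m, n_snps=5, positions=(1, 2), seed=0)

    def test_conditional_sampling_goodness_of_fit(self, model):
        # empirical P(g_a, g_b | class) vs the analytic conditional
        ds = simulate_pure(
            model, n_cases=10000, n_controls=10000, n_snps=2, positions=(1, 2), seed=8
        )
        v = ds.genotypes.values
        for case in (True, False):
            sel = ds.phenotype.labels == (1 if case else 0)
            cells = np.bincount(3 * v[sel, 0] + v[sel, 1], minlength=9)
            expected = _conditional_joint(model, case).ravel() * sel.sum()
            keep = expected > 0
            chi2 = stats.chisquare(cells[keep], expected[keep])
            assert chi2.pvalue > 0.001

    def test_noise_maf_range_validated(self, model):
        with pytest.raises(ValueError, match="MAF range"):
            simulate_pure(
                model, n_snps=5, positions=(1, 2), noise_maf_range=(0.0, 0.6), seed=0
            )


class TestSimulateHybrid:
    def test_truth_positions(self, hybrid):
        ds = simulate_hybrid(hybrid, seed=2)
        assert ds.truth.pairs == DEFAULT_HYBRID_POSITIONS
        assert len(ds.truth.model_hashes) == 5

    def test_disease_locus_mafs(self, hybrid):
        ds = simulate_hybrid(hybrid, n_cases=200, n_controls=200, seed=3)
        v = ds.genotypes.values
        for a, b in ds.truth.pairs:
            for pos in (a, b):
                maf_hat = v[:, pos - 1].mean() / 2  # mean minor-allele count / 2
                # zero-marginal models keep the case-control mix near HWE
                assert abs(maf_hat - 0.4) < 0.08  # ~4.5 sigma at n=400
    def test_cross_pair_independence(self, hybrid):
        ds = simulate_hybrid(hybrid, n_cases=500, n_controls=500, seed=4)
        v = ds.genotypes.values.astype(float)
        loci = [p - 1 for pair in ds.truth.pairs for p in pair]
        corr = np.corrcoef(v[:, loci].T)
        off = corr[np.triu_indices(10, 1)]
        # within-pair correlation is expected; across pairs it must vanish
        across = [
            corr[i, j]
            for i in range(10)
            for j in range(i + 1, 10)
            if i // 2 != j // 2
        ]
        assert np.abs(across).max() < 0.12

    def test_n_snps_too_small(self, hybrid):
        with pytest.raises(ValueError, match="too small"):
            simulate_hybrid(hybrid, n_snps=800)

    def test_position_clash_rejected(self):
        models = [xor_model(0.4, 0.1)] * 5
        with pytest.raises(ValueError, match="clash"):
            HybridModel(models=models, positions=((1, 2), (2, 3), (4, 5), (6, 7), (8, 9)))

    def test_needs_five_models(self):
        with pytest.raises(ValueError, match="exactly 5"):
            HybridModel(models=[xor_model(0.4, 0.1)] * 4)

    def test_deterministic(self, hybrid):
        d1 = simulate_hybrid(hybrid, seed=9)
        d2 = simulate_hybrid(hybrid, seed=9)
        assert (d1.genotypes.values == d2.genotypes.values).all()
        assert (d1.phenotype.labels == d2.phenotype.labels).all()


class TestPenetranceModelValidation:
    def test_shape(self):
        with pytest.raises(ValueError, match="3x3"):
            PenetranceModel(f=np.zeros((2, 2)), maf_a=0.3, maf_b=0.3)

    def test_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            PenetranceModel(f=np.full((3, 3), 1.5), maf_a=0.3, maf_b=0.3)
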