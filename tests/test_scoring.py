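import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenofuse.errors import (
    CalibrationUnavailableError,
    DegeneratePredictorError,
    InputError,
)
from phenofuse.scoring import (
    build_null_sample,
    calibrate_p,
    clean_associations,
    genotype_matrix,
    genotype_vector,
    pair_genotype_similarity,
    sample_null_pairs,
    score_gene,
    slope_test,
    slope_test_batch,
)
from phenofuse.similarity import SimilarityMatrix


def _phi(values, labels):
    return SimilarityMatrix(labels=tuple(labels), values=np.asarray(values, float),
                            kind="transformed", source="toy")


@pytest.fixture
def toy_phi():
    labels = ["g", "h1", "h2"]
    v = np.array([[1.0, 0.2, 0.3],
                  [0.2, 1.0, 0.1],
                  [0.3, 0.1, 1.0]])
    return _phi(v, labels)


class TestGenotypeVector:
    def test_self_association_gives_one(self, toy_phi):
        x = genotype_vector("g", ["d1"], {"d1": {"g"}}, toy_phi)
        assert x[0] == 1.0

    def test_sum_of_two_terms(self, toy_phi):
        x = genotype_vector("g", ["d1"], {"d1": {"h1", "h2"}}, toy_phi)
        assert x[0] == pytest.approx(0.5)

    def test_matches_brute_force_loop(self, rng):
        n_g, n_d = 8, 5
        labels = [f"g{i}" for i in range(n_g)]
        v = rng.uniform(0, 1, size=(n_g, n_g))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        phi = _phi(v, labels)
        assoc = {f"d{i}": set(rng.choice(labels, size=rng.integers(1, 4),
                                         replace=False))
                 for i in range(n_d)}
        diseases = sorted(assoc)
        for query in labels[:3]:
            x = genotype_vector(query, diseases, assoc, phi)
            brute = [sum(phi.loc(query, k) for k in assoc[d]) for d in diseases]
            assert np.allclose(x, brute, atol=1e-12)
            # and the vectorized matrix path agrees column-wise
            X = genotype_matrix([query], diseases, assoc, phi)
            assert np.allclose(X[:, 0], brute, atol=1e-12)

    def test_missing_entries_skipped(self):
        labels = ["g", "h"]
        v = np.array([[1.0, 0.4], [0.4, 1.0]])
        miss = np.zeros((2, 2), bool)
        miss[0, 1] = miss[1, 0] = True
        phi = SimilarityMatrix(labels=tuple(labels), values=v, kind="transformed",
                               missing=miss)
        x = genotype_vector("g", ["d"], {"d": {"h"}}, phi)
        assert x[0] == 0.0


class TestPairGenotypeSimilarity:
    def test_shared_gene(self, toy_phi):
        assert pair_genotype_similarity({"g"}, {"g"}, toy_phi) == 1.0

    def test_single_cross_pair(self, toy_phi):
        assert pair_genotype_similarity({"g"}, {"h1"}, toy_phi) == pytest.approx(0.2)

    def test_six_term_hand_sum(self, toy_phi):
        D, E = {"g", "h1"}, {"g", "h1", "h2"}
        expected = sum(toy_phi.loc(a, b) for a in D for b in E)
        assert pair_genotype_similarity(D, E, toy_phi) == pytest.approx(expected)

    def test_unresolvable_raises(self, toy_phi):
        with pytest.raises(InputError):
            pair_genotype_similarity({"nope"}, {"g"}, toy_phi)


class TestSlopeTest:
    def test_zero_slope_gives_half(self):
        beta, t, p = slope_test([0, 1, 2, 3], [1, 0, 0, 1])
        assert beta == pytest.approx(0.0)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_negative_slope_p_above_half(self):
        _, t, p = slope_test([0, 1, 2, 3], [3.0, 2.1, 0.9, 0.2])
        assert t < 0 and p > 0.5

    def test_agrees_with_ols_oracle(self, rng):
        """Closed form vs statsmodels OLS + one-sided t tail, 100 instances."""
        import statsmodels.api as sm

        for _ in range(100):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + rng.normal() * x
            beta, t, p = slope_test(x, y)
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            assert beta == pytest.approx(fit.params[1], abs=1e-10)
            assert t == pytest.approx(fit.tvalues[1], abs=1e-10)
            assert p == pytest.approx(stats.t.sf(fit.tvalues[1], n - 2), abs=1e-10)

    def test_degenerate_predictor_raises(self):
        with pytest.raises(DegeneratePredictorError):
            slope_test([1, 1, 1, 1], [0, 1, 2, 3])

    def test_perfect_fit_underflows_not_zero(self):
        _, t, p = slope_test([0, 1, 2, 3], [0, 1, 2, 3])
        assert t == np.inf
        assert 0 < p <= 1e-300

    def test_batch_matches_scalar(self, rng):
        n, g = 20, 15
        X = rng.normal(size=(n, g))
        y = rng.normal(size=n)
        beta, t, p = slope_test_batch(X.copy(), y)
        for j in range(g):
            b0, t0, p0 = slope_test(X[:, j], y)
            assert beta[j] == pytest.approx(b0, abs=1e-12)
            assert t[j] == pytest.approx(t0, abs=1e-12)
            assert p[j] == pytest.approx(p0, abs=1e-12)

    def test_type_I_error_calibrated_under_null(self, rng):
        """Under H0 the one-sided p is Uniform(0,1): empirical rejection at
        alpha=0.05 within binomial 3 sigma over 2500 simulated tests."""
        reps, n, alpha = 2500, 30, 0.05
        hits = 0
        for _ in range(25):
            X = rng.normal(size=(n, reps // 25))
            y = rng.normal(size=n)
            _, _, p = slope_test_batch(X, y)
            hits += int((p < alpha).sum())
        rate = hits / reps
        band = 3 * np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < band


class TestCalibration:
    def test_upper_extreme(self):
        null = np.linspace(0.001, 0.99, 99)
        assert calibrate_p(0.999, null) == pytest.approx(1.0)

    def test_lower_extreme(self):
        null = np.linspace(0.01, 0.99, 99)
        assert calibrate_p(1e-6, null) == pytest.approx(0.01)

    def test_median_maps_near_half(self):
        null = np.sort(np.linspace(0.0, 1.0, 99))
        med = np.median(null)
        assert calibrate_p(med, null) == pytest.approx(0.51, abs=0.02)

    def test_monotone(self, rng):
        null = rng.uniform(size=200)
        ps = np.sort(rng.uniform(size=50))
        cal = [calibrate_p(p, null) for p in ps]
        assert all(a <= b for a, b in zip(cal, cal[1:]))

    def test_duplication_invariant(self, rng):
        null = rng.uniform(size=101)
        p = 0.3
        a = calibrate_p(p, null)
        b = calibrate_p(p, np.concatenate([null, null]))
        # add-one smoothing shifts by O(1/M); ranks themselves are invariant
        assert a == pytest.approx(b, abs=1.0 / len(null))

    def test_empty_null_raises(self):
        with pytest.raises(CalibrationUnavailableError):
            calibrate_p(0.5, [])


class TestNullSample:
    def test_deterministic_for_fixed_seed(self, null_world):
        w = null_world
        phi = w.sources["src0"]
        a = build_null_sample(w.assoc, w.phenotype, phi, m_pairs=150, seed=3)
        b = build_null_sample(w.assoc, w.phenotype, phi, m_pairs=150, seed=3)
        assert np.array_equal(a, b)

    def test_excludes_annotated_pairs(self, null_world):
        w = null_world
        pairs = sample_null_pairs(w.assoc, w.phenotype, w.genes, 300, seed=1)
        assert all(g not in w.assoc[d] for d, g in pairs)

    def test_zero_pairs_raises(self, null_world):
        w = null_world
        with pytest.raises(InputError):
            sample_null_pairs(w.assoc, w.phenotype, w.genes, 0, seed=1)

    def test_small_universe_uses_all_with_warning(self):
        labels = ("d1", "d2", "d3", "d4")
        v = np.full((4, 4), 0.3)
        np.fill_diagonal(v, 1.0)
        pheno = SimilarityMatrix(labels=labels, values=v, kind="raw")
        assoc = {d: {"g1"} for d in labels}
        with pytest.warns(UserWarning):
            pairs = sample_null_pairs(assoc, pheno, ["g1", "g2"], 500, seed=0)
        assert len(pairs) == 4  # only (d, g2) pairs are eligible


class TestScoreGene:
    def test_reference_count_excludes_query(self, null_world):
        w = null_world
        d = sorted(w.assoc)[0]
        g = sorted(w.assoc[d])[0]
        s = score_gene(d, g, w.phenotype, w.sources["src0"], w.assoc)
        n_annotated = sum(1 for dd in w.phenotype.labels if w.assoc.get(dd))
        assert s.n_used == n_annotated - 1

    def test_absent_gene_signals_missing_source(self, null_world):
        w = null_world
        d = sorted(w.assoc)[0]
        assert score_gene(d, "NOT_A_GENE", w.phenotype, w.sources["src0"],
                          w.assoc) is None

    def test_invariant_to_reference_ordering(self, null_world):
        """Scores do not depend on the ordering of the phenotype labels."""
        w = null_world
        d = sorted(w.assoc)[5]
        g = sorted(w.genes)[17]
        s1 = score_gene(d, g, w.phenotype, w.sources["src0"], w.assoc)
        perm = np.random.default_rng(0).permutation(w.phenotype.n)
        pheno2 = SimilarityMatrix(
            labels=tuple(w.phenotype.labels[i] for i in perm),
            values=w.phenotype.values[np.ix_(perm, perm)],
            kind=w.phenotype.kind)
        s2 = score_gene(d, g, pheno2, w.sources["src0"], w.assoc)
        assert s1.raw_p == pytest.approx(s2.raw_p, abs=1e-12)
        assert s1.beta_hat == pytest.approx(s2.beta_hat, abs=1e-12)

    def test_planted_association_scores_small(self, signal_world):
        """With a planted module effect the true gene's p-value is tiny."""
        w = signal_world
        null = build_null_sample(w.assoc, w.phenotype, w.sources["src0"],
                                 m_pairs=400, seed=2)
        hits = 0
        for d in sorted(w.assoc)[:20]:
            g = sorted(w.assoc[d])[0]
            s = score_gene(d, g, w.phenotype, w.sources["src0"], w.assoc,
                           null_sample=null)
            hits += s.calibrated_p < 0.05
        assert hits >= 19


class TestCleanAssociations:
    def test_drops_unresolvable(self):
        assoc = {"d1": {"g1", "gX"}, "d2": {"gY"}}
        out, dropped = clean_associations(assoc, genes={"g1"})
        assert out == {"d1": {"g1"}}
        assert dropped == 2
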