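"""Score-test scan, REML variance components, thresholds, peaks, effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tetraqtl as tq
from tetraqtl.qtl_scan import (
    ScanEngine,
    Threshold,
    VarianceFit,
    call_peaks,
    imhof_sf,
    reml_fit,
)
from tetraqtl.relationship import locus_G


class TestFitNull:
    def test_closed_form(self):
        mu, s2 = tq.fit_null(np.array([1.0, 2.0, 3.0]))
        assert mu == 2.0
        assert s2 == pytest.approx(2.0 / 3.0)

    def test_constant_trait_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            tq.fit_null(np.full(10, 3.3))

    def test_standardized_trait(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=500)
        y = (y - y.mean()) / y.std()
        mu, s2 = tq.fit_null(y)
        assert mu == pytest.approx(0.0, abs=1e-12)
        assert s2 == pytest.approx(1.0, abs=1e-12)


class TestScoreTest:
    def test_zero_G_gives_p_one(self):
        y = np.random.default_rng(2).normal(size=30)
        u, p = tq.score_test(y, np.zeros((30, 30)))
        assert u == 0.0 and p == 1.0

    def test_identity_G_is_calibrated(self):
        """With G = I the statistic reduces to a chi-square scale check."""
        rng = np.random.default_rng(3)
        n = 237
        pvals = [tq.score_test(rng.normal(size=n), np.eye(n))[1]
                 for _ in range(20)]
        assert 0.3 < np.median(pvals) < 0.7

    def test_non_psd_rejected(self):
        y = np.arange(5.0)
        G = -np.eye(5)
        with pytest.raises(ValueError):
            tq.score_test(y, G)

    def test_imhof_matches_chi2_on_known_mixtures(self):
        # single weight: slowly decaying integrand, oracle tolerance
        for x in (0.5, 2.0, 6.0):
            assert imhof_sf(x, np.array([1.0])) == pytest.approx(
                stats.chi2.sf(x, 1), abs=2e-3
            )
        # equal weights: sum of m chi2_1 = chi2_m, fast-decaying tail
        for x in (5.0, 12.0):
            assert imhof_sf(x, np.ones(10)) == pytest.approx(
                stats.chi2.sf(x, 10), abs=1e-6
            )

    def test_satterthwaite_close_to_exact_on_real_G(self, dense_cross):
        """Moment matching tracks the Imhof weighted-chi-square tail."""
        _, _, gp = dense_cross
        G = locus_G(gp.at(40))
        rng = np.random.default_rng(8)
        for _ in range(5):
            y = rng.normal(size=gp.n)
            _, p_satt = tq.score_test(y, G, method="satterthwaite")
            _, p_exact = tq.score_test(y, G, method="exact")
            assert p_satt == pytest.approx(p_exact, abs=0.02)


class TestScan:
    def test_affine_invariance(self, dense_cross):
        _, _, gp = dense_cross
        y = np.random.default_rng(9).normal(size=gp.n)
        a = tq.scan(y, gp)
        b = tq.scan(3.5 * y - 7.0, gp)
        assert np.allclose(a["lop"], b["lop"], atol=1e-9)

    def test_engine_batch_matches_single(self, dense_cross):
        _, _, gp = dense_cross
        rng = np.random.default_rng(10)
        Y = rng.normal(size=(gp.n, 3))
        engine = ScanEngine(gp)
        _, P = engine.pvalues(Y)
        for k in range(3):
            single = tq.scan(Y[:, k], gp, engine=engine)
            assert np.allclose(single["pvalue"], P[:, k])

    def test_misaligned_phenotype_rejected(self, dense_cross):
        _, _, gp = dense_cross
        with pytest.raises(ValueError):
            tq.scan(np.ones(gp.n + 1), gp)


class TestReml:
    def test_identity_G_recovers_total_variance_and_flags(self):
        rng = np.random.default_rng(12)
        y = rng.normal(loc=5.0, scale=2.0, size=200)
        fit = reml_fit(y, np.eye(200))
        assert not fit.identifiable
        assert fit.sigma_q2 + fit.sigma_e2 == pytest.approx(y.var(ddof=1), rel=0.01)

    def test_null_traits_hit_boundary_often(self, dense_cross):
        """REML puts sigma_q^2 on the zero boundary ~half the time."""
        _, _, gp = dense_cross
        G = locus_G(gp.at(40))
        eig = np.linalg.eigh(G)
        rng = np.random.default_rng(13)
        zeros = 0
        for _ in range(40):
            fit = reml_fit(rng.normal(size=gp.n), G,
                           eig=(eig.eigenvalues, eig.eigenvectors))
            zeros += fit.sigma_q2 == 0.0
        assert zeros >= 16  # >= 40%

    def test_planted_signal_recovered(self, dense_cross):
        pmap, paths, gp = dense_cross
        G = locus_G(gp.at(gp.position_index(1, 50.0)))
        ests = []
        for rep in range(10):
            st = tq.simulate_trait(
                paths, pmap,
                tq.TraitModel(qtl_positions=[(1, 50.0)], qtl_h2=[0.3],
                              seed=500 + rep),
            )
            ests.append(tq.qtl_h2(reml_fit(st.phenotypes, G)))
        assert np.mean(ests) == pytest.approx(0.3, abs=0.08)


class TestQtlH2:
    @pytest.mark.parametrize(
        "sq,se,expected",
        [(298.04, 356.76, 0.46), (0.0, 1.0, 0.0), (2.0, 2.0, 0.5)],
    )
    def test_ratio(self, sq, se, expected):
        fit = VarianceFit(sq, se, 0.0, np.zeros(1))
        assert round(tq.qtl_h2(fit), 2) == expected

    def test_zero_variances_rejected(self):
        fit = VarianceFit(0.0, 0.0, 0.0, np.zeros(1))
        with pytest.raises(ValueError):
            tq.qtl_h2(fit)


@pytest.fixture(scope="module")
def multi_lg():
    p1, p2, pmap = tq.simulate_parents(
        n_lg=3, markers_per_lg=25, lg_length_cm=60, seed=61
    )
    d, _ = tq.simulate_population(p1, p2, pmap, n=80, seed=62)
    gp = tq.conditional_probs(d, pmap, tq.EmissionModel(0.02),
                              include_markers=False)
    y = np.random.default_rng(63).normal(size=80)
    return y, gp


class TestPermutationThreshold:
    def test_rank3_below_rank2_and_deterministic(self, multi_lg):
        y, gp = multi_lg
        a = tq.permutation_threshold(y, gp, n_perm=100, seed=7)
        b = tq.permutation_threshold(y, gp, n_perm=100, seed=7)
        assert a[3].value <= a[2].value
        assert a[2].value == b[2].value and a[3].value == b[3].value

    def test_too_few_lgs_rejected(self, multi_lg):
        y, gp = multi_lg
        with pytest.raises(ValueError, match="linkage groups"):
            tq.permutation_threshold(y, gp, n_perm=100, ranks=(2, 4), seed=1)

    def test_too_few_permutations_rejected(self, multi_lg):
        y, gp = multi_lg
        with pytest.raises(ValueError):
            tq.permutation_threshold(y, gp, n_perm=50, seed=1)


class TestCallPeaks:
    def _profile(self, positions, lops, lg=7):
        return pd.DataFrame(
            {"lg": lg, "position_cm": positions, "lop": lops}
        )

    def test_one_drop_interval_matches_published_shape(self):
        """A 4.29 spike with a >=3.29 shoulder spans the shoulder run."""
        pos = [20.0, 24.0, 26.42, 28.0, 31.11, 35.0, 38.38, 40.0]
        lop = [1.0, 2.0, 3.30, 3.60, 4.29, 3.50, 3.29, 2.0]
        peaks = call_peaks(self._profile(pos, lop), 3.0)
        (p,) = peaks
        assert p.peak_cm == 31.11 and p.peak_lop == 4.29
        assert (p.lower_cm, p.upper_cm) == (26.42, 38.38)

    def test_flat_profile_yields_no_peaks(self):
        peaks = call_peaks(self._profile([0, 1, 2], [0.5, 0.4, 0.3]), 3.0)
        assert peaks == []

    def test_plateau_tie_breaks_to_smallest_cm(self):
        peaks = call_peaks(self._profile([0, 1, 2, 3], [1, 4, 4, 1]), 3.0)
        assert peaks[0].peak_cm == 1.0

    def test_threshold_object_accepted(self):
        thr = Threshold(level=0.95, peak_rank=2, value=3.0, n_permutations=100)
        peaks = call_peaks(self._profile([0, 1], [5.0, 1.0]), thr)
        assert len(peaks) == 1

    def test_peak_annotation_with_reml_and_marker(self, dense_cross):
        pmap, paths, gp = dense_cross
        st = tq.simulate_trait(
            paths, pmap,
            tq.TraitModel(qtl_positions=[(1, 50.0)], qtl_h2=[0.4], seed=99),
        )
        profile = tq.scan(st.phenotypes, gp)
        peaks = call_peaks(profile, 3.0, y=st.phenotypes, probs=gp, pmap=pmap)
        assert peaks, "strong planted QTL must be detected"
        p = peaks[0]
        # single-replicate smoke check: peak lands near the planted QTL
        # (coverage rates are measured properly in the acceptance study)
        assert abs(p.peak_cm - 50.0) <= 15.0
        assert p.lower_cm <= p.peak_cm <= p.upper_cm
        assert 0.0 <= p.h_q2 <= 1.0
        assert p.nearest_marker in pmap.df["marker"].tolist()


class TestAlleleEffects:
    def test_equal_blups_give_zero_effects(self, dense_cross):
        _, _, gp = dense_cross
        fit = VarianceFit(1.0, 1.0, 0.0, np.full(gp.n, 2.5))
        eff = tq.allele_effects(fit, gp.at(0))
        assert np.allclose(eff.homolog, 0.0)
        assert np.allclose(eff.p1_pairs, 0.0)

    def test_planted_homolog_effect_is_largest(self, dense_cross):
        pmap, paths, gp = dense_cross
        model = tq.TraitModel(
            qtl_positions=[(1, 50.0)], qtl_h2=[0.35],
            allele_effects=[[1.0, 0, 0, 0, 0, 0, 0, 0]], seed=7,
        )
        st = tq.simulate_trait(paths, pmap, model)
        idx = gp.position_index(1, 50.0)
        fit = reml_fit(st.phenotypes, locus_G(gp.at(idx)))
        eff = tq.allele_effects(fit, gp.at(idx))
        assert np.argmax(eff.homolog) == 0
        # probability-weighted homolog effects balance within a parent
        Z = gp.at(idx)
        from tetraqtl.hmm_probs import PAIR_MEMBER
        w1 = Z.reshape(gp.n, 6, 6).sum(axis=2) @ PAIR_MEMBER
        weighted = (w1.sum(axis=0) / w1.sum()) @ (eff.homolog[:4])
        assert abs(weighted) < 1e-6 * max(1.0, np.abs(fit.blups).max()) + 0.02
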