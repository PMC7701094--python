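"""Simulator: meiosis laws, segregation, determinism, trait structure."""

import numpy as np
import pytest

import tetraqtl as tq
from tetraqtl.genotype_qc import expected_segregation, gamete_law
from tetraqtl.hmm_probs import haldane_r
from tetraqtl.sim_cross import MeiosisConfig, ParentalGenome, simulate_meiosis

from conftest import manual_map


def _single_lg_parent(phase_rows):
    phase_rows = np.asarray(phase_rows, dtype=np.int8)
    return ParentalGenome("P", {1: phase_rows.T.copy()})


class TestMeiosis:
    @pytest.mark.parametrize("dosage", [0, 1, 2, 3, 4])
    def test_gamete_dosage_is_hypergeometric(self, dosage):
        """Monte Carlo gamete dosages match C(d,k)C(4-d,2-k)/6 within 3 SE."""
        phase = np.zeros((1, 4), dtype=np.int8)
        phase[0, :dosage] = 1
        parent = _single_lg_parent(phase)
        pmap = manual_map([0.0], phase, np.zeros((1, 4)))
        rng = np.random.default_rng(42)
        n = 10_000
        counts = np.zeros(3)
        for _ in range(n):
            g = simulate_meiosis(parent, pmap, MeiosisConfig(), rng)
            counts[int(g.alleles[1][0])] += 1
        expected = gamete_law(dosage)
        for k in range(3):
            se = np.sqrt(max(expected[k] * (1 - expected[k]) / n, 1e-12))
            assert abs(counts[k] / n - expected[k]) <= 3 * se + 1e-9

    def test_progeny_distribution_is_convolution(self):
        """Simplex x nulliplex segregates 1:1 over dosages {0, 1}."""
        pmap = manual_map([0.0], [[1, 0, 0, 0]], [[0, 0, 0, 0]])
        p1 = _single_lg_parent([[1, 0, 0, 0]])
        p2 = _single_lg_parent([[0, 0, 0, 0]])
        dosages, _ = tq.simulate_population(
            p1, p2, pmap, n=4000, dosage_error=0.0, missing_rate=0.0, seed=7
        )
        vals = dosages.dosage[:, 0]
        assert set(np.unique(vals)) <= {0.0, 1.0}
        expected = expected_segregation(1, 0)
        assert expected[0] == expected[1] == 0.5
        se = np.sqrt(0.25 / 4000)
        assert abs(vals.mean() - 0.5) <= 3 * se

    def test_recombination_follows_haldane(self):
        """Chromatid-track switch rate between two markers matches Haldane."""
        x = 20.0
        phase = np.zeros((2, 4), dtype=np.int8)
        parent = _single_lg_parent(phase)
        pmap = manual_map([0.0, x], phase, phase)
        rng = np.random.default_rng(3)
        n = 5000
        switches = 0
        for _ in range(n):
            g = simulate_meiosis(parent, pmap, MeiosisConfig(), rng)
            tracks = g.homolog_tracks[1]
            switches += tracks[0, 0] != tracks[1, 0]
        r = haldane_r(x)
        se = np.sqrt(r * (1 - r) / n)
        assert abs(switches / n - r) <= 3 * se

    def test_zero_length_lg_never_recombines(self):
        phase = np.zeros((5, 4), dtype=np.int8)
        parent = _single_lg_parent(phase)
        pmap = manual_map(np.linspace(0, 1e-4, 5), phase, phase)
        rng = np.random.default_rng(11)
        for _ in range(50):
            g = simulate_meiosis(parent, pmap, MeiosisConfig(), rng)
            tracks = g.homolog_tracks[1]
            assert (tracks == tracks[0]).all()


class TestSimulateParents:
    def test_forced_spectrum_fixes_parental_dosages(self):
        _, _, pmap = tq.simulate_parents(
            n_lg=1, markers_per_lg=10, dosage_spectrum=[0, 1, 0, 0, 0], seed=5
        )
        pd_ = pmap.parental_dosages()
        assert (pd_["p1"] == 1).all() and (pd_["p2"] == 1).all()

    def test_study_scale_map_totals(self):
        """Default-scale map reaches ~11,292 markers over ~1,954 cM."""
        _, _, pmap = tq.simulate_parents(seed=1)
        assert pmap.n_markers == 11_292
        total = sum(pmap.positions(lg)[-1] - pmap.positions(lg)[0]
                    for lg in pmap.lgs)
        assert total == pytest.approx(1953.96, abs=0.5)

    def test_degenerate_spectrum_rejected(self):
        with pytest.raises(ValueError, match="no informative markers"):
            tq.simulate_parents(
                n_lg=1, markers_per_lg=5, dosage_spectrum=[0.5, 0, 0, 0, 0.5],
                seed=0,
            )

    def test_same_seed_reproduces_map(self):
        _, _, a = tq.simulate_parents(n_lg=2, markers_per_lg=30, seed=9)
        _, _, b = tq.simulate_parents(n_lg=2, markers_per_lg=30, seed=9)
        assert a.df.equals(b.df)


class TestSimulatePopulation:
    def test_error_free_observation_equals_truth(self, small_cross):
        p1, p2, pmap, _, _ = small_cross
        d, paths = tq.simulate_population(
            p1, p2, pmap, n=25, dosage_error=0.0, missing_rate=0.0, seed=55
        )
        assert not np.isnan(d.dosage).any()
        # recompute truth from inheritance paths and phases
        ph1, ph2 = pmap.phases(1)
        from tetraqtl.core import PAIRS
        pm = np.array([[1 if h in p else 0 for h in range(4)] for p in PAIRS])
        truth = (
            (pm[paths.p1_pair] * ph1[None, :, :]).sum(axis=2)
            + (pm[paths.p2_pair] * ph2[None, :, :]).sum(axis=2)
        )
        assert np.array_equal(d.dosage, truth.astype(float))

    def test_double_nulliplex_marker_yields_dosage_zero(self):
        pmap = manual_map([0.0, 5.0], [[0, 0, 0, 0], [1, 0, 0, 0]],
                          [[0, 0, 0, 0], [0, 0, 0, 0]])
        p1 = _single_lg_parent([[0, 0, 0, 0], [1, 0, 0, 0]])
        p2 = _single_lg_parent([[0, 0, 0, 0], [0, 0, 0, 0]])
        d, _ = tq.simulate_population(p1, p2, pmap, n=50, dosage_error=0.0,
                                      missing_rate=0.0, seed=8)
        assert (d.dosage[:, 0] == 0).all()

    def test_posteriors_sum_to_one_and_seed_reproduces(self, small_cross):
        p1, p2, pmap, _, _ = small_cross
        a, _ = tq.simulate_population(p1, p2, pmap, n=10, seed=77)
        b, _ = tq.simulate_population(p1, p2, pmap, n=10, seed=77)
        assert np.allclose(a.posterior.sum(axis=2), 1.0)
        assert np.array_equal(a.dosage, b.dosage, equal_nan=True)
        assert np.array_equal(a.posterior, b.posterior)

    def test_empty_population_rejected(self, small_cross):
        p1, p2, pmap, _, _ = small_cross
        with pytest.raises(ValueError):
            tq.simulate_population(p1, p2, pmap, n=0, seed=1)


class TestSimulateTrait:
    def test_null_model_gives_pure_noise(self, small_cross):
        *_, pmap, _, paths = small_cross
        st = tq.simulate_trait(paths, pmap, tq.TraitModel(seed=3))
        assert np.allclose(st.genetic_values, 0.0)
        assert st.phenotypes.std() > 0

    def test_h2_budget_enforced(self, small_cross):
        *_, pmap, _, paths = small_cross
        with pytest.raises(ValueError):
            tq.TraitModel(qtl_positions=[(1, 10.0)], qtl_h2=[1.2])
        with pytest.raises(ValueError):
            tq.TraitModel(qtl_positions=[(1, 10.0), (1, 40.0)], qtl_h2=[0.6, 0.5])

    def test_qtl_outside_map_rejected(self, small_cross):
        *_, pmap, _, paths = small_cross
        model = tq.TraitModel(qtl_positions=[(1, 500.0)], qtl_h2=[0.2], seed=1)
        with pytest.raises(ValueError, match="outside"):
            tq.simulate_trait(paths, pmap, model)

    def test_residual_is_uncorrelated_with_genetic_value(self, dense_cross):
        pmap, paths, _ = dense_cross
        model = tq.TraitModel(qtl_positions=[(1, 50.0)], qtl_h2=[0.3], seed=21)
        st = tq.simulate_trait(paths, pmap, model)
        e = st.phenotypes - st.genetic_values
        g = st.genetic_values
        assert abs(np.corrcoef(e, g)[0, 1]) < 1e-10
        assert np.std(e - e.mean()) == pytest.approx(1.0, rel=1e-9)
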