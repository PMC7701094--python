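"""Calibration and recovery studies for the scan machinery.

Self-contained simulation studies that measure, under the generator's
study conditions (n = 237 offspring, 12 linkage groups for genome-wide
questions), the operating characteristics of the pipeline: type-I
error of the ranked permutation thresholds, recovery of planted QTL
heritabilities, coverage of LOP 1-drop support intervals, two-point
recombination-fraction recovery, and uniformity of score-test p-values
under the permutation null.  Maps are scaled down from the study's
~941 markers / 162.83 cM per linkage group to keep each study at
desk scale; see docs/methods.md for the chosen problem sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import sim_cross
from .core import PHASE_COLUMNS, PhasedMap
from .hmm_probs import EmissionModel, conditional_probs, haldane_cm, pairwise_rf
from .qtl_scan import ScanEngine, qtl_h2, reml_fit
from .relationship import locus_G


def _seeds(seed: int, k: int) -> list[int]:
    """Derive k independent child seeds (< 2**31) from one master seed."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(seed).spawn(k)]


def null_threshold_study(
    seed: int,
    n_reps: int = 500,
    n_perm: int = 100,
    n: int = 237,
    n_lg: int = 12,
    markers_per_lg: int = 40,
    lg_length_cm: float = 100.0,
    level: float = 0.95,
) -> dict:
    """Type-I error of the ranked permutation thresholds under the null.

    One simulated 12-LG population is scanned with ``n_reps``
    independent pure-noise traits; for each trait the rank-2 and rank-3
    thresholds are estimated from ``n_perm`` fresh permutations of that
    trait, and exceedance of the threshold by the trait's own rank-k
    genome-wide peak is recorded.  By exchangeability the rank-k
    exceedance rate should sit near 1 - level.
    """
    s = _seeds(seed, 4)
    p1, p2, pmap = sim_cross.simulate_parents(
        n_lg=n_lg, markers_per_lg=markers_per_lg, lg_length_cm=lg_length_cm,
        seed=s[0],
    )
    dosages, _ = sim_cross.simulate_population(p1, p2, pmap, n=n, seed=s[1])
    gp = conditional_probs(dosages, pmap, EmissionModel(0.02),
                           include_markers=False)
    engine = ScanEngine(gp)
    lg_idx = [gp.lg_indices(lg) for lg in gp.lgs]
    rng = np.random.default_rng(s[2])
    exceed = {2: 0, 3: 0}
    thr_sum = {2: 0.0, 3: 0.0}
    for _ in range(n_reps):
        y = rng.normal(size=n)
        perms = np.stack([rng.permutation(n) for _ in range(n_perm)], axis=1)
        Y = np.concatenate([y[:, None], y[perms]], axis=1)
        _, p = engine.pvalues(Y)
        lop = -np.log10(p)
        per_lg = np.stack([lop[ix].max(axis=0) for ix in lg_idx])
        ordered = np.sort(per_lg, axis=0)[::-1]  # rank 1 first
        for k in (2, 3):
            thr = np.quantile(ordered[k - 1, 1:], level, method="higher")
            thr_sum[k] += thr
            exceed[k] += ordered[k - 1, 0] > thr
    return {
        "rank2_rate": exceed[2] / n_reps,
        "rank3_rate": exceed[3] / n_reps,
        "mean_threshold_rank2": thr_sum[2] / n_reps,
        "mean_threshold_rank3": thr_sum[3] / n_reps,
        "n_reps": n_reps,
        "n_perm": n_perm,
    }


def _dense_population(seed: int, n: int = 237, markers: int = 150,
                      length_cm: float = 100.0):
    """One-LG population dense enough for near-certain class posteriors."""
    s = _seeds(seed, 2)
    p1, p2, pmap = sim_cross.simulate_parents(
        n_lg=1, markers_per_lg=markers, lg_length_cm=length_cm, seed=s[0]
    )
    dosages, paths = sim_cross.simulate_population(
        p1, p2, pmap, n=n, dosage_error=0.02, missing_rate=0.05, seed=s[1]
    )
    gp = conditional_probs(dosages, pmap, EmissionModel(0.02),
                           include_markers=False)
    return pmap, paths, gp


def qtl_recovery_study(
    seed: int,
    targets: tuple = (0.16, 0.19, 0.27),
    n_reps: int = 200,
    n: int = 237,
    qtl_cm: float = 50.0,
    detect_lop: float = 3.0,
) -> dict:
    """Recovery of planted QTL heritabilities and 1-drop interval coverage.

    For each target h_q^2, ``n_reps`` traits are planted at ``qtl_cm``
    on a dense single linkage group (fresh homolog effects per
    replicate); h_q^2 is re-estimated by REML at the true position, and
    each trait is scanned to check whether the LOP 1-drop interval of
    a detected peak (peak LOP >= ``detect_lop``) covers the planted
    position.
    """
    pmap, paths, gp = _dense_population(seed, n=n)
    engine = ScanEngine(gp)
    idx = gp.position_index(1, qtl_cm)
    G = locus_G(gp.at(idx))
    eig = np.linalg.eigh(0.5 * (G + G.T))
    eig = (eig.eigenvalues, eig.eigenvectors)
    positions = gp.grid["position_cm"].to_numpy(float)
    rep_seeds = _seeds(seed + 1, len(targets))
    out = {"targets": list(targets), "bias": [], "mean_estimate": [],
           "n_reps": n_reps}
    detected = 0
    covered = 0
    for h2t, rs in zip(targets, rep_seeds):
        ests = []
        Y = np.empty((n, n_reps))
        for rep in range(n_reps):
            st = sim_cross.simulate_trait(
                paths, pmap,
                sim_cross.TraitModel(qtl_positions=[(1, qtl_cm)],
                                     qtl_h2=[h2t], seed=rs + rep),
            )
            Y[:, rep] = st.phenotypes
            fit = reml_fit(st.phenotypes, G, eig=eig)
            ests.append(qtl_h2(fit))
        out["mean_estimate"].append(float(np.mean(ests)))
        out["bias"].append(float(np.mean(ests) - h2t))
        _, p = engine.pvalues(Y)
        lop = -np.log10(p)  # (P, n_reps)
        for rep in range(n_reps):
            prof = lop[:, rep]
            i = int(np.argmax(prof))
            if prof[i] < detect_lop:
                continue
            detected += 1
            lo = i
            while lo > 0 and prof[lo - 1] >= prof[i] - 1.0:
                lo -= 1
            hi = i
            while hi < len(prof) - 1 and prof[hi + 1] >= prof[i] - 1.0:
                hi += 1
            if positions[lo] - 1e-9 <= qtl_cm <= positions[hi] + 1e-9:
                covered += 1
    out["n_detected"] = detected
    out["interval_coverage"] = covered / detected if detected else float("nan")
    out["max_abs_bias"] = float(np.max(np.abs(out["bias"])))
    return out


def _two_marker_map(r_true: float) -> tuple:
    """Simplex-coupling parent pair with two markers at distance d(r)."""
    d = float(haldane_cm(r_true))
    hom1 = np.zeros((4, 2), dtype=np.int8)
    hom1[0, :] = 1  # coupling: homolog 1 carries both alternate alleles
    hom2 = np.zeros((4, 2), dtype=np.int8)
    rows = [
        ["m1", 1, 0.0, *hom1[:, 0], *hom2[:, 0]],
        ["m2", 1, d, *hom1[:, 1], *hom2[:, 1]],
    ]
    pmap = PhasedMap(pd.DataFrame(
        rows, columns=["marker", "lg", "position_cm", *PHASE_COLUMNS]))
    return (
        sim_cross.ParentalGenome("P1", {1: hom1}),
        sim_cross.ParentalGenome("P2", {1: hom2}),
        pmap,
    )


def rf_recovery_study(
    seed: int, n_reps: int = 200, n: int = 200, r_true: float = 0.1,
    window: tuple = (0.05, 0.16),
) -> dict:
    """Sampling behavior of the two-point recombination-fraction MLE."""
    p1, p2, pmap = _two_marker_map(r_true)
    rep_seeds = _seeds(seed, n_reps)
    r_hats = []
    for rs in rep_seeds:
        dosages, _ = sim_cross.simulate_population(
            p1, p2, pmap, n=n, dosage_error=0.0, missing_rate=0.0, seed=rs
        )
        r_hat, _ = pairwise_rf(dosages, "m1", "m2", pmap)
        r_hats.append(r_hat)
    r_hats = np.asarray(r_hats)
    inside = float(np.mean((r_hats > window[0]) & (r_hats < window[1])))
    return {
        "r_true": r_true,
        "mean_r_hat": float(r_hats.mean()),
        "rate_in_window": inside,
        "n_reps": n_reps,
        "n": n,
    }


def pvalue_uniformity_study(seed: int, n_perm: int = 1000,
                            position_cm: float = 50.0) -> dict:
    """KS uniformity of score-test p-values under the permutation null."""
    _, _, gp = _dense_population(seed, n=237)
    engine = ScanEngine(gp)
    idx = gp.position_index(1, position_cm)
    rng = np.random.default_rng(_seeds(seed + 2, 1)[0])
    y = rng.normal(size=237)
    perms = np.stack([rng.permutation(y.size) for _ in range(n_perm)], axis=1)
    _, p = engine.pvalues(y[perms])
    ks = stats.kstest(p[idx], "uniform")
    return {"ks_statistic": float(ks.statistic), "ks_pvalue": float(ks.pvalue),
            "n_perm": n_perm}
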