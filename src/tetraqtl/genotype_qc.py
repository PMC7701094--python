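"""Dosage-level marker quality control for tetraploid F1 populations.

The filter chain applied before mapping:

1. dosage calls whose maximum posterior probability falls below a
   confidence threshold (default 0.80) become missing;
2. markers with more than a maximum fraction of missing calls (default
   20%, strict inequality) are dropped;
3. markers whose progeny dosage counts deviate from the polysomic
   Mendelian expectation (chi-square goodness of fit, Bonferroni-
   corrected at alpha = 0.05) are dropped.

The expected progeny distribution of a marker is the convolution of the
two parental gamete laws, each hypergeometric:
P(k | d) = C(d, k) C(4 - d, 2 - k) / C(4, 2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import stats

from .core import DosageMatrix, PhasedMap


@dataclass
class FilterReport:
    """Per-stage retained-marker counts and per-marker rejection reasons."""

    stage_counts: list = field(default_factory=list)  # [(stage, n_retained)]
    rejections: dict = field(default_factory=dict)  # marker -> reason

    def record(self, stage: str, n_retained: int) -> None:
        if self.stage_counts and n_retained > self.stage_counts[-1][1]:
            raise ValueError("retained counts must be non-increasing")
        self.stage_counts.append((stage, n_retained))

    def reject(self, marker: str, reason: str) -> None:
        self.rejections.setdefault(marker, reason)

    def to_json(self, path) -> None:
        payload = {
            "stage_counts": [{"stage": s, "retained": n} for s, n in self.stage_counts],
            "rejections": self.rejections,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def mask_low_confidence(
    dosages: DosageMatrix, threshold: float = 0.80
) -> DosageMatrix:
    """Set dosage calls with max posterior < threshold to missing.

    Confident cells are re-called as the argmax dosage class.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if dosages.posterior is None:
        raise ValueError("posterior probabilities required")
    best = dosages.posterior.max(axis=2)
    call = dosages.posterior.argmax(axis=2).astype(float)
    call[best < threshold] = np.nan
    return DosageMatrix(
        list(dosages.individuals), list(dosages.markers), call, dosages.posterior
    )


def filter_missing(
    dosages: DosageMatrix,
    max_missing: float = 0.20,
    report: FilterReport | None = None,
):
    """Drop markers whose missing fraction strictly exceeds ``max_missing``."""
    if dosages.n < 1:
        raise ValueError("empty population")
    report = report or FilterReport()
    frac = dosages.missing_fraction()
    keep = frac <= max_missing
    for m, bad in zip(dosages.markers, ~keep):
        if bad:
            report.reject(m, "missing_fraction")
    out = dosages.subset_markers([m for m, k in zip(dosages.markers, keep) if k])
    report.record("missing_filter", out.m)
    return out, report


def gamete_law(d: int) -> np.ndarray:
    """Hypergeometric gamete dosage law of a parent with dosage ``d``.

    P(k) = C(d, k) C(4 - d, 2 - k) / C(4, 2) over k = 0, 1, 2.
    """
    if d not in (0, 1, 2, 3, 4):
        raise ValueError("parental dosage must be in 0..4")
    return np.array([comb(d, k) * comb(4 - d, 2 - k) for k in (0, 1, 2)]) / comb(4, 2)


def expected_segregation(d1: int, d2: int) -> np.ndarray:
    """Expected progeny dosage distribution (0..4) under polysomic meiosis.

    Convolution of the two parental hypergeometric gamete laws; sums to
    1 exactly.
    """
    return np.convolve(gamete_law(d1), gamete_law(d2))


def segregation_test(counts: np.ndarray, d1: int, d2: int) -> float:
    """Chi-square goodness-of-fit p-value of observed progeny counts.

    Classes with expected probability zero are excluded from the
    statistic; df = (non-empty classes - 1).  Observations in a
    zero-expectation class are dosage-call errors rather than
    segregation signal and are excluded from the test, except in the
    degenerate single-support-class case where any disagreement makes
    the marker impossible under the model (p = 0).
    """
    counts = np.asarray(counts, dtype=float)
    expected = expected_segregation(d1, d2)
    support = expected > 0
    if support.sum() == 1:
        return 0.0 if counts[~support].sum() > 0 else 1.0
    f_obs = counts[support]
    n = f_obs.sum()
    if n == 0:
        return 1.0
    f_exp = expected[support] * n
    return float(stats.chisquare(f_obs, f_exp).pvalue)


def segregation_filter(
    dosages: DosageMatrix,
    pmap: PhasedMap,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    report: FilterReport | None = None,
):
    """Drop markers with Mendelian segregation distortion.

    A marker is dropped when its goodness-of-fit p-value falls below
    ``alpha / M`` with M the number of markers entering the test.
    """
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is supported")
    report = report or FilterReport()
    pdos = pmap.parental_dosages().set_index("marker")
    missing_parents = [m for m in dosages.markers if m not in pdos.index]
    if missing_parents:
        raise ValueError(f"parental dosages unknown for {missing_parents[:3]}...")
    M = dosages.m
    cutoff = alpha / M
    keep = []
    for j, marker in enumerate(dosages.markers):
        col = dosages.dosage[:, j]
        col = col[~np.isnan(col)]
        counts = np.bincount(col.astype(int), minlength=5)[:5]
        p = segregation_test(counts, int(pdos.loc[marker, "p1"]), int(pdos.loc[marker, "p2"]))
        if p < cutoff:
            report.reject(marker, "segregation_distortion")
        else:
            keep.append(marker)
    out = dosages.subset_markers(keep)
    report.record("segregation_filter", out.m)
    return out, report


def qc_chain(
    dosages: DosageMatrix,
    pmap: PhasedMap,
    min_posterior: float = 0.80,
    max_missing: float = 0.20,
    alpha: float = 0.05,
):
    """Full filter chain: confidence mask -> missing filter -> segregation.

    Returns the filtered matrix and a report with the stage counts.
    Stages never resurrect a dropped marker.
    """
    report = FilterReport()
    report.record("input", dosages.m)
    if dosages.posterior is not None:
        dosages = mask_low_confidence(dosages, min_posterior)
        report.record("confidence_mask", dosages.m)
    dosages, report = filter_missing(dosages, max_missing, report)
    dosages, report = segregation_filter(dosages, pmap, alpha, report=report)
    return dosages, report
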