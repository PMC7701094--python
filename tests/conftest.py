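"""Shared fixtures: small simulated crosses generated at test time."""

import numpy as np
import pandas as pd
import pytest

import tetraqtl as tq
from tetraqtl.core import PHASE_COLUMNS


@pytest.fixture(scope="session")
def small_cross():
    """One-LG cross: 20 markers / 50 cM, 40 offspring, clean-ish calls."""
    p1, p2, pmap = tq.simulate_parents(
        n_lg=1, markers_per_lg=20, lg_length_cm=50.0, seed=101
    )
    dosages, paths = tq.simulate_population(
        p1, p2, pmap, n=40, dosage_error=0.02, missing_rate=0.05, seed=102
    )
    return p1, p2, pmap, dosages, paths


@pytest.fixture(scope="session")
def dense_cross():
    """Dense one-LG cross (150 markers / 100 cM, n=120) with probabilities."""
    p1, p2, pmap = tq.simulate_parents(
        n_lg=1, markers_per_lg=150, lg_length_cm=100.0, seed=201
    )
    dosages, paths = tq.simulate_population(
        p1, p2, pmap, n=120, dosage_error=0.02, missing_rate=0.05, seed=202
    )
    gp = tq.conditional_probs(
        dosages, pmap, tq.EmissionModel(0.02), include_markers=False
    )
    return pmap, paths, gp


def manual_map(positions_cm, phase1_rows, phase2_rows, lg=1):
    """Build a PhasedMap from explicit per-marker phases.

    ``phase*_rows`` are (m, 4) 0/1 arrays: allele of each homolog at
    each marker.
    """
    phase1_rows = np.asarray(phase1_rows)
    phase2_rows = np.asarray(phase2_rows)
    rows = [
        [f"m{j + 1}", lg, float(p), *phase1_rows[j], *phase2_rows[j]]
        for j, p in enumerate(positions_cm)
    ]
    return tq.PhasedMap(
        pd.DataFrame(rows, columns=["marker", "lg", "position_cm", *PHASE_COLUMNS])
    )
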