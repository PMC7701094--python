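"""Synthetic autotetraploid F1 crosses with planted QTLs.

The generator mirrors the statistical structure the downstream analysis
assumes: two heterozygous tetraploid parents, polysomic (bivalent)
meiosis without double reduction, crossovers as a no-interference
Poisson process (Haldane map function), dosage-call error uniform over
the four incorrect classes, and traits built from additive effects of
the eight parental homologs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    PAIR_INDEX,
    PHASE_COLUMNS,
    DosageMatrix,
    PhasedMap,
)

#: the three bivalent pairing configurations of four homologs
PAIRINGS: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = (
    ((0, 1), (2, 3)),
    ((0, 2), (1, 3)),
    ((0, 3), (1, 2)),
)

#: default spectrum over parental dosages 0..4 (nulliplex..quadruplex);
#: weighted toward simplex/duplex configurations typical of F1 maps
DEFAULT_DOSAGE_SPECTRUM = np.array([0.30, 0.30, 0.20, 0.15, 0.05])


@dataclass
class ParentalGenome:
    """Phased genome of one tetraploid parent.

    ``homologs`` maps each linkage group to a (4, m) 0/1 array, one row
    per homolog.
    """

    parent_id: str
    homologs: dict

    def __post_init__(self):
        for lg, h in self.homologs.items():
            h = np.asarray(h, dtype=np.int8)
            if h.ndim != 2 or h.shape[0] != 4 or h.shape[1] < 1:
                raise ValueError(f"LG {lg!r}: need a (4, m>=1) homolog array")
            if not np.isin(h, (0, 1)).all():
                raise ValueError(f"LG {lg!r}: alleles must be 0/1")
            self.homologs[lg] = h


@dataclass
class MeiosisConfig:
    """Meiosis parameters: bivalent pairing only, no double reduction."""

    crossover_rate: float = 1.0  # expected crossovers per bivalent per Morgan
    pairing: str = "random_bivalent"
    seed: int | None = None

    def __post_init__(self):
        if self.pairing != "random_bivalent":
            raise ValueError("only random bivalent pairing is supported")
        if self.crossover_rate < 0:
            raise ValueError("crossover_rate must be non-negative")


@dataclass
class InheritancePath:
    """Ground-truth transmitted homolog pairs, aligned to map markers.

    ``p1_pair`` / ``p2_pair`` are (n, M) arrays of pair indices (0-5,
    lexicographic over the six 2-subsets of the four homologs), one
    column per marker in map order.
    """

    individuals: list
    markers: list
    p1_pair: np.ndarray
    p2_pair: np.ndarray

    def class_indices(self) -> np.ndarray:
        """(n, M) indices into the 36 genotype classes."""
        return 6 * self.p1_pair.astype(int) + self.p2_pair.astype(int)


@dataclass
class TraitModel:
    """Additive QTL trait model: y = mu + sum of homolog effects + noise.

    ``allele_effects`` holds, per QTL, eight per-homolog effects (four
    for each parent); when None they are drawn i.i.d. standard normal,
    which makes the variance-component working model exact in
    expectation.  ``qtl_h2`` targets the model-scale QTL heritability
    h_q^2 = sigma_q^2 / (sum sigma_q^2 + sigma_e^2), where sigma_q^2 is
    the variance scale of the relationship-matrix model (diagonal of
    the IBD sharing matrix = 1).  In a single full-sib family roughly
    half of sigma_q^2 is the family-mean component shared by all
    offspring, so the phenotypic variance fraction realized in-sample
    is smaller than the nominal h_q^2 by the mean centered IBD share
    (~0.5); effects are rescaled against that share so the REML
    estimate of h_q^2 is centered on the target.
    """

    qtl_positions: list = field(default_factory=list)  # [(lg, cM), ...]
    qtl_h2: list = field(default_factory=list)
    allele_effects: list | None = None
    residual_sd: float = 1.0
    mu: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if len(self.qtl_positions) != len(self.qtl_h2):
            raise ValueError("one h2 per QTL position required")
        if any(h < 0 for h in self.qtl_h2) or sum(self.qtl_h2) >= 1:
            raise ValueError("qtl_h2 values must be >= 0 and sum to < 1")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")


@dataclass
class SimulatedTrait:
    """Phenotypes plus the latent genetic values that produced them."""

    table: pd.DataFrame  # genotype, trait, year, value
    genetic_values: np.ndarray
    phenotypes: np.ndarray


def simulate_parents(
    n_lg: int = 12,
    markers_per_lg: int = 941,
    lg_length_cm: float = 162.83,
    dosage_spectrum: np.ndarray | None = None,
    seed: int | None = None,
):
    """Draw two phased tetraploid parents and their shared marker map.

    Defaults are study-scale: 12 linkage groups of 162.83 cM carrying
    941 markers each (~11,292 markers over ~1,954 cM).  Marker positions
    are uniformly spaced within each LG.  Parental dosages are drawn
    independently from ``dosage_spectrum``; marker configurations with
    no heterozygous parent are redrawn, so every marker segregates.

    Returns
    -------
    (ParentalGenome, ParentalGenome, PhasedMap)
    """
    if markers_per_lg < 2:
        raise ValueError("markers_per_lg must be >= 2")
    if lg_length_cm <= 0:
        raise ValueError("lg_length_cm must be positive")
    spectrum = DEFAULT_DOSAGE_SPECTRUM if dosage_spectrum is None else np.asarray(
        dosage_spectrum, dtype=float
    )
    if spectrum.shape != (5,) or (spectrum < 0).any() or spectrum.sum() <= 0:
        raise ValueError("dosage_spectrum must be 5 non-negative weights")
    spectrum = spectrum / spectrum.sum()
    if spectrum[1:4].sum() == 0:
        # both parents can only be homozygous -> nothing ever segregates
        raise ValueError("no informative markers possible")

    rng = np.random.default_rng(seed)
    hom1: dict = {}
    hom2: dict = {}
    rows = []
    for g in range(1, n_lg + 1):
        lg = g
        positions = np.linspace(0.0, lg_length_cm, markers_per_lg)
        h1 = np.zeros((4, markers_per_lg), dtype=np.int8)
        h2 = np.zeros((4, markers_per_lg), dtype=np.int8)
        for j in range(markers_per_lg):
            while True:
                d1, d2 = rng.choice(5, size=2, p=spectrum)
                if d1 in (1, 2, 3) or d2 in (1, 2, 3):
                    break
            h1[rng.permutation(4)[: int(d1)], j] = 1
            h2[rng.permutation(4)[: int(d2)], j] = 1
        hom1[lg] = h1
        hom2[lg] = h2
        for j in range(markers_per_lg):
            rows.append(
                [f"lg{lg}_m{j + 1}", lg, positions[j], *h1[:, j], *h2[:, j]]
            )
    df = pd.DataFrame(rows, columns=["marker", "lg", "position_cm", *PHASE_COLUMNS])
    pmap = PhasedMap(df)
    return (
        ParentalGenome("P1", hom1),
        ParentalGenome("P2", hom2),
        pmap,
    )


@dataclass
class Gamete:
    """One meiotic product: homolog-origin tracks and its allele sums."""

    homolog_tracks: dict  # lg -> (m, 2) transmitted homolog indices
    alleles: dict  # lg -> (m,) 0/1/2 allele counts


def _bivalent_track(
    positions: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """0/1 chromatid track along one bivalent (Poisson crossovers)."""
    length_m = (positions[-1] - positions[0]) / 100.0 if len(positions) > 1 else 0.0
    start = rng.integers(2)
    n_x = rng.poisson(rate * length_m) if length_m > 0 else 0
    if n_x == 0:
        return np.full(len(positions), start, dtype=np.int8)
    xpos = rng.uniform(positions[0], positions[-1], size=n_x)
    crossings = (xpos[None, :] < positions[:, None]).sum(axis=1)
    return ((start + crossings) % 2).astype(np.int8)


def simulate_meiosis(
    parent: ParentalGenome, pmap: PhasedMap, cfg: MeiosisConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Gamete:
    """Simulate one gamete under bivalent polysomic meiosis.

    Per linkage group a pairing configuration is drawn uniformly from
    the three possibilities; within each bivalent the transmitted
    chromatid switches homolog at Poisson crossover points (rate
    ``crossover_rate`` per Morgan, no interference), so adjacent-marker
    recombination follows Haldane's map function.
    """
    cfg = cfg or MeiosisConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    tracks: dict = {}
    alleles: dict = {}
    for lg in pmap.lgs:
        positions = pmap.positions(lg)
        if not np.isfinite(positions).all():
            raise ValueError(f"non-finite positions on LG {lg!r}")
        hom = parent.homologs[lg]
        pairing = PAIRINGS[rng.integers(3)]
        per_marker = np.empty((len(positions), 2), dtype=np.int8)
        for b, bivalent in enumerate(pairing):
            track = _bivalent_track(positions, cfg.crossover_rate, rng)
            per_marker[:, b] = np.asarray(bivalent, dtype=np.int8)[track]
        tracks[lg] = per_marker
        alleles[lg] = hom[per_marker[:, 0], np.arange(len(positions))] + hom[
            per_marker[:, 1], np.arange(len(positions))
        ]
    return Gamete(tracks, alleles)


def simulate_population(
    parent1: ParentalGenome,
    parent2: ParentalGenome,
    pmap: PhasedMap,
    n: int = 237,
    dosage_error: float = 0.02,
    missing_rate: float = 0.05,
    posterior_sharpness: float = 8.0,
    crossover_rate: float = 1.0,
    seed: int | None = None,
):
    """Simulate an F1 population of ``n`` offspring.

    The true dosage of an offspring is the allele sum of the four
    transmitted homologs.  Observed dosages equal the truth with
    probability ``1 - dosage_error`` and are otherwise uniform over the
    four other classes.  Per-cell posterior vectors put mass
    ``p ~ Beta(a_j, 1)`` on the observed class (the rest spread
    uniformly), emulating dosage-caller confidence; marker quality is
    heterogeneous, with per-marker concentration a_j drawn uniformly
    from 0.25-2.5 times ``posterior_sharpness`` (mimicking variable
    capture depth, so a realistic fraction of markers later fails the
    low-confidence/missingness filters).  Cells are flagged missing
    with probability ``missing_rate`` (uniform 0.2 posterior).

    Returns
    -------
    (DosageMatrix, InheritancePath)
    """
    if n < 1:
        raise ValueError("population size n must be >= 1")
    if not (0 <= dosage_error < 1 and 0 <= missing_rate < 1):
        raise ValueError("dosage_error and missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cfg = MeiosisConfig(crossover_rate=crossover_rate)
    markers = pmap.df["marker"].tolist()
    M = len(markers)
    individuals = [f"F1_{i + 1:04d}" for i in range(n)]

    truth = np.empty((n, M), dtype=np.int8)
    p1_pair = np.empty((n, M), dtype=np.int8)
    p2_pair = np.empty((n, M), dtype=np.int8)
    # marker column offsets per LG within the concatenated map order
    offsets = {}
    off = 0
    for lg in pmap.lgs:
        m_lg = len(pmap.lg_frame(lg))
        offsets[lg] = (off, off + m_lg)
        off += m_lg

    for i in range(n):
        g1 = simulate_meiosis(parent1, pmap, cfg, rng)
        g2 = simulate_meiosis(parent2, pmap, cfg, rng)
        for lg in pmap.lgs:
            a, b = offsets[lg]
            truth[i, a:b] = g1.alleles[lg] + g2.alleles[lg]
            t1 = np.sort(g1.homolog_tracks[lg], axis=1)
            t2 = np.sort(g2.homolog_tracks[lg], axis=1)
            p1_pair[i, a:b] = [PAIR_INDEX[(x, y)] for x, y in t1]
            p2_pair[i, a:b] = [PAIR_INDEX[(x, y)] for x, y in t2]

    observed = truth.astype(float)
    if dosage_error > 0:
        err = rng.random((n, M)) < dosage_error
        # uniform over the four dosages other than the truth
        shift = rng.integers(1, 5, size=(n, M))
        observed[err] = (truth[err] + shift[err]) % 5

    posterior = np.full((n, M, 5), 0.2)
    sharp = posterior_sharpness * rng.uniform(0.25, 2.5, size=M)
    p_top = rng.beta(np.broadcast_to(sharp, (n, M)), 1.0)
    obs_idx = observed.astype(int)
    ii, jj = np.meshgrid(np.arange(n), np.arange(M), indexing="ij")
    posterior[:] = ((1.0 - p_top) / 4.0)[..., None]
    posterior[ii, jj, obs_idx] = p_top

    missing = rng.random((n, M)) < missing_rate
    observed[missing] = np.nan
    posterior[missing] = 0.2

    dosages = DosageMatrix(individuals, markers, observed, posterior)
    paths = InheritancePath(individuals, markers, p1_pair, p2_pair)
    return dosages, paths


def genetic_values(
    paths: InheritancePath,
    pmap: PhasedMap,
    lg,
    position_cm: float,
    effects8: np.ndarray,
) -> np.ndarray:
    """Per-offspring genetic value at the marker nearest a map position.

    ``effects8`` holds four parent-1 homolog effects followed by four
    parent-2 homolog effects; an offspring's value is the sum over its
    four transmitted homologs.
    """
    sub = pmap.lg_frame(lg)
    pos = sub["position_cm"].to_numpy(float)
    if not (pos.min() - 1e-9 <= position_cm <= pos.max() + 1e-9):
        raise ValueError(f"position {position_cm} cM outside LG {lg!r}")
    marker = sub["marker"].iloc[int(np.argmin(np.abs(pos - position_cm)))]
    j = paths.markers.index(marker)
    effects8 = np.asarray(effects8, dtype=float)
    pair_members = np.array([[a, b] for a, b in (
        (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))])
    e1 = effects8[:4][pair_members].sum(axis=1)  # per pair index
    e2 = effects8[4:][pair_members].sum(axis=1)
    return e1[paths.p1_pair[:, j]] + e2[paths.p2_pair[:, j]]


# shared-homolog count between two transmitted pairs (6 x 6)
_PAIR_SHARE = np.array(
    [[len(set(a) & set(b)) for b in (
        (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))]
     for a in ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))],
    dtype=float,
)


def _centered_ibd_share(paths: InheritancePath, j: int) -> float:
    """Mean centered IBD self-share at marker column ``j``.

    tr(C S C)/n for the true-class sharing matrix S (diagonal 1); this
    is the factor linking the model-scale QTL variance sigma_q^2 to the
    in-sample genetic variance of a single full-sib family (~0.5).
    """
    s1 = _PAIR_SHARE[np.ix_(paths.p1_pair[:, j], paths.p1_pair[:, j])]
    s2 = _PAIR_SHARE[np.ix_(paths.p2_pair[:, j], paths.p2_pair[:, j])]
    S = (s1 + s2) / 4.0
    return float(1.0 - S.mean())


def simulate_trait(
    paths: InheritancePath,
    pmap: PhasedMap,
    model: TraitModel,
    trait: str = "trait",
    year: int = 2019,
) -> SimulatedTrait:
    """Simulate a quantitative trait with planted QTLs.

    Per QTL, sigma_q^2 = h_q^2 * sigma_T^2 with sigma_T^2 =
    sigma_e^2 / (1 - sum h^2); the QTL genetic values are rescaled so
    their centered sample variance equals sigma_q^2 times the mean
    centered IBD share of the family at the QTL (the in-sample variance
    the relationship-matrix model attributes to that sigma_q^2).  The
    residual is drawn at ``residual_sd`` and decorrelated in-sample
    from the genetic value.
    """
    rng = np.random.default_rng(model.seed)
    n = len(paths.individuals)
    sigma_e2 = model.residual_sd**2
    total_h2 = float(sum(model.qtl_h2))
    sigma_t2 = sigma_e2 / (1.0 - total_h2) if total_h2 > 0 else sigma_e2

    g = np.zeros(n)
    for k, ((lg, cm), h2) in enumerate(zip(model.qtl_positions, model.qtl_h2)):
        if model.allele_effects is not None:
            eff = np.asarray(model.allele_effects[k], dtype=float)
        else:
            eff = rng.normal(size=8)
        gk = genetic_values(paths, pmap, lg, cm, eff)
        gk = gk - gk.mean()
        sd = gk.std()
        if h2 > 0:
            if sd == 0:
                raise ValueError("planted QTL is monomorphic in this population")
            sub = pmap.lg_frame(lg)
            pos = sub["position_cm"].to_numpy(float)
            marker = sub["marker"].iloc[int(np.argmin(np.abs(pos - cm)))]
            c_share = _centered_ibd_share(paths, paths.markers.index(marker))
            sigma_q2 = h2 * sigma_t2
            gk = gk * np.sqrt(sigma_q2 * c_share) / sd
        else:
            gk = np.zeros(n)
        g += gk

    e = rng.normal(scale=model.residual_sd, size=n)
    e = e - e.mean()
    if g.std() > 0:
        e = e - (e @ g) / (g @ g) * g  # decorrelate in-sample
    if e.std() > 0:
        e = e * model.residual_sd / e.std()
    y = model.mu + g + e
    table = pd.DataFrame(
        {"genotype": paths.individuals, "trait": trait, "year": year, "value": y}
    )
    return SimulatedTrait(table, g, y)
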