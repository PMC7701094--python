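"""Multipoint genotype-class probabilities for tetraploid F1 offspring.

A hidden Markov model on each linkage group assigns every offspring a
conditional probability over the 36 possible parental-homolog
combinations (the 6 x 6 unordered pairs transmitted by each parent) at
every grid position, given its observed allele dosages and the phased
parental map.

Hidden state
    Per parent: (bivalent pairing configuration, chromatid choice in
    each bivalent) = 3 x 4 = 12 states; pairing is static along a
    linkage group and uniform over its three configurations.  The two
    parents are independent, giving 144 joint states that collapse
    exactly onto the 36 transmitted-pair classes.

Transitions
    Conditional on the pairing, each transmitted chromatid stays on its
    homolog with probability 1 - r and switches to its pairing partner
    with probability r, independently across bivalents and parents;
    map distances convert to r through Haldane's map function (no
    interference), matching the meiosis simulator.

Emissions
    P(observed dosage | class) = 1 - eps if the observation equals the
    class dosage implied by the marker phase, else eps / 4; missing
    observations are uninformative (emit 1 for every class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core import (
    N_CLASSES,
    PAIR_INDEX,
    PAIRS,
    DosageMatrix,
    GenotypeProbabilities,
    PhasedMap,
    class_pairs,
)
from .sim_cross import PAIRINGS

N_PARENT_STATES = 12
N_JOINT_STATES = 144

# pair-membership incidence: PAIR_MEMBER[p, h] = 1 if homolog h in pair p
PAIR_MEMBER = np.zeros((6, 4), dtype=float)
for _p, (_a, _b) in enumerate(PAIRS):
    PAIR_MEMBER[_p, _a] = PAIR_MEMBER[_p, _b] = 1.0

# per-parent state -> transmitted pair index
STATE_PAIR = np.empty(N_PARENT_STATES, dtype=int)
for _c in range(3):
    for _s1 in range(2):
        for _s2 in range(2):
            _h = (PAIRINGS[_c][0][_s1], PAIRINGS[_c][1][_s2])
            STATE_PAIR[4 * _c + 2 * _s1 + _s2] = PAIR_INDEX[tuple(sorted(_h))]

# joint state -> class index, and the 144 -> 36 collapse matrix
JOINT_CLASS = np.array(
    [6 * STATE_PAIR[s1] + STATE_PAIR[s2]
     for s1 in range(N_PARENT_STATES) for s2 in range(N_PARENT_STATES)]
)
COLLAPSE = np.zeros((N_JOINT_STATES, N_CLASSES))
COLLAPSE[np.arange(N_JOINT_STATES), JOINT_CLASS] = 1.0

# joint state -> pairing block (c1, c2) of the two parents
JOINT_BLOCK = np.array(
    [3 * (s1 // 4) + (s2 // 4)
     for s1 in range(N_PARENT_STATES) for s2 in range(N_PARENT_STATES)]
)


def haldane_r(d_cm) -> np.ndarray | float:
    """Map distance (cM) to recombination fraction, no interference."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def haldane_cm(r) -> np.ndarray | float:
    """Inverse Haldane transform (r < 0.5)."""
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(r, dtype=float))


@dataclass(frozen=True)
class GenotypeClass:
    """One of the 36 parental-homolog combinations."""

    p1_pair: tuple
    p2_pair: tuple

    @property
    def index(self) -> int:
        return 6 * PAIR_INDEX[tuple(sorted(self.p1_pair))] + PAIR_INDEX[
            tuple(sorted(self.p2_pair))
        ]

    @classmethod
    def from_index(cls, index: int) -> "GenotypeClass":
        p1, p2 = class_pairs(index)
        return cls(p1, p2)


@dataclass
class EmissionModel:
    """Dosage-observation error model (uniform over wrong classes)."""

    error: float = 0.05

    def __post_init__(self):
        if not 0 <= self.error < 1:
            raise ValueError("emission error must be in [0, 1)")


def class_dosage(cls: GenotypeClass, phase8) -> int:
    """Expected offspring dosage of a class given the 8 phased alleles.

    ``phase8`` lists the 0/1 allele on parent-1 homologs 1-4 followed by
    parent-2 homologs 1-4; the class dosage is the allele sum over the
    four transmitted homologs.
    """
    phase8 = np.asarray(phase8)
    if not np.isin(phase8, (0, 1)).all() or phase8.shape != (8,):
        raise ValueError("phase8 must be eight 0/1 alleles")
    return int(
        sum(phase8[h] for h in cls.p1_pair) + sum(phase8[4 + h] for h in cls.p2_pair)
    )


def _class_dosages(phase1: np.ndarray, phase2: np.ndarray) -> np.ndarray:
    """(m, 36) class dosages for all markers of one LG."""
    d1 = phase1 @ PAIR_MEMBER.T  # (m, 6)
    d2 = phase2 @ PAIR_MEMBER.T
    return (d1[:, :, None] + d2[:, None, :]).reshape(len(phase1), N_CLASSES)


def transition_kernel(r: float) -> np.ndarray:
    """Per-parent 12x12 transition matrix for recombination fraction r."""
    if not 0 <= r <= 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5]")
    k2 = np.array([[1.0 - r, r], [r, 1.0 - r]])
    t4 = np.kron(k2, k2)
    t12 = np.zeros((N_PARENT_STATES, N_PARENT_STATES))
    for c in range(3):
        t12[4 * c: 4 * c + 4, 4 * c: 4 * c + 4] = t4
    return t12


def _joint_kernel(r: float) -> np.ndarray:
    t12 = transition_kernel(r)
    return np.kron(t12, t12)


class _KernelCache(dict):
    def get_r(self, r: float) -> np.ndarray:
        key = round(float(r), 12)
        if key not in self:
            self[key] = _joint_kernel(key)
        return self[key]


def _emission36(obs: np.ndarray, dose36: np.ndarray, error: float) -> np.ndarray:
    """(n, 36) emission likelihoods at one marker.

    ``obs`` is the n observed dosages (NaN = missing), ``dose36`` the
    class dosages of the marker.
    """
    n = len(obs)
    out = np.ones((n, N_CLASSES))
    seen = ~np.isnan(obs)
    match = obs[seen, None] == dose36[None, :]
    out[seen] = np.where(match, 1.0 - error, error / 4.0)
    return out


def _lg_grid(positions: np.ndarray, grid_step: float, include_markers: bool):
    """Evaluation positions for one LG.

    The chain always runs over the union of the regular grid (anchored
    at the first marker, spacing ``grid_step``) and the exact marker
    positions; ``include_markers`` controls whether marker-only
    positions are part of the *reported* grid.  Returns the ordered
    positions, the reported mask, and per-position marker indices
    (-1 = pure grid point).
    """
    length = positions[-1] - positions[0]
    base = positions[0] + np.arange(0.0, length + 1e-9, grid_step)
    # grid points that coincide with a marker are represented by the
    # marker itself (exact position, informative emission)
    if len(positions):
        near_marker = np.min(
            np.abs(base[:, None] - positions[None, :]), axis=1
        ) < 1e-6
        base = base[~near_marker]
    allpos = np.concatenate([base, positions])
    src = np.concatenate(
        [np.full(len(base), -1, dtype=int), np.arange(len(positions))]
    )
    order = np.argsort(allpos, kind="stable")
    allpos, src = allpos[order], src[order]
    offset = (positions - positions[0]) % grid_step
    marker_on_grid = (offset < 1e-6) | (grid_step - offset < 1e-6)
    keep = (src < 0) | (include_markers | marker_on_grid[np.maximum(src, 0)])
    return allpos, keep, src


def conditional_probs(
    dosages: DosageMatrix,
    pmap: PhasedMap,
    em: EmissionModel | None = None,
    grid_step: float = 1.0,
    include_markers: bool = True,
    pairing_mode: str = "mix",
) -> GenotypeProbabilities:
    """Forward-backward genotype-class posteriors on a cM grid.

    Parameters
    ----------
    dosages
        Offspring dosage matrix; markers must cover the map (extra
        columns are ignored, order is taken from the map).
    pmap
        Phased parental map.
    em
        Emission model (default 5% dosage error).
    grid_step
        Grid spacing in cM (default every 1 cM, anchored at the first
        marker of each linkage group).
    include_markers
        Also report posteriors at marker positions (default True).
    pairing_mode
        ``"mix"`` averages over the 3 x 3 static pairing configurations
        (uniform prior); ``"condition"`` conditions each individual on
        its most probable pairing configuration.
    """
    if pairing_mode not in ("mix", "condition"):
        raise ValueError("pairing_mode must be 'mix' or 'condition'")
    em = em or EmissionModel()
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    # markers dropped upstream (QC) are simply absent from the dosage
    # matrix; the chain runs on the intersection, in map order
    have = set(dosages.markers)
    pmap = pmap.subset([m for m in pmap.df["marker"] if m in have])
    dosages = dosages.align_to(pmap)
    cache = _KernelCache()
    n = dosages.n
    grid_frames = []
    prob_blocks = []
    col = 0
    for lg in pmap.lgs:
        sub = pmap.lg_frame(lg)
        if len(sub) == 0:
            raise ValueError(f"empty linkage group {lg!r}")
        positions = sub["position_cm"].to_numpy(float)
        m_lg = len(positions)
        obs = dosages.dosage[:, col: col + m_lg]
        col += m_lg
        phase1, phase2 = pmap.phases(lg)
        dose36 = _class_dosages(phase1, phase2)

        allpos, keep, src = _lg_grid(positions, grid_step, include_markers)
        T = len(allpos)
        emissions = [
            None if j < 0 else _emission36(obs[:, j], dose36[j], em.error)
            for j in src
        ]

        post = _forward_backward(emissions, allpos, cache, n, pairing_mode)
        prob_blocks.append(post[:, keep, :])
        grid_frames.append(
            pd.DataFrame({"lg": lg, "position_cm": allpos[keep]})
        )
    grid = pd.concat(grid_frames, ignore_index=True)
    probs = np.concatenate(prob_blocks, axis=1)
    return GenotypeProbabilities(list(dosages.individuals), grid, probs)


def _forward_backward(emissions, positions, cache, n, pairing_mode):
    """Scaled forward-backward over the 144 joint states.

    ``emissions[t]`` is (n, 36) or None (uninformative position).
    Returns (n, T, 36) class posteriors.
    """
    T = len(positions)
    rs = haldane_r(np.diff(positions))

    def e144(t):
        e = emissions[t]
        return None if e is None else e[:, JOINT_CLASS]

    alphas = np.empty((T, n, N_JOINT_STATES))
    alpha = np.full((n, N_JOINT_STATES), 1.0 / N_JOINT_STATES)
    e0 = e144(0)
    if e0 is not None:
        alpha = alpha * e0
    alpha = _rescale(alpha)
    alphas[0] = alpha
    for t in range(1, T):
        alpha = alpha @ cache.get_r(rs[t - 1])
        et = e144(t)
        if et is not None:
            alpha = alpha * et
        alpha = _rescale(alpha)
        alphas[t] = alpha

    out = np.empty((n, T, N_CLASSES))
    beta = np.ones((n, N_JOINT_STATES))
    post144_first = None
    post_joint = np.empty((T, n, N_JOINT_STATES))
    for t in range(T - 1, -1, -1):
        p = alphas[t] * beta
        p = _rescale(p)
        post_joint[t] = p
        if t > 0:
            et = e144(t)
            b = beta if et is None else beta * et
            beta = _rescale(b @ cache.get_r(rs[t - 1]).T)

    if pairing_mode == "condition":
        # pairing is static, so the block posterior is position-free;
        # read it at the first position and condition every slice on
        # the per-individual argmax block
        bm = np.zeros((n, 9))
        for b in range(9):
            bm[:, b] = post_joint[0][:, JOINT_BLOCK == b].sum(axis=1)
        best = bm.argmax(axis=1)
        mask = (JOINT_BLOCK[None, :] == best[:, None]).astype(float)
        for t in range(T):
            post_joint[t] = _rescale(post_joint[t] * mask)

    for t in range(T):
        out[:, t, :] = post_joint[t] @ COLLAPSE
    return out


def _rescale(a: np.ndarray) -> np.ndarray:
    """Row-normalize, falling back to uniform for all-zero rows.

    An all-zero row means the observations are impossible under the
    model (only reachable with emission error 0 and inconsistent data);
    the uniform fallback keeps the chain defined.
    """
    s = a.sum(axis=1, keepdims=True)
    bad = s[:, 0] == 0
    if bad.any():
        a = a.copy()
        a[bad] = 1.0
        s = a.sum(axis=1, keepdims=True)
    return a / s


def _marker_informative(pmap: PhasedMap, marker: str) -> bool:
    row = pmap.df.loc[pmap.df["marker"] == marker]
    if row.empty:
        raise KeyError(f"marker {marker!r} not in map")
    d1 = int(row[[f"P1_h{h}" for h in (1, 2, 3, 4)]].to_numpy().sum())
    d2 = int(row[[f"P2_h{h}" for h in (1, 2, 3, 4)]].to_numpy().sum())
    return d1 in (1, 2, 3) or d2 in (1, 2, 3)


def pairwise_rf(
    dosages: DosageMatrix,
    marker_i: str,
    marker_j: str,
    pmap: PhasedMap,
    em: EmissionModel | None = None,
    tol: float = 1e-4,
):
    """Two-point maximum-likelihood recombination fraction.

    Maximizes the two-marker chain likelihood over r in [0, 0.5] given
    the known parental phases.  Returns ``(r_hat, loglik)``.
    """
    em = em or EmissionModel(0.0)
    if not (_marker_informative(pmap, marker_i) and _marker_informative(pmap, marker_j)):
        raise ValueError("uninformative marker pair (no heterozygous parent)")

    def marker_emission(marker):
        row = pmap.df.loc[pmap.df["marker"] == marker].iloc[0]
        phase1 = row[[f"P1_h{h}" for h in (1, 2, 3, 4)]].to_numpy(int)[None, :]
        phase2 = row[[f"P2_h{h}" for h in (1, 2, 3, 4)]].to_numpy(int)[None, :]
        dose36 = _class_dosages(phase1, phase2)[0]
        obs = dosages.dosage[:, dosages.markers.index(marker)]
        return _emission36(obs, dose36, em.error)[:, JOINT_CLASS]

    e1 = marker_emission(marker_i)
    e2 = marker_emission(marker_j)

    def negll(r):
        t = _joint_kernel(float(r))
        v = ((e1 @ t) * e2).sum(axis=1) / N_JOINT_STATES
        v = np.maximum(v, 1e-300)
        return -np.log(v).sum()

    res = minimize_scalar(negll, bounds=(0.0, 0.5), method="bounded",
                          options={"xatol": tol})
    r_hat = float(res.x)
    # the bounded optimizer never lands exactly on a boundary; check both
    for edge in (0.0, 0.5):
        if negll(edge) < res.fun:
            r_hat = edge
            res.fun = negll(edge)
    return r_hat, -float(res.fun)
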