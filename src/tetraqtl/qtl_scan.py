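"""Random-effect interval mapping for autotetraploid F1 populations.

At every grid position q the single-QTL model

    y = mu + g_q + e,   g_q ~ MVN(0, G_q sigma_q^2),   e ~ MVN(0, I sigma_e^2)

is evaluated through the variance-component score statistic

    U_q = 1/2 * e0' G_q e0 / sigma_e^4,   e0 = y - mean(y),

whose null distribution is a weighted sum of chi-squares with weights
given by the eigenvalues of (1/2) C G_q C / sigma_e^2 (C the centering
projector).  p-values use Satterthwaite moment matching by default; an
exact Imhof evaluation of the weighted chi-square tail is available as
a cross-check.  LOP = -log10(p).  Genome-wide significance uses the
95% quantile of the second- and third-highest per-linkage-group peak
across permutations of the phenotype; support intervals follow the
LOP 1-drop rule, and QTL heritability h_q^2 = sigma_q^2 / (sigma_q^2 +
sigma_e^2) comes from a REML fit at the peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, special, stats
from scipy.optimize import minimize_scalar

from .core import N_CLASSES, GenotypeProbabilities
from .relationship import _PI, locus_G

P_FLOOR = 1e-300  # keeps LOP finite


@dataclass
class VarianceFit:
    """REML variance components for the single-QTL random-effect model."""

    sigma_q2: float
    sigma_e2: float
    mu: float
    blups: np.ndarray
    converged: bool = True
    identifiable: bool = True
    loglik: float = np.nan

    @property
    def ratio(self) -> float:
        return self.sigma_q2 / self.sigma_e2


@dataclass
class QtlPeak:
    """A called QTL peak with its 1-drop support interval."""

    lg: object
    peak_cm: float
    peak_lop: float
    lower_cm: float
    upper_cm: float
    h_q2: float | None = None
    nearest_marker: str | None = None
    fit: VarianceFit | None = None

    def __post_init__(self):
        if not self.lower_cm <= self.peak_cm <= self.upper_cm:
            raise ValueError("support interval must contain the peak")


@dataclass
class Threshold:
    """Genome-wide LOP threshold from ranked permutation peaks."""

    level: float
    peak_rank: int
    value: float
    n_permutations: int


@dataclass
class AlleleEffects:
    """BLUP decomposition into parental homolog and pair effects."""

    homolog: np.ndarray  # 8 effects: P1 h1-4 then P2 h1-4
    p1_pairs: np.ndarray  # 6 pair-combination effects of parent 1
    p2_pairs: np.ndarray


def fit_null(y: np.ndarray) -> tuple[float, float]:
    """Null-model fit: sample mean and ML residual variance (divisor n)."""
    y = np.asarray(y, dtype=float)
    if y.size < 3 or not np.isfinite(y).all():
        raise ValueError("need >= 3 finite phenotype values")
    mu = float(y.mean())
    sigma_e2 = float(((y - mu) ** 2).mean())
    if sigma_e2 == 0:
        raise ValueError("degenerate trait (zero variance)")
    return mu, sigma_e2


def imhof_sf(x: float, weights: np.ndarray, limit: int = 200) -> float:
    """Exact survival function of Q = sum_k w_k chi2_1 at ``x`` (Imhof).

    Numerical inversion of the characteristic function; serves as the
    independent oracle for the Satterthwaite approximation.
    """
    w = np.asarray(weights, dtype=float)
    w = w[np.abs(w) > 1e-14]
    if w.size == 0:
        return 1.0

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(w * u)) - 0.5 * x * u
        rho = np.prod((1.0 + (w * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho)

    import warnings

    with warnings.catch_warnings():
        # the integrand decays like u^-(m/2+1) for m weights; for very
        # small m quad converges slowly, which is fine at oracle
        # tolerance
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0.0, np.inf, limit=limit)
    return float(min(1.0, max(P_FLOOR, 0.5 + val / np.pi)))


def _satterthwaite_sf(u: float, weights: np.ndarray) -> float:
    """Scaled chi-square tail matching mean and variance of the mixture."""
    s1 = float(np.sum(weights))
    s2 = float(np.sum(weights**2))
    if s1 <= 0 or s2 <= 0:
        return 1.0
    a = s2 / s1  # scale = var / (2 mean)
    b = s1**2 / s2  # df = 2 mean^2 / var
    return float(max(P_FLOOR, special.chdtrc(b, u / a)))


def score_test(
    y: np.ndarray, G: np.ndarray, method: str = "satterthwaite"
) -> tuple[float, float]:
    """Variance-component score test of sigma_q^2 = 0.

    Returns ``(U, p)``.  The null weights are the nonzero eigenvalues of
    C G C / (2 sigma_e^2) with C the centering projector.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    n = y.size
    if G.shape != (n, n):
        raise ValueError("G must be n x n aligned with y")
    eig = np.linalg.eigvalsh(0.5 * (G + G.T))
    if eig.min() < -1e-8 * max(1.0, eig.max()):
        raise ValueError("G must be positive semidefinite")
    mu, sigma_e2 = fit_null(y)
    e0 = y - mu
    U = 0.5 * float(e0 @ G @ e0) / sigma_e2**2
    Gc = G - G.mean(axis=0) - G.mean(axis=1)[:, None] + G.mean()
    lam = np.clip(np.linalg.eigvalsh(Gc), 0.0, None)
    weights = lam / (2.0 * sigma_e2)
    if weights.sum() == 0:
        return U, 1.0
    if method == "satterthwaite":
        return U, _satterthwaite_sf(U, weights)
    if method == "exact":
        return U, imhof_sf(U, weights)
    raise ValueError("method must be 'satterthwaite' or 'exact'")


class ScanEngine:
    """Precomputed per-position quantities for fast (batched) scans.

    For G_q = Z Π Z' the nonzero eigenvalues of C G_q C equal those of
    the 36 x 36 matrix Π^{1/2} Zc' Zc Π^{1/2}, so the Satterthwaite
    scale and df per position are computed once; per phenotype only the
    quadratic form e0' Z Π Z' e0 remains.
    """

    def __init__(self, probs: GenotypeProbabilities):
        self.probs = probs
        w, Q = np.linalg.eigh(_PI)
        pih = (Q * np.sqrt(np.clip(w, 0.0, None))) @ Q.T
        P = probs.n_positions
        self.Z = probs.probs  # (n, P, 36)
        self.S1 = np.empty(P)
        self.S2 = np.empty(P)
        for t in range(P):
            Zc = self.Z[:, t, :] - self.Z[:, t, :].mean(axis=0)
            M = pih @ (Zc.T @ Zc) @ pih
            lam = np.clip(np.linalg.eigvalsh(M), 0.0, None)
            self.S1[t] = lam.sum()
            self.S2[t] = (lam**2).sum()

    def pvalues(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Score statistics and p-values for phenotype columns.

        ``Y`` is (n, K); returns ``(U, p)`` each (P, K).
        """
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] != self.probs.n:
            Y = Y.T
        E = Y - Y.mean(axis=0)
        sigma_e2 = (E**2).mean(axis=0)  # ML variance, divisor n
        if np.any(sigma_e2 == 0):
            raise ValueError("degenerate trait (zero variance)")
        P = self.probs.n_positions
        K = Y.shape[1]
        U = np.empty((P, K))
        pvals = np.empty((P, K))
        for t in range(P):
            V = self.Z[:, t, :].T @ E  # (36, K)
            u_raw = np.einsum("ik,ik->k", V, _PI @ V)  # e0' G e0
            U[t] = 0.5 * u_raw / sigma_e2**2
            s1, s2 = self.S1[t], self.S2[t]
            if s2 <= 0:
                pvals[t] = 1.0
                continue
            # weights = lam / (2 sigma_e2): scale a = s2/(s1 2 sigma_e2),
            # df b = s1^2/s2 (sigma-free)
            b = s1**2 / s2
            x = U[t] * (s1 * 2.0 * sigma_e2) / s2
            pvals[t] = np.maximum(special.chdtrc(b, x), P_FLOOR)
        return U, pvals


def scan(y: np.ndarray, probs: GenotypeProbabilities,
         engine: ScanEngine | None = None) -> pd.DataFrame:
    """Score-test scan over the probability grid.

    Returns a profile frame with columns ``lg, position_cm, score,
    pvalue, lop``.
    """
    y = np.asarray(y, dtype=float)
    if y.size != probs.n:
        raise ValueError("phenotype not aligned with probability individuals")
    engine = engine or ScanEngine(probs)
    U, p = engine.pvalues(y[:, None])
    out = probs.grid.copy()
    out["score"] = U[:, 0]
    out["pvalue"] = p[:, 0]
    out["lop"] = -np.log10(p[:, 0])
    return out


def reml_fit(y: np.ndarray, G: np.ndarray, tol: float = 1e-6,
             eig: tuple | None = None) -> VarianceFit:
    """REML fit of the single-QTL variance-component model.

    Profiles the variance ratio phi = sigma_q^2 / sigma_e^2 on a log
    grid, refines by bounded search, and reports BLUPs
    g = sigma_q^2 G V^{-1} (y - mu).  Boundary estimates are reported
    as sigma_q^2 = 0 with ``converged=True``.  Pass a precomputed
    ``eig = (eigenvalues, eigenvectors)`` of G to amortize repeated
    fits at the same position.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if eig is None:
        lam, Q = np.linalg.eigh(0.5 * (np.asarray(G) + np.asarray(G).T))
    else:
        lam, Q = eig
    lam = np.clip(lam, 0.0, None)
    yt = Q.T @ y
    xt = Q.T @ np.ones(n)

    def profile(phi):
        d = 1.0 + phi * lam
        xx = np.sum(xt**2 / d)
        mu = np.sum(xt * yt / d) / xx
        r = yt - xt * mu
        sigma_e2 = np.sum(r**2 / d) / (n - 1)
        ll = -0.5 * (
            (n - 1) * (1.0 + np.log(2 * np.pi * sigma_e2))
            + np.sum(np.log(d))
            + np.log(xx)
        )
        return ll, mu, sigma_e2, r, d

    grid = np.concatenate([[0.0], np.logspace(-4, 4, 65)])
    lls = np.array([profile(p)[0] for p in grid])
    i = int(np.argmax(lls))
    if i == 0:
        phi_hat = 0.0
    else:
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        lo = max(lo, 1e-12)
        res = minimize_scalar(
            lambda t: -profile(np.exp(t))[0],
            bounds=(np.log(lo), np.log(hi)),
            method="bounded",
            options={"xatol": tol},
        )
        phi_hat = float(np.exp(res.x))
        if profile(0.0)[0] >= profile(phi_hat)[0]:
            phi_hat = 0.0
    ll, mu, sigma_e2, r, d = profile(phi_hat)
    sigma_q2 = phi_hat * sigma_e2
    # BLUP: sigma_q2 G V^-1 (y - mu) with V = Q diag(sigma_e2 d) Q'
    blups = Q @ (phi_hat * lam * r / d)
    spread = lam.max() - lam.min() if n else 0.0
    identifiable = bool(spread > 1e-8 * max(1.0, lam.max()))
    return VarianceFit(
        sigma_q2=float(sigma_q2),
        sigma_e2=float(sigma_e2),
        mu=float(mu),
        blups=blups,
        converged=True,
        identifiable=identifiable,
        loglik=float(ll),
    )


def qtl_h2(fit: VarianceFit) -> float:
    """QTL heritability h_q^2 = sigma_q^2 / (sigma_q^2 + sigma_e^2)."""
    if not fit.converged:
        raise ValueError("variance fit did not converge")
    tot = fit.sigma_q2 + fit.sigma_e2
    if tot == 0:
        raise ValueError("both variance components are zero")
    return float(fit.sigma_q2 / tot)


def permutation_threshold(
    y: np.ndarray,
    probs: GenotypeProbabilities,
    n_perm: int = 1000,
    level: float = 0.95,
    ranks: tuple = (2, 3),
    seed: int | None = None,
    engine: ScanEngine | None = None,
) -> dict[int, Threshold]:
    """Genome-wide LOP thresholds from ranked permutation peaks.

    Each permutation shuffles the phenotype (the probability tensor is
    untouched), rescans, and records the per-linkage-group maximum LOP
    sorted in decreasing order; the threshold of rank k is the
    ``level`` quantile of the k-th value across permutations, taken as
    the ceiling order statistic (the usual conservative convention for
    permutation thresholds).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    lgs = probs.lgs
    if len(lgs) < max(ranks):
        raise ValueError("fewer linkage groups than the requested peak rank")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(y.size) for _ in range(n_perm)], axis=1)
    Y = y[perms]  # (n, n_perm)
    engine = engine or ScanEngine(probs)
    _, p = engine.pvalues(Y)
    lop = -np.log10(p)
    per_lg = np.stack([lop[probs.lg_indices(lg)].max(axis=0) for lg in lgs])
    ordered = np.sort(per_lg, axis=0)[::-1]  # descending by rank
    return {
        k: Threshold(
            level=level,
            peak_rank=k,
            value=float(np.quantile(ordered[k - 1], level, method="higher")),
            n_permutations=n_perm,
        )
        for k in ranks
    }


def call_peaks(
    profile: pd.DataFrame,
    threshold: float | Threshold,
    y: np.ndarray | None = None,
    probs: GenotypeProbabilities | None = None,
    pmap=None,
) -> list[QtlPeak]:
    """Call one peak per linkage group above the threshold.

    The peak sits at the LOP argmax (ties broken toward the smallest
    cM); its support interval is the maximal contiguous grid run
    containing the peak with LOP >= peak - 1 (LOP 1-drop rule).  When
    ``y`` and ``probs`` are supplied, a REML fit at the peak adds
    h_q^2; a phased map adds the nearest marker label.
    """
    if len(profile) == 0:
        raise ValueError("empty scan profile")
    thr = threshold.value if isinstance(threshold, Threshold) else float(threshold)
    peaks: list[QtlPeak] = []
    for lg in pd.unique(profile["lg"]):
        sub = profile[profile["lg"] == lg].reset_index(drop=True)
        lop = sub["lop"].to_numpy(float)
        if lop.max() < thr:
            continue
        i = int(np.argmax(lop))  # first max = smallest cM (sorted grid)
        lo = i
        while lo > 0 and lop[lo - 1] >= lop[i] - 1.0:
            lo -= 1
        hi = i
        while hi < len(lop) - 1 and lop[hi + 1] >= lop[i] - 1.0:
            hi += 1
        peak = QtlPeak(
            lg=lg,
            peak_cm=float(sub["position_cm"].iloc[i]),
            peak_lop=float(lop[i]),
            lower_cm=float(sub["position_cm"].iloc[lo]),
            upper_cm=float(sub["position_cm"].iloc[hi]),
        )
        if y is not None and probs is not None:
            idx = probs.position_index(lg, peak.peak_cm)
            fit = reml_fit(np.asarray(y, float), locus_G(probs.at(idx)))
            peak.fit = fit
            peak.h_q2 = qtl_h2(fit)
        if pmap is not None:
            sub_map = pmap.lg_frame(lg)
            pos = sub_map["position_cm"].to_numpy(float)
            peak.nearest_marker = str(
                sub_map["marker"].iloc[int(np.argmin(np.abs(pos - peak.peak_cm)))]
            )
        peaks.append(peak)
    return peaks


def allele_effects(fit: VarianceFit, Z: np.ndarray) -> AlleleEffects:
    """Decompose BLUPs into parental homolog and pair-combination effects.

    The effect of homolog h is the probability-weighted mean of the
    individual BLUPs among carriers of h, centered on the grand BLUP
    mean; pair-combination effects are analogous over the six pairs of
    each parent.
    """
    Z = np.asarray(Z, dtype=float)
    b = np.asarray(fit.blups, dtype=float)
    n = len(b)
    if Z.shape != (n, N_CLASSES):
        raise ValueError("Z must be n x 36 aligned with the BLUPs")
    from .hmm_probs import PAIR_MEMBER  # local import avoids cycle

    marg1 = Z.reshape(n, 6, 6).sum(axis=2)  # P(parent-1 pair)
    marg2 = Z.reshape(n, 6, 6).sum(axis=1)
    carrier1 = marg1 @ PAIR_MEMBER  # (n, 4) P(carry homolog h of P1)
    carrier2 = marg2 @ PAIR_MEMBER
    grand = b.mean()

    def weighted(w):
        tot = w.sum(axis=0)
        tot = np.where(tot == 0, 1.0, tot)
        return (w.T @ b) / tot - grand

    homolog = np.concatenate([weighted(carrier1), weighted(carrier2)])
    return AlleleEffects(
        homolog=homolog, p1_pairs=weighted(marg1), p2_pairs=weighted(marg2)
    )


def profile_to_tsv(profile: pd.DataFrame, path) -> None:
    profile.to_csv(path, sep="\t", index=False)


def peaks_to_records(peaks: list[QtlPeak]) -> list[dict]:
    """JSON-ready peak records mirroring the usual QTL summary columns."""
    out = []
    for p in peaks:
        out.append(
            {
                "lg": p.lg if not hasattr(p.lg, "item") else p.lg.item(),
                "lop": p.peak_lop,
                "peak_cm": p.peak_cm,
                "lower_cm": p.lower_cm,
                "upper_cm": p.upper_cm,
                "nearest_marker": p.nearest_marker,
                "h_q2": p.h_q2,
            }
        )
    return out
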