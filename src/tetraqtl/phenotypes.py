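"""Trait construction and heritability for berry firmness phenotypes.

Traits handled here follow standard fruit-quality phenotyping:
compression firmness (g/mm, averaged per genotype within year),
firmness retention (firmness before minus after four weeks of cold
storage; positive = softening), fruit detachment force (FDF, newtons,
with a 0.1 N floor for berries that fall before being pulled) and its
ripe-minus-green differential (ΔFDF).  Adjusted genotype means
(ls-means) come from an additive genotype + year fixed-effects fit,
and heritabilities from variance components, either supplied directly
or REML-estimated against a genomic relationship matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .qtl_scan import VarianceFit, qtl_h2, reml_fit

FDF_FLOOR_N = 0.1  # force recorded for berries that fall unpulled


def aggregate(measurements: pd.DataFrame, trait: str, year=None) -> pd.DataFrame:
    """Arithmetic mean of replicate measurements per genotype.

    ``measurements`` needs columns ``genotype, trait, value`` (plus
    optional ``year``); empty genotype groups are dropped with a
    warning.
    """
    df = measurements[measurements["trait"] == trait]
    if year is not None:
        df = df[df["year"] == year]
    df = df.dropna(subset=["value"])
    if df.empty:
        warnings.warn(f"no measurements for trait {trait!r}", stacklevel=2)
    out = (
        df.groupby("genotype", sort=True)["value"]
        .mean()
        .reset_index()
        .assign(trait=trait, year=year)
    )
    return out[["genotype", "trait", "year", "value"]]


def apply_fdf_floor(values: pd.Series | np.ndarray) -> np.ndarray:
    """Censor fallen-berry FDF readings at the 0.1 N recording floor."""
    return np.maximum(np.asarray(values, dtype=float), FDF_FLOOR_N)


def _paired_difference(a: pd.DataFrame, b: pd.DataFrame, trait: str) -> pd.DataFrame:
    common = sorted(set(a["genotype"]) & set(b["genotype"]))
    dropped = (set(a["genotype"]) | set(b["genotype"])) - set(common)
    if dropped:
        warnings.warn(
            f"{len(dropped)} genotypes present in only one table were excluded",
            stacklevel=3,
        )
    am = a.set_index("genotype")["value"]
    bm = b.set_index("genotype")["value"]
    return pd.DataFrame(
        {
            "genotype": common,
            "trait": trait,
            "year": None,
            "value": [am[g] - bm[g] for g in common],
        }
    )


def delta_fdf(ripe: pd.DataFrame, green: pd.DataFrame) -> pd.DataFrame:
    """ΔFDF = mean ripe-berry FDF minus mean green-berry FDF, per genotype."""
    return _paired_difference(ripe, green, "delta_fdf")


def retention(firmness_day1: pd.DataFrame, firmness_week4: pd.DataFrame) -> pd.DataFrame:
    """Firmness retention = firmness before minus after cold storage."""
    return _paired_difference(firmness_day1, firmness_week4, "firmness_retention")


def ls_means(values: pd.DataFrame) -> pd.DataFrame:
    """Adjusted genotype means from an additive genotype + year OLS fit.

    Uses sum-to-zero contrasts so the ls-mean of genotype g is
    intercept + genotype effect (year effects average to zero by
    construction).  With a single year this reduces to plain genotype
    means.  ``values`` needs columns ``genotype, year, value``.
    """
    df = values.dropna(subset=["value"]).copy()
    years = pd.unique(df["year"])
    if len(years) < 2:
        out = df.groupby("genotype", sort=True)["value"].mean().reset_index()
        out["trait"] = "ls_mean"
        out["year"] = years[0] if len(years) else None
        return out[["genotype", "trait", "year", "value"]]
    df["genotype"] = df["genotype"].astype(str)
    df["year"] = df["year"].astype(str)
    model = smf.ols("value ~ C(genotype, Sum) + C(year, Sum)", data=df)
    res = model.fit()
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("design is rank deficient beyond the two-factor constraints")
    params = res.params
    geno_levels = sorted(df["genotype"].unique())
    effects = {}
    acc = 0.0
    for g in geno_levels[:-1]:
        effects[g] = params[f"C(genotype, Sum)[S.{g}]"]
        acc += effects[g]
    effects[geno_levels[-1]] = -acc  # sum-to-zero completion
    intercept = params["Intercept"]
    out = pd.DataFrame(
        {
            "genotype": geno_levels,
            "trait": "ls_mean",
            "year": "all",
            "value": [intercept + effects[g] for g in geno_levels],
        }
    )
    return out


def heritability(sigma_g2: float, sigma_e2: float) -> float:
    """Broad-sense heritability h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)."""
    if sigma_g2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    tot = sigma_g2 + sigma_e2
    if tot == 0:
        raise ValueError("both variance components are zero")
    return float(sigma_g2 / tot)


def genomic_h2(y: np.ndarray, K_g: np.ndarray) -> tuple[float, VarianceFit]:
    """Genomic heritability from a REML fit of y = mu + g + e, g ~ (0, K_g σg²).

    Returns ``(h2, fit)``.  When K_g is (numerically) proportional to
    the identity the partition is unidentifiable and the fit is flagged
    (``fit.identifiable = False``).
    """
    K_g = np.asarray(K_g, dtype=float)
    eigs = np.linalg.eigvalsh(0.5 * (K_g + K_g.T))
    if eigs.min() < -1e-8 * max(1.0, eigs.max()):
        raise ValueError("K_g must be positive semidefinite")
    fit = reml_fit(np.asarray(y, dtype=float), K_g)
    return qtl_h2(fit), fit
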