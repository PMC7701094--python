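"""Shared data containers for autotetraploid mapping populations.

Three containers travel through the whole pipeline:

``PhasedMap``
    Markers with linkage-group labels, cM positions and the phased 0/1
    allele carried by each of the four homologs of each parent (eight
    phase columns in total).

``DosageMatrix``
    Individuals x markers tetraploid allele dosages (0-4, NaN =
    missing), optionally with a per-cell posterior distribution over
    the five dosage classes.

``GenotypeProbabilities``
    Individuals x grid-positions x 36 conditional probabilities of the
    parental-homolog combinations, as produced by the multipoint HMM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PHASE_COLUMNS = [f"P{p}_h{h}" for p in (1, 2) for h in (1, 2, 3, 4)]
MAP_COLUMNS = ["marker", "lg", "position_cm", *PHASE_COLUMNS]

#: the six unordered pairs of homolog indices (0-based), lexicographic
PAIRS: tuple[tuple[int, int], ...] = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
PAIR_INDEX: dict[tuple[int, int], int] = {p: i for i, p in enumerate(PAIRS)}
N_CLASSES = 36


def class_index(p1_pair: tuple[int, int], p2_pair: tuple[int, int]) -> int:
    """Index (0-35) of a genotype class from its two transmitted pairs.

    Classes are ordered lexicographically by (parent-1 pair, parent-2
    pair) with pairs themselves in lexicographic order.
    """
    return 6 * PAIR_INDEX[tuple(sorted(p1_pair))] + PAIR_INDEX[tuple(sorted(p2_pair))]


def class_pairs(index: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Inverse of :func:`class_index`."""
    if not 0 <= index < N_CLASSES:
        raise ValueError(f"class index out of range: {index}")
    return PAIRS[index // 6], PAIRS[index % 6]


def class_labels() -> list[str]:
    """Human-readable labels like ``'12|34'`` (1-based homolog ids)."""
    out = []
    for k in range(N_CLASSES):
        (a, b), (c, d) = class_pairs(k)
        out.append(f"{a + 1}{b + 1}|{c + 1}{d + 1}")
    return out


class PhasedMap:
    """A phased genetic map for a biparental tetraploid cross.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``marker, lg, position_cm, P1_h1..P1_h4, P2_h1..P2_h4``.
        Phase entries must be 0/1.  Rows are sorted by (lg, position).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in MAP_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phased map missing columns: {missing}")
        df = df.loc[:, MAP_COLUMNS].copy()
        phase = df[PHASE_COLUMNS].to_numpy()
        if not np.isin(phase, (0, 1)).all():
            raise ValueError("phase columns must be 0/1 (map must be phased)")
        if df["marker"].duplicated().any():
            raise ValueError("duplicate marker names in map")
        df = df.sort_values(["lg", "position_cm"], kind="stable").reset_index(drop=True)
        self.df = df

    # -- basic accessors -------------------------------------------------
    @property
    def lgs(self) -> list:
        return list(pd.unique(self.df["lg"]))

    @property
    def n_markers(self) -> int:
        return len(self.df)

    def lg_frame(self, lg) -> pd.DataFrame:
        sub = self.df[self.df["lg"] == lg]
        if sub.empty:
            raise KeyError(f"no markers on linkage group {lg!r}")
        return sub

    def positions(self, lg) -> np.ndarray:
        return self.lg_frame(lg)["position_cm"].to_numpy(float)

    def phases(self, lg) -> tuple[np.ndarray, np.ndarray]:
        """(m, 4) parent-1 and parent-2 phase arrays for one LG."""
        sub = self.lg_frame(lg)
        p1 = sub[[f"P1_h{h}" for h in (1, 2, 3, 4)]].to_numpy(int)
        p2 = sub[[f"P2_h{h}" for h in (1, 2, 3, 4)]].to_numpy(int)
        return p1, p2

    def parental_dosages(self) -> pd.DataFrame:
        """Per-marker parental dosages (row sums of each parent's phase)."""
        d1 = self.df[[f"P1_h{h}" for h in (1, 2, 3, 4)]].sum(axis=1)
        d2 = self.df[[f"P2_h{h}" for h in (1, 2, 3, 4)]].sum(axis=1)
        return pd.DataFrame(
            {"marker": self.df["marker"], "lg": self.df["lg"], "p1": d1, "p2": d2}
        )

    def subset(self, markers) -> "PhasedMap":
        keep = self.df["marker"].isin(set(markers))
        return PhasedMap(self.df[keep])

    # -- IO --------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "PhasedMap":
        return cls(pd.read_csv(path, sep="\t"))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhasedMap({self.n_markers} markers, {len(self.lgs)} LGs)"


@dataclass
class DosageMatrix:
    """Tetraploid allele dosages for a population.

    ``dosage`` is (n, m) float with values in {0..4} or NaN for missing;
    ``posterior``, when present, is (n, m, 5) with each cell summing to 1.
    """

    individuals: list[str]
    markers: list[str]
    dosage: np.ndarray
    posterior: np.ndarray | None = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.individuals) or m != len(self.markers):
            raise ValueError("dosage shape does not match labels")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and (not np.isin(vals, (0, 1, 2, 3, 4)).all()):
            raise ValueError("dosages must be integers 0-4 or missing")
        if self.posterior is not None:
            self.posterior = np.asarray(self.posterior, dtype=float)
            if self.posterior.shape != (n, m, 5):
                raise ValueError("posterior must have shape (n, m, 5)")
            sums = self.posterior.sum(axis=2)
            if not np.allclose(sums, 1.0, atol=1e-8):
                raise ValueError("posterior slices must sum to 1")

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def m(self) -> int:
        return len(self.markers)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.isnan(self.dosage).mean(axis=0)

    def subset_markers(self, markers) -> "DosageMatrix":
        markers = list(markers)
        idx = [self.markers.index(m) for m in markers]
        post = self.posterior[:, idx, :] if self.posterior is not None else None
        return DosageMatrix(list(self.individuals), markers, self.dosage[:, idx], post)

    def align_to(self, pmap: PhasedMap) -> "DosageMatrix":
        """Reorder/subset columns to match a map's marker order."""
        return self.subset_markers(pmap.df["marker"].tolist())

    # -- IO --------------------------------------------------------------
    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.dosage, index=self.individuals, columns=self.markers)
        df.index.name = "individual"
        df.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def read_tsv(cls, path) -> "DosageMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float))


@dataclass
class GenotypeProbabilities:
    """Conditional probabilities over the 36 genotype classes on a grid.

    ``grid`` has columns ``lg, position_cm`` (one row per evaluation
    position, in scan order); ``probs`` is (n, n_positions, 36) with each
    (individual, position) slice a probability distribution.
    """

    individuals: list[str]
    grid: pd.DataFrame
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.individuals), len(self.grid), N_CLASSES):
            raise ValueError("probs must have shape (n, n_positions, 36)")

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def n_positions(self) -> int:
        return len(self.grid)

    @property
    def lgs(self) -> list:
        return list(pd.unique(self.grid["lg"]))

    def lg_indices(self, lg) -> np.ndarray:
        idx = np.flatnonzero((self.grid["lg"] == lg).to_numpy())
        if idx.size == 0:
            raise KeyError(f"no grid positions on linkage group {lg!r}")
        return idx

    def position_index(self, lg, position_cm: float) -> int:
        """Grid index of the position on ``lg`` closest to ``position_cm``."""
        idx = self.lg_indices(lg)
        pos = self.grid["position_cm"].to_numpy(float)[idx]
        return int(idx[np.argmin(np.abs(pos - position_cm))])

    def at(self, index: int) -> np.ndarray:
        """(n, 36) class probabilities at one grid position."""
        return self.probs[:, index, :]

    # -- IO --------------------------------------------------------------
    def save(self, prefix) -> None:
        """Write ``<prefix>.npy`` plus a JSON sidecar with grid/labels."""
        prefix = str(prefix)
        np.save(f"{prefix}.npy", self.probs)
        sidecar = {
            "individuals": list(self.individuals),
            "class_labels": class_labels(),
            "grid": self.grid.to_dict(orient="list"),
        }
        Path(f"{prefix}.json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, prefix) -> "GenotypeProbabilities":
        prefix = str(prefix)
        probs = np.load(f"{prefix}.npy")
        sidecar = json.loads(Path(f"{prefix}.json").read_text())
        grid = pd.DataFrame(sidecar["grid"])
        return cls(sidecar["individuals"], grid, probs)

    def individual_tsv(self, individual: str, path) -> None:
        """Export one individual's probability profile as TSV."""
        i = self.individuals.index(individual)
        df = pd.concat(
            [self.grid.reset_index(drop=True),
             pd.DataFrame(self.probs[i], columns=class_labels())],
            axis=1,
        )
        df.to_csv(path, sep="\t", index=False)
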