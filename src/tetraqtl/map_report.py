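"""Linkage-map summary statistics.

Per linkage group: marker count, map length (last minus first marker
position), and counts of adjacent-marker gaps strictly greater than
each threshold (default 5, 10, 15 cM); overall totals, mean LG length,
and marker density (markers per cM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PhasedMap


@dataclass
class MapSummary:
    per_lg: pd.DataFrame  # lg, n_markers, length_cm, gaps_gt_<t>...
    total_markers: int
    total_length_cm: float
    mean_lg_length_cm: float
    density_per_cm: float

    def to_tsv(self, path) -> None:
        df = self.per_lg.copy()
        total = {"lg": "Total", "n_markers": self.total_markers,
                 "length_cm": round(self.total_length_cm, 2)}
        for c in df.columns:
            if c.startswith("gaps_gt_"):
                total[c] = int(df[c].sum())
        df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
        df.to_csv(path, sep="\t", index=False)


def summarize_map(pmap: PhasedMap, gap_thresholds=(5.0, 10.0, 15.0)) -> MapSummary:
    """Summarize a phased map (lengths anchored at the first marker)."""
    rows = []
    for lg in pmap.lgs:
        pos = pmap.positions(lg)
        if len(pos) == 1:
            warnings.warn(f"single-marker linkage group {lg!r}", stacklevel=2)
        gaps = np.diff(pos)
        row = {"lg": lg, "n_markers": len(pos), "length_cm": float(pos[-1] - pos[0])}
        for t in gap_thresholds:
            row[f"gaps_gt_{t:g}"] = int((gaps > t).sum())
        rows.append(row)
    per_lg = pd.DataFrame(rows)
    return _finish(per_lg)


def summary_from_counts(n_markers, lengths_cm, lgs=None) -> MapSummary:
    """Summary arithmetic from per-LG marker counts and lengths alone.

    Useful for published map tables where only the per-LG totals are
    available (gap columns are omitted).
    """
    n_markers = list(n_markers)
    lengths_cm = list(lengths_cm)
    per_lg = pd.DataFrame(
        {
            "lg": lgs if lgs is not None else list(range(1, len(n_markers) + 1)),
            "n_markers": n_markers,
            "length_cm": lengths_cm,
        }
    )
    return _finish(per_lg)


def _finish(per_lg: pd.DataFrame) -> MapSummary:
    total_markers = int(per_lg["n_markers"].sum())
    total_length = float(per_lg["length_cm"].sum())
    return MapSummary(
        per_lg=per_lg,
        total_markers=total_markers,
        total_length_cm=total_length,
        mean_lg_length_cm=total_length / len(per_lg),
        density_per_cm=round(total_markers / total_length, 2) if total_length else np.nan,
    )
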