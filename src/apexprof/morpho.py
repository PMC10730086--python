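"""Landmark-based meristem width and height measurements.

Width is measured as the chord from the axil of the youngest primordium
flanking the shoot apex to the opposite side of the meristem; height is the
perpendicular distance from the central meristem tip to that chord.  The
chord (not the image x-axis) defines "horizontal", so the measures are
invariant under rotation of the mounted sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .stats import compact_letters, dunn_posthoc


@dataclass
class ShapeLandmarks:
    """Tip and width-line endpoints of one sagittal meristem section (um)."""

    tip: tuple[float, float]
    axil1: tuple[float, float]
    axil2: tuple[float, float]
    meristem_id: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        pts = {tuple(self.tip), tuple(self.axil1), tuple(self.axil2)}
        if len(pts) < 3:
            raise ValueError("landmarks must be three distinct points")


@dataclass
class ShapeMeasure:
    width: float
    height: float
    meristem_id: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height < 0:
            raise ValueError("width must be positive and height non-negative")


def measure_shape(landmarks: ShapeLandmarks) -> ShapeMeasure:
    """Width = distance between axil points; height = tip-to-chord distance."""
    a = np.asarray(landmarks.axil1, dtype=float)
    b = np.asarray(landmarks.axil2, dtype=float)
    t = np.asarray(landmarks.tip, dtype=float)
    base = b - a
    width = float(np.hypot(*base))
    if width == 0:
        raise ValueError("width endpoints coincide")
    rel = t - a
    height = float(abs(base[0] * rel[1] - base[1] * rel[0]) / width)
    return ShapeMeasure(
        width=width,
        height=height,
        meristem_id=landmarks.meristem_id,
        timepoint=landmarks.timepoint,
    )


def measure_table(landmarks: pd.DataFrame) -> pd.DataFrame:
    """Vectorised measurement of a landmark table.

    Expects columns id, timepoint, genotype, tip_x, tip_y, ax1_x, ax1_y,
    ax2_x, ax2_y (the landmark CSV layout); returns one row of width/height
    per input row with identifiers carried through.
    """
    required = {"tip_x", "tip_y", "ax1_x", "ax1_y", "ax2_x", "ax2_y"}
    missing = required - set(landmarks.columns)
    if missing:
        raise ValueError(f"landmark table missing columns: {sorted(missing)}")
    rows = []
    for _, r in landmarks.iterrows():
        m = measure_shape(
            ShapeLandmarks(
                tip=(r["tip_x"], r["tip_y"]),
                axil1=(r["ax1_x"], r["ax1_y"]),
                axil2=(r["ax2_x"], r["ax2_y"]),
                meristem_id=str(r.get("id", "")),
                timepoint=str(r.get("timepoint", "")),
            )
        )
        rows.append(
            {
                "id": m.meristem_id,
                "timepoint": m.timepoint,
                "genotype": r.get("genotype", ""),
                "width_um": m.width,
                "height_um": m.height,
            }
        )
    return pd.DataFrame(rows)


def compare_shape_groups(
    samples: dict[str, np.ndarray],
    method: str = "anova",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, str], dict]:
    """Group comparison with a compact letter display.

    ``method='anova'`` runs one-way ANOVA with Tukey's HSD pairwise
    comparisons (normally distributed data); ``method='kruskal'`` runs the
    Kruskal-Wallis test with Dunn's pairwise comparisons (non-normal data).
    Returns (pairwise table, letters, omnibus summary).  Degenerate inputs
    with zero variance everywhere are reported with all groups sharing one
    letter.
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for g in names:
        if len(samples[g]) < 3:
            raise ValueError(f"group {g!r} needs at least 3 samples")
    arrays = {g: np.asarray(samples[g], dtype=float) for g in names}
    means = {g: float(a.mean()) for g, a in arrays.items()}

    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:
        pairwise = {
            (a, b): 1.0 for i, a in enumerate(names) for b in names[i + 1 :]
        }
        table = pd.DataFrame(
            [{"group1": a, "group2": b, "p_adj": 1.0} for (a, b) in pairwise]
        )
        letters = compact_letters(names, pairwise, means, alpha)
        return table, letters, {"test": method, "statistic": np.nan, "p": 1.0,
                                "degenerate": True}

    if method == "anova":
        stat, p = sps.f_oneway(*arrays.values())
        endog = pooled
        groups = np.concatenate([[g] * len(arrays[g]) for g in names])
        tukey = pairwise_tukeyhsd(endog, groups, alpha=alpha)
        pairwise = {}
        rows = []
        res = tukey.summary().data[1:]
        for row in res:
            a, b, _, p_adj = str(row[0]), str(row[1]), row[2], float(row[3])
            key = (a, b) if (a, b) in [(x, y) for i, x in enumerate(names)
                                       for y in names[i + 1 :]] else (b, a)
            pairwise[key] = p_adj
            rows.append({"group1": key[0], "group2": key[1], "p_adj": p_adj})
        table = pd.DataFrame(rows)
    elif method == "kruskal":
        stat, p = sps.kruskal(*arrays.values())
        pairwise = dunn_posthoc(arrays)
        table = pd.DataFrame(
            [{"group1": a, "group2": b, "p_adj": v} for (a, b), v in pairwise.items()]
        )
    else:
        raise ValueError("method must be 'anova' or 'kruskal'")

    letters = compact_letters(names, pairwise, means, alpha)
    return table, letters, {"test": method, "statistic": float(stat),
                            "p": float(p), "degenerate": False}
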