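"""Scoring of 96-well Phenol-Red (PSP) hydrolysis screens.

PET/BHET hydrolysis releases carboxylic products that acidify a weakly
buffered reaction; the PSP dye reports the pH drop as a decrease in A540.
Each plate carries parent-enzyme positive controls and empty-vector
negative controls, and every sample well is scored on a relative-activity
scale anchored to the controls:

    activity% = (mean_neg - A540_well) / (mean_neg - mean_parent) * 100

so negative controls sit at 0%, parent controls at 100% and improved
clones above 100%.  Hits are wells exceeding 100% by more than a margin
expressed in pooled control standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ROLES", "PlateLayout", "PlateReading", "RelativeActivity",
    "LibrarySummary", "score_plate", "summarize_library",
    "read_plate_csv", "read_layout_csv",
]

ROLES = ("sample", "parent_control", "negative_control", "blank", "empty")

_ROWS = "ABCDEFGH"
_WELLS = tuple(f"{r}{c}" for r in _ROWS for c in range(1, 13))


@dataclass(frozen=True)
class PlateLayout:
    """Role assignment for the wells of a 96-well plate."""

    roles: dict[str, str]

    def __post_init__(self):
        for well, role in self.roles.items():
            if well not in _WELLS:
                raise ValueError(f"invalid well id {well!r}")
            if role not in ROLES:
                raise ValueError(f"invalid role {role!r} for well {well}")
        if not self.wells_with_role("parent_control"):
            raise ValueError("layout needs >= 1 parent_control well")
        if not self.wells_with_role("negative_control"):
            raise ValueError("layout needs >= 1 negative_control well")

    def wells_with_role(self, role: str) -> list[str]:
        return [w for w, r in self.roles.items() if r == role]


@dataclass(frozen=True)
class PlateReading:
    """A540 endpoint readings for one plate."""

    layout: PlateLayout
    a540: dict[str, float]
    substrate: str = "PET-nanoparticles"   # or "BHET"
    incubation: float = 3.0                # hours
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        for well, role in self.layout.roles.items():
            if role != "empty" and well not in self.a540:
                raise ValueError(f"missing A540 for non-empty well {well}")
        for well, val in self.a540.items():
            if val < 0:
                raise ValueError(f"negative A540 in well {well}")


@dataclass(frozen=True)
class RelativeActivity:
    """Control-anchored activity of one sample well."""

    well: str
    activity_pct: float
    hit_flag: bool
    z_margin: float  # (activity - 100) in pooled-control-SD units


@dataclass(frozen=True)
class LibrarySummary:
    """Library-level screening statistics."""

    n_wells: int
    fraction_lower: float
    fraction_improved: float
    top_wells: tuple[RelativeActivity, ...]


def _pooled_sd(groups: list[np.ndarray]) -> float:
    num = den = 0.0
    for g in groups:
        if g.size >= 2:
            num += (g.size - 1) * float(np.var(g, ddof=1))
            den += g.size - 1
    return float(np.sqrt(num / den)) if den > 0 else 0.0


def score_plate(reading: PlateReading, hit_margin_sd: float = 2.0,
                aggregator: str = "mean") -> list[RelativeActivity]:
    """Score all sample wells against the on-plate controls.

    Parameters
    ----------
    hit_margin_sd : float
        A well is a hit when its activity exceeds 100% by more than this
        many pooled control standard deviations (on the activity scale).
    aggregator : {"mean", "median"}
        How replicate control wells are aggregated; median is robust to a
        single failed control well.

    Raises
    ------
    ValueError
        When the two control means coincide (no assay dynamic range).
    """
    agg = {"mean": np.mean, "median": np.median}[aggregator]
    neg = np.array([reading.a540[w]
                    for w in reading.layout.wells_with_role("negative_control")])
    par = np.array([reading.a540[w]
                    for w in reading.layout.wells_with_role("parent_control")])
    neg_c, par_c = float(agg(neg)), float(agg(par))
    span = neg_c - par_c
    if span == 0:
        raise ValueError("no assay dynamic range: control means are equal")
    # control SD propagated to the activity scale (percentage points)
    sd_act = _pooled_sd([neg, par]) / abs(span) * 100.0
    margin = hit_margin_sd * sd_act
    out = []
    for well in reading.layout.wells_with_role("sample"):
        act = (neg_c - reading.a540[well]) / span * 100.0
        z = (act - 100.0) / sd_act if sd_act > 0 else (
            np.inf if act > 100 else (-np.inf if act < 100 else 0.0))
        out.append(RelativeActivity(well=well, activity_pct=act,
                                    hit_flag=act > 100.0 + margin,
                                    z_margin=float(z)))
    return out


def summarize_library(scores: list[RelativeActivity],
                      z_threshold: float = 2.0,
                      top_k: int = 10) -> LibrarySummary:
    """Summarise a screened library.

    ``fraction_lower`` counts wells clearly below the parent (z below
    -z_threshold), ``fraction_improved`` counts flagged hits, and the
    top-k wells are returned ranked by activity.
    """
    if not scores:
        raise ValueError("no sample wells to summarise")
    n = len(scores)
    lower = sum(1 for s in scores if s.z_margin < -z_threshold)
    improved = sum(1 for s in scores if s.hit_flag)
    ranked = sorted(scores, key=lambda s: s.activity_pct, reverse=True)
    return LibrarySummary(
        n_wells=n, fraction_lower=lower / n, fraction_improved=improved / n,
        top_wells=tuple(ranked[:top_k]),
    )


def read_layout_csv(path) -> PlateLayout:
    """Read a layout CSV with columns well, role."""
    df = pd.read_csv(path, comment="#")
    return PlateLayout(dict(zip(df["well"].astype(str), df["role"])))


def read_plate_csv(path, layout: PlateLayout, **kwargs) -> PlateReading:
    """Read plate readings: long format (well, a540) or an 8x12 grid.

    The grid form has 8 rows and 12 unnamed columns in plate order A1..H12.
    """
    df = pd.read_csv(path, comment="#", header=None
                     if _looks_like_grid(path) else 0)
    if df.shape == (8, 12):
        values = {f"{_ROWS[i]}{j + 1}": float(df.iat[i, j])
                  for i in range(8) for j in range(12)}
    else:
        df.columns = [str(c).strip() for c in df.columns]
        values = dict(zip(df["well"].astype(str), df["a540"].astype(float)))
    a540 = {w: v for w, v in values.items()
            if layout.roles.get(w, "empty") != "empty"}
    return PlateReading(layout=layout, a540=a540, **kwargs)


def _looks_like_grid(path) -> bool:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                return "well" not in line.lower()
    return False
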