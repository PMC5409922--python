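"""Descriptive statistics: nest densities, control percentages, habitats.

Densities are colonies per km² over the whole commune or over its urban part
only (nearly every nest was reported inside the urban area, so the urban
density is the more meaningful figure).  The destroyed-while-active
percentage is the fraction of each year's detections that were removed while
the colony was still alive — the only destructions that actually control the
invasion.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from .nest_records import (
    NestRecord,
    Stage,
    StructureClass,
    YearlyCounts,
    detected_colonies,
)

__all__ = [
    "TerrainConfig",
    "HabitatSummary",
    "nest_density",
    "density_table",
    "pct_destroyed_active",
    "pct_destroyed_active_series",
    "habitat_summary",
]

Scope = Literal["whole_commune", "urban_only"]


@dataclass(frozen=True)
class TerrainConfig:
    """Study-area geometry: commune area (km²) and its urban fraction."""

    commune_area_km2: float = 20.59
    urban_fraction: float = 0.47

    def __post_init__(self) -> None:
        if self.commune_area_km2 <= 0:
            raise ValueError("commune_area_km2 must be positive")
        if not 0 < self.urban_fraction <= 1:
            raise ValueError("urban_fraction must be in (0, 1]")

    @property
    def urban_area_km2(self) -> float:
        return self.urban_fraction * self.commune_area_km2


DEFAULT_TERRAIN = TerrainConfig()

#: Documented alternative: the land-cover source puts urban cover at ~48%.
ALTERNATIVE_TERRAIN = TerrainConfig(urban_fraction=0.48)


def nest_density(
    n_colonies: float,
    terrain: TerrainConfig = DEFAULT_TERRAIN,
    scope: Scope = "whole_commune",
) -> float:
    """Colony density (per km²), unrounded; report to 2 dp."""
    if n_colonies < 0:
        raise ValueError("n_colonies must be non-negative")
    if scope == "whole_commune":
        return n_colonies / terrain.commune_area_km2
    if scope == "urban_only":
        return n_colonies / terrain.urban_area_km2
    raise ValueError(f"unknown scope {scope!r}")


def density_table(
    counts: Sequence[YearlyCounts],
    terrain: TerrainConfig = DEFAULT_TERRAIN,
) -> pd.DataFrame:
    """Yearly colony densities (rounded to 2 dp alongside the raw values)."""
    rows = []
    for c in sorted(counts, key=lambda c: c.year):
        n = detected_colonies(c)
        dc = nest_density(n, terrain, "whole_commune")
        du = nest_density(n, terrain, "urban_only")
        rows.append({
            "year": c.year,
            "colonies": n,
            "density_commune": round(dc, 2),
            "density_urban": round(du, 2),
            "density_commune_raw": dc,
            "density_urban_raw": du,
        })
    return pd.DataFrame(rows)


def pct_destroyed_active(counts: YearlyCounts) -> Optional[float]:
    """Percent of the year's detected nests destroyed while active (raw).

    Returns ``None`` when no nests were detected that year.
    """
    if counts.n_detected_total == 0:
        return None
    active = (
        counts.n_active_primary_destroyed
        + counts.n_active_secondary_destroyed
        + counts.n_active_unclassified_destroyed
    )
    return 100.0 * active / counts.n_detected_total


def pct_destroyed_active_series(counts: Sequence[YearlyCounts]) -> dict[int, Optional[int]]:
    """Per-year destroyed-while-active percentages, rounded to integers."""
    out: dict[int, Optional[int]] = {}
    for c in sorted(counts, key=lambda c: c.year):
        pct = pct_destroyed_active(c)
        out[c.year] = None if pct is None else round(pct)
    return out


@dataclass
class HabitatSummary:
    """Structure breakdown over records with a recorded nest structure."""

    n_records: int = 0
    n_with_structure: int = 0
    n_natural: int = 0
    n_man_made: int = 0
    n_unmapped: int = 0
    n_trees: int = 0
    genus_counts: dict[str, int] = field(default_factory=dict)
    #: stage -> {"natural": int, "man_made": int, "with_structure": int,
    #:           "trees": int}
    by_stage: dict[Stage, dict[str, int]] = field(default_factory=dict)

    def pct_of_structure_recorded(self, count: int) -> float:
        """`count` as a percentage of structure-recorded nests, 1 dp."""
        if self.n_with_structure == 0:
            return 0.0
        return round(100.0 * count / self.n_with_structure, 1)

    def pct_of_trees(self, count: int) -> float:
        if self.n_trees == 0:
            return 0.0
        return round(100.0 * count / self.n_trees, 1)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"quantity": "structure recorded", "count": self.n_with_structure,
             "pct_of_recorded": 100.0},
            {"quantity": "natural structure", "count": self.n_natural,
             "pct_of_recorded": self.pct_of_structure_recorded(self.n_natural)},
            {"quantity": "man-made structure", "count": self.n_man_made,
             "pct_of_recorded": self.pct_of_structure_recorded(self.n_man_made)},
            {"quantity": "on trees", "count": self.n_trees,
             "pct_of_recorded": self.pct_of_structure_recorded(self.n_trees)},
        ]
        for genus, n in sorted(self.genus_counts.items(), key=lambda kv: -kv[1]):
            rows.append({
                "quantity": f"{genus} tree", "count": n,
                "pct_of_recorded": self.pct_of_structure_recorded(n),
                "pct_of_trees": self.pct_of_trees(n),
            })
        return pd.DataFrame(rows)


def plot_habitat(summary: HabitatSummary, path) -> None:
    """Bar chart of nest structures by class and stage (PNG/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].bar(
        ["natural", "man-made"], [summary.n_natural, summary.n_man_made],
        color=["forestgreen", "grey"],
    )
    axes[0].set_title("All structure-recorded nests")
    axes[0].set_ylabel("nests")
    stages = [s for s in (Stage.PRIMARY, Stage.SECONDARY) if s in summary.by_stage]
    x = range(len(stages))
    nat = [summary.by_stage[s]["natural"] for s in stages]
    man = [summary.by_stage[s]["man_made"] for s in stages]
    axes[1].bar([i - 0.2 for i in x], nat, width=0.4, label="natural", color="forestgreen")
    axes[1].bar([i + 0.2 for i in x], man, width=0.4, label="man-made", color="grey")
    axes[1].set_xticks(list(x), [s.value for s in stages])
    axes[1].set_title("By nest stage")
    axes[1].legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def habitat_summary(records: Iterable[NestRecord]) -> HabitatSummary:
    """Summarise nest structures; only structure-recorded nests enter counts."""
    s = HabitatSummary()
    genus: Counter[str] = Counter()
    for rec in records:
        s.n_records += 1
        if rec.structure_text is None:
            continue
        s.n_with_structure += 1
        stage = s.by_stage.setdefault(
            rec.stage, {"with_structure": 0, "natural": 0, "man_made": 0, "trees": 0}
        )
        stage["with_structure"] += 1
        if rec.structure_class is StructureClass.NATURAL:
            s.n_natural += 1
            stage["natural"] += 1
        elif rec.structure_class is StructureClass.MAN_MADE:
            s.n_man_made += 1
            stage["man_made"] += 1
        else:
            s.n_unmapped += 1
        if rec.is_tree:
            s.n_trees += 1
            stage["trees"] += 1
            if rec.tree_genus is not None:
                genus[rec.tree_genus] += 1
    s.genus_counts = dict(genus)
    return s
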