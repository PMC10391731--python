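"""Organ volumetry and tumor-burden arithmetic on tabulated measurements.

Thyroid lobe volume uses the ellipsoid formula V = h * w * d * pi / 6 on
calliper diameters; when no dorsoventral depth was measured, the transverse
width stands in for it.  Lung tumor burden pools tumor area over total lung
area across the standardized section levels of a specimen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd


@dataclass(frozen=True)
class LobeDimensions:
    """Calliper diameters of one lobe; depth may be unmeasured."""

    height: float
    width: float
    depth: float | None = None

    def __post_init__(self) -> None:
        for name in ("height", "width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.depth is not None and self.depth <= 0:
            raise ValueError("depth must be strictly positive when given")


@dataclass(frozen=True)
class SectionAreas:
    """Tumor and total tissue area of one histological section."""

    section_id: str
    tumor_area: float
    total_area: float

    def __post_init__(self) -> None:
        if not 0 <= self.tumor_area <= self.total_area:
            raise ValueError("areas must satisfy 0 <= tumor_area <= total_area")


def ellipsoid_volume(dims: LobeDimensions) -> float:
    """Ellipsoid volume from lobe diameters; width substitutes a missing depth."""
    depth = dims.depth if dims.depth is not None else dims.width
    return dims.height * dims.width * depth * math.pi / 6.0


def tumor_burden(sections: Iterable[SectionAreas]) -> float:
    """Pooled tumor-area fraction: sum(tumor) / sum(total) over sections."""
    sections = list(sections)
    if not sections:
        raise ValueError("at least one section is required")
    total = sum(s.total_area for s in sections)
    if total == 0:
        raise ValueError("total area is zero across all sections")
    return sum(s.tumor_area for s in sections) / total


def per_section_burden(sections: Iterable[SectionAreas]) -> pd.DataFrame:
    rows = [
        {
            "section_id": s.section_id,
            "tumor_area": s.tumor_area,
            "total_area": s.total_area,
            "burden": s.tumor_area / s.total_area if s.total_area else float("nan"),
        }
        for s in sections
    ]
    return pd.DataFrame(rows)


def lobe_volumes_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Add an ellipsoid volume column to a (sample, height, width[, depth]) table."""
    out = measurements.copy()
    depths = out["depth"] if "depth" in out else pd.Series(index=out.index, dtype=float)
    out["volume"] = [
        ellipsoid_volume(
            LobeDimensions(
                row["height"],
                row["width"],
                None if pd.isna(depths.get(i)) else float(depths.get(i)),
            )
        )
        for i, row in out.iterrows()
    ]
    return out


def tumor_burden_table(areas: pd.DataFrame) -> pd.DataFrame:
    """Pooled burden per sample from a (sample, section, tumor_area, total_area) table."""
    rows = []
    for sample, grp in areas.groupby("sample"):
        sections = [
            SectionAreas(str(r["section"]), r["tumor_area"], r["total_area"])
            for _, r in grp.iterrows()
        ]
        rows.append({"sample": sample, "burden": tumor_burden(sections)})
    return pd.DataFrame(rows)
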