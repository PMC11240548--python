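"""Keratinocyte numerical density from manual dot annotations.

Cell centres are marked as dots on en-face images of the stratum granulosum
(SG) and stratum spinosum (SS); density is the dot count divided by the
en-face area of the counted region in mm².  Counting stays annotation-driven
(the dots are produced by a blinded human rater); no automatic nucleus
detector is included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import TIMEPOINT_ORDER, CellAnnotations


@dataclass(frozen=True)
class DensityReport:
    """Cell count, en-face area and numerical density for one layer."""

    layer: str
    n_cells: int
    area_mm2: float
    density: float  # cells per en-face mm²

    def __post_init__(self) -> None:
        if not (self.area_mm2 > 0):
            raise ValueError("area_mm2 must be > 0")

    def as_dict(self) -> dict:
        return {
            "layer": self.layer,
            "n_cells": self.n_cells,
            "area_mm2": self.area_mm2,
            "density": self.density,
        }


def compute_density(ann: CellAnnotations, pixel_size_xy: float) -> DensityReport:
    """Cells per en-face mm²: dot count over the annotated region's area.

    ``area_mm2 = area_px * pixel_size_xy² * 1e-6`` with ``pixel_size_xy`` in
    µm/pixel.
    """
    if not (pixel_size_xy > 0):
        raise ValueError("pixel_size_xy must be > 0")
    area_mm2 = ann.area_px * pixel_size_xy**2 * 1e-6
    if area_mm2 <= 0:
        raise ValueError("counted region has zero area")
    return DensityReport(
        layer=ann.layer,
        n_cells=ann.n_cells,
        area_mm2=area_mm2,
        density=ann.n_cells / area_mm2,
    )


def density_timecourse(
    reports: "Mapping[str, DensityReport | Sequence[DensityReport]]",
) -> pd.DataFrame:
    """Long-format table (timepoint, layer, n_cells, density) over a study.

    ``reports`` maps timepoint label to one report or a sequence of reports
    (one per layer).  Rows are sorted by the declared study order
    (baseline → 2w; unknown labels sort after, alphabetically).  Duplicate
    (timepoint, layer) pairs are an error.
    """
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    seen = set()
    for timepoint, entry in reports.items():
        entries = [entry] if isinstance(entry, DensityReport) else list(entry)
        for rep in entries:
            key = (timepoint, rep.layer)
            if key in seen:
                raise ValueError(f"duplicate (timepoint, layer) pair {key}")
            seen.add(key)
            rows.append(
                {
                    "timepoint": timepoint,
                    "layer": rep.layer,
                    "n_cells": rep.n_cells,
                    "density": rep.density,
                }
            )
    df = pd.DataFrame(rows)
    order = {tp: i for i, tp in enumerate(TIMEPOINT_ORDER)}
    df["_rank"] = df["timepoint"].map(lambda tp: order.get(tp, len(order)))
    df = df.sort_values(["_rank", "timepoint", "layer"], kind="stable")
    return df.drop(columns="_rank").reset_index(drop=True)
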