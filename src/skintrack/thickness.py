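"""Epidermal thickness from vertical (XZ) sections.

Ten adjacent XZ sections are sliced from the co-registered z-stack around
its mid-y row.  Per image column, three boundaries are detected on
z-smoothed intensity profiles using gain-invariant relative thresholds:

* the skin **surface** — shallowest depth where the RCM signal sustains
  50 % of that column's maximum for at least 3 consecutive planes (the SC
  is the brightest reflectance structure);
* the **DEJ** — the same criterion on the SHG collagen signal, which only
  exists in the dermis;
* the **SC bottom** — shallowest depth below the surface where the 810 nm
  TPF (SC keratin) falls below 50 % of its SC-band peak for at least 3
  consecutive planes.

Total epidermal thickness (ET) is the mean of per-column surface→DEJ
distances over all valid columns of all sections; SC thickness is the mean
surface→SC-bottom distance, and the viable-epidermis thickness is exactly
their difference.  Columns violating surface ≤ SC bottom ≤ DEJ (or with no
detectable signal) are flagged invalid and excluded, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io_formats import MultimodalStack


@dataclass(frozen=True)
class BoundaryConfig:
    """Tunable parameters of per-column boundary detection."""

    smooth_sigma_planes: float = 2.0  # Gaussian sigma along z, in planes
    threshold_frac: float = 0.5  # fraction of per-column max / SC-band peak
    min_run_planes: int = 3  # consecutive planes required at threshold
    sc_peak_window_planes: int = 8  # SC-band peak search window below surface
    surface_channel: str = "rcm"  # "rcm" or "tpf810" fallback


@dataclass
class XZSection:
    """One vertical section: (z, x) slices of RCM, SHG and 810 nm TPF."""

    rcm: np.ndarray
    shg: np.ndarray
    tpf810: np.ndarray
    z_step: float
    pixel_size_x: float

    def __post_init__(self) -> None:
        shapes = {self.rcm.shape, self.shg.shape, self.tpf810.shape}
        if len(shapes) != 1:
            raise ValueError("XZ section channels must share one (z, x) shape")
        if not (self.z_step > 0 and self.pixel_size_x > 0):
            raise ValueError("calibrations must be > 0")


@dataclass
class LayerBoundaries:
    """Per-column boundary depths (µm) of one section, with validity flags."""

    surface_um: np.ndarray
    sc_bottom_um: np.ndarray
    dej_um: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.surface_um)
        if not (len(self.sc_bottom_um) == len(self.dej_um) == len(self.valid) == n):
            raise ValueError("boundary arrays must have equal length")
        v = self.valid
        if np.any(self.surface_um[v] > self.sc_bottom_um[v]) or np.any(
            self.sc_bottom_um[v] > self.dej_um[v]
        ):
            raise ValueError("valid columns must satisfy surface <= SC bottom <= DEJ")

    @property
    def n_columns(self) -> int:
        return len(self.surface_um)


@dataclass(frozen=True)
class ThicknessReport:
    """Mean epidermal, SC, and viable-epidermis thicknesses in µm."""

    et_um: float
    sc_um: float
    viable_um: float
    n_columns_used: int
    n_columns_total: int

    def __post_init__(self) -> None:
        if self.n_columns_used > self.n_columns_total:
            raise ValueError("used columns cannot exceed total")

    def as_dict(self) -> dict:
        return {
            "et_um": self.et_um,
            "sc_um": self.sc_um,
            "viable_um": self.viable_um,
            "n_columns_used": self.n_columns_used,
            "n_columns_total": self.n_columns_total,
        }


def extract_vertical_sections(
    stack: MultimodalStack, n_sections: int = 10
) -> list:
    """Slice ``n_sections`` adjacent XZ sections centred on the stack mid-y row."""
    nz, ny, nx = stack.shape
    if n_sections < 1 or n_sections > ny:
        raise ValueError(f"n_sections must be in [1, {ny}]")
    for name in ("RCM", "SHG810", "TPF810"):
        if name not in stack.channels:
            raise ValueError(f"stack lacks channel {name!r}")
    start = (ny - n_sections) // 2
    return [
        XZSection(
            rcm=stack.channels["RCM"][:, y, :],
            shg=stack.channels["SHG810"][:, y, :],
            tpf810=stack.channels["TPF810"][:, y, :],
            z_step=stack.z_step,
            pixel_size_x=stack.pixel_size_xy,
        )
        for y in range(start, start + n_sections)
    ]


def _first_sustained(flags: np.ndarray, min_run: int) -> tuple:
    """Per column, first z index opening a run of >= min_run True planes.

    Returns (index, found) arrays for a (z, x) boolean input.
    """
    nz = flags.shape[0]
    if nz < min_run:
        n = flags.shape[1]
        return np.zeros(n, dtype=int), np.zeros(n, dtype=bool)
    run = flags[: nz - min_run + 1].copy()
    for j in range(1, min_run):
        run &= flags[j : nz - min_run + 1 + j]
    found = run.any(axis=0)
    idx = run.argmax(axis=0)
    return idx, found


def detect_boundaries(
    section: XZSection, config: BoundaryConfig = BoundaryConfig()
) -> LayerBoundaries:
    """Detect surface, SC bottom, and DEJ per column of one XZ section."""
    sig = config.smooth_sigma_planes
    sm_rcm = gaussian_filter1d(section.rcm.astype(float), sig, axis=0, mode="nearest")
    sm_shg = gaussian_filter1d(section.shg.astype(float), sig, axis=0, mode="nearest")
    sm_tpf = gaussian_filter1d(section.tpf810.astype(float), sig, axis=0, mode="nearest")
    if config.surface_channel == "tpf810":
        sm_surf = sm_tpf
    elif config.surface_channel == "rcm":
        sm_surf = sm_rcm
    else:
        raise ValueError("surface_channel must be 'rcm' or 'tpf810'")

    nz, ncol = sm_rcm.shape
    frac = config.threshold_frac
    run = config.min_run_planes
    zidx = np.arange(nz)[:, None]

    surf_max = sm_surf.max(axis=0)
    surf_idx, surf_found = _first_sustained(sm_surf >= frac * surf_max, run)
    surf_found &= surf_max > 0

    dej_max = sm_shg.max(axis=0)
    dej_idx, dej_found = _first_sustained(sm_shg >= frac * dej_max, run)
    dej_found &= dej_max > 0

    # SC-band peak: brightest TPF810 within a short window below the surface
    window = (zidx >= surf_idx[None, :]) & (
        zidx < surf_idx[None, :] + config.sc_peak_window_planes
    )
    sc_peak = np.where(window, sm_tpf, -np.inf).max(axis=0)
    below = (sm_tpf < frac * sc_peak) & (zidx > surf_idx[None, :])
    sc_idx, sc_found = _first_sustained(below, run)
    sc_found &= surf_found & np.isfinite(sc_peak) & (sc_peak > 0)

    valid = surf_found & sc_found & dej_found
    valid &= surf_idx <= sc_idx
    valid &= sc_idx <= dej_idx
    if not valid.any():
        raise ValueError("no valid columns: boundary detection failed everywhere")

    step = section.z_step
    # clamp invalid columns to an ordered triple so array invariants hold
    surface_um = np.where(valid, surf_idx, 0) * step
    sc_um = np.where(valid, sc_idx, 0) * step
    dej_um = np.where(valid, dej_idx, 0) * step
    return LayerBoundaries(
        surface_um=surface_um.astype(float),
        sc_bottom_um=sc_um.astype(float),
        dej_um=dej_um.astype(float),
        valid=valid,
    )


def thickness_report(
    sections: Sequence[LayerBoundaries],
    max_invalid_fraction: float = 0.5,
) -> ThicknessReport:
    """Average per-column distances over all valid columns of all sections.

    ET is the flat mean of (DEJ − surface) over every valid column, SC the
    mean of (SC bottom − surface), and viable their exact difference.
    Raises if no column is valid or more than ``max_invalid_fraction`` of
    columns are invalid (silent imputation would bias the means).
    """
    if not sections:
        raise ValueError("need at least one section")
    et_all, sc_all = [], []
    total = 0
    for b in sections:
        total += b.n_columns
        v = b.valid
        et_all.append(b.dej_um[v] - b.surface_um[v])
        sc_all.append(b.sc_bottom_um[v] - b.surface_um[v])
    et = np.concatenate(et_all)
    sc = np.concatenate(sc_all)
    if et.size == 0:
        raise ValueError("no valid columns across sections")
    if 1.0 - et.size / total > max_invalid_fraction:
        raise ValueError(
            f"{total - et.size}/{total} columns invalid: refusing to report a "
            "mean dominated by exclusions"
        )
    et_um = float(et.mean())
    sc_um = float(sc.mean())
    return ThicknessReport(
        et_um=et_um,
        sc_um=sc_um,
        viable_um=et_um - sc_um,
        n_columns_used=int(et.size),
        n_columns_total=int(total),
    )


def summarize_boundaries(
    boundaries: "LayerBoundaries | Sequence[LayerBoundaries]",
) -> tuple:
    """Mean (top-of-SG, DEJ) depth in µm over valid columns.

    The top of the SG layer is taken as the mean SC-bottom depth (the SG
    starts where the SC ends).
    """
    if isinstance(boundaries, LayerBoundaries):
        boundaries = [boundaries]
    scb = np.concatenate([b.sc_bottom_um[b.valid] for b in boundaries])
    dej = np.concatenate([b.dej_um[b.valid] for b in boundaries])
    if scb.size == 0:
        raise ValueError("no valid columns")
    return float(scb.mean()), float(dej.mean())


def boundaries_to_json(sections: Sequence[LayerBoundaries], z_step: float) -> dict:
    """JSON-serializable boundary record consumed by the melanin pipeline."""
    top_sg, dej = summarize_boundaries(list(sections))
    return {
        "z_step_um": z_step,
        "top_sg_um": top_sg,
        "dej_um": dej,
        "sections": [
            {
                "surface_um": b.surface_um.tolist(),
                "sc_bottom_um": b.sc_bottom_um.tolist(),
                "dej_um": b.dej_um.tolist(),
                "valid": b.valid.astype(bool).tolist(),
            }
            for b in sections
        ],
    }


def boundaries_from_json(record: dict) -> list:
    return [
        LayerBoundaries(
            surface_um=np.asarray(s["surface_um"], dtype=float),
            sc_bottom_um=np.asarray(s["sc_bottom_um"], dtype=float),
            dej_um=np.asarray(s["dej_um"], dtype=float),
            valid=np.asarray(s["valid"], dtype=bool),
        )
        for s in record["sections"]
    ]
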