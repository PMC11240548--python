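"""Presumed-melanin quantification from 810 nm TPF with SHG collagen masking.

At 810 nm excitation the epidermal TPF signal is dominated by melanin, but
elastin at the dermal–epidermal junction (DEJ) and in the dermis also
fluoresces.  Because elastin colocates with collagen, the co-registered SHG
collagen signal is used to strip it: each SHG plane in the DEJ/dermis
transition band is segmented into a binary mask (0 inside collagen, 1
elsewhere) and multiplied into the corresponding TPF plane.  The remaining
epidermal signal is summed per depth — the SC is excluded because keratin
fluoresces strongly there — and integrated from the top of the stratum
granulosum (where the SC ends) down to the DEJ to give the volumetric
presumed-melanin intensity.  Time-course change is reported as the fold
change versus the baseline session.

Collagen segmentation is a deterministic parameter-light recipe: Gaussian
smoothing (σ = 2 px) → Otsu threshold → morphological closing (disk r = 3 px)
→ removal of foreground components < 25 px.  Planes where Otsu has nothing
to separate (no collagen in view: the foreground/background contrast falls
below ``min_contrast`` background standard deviations) are returned as
all-ones masks, i.e. "no collagen here".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk

from .io_formats import MultimodalStack
from .thickness import LayerBoundaries, summarize_boundaries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MelaninConfig:
    """Parameters of collagen segmentation and depth integration."""

    smooth_sigma_px: float = 2.0
    closing_radius_px: int = 3
    min_object_px: int = 25
    min_contrast: float = 4.0  # Otsu class separation, in background SDs
    mask_band_above_dej_um: float = 10.0  # masking starts this far above mean DEJ


@dataclass
class CollagenMask:
    """Per-depth binary masks: 0 inside collagen, 1 elsewhere."""

    mask: np.ndarray  # (z, y, x), values {0, 1}

    def __post_init__(self) -> None:
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("mask must be binary {0, 1}")


@dataclass
class DepthProfile:
    """Summed masked TPF intensity per depth (a.u.)."""

    depth_um: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.depth_um = np.asarray(self.depth_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.depth_um.shape != self.intensity.shape:
            raise ValueError("depth and intensity must have the same length")
        if self.depth_um.size >= 2:
            steps = np.diff(self.depth_um)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValueError("depths must increase with uniform spacing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class MelaninReport:
    """Volumetric presumed-melanin intensity and its integration bounds."""

    volumetric_intensity: float
    integration_bounds: tuple  # (top-of-SG depth, DEJ depth), µm
    fold_change_vs_baseline: float | None = None
    mean_intensity_per_plane: float | None = None

    def __post_init__(self) -> None:
        top, dej = self.integration_bounds
        if not (top < dej):
            raise ValueError("top-of-SG depth must lie above the DEJ")
        if self.fold_change_vs_baseline is not None and not (
            self.fold_change_vs_baseline > 0
        ):
            raise ValueError("fold change must be > 0")

    def as_dict(self) -> dict:
        return {
            "volumetric_intensity": self.volumetric_intensity,
            "integration_bounds_um": list(self.integration_bounds),
            "fold_change_vs_baseline": self.fold_change_vs_baseline,
            "mean_intensity_per_plane": self.mean_intensity_per_plane,
        }


def segment_collagen(
    shg_plane: np.ndarray, config: MelaninConfig = MelaninConfig()
) -> np.ndarray:
    """Binary collagen mask of one SHG plane: 0 inside collagen, 1 elsewhere."""
    plane = np.asarray(shg_plane, dtype=float)
    if plane.ndim != 2:
        raise ValueError("shg_plane must be 2D")
    if not np.all(np.isfinite(plane)) or plane.min() < 0:
        raise ValueError("intensities must be finite and >= 0")
    ones = np.ones(plane.shape, dtype=np.uint8)
    if plane.max() == 0:
        logger.info("segment_collagen: all-zero SHG plane, no collagen found")
        return ones
    smooth = gaussian_filter(plane, config.smooth_sigma_px)
    if np.ptp(smooth) == 0:
        logger.info("segment_collagen: constant SHG plane, no collagen found")
        return ones
    thr = threshold_otsu(smooth)
    fg = smooth > thr
    if not fg.any() or fg.all():
        logger.info("segment_collagen: degenerate Otsu split, no collagen found")
        return ones
    contrast = (smooth[fg].mean() - smooth[~fg].mean()) / (smooth[~fg].std() + 1e-12)
    if contrast < config.min_contrast:
        logger.info(
            "segment_collagen: contrast %.2f below %.2f, treating plane as "
            "collagen-free",
            contrast,
            config.min_contrast,
        )
        return ones
    fg = closing(fg, disk(config.closing_radius_px))
    labels, n_lab = ndimage.label(fg)
    if n_lab:
        sizes = np.bincount(labels.ravel())
        small = sizes < config.min_object_px
        small[0] = False
        fg[small[labels]] = False
    return (~fg).astype(np.uint8)


def mask_tpf(tpf810_plane: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Strip dermal signal: elementwise product of a TPF plane and a mask."""
    plane = np.asarray(tpf810_plane, dtype=float)
    m = np.asarray(mask)
    if plane.shape != m.shape:
        raise ValueError(f"shape mismatch: {plane.shape} vs {m.shape}")
    return plane * m


def melanin_depth_profile(
    stack: MultimodalStack,
    boundaries: "LayerBoundaries | Sequence[LayerBoundaries]",
    config: MelaninConfig = MelaninConfig(),
) -> DepthProfile:
    """Summed presumed-melanin intensity per depth, SC excluded.

    The profile spans the epidermal analysis range [top of SG, mean DEJ].
    Planes within ``mask_band_above_dej_um`` of the mean DEJ are collagen
    masked before summation (the DEJ undulates, so collagen enters the view
    above its mean depth); shallower planes are summed as-is.
    """
    for name in ("TPF810", "SHG810"):
        if name not in stack.channels:
            raise ValueError(f"stack lacks channel {name!r}")
    top_sg_um, dej_um = summarize_boundaries(boundaries)
    step = stack.z_step
    k0 = int(np.ceil(top_sg_um / step - 1e-9))
    k1 = int(np.floor(dej_um / step + 1e-9))
    nz = stack.shape[0]
    k1 = min(k1, nz - 1)
    if k0 > k1:
        raise ValueError("no planes between top of SG and DEJ")
    band_start_um = dej_um - config.mask_band_above_dej_um
    tpf = stack.channels["TPF810"]
    shg = stack.channels["SHG810"]
    intensity = np.empty(k1 - k0 + 1)
    for i, k in enumerate(range(k0, k1 + 1)):
        plane = tpf[k]
        if k * step >= band_start_um:
            plane = mask_tpf(plane, segment_collagen(shg[k], config))
        intensity[i] = float(np.asarray(plane).sum())
    depth = np.arange(k0, k1 + 1, dtype=float) * step
    return DepthProfile(depth_um=depth, intensity=intensity)


def integrate_melanin(profile: DepthProfile, top_sg_um: float, dej_um: float) -> float:
    """Sum profile intensities at depths in [top_sg_um, dej_um], inclusive."""
    if not (top_sg_um < dej_um):
        raise ValueError("top_sg_um must be < dej_um")
    lo, hi = profile.depth_um.min(), profile.depth_um.max()
    if top_sg_um < lo - 1e-9 or dej_um > hi + 1e-9:
        raise ValueError(
            f"bounds [{top_sg_um}, {dej_um}] outside profile range [{lo}, {hi}]"
        )
    sel = (profile.depth_um >= top_sg_um - 1e-9) & (profile.depth_um <= dej_um + 1e-9)
    return float(profile.intensity[sel].sum())


def fold_change(current: MelaninReport, baseline: MelaninReport) -> float:
    """Ratio of volumetric intensities, current over baseline."""
    if not (baseline.volumetric_intensity > 0):
        raise ValueError("baseline volumetric intensity must be > 0")
    return current.volumetric_intensity / baseline.volumetric_intensity


def analyze_melanin(
    stack: MultimodalStack,
    boundaries: "LayerBoundaries | Sequence[LayerBoundaries]",
    baseline: MelaninReport | None = None,
    config: MelaninConfig = MelaninConfig(),
) -> tuple:
    """Full pipeline: profile, volumetric integral, optional fold change.

    Returns ``(MelaninReport, DepthProfile)``.
    """
    top_sg_um, dej_um = summarize_boundaries(boundaries)
    profile = melanin_depth_profile(stack, boundaries, config)
    total = integrate_melanin(
        profile, float(profile.depth_um.min()), float(profile.depth_um.max())
    )
    report = MelaninReport(
        volumetric_intensity=total,
        integration_bounds=(top_sg_um, dej_um),
        mean_intensity_per_plane=total / profile.depth_um.size,
    )
    if baseline is not None:
        report.fold_change_vs_baseline = fold_change(report, baseline)
    return report, profile
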