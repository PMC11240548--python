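"""Synthetic multimodal skin phantoms with exported ground truth.

Every analysis in this package is validated against phantoms that emulate
the structures the four imaging channels report on:

* a layered epidermis — stratum corneum (SC) over the viable layers
  (granulosum SG, spinosum SS, basale SB) — above a collagen-textured
  dermis, separated by a sinusoidally undulating dermal–epidermal
  junction (DEJ);
* RCM bright in the keratin-rich SC and at cell borders, TPF at 735 nm
  from cell cytoplasm, TPF at 810 nm from SC keratin plus melanin
  granules (and optionally elastin colocated with dermal collagen),
  SHG at 810 nm from oriented collagen fibres below the DEJ only;
* vessels whose speckle decorrelates frame to frame, on a static
  background, for flow mapping;
* marker landmark sessions related by a known similarity transform with
  localization noise, for registration accuracy studies.

Boundaries are rendered with one-plane linear coverage ramps so that a
boundary at depth ``d`` µm crosses 50 % intensity at plane ``round(d)``:
threshold-based detection is unbiased and exact for integer boundaries.

Default geometry: 200 µm field of view sampled at 256 px, 1 µm z-step over
120 planes; SC thickness 12.0 µm and total epidermal thickness 40.4 µm,
with a 6 µm amplitude / 64 µm period DEJ undulation.  All generators are
fully determined by ``seed``; independent sub-streams are derived per
component so adding one component never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .io_formats import FrameSeries, MultimodalStack
from .registration import LandmarkSet, SimilarityTransform2D

# Rendering amplitudes (arbitrary units, unit-signal convention).
_RCM_SC_AMP = 1.0
_RCM_BORDER_AMP = 0.6
_RCM_DERMIS_AMP = 0.1
_TPF735_CYTO_AMP = 0.8
_TPF810_SC_AMP = 1.0
_SHG_BASE = 0.6
_SHG_FRINGE_AMP = 0.4

# Approximate cell diameters per layer, µm (SB cells smallest).
_CELL_DIAMETER_UM = {"SG": 28.0, "SS": 22.0, "SB": 11.0}


@dataclass(frozen=True)
class PhantomConfig:
    """Ground-truth parameters of the synthetic skin volume."""

    fov_um: float = 200.0
    n_px: int = 256
    z_step_um: float = 1.0
    n_planes: int = 120
    surface_depth_um: float = 5.0
    sc_thickness_um: float = 12.0
    et_um: float = 40.4
    dej_undulation_amp_um: float = 6.0
    dej_undulation_period_um: float = 64.0
    melanin_depth_profile: dict = field(
        default_factory=lambda: {"SG": 0.3, "SS": 0.6, "SB": 1.2}
    )
    melanin_scale: float = 1.0
    melanin_granules_per_layer: int = 800
    melanin_granule_sigma_um: float = 1.8
    collagen_fiber_density: float = 0.2  # fibres per pixel (fringe frequency)
    elastin_amp: float = 0.0  # dermal TPF810 colocated with collagen
    vessel_radius_um: float = 5.0
    vessel_flow_amplitude: float = 0.5
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fov_um", "z_step_um", "sc_thickness_um", "et_um",
            "dej_undulation_period_um", "vessel_radius_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_px < 8 or self.n_planes < 8:
            raise ValueError("n_px and n_planes must be >= 8")
        if self.et_um <= self.sc_thickness_um:
            raise ValueError("et_um must exceed sc_thickness_um")
        if self.n_planes * self.z_step_um <= self.et_um + 20.0:
            raise ValueError("stack must extend at least 20 µm below the epidermis")
        if self.noise_sigma < 0 or self.dej_undulation_amp_um < 0:
            raise ValueError("noise_sigma and undulation amplitude must be >= 0")

    @property
    def pixel_size_xy(self) -> float:
        return self.fov_um / self.n_px


@dataclass
class PhantomTruth:
    """Ground truth exported alongside a generated phantom."""

    seed: int
    surface_um: np.ndarray | None = None  # (y, x)
    sc_bottom_um: np.ndarray | None = None
    dej_um: np.ndarray | None = None
    collagen_mask: np.ndarray | None = None  # (z, y, x) bool, True = collagen
    melanin_total: float | None = None
    melanin_component: np.ndarray | None = None  # noiseless scaled melanin field
    vessel_mask: np.ndarray | None = None  # (y, x) bool
    transform: SimilarityTransform2D | None = None

    @property
    def et_um(self) -> float:
        return float(np.mean(self.dej_um - self.surface_um))

    @property
    def sc_um(self) -> float:
        return float(np.mean(self.sc_bottom_um - self.surface_um))


def _coverage_below(z_um: np.ndarray, boundary_um: np.ndarray) -> np.ndarray:
    """Fraction of plane z lying below a boundary, one-plane linear ramp.

    1 for planes a full step below the boundary, 0 a full step above, and the
    50 % crossing at ``round(boundary)`` for unit z-step.
    """
    return np.clip(z_um[:, None, None] - boundary_um[None, :, :] + 1.0, 0.0, 1.0)


def _voronoi_border(n_px: int, cell_diameter_px: float, rng) -> np.ndarray:
    """Binary 2D map of Voronoi-like cell borders (1 on borders)."""
    n_cells = max(4, int(round((n_px / cell_diameter_px) ** 2)))
    sites = rng.uniform(0, n_px, size=(n_cells, 2))
    yy, xx = np.mgrid[0:n_px, 0:n_px]
    pts = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    d, _ = cKDTree(sites).query(pts, k=2)
    border = (d[:, 1] - d[:, 0]) < 1.5
    return border.reshape(n_px, n_px).astype(np.float32)


def _fringe_pattern(n_px: int, density: float, rng) -> np.ndarray:
    """Oriented sinusoidal fibre texture in [_SHG_BASE, _SHG_BASE+_SHG_FRINGE_AMP]."""
    theta = rng.uniform(0, np.pi)
    phase = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:n_px, 0:n_px]
    coord = xx * np.cos(theta) + yy * np.sin(theta)
    unit = 0.5 + 0.5 * np.sin(2 * np.pi * density * coord + phase)
    return (_SHG_BASE + _SHG_FRINGE_AMP * unit).astype(np.float32)


def _render_granules(
    shape: tuple,
    centers: np.ndarray,
    amps: np.ndarray,
    sigma_z: float,
    sigma_xy: float,
) -> np.ndarray:
    """Sum of 3D Gaussian blobs at ``centers`` (z, y, x) with peak ``amps``."""
    out = np.zeros(shape, dtype=np.float32)
    rz = int(np.ceil(3 * sigma_z))
    rxy = int(np.ceil(3 * sigma_xy))
    dz = np.arange(-rz, rz + 1, dtype=np.float32)
    dxy = np.arange(-rxy, rxy + 1, dtype=np.float32)
    kz = np.exp(-0.5 * (dz / sigma_z) ** 2)
    kxy = np.exp(-0.5 * (dxy / sigma_xy) ** 2)
    blob = kz[:, None, None] * kxy[None, :, None] * kxy[None, None, :]
    nz, ny, nx = shape
    for (zc, yc, xc), amp in zip(centers, amps):
        zc, yc, xc = int(round(zc)), int(round(yc)), int(round(xc))
        z0, z1 = max(0, zc - rz), min(nz, zc + rz + 1)
        y0, y1 = max(0, yc - rxy), min(ny, yc + rxy + 1)
        x0, x1 = max(0, xc - rxy), min(nx, xc + rxy + 1)
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue
        out[z0:z1, y0:y1, x0:x1] += amp * blob[
            z0 - zc + rz : z1 - zc + rz,
            y0 - yc + rxy : y1 - yc + rxy,
            x0 - xc + rxy : x1 - xc + rxy,
        ]
    return out


def generate_stack(config: PhantomConfig) -> tuple:
    """Generate a 4-channel multimodal z-stack and its ground truth.

    Returns ``(MultimodalStack, PhantomTruth)``.  Deterministic given
    ``config.seed``; the truth melanin total scales exactly with
    ``melanin_scale`` for a fixed seed and geometry.
    """
    cfg = config
    n = cfg.n_px
    px = cfg.pixel_size_xy
    rng_geom = np.random.default_rng([cfg.seed, 1])
    rng_cells = np.random.default_rng([cfg.seed, 2])
    rng_mel = np.random.default_rng([cfg.seed, 3])
    rng_noise = np.random.default_rng([cfg.seed, 4])

    z_um = np.arange(cfg.n_planes, dtype=np.float32) * cfg.z_step_um
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float32)
    x_um, y_um = xx * px, yy * px

    # --- geometry -------------------------------------------------------
    surface = np.full((n, n), cfg.surface_depth_um, dtype=np.float32)
    sc_bottom = surface + cfg.sc_thickness_um
    phx, phy = rng_geom.uniform(0, 2 * np.pi, size=2)
    k_und = 2 * np.pi / cfg.dej_undulation_period_um
    dej = (
        surface
        + cfg.et_um
        + cfg.dej_undulation_amp_um
        * np.sin(k_und * x_um + phx)
        * np.sin(k_und * y_um + phy)
    ).astype(np.float32)

    cov_surface = _coverage_below(z_um, surface)
    cov_scb = _coverage_below(z_um, sc_bottom)
    cov_dej = _coverage_below(z_um, dej)
    in_sc = cov_surface - cov_scb
    in_viable = cov_scb - cov_dej
    in_dermis = cov_dej

    viable_span = dej - sc_bottom
    layer_bounds = {
        "SG": (sc_bottom, sc_bottom + viable_span / 3),
        "SS": (sc_bottom + viable_span / 3, sc_bottom + 2 * viable_span / 3),
        "SB": (sc_bottom + 2 * viable_span / 3, dej),
    }

    # --- cell borders (RCM) and cytoplasm (TPF735) ----------------------
    rcm = _RCM_SC_AMP * in_sc + _RCM_DERMIS_AMP * in_dermis
    tpf735 = np.zeros_like(rcm)
    for layer, (top, bottom) in layer_bounds.items():
        border = _voronoi_border(n, _CELL_DIAMETER_UM[layer] / px, rng_cells)
        in_layer = _coverage_below(z_um, top) - _coverage_below(z_um, bottom)
        rcm += _RCM_BORDER_AMP * border[None] * in_layer
        tpf735 += _TPF735_CYTO_AMP * (1.0 - border)[None] * in_layer

    # --- melanin granules (TPF810) --------------------------------------
    melanin = np.zeros(rcm.shape, dtype=np.float32)
    sigma_xy_px = cfg.melanin_granule_sigma_um / px
    sigma_z_pl = cfg.melanin_granule_sigma_um / cfg.z_step_um
    for layer, (top, bottom) in layer_bounds.items():
        amp = float(cfg.melanin_depth_profile.get(layer, 0.0))
        if amp <= 0 or cfg.melanin_granules_per_layer <= 0:
            continue
        m = cfg.melanin_granules_per_layer
        gx = rng_mel.integers(0, n, size=m)
        gy = rng_mel.integers(0, n, size=m)
        t = top[gy, gx]
        b = bottom[gy, gx]
        gz = rng_mel.uniform(t, b) / cfg.z_step_um
        amps = amp * rng_mel.uniform(0.6, 1.0, size=m)
        centers = np.column_stack([gz, gy, gx])
        melanin += _render_granules(rcm.shape, centers, amps, sigma_z_pl, sigma_xy_px)
    # melanin is strictly epidermal: clip it out of the dermis (hard cut at
    # the half-coverage boundary so it is exactly disjoint from the truth
    # collagen mask)
    melanin *= in_dermis < 0.5
    melanin_scaled = cfg.melanin_scale * melanin

    # --- dermis: collagen fringes (SHG810), optional elastin (TPF810) ---
    fringe = _fringe_pattern(n, cfg.collagen_fiber_density, rng_geom)
    shg = fringe[None] * in_dermis
    tpf810 = (
        _TPF810_SC_AMP * in_sc
        + melanin_scaled
        + cfg.elastin_amp * fringe[None] * in_dermis
    )

    # --- truth melanin total over [mean top-of-SG, mean DEJ] ------------
    k0 = int(round(float(sc_bottom.mean()) / cfg.z_step_um))
    k1 = int(round(float(dej.mean()) / cfg.z_step_um))
    melanin_total = float(melanin_scaled[k0 : k1 + 1].sum())

    channels = {"RCM": rcm, "TPF735": tpf735, "TPF810": tpf810, "SHG810": shg}
    if cfg.noise_sigma > 0:
        for name in channels:
            noisy = channels[name] + rng_noise.normal(
                0.0, cfg.noise_sigma, size=channels[name].shape
            )
            channels[name] = np.clip(noisy, 0.0, None).astype(np.float32)
    else:
        channels = {k: v.astype(np.float32) for k, v in channels.items()}

    stack = MultimodalStack(
        channels=channels,
        pixel_size_xy=px,
        z_step=cfg.z_step_um,
        fov_um=cfg.fov_um,
        session_id=f"phantom-{cfg.seed}",
        timepoint="baseline",
    )
    truth = PhantomTruth(
        seed=cfg.seed,
        surface_um=surface,
        sc_bottom_um=sc_bottom,
        dej_um=dej,
        collagen_mask=in_dermis >= 0.5,
        melanin_total=melanin_total,
        melanin_component=melanin_scaled,
    )
    return stack, truth


def generate_flow_series(config: PhantomConfig, n_frames: int = 10) -> tuple:
    """Generate an RCM frame series with temporally fluctuating vessel speckle.

    The background speckle is static across frames; pixels inside the vessel
    tubes are re-sampled independently each frame with amplitude
    ``vessel_flow_amplitude`` (zero amplitude leaves only the detector-noise
    floor).  Returns ``(FrameSeries, PhantomTruth)`` with the vessel mask.
    """
    cfg = config
    n = cfg.n_px
    rng_bg = np.random.default_rng([cfg.seed, 10])
    rng_flow = np.random.default_rng([cfg.seed, 11])
    rng_noise = np.random.default_rng([cfg.seed, 12])

    background = 0.2 + 0.3 * np.clip(
        gaussian_filter(rng_bg.normal(0, 1, size=(n, n)), 1.5) * 2.0 + 0.5, 0, None
    )

    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    r_px = cfg.vessel_radius_um / cfg.pixel_size_xy
    c1 = 0.40 * n + 0.08 * n * np.sin(2 * np.pi * xx / n * 1.5)
    c2 = 0.70 * n + 0.05 * n * np.cos(2 * np.pi * xx / n * 2.0)
    vessel = (np.abs(yy - c1) < r_px) | (np.abs(yy - c2) < r_px)

    frames = np.repeat(background[None], n_frames, axis=0)
    if cfg.vessel_flow_amplitude > 0:
        n_v = int(vessel.sum())
        for t in range(n_frames):
            frames[t][vessel] = 0.2 + cfg.vessel_flow_amplitude * np.abs(
                rng_flow.normal(0.0, 1.0, size=n_v)
            )
    if cfg.noise_sigma > 0:
        frames = frames + rng_noise.normal(0, cfg.noise_sigma, size=frames.shape)
    frames = np.clip(frames, 0.0, None).astype(np.float32)

    series = FrameSeries(frames=frames, pixel_size_xy=cfg.pixel_size_xy)
    truth = PhantomTruth(seed=cfg.seed, vessel_mask=vessel)
    return series, truth


def default_marker_landmarks(
    opening_length_um: float = 8000.0,
    opening_width_um: float = 2500.0,
    tip_inset_frac: float = 0.25,
    session_id: str = "baseline",
) -> LandmarkSet:
    """Baseline tip geometry of the surface marker's rectangular opening.

    The marker opening is 2.5 × 8 mm; the two navigational tips sit on
    opposite long edges, inset from the ends, giving the defaults a tip
    span of 6500 µm.  Coordinates are stage µm centred on the opening.
    """
    hx = opening_length_um / 2 * (1 - tip_inset_frac)
    hy = opening_width_um / 2
    return LandmarkSet(session_id=session_id, p1=(-hx, -hy), p2=(hx, hy))


def generate_marker_sessions(
    truth_transform: SimilarityTransform2D,
    landmark_noise_sigma: float,
    n_sessions: int,
    seed: int,
    baseline: LandmarkSet | None = None,
) -> tuple:
    """Simulate landmark recordings over repeated imaging sessions.

    The first session is the exact baseline; each follow-up applies the truth
    transform to the baseline tips and adds isotropic Gaussian localization
    noise (``landmark_noise_sigma`` µm per coordinate).  Returns
    ``(list[LandmarkSet], PhantomTruth)``.
    """
    if n_sessions < 2:
        raise ValueError("need at least a baseline and one follow-up session")
    if baseline is None:
        baseline = default_marker_landmarks()
    rng = np.random.default_rng([seed, 20])
    true_pts = truth_transform.apply(np.array([baseline.p1, baseline.p2], float))
    sessions = [baseline]
    for i in range(1, n_sessions):
        noisy = true_pts + rng.normal(0.0, landmark_noise_sigma, size=(2, 2))
        sessions.append(
            LandmarkSet(
                session_id=f"followup-{i}", p1=tuple(noisy[0]), p2=tuple(noisy[1])
            )
        )
    truth = PhantomTruth(seed=seed, transform=truth_transform)
    return sessions, truth
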