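# skintrack

Serial microregistration and quantitative analysis for longitudinal
multimodal skin microscopy.

Tracking the *same* skin cells in a living person across days or weeks
requires relocating a 200 × 200 µm² microscope field of view to the same
tissue microlocation at every session. `skintrack` implements the
marker-based relocalization that makes this possible, plus the
quantitative readouts of a co-registered multimodal z-stack — reflectance
confocal microscopy (RCM), two-photon fluorescence (TPF at 735 and
810 nm), and second harmonic generation (SHG at 810 nm):

- **Registration** — a 2D similarity transform estimated exactly from two
  surface-marker reference tips,
  `θ = angle(f₂−f₁) − angle(b₂−b₁)`, `s = |f₂−f₁|/|b₂−b₁|`, midpoint-anchored
  translation; ROI prediction, correlation-based fine-tuning, and the
  relocalization metrics: radial-distance consistency
  `100·max(0, 1 − d/200 µm)` % and square-FOV overlap
  `max(0, L−|dx|)·max(0, L−|dy|)/L²`.
- **Melanin** — 810 nm TPF with dermal elastin stripped by SHG-derived
  binary collagen masks (0 inside collagen, 1 elsewhere); depth profiles
  and the volumetric integral from the top of the stratum granulosum to
  the dermal–epidermal junction (DEJ), with fold change vs. baseline.
- **Thickness** — per-column surface / SC-bottom / DEJ detection in ten
  adjacent XZ sections; total epidermal, stratum-corneum, and viable
  (ET − SC) thickness averaged over all 256 × 10 columns.
- **Blood flow** — per-pixel standard deviation over 10 RCM frames;
  vessel flow index and red/cyan STD-over-SHG overlays.
- **Cell density** — granular/spinous keratinocytes per en-face mm² from
  manual dot annotations, with study time-course tables.
- **Phantom** — a seeded synthetic multimodal skin volume (layered
  epidermis, undulating DEJ, collagen texture, melanin granules, speckled
  vessels, marker landmark sessions) with exported ground truth, so every
  pipeline is testable without a microscope.

See `docs/methods.md` for the models, parameter defaults, and limitations.

## Worked example

```python
import numpy as np
from skintrack import *

# --- registration accuracy under 10 µm landmark-localization noise ------
truth = SimilarityTransform2D(theta=0.2, scale=1.0, t=(300.0, -150.0))
mc = accuracy_monte_carlo(truth, landmark_noise_sigma=10.0, n_trials=1000, seed=1)
print(mc.mean_radial_error_um, mc.mean_consistency_pct, mc.mean_overlap_fraction)
# 8.97 95.51 0.944

# --- phantom stack -> thickness -> melanin ------------------------------
stack, truth_p = generate_stack(PhantomConfig(seed=1))          # ET 40.4, SC 12.0
bounds = [detect_boundaries(s) for s in extract_vertical_sections(stack, 10)]
rep = thickness_report(bounds)
print(rep.et_um, rep.sc_um, rep.viable_um)
# 40.564 12.035 28.529        (truth: 40.4 / 12.0 / 28.4 µm)

melanin_rep, profile = analyze_melanin(stack, bounds)
print(melanin_rep.volumetric_intensity, melanin_rep.integration_bounds)
# 179802.7 (17.035, 45.564)   (truth total: 177448.1 a.u., i.e. +1.3 %)

# a second session with 1.6x the melanin, same geometry
stack2, _ = generate_stack(PhantomConfig(seed=1, melanin_scale=1.6))
bounds2 = [detect_boundaries(s) for s in extract_vertical_sections(stack2, 10)]
rep2, _ = analyze_melanin(stack2, bounds2, baseline=melanin_rep)
print(rep2.fold_change_vs_baseline)
# 1.581                        (truth: 1.6)

# --- capillary flow ------------------------------------------------------
series, truth_f = generate_flow_series(PhantomConfig(seed=1))
fmap = std_map(series)
print(flow_index(fmap, truth_f.vessel_mask))
# 0.2759                       (background STD: 0.0185, a 15x contrast)
```

The registration numbers say that with 10 µm tip-localization noise the
predicted ROI lands on average 9 µm from the true location — a 95.5 %
radial consistency and 94 % field overlap, comfortably inside the 50 µm /
56 % regime where the same microstructures remain identifiable. The
thickness and melanin numbers recover the phantom's built-in truth to
within the stated tolerances (±1.5 µm; ±5 % on fold change).

## Command line

```bash
skintrack simulate stack --seed 1 --out phantom/
skintrack thickness --stack phantom/stack.tif --n-sections 10 \
    --report thick.json --boundaries-out bounds.json
skintrack melanin --stack phantom/stack.tif --boundaries bounds.json --report mel.json
skintrack register --baseline lm_base.csv --followup lm_d5.csv \
    --roi 0,0,200 --report reg.json
skintrack flow --frames frames.tif --mask vessels.tif --report flow.json --overlay flow.png
skintrack density --annotations dots.csv --pixel-size 0.78125 --report dens.json
```

Every report is self-describing JSON: schema version, resolved
configuration, seed, and SHA-256 hashes of the inputs. No timestamps, so
identical config + seed gives byte-identical reports.

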