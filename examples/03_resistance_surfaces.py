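"""Build the 15-variant resistance-surface family of one covariate.

Five parameterizations (untransformed, high/low exponential at alpha 5 and
10) crossed with three circular focal-window radii (1.5, 6.44, 17.33 km).
The high transformation spreads differences among high-resistance cells; the
low transformation spreads differences among favourable cells.
"""

import numpy as np

from ibrkit import (
    LandscapeParams,
    build_variant_family,
    reverse_surface,
    road_decay,
    simulate_landscape,
    transform_high,
    Raster,
)

cover = simulate_landscape(LandscapeParams(nrows=50, ncols=50, cell_size=300.0,
                                           correlation_range=4000.0,
                                           value_range=(0.0, 100.0), seed=31))
# high cover facilitates gene flow -> reverse so high values mean resistance
resistance = reverse_surface(cover)
print(f"reversed surface: min {np.nanmin(resistance.values):.2f} "
      "(the 0.1 floor keeps every cell traversable)")

family = build_variant_family("SAGE", resistance)
print(f"variant family size: {len(family)} (5 transformations x 3 windows)")
for variant, surf in family[:5]:
    print(f"  {variant.label:32s} range [{np.nanmin(surf.values):9.3f}, "
          f"{np.nanmax(surf.values):10.3f}]")
print("  -> high10 tops out at e^10 ~ 22026: unfavourable habitat dominates cost")

high10 = transform_high(resistance, 10.0)
print(f"high10 max = {np.nanmax(high10.values):.3f} (= exp(10) = {np.exp(10):.3f})")

dist_km = Raster(values=np.abs(np.arange(-10, 11, dtype=float))[None, :] * 0.3,
                 cell_size=300.0)
roads = road_decay(dist_km, alpha_km=0.564)
print(f"road decay at 0, 0.564 and 3 km: {roads.values[0, 10]:.3f}, "
      f"{np.exp(-1):.3f}, {np.exp(-3/0.564):.4f}")
print("  -> resistance contribution of a road fades by 1/e every 0.564 km")
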