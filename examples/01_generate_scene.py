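"""Generate a synthetic study scene and look at what it contains.

A scene bundles everything the exposure pipeline needs: block centroids with
housing attributes, a sparse monitor network observing a smooth background
concentration field, hourly meteorology at a few stations, road segments with
traffic, and the latent "true" background used for recovery experiments.
"""

import pandas as pd

import airtier as at

config = at.SceneConfig(
    n_blocks=20,
    n_monitors=8,
    hours=pd.date_range("2012-01-01", periods=168, freq="h"),
    seed=11,
)
scene = at.generate_scene(config)

print(f"blocks: {len(scene.blocks)} over a "
      f"{config.domain_extent[0]:.0f}x{config.domain_extent[1]:.0f} km domain")
print(f"monitors: {scene.monitors['station_id'].nunique()} stations x "
      f"{len(scene.hours)} hours")
print(f"met stations: {scene.met['station_id'].nunique()}, "
      f"mean wind {scene.met['wind_speed'].mean():.1f} m/s")
print(f"roads: {len(scene.roads)}, AADT "
      f"{min(r.aadt for r in scene.roads):.0f}-{max(r.aadt for r in scene.roads):.0f} veh/day")
print(f"houses: {len(scene.houses)} "
      f"({scene.houses['income_low'].mean():.0%} low-income)")
print(f"true background: mean {scene.true_field.values.mean():.2f} ug/m3, "
      f"sd {scene.true_field.values.std():.2f}")
# The monitor series and the true block field are one joint Gaussian-process
# realization, so kriging the monitors genuinely informs the blocks.
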