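# fintrack

Video tracking and statistics for small-fish exposure assays.

`fintrack` is a Python library and command-line tool for laboratories
that assess environmental exposures (for example static magnetic fields
in the millitesla range) with medaka fish. It covers both arms of such
an assay:

* **Behavior** — grayscale tank recordings are turned into per-fish
  trajectories by background subtraction, blob segmentation and
  shortest-Euclidean-distance identity mapping; trajectories are
  summarized as per-clip swimming velocities and spatial occupancy
  heatmaps with dwell fractions in user-defined field zones.
* **Embryo development** — daily staging records of embryo dishes are
  summarized as hatchability, days to hatch and abnormality rate, and
  developmental trajectories of two groups are compared day by day.

A seeded synthetic-data generator produces tank clips with known
ground-truth trajectories and embryo cohorts with known stage dynamics,
so the whole pipeline is testable without any recording.

## The method

For each frame `i`, detected fish positions `(s_x,i, s_y,i)` are linked
to the previous frame by the injective matching minimizing the total
Euclidean distance

    d_i = sqrt((s_x,i − s_x,i−1)² + (s_y,i − s_y,i−1)²)

over all candidate pairs (optimal assignment with a distance gate).
A clip's total swimming distance is the superposition of these
consecutive-frame distances over all `n_c` frames, and the average
velocity is that distance divided by `n_c − 1` transitions
(pixel/frame) or by the clip duration (pixel/s; 5-minute clips by
default). Group comparisons use a two-tailed paired t-test,
`t = mean(d)/(sd(d)/√n)` with `n − 1` degrees of freedom, and the
headline effect size is the percent difference of group mean
velocities. Embryo development is recorded on the standard medaka
staging ladder (stage 14, pre-mid-gastrula, through stage 40, first
fry); a dish's hatchability counts embryos hatched before a 20-day
abandonment cutoff.

## Worked example

```python
import fintrack as ft

# synthetic two-fish clip with ground truth
cfg = ft.TankSimConfig(n_fish=2, n_frames=300, noise_sigma=3.0, seed=7)
stack, truth = ft.simulate_tank(cfg)

model = ft.train_background(stack)            # per-pixel median reference
detections = ft.detect_stack(stack, model)    # blobs per frame
tracks = ft.build_tracks(detections, n_fish=2)

print(ft.count_identity_swaps(tracks, truth.positions))
cv = ft.clip_velocity(tracks[0])
print(round(cv.velocity_px_per_frame, 3), round(cv.total_distance_px, 1))
```

prints

```
0
2.969 887.8
```

— the tracker followed both fish without ever swapping identities, and
fish 0 swam 887.8 px over the clip, an average of 2.969 pixel/frame.

The packaged per-clip velocity table of a published exposure experiment
ships with the library:

```sh
fintrack stats --table3
```

```json
{
  "groups": ["control", "treated"],
  "means": {"control": 2.584, "treated": 1.9483},
  "percent_difference": 24.6,
  "t_stat": 11.352022117689486,
  "df": 11,
  "p_two_tailed": 2.0538185751665536e-07,
  "significant_at_alpha": true,
  "alpha": 0.05
}
```

— the exposed group swims 24.6% slower than control, a difference that
is highly significant under the paired t-test.

The CLI exposes the full pipeline as subcommands (`simulate`, `detect`,
`track`, `velocity`, `heatmap`, `stats`, `embryo`); every output
directory receives a JSON provenance sidecar with config, seed and
input hashes.

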