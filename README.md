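# tipcollide

Quantitative analysis of collisions between growing microtubule plus-ends
and membrane-associated protein clusters in plant cells.

In interphase plant epidermal cells, cortical microtubules (MTs) elongate
along the plasma membrane. The growing plus-end can be labeled with the
end-binding protein EB1, whose fluorescent "comet" traces the growth
trajectory of each MT. Membrane-associated proteins such as the myosin
VIII ATM1 IQ-tail fragment or remorins form near-immobile sub-micrometre
clusters ("spots") on the same membrane. `tipcollide` takes
particle-tracking tables of comet tracks and cluster spots (as exported by
tracking software such as Imaris, or in a flat canonical CSV schema) and
answers: how often do growing tips collide with clusters, and what happens
to MT growth speed and straightness when they do?

## What it computes

**Collision detection.** A comet center at distance *d* from a spot of
diameter *D* is in contact when

&nbsp;&nbsp;&nbsp;&nbsp;*d* < *D*/2 + *b*

with a configurable border allowance *b* (default 0.1 µm). Runs of
consecutive contact frames of one (track, spot) pair merge into a single
*collision episode*, anchored at the frame of closest approach. A
compatibility criterion (*d* < *D*) reproducing an older screening rule is
available as `criterion="diameter"`.

**Track and spot statistics.** Per-step speeds (µm/s), path length,
displacement, straightness = displacement / path length ∈ [0, 1], spot
maximal displacement from its first position, collision counts per track
and per spot.

**Collision kinetics.** Mean speed in a −1/+3 frame window around each
episode anchor, compared to the whole-track mean speed: collisions are
classified *accelerated* / *decelerated* / *unaffected* (5% relative
tolerance by default); straightness is also compared before vs after the
collision. Per cell, the percentages of colliding tracks and spots and
the class mix over colliding tracks (tracks > 5 µm) are summarized.

**Orientation dispersion.** For images of fibrous structures (e.g. MT
arrays), a structure-tensor orientation histogram over [−90°, 90°) is
computed and a Gaussian is fitted to its highest peak. Reported are the
**dispersion** (Gaussian σ, degrees) and the **amount** (fraction of
histogram mass within ±1σ of the peak — ≈ 0.68 for a perfectly Gaussian
orientation distribution).

**Synthetic data.** Persistent-walk comet tracks, jittering spots, and
fiber images with known ground truth; collisions can be *planted* with a
chosen outcome (pass through, pause and disappear, detach and turn,
retract), so every stage of the analysis is testable without microscopy
data.

**Animation.** Per-frame rendering of growing tracks and spot circles;
elements turn white from their first collision frame on (GIF/MP4 export).

## Worked example

```python
from tipcollide import (AnalysisConfig, PlannedCollision, SpotSimParams,
                        TrackSimParams, analyze_cell, plant_collisions,
                        simulate_tracks)

tracks, _ = simulate_tracks(TrackSimParams(n_tracks=10, n_frames=50, seed=3))
plan = [PlannedCollision(track_id=2, frame=20, outcome="pass", speed_factor=0.5),
        PlannedCollision(track_id=5, frame=30, outcome="retract", speed_factor=0.5)]
tracks, spots, _ = plant_collisions(tracks, SpotSimParams(n_spots=8, seed=4), plan)

res = analyze_cell(tracks, spots, AnalysisConfig())
s = res.summary
print(f"{s.pct_tracks_colliding:.1f}% tracks colliding, "
      f"{s.pct_spots_colliding:.1f}% spots colliding")
print(f"acc {s.pct_acc:.1f}% / dec {s.pct_dec:.1f}% / unaffected {s.pct_unaffected:.1f}%")
```

prints

```
20.0% tracks colliding, 25.0% spots colliding
acc 0.0% / dec 100.0% / unaffected 0.0%
```

Two of the ten simulated tracks were routed through a planted spot with
their growth speed halved from the collision frame on. Both planted
episodes are detected (2/10 tracks = 20% colliding; the two planted spots
out of eight total = 25% colliding spots), and both colliding tracks
classify as decelerated: their near-collision speed falls more than 5%
below their whole-track mean.

The same pipeline runs from the shell:

```bash
tipcollide simulate --n-tracks 30 --n-frames 50 --seed 7 --out-prefix sim_
tipcollide detect --tracks sim_tracks.csv --spots sim_spots.csv --out collisions.csv
tipcollide metrics --tracks sim_tracks.csv --spots sim_spots.csv --out-prefix cell1_
tipcollide directionality --images 'imgs/*.tif' --out directionality.csv
tipcollide animate --tracks sim_tracks.csv --spots sim_spots.csv \
    --collisions collisions.csv --select 10 --out cell.gif
```

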