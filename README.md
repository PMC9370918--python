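# liftkin

Upper-body kinematics of repetitive palletizing work, from raw optical-capture
marker trajectories to a paired statistical comparison of first and last work
sessions.

Order pickers in warehouses repeat the same pick–carry–place cycle hundreds of
times a shift, and the bending/straightening phases of picking and placing
load the back and shoulder differently depending on whether the box is in
hand. `liftkin` is a pipeline for quantifying exactly that: it separates each
repetitive lifting session into labelled **bending** and **straightening**
events of **picking** and **placing** (hence loaded vs. unloaded), and tracks
how timings, joint angles, back–shoulder coordination, movement variability
and shoulder moments change with repeated sessions. It is aimed at
occupational-biomechanics researchers and ergonomists working with marker
data of repetitive manual materials handling.

## What it computes

With markers in a +Z-up global frame (meters):

* **Trunk inclination** θ — signed angle between the sagittal projection of
  the L5→C7 spine vector and vertical (positive = forward flexion).
* **Shoulder flexion** φ — signed angle between the sagittal projections of
  the upper-arm vector (glenohumeral centre → elbow centre) and the C7→T8
  trunk line (positive = arm anterior to the trunk line).
* **Shoulder moment** m = (m_box·g/2)·d, with d the signed sagittal lever arm
  from the glenohumeral centre to the wrist-midpoint box proxy, and the
  **cumulative moment** CM = Σᵢ mᵢ·δt over each loaded event.
* **Segmentation** — the vertical C7 trajectory, low-passed at 1 Hz, dips at
  every deep bend; the 24 lowest troughs are the ground-level bends, the
  first 12 the palletization half, and event boundaries are found where the
  trunk-inclination rate of change crosses a threshold near each trough.
* **Per-event metrics** — total time, time to (80 % of) maximum, angle
  max/mean/median, moment peak/mean/CM; per-event-type coordination
  (enclosed area between mean trunk and shoulder profiles on a 0–100 %
  time base, peak-timing offsets) and variability (SDs of maxima, mean
  point-wise SD).
* **Statistics** — two-sided paired t-tests of participant means, session 1
  vs. 3, α = 0.05.

Because real sessions of this protocol are not public, the package includes a
forward-kinematic **generator** of synthetic marker sessions with known
ground truth (true angles, boundaries, labels), used by the test suite and
the reproduction script. See `docs/methods.md` for the model, conventions
and generator details.

## Worked example

```python
from liftkin import SyntheticSessionSpec, generate_session, process_session

ts, truth = generate_session(SyntheticSessionSpec(seed=7))   # ~10 min at 50 Hz
res = process_session(ts)
print(len(res.events))                      # 24
ev = res.events.to_frame()
print(ev[["start_s", "trough_s", "end_s", "phase", "action", "load"]].head(4))
```

```
24
   start_s  trough_s  end_s          phase   action      load
0     0.44      2.18   2.18        bending  picking  unloaded
1     2.18      2.18   4.00  straightening  picking    loaded
2     8.28     10.30  10.30        bending  placing    loaded
3    10.30     10.30  12.30  straightening  placing  unloaded
```

The first pick's bending runs from 0.44 s to the trough at 2.18 s (the
instant of maximum back flexion, ~1.7 s of bending for this draw from the
1.92 ± 0.32 s timing distribution), straightening with the box follows until
4.00 s, and the loaded placing bend starts 8.3 s in — one 12 s
pick–carry–place cycle.

The numbered scripts under `analysis/` run the whole study design: simulate
a 9-participant, two-session cohort (`01`), process every session and
tabulate metrics (`02`), and compare sessions (`03`). On the default cohort,
`03` prints `22/72 comparisons significant at alpha=0.05`, with the changes
concentrated in the loaded events (median shoulder flexion in
placing-bending 53.4° → 47.4°, picking-bending timings, placing-bending
peak and cumulative moments) — the pattern the injected session-3 parameter
shifts encode.

From a shell, the same pipeline runs over marker files:

```sh
liftkin simulate --seed 3 --participants 9 --out data/
liftkin run data/*.trc --out out/
```

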