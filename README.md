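# nucleitrack

Counting, localizing and tracking overlapping cell nuclei in time-lapse
videos of micropatterned cell clusters — and pinning down, to a single
frame, the moment a two-cell cluster becomes three, so the orientation
of that division can be measured.

## The problem

Cells cultured on small printed adhesive disks (micropatterns) grow as
isolated clusters, imaged for days by automated fluorescence
microscopy through a chromatin reporter such as H2B-mCherry. Screens of
this kind produce thousands of single-cluster videos per condition, far
beyond manual analysis — yet confined nuclei pack, overlap and drift out
of focus, which defeats the standard seed-then-segment cell detectors.
The quantity of interest here is the **division angle**: when one of two
sister cells divides, the angle between the new daughter–daughter axis
and the axis of the two pre-existing cells, folded into [0°, 90°].
Getting it right requires knowing the *exact frame* of the transition,
because packed clusters rotate quickly.

## The method

Each frame is fitted with two competing image models: a 2-component and
a 3-component 2D Gaussian mixture,

  M_K(x, y) = Σₖ wₖ · exp(−½ (x − μₖ)ᵀ Sₖ⁻¹ (x − μₖ)),  K ∈ {2, 3},

minimizing, with Powell's derivative-free method, the penalized
least-squares objective

  f_global = f_err · (1 + f_loc + f_vol + f_int),

where `f_err = Σ (I − M_K)²` and the three penalties anchor component
locations to the image foreground (via a distance transform), component
areas to `Ā_nuc = π d̄²_nuc/4`, and peak intensities to `w̄_nuc`. Only
two biological parameters enter: the average nucleus diameter `d̄_nuc`
(px) and peak intensity `w̄_nuc` (of intensity-normalized images).

The transition is then found in time from three per-frame features:
the residual ratio `F1 = f3/f2`, the minimum distance `F2` among the
3-component centers, and the intensity variance `F3` along the segment
joining the two closest centers. The first frame containing three cells
is the earliest significant peak of the product of their (robustly
normalized) derivatives, confirmed by a persistent change of `F1` —
a division permanently changes which model describes the cluster.
At that frame the daughter axis and the previous 2-cell axis give the
division angle. A Kolmogorov–Smirnov utility compares angle
distributions between conditions.

Everything is validated against a built-in, seeded synthetic-video
generator with an exact truth channel (`nucleitrack.synthetic_video`),
which emulates drifting, rotating, overlapping and defocusing nuclei
and a programmed division. See `docs/methods.md` for the model,
the detector design and its limitations.

## Worked example

Simulate a ground-truthed cluster video (division at frame 22 at 60°),
then run the full analysis:

```
$ nucleitrack simulate demo.tif --n-frames 40 --division-frame 22 --division-angle 60 --seed 7
wrote demo.tif (40 frames)
$ nucleitrack angle demo.tif --seed 7
{"sequence_id": "demo", "event_frame": 22, "excluded_reason": null,
 "angle_deg": 60.0, ...}
```

Or from Python:

```python
import numpy as np
from nucleitrack import Scenario, generate_cluster_video, RunConfig, analyze_sequence

scenario = Scenario(n_frames=40, division_frame=22, division_angle=60.0, seed=7)
stack, truth = generate_cluster_video(scenario)
result = analyze_sequence(stack, RunConfig(seed=7), sequence_id="demo")
print(result.event.event_frame, round(result.angle.angle, 1))
# 22 60.0
```

The detected frame matches the programmed division frame exactly and
the measured angle matches the programmed 60° to within a twentieth of a degree: the
residual ratio of the two mixture models collapses at frame 22, the
call is confirmed, and the refined 3-component fit at that frame yields
the daughter axis.

A full batch goes through the CLI: `extract` crops one sub-video per
micropattern from a field-of-view TIFF plus a pattern reference image;
`run` fits, detects and measures every sequence in a directory into one
results table (CSV) with an explicit exclusion reason for every video
that yields no angle; `compare` runs the KS test between two result
tables. `--d-nuc`, `--w-nuc`, `--peak-c` and `--seed` override the YAML
config.

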