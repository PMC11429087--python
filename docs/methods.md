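# Methods

This note documents the models, conventions and numerical choices behind
tectapipe, in the order the pipeline runs.

## Synthetic LFP recordings

The generator emulates 20-minute single-channel recordings from the larval
zebrafish optic tectum at 4 dpf. The background is Gaussian noise shaped
to a 1/f^α spectrum (α = 1 by default, flat below 1 Hz to avoid the DC
singularity) and rescaled to an exact target RMS (10 µV-equivalent units
by default). The sampling rate defaults to 2000 Hz so that the highest
analysis band (250–500 Hz) sits comfortably below Nyquist; rates below
1000 Hz are rejected.

Ictal-like events are tapered polyspike bursts: a cubed sine carrier at
`spike_rate_hz` (150 Hz default, putting ~90% of the energy at the
fundamental and ~10% at the third harmonic — all above 100 Hz) under a
Hann taper, with peak amplitude `amp_factor` × the analytic background
estimate of the clean baseline (the same median-envelope convention the
detector uses, which makes the 3× detection threshold meaningful by
construction). `amp_factor` is drawn uniformly from (4, 8): clearly
supra-threshold, as described for the knockdown discharges
(≥ 3× baseline). Event counts per recording are Poisson with mean
`event_rate`; durations are uniform in (0.3, 1.5) s. Artifact swells use
the same construction at a 5 Hz carrier — high amplitude but no >100 Hz
energy — to exercise the detector's frequency gating.

Events are placed uniformly at random by rejection sampling (50 attempts
per event, then a placement error), with a minimum silent gap of 1.0 s
between events. The gap is deliberately larger than the detector's 0.5 s
merge window so that two distinct injected events can never be fused into
one detection; without it, count-recovery tests would confound placement
with detection.

Per-recording seeds in a cohort are drawn from a generator seeded with the
cohort seed, so any cohort is reproducible from a single integer.

What the generator does *not* emulate: electrode drift, line noise,
muscle-contraction artifacts with broadband energy, non-stationary
backgrounds, or realistic spike-wave morphology. Detector performance
measured on this synthetic data therefore reflects the idealized regime
the detection criterion defines (events ≥ 3× background with HFO content),
not performance on arbitrary real recordings.

## Event detection

Bands 1–100, 100–250, 250–500 Hz; zero-phase (forward-backward) 4th-order
Butterworth filtering so onsets are not biased by filter delay. The
amplitude envelope is the magnitude of the analytic signal (Hilbert
transform), smoothed with a 20 ms moving average. The *background* of a
band is the median of its envelope over the whole recording — "background"
has no standard operational definition for such recordings, and a median
is robust to the rare large events being detected, where a mean would be
inflated by them. Thresholding is strict (`envelope > 3 ×
background`); boundary equality has measure zero on real-valued data.

Supra-threshold runs shorter than 0.1 s are discarded (suppresses
single-sample crossings) and runs closer than 0.5 s are merged (counts a
polyspike train as one event); both are exposed as parameters and CLI
flags. Per-band intervals are unioned into candidate events, and an event
is classified ictal-like iff some band with low edge ≥ 100 Hz crossed
threshold during it. Power spectra use Welch's averaged periodogram (Hann,
50% overlap, 2 s segments by default), which conserves total variance to
within a few percent.

Per-recording counts feed the cohort summary (n, mean, SEM, fraction of
recordings with more than 3 events; SEM reported absent for n = 1).

## Synthetic arbors and stack rendering

Arbors grow as stochastic binary trees: per growth step each active tip
either bifurcates (probability `branch_prob`) or extends, so the expected
tip count after n steps is (1 + branch_prob)^n and arbor complexity is
controlled by a single knob. Daughters of a bifurcation split by
±`branch_angle`/2 (default 0.9 rad total) in the lateral plane — prompt
divergence, as in real dendritic bifurcations — and every direction gets
Gaussian jitter with a damped z-component, keeping arbors roughly planar
as dorsally-imaged tectal arbors are. Tips that would leave the field
terminate (1 µm margin) rather than clamp, so no segment ever hugs the
boundary. Segment lengths vary ±20% around `segment_len_um`.

Rendering samples each segment at quarter-voxel steps into a (z, y, x)
boolean mask (pixel centers at integer × voxel size), dilates it with the
face-connected structuring element — thick enough that thin structures
survive a 3×3×3 median filter, thin enough that nearby branches remain
resolvable — sets foreground intensity 200, and adds clipped Gaussian
noise. The geometric ground truth is computed *before* rasterization:
for each radius, the number of crossings of the segments (projected to the
lateral plane) with the circle around the soma centroid, obtained from the
quadratic for each segment–circle pair. The axial step defaults to
0.44 µm, matching the confocal z-resolution being emulated.

## Sholl quantification

3-D median filter (3×3×3 default), maximum-intensity z-projection,
binarization by Otsu's between-class-variance criterion (parameter-free;
a fixed threshold is available), then concentric circles at 2 µm steps
from the soma centroid out to the nearest image edge by default. Each
circle is sampled at ≤ 0.25-pixel arc increments; the intersection count
is the number of maximal contiguous foreground runs along the circular
path (first/last runs merged across the wrap), the convention of the
standard image-analysis Sholl plug-in. Radii that leave the image are
counted on the in-bounds arc with a warning. The reported score is the
summed intersection count divided by the caller-supplied neuron count —
summed rather than per-radius normalization, since the reference tables
report a single number per larva. Soma counting is not automated; an
advisory blob-counting helper exists but normalization always uses the
caller's count.

Pixel-based counts agree with the geometric oracle to ±1 for ≥95% of radii
on small radial trees (the acceptance property). The residual ±1
discrepancies are inherent to rasterization: sister branches within ~1 µm
of a bifurcation merge into one arc, and dilated end-caps extend a branch
by one radius step past its geometric tip.

## Statistics

Percent-to-count reconstruction uses largest-remainder rounding per group
(floors first, remaining units to the largest fractional remainders, ties
broken by category order normal → mild → moderate → severe), so each row
sums exactly to the printed group size. Percentages left unstated share
the remainder to 100%, assigned to the first unlisted category in that
order; "more than 94% normal" in the rescue controls is operationalized as
95% normal, remainder mild. Chi-square is Pearson's without Yates
correction (cells are large), all four severity categories retained;
a zero row/column margin is an error rather than silently dropped.

ANOVA from summaries uses SS_within = Σ (nᵢ−1)·nᵢ·SEMᵢ² (since
SEM = SD/√n) and SS_between = Σ nᵢ(meanᵢ − grand mean)²; the raw-data
route computes the same decomposition and is cross-checked against an
independent implementation in the tests. Zero within-group variance with
distinct means reports F = ∞, p = 0; identical groups report F = 0,
p = 1. No post-hoc pairwise tests are provided (only omnibus p-values are
reconstructable from the reference summaries).

Densitometry: band intensity / total-protein intensity, scaled so the
reference lane equals 1.0.

## Amplicon model

Lengths only: an amplicon is the sum of per-exon contributions between the
primer anchors; skipping internal exon k subtracts exactly its
contribution, a cryptic insertion adds its length. The bundled zebrafish
*dhps* fixture encodes the 375 bp exon-1–3 amplicon with a 203 bp exon-2
contribution (375 − 172); the split of the remaining 172 bp between the
terminal exons is a fixture convention, as only totals are constrained.

## Problem sizes and determinism

Every generator is a pure function of (config, seed); detection and Sholl
are deterministic. The acceptance script simulates 200 cohort replicates
of 23 (knockdown, Poisson mean 3.74 events/recording) and 22 (control,
0.68) recordings; recordings are shortened to 2 minutes with the
per-recording Poisson mean held at the published per-20-min value, which
leaves the distribution of per-recording counts — and hence the >3-event
fraction — unchanged while keeping the run lightweight. Property tests use
30–60 s recordings for sensitivity (duration does not affect per-event
detection) and full 20-minute recordings for the false-positive rate,
which *is* duration-dependent.

## Known limitations

- The detector assumes a stationary background; slow drifts would inflate
  the median envelope and reduce sensitivity.
- Projection-mode Sholl only; no spherical (3-D) analysis of the
  un-projected stack, no tracing or per-cell segmentation.
- The arbor generator controls relative complexity, not biologically
  calibrated morphometrics; group comparisons on synthetic stacks test
  ordering, not absolute intersection counts.
- Contingency reconstruction inherits the rounding of the printed
  percentages; cell counts may differ by ±1 from the original tallies,
  which is immaterial at these group sizes.
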