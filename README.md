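# tectapipe

Quantitative analysis pipeline for a larval zebrafish model of DHPS
deficiency (morpholino knockdown of *dhps*, the deoxyhypusine synthase
gene): epileptiform-event detection in tectal local field potential (LFP)
recordings, Sholl quantification of GABAergic neuronal arborization from
confocal z-stacks, and the group-level statistics that connect them —
together with seeded synthetic-data generators so every stage can be
validated end to end against known ground truth.

It is written for electrophysiologists and imaging scientists who score
larval seizure phenotypes and arbor complexity, and for anyone who needs to
recompute the group statistics of such an experiment from published
summary numbers (group sizes, category percentages, means and SEMs).

## The methods in brief

**Ictal-like event detection.** A recording sampled at `fs` Hz is
decomposed with zero-phase 4th-order Butterworth band-passes into the
1–100, 100–250 and 250–500 Hz bands. Within each band the smoothed
analytic-signal envelope `e_b(t)` is compared against a robust background
level `B_b = median(e_b)`; maximal runs with `e_b(t) > 3·B_b` become
candidate events (runs < 0.1 s discarded, runs < 0.5 s apart merged). An
event is *ictal-like* only if a band at or above 100 Hz crossed threshold
during it — the high-frequency-oscillation (HFO) criterion that excludes
movement artifacts of arbitrary amplitude.

**Sholl quantification.** A z-stack (0.44 µm axial step) is 3-D
median-filtered, max-projected along z, binarized (Otsu), and intersected
with concentric circles around the soma centroid at 2 µm radius steps;
the summed intersection count is divided by the number of neurons in the
imaged area: `score = Σ_r N(r) / n_neurons`.

**Statistics.** Contingency tables are rebuilt from printed group sizes
and category percentages by largest-remainder rounding (rows sum exactly
to *n*) and tested with Pearson's chi-square; one-way ANOVA is computed
either from raw values or directly from printed (n, mean, SEM) triples via
`SS_within = Σ (n_i−1)·n_i·SEM_i²`; densitometry is normalized as
`(band/total protein)` relative to a reference lane. Amplicon lengths of
splice variants (exon skips, cryptic insertions) are predicted additively
from per-exon contributions.

## Worked example

```python
import tectapipe as tp

# simulate a 2-minute recording with ~4 ictal-like events and detect them
cfg = tp.LFPSimConfig(duration_s=120, event_rate=4.0)
rec, truth = tp.simulate_recording(cfg, seed=42)
res = tp.detect(rec, compute_psd=False)
print(truth.n_true_ictal, res.n_ictal)

# one-way ANOVA from the published per-larva ictal-event summaries
from tectapipe import datasets as ds
r = tp.anova_from_summary(ds.ICTAL_EVENTS_4DPF)
print(f"F = {r.statistic:.3f}, df = {r.df}, p = {r.pvalue:.4f}")
```

prints

```
6 6
F = 5.846, df = (2, 62), p = 0.0047
```

The first line shows that the detector recovered all six injected
HFO-bearing events for this seed (a Poisson(4.0) draw). The second line is
the omnibus test across the wild-type (n=20, 0.25 ± 0.14 events/20 min),
control-morpholino (n=22, 0.68 ± 0.24) and knockdown (n=23, 3.74 ± 1.27)
groups: the event frequency differs significantly (p ≤ 0.02).

The same stages are exposed on the command line:

```bash
tectapipe simulate lfp --seed 1 --n 5 --out-dir sim/
tectapipe detect --in sim/ --threshold-factor 3
tectapipe sholl --in stack.tif --n-neurons 4 --step-um 2
tectapipe stats anova --summary summary.csv
tectapipe amplicon --gene gene.json --skip 2
tectapipe run --seed 0 --out-dir demo/
```

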