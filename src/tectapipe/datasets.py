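"""Reference summary tables for the zebrafish dhps-knockdown experiments.

These are the published group-level summaries (group sizes, phenotype
category percentages, ictal-event means with SEMs, Sholl means with SEMs)
that the statistics layer consumes.  They are inputs, not results: raw
recordings and images were never deposited, so group statistics are
recomputed from these printed summaries and detector performance is
assessed on synthetic data anchored to the printed rates.
"""

from __future__ import annotations

from .stats import GroupSummary

# ----- Phenotype scoring at 5 dpf (morphant vs control dysmorphology) -----
# Percentages per severity category; unlisted categories absorb the
# remainder to 100% (controls: 96% normal, remainder scored mild).
PHENOTYPE_5DPF_SIZES = {
    "Wt": 168,
    "Ctrl MO": 148,
    "dhps E2I2 MO": 180,
    "dhps AUG MO": 126,
}
PHENOTYPE_5DPF_PCT = {
    "Wt": {"normal": 96.0},
    "Ctrl MO": {"normal": 96.0},
    "dhps E2I2 MO": {"severe": 13.0, "moderate": 38.0, "mild": 16.0},
    "dhps AUG MO": {"severe": 4.0, "moderate": 7.0, "mild": 13.0},
}

# ----- mRNA co-injection rescue scoring at 1 dpf -----
# Controls are reported as "more than 94%" normal; operationalized as 95%
# with the remainder scored mild.
RESCUE_1DPF_SIZES = {
    "Wt": 163,
    "dhps mRNA": 111,
    "dhps E2I2 MO": 371,
    "E2I2 MO + mRNA": 179,
}
RESCUE_1DPF_PCT = {
    "Wt": {"normal": 95.0},
    "dhps mRNA": {"normal": 95.0},
    "dhps E2I2 MO": {"normal": 34.0, "mild": 41.0, "moderate": 17.0},
    "E2I2 MO + mRNA": {"normal": 49.0, "mild": 31.0, "moderate": 16.0},
}

# ----- Ictal-like event counts per 20-min tectal LFP recording, 4 dpf -----
ICTAL_EVENTS_4DPF = GroupSummary(
    labels=("Wt", "Ctrl MO", "dhps E2I2 MO"),
    n=(20, 22, 23),
    mean=(0.25, 0.68, 3.74),
    sem=(0.14, 0.24, 1.27),
)

# Per-group thresholds on the share of larvae with >3 ictal-like events per
# 20-min recording: <10% in Ctrl MO, >43% in the knockdown group.
GT3_FRACTION_BOUNDS = {"Ctrl MO": ("<", 10.0), "dhps E2I2 MO": (">", 43.0)}

# ----- Neuron-normalized Sholl intersection scores (GABAergic arbors) -----
ARBOR_SHOLL = {
    "3dpf": GroupSummary(
        labels=("Wt", "Ctrl MO", "dhps E2I2 MO"),
        n=(7, 6, 14),
        mean=(93.22, 88.33, 42.57),
        sem=(7.01, 8.54, 4.23),
    ),
    "5dpf": GroupSummary(
        labels=("Wt", "Ctrl MO", "dhps E2I2 MO"),
        n=(6, 6, 7),
        mean=(110.4, 108.3, 47.55),
        sem=(8.5, 3.8, 9.49),
    ),
    "7dpf": GroupSummary(
        labels=("Wt", "Ctrl MO", "dhps E2I2 MO"),
        n=(7, 9, 6),
        mean=(107.3, 109.6, 48.19),
        sem=(7.41, 7.89, 6.38),
    ),
}
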