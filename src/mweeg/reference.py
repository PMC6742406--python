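"""Reference values from the live-lecture mind-wandering study this
pipeline models.

These are published summary numbers, kept here as inputs so that tests and
the acceptance script share one copy: the per-participant epoch class
distribution after artifact rejection, and spot-check F statistics from
the repeated-measures ANOVA tables (used to verify the partial eta squared
computation against the printed effect sizes).
"""

from __future__ import annotations

import numpy as np

#: participant -> (MW epochs, non-MW epochs) after epoch rejection
EPOCH_CLASS_DISTRIBUTION: dict[str, tuple[int, int]] = {
    "P1": (25, 22),
    "P2": (15, 45),
    "P3": (15, 45),
    "P4": (10, 30),
    "P5": (5, 30),
    "P6": (15, 33),
    "P7": (30, 30),
    "P8": (20, 25),
    "P9": (10, 25),
    "P10": (15, 15),
    "P11": (20, 40),
    "P12": (20, 35),
    "P13": (15, 40),
    "P14": (20, 25),
    "P15": (20, 35),
}

#: usable probes per participant in the study design (13 of 15 probes,
#: two lost to a technical error), at 5 epochs per 10 s pre-probe window
USABLE_PROBES = 13
EPOCHS_PER_PROBE = 5

#: spot-checked ANOVA results: name -> (F, df1, df2, printed eta_p^2)
#: participant-wise models (units = channels) and one channel-wise model
#: (units = participants)
ANOVA_SPOT_CHECKS: dict[str, tuple[float, int, int, float]] = {
    "participant_P1_MW": (400.95, 1, 15, 0.96),
    "participant_P2_MW": (95.49, 1, 14, 0.87),
    "participant_P8_MW": (22.51, 1, 15, 0.60),
    "channel_F7_MW": (2.99, 1, 13, 0.19),
}


def epoch_count_summary() -> dict[str, float]:
    """Column means of the epoch distribution plus the mean observed MW
    rate (mean over participants of MW / total)."""
    mw = np.array([v[0] for v in EPOCH_CLASS_DISTRIBUTION.values()], float)
    non = np.array([v[1] for v in EPOCH_CLASS_DISTRIBUTION.values()], float)
    total = mw + non
    return {
        "mean_mw_epochs": float(mw.mean()),
        "mean_non_mw_epochs": float(non.mean()),
        "mean_total_epochs": float(total.mean()),
        "mean_observed_mw_rate": float((mw / total).mean()),
    }
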