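"""Reference subject-level parameter sets for the synthetic study.

These are published best-fit full-model parameters for the five observers
of a saccadic color-oddball priming experiment, expressed on the Ratcliff
scale (s = 0.1).  They serve two purposes: as the default generating
parameters of the synthetic-data pipeline (so that simulated studies have
realistic accuracies around 92-100% and saccade latencies around
250-400 ms), and as worked-example inputs for the group-level statistics.

``REFERENCE_FIT_CHISQ`` holds the corresponding minimized chi-square
statistics and ``FALSE_ALARM_RATES`` the observed per-subject rates of
saccades on target-absent trials.
"""

from __future__ import annotations

from .conditions import FullModelParams

__all__ = ["SUBJECT_PRESETS", "REFERENCE_FIT_CHISQ", "FALSE_ALARM_RATES"]

SUBJECT_PRESETS: dict[str, FullModelParams] = {
    "P1": FullModelParams(dB_DPE=0.1852, dB_POP=0.1437, v0=0.6785,
                          dv_DPE=-0.0839, dv_POP=-0.0168,
                          a_DPE=0.0567, a_POP=0.0640,
                          T_DPE=0.2579, T_POP=0.2466,
                          Sz=0.0000, St=0.0467, eta=0.2083),
    "P2": FullModelParams(dB_DPE=0.1560, dB_POP=0.0960, v0=0.5084,
                          dv_DPE=-0.0102, dv_POP=0.0017,
                          a_DPE=0.0749, a_POP=0.0759,
                          T_DPE=0.2497, T_POP=0.2419,
                          Sz=0.0000, St=0.0726, eta=0.0000),
    "P3": FullModelParams(dB_DPE=0.1038, dB_POP=0.0889, v0=0.7754,
                          dv_DPE=0.0187, dv_POP=0.0582,
                          a_DPE=0.1229, a_POP=0.0832,
                          T_DPE=0.2313, T_POP=0.2415,
                          Sz=0.0674, St=0.0490, eta=0.5000),
    "P4": FullModelParams(dB_DPE=-0.0517, dB_POP=0.1379, v0=0.5854,
                          dv_DPE=0.0798, dv_POP=-0.1287,
                          a_DPE=0.0749, a_POP=0.0941,
                          T_DPE=0.3275, T_POP=0.3052,
                          Sz=0.0000, St=0.0903, eta=0.1439),
    "P5": FullModelParams(dB_DPE=0.0621, dB_POP=0.0666, v0=0.6466,
                          dv_DPE=0.0201, dv_POP=-0.0187,
                          a_DPE=0.0916, a_POP=0.0933,
                          T_DPE=0.2530, T_POP=0.2537,
                          Sz=0.0623, St=0.0157, eta=0.0000),
}

REFERENCE_FIT_CHISQ: dict[str, float] = {
    "P1": 8.617, "P2": 14.928, "P3": 23.202, "P4": 3.693, "P5": 18.871,
}

FALSE_ALARM_RATES: dict[str, float] = {
    "P1": 0.0094, "P2": 0.0484, "P3": 0.1059, "P4": 0.0098, "P5": 0.0062,
}
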