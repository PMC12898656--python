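"""Published 31-control / 34-AUD group summaries.

The printed summary statistics of the case-control comparison the default
simulator configs are calibrated to: per-TSP (n, mean, SD) for a healthy
control group (n = 31) and an alcohol-use-disorder group (n = 34), plus the
demographic comparisons (age summaries and the gender contingency table).
These are *inputs* for summary-statistic mode — raw recordings of such
clinical cohorts are not distributable, printed summaries are.
"""

from __future__ import annotations

from .stats import GroupSummary

__all__ = [
    "N_CONTROL",
    "N_AUD",
    "TSP_SUMMARIES",
    "AGE_SUMMARIES",
    "GENDER_TABLE",
]

N_CONTROL = 31
N_AUD = 34


def _pair(cm: float, cs: float, am: float, asd: float):
    return (GroupSummary(N_CONTROL, cm, cs), GroupSummary(N_AUD, am, asd))


#: (control, AUD) summary per TSP, in canonical feature-column order.
TSP_SUMMARIES: dict[str, tuple[GroupSummary, GroupSummary]] = {
    "utterance_length": _pair(84.052, 34.760, 77.569, 44.481),
    "articulation_tempo": _pair(14.743, 1.544, 14.551, 1.186),
    "speech_tempo": _pair(9.647, 1.551, 7.877, 2.038),
    "silent_pause_occurrence_rate": _pair(4.850, 1.628, 5.243, 1.907),
    "filled_pause_occurrence_rate": _pair(1.512, 0.897, 2.831, 1.695),
    "total_pause_occurrence_rate": _pair(6.362, 1.935, 8.074, 2.491),
    "silent_pause_duration_rate": _pair(30.538, 9.739, 39.112, 15.862),
    "filled_pause_duration_rate": _pair(3.798, 2.618, 6.914, 5.704),
    "total_pause_duration_rate": _pair(34.336, 9.568, 46.025, 12.984),
    "silent_pause_frequency": _pair(0.480, 0.115, 0.419, 0.113),
    "filled_pause_frequency": _pair(0.154, 0.087, 0.245, 0.155),
    "total_pause_frequency": _pair(0.634, 0.131, 0.663, 0.196),
    "silent_pause_average_duration": _pair(0.641, 0.155, 0.983, 0.488),
    "filled_pause_average_duration": _pair(0.243, 0.078, 0.246, 0.090),
    "total_pause_average_duration": _pair(0.550, 0.142, 0.775, 0.406),
}

#: (control, AUD) age summaries.
AGE_SUMMARIES = _pair(50.71, 9.795, 48.35, 9.39)

#: Gender counts, rows = (AUD, control), columns = (female, male).
GENDER_TABLE = [[7, 27], [11, 20]]
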