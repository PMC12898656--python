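"""The fifteen temporal speech parameters (TSPs).

Each parameter is a scalar timing statistic of one subject's spontaneous
speech, computed from a normalized token timeline.  The pause statistics come
in three scopes — silent pauses only, filled pauses only, and both together —
giving the canonical set of fifteen:

========================================  =========  ==============================
parameter                                 unit       definition
========================================  =========  ==============================
utterance length                          s          last token end − first start
articulation tempo                        phone/s    phones / (length − pause time)
speech tempo                              phone/s    phones / length
pause occurrence rate  (×3 scopes)        %          pauses × 100 / phones
pause duration rate    (×3 scopes)        %          pause time × 100 / length
pause frequency        (×3 scopes)        1/s        pauses / length
pause average duration (×3 scopes)        s          pause time / pauses
========================================  =========  ==============================

"Phones" counts phone-category tokens only; pause tokens never count as
phones, otherwise articulation tempo would depend on pause segmentation.
An average duration with zero pauses of its scope is *undefined* and is
propagated as NaN/missing, never as 0 — a zero would bias group means
downward for pause-free speakers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .timeline import DegenerateTimelineError, SpeechTimeline, TokenCategory

__all__ = [
    "PAUSE_SCOPES",
    "TSP_COLUMNS",
    "TSPVector",
    "compute_tsp",
    "build_feature_table",
    "TSPExtractor",
]

PAUSE_SCOPES = ("silent", "filled", "total")

#: Feature-table column order (fixed, schema version 1).
TSP_COLUMNS = (
    "utterance_length",
    "articulation_tempo",
    "speech_tempo",
    "silent_pause_occurrence_rate",
    "filled_pause_occurrence_rate",
    "total_pause_occurrence_rate",
    "silent_pause_duration_rate",
    "filled_pause_duration_rate",
    "total_pause_duration_rate",
    "silent_pause_frequency",
    "filled_pause_frequency",
    "total_pause_frequency",
    "silent_pause_average_duration",
    "filled_pause_average_duration",
    "total_pause_average_duration",
)


@dataclass(frozen=True)
class TSPVector:
    """All fifteen TSPs for one subject, plus the raw tallies behind them.

    ``pause_average_duration[scope]`` is NaN when the scope has no pauses.
    """

    utterance_length: float
    articulation_tempo: float
    speech_tempo: float
    occurrence_rate: dict[str, float]
    duration_rate: dict[str, float]
    pause_frequency: dict[str, float]
    pause_average_duration: dict[str, float]
    n_phones: int
    n_pauses: dict[str, int]
    pause_time: dict[str, float]

    def as_dict(self) -> dict[str, float]:
        """Flatten to the fixed :data:`TSP_COLUMNS` order."""
        out = {
            "utterance_length": self.utterance_length,
            "articulation_tempo": self.articulation_tempo,
            "speech_tempo": self.speech_tempo,
        }
        for scope in PAUSE_SCOPES:
            out[f"{scope}_pause_occurrence_rate"] = self.occurrence_rate[scope]
        for scope in PAUSE_SCOPES:
            out[f"{scope}_pause_duration_rate"] = self.duration_rate[scope]
        for scope in PAUSE_SCOPES:
            out[f"{scope}_pause_frequency"] = self.pause_frequency[scope]
        for scope in PAUSE_SCOPES:
            out[f"{scope}_pause_average_duration"] = self.pause_average_duration[scope]
        return {k: out[k] for k in TSP_COLUMNS}


def compute_tsp(timeline: SpeechTimeline) -> TSPVector:
    """Evaluate all fifteen TSP definitions on a normalized timeline.

    Raises
    ------
    ValueError
        If the timeline is not normalized.
    DegenerateTimelineError
        If it contains no phone tokens.
    """
    if not timeline.normalized:
        raise ValueError(
            f"{timeline.subject_id}: timeline must be normalized before TSP "
            "computation (see normalize_timeline)"
        )
    n_phones = 0
    n_sil = n_fil = 0
    t_sil = t_fil = 0.0
    for tok in timeline.tokens:
        if tok.category is TokenCategory.PHONE:
            n_phones += 1
        elif tok.category is TokenCategory.SILENT_PAUSE:
            n_sil += 1
            t_sil += tok.duration
        else:
            n_fil += 1
            t_fil += tok.duration
    if n_phones == 0:
        raise DegenerateTimelineError(f"{timeline.subject_id}: no phone tokens")
    length = timeline.span
    n_pauses = {"silent": n_sil, "filled": n_fil, "total": n_sil + n_fil}
    pause_time = {"silent": t_sil, "filled": t_fil, "total": t_sil + t_fil}
    articulation_time = length - pause_time["total"]
    return TSPVector(
        utterance_length=length,
        articulation_tempo=n_phones / articulation_time,
        speech_tempo=n_phones / length,
        occurrence_rate={s: n_pauses[s] * 100.0 / n_phones for s in PAUSE_SCOPES},
        duration_rate={s: pause_time[s] * 100.0 / length for s in PAUSE_SCOPES},
        pause_frequency={s: n_pauses[s] / length for s in PAUSE_SCOPES},
        pause_average_duration={
            s: (pause_time[s] / n_pauses[s]) if n_pauses[s] > 0 else math.nan
            for s in PAUSE_SCOPES
        },
        n_phones=n_phones,
        n_pauses=n_pauses,
        pause_time=pause_time,
    )


def build_feature_table(
    timelines: list[SpeechTimeline], group_column: str = "group"
) -> pd.DataFrame:
    """One TSP row per subject, indexed by subject id, columns in fixed order.

    Undefined cells (average duration of an absent pause scope) are NaN and
    serialize to empty CSV cells.  Duplicate subject ids are an error.
    """
    seen: set[str] = set()
    rows = []
    index = []
    for tl in timelines:
        if tl.subject_id in seen:
            raise ValueError(f"duplicate subject_id {tl.subject_id!r}")
        seen.add(tl.subject_id)
        row = compute_tsp(tl).as_dict()
        row[group_column] = tl.group_label
        rows.append(row)
        index.append(tl.subject_id)
    table = pd.DataFrame(
        rows, index=pd.Index(index, name="subject_id"),
        columns=list(TSP_COLUMNS) + [group_column],
    )
    return table


class TSPExtractor(TransformerMixin, BaseEstimator):
    """Transformer from speech timelines to the 15-column TSP feature table.

    Stateless (``fit`` only validates); composes with sklearn pipelines whose
    downstream steps consume the numeric feature frame.

    Parameters
    ----------
    min_pause_s : float, default 0.03
        Silent pauses shorter than this are dropped from the pause inventory
        during normalization.
    trim_edges : bool, default True
        Delete leading/trailing silences (recording lead-in/out is a session
        artifact, not speech planning); shrinks utterance length.
    group_column : str, default "group"
        Name of the label column appended to the output frame.
    """

    def __init__(
        self,
        min_pause_s: float = 0.03,
        trim_edges: bool = True,
        group_column: str = "group",
    ):
        self.min_pause_s = min_pause_s
        self.trim_edges = trim_edges
        self.group_column = group_column

    def fit(self, X: list[SpeechTimeline], y=None) -> "TSPExtractor":
        if not isinstance(X, (list, tuple)):
            raise TypeError("X must be a list of SpeechTimeline")
        self.n_features_in_ = len(TSP_COLUMNS)
        return self

    def transform(self, X: list[SpeechTimeline]) -> pd.DataFrame:
        from .timeline import normalize_timeline

        normalized = [
            tl
            if tl.normalized
            else normalize_timeline(tl, self.min_pause_s, self.trim_edges)
            for tl in X
        ]
        return build_feature_table(normalized, group_column=self.group_column)

    def get_feature_names_out(self, input_features=None):
        import numpy as np

        return np.asarray(TSP_COLUMNS, dtype=object)
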