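"""Time-aligned token sequences of spontaneous speech.

A phone-level recognizer (or a Praat-style manual alignment) turns a recording
into an ordered sequence of labelled intervals: phones, silent pauses, and
filled pauses ("umm"-type hesitations, which such recognizers emit as labelled
tokens just like phones).  :class:`SpeechTimeline` is that sequence for one
subject; it is the only input the temporal-parameter engine consumes.

Category assignment is always mediated by a :class:`LabelMap` so that the
mapping from a recognizer's symbol inventory to {phone, silent pause, filled
pause} is explicit configuration, never guessed from label strings.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

__all__ = [
    "TokenCategory",
    "Token",
    "LabelMap",
    "SpeechTimeline",
    "TimelineValidationError",
    "DegenerateTimelineError",
    "normalize_timeline",
]


class TimelineValidationError(ValueError):
    """A timeline violates an ordering/overlap/duration invariant."""


class DegenerateTimelineError(ValueError):
    """A timeline has no phone content to analyze."""


class TokenCategory(str, enum.Enum):
    PHONE = "phone"
    SILENT_PAUSE = "silent_pause"
    FILLED_PAUSE = "filled_pause"


@dataclass(frozen=True, slots=True)
class Token:
    """One labelled interval: a phone-like unit or a pause.

    ``category`` must come from a :class:`LabelMap`; ``start``/``end`` are in
    seconds from the start of the recording.
    """

    label: str
    category: TokenCategory
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise TimelineValidationError(
                f"token {self.label!r}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


# Filled-pause labels a Hungarian phone-level recognizer typically emits,
# plus common phonetics conventions.  Silent-pause labels follow HTK/Kaldi
# practice.  Both sets are configuration, not detection.
DEFAULT_SILENT_LABELS = frozenset({"sil", "sp", "pau", "<sil>", "SIL"})
DEFAULT_FILLED_LABELS = frozenset({"fp", "hes", "um", "uh", "ööö", "<fp>"})


@dataclass(frozen=True)
class LabelMap:
    """Binds a recognizer's symbol inventory to token categories.

    Any label in neither set gets ``default_category`` (phone).
    """

    silent_labels: frozenset[str] = DEFAULT_SILENT_LABELS
    filled_labels: frozenset[str] = DEFAULT_FILLED_LABELS
    default_category: TokenCategory = TokenCategory.PHONE

    def __post_init__(self) -> None:
        object.__setattr__(self, "silent_labels", frozenset(self.silent_labels))
        object.__setattr__(self, "filled_labels", frozenset(self.filled_labels))
        overlap = self.silent_labels & self.filled_labels
        if overlap:
            raise ValueError(
                f"labels cannot be both silent and filled: {sorted(overlap)}"
            )

    def categorize(self, label: str) -> TokenCategory:
        if label in self.silent_labels:
            return TokenCategory.SILENT_PAUSE
        if label in self.filled_labels:
            return TokenCategory.FILLED_PAUSE
        return self.default_category


@dataclass
class SpeechTimeline:
    """Ordered, non-overlapping token sequence for one subject/utterance.

    ``normalized`` marks that pause post-processing (gap filling, merging of
    adjacent silences, minimum-duration filtering, optional edge trimming)
    has been applied; the feature engine requires it.
    """

    subject_id: str
    tokens: list[Token] = field(default_factory=list)
    group_label: str | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for prev, cur in zip(self.tokens, self.tokens[1:]):
            if cur.start < prev.start:
                raise TimelineValidationError(
                    f"{self.subject_id}: tokens not sorted by start time "
                    f"({prev.label!r}@{prev.start} before {cur.label!r}@{cur.start})"
                )
            # allow a hair of float slack from serialization rounding
            if cur.start < prev.end - 1e-9:
                raise TimelineValidationError(
                    f"{self.subject_id}: overlapping tokens "
                    f"{prev.label!r}[{prev.start},{prev.end}] and "
                    f"{cur.label!r}[{cur.start},{cur.end}]"
                )

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def span(self) -> float:
        """Utterance length: last token end minus first token start."""
        if not self.tokens:
            return 0.0
        return self.tokens[-1].end - self.tokens[0].start

    def counts(self) -> dict[TokenCategory, int]:
        out = {c: 0 for c in TokenCategory}
        for t in self.tokens:
            out[t.category] += 1
        return out


def _fill_gaps(tokens: list[Token]) -> list[Token]:
    # Unlabelled time between consecutive tokens is treated as silence:
    # phone-level recognizer output is exhaustive, so gaps only occur in
    # third-party alignments.
    out: list[Token] = []
    for tok in tokens:
        if out and tok.start > out[-1].end + 1e-9:
            out.append(
                Token("sil", TokenCategory.SILENT_PAUSE, out[-1].end, tok.start)
            )
        out.append(tok)
    return out


def _merge_adjacent_silences(tokens: list[Token]) -> list[Token]:
    out: list[Token] = []
    for tok in tokens:
        if (
            out
            and tok.category is TokenCategory.SILENT_PAUSE
            and out[-1].category is TokenCategory.SILENT_PAUSE
        ):
            prev = out[-1]
            out[-1] = replace(prev, end=tok.end)
        else:
            out.append(tok)
    return out


def normalize_timeline(
    timeline: SpeechTimeline,
    min_pause_s: float = 0.03,
    trim_edges: bool = True,
) -> SpeechTimeline:
    """Canonicalize the pause structure of a timeline.

    Steps, in order: fill unlabelled gaps with silent pauses; merge runs of
    adjacent silent pauses; drop silent pauses shorter than ``min_pause_s``
    from the pause inventory (the spanned time stays inside the utterance but
    contributes to no pause statistic); if ``trim_edges``, delete leading and
    trailing silent pauses outright, shrinking the utterance.  Idempotent.

    ``min_pause_s`` defaults to 0.03 s: below roughly three recognizer frame
    steps an alignment gap is not credible as a planned pause.

    Raises
    ------
    DegenerateTimelineError
        If no phone tokens remain after normalization.
    """
    if timeline.normalized:
        return timeline
    tokens = _fill_gaps(list(timeline.tokens))
    tokens = _merge_adjacent_silences(tokens)
    tokens = [
        t
        for t in tokens
        if t.category is not TokenCategory.SILENT_PAUSE
        or t.duration >= min_pause_s - 1e-9
    ]
    if trim_edges:
        while tokens and tokens[0].category is TokenCategory.SILENT_PAUSE:
            tokens.pop(0)
        while tokens and tokens[-1].category is TokenCategory.SILENT_PAUSE:
            tokens.pop()
    if not any(t.category is TokenCategory.PHONE for t in tokens):
        raise DegenerateTimelineError(
            f"{timeline.subject_id}: no phone tokens remain after normalization"
        )
    return SpeechTimeline(
        subject_id=timeline.subject_id,
        tokens=tokens,
        group_label=timeline.group_label,
        normalized=True,
    )
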