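"""Readers and writers for time-aligned token sequences.

Two textual alignment dialects are supported:

* **CTM** — the canonical exchange format here: one token per line,
  ``<utterance-id> <channel> <start> <duration> <label>``, ``#`` comments
  ignored.  This is exactly the start/duration-stamped token list a
  phone-level recognizer emits.
* **Praat TextGrid** — interval tiers of the long ("ooTextFile") and short
  text formats.  Empty interval labels are silent pauses by convention;
  filled pauses must be explicit labels in the :class:`~tempospeech.timeline.LabelMap`.
"""

from __future__ import annotations

import re
from pathlib import Path

import yaml

from .timeline import LabelMap, SpeechTimeline, Token, TokenCategory

__all__ = [
    "CTMParseError",
    "TextGridError",
    "read_ctm",
    "write_ctm",
    "read_textgrid",
    "read_label_map",
]


class CTMParseError(ValueError):
    """A CTM line could not be parsed; the message names the line number."""


class TextGridError(ValueError):
    """The TextGrid is malformed or the requested tier is unusable."""


# ---------------------------------------------------------------------------
# CTM
# ---------------------------------------------------------------------------

def read_ctm(path: str | Path, label_map: LabelMap | None = None) -> list[SpeechTimeline]:
    """Parse a CTM file into one timeline per utterance id.

    Tokens are grouped by the first field, sorted by start time within each
    utterance, and categorized through ``label_map``.  Timelines come back
    un-normalized.  Utterances appear in order of first occurrence.
    """
    label_map = label_map or LabelMap()
    path = Path(path)
    per_utt: dict[str, list[Token]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 5:
                raise CTMParseError(
                    f"{path}:{lineno}: expected at least 5 fields "
                    f"(utt channel start duration label), got {len(fields)}"
                )
            utt = fields[0]
            try:
                start = float(fields[2])
                duration = float(fields[3])
            except ValueError as exc:
                raise CTMParseError(
                    f"{path}:{lineno}: unparsable numeric field: {exc}"
                ) from None
            if duration <= 0:
                raise CTMParseError(
                    f"{path}:{lineno}: non-positive duration {duration}"
                )
            label = fields[4]
            per_utt.setdefault(utt, []).append(
                Token(label, label_map.categorize(label), start, start + duration)
            )
    timelines = []
    for utt, tokens in per_utt.items():
        tokens.sort(key=lambda t: (t.start, t.end))
        timelines.append(SpeechTimeline(subject_id=utt, tokens=tokens))
    return timelines


def write_ctm(timelines: list[SpeechTimeline], path: str | Path) -> None:
    """Write timelines as CTM with times rendered to 3 decimal places.

    Round-trip guarantee: ``read_ctm(write_ctm(T))`` reproduces labels,
    categories and times to the 3-decimal serialization precision (categories
    provided the same label map is used).
    """
    path = Path(path)
    with path.open("w") as fh:
        for tl in timelines:
            for tok in tl.tokens:
                # duration derived from the *rounded* endpoints, so adjacent
                # tokens can never overlap after serialization rounding
                start = round(tok.start, 3)
                dur = round(tok.end, 3) - start
                fh.write(f"{tl.subject_id} 1 {start:.3f} {dur:.3f} {tok.label}\n")


# ---------------------------------------------------------------------------
# Praat TextGrid
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?")
_STR_RE = re.compile(r'"((?:[^"]|"")*)"')


def _textgrid_items(text: str) -> list[str]:
    """Flatten a TextGrid body into a stream of quoted strings and numbers.

    Works for both the long format (``key = value`` lines with headers) and
    the short format (bare values): the grammar of both is fully determined
    by the ordered sequence of string/number literals.
    """
    items: list[str] = []
    pos = 0
    while pos < len(text):
        ch = text[pos]
        if ch == '"':
            m = _STR_RE.match(text, pos)
            if not m:
                raise TextGridError("unterminated string literal in TextGrid")
            items.append('"' + m.group(1).replace('""', '"'))
            pos = m.end()
        elif ch == "[":  # bracketed indices like "item [1]:" are decoration
            close = text.find("]", pos)
            pos = len(text) if close == -1 else close + 1
        elif ch.isdigit() or (ch == "-" and pos + 1 < len(text) and text[pos + 1].isdigit()):
            m = _NUM_RE.match(text, pos)
            items.append(m.group(0))
            pos = m.end()
        else:
            pos += 1
    return items


def _parse_textgrid(path: Path) -> dict[str, tuple[str, list]]:
    """Return {tier name: (tier class, intervals-or-points)}."""
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    if "ooTextFile" not in text:
        raise TextGridError(f"{path}: not a Praat text TextGrid")
    items = _textgrid_items(text)
    # skip "ooTextFile", "TextGrid", global xmin/xmax; the next bare number
    # after the optional <exists> flag is the tier count.
    it = iter(items)

    def next_num():
        for v in it:
            if not v.startswith('"'):
                return float(v)
        raise TextGridError("unexpected end of TextGrid")

    def next_str():
        for v in it:
            if v.startswith('"'):
                return v[1:]
        raise TextGridError("unexpected end of TextGrid")

    next_num()  # file xmin
    next_num()  # file xmax
    n_tiers = int(next_num())
    tiers: dict[str, tuple[str, list]] = {}
    for _ in range(n_tiers):
        tier_class = next_str()  # "IntervalTier" | "TextTier"
        tier_name = next_str()
        next_num()  # tier xmin
        next_num()  # tier xmax
        n_items = int(next_num())
        entries = []
        for _ in range(n_items):
            if tier_class == "IntervalTier":
                xmin = next_num()
                xmax = next_num()
                label = next_str()
                entries.append((xmin, xmax, label))
            else:
                t = next_num()
                label = next_str()
                entries.append((t, label))
        tiers[tier_name] = (tier_class, entries)
    return tiers


def read_textgrid(
    path: str | Path,
    tier_name: str,
    label_map: LabelMap | None = None,
    subject_id: str | None = None,
) -> SpeechTimeline:
    """Read one interval tier of a Praat TextGrid as a timeline.

    Non-empty interval labels are categorized through ``label_map``; empty
    labels become silent pauses.  The timeline comes back un-normalized.

    Raises
    ------
    TextGridError
        If the tier is missing (the message lists available tiers) or is a
        point tier.
    """
    label_map = label_map or LabelMap()
    path = Path(path)
    tiers = _parse_textgrid(path)
    if tier_name not in tiers:
        raise TextGridError(
            f"{path}: no tier named {tier_name!r}; available tiers: "
            f"{sorted(tiers)}"
        )
    tier_class, entries = tiers[tier_name]
    if tier_class != "IntervalTier":
        raise TextGridError(
            f"{path}: tier {tier_name!r} is a {tier_class}; only interval "
            "tiers carry token durations"
        )
    tokens = []
    for xmin, xmax, label in entries:
        if xmax <= xmin:
            continue  # zero-width placeholder intervals
        if label == "":
            tokens.append(Token("sil", TokenCategory.SILENT_PAUSE, xmin, xmax))
        else:
            tokens.append(Token(label, label_map.categorize(label), xmin, xmax))
    tokens.sort(key=lambda t: (t.start, t.end))
    return SpeechTimeline(subject_id=subject_id or path.stem, tokens=tokens)


# ---------------------------------------------------------------------------
# Label map configuration
# ---------------------------------------------------------------------------

def read_label_map(path: str | Path) -> LabelMap:
    """Load a LabelMap from a YAML file.

    Schema::

        silent_labels: [sil, sp, pau]
        filled_labels: [fp, hes, um, uh]
    """
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: label map must be a mapping")
    kwargs = {}
    if "silent_labels" in data:
        kwargs["silent_labels"] = frozenset(str(s) for s in data["silent_labels"])
    if "filled_labels" in data:
        kwargs["filled_labels"] = frozenset(str(s) for s in data["filled_labels"])
    return LabelMap(**kwargs)
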