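import numpy as np
import pytest

from tempospeech.timeline import SpeechTimeline, Token, TokenCategory

PH = TokenCategory.PHONE
SIL = TokenCategory.SILENT_PAUSE
FP = TokenCategory.FILLED_PAUSE


def make_timeline(segments, subject_id="s", group=None, normalized=False):
    """Build a timeline from (category, duration) pairs laid out contiguously."""
    tokens, t = [], 0.0
    for cat, dur in segments:
        label = {PH: "ph", SIL: "sil", FP: "fp"}[cat]
        tokens.append(Token(label, cat, t, t + dur))
        t += dur
    return SpeechTimeline(subject_id=subject_id, tokens=tokens,
                          group_label=group, normalized=normalized)


@pytest.fixture
def worked_timeline():
    """10 phones of 1.5 s total, one 0.4 s silent and one 0.1 s filled pause."""
    segs = [(PH, 0.15)] * 4 + [(SIL, 0.4)] + [(PH, 0.15)] * 3 + [(FP, 0.1)]
    segs += [(PH, 0.15)] * 3
    return make_timeline(segs, normalized=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240131)


@pytest.fixture(scope="session")
def small_cohort():
    """Calibrated 31+34 cohort with timelines (session-scoped: reused a lot)."""
    from tempospeech.simulate import default_cohort_spec, simulate_cohort

    timelines, table = simulate_cohort(default_cohort_spec(seed=12345))
    return timelines, table


def random_normalized_timeline(rng, max_tokens=12):
    """Random small normalized timeline: phones interleaved with pauses."""
    n_phones = int(rng.integers(1, 7))
    n_pauses = int(rng.integers(0, max(1, n_phones)))
    segs = []
    phone_slots = [[] for _ in range(max(n_phones - 1, 0))]
    if phone_slots and n_pauses:
        for b in rng.choice(len(phone_slots), size=min(n_pauses, len(phone_slots)),
                            replace=False):
            cat = SIL if rng.random() < 0.6 else FP
            phone_slots[b].append((cat, float(rng.uniform(0.05, 1.2))))
    for i in range(n_phones):
        segs.append((PH, float(rng.uniform(0.03, 0.4))))
        if i < len(phone_slots):
            segs.extend(phone_slots[i])
    return make_timeline(segs, normalized=True)
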