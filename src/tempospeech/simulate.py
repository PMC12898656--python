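"""Calibrated synthetic speech-timeline cohorts.

Real case-control speech corpora are rarely shareable, but the published
group summaries (means and SDs of the temporal speech parameters) are.  This
module generates per-subject token timelines whose TSP distributions emulate
a printed control group and alcohol-use-disorder (AUD) group, so the entire
pipeline — alignment I/O, feature extraction, group statistics, ROC — runs
end-to-end with no recordings.

The parameterization is *constructive*: six free quantities are sampled per
subject —

* utterance length (s) and articulation tempo (phone/s): truncated normals
  whose location is solved so the truncated mean equals the printed mean;
* silent and filled pause occurrence rates (% of phones): truncated normals
  for across-subject heterogeneity; the realized per-subject counts are
  Poisson with intensity rate/100 × phone count, and the across-subject
  variance is decomposed so that heterogeneity + mean Poisson noise add up
  to the printed SD²;
* silent and filled average pause durations (s): log-normal across subjects
  (positive, right-skewed, matching the large printed duration SDs),
  constant within a subject.

— and a timeline is then built deterministically from them, which makes the
generator exactly invertible by :func:`tempospeech.features.compute_tsp` and
gives a sharp test oracle.  All remaining TSPs (speech tempo, duration
rates, frequencies, totals) are derived, not set, and emerge near their
printed values.

Free parameters are sampled independently across subjects and of each other
(the published marginals carry no joint information; independence is the
documented default).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .features import TSP_COLUMNS, compute_tsp
from .timeline import SpeechTimeline, Token, TokenCategory

__all__ = [
    "NormalSpec",
    "LogNormalSpec",
    "SubjectParams",
    "GroupGeneratorConfig",
    "CohortSpec",
    "sample_subject",
    "construct_timeline",
    "simulate_cohort",
    "default_configs",
]

#: Silent pauses this short would be dropped by default normalization; the
#: generator never emits pauses below it so its cohorts survive a CTM
#: round-trip through the extraction pipeline unchanged.
MIN_SIM_PAUSE_S = 0.06

_MAX_RESAMPLE = 1000


@dataclass(frozen=True)
class NormalSpec:
    """Truncated-normal spec whose *truncated* mean is moment-matched.

    ``mean``/``sd`` are the targets; sampling uses a normal with scale
    ``sd`` truncated to [lower, upper] whose location is solved numerically
    so the truncated mean equals ``mean`` (a plain truncation would bias the
    mean whenever the bounds are asymmetric around it).
    """

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not self.lower < self.upper:
            raise ValueError("lower must be < upper")
        if self.sd == 0 and not (self.lower <= self.mean <= self.upper):
            raise ValueError("degenerate spec outside its own bounds")


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal spec on the natural scale: target mean and SD.

    Standard moment inversion: sigma² = ln(1 + (sd/mean)²),
    mu = ln(mean) − sigma²/2.  ``floor`` clips pathological small draws.
    """

    mean: float
    sd: float
    floor: float = MIN_SIM_PAUSE_S

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd < 0:
            raise ValueError("mean must be > 0 and sd >= 0")

    @property
    def mu_sigma(self) -> tuple[float, float]:
        if self.sd == 0:
            return math.log(self.mean), 0.0
        s2 = math.log(1.0 + (self.sd / self.mean) ** 2)
        return math.log(self.mean) - s2 / 2.0, math.sqrt(s2)


@lru_cache(maxsize=256)
def _matched_truncnorm(mean: float, sd: float, lower: float, upper: float):
    """Frozen truncnorm with location solved for the target truncated mean."""

    def gap(loc: float) -> float:
        a, b = (lower - loc) / sd, (upper - loc) / sd
        return sps.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    loc = brentq(gap, mean - 10 * sd, mean + 10 * sd)
    a, b = (lower - loc) / sd, (upper - loc) / sd
    return sps.truncnorm(a, b, loc=loc, scale=sd)


def _draw_normal(spec: NormalSpec, rng: np.random.Generator) -> float:
    if spec.sd == 0:
        return spec.mean
    dist = _matched_truncnorm(spec.mean, spec.sd, spec.lower, spec.upper)
    return float(dist.rvs(random_state=rng))


def _draw_lognormal(spec: LogNormalSpec, rng: np.random.Generator) -> float:
    mu, sigma = spec.mu_sigma
    if sigma == 0:
        return max(spec.mean, spec.floor)
    return max(float(rng.lognormal(mu, sigma)), spec.floor)


@dataclass(frozen=True)
class SubjectParams:
    """The free quantities from which one subject's timeline is built.

    Implied phone count is round(articulation_tempo × (utterance_length −
    total pause time)) and must be ≥ 1, with enough internal phone
    boundaries to host every pause.
    """

    utterance_length: float
    articulation_tempo: float
    n_silent: int
    n_filled: int
    silent_durations: tuple[float, ...]
    filled_durations: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.silent_durations) != self.n_silent:
            raise ValueError("silent_durations length must equal n_silent")
        if len(self.filled_durations) != self.n_filled:
            raise ValueError("filled_durations length must equal n_filled")
        if self.pause_time >= self.utterance_length:
            raise ValueError("total pause time must be < utterance length")
        if self.n_phones < 1:
            raise ValueError("implied phone count must be >= 1")

    @property
    def pause_time(self) -> float:
        return sum(self.silent_durations) + sum(self.filled_durations)

    @property
    def n_phones(self) -> int:
        return round(self.articulation_tempo * (self.utterance_length - self.pause_time))


@dataclass(frozen=True)
class GroupGeneratorConfig:
    """Distribution spec of the six free parameters for one group.

    ``silent_rate``/``filled_rate`` are pause occurrence rates in % of
    phones; their SD is the *total* across-cohort SD — the sampler splits it
    into across-subject heterogeneity plus per-subject Poisson count noise.
    ``deterministic_counts`` replaces the Poisson draw by rounding the
    intensity (useful for fully degenerate, repeatable configs).
    """

    utterance_length: NormalSpec
    articulation_tempo: NormalSpec
    silent_rate: NormalSpec
    filled_rate: NormalSpec
    silent_duration: LogNormalSpec
    filled_duration: LogNormalSpec
    deterministic_counts: bool = False

    @property
    def nominal_phone_count(self) -> float:
        """Phone count at the config means: n = AT·L / (1 + AT·g/100)."""
        g = (
            self.silent_rate.mean * self.silent_duration.mean
            + self.filled_rate.mean * self.filled_duration.mean
        )
        u = self.articulation_tempo.mean * g / 100.0
        return self.articulation_tempo.mean * self.utterance_length.mean / (1.0 + u)

    def _heterogeneity(self, rate: NormalSpec) -> NormalSpec:
        # across-subject SD² = total SD² − mean Poisson variance of the
        # realized rate (= 100·mean/n at the nominal phone count)
        poisson_var = 100.0 * rate.mean / self.nominal_phone_count
        across = math.sqrt(max(rate.sd**2 - poisson_var, 0.0))
        return NormalSpec(rate.mean, across, rate.lower, rate.upper)


@dataclass(frozen=True)
class CohortSpec:
    """Group sizes, per-group configs and the single global seed."""

    n_per_group: dict[str, int]
    configs: dict[str, GroupGeneratorConfig]
    seed: int = 0

    def __post_init__(self) -> None:
        for group, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"group {group!r}: need >= 2 subjects, got {n}")
            if group not in self.configs:
                raise ValueError(f"group {group!r} has no generator config")


def sample_subject(
    config: GroupGeneratorConfig, rng: np.random.Generator
) -> SubjectParams:
    """Draw one subject's free parameters.

    Resamples (bounded) until the implied phone count can host every pause
    at a distinct internal boundary.
    """
    sil_rate_spec = config._heterogeneity(config.silent_rate)
    fil_rate_spec = config._heterogeneity(config.filled_rate)
    for _ in range(_MAX_RESAMPLE):
        at = _draw_normal(config.articulation_tempo, rng)
        length0 = _draw_normal(config.utterance_length, rng)
        r_sil = _draw_normal(sil_rate_spec, rng)
        r_fil = _draw_normal(fil_rate_spec, rng)
        m_sil = _draw_lognormal(config.silent_duration, rng)
        m_fil = _draw_lognormal(config.filled_duration, rng)
        # phone count at the drawn parameters: fixed point of
        # n = AT·(L − pause_time) with pause_time = (r_s·m_s + r_f·m_f)·n/100
        g = r_sil * m_sil + r_fil * m_fil
        n_phones = round(at * length0 / (1.0 + at * g / 100.0))
        if n_phones < 2:
            continue
        if config.deterministic_counts:
            n_sil = round(r_sil / 100.0 * n_phones)
            n_fil = round(r_fil / 100.0 * n_phones)
        else:
            n_sil = int(rng.poisson(r_sil / 100.0 * n_phones))
            n_fil = int(rng.poisson(r_fil / 100.0 * n_phones))
        if n_sil + n_fil > n_phones - 1:
            continue
        pause_time = n_sil * m_sil + n_fil * m_fil
        # utterance length re-derived from the fixed phone count, so the
        # realized length stays consistent with AT and the realized pauses
        length = n_phones / at + pause_time
        return SubjectParams(
            utterance_length=length,
            articulation_tempo=at,
            n_silent=n_sil,
            n_filled=n_fil,
            silent_durations=(m_sil,) * n_sil,
            filled_durations=(m_fil,) * n_fil,
        )
    raise RuntimeError(
        f"could not draw a valid subject in {_MAX_RESAMPLE} attempts; the "
        "config's pause budget likely exceeds its utterance length"
    )


def construct_timeline(
    params: SubjectParams,
    rng: np.random.Generator,
    subject_id: str = "sim",
    group_label: str | None = None,
) -> SpeechTimeline:
    """Deterministically build a normalized timeline realizing ``params``.

    Phones get equal durations; each pause occupies its own uniformly chosen
    internal phone boundary (never the edges, so no trimming or merging can
    alter it), hence the output is already in normalized form and
    ``compute_tsp`` reproduces every TSP implied by ``params``.
    """
    n_phones = params.n_phones
    n_pauses = params.n_silent + params.n_filled
    if n_pauses > n_phones - 1:
        raise ValueError(
            f"{n_pauses} pauses cannot occupy {n_phones - 1} internal boundaries"
        )
    phone_dur = (params.utterance_length - params.pause_time) / n_phones
    pause_at: dict[int, Token] = {}
    if n_pauses:
        boundaries = rng.choice(np.arange(1, n_phones), size=n_pauses, replace=False)
        pauses = [("sil", TokenCategory.SILENT_PAUSE, d) for d in params.silent_durations]
        pauses += [("fp", TokenCategory.FILLED_PAUSE, d) for d in params.filled_durations]
        order = rng.permutation(n_pauses)
        for b, k in zip(sorted(boundaries), order):
            pause_at[int(b)] = pauses[k]
    tokens: list[Token] = []
    t = 0.0
    for i in range(n_phones):
        if i in pause_at:
            label, cat, dur = pause_at[i]
            tokens.append(Token(label, cat, t, t + dur))
            t += dur
        tokens.append(Token("ph", TokenCategory.PHONE, t, t + phone_dur))
        t += phone_dur
    return SpeechTimeline(
        subject_id=subject_id,
        tokens=tokens,
        group_label=group_label,
        normalized=True,
    )


def _substream(seed: int, group: str, index: int) -> np.random.Generator:
    # stable per-subject substream: hash (group, index) into a spawn key so
    # cohorts are reproducible under group/subject reordering
    digest = hashlib.sha256(f"{group}\x00{index}".encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key, index)))


def simulate_cohort(
    spec: CohortSpec, return_timelines: bool = True
) -> tuple[list[SpeechTimeline] | None, pd.DataFrame]:
    """Generate a full cohort and its TSP feature table.

    Deterministic given ``spec.seed`` (per-subject substreams, so adding a
    group never changes another group's subjects).  With
    ``return_timelines=False`` timelines are discarded after feature
    extraction, which keeps very large cohorts in constant memory.
    """
    timelines: list[SpeechTimeline] | None = [] if return_timelines else None
    rows, index, groups = [], [], []
    for group in spec.n_per_group:
        config = spec.configs[group]
        for i in range(spec.n_per_group[group]):
            rng = _substream(spec.seed, group, i)
            params = sample_subject(config, rng)
            tl = construct_timeline(
                params, rng, subject_id=f"{group}_{i:05d}", group_label=group
            )
            rows.append(compute_tsp(tl).as_dict())
            index.append(tl.subject_id)
            groups.append(group)
            if timelines is not None:
                timelines.append(tl)
    table = pd.DataFrame(rows, index=pd.Index(index, name="subject_id"),
                         columns=list(TSP_COLUMNS))
    table["group"] = groups
    return timelines, table


def default_configs() -> dict[str, GroupGeneratorConfig]:
    """Configs calibrated to a published 31-control / 34-AUD comparison.

    Free-parameter targets (mean, SD) per group; truncation bounds keep the
    draws physiologically plausible (utterance length 15–300 s of monologue,
    articulation tempo 8–22 phone/s for adult speech, rates positive).
    """

    def cfg(length, at, r_sil, r_fil, m_sil, m_fil):
        return GroupGeneratorConfig(
            utterance_length=NormalSpec(*length, lower=15.0, upper=300.0),
            articulation_tempo=NormalSpec(*at, lower=8.0, upper=22.0),
            silent_rate=NormalSpec(*r_sil, lower=0.05, upper=r_sil[0] + 8 * r_sil[1]),
            filled_rate=NormalSpec(*r_fil, lower=0.05, upper=r_fil[0] + 8 * r_fil[1]),
            silent_duration=LogNormalSpec(*m_sil),
            filled_duration=LogNormalSpec(*m_fil),
        )

    return {
        "control": cfg(
            length=(84.052, 34.760),
            at=(14.743, 1.544),
            r_sil=(4.850, 1.628),
            r_fil=(1.512, 0.897),
            m_sil=(0.641, 0.155),
            m_fil=(0.243, 0.078),
        ),
        "aud": cfg(
            length=(77.569, 44.481),
            at=(14.551, 1.186),
            r_sil=(5.243, 1.907),
            r_fil=(2.831, 1.695),
            m_sil=(0.983, 0.488),
            m_fil=(0.246, 0.090),
        ),
    }


def default_cohort_spec(
    n_control: int = 31, n_aud: int = 34, seed: int = 0
) -> CohortSpec:
    """The published group sizes (31 control, 34 AUD) with default configs."""
    return CohortSpec(
        n_per_group={"control": n_control, "aud": n_aud},
        configs=default_configs(),
        seed=seed,
    )
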