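"""Event-duration models, negative-event generation, and excerpting.

The negative ("other") class can be built in two modes:

* **fixed** — events of exactly 50 ms and 150 ms, the conventional design in
  which the negative class has a duration signature of its own;
* **variable** — event durations drawn from truncated Burr Type XII models
  fitted to the annotated crackle and wheeze duration distributions, so the
  negatives are duration-matched to the positives and classifiers cannot
  lean on duration as a shortcut.

The Burr Type XII density with shape parameters ``c``, ``k`` and scale
``alpha`` is

    f(x) = (k*c/alpha) * (x/alpha)**(c-1) / (1 + (x/alpha)**c)**(k+1)

with CDF ``F(x) = 1 - (1 + (x/alpha)**c)**(-k)``; sampling uses the closed
form inverse CDF restricted to the truncation interval, equivalent in
distribution to rejecting out-of-range draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import GenerationError, ValidationError
from .io_rsd import AnnotatedEvent, AudioRecording, event_to_samples


@dataclass(frozen=True)
class BurrParams:
    """Truncated Burr Type XII duration model (seconds)."""

    alpha: float  # scale, s
    c: float  # first shape
    k: float  # second shape
    lower: float = 0.0  # truncation floor, s
    upper: float = np.inf  # truncation ceiling, s

    def __post_init__(self) -> None:
        if min(self.alpha, self.c, self.k) <= 0:
            raise ValidationError("Burr parameters alpha, c, k must all be > 0")
        if not (0 <= self.lower < self.upper):
            raise ValidationError("need 0 <= lower < upper")

    @property
    def frozen(self):
        return stats.burr12(c=self.c, d=self.k, scale=self.alpha)


#: Model for negatives shorter than 100 ms, fitted to annotated crackle durations.
OTHER_CRACKLE_BURR = BurrParams(alpha=0.199, c=7.6698, k=0.3146, lower=0.0, upper=0.1)
#: Model for negatives longer than 100 ms, fitted to annotated wheeze durations.
OTHER_WHEEZE_BURR = BurrParams(alpha=0.2266, c=4.1906, k=0.3029, lower=0.1, upper=2.0)


def burr_pdf(x, p: BurrParams):
    """Burr XII density; defined on x > 0 (0 elsewhere), ignoring truncation."""
    x = np.asarray(x, dtype=np.float64)
    if np.any(x <= 0):
        raise ValidationError("burr_pdf requires x > 0")
    return p.frozen.pdf(x)


def burr_cdf(x, p: BurrParams):
    x = np.asarray(x, dtype=np.float64)
    return p.frozen.cdf(np.maximum(x, 0.0))


def burr_ppf(q, p: BurrParams):
    return p.frozen.ppf(q)


def burr_mode(p: BurrParams) -> float:
    """Closed-form mode of the (untruncated) Burr XII density."""
    if p.c <= 1:
        return 0.0
    return p.alpha * ((p.c - 1) / (p.k * p.c + 1)) ** (1 / p.c)


def sample_durations(p: BurrParams, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` durations from the truncated Burr model.

    Implemented as inverse-CDF sampling restricted to the truncation
    interval: a uniform draw on ``(F(lower), F(upper)]`` is passed through
    the quantile function, which matches the distribution of rejecting
    out-of-range draws while using exactly ``n`` uniforms.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    lo = float(p.frozen.cdf(p.lower))
    hi = float(p.frozen.cdf(p.upper)) if np.isfinite(p.upper) else 1.0
    if hi - lo < 1e-6:
        raise GenerationError(
            f"truncation window [{p.lower}, {p.upper}] keeps probability "
            f"{hi - lo:.2e} < 1e-6"
        )
    if n == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    u = lo + (hi - lo) * rng.uniform(size=n)
    x = p.frozen.ppf(u)
    # guard against floating point landing exactly on the open lower bound
    return np.clip(x, np.nextafter(p.lower, np.inf), p.upper)


def derive_seed(master_seed: int, *tokens: str) -> int:
    """Stable per-file seed below 2**31 derived from a master seed and identifiers."""
    payload = (":".join([str(master_seed), *tokens])).encode()
    return zlib.crc32(payload) % (2**31)


def _place_events(
    rec: AudioRecording,
    durations_labels: list[tuple[float, str]],
    forbidden: list[tuple[float, float]],
    rng: np.random.Generator,
    avoid_overlap: bool,
    max_tries: int = 1000,
) -> list[AnnotatedEvent]:
    """Place events uniformly at random, optionally avoiding given intervals."""
    total = rec.duration
    out: list[AnnotatedEvent] = []
    for dur, label in durations_labels:
        if dur >= total:
            raise GenerationError(
                f"recording {rec.recording_id!r} ({total:.2f}s) shorter than event ({dur:.3f}s)"
            )
        placed = False
        for _ in range(max_tries):
            start = rng.uniform(0.0, total - dur)
            end = start + dur
            if avoid_overlap and any(start < b and a < end for a, b in forbidden):
                continue
            out.append(AnnotatedEvent(start, end, label))
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place a {dur:.3f}s event in {rec.recording_id!r} "
                f"after {max_tries} tries"
            )
    return out


FIXED_LABELS = {0.050: "other50", 0.150: "other150"}


def generate_fixed_rge(
    rec: AudioRecording,
    ars: list[AnnotatedEvent],
    counts: dict[float, int],
    seed: int,
    avoid_ars: bool = True,
) -> list[AnnotatedEvent]:
    """Generate fixed-duration negative events (50 ms / 150 ms).

    The effective seed is derived from ``(seed, rec.recording_id)`` so each
    file gets its own predetermined random stream.  By default the generated
    events may not overlap the annotated adventitious events.
    """
    jobs: list[tuple[float, str]] = []
    for dur in sorted(counts):
        key = round(dur, 3)
        if key not in FIXED_LABELS:
            raise ValidationError(f"fixed mode supports durations {sorted(FIXED_LABELS)}, got {dur}")
        if counts[dur] < 0:
            raise ValidationError("counts must be >= 0")
        jobs.extend([(float(key), FIXED_LABELS[key])] * counts[dur])
    rng = np.random.default_rng(derive_seed(seed, rec.recording_id, "fixed"))
    forbidden = [(e.start, e.end) for e in ars]
    return _place_events(rec, jobs, forbidden, rng, avoid_ars)


def generate_variable_rge(
    rec: AudioRecording,
    ars: list[AnnotatedEvent],
    n_crackle_like: int,
    n_wheeze_like: int,
    models: tuple[BurrParams, BurrParams] = (OTHER_CRACKLE_BURR, OTHER_WHEEZE_BURR),
    seed: int = 0,
    avoid_ars: bool = True,
) -> list[AnnotatedEvent]:
    """Generate Burr variable-duration negatives (otherCrackle / otherWheeze)."""
    if min(n_crackle_like, n_wheeze_like) < 0:
        raise ValidationError("counts must be >= 0")
    file_seed = derive_seed(seed, rec.recording_id, "variable")
    dur_c = sample_durations(models[0], n_crackle_like, derive_seed(file_seed, "c"))
    dur_w = sample_durations(models[1], n_wheeze_like, derive_seed(file_seed, "w"))
    jobs = [(float(d), "otherCrackle") for d in dur_c] + [
        (float(d), "otherWheeze") for d in dur_w
    ]
    rng = np.random.default_rng(file_seed)
    forbidden = [(e.start, e.end) for e in ars]
    return _place_events(rec, jobs, forbidden, rng, avoid_ars)


@dataclass(frozen=True)
class ExcerptPolicy:
    """Fixed-length excerpt policy: pad short events, truncate overlong ones.

    ``max_len`` is the event-length ceiling in seconds (default 2 s, the
    median-plus-two-standard-deviations of annotated wheeze durations).
    Shorter events are centered and zero-padded; longer events keep only
    their first ``max_len`` seconds.
    """

    max_len: float = 2.0

    def __post_init__(self) -> None:
        if self.max_len <= 0:
            raise ValidationError("max_len must be > 0")


def excerpt_event(
    rec: AudioRecording, ev: AnnotatedEvent, policy: ExcerptPolicy = ExcerptPolicy()
) -> np.ndarray:
    """Extract a fixed-length waveform excerpt for one annotated event.

    The output always has exactly ``round(policy.max_len * rate)`` samples.
    Zero padding is symmetric, with the extra sample on the right when the
    pad is odd; truncation keeps the first ``max_len`` seconds.
    """
    n_out = int(round(policy.max_len * rec.rate))
    i0, i1 = event_to_samples(ev, rec.rate)
    if i0 < 0 or ev.end > rec.duration + 0.5 / rec.rate:
        raise ValidationError(
            f"event [{ev.start}, {ev.end}) outside recording of {rec.duration:.3f}s"
        )
    i1 = min(i1, rec.samples.size)
    seg = rec.samples[i0:i1]
    if seg.size >= n_out:
        return seg[:n_out].copy()
    left = (n_out - seg.size) // 2
    out = np.zeros(n_out)
    out[left : left + seg.size] = seg
    return out


def event_counts(events: list[AnnotatedEvent]) -> dict[str, int]:
    """Per-label bookkeeping of an event list (logged for every generated set)."""
    counts: dict[str, int] = {}
    for ev in events:
        counts[ev.label] = counts.get(ev.label, 0) + 1
    return counts


__all__ = [
    "BurrParams",
    "OTHER_CRACKLE_BURR",
    "OTHER_WHEEZE_BURR",
    "burr_pdf",
    "burr_cdf",
    "burr_ppf",
    "burr_mode",
    "sample_durations",
    "derive_seed",
    "generate_fixed_rge",
    "generate_variable_rge",
    "ExcerptPolicy",
    "excerpt_event",
    "event_counts",
]
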