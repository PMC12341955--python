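"""Temperature zeitgeber schedules.

A :class:`TemperaturePattern` is a square wave: warm at ``mean + amplitude/2``
for the first ``warm_fraction`` of each cycle and cold at ``mean -
amplitude/2`` for the rest ("normal" orientation), or the 12 h-translated
inverse ("reversed").  All intervals are left-closed/right-open.  A
:class:`Schedule` is a contiguous sequence of segments, each holding one
pattern (or a constant temperature, which is simply a zero-amplitude pattern);
segment boundaries fall on pattern-cycle boundaries so that alternating shift
schedules swap whole days while keeping the global 24 h grid.

Zeitgeber time (ZT) is global simulation time modulo the pattern period, with
ZT0 at t = 0.  Shift-work-style alternating schedules are written with the
``"N-n1:n2"`` grammar: a repeating N-day unit spending ``n1:n2`` of its days
in the reversed and then the normal pattern (R:N order).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ScheduleError

__all__ = [
    "TemperaturePattern",
    "Segment",
    "Schedule",
    "parse_ass",
    "ass_protocol",
    "validation_protocol",
]


@dataclass(frozen=True)
class TemperaturePattern:
    """Square-wave temperature pattern.

    ``amplitude`` is peak-to-trough (degC); the warm plateau sits at
    ``mean + amplitude/2``.  ``reversed_`` flips warm and cold halves, which
    for ``warm_fraction = 0.5`` equals a half-period translation.
    """

    mean: float = 37.0
    amplitude: float = 3.0
    period: float = 24.0
    warm_fraction: float = 0.5
    reversed_: bool = False

    def __post_init__(self):
        if self.amplitude < 0:
            raise ScheduleError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.period <= 0:
            raise ScheduleError(f"period must be > 0, got {self.period}")
        if not 0 < self.warm_fraction < 1:
            raise ScheduleError(
                f"warm_fraction must lie in (0, 1), got {self.warm_fraction}")

    @property
    def t_warm(self) -> float:
        return self.mean + self.amplitude / 2.0

    @property
    def t_cold(self) -> float:
        return self.mean - self.amplitude / 2.0

    def warm_onset(self) -> float:
        """ZT of the warm-phase onset (0 for normal, cold span for reversed)."""
        return 0.0 if not self.reversed_ else (1.0 - self.warm_fraction) * self.period

    def cold_onset(self) -> float:
        return self.warm_fraction * self.period if not self.reversed_ else 0.0

    def temperature(self, t: float) -> float:
        zt = t % self.period
        warm = zt < self.warm_fraction * self.period
        if self.reversed_:
            warm = not warm
        return self.t_warm if warm else self.t_cold

    def edges(self, t0: float, t1: float) -> np.ndarray:
        """Warm/cold switch times in [t0, t1] (empty for a constant pattern)."""
        if self.amplitude == 0:
            return np.empty(0)
        half = self.warm_fraction * self.period
        out = []
        k0 = int(np.floor(t0 / self.period)) - 1
        k1 = int(np.ceil(t1 / self.period)) + 1
        for k in range(k0, k1 + 1):
            for e in (k * self.period, k * self.period + half):
                if t0 <= e <= t1:
                    out.append(e)
        return np.array(sorted(out))

    def reversed_copy(self) -> "TemperaturePattern":
        return replace(self, reversed_=not self.reversed_)


def constant_pattern(temperature: float) -> TemperaturePattern:
    return TemperaturePattern(mean=temperature, amplitude=0.0)


@dataclass(frozen=True)
class Segment:
    start_h: float
    end_h: float
    pattern: TemperaturePattern

    def __post_init__(self):
        if self.end_h <= self.start_h:
            raise ScheduleError(
                f"segment [{self.start_h}, {self.end_h}) has non-positive length")


class Schedule:
    """Contiguous sequence of temperature-pattern segments on [t0, t_end)."""

    def __init__(self, segments: Sequence[Segment]):
        if not segments:
            raise ScheduleError("schedule needs at least one segment")
        segments = sorted(segments, key=lambda s: s.start_h)
        for a, b in zip(segments[:-1], segments[1:]):
            if abs(a.end_h - b.start_h) > 1e-9:
                raise ScheduleError(
                    f"segments not contiguous at t = {a.end_h} h vs {b.start_h} h")
        self.segments = tuple(segments)

    # -- constructors ------------------------------------------------------
    @classmethod
    def constant(cls, temperature: float, t_end: float, t_start: float = 0.0):
        return cls([Segment(t_start, t_end, constant_pattern(temperature))])

    @classmethod
    def rhythmic(cls, pattern: TemperaturePattern = TemperaturePattern(),
                 t_end: float = 1200.0, t_start: float = 0.0):
        return cls([Segment(t_start, t_end, pattern)])

    @classmethod
    def from_blocks(cls, blocks) -> "Schedule":
        """Build from ``(start_day, days, pattern_or_temperature)`` triples."""
        segs = []
        for start_day, days, pat in blocks:
            if not isinstance(pat, TemperaturePattern):
                pat = constant_pattern(float(pat))
            segs.append(Segment(start_day * 24.0, (start_day + days) * 24.0, pat))
        return cls(segs)

    # -- domain ------------------------------------------------------------
    @property
    def t_start(self) -> float:
        return self.segments[0].start_h

    @property
    def t_end(self) -> float:
        return self.segments[-1].end_h

    def segment_at(self, t: float) -> Segment:
        if not (self.t_start <= t < self.t_end or np.isclose(t, self.t_start)):
            raise ScheduleError(
                f"t = {t} h outside schedule domain [{self.t_start}, {self.t_end})")
        for seg in self.segments:
            if seg.start_h <= t < seg.end_h:
                return seg
        return self.segments[-1]

    def temperature_at(self, t: float) -> tuple[float, float]:
        """Return ``(T, Tavg)`` at time ``t``: the square-wave value of the
        active segment and the active pattern's cycle mean."""
        seg = self.segment_at(t)
        pat = seg.pattern
        tavg = pat.mean if pat.warm_fraction == 0.5 else (
            pat.warm_fraction * pat.t_warm + (1 - pat.warm_fraction) * pat.t_cold)
        return pat.temperature(t), tavg

    def discontinuities(self, t_span: tuple[float, float] | None = None) -> np.ndarray:
        """Sorted, deduplicated switch times (warm/cold edges and segment
        boundaries) in ``(t_span[0], t_span[1]]``."""
        a, b = t_span if t_span is not None else (self.t_start, self.t_end)
        pts: list[float] = []
        for seg in self.segments:
            lo, hi = max(a, seg.start_h), min(b, seg.end_h)
            if hi <= lo:
                continue
            pts.extend(seg.pattern.edges(lo, hi))
            # interior segment boundaries are switches; the schedule's own
            # start/end are not
            for edge in (seg.start_h, seg.end_h):
                if self.t_start < edge < self.t_end:
                    pts.append(edge)
        pts = [t for t in pts if a < t <= b]
        return np.unique(np.round(np.array(sorted(pts)), 9))

    def piecewise(self, t_span: tuple[float, float]) -> list[tuple[float, float, float, float]]:
        """Maximal constant-temperature pieces ``(a, b, T, Tavg)`` covering
        ``t_span`` — the integration plan for the square wave."""
        a, b = t_span
        if not (self.t_start <= a < b <= self.t_end + 1e-9):
            raise ScheduleError(
                f"t_span {t_span} outside schedule domain "
                f"[{self.t_start}, {self.t_end}]")
        inner = self.discontinuities((a, b))
        inner = inner[inner < b - 1e-9]
        cuts = np.concatenate([[a], inner, [b]])
        out = []
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            T, tavg = self.temperature_at(0.5 * (lo + hi))
            out.append((float(lo), float(hi), T, tavg))
        return out

    def warm_onsets(self, t_span: tuple[float, float],
                    reference: str = "warm") -> np.ndarray:
        """Times of warm-phase (or ``reference="cold"``: cold-phase) onsets of
        the active patterns within ``t_span``.  Used as the phase reference."""
        a, b = t_span
        out = []
        for seg in self.segments:
            lo, hi = max(a, seg.start_h), min(b, seg.end_h)
            if hi <= lo:
                continue
            pat = seg.pattern
            onset = pat.warm_onset() if reference == "warm" else pat.cold_onset()
            k0 = int(np.floor((lo - onset) / pat.period))
            for k in range(k0, int(np.ceil(hi / pat.period)) + 1):
                t = onset + k * pat.period
                if lo <= t < hi:
                    out.append(t)
        return np.unique(np.round(np.array(sorted(out)), 9))

    # -- serialization -----------------------------------------------------
    def to_list(self) -> list[dict]:
        out = []
        for seg in self.segments:
            pat = seg.pattern
            d = {"start_day": seg.start_h / 24.0,
                 "days": (seg.end_h - seg.start_h) / 24.0}
            if pat.amplitude == 0:
                d["constant"] = pat.mean
            else:
                d["pattern"] = {
                    "mean": pat.mean, "amplitude": pat.amplitude,
                    "period": pat.period, "warm_fraction": pat.warm_fraction,
                    "orientation": "reversed" if pat.reversed_ else "normal",
                }
            out.append(d)
        return out

    @classmethod
    def from_list(cls, items: Sequence[dict]) -> "Schedule":
        segs = []
        for d in items:
            start = float(d["start_day"]) * 24.0
            end = start + float(d["days"]) * 24.0
            if "constant" in d:
                pat = constant_pattern(float(d["constant"]))
            else:
                p = dict(d["pattern"])
                pat = TemperaturePattern(
                    mean=float(p.get("mean", 37.0)),
                    amplitude=float(p.get("amplitude", 3.0)),
                    period=float(p.get("period", 24.0)),
                    warm_fraction=float(p.get("warm_fraction", 0.5)),
                    reversed_=p.get("orientation", "normal") == "reversed",
                )
            segs.append(Segment(start, end, pat))
        return cls(segs)

    def __repr__(self):
        return f"Schedule({len(self.segments)} segments, [{self.t_start}, {self.t_end}) h)"


_ASS_RE = re.compile(r"^(\d+)-(\d+):(\d+)$")


def parse_ass(spec: str, total_days: float, *,
              pattern: TemperaturePattern = TemperaturePattern(),
              reversed_pattern: TemperaturePattern | None = None,
              start_day: float = 0.0, r_first: bool = True) -> Schedule:
    """Build an alternating shift schedule from an ``"N-n1:n2"`` string.

    The non-repeating unit spans N days: ``n1/(n1+n2)`` of it in the reversed
    pattern then the rest in the normal pattern (R:N order; ``r_first=False``
    swaps).  ``n1:n2`` is scaled so block lengths sum to N whole days
    (``"28-5:2"`` -> 20 d reversed + 8 d normal).  ``reversed_pattern`` lets
    the reversed block use a different amplitude.
    """
    m = _ASS_RE.match(spec.strip())
    if not m:
        raise ScheduleError(f"cannot parse ASS spec {spec!r}; expected 'N-n1:n2'")
    N, n1, n2 = (int(g) for g in m.groups())
    if n1 <= 0 or n2 <= 0:
        raise ScheduleError(f"{spec!r}: zero-length block")
    d1 = N * n1 / (n1 + n2)
    if abs(d1 - round(d1)) > 1e-9:
        raise ScheduleError(
            f"{spec!r}: day split {N}*{n1}/{n1 + n2} is not a whole number of days")
    d1 = int(round(d1))
    d2 = N - d1
    if d1 == 0 or d2 == 0:
        raise ScheduleError(f"{spec!r}: zero-length block after scaling")
    rev = reversed_pattern if reversed_pattern is not None else pattern.reversed_copy()
    if not rev.reversed_:
        rev = rev.reversed_copy()
    first, fdays, second, sdays = (rev, d1, pattern, d2) if r_first else \
        (pattern, d2, rev, d1)
    blocks = []
    day = start_day
    n_units = int(np.ceil(total_days / N))
    for _ in range(n_units):
        blocks.append((day, fdays, first))
        blocks.append((day + fdays, sdays, second))
        day += N
    sched = Schedule.from_blocks(blocks)
    # trim to the requested horizon
    segs = [s for s in sched.segments if s.start_h < (start_day + total_days) * 24.0]
    last = segs[-1]
    if last.end_h > (start_day + total_days) * 24.0:
        segs[-1] = Segment(last.start_h, (start_day + total_days) * 24.0, last.pattern)
    return Schedule(segs)


def ass_protocol(spec: str, *, pre_days: float = 50.0, post_days: float = 100.0,
                 pattern: TemperaturePattern = TemperaturePattern(),
                 reversed_pattern: TemperaturePattern | None = None,
                 r_first: bool = True) -> Schedule:
    """Shift-work protocol: normal pattern for ``pre_days``, then the
    alternating schedule ``spec`` for ``post_days``."""
    pre = Segment(0.0, pre_days * 24.0, pattern)
    ass = parse_ass(spec, post_days, pattern=pattern,
                    reversed_pattern=reversed_pattern, start_day=pre_days,
                    r_first=r_first)
    return Schedule([pre, *ass.segments])


def validation_protocol(*, amplitude: float = 3.0, mean: float = 37.0,
                        reversed_: bool = False, const_until_day: float = 10.0,
                        rhythmic_until_day: float = 65.0,
                        end_day: float = 90.0) -> Schedule:
    """On/off rhythm protocol: constant temperature, then a square-wave
    rhythm, then constant again (synchronize/desynchronize experiment)."""
    pat = TemperaturePattern(mean=mean, amplitude=amplitude, reversed_=reversed_)
    return Schedule.from_blocks([
        (0.0, const_until_day, mean),
        (const_until_day, rhythmic_until_day - const_until_day, pat),
        (rhythmic_until_day, end_day - rhythmic_until_day, mean),
    ])
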