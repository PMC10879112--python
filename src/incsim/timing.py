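"""Camera / SLM / LED synchronization schedules.

Ferroelectric LCOS pixels must spend equal time in each state to avoid
charge build-up, so after every pattern the display shows its inverse for
an equal duration (DC balance) and the LED must be blanked during both the
refresh gap and the inverted display.  The schedule here encodes one
camera exposure per pattern containing: normal display (LED on), refresh
gap (LED off), inverted display (LED off).

Times are integer microseconds throughout — exact comparisons, no float
timing.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "TimingEvent",
    "TimingScheme",
    "build_timing",
    "validate_timing",
    "illumination_duty",
]


@dataclass(frozen=True)
class TimingEvent:
    """One interval on one hardware channel.

    channel: 'camera' | 'slm' | 'led'; state e.g. 'expose',
    'display(3,normal)', 'display(3,inverted)', 'refresh', 'on'.
    """

    channel: str
    state: str
    t_start: int  # µs
    duration: int  # µs
    pattern: int | None = None  # pattern index when applicable

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("event duration must be positive")
        if self.channel not in ("camera", "slm", "led"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def t_end(self) -> int:
        return self.t_start + self.duration


@dataclass
class TimingScheme:
    """Time-sorted event list for one repertoire acquisition."""

    events: list[TimingEvent]
    sequence_length: int
    period: int  # µs per pattern

    def channel(self, name: str) -> list[TimingEvent]:
        return [e for e in self.events if e.channel == name]


def build_timing(
    sequence_length: int,
    exposure: int,
    display: int,
    refresh: int,
) -> TimingScheme:
    """Constructively correct schedule: one exposure per pattern.

    Within each camera exposure: normal display with LED on, a refresh
    gap, then the inverted display (same duration, LED off).  Requires
    ``exposure >= 2*display + refresh``.
    """
    if sequence_length < 1:
        raise ValueError("sequence_length must be >= 1")
    for name, v in (("exposure", exposure), ("display", display), ("refresh", refresh)):
        if v <= 0:
            raise ValueError(f"{name} must be a positive integer number of µs")
    if exposure < 2 * display + refresh:
        raise ValueError(
            f"exposure {exposure} µs too short to contain display + refresh "
            f"+ inverted display ({2 * display + refresh} µs)"
        )
    events: list[TimingEvent] = []
    for p in range(sequence_length):
        t0 = p * exposure
        events.append(TimingEvent("camera", "expose", t0, exposure, p))
        events.append(TimingEvent("slm", f"display({p},normal)", t0, display, p))
        events.append(TimingEvent("led", "on", t0, display, p))
        events.append(TimingEvent("slm", "refresh", t0 + display, refresh, p))
        events.append(
            TimingEvent("slm", f"display({p},inverted)", t0 + display + refresh,
                        display, p)
        )
    events.sort(key=lambda e: (e.t_start, e.channel))
    return TimingScheme(events=events, sequence_length=sequence_length,
                        period=exposure)


def _overlaps(a: TimingEvent, b: TimingEvent) -> bool:
    return a.t_start < b.t_end and b.t_start < a.t_end


def validate_timing(scheme: TimingScheme) -> list[str]:
    """All violations of the synchronization contract; empty iff valid.

    Checks: per-channel non-overlap; DC balance (equal normal/inverted
    display time per pattern); every LED-on interval contained in a
    normal-display interval; LED off during every refresh and inverted
    display.
    """
    violations: list[str] = []
    for channel in ("camera", "slm", "led"):
        evs = sorted(scheme.channel(channel), key=lambda e: e.t_start)
        for a, b in zip(evs, evs[1:]):
            if _overlaps(a, b):
                violations.append(
                    f"{channel}: overlapping events at t={a.t_start} and "
                    f"t={b.t_start}"
                )

    slm = scheme.channel("slm")
    normal = [e for e in slm if "normal" in e.state]
    inverted = [e for e in slm if "inverted" in e.state]
    refreshes = [e for e in slm if e.state == "refresh"]
    for p in range(scheme.sequence_length):
        tn = sum(e.duration for e in normal if e.pattern == p)
        ti = sum(e.duration for e in inverted if e.pattern == p)
        if tn != ti:
            violations.append(
                f"pattern {p}: DC balance violated (normal {tn} µs vs "
                f"inverted {ti} µs)"
            )

    for led in scheme.channel("led"):
        if not any(
            led.t_start >= n.t_start and led.t_end <= n.t_end for n in normal
        ):
            violations.append(
                f"LED on at t={led.t_start} not contained in any "
                "normal-display interval"
            )
        for r in refreshes:
            if _overlaps(led, r):
                violations.append(
                    f"LED on at t={led.t_start} overlaps SLM refresh at "
                    f"t={r.t_start}"
                )
        for inv in inverted:
            if _overlaps(led, inv):
                violations.append(
                    f"LED on at t={led.t_start} overlaps inverted display at "
                    f"t={inv.t_start}"
                )
    return violations


def illumination_duty(scheme: TimingScheme) -> float:
    """Fraction of total acquisition time with the LED on."""
    total = scheme.period * scheme.sequence_length
    on = sum(e.duration for e in scheme.channel("led"))
    return on / total if total > 0 else 0.0
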