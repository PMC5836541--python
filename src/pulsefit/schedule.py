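"""Schedule algebra for serial-dilution competitions under periodic environments.

A culture regime is a sequence of 3-h transfer slots, each spent in one of two
media (canonically "N", the permissive medium, and "S", the stress medium).
Steady regimes stay in one medium; periodic regimes alternate with a period
that is a multiple of two slots, so each half-period is a whole number of
slots.  Day ``d`` covers the half-open interval ``(0, 24*d]`` hours after the
end of the initialization growth phase.

The quantities derived here — hours of exposure to each medium, the number of
medium changes experienced, and the time fractions — are the covariates of the
inhomogeneity GLM and the weights of the time-average fitness expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field


MEDIA = ("N", "S")


@dataclass(frozen=True)
class Schedule:
    """A culture regime on the 3-h transfer grid.

    Parameters
    ----------
    condition
        Label, e.g. ``"N"``, ``"S"``, ``"NS6"``.
    period_h
        Oscillation period in hours; 0 means steady.
    steady_medium
        Medium of a steady regime (ignored for periodic ones).
    first_condition
        Medium occupied during the first half-period of a periodic regime.
    transfer_interval_h
        Slot length in hours (one generation per slot by design).
    total_h
        Regime duration after initialization.
    """

    condition: str
    period_h: int = 0
    steady_medium: str = "N"
    first_condition: str = "S"
    transfer_interval_h: int = 3
    total_h: int = 72

    def __post_init__(self) -> None:
        if self.period_h < 0:
            raise ValueError("period_h must be >= 0")
        if self.period_h and self.period_h % (2 * self.transfer_interval_h):
            raise ValueError(
                f"period {self.period_h} h is not a multiple of two "
                f"{self.transfer_interval_h}-h slots"
            )
        for m in (self.steady_medium, self.first_condition):
            if m not in MEDIA:
                raise ValueError(f"unknown medium {m!r}")

    @property
    def is_periodic(self) -> bool:
        return self.period_h > 0

    @property
    def slots_per_half_period(self) -> int:
        if not self.is_periodic:
            raise ValueError("steady schedule has no period")
        return self.period_h // (2 * self.transfer_interval_h)

    def slot_medium(self, slot: int) -> str:
        """Medium occupied during slot ``slot`` (1-based; slot k spans
        ``(3(k-1), 3k]`` hours)."""
        if slot < 1:
            raise ValueError("slots are 1-based")
        if not self.is_periodic:
            return self.steady_medium
        half = self.slots_per_half_period
        phase = ((slot - 1) // half) % 2
        if phase == 0:
            return self.first_condition
        return MEDIA[1 - MEDIA.index(self.first_condition)]

    def slot_media(self, n_slots: int) -> list[str]:
        return [self.slot_medium(k) for k in range(1, n_slots + 1)]


@dataclass(frozen=True)
class DesignRow:
    """Per condition and day: exposure times, change count, time fractions."""

    condition: str
    day: int
    t_N: float
    t_S: float
    n_changes: int
    f_N: float = field(init=False)
    f_S: float = field(init=False)

    def __post_init__(self) -> None:
        tot = self.t_N + self.t_S
        if tot <= 0:
            raise ValueError("t_N + t_S must be positive")
        object.__setattr__(self, "f_N", self.t_N / tot)
        object.__setattr__(self, "f_S", self.t_S / tot)


def design_row(schedule: Schedule, day: int) -> DesignRow:
    """Exposure times, change count and time fractions for ``day``.

    Slots ``1..8*day`` are enumerated; t_N/t_S are summed slot durations.
    A medium change is counted at the end boundary of every slot whose
    successor slot is in the other medium, i.e. at times
    ``{3k : k = 1..8d, medium(k) != medium(k+1)}`` — switches strictly inside
    ``(0, 24d]`` including the day-boundary switch itself when the regime
    flips there.
    """
    if day < 1:
        raise ValueError("day must be >= 1")
    if 24 * day > schedule.total_h:
        raise ValueError(f"day {day} exceeds schedule duration {schedule.total_h} h")
    dt = schedule.transfer_interval_h
    n_slots = 24 * day // dt
    media = schedule.slot_media(n_slots + 1)  # +1 to see the switch at 24d
    t_n = dt * sum(m == "N" for m in media[:n_slots])
    t_s = dt * sum(m == "S" for m in media[:n_slots])
    changes = sum(media[k] != media[k + 1] for k in range(n_slots))
    return DesignRow(schedule.condition, day, float(t_n), float(t_s), changes)


def design_table(schedules: list[Schedule], days: list[int]):
    """DataFrame of design rows for every schedule x day (day 0 rows are all
    zeros, anchoring the GLM offsets)."""
    import pandas as pd

    rows = []
    for sch in schedules:
        for d in days:
            if d == 0:
                rows.append(
                    dict(condition=sch.condition, day=0, t_N=0.0, t_S=0.0,
                         n_changes=0, f_N=0.0, f_S=0.0)
                )
            else:
                r = design_row(sch, d)
                rows.append(
                    dict(condition=r.condition, day=r.day, t_N=r.t_N, t_S=r.t_S,
                         n_changes=r.n_changes, f_N=r.f_N, f_S=r.f_S)
                )
    return pd.DataFrame(rows)


def standard_schedules(
    periods: tuple[int, ...] = (6, 12, 18, 24, 42),
    first_condition: str = "S",
    total_h: int = 72,
) -> list[Schedule]:
    """The canonical condition set: steady N, steady S, and one alternating
    regime per period (labelled NS6, NS12, ...)."""
    out = [
        Schedule("N", 0, steady_medium="N", total_h=total_h),
        Schedule("S", 0, steady_medium="S", total_h=total_h),
    ]
    for p in periods:
        out.append(
            Schedule(f"NS{p}", p, first_condition=first_condition, total_h=total_h)
        )
    return out
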