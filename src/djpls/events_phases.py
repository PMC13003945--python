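"""Ground-contact event detection and eccentric/concentric phase segmentation.

Contact and take-off are found by threshold crossings (default 20 N) of the
summed vertical ground reaction force; the eccentric/concentric split is at
the minimum vertical position of the whole-body centre of mass during ground
contact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .signal_processing import SampledSignal

__all__ = ["TrialEvents", "IncompleteTrialError", "detect_contact_takeoff", "segment_phases"]

DEFAULT_FORCE_THRESHOLD_N = 20.0
#: crossings must persist this long to count (spike rejection)
MIN_DWELL_S = 0.005


class IncompleteTrialError(ValueError):
    """Raised when a required force-plate event cannot be located."""


@dataclass
class TrialEvents:
    """Key instants of one drop jump, in seconds on the force timebase."""

    t_contact: float
    t_takeoff: float
    t_landing: float
    t_com_min: float | None = None

    @property
    def contact_time(self) -> float:
        return self.t_takeoff - self.t_contact

    @property
    def flight_time(self) -> float:
        return self.t_landing - self.t_takeoff

    @property
    def ecc_duration(self) -> float:
        self._require_com_min()
        return self.t_com_min - self.t_contact

    @property
    def con_duration(self) -> float:
        self._require_com_min()
        return self.t_takeoff - self.t_com_min

    @property
    def ecc_interval(self) -> tuple[float, float]:
        self._require_com_min()
        return (self.t_contact, self.t_com_min)

    @property
    def con_interval(self) -> tuple[float, float]:
        self._require_com_min()
        return (self.t_com_min, self.t_takeoff)

    @property
    def contact_interval(self) -> tuple[float, float]:
        return (self.t_contact, self.t_takeoff)

    def _require_com_min(self) -> None:
        if self.t_com_min is None:
            raise ValueError("phases not yet segmented (t_com_min is unset)")

    def validate(self) -> None:
        if not self.t_contact < self.t_takeoff < self.t_landing:
            raise ValueError("event ordering violated: contact < takeoff < landing")
        if self.t_com_min is not None and not (
            self.t_contact < self.t_com_min < self.t_takeoff
        ):
            raise ValueError("event ordering violated: contact < COM-min < takeoff")

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(
            contact_time=self.contact_time,
            flight_time=self.flight_time,
        )
        if self.t_com_min is not None:
            d.update(ecc_duration=self.ecc_duration, con_duration=self.con_duration)
        return d


def _sustained_crossings(above: np.ndarray, dwell: int) -> list[tuple[int, str]]:
    """Indices where `above` flips state and holds for >= dwell samples.

    Returns a list of (index, kind) with kind "up" (first sample above) or
    "down" (first sample below).
    """
    out: list[tuple[int, str]] = []
    n = above.size
    state = bool(above[0])
    i = 1
    while i < n:
        if bool(above[i]) != state:
            run_end = i
            while run_end < n and bool(above[run_end]) != state:
                run_end += 1
            if run_end - i >= dwell or run_end == n:
                out.append((i, "up" if not state else "down"))
                state = not state
            i = run_end
        else:
            i += 1
    return out


def detect_contact_takeoff(
    fz_total: SampledSignal,
    threshold_n: float = DEFAULT_FORCE_THRESHOLD_N,
) -> tuple[float, float, float]:
    """Locate ground contact, take-off, and landing from summed vertical GRF.

    Contact is the first sustained upward crossing of ``threshold_n``,
    take-off the next sustained downward crossing, landing the following
    upward crossing.  Crossings must persist for at least 5 ms.

    Raises
    ------
    IncompleteTrialError
        If any of the three events is missing, naming the missing event.
    """
    if threshold_n <= 0:
        raise ValueError("threshold must be positive")
    fz = np.asarray(fz_total.values, dtype=float)
    if fz.ndim != 1:
        raise ValueError("fz_total must be a single summed channel")
    dwell = max(int(round(MIN_DWELL_S * fz_total.rate_hz)), 1)
    crossings = _sustained_crossings(fz >= threshold_n, dwell)
    if fz[0] >= threshold_n:
        # skip any initial stance (e.g. on an instrumented box): first event
        # of interest is an upward crossing after force has dropped away.
        crossings = [c for i, c in enumerate(crossings) if c[1] == "up" or i > 0]
    ups = [i for i, kind in crossings if kind == "up"]
    downs = [i for i, kind in crossings if kind == "down"]
    if not ups:
        raise IncompleteTrialError("incomplete trial: no ground contact found")
    i_contact = ups[0]
    later_downs = [i for i in downs if i > i_contact]
    if not later_downs:
        raise IncompleteTrialError("incomplete trial: no take-off found")
    i_takeoff = later_downs[0]
    later_ups = [i for i in ups if i > i_takeoff]
    if not later_ups:
        raise IncompleteTrialError("incomplete trial: no landing found")
    i_landing = later_ups[0]
    t = fz_total.times
    return float(t[i_contact]), float(t[i_takeoff]), float(t[i_landing])


def segment_phases(com_z: SampledSignal, events: TrialEvents) -> TrialEvents:
    """Split ground contact at the minimum vertical COM position.

    The eccentric phase runs from contact to the COM minimum, the concentric
    phase from the minimum to take-off.  Ties are broken to the earliest
    sample; a boundary minimum (monotone COM over contact) is accepted with
    a warning.
    """
    i0 = com_z.index_at(events.t_contact)
    i1 = com_z.index_at(events.t_takeoff)
    if i1 <= i0:
        raise ValueError("com_z does not cover the contact interval")
    window = np.asarray(com_z.values[i0 : i1 + 1], dtype=float)
    i_min = int(np.argmin(window))  # argmin takes the earliest tie
    if i_min == 0 or i_min == window.size - 1:
        warnings.warn(
            "COM minimum falls on a contact boundary (monotone COM during "
            "contact); accepting boundary minimum",
            RuntimeWarning,
        )
    events.t_com_min = float(com_z.times[i0 + i_min])
    return events
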