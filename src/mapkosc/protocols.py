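"""EGF stimulation protocols: sustained doses, pulses, washout, inhibitors.

A protocol is a list of non-overlapping dose segments; the dose is zero
outside all segments (washout removes free ligand instantaneously).
An EGFR-kinase inhibitor event (gefitinib-like) zeroes the activation
gain from its onset onward; already-active receptors decay at their
normal rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["DoseSegment", "InhibitorEvent", "StimulationProtocol"]


@dataclass(frozen=True)
class DoseSegment:
    t_start: float
    t_end: float
    dose: float  # pg/ml

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("segment must have t_end > t_start")
        if self.dose < 0:
            raise ValueError("dose must be nonnegative")


@dataclass(frozen=True)
class InhibitorEvent:
    time: float
    target: str = "EGFR"

    def __post_init__(self) -> None:
        if self.target != "EGFR":
            raise ValueError(f"unsupported inhibitor target {self.target!r}")


@dataclass(frozen=True)
class StimulationProtocol:
    segments: tuple[DoseSegment, ...] = ()
    inhibitors: tuple[InhibitorEvent, ...] = ()

    def __post_init__(self) -> None:
        segs = tuple(sorted(self.segments, key=lambda s: s.t_start))
        for a, b in zip(segs[:-1], segs[1:]):
            if b.t_start < a.t_end:
                raise ValueError("dose segments overlap")
        object.__setattr__(self, "segments", segs)
        object.__setattr__(
            self, "inhibitors",
            tuple(sorted(self.inhibitors, key=lambda e: e.time)),
        )

    # -- constructors ------------------------------------------------

    @classmethod
    def sustained(cls, dose: float, t_end: float = math.inf
                  ) -> "StimulationProtocol":
        return cls(segments=(DoseSegment(0.0, t_end, dose),))

    @classmethod
    def pulse(cls, dose: float, duration: float, t_start: float = 0.0
              ) -> "StimulationProtocol":
        """Single pulse followed by washout (free ligand removed)."""
        return cls(segments=(DoseSegment(t_start, t_start + duration, dose),))

    def with_inhibitor(self, time: float) -> "StimulationProtocol":
        return StimulationProtocol(
            segments=self.segments,
            inhibitors=self.inhibitors + (InhibitorEvent(time),),
        )

    # -- evaluation --------------------------------------------------

    def dose_at(self, t: float) -> float:
        """Effective activating dose at time ``t`` (0 once inhibited)."""
        for ev in self.inhibitors:
            if t >= ev.time:
                return 0.0
        for seg in self.segments:
            if seg.t_start <= t < seg.t_end:
                return seg.dose
        return 0.0

    def breakpoints(self, t_end: float) -> list[float]:
        """Times at which the dose is discontinuous, within [0, t_end]."""
        pts = {0.0, t_end}
        for seg in self.segments:
            for t in (seg.t_start, seg.t_end):
                if 0.0 < t < t_end:
                    pts.add(t)
        for ev in self.inhibitors:
            if 0.0 < ev.time < t_end:
                pts.add(ev.time)
        return sorted(pts)

    # -- (de)serialization -------------------------------------------

    def to_dict(self) -> dict:
        return {
            "segments": [
                {"t_start": s.t_start, "t_end": s.t_end, "dose": s.dose}
                for s in self.segments
            ],
            "inhibitors": [
                {"time": e.time, "target": e.target} for e in self.inhibitors
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationProtocol":
        unknown = set(d) - {"segments", "inhibitors"}
        if unknown:
            raise ValueError(f"unknown protocol keys: {sorted(unknown)}")

        def seg(s: dict) -> DoseSegment:
            t_end = s["t_end"]
            if isinstance(t_end, str) and t_end.lower() in ("inf", ".inf"):
                t_end = math.inf
            return DoseSegment(float(s["t_start"]), float(t_end),
                               float(s["dose"]))

        return cls(
            segments=tuple(seg(s) for s in d.get("segments", ())),
            inhibitors=tuple(
                InhibitorEvent(float(e["time"]), e.get("target", "EGFR"))
                for e in d.get("inhibitors", ())
            ),
        )
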