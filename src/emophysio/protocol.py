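"""Experimental protocol timeline.

The affective-stimulation protocol presents three randomized phases (images,
sounds, images+sounds) separated by rest. Each phase contains four 90-second
sessions of strictly increasing arousal (A1..A4); each session holds six
15-second stimuli, the first half at low valence and the second half at high
valence. Crossing the two extreme arousal sessions (A1, A4) with the two
valence halves yields the four emotion classes of Russell's circumplex
(quadrants); the intermediate sessions A2/A3 carry no class label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "Phase",
    "Session",
    "ValenceHalf",
    "Quadrant",
    "StimulusWindow",
    "ProtocolTimeline",
    "build_timeline",
    "quadrant_of",
    "analysis_windows",
]

SESSION_S = 90.0
STIMULUS_S = 15.0
STIMULI_PER_SESSION = 6
WINDOW_S = 45.0  # one valence half: 3 stimuli x 15 s


class Phase(str, Enum):
    IMAGES = "IMAGES"
    SOUNDS = "SOUNDS"
    COMBINED = "COMBINED"


class Session(str, Enum):
    A1 = "A1"
    A2 = "A2"
    A3 = "A3"
    A4 = "A4"


class ValenceHalf(str, Enum):
    LOW = "LOW"
    HIGH = "HIGH"


class Quadrant(str, Enum):
    A1_LV = "A1_LV"  # sadness / depression
    A1_HV = "A1_HV"  # relaxation / pleasure
    A4_LV = "A4_LV"  # fear / anger
    A4_HV = "A4_HV"  # happiness / amusement
    NONE = "NONE"


def quadrant_of(session: Session, valence_half: ValenceHalf) -> Quadrant:
    """Map an (arousal session, valence half) cell to its circumplex quadrant.

    Only the extreme arousal sessions A1 and A4 define emotion classes; the
    middle sessions of increasing arousal (A2, A3) return ``Quadrant.NONE``.
    """
    session = Session(session)
    valence_half = ValenceHalf(valence_half)
    if session in (Session.A2, Session.A3):
        return Quadrant.NONE
    key = (session, valence_half)
    return {
        (Session.A1, ValenceHalf.LOW): Quadrant.A1_LV,
        (Session.A1, ValenceHalf.HIGH): Quadrant.A1_HV,
        (Session.A4, ValenceHalf.LOW): Quadrant.A4_LV,
        (Session.A4, ValenceHalf.HIGH): Quadrant.A4_HV,
    }[key]


@dataclass(frozen=True)
class StimulusWindow:
    """One valence half of one session: the 45 s analysis unit.

    Times are seconds from phase start, half-open interval [t_start, t_end).
    """

    phase: Phase
    session: Session
    valence_half: ValenceHalf
    t_start: float
    t_end: float
    quadrant: Quadrant

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class ProtocolTimeline:
    """Full per-subject schedule: phase order plus the 24 stimulus windows."""

    subject_id: str
    phase_order: tuple[Phase, Phase, Phase]
    rest_pre_phase: float = 300.0
    inter_phase_rest: float = 120.0
    inter_session_gap: float = 0.0
    windows: list[StimulusWindow] = field(default_factory=list)

    @property
    def phase_duration(self) -> float:
        """Length of one phase in seconds (rest + 4 sessions + gaps)."""
        return self.rest_pre_phase + 4 * SESSION_S + 3 * self.inter_session_gap

    def session_start(self, session: Session) -> float:
        i = list(Session).index(Session(session))
        return self.rest_pre_phase + i * (SESSION_S + self.inter_session_gap)

    def windows_of_phase(self, phase: Phase) -> list[StimulusWindow]:
        return [w for w in self.windows if w.phase == Phase(phase)]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subject_id": self.subject_id,
            "phase_order": [p.value for p in self.phase_order],
            "rest_pre_phase": self.rest_pre_phase,
            "inter_phase_rest": self.inter_phase_rest,
            "inter_session_gap": self.inter_session_gap,
            "windows": [
                {k: (v.value if isinstance(v, Enum) else v) for k, v in asdict(w).items()}
                for w in self.windows
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProtocolTimeline":
        d = json.loads(Path(path).read_text())
        tl = cls(
            subject_id=d["subject_id"],
            phase_order=tuple(Phase(p) for p in d["phase_order"]),
            rest_pre_phase=d["rest_pre_phase"],
            inter_phase_rest=d["inter_phase_rest"],
            inter_session_gap=d["inter_session_gap"],
        )
        tl.windows = [
            StimulusWindow(
                phase=Phase(w["phase"]),
                session=Session(w["session"]),
                valence_half=ValenceHalf(w["valence_half"]),
                t_start=w["t_start"],
                t_end=w["t_end"],
                quadrant=Quadrant(w["quadrant"]),
            )
            for w in d["windows"]
        ]
        return tl


def subject_seed(global_seed: int, subject_index: int) -> int:
    """Derive a stable per-subject seed from the run seed."""
    ss = np.random.SeedSequence([int(global_seed), int(subject_index)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def build_timeline(
    subject_id: str,
    seed: int,
    *,
    subject_index: int = 0,
    rest_pre_phase: float = 300.0,
    inter_phase_rest: float = 120.0,
    inter_session_gap: float = 0.0,
) -> ProtocolTimeline:
    """Build the deterministic per-subject schedule.

    Phase order is a permutation drawn from a per-subject RNG derived from
    ``(seed, subject_index)``; the within-phase session/valence structure is
    fixed by the protocol. Identical arguments give identical timelines.
    """
    rng = np.random.default_rng(subject_seed(seed, subject_index))
    order = tuple(Phase(p) for p in rng.permutation([p.value for p in Phase]))
    tl = ProtocolTimeline(
        subject_id=subject_id,
        phase_order=order,
        rest_pre_phase=rest_pre_phase,
        inter_phase_rest=inter_phase_rest,
        inter_session_gap=inter_session_gap,
    )
    for phase in order:
        for session in Session:
            t0 = tl.session_start(session)
            for half, off in ((ValenceHalf.LOW, 0.0), (ValenceHalf.HIGH, WINDOW_S)):
                tl.windows.append(
                    StimulusWindow(
                        phase=phase,
                        session=session,
                        valence_half=half,
                        t_start=t0 + off,
                        t_end=t0 + off + WINDOW_S,
                        quadrant=quadrant_of(session, half),
                    )
                )
    return tl


def analysis_windows(timeline: ProtocolTimeline) -> list[StimulusWindow]:
    """Return the class-labeled 45 s windows (quadrant != NONE): 12 per subject."""
    return [w for w in timeline.windows if w.quadrant is not Quadrant.NONE]
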