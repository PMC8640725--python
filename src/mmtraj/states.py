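"""Five-state space for LTC-count trajectories.

Living states index the number of active long-term conditions capped at
three ("3+"); death is absorbing.  Allowed moves are a single count step up
(progressing), a single step down (resolving/remitting), or death from any
living state — ten transitions in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

S0, S1, S2, S3PLUS, DEATH = range(5)
N_STATES = 5
LIVING_STATES = (S0, S1, S2, S3PLUS)
STATE_LABELS = ("S0", "S1", "S2", "S3plus", "Death")

PROGRESSING = ((S0, S1), (S1, S2), (S2, S3PLUS))
TO_DEATH = ((S0, DEATH), (S1, DEATH), (S2, DEATH), (S3PLUS, DEATH))
RESOLVING = ((S1, S0), (S2, S1), (S3PLUS, S2))

#: Reporting order: progressing, death, then resolving/remitting columns.
TRANSITIONS: tuple[tuple[int, int], ...] = PROGRESSING + TO_DEATH + RESOLVING


def state_of_count(count: int) -> int:
    """Map an (uncapped) active-condition count to its living state."""
    if count < 0:
        raise ValueError(f"negative condition count: {count}")
    return min(count, 3)


def transition_label(trans: tuple[int, int]) -> str:
    r, s = trans
    return f"{STATE_LABELS[r]}->{STATE_LABELS[s]}"


@dataclass(frozen=True)
class TransitionStructure:
    """The set of allowed instantaneous moves on the five-state space."""

    allowed: tuple[tuple[int, int], ...] = field(default=TRANSITIONS)

    def __post_init__(self):
        for r, s in self.allowed:
            if r == DEATH:
                raise ValueError("death is absorbing; no outgoing transitions")
            if s != DEATH and abs(r - s) != 1:
                raise ValueError(f"disallowed multi-step transition {(r, s)}")

    def is_allowed(self, r: int, s: int) -> bool:
        return (r, s) in self.allowed

    def from_state(self, r: int) -> tuple[tuple[int, int], ...]:
        return tuple(t for t in self.allowed if t[0] == r)


DEFAULT_STRUCTURE = TransitionStructure()
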