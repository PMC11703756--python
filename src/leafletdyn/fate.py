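"""Sequence-dependent differentiation logic of the pluripotent synthetic cell.

A GUV loaded with three dormant apo-metalloenzymes (urease/Ni²⁺,
galactose oxidase/Cu²⁺, PLA₂/Ca²⁺) commits to a fate determined by the
*order* in which the three cognate ionophores (A, B, C) are added:

* the first ionophore decides the branch — A: intracellular pH rise (urease),
  B: H₂O₂ production (oxidase), C: lysis (lipase), the latter absorbing;
* the second ionophore elicits only a dampened response because spectator
  ionophores in the membrane suppress later transport, giving the four
  two-step fates A-b, A-c, B-a, B-c;
* a third ionophore has no further effect: the state is terminally locked.

Enumerating all six orders therefore yields exactly five distinct terminal
fates, both C-first orders collapsing to lysis.  The module also classifies
fates from sensor readouts (urease and oxidase sensor fold changes, dye
leakage, lysis flag) with an explicit unclassified category, since readout
clouds of the leaky fates can overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import permutations
from typing import Iterable, Sequence

__all__ = [
    "FateState",
    "SensorReadout",
    "FateThresholds",
    "IONOPHORES",
    "TERMINAL_FATES",
    "apply_step",
    "classify_fate",
    "enumerate_fates",
    "classify_from_readouts",
]

IONOPHORES = ("A", "B", "C")
#: terminal labels reachable from the pluripotent state ("C" is the lysed fate)
TERMINAL_FATES = frozenset({"A-b", "A-c", "B-a", "B-c", "C"})

_SECOND_STEP = {
    ("A", "B"): "A-b",
    ("A", "C"): "A-c",
    ("B", "A"): "B-a",
    ("B", "C"): "B-c",
}


@dataclass(frozen=True)
class FateState:
    """Differentiation state: label, input history and lock flag."""

    label: str = "pluripotent"
    history: tuple[str, ...] = ()
    terminal_locked: bool = False

    @property
    def lysed(self) -> bool:
        return self.label == "C"


@dataclass(frozen=True)
class SensorReadout:
    """End-point sensor panel of one GUV.

    Fold changes are final/baseline intensity of the urease (pH) and oxidase
    (H₂O₂) sensors; ``leakage_pct`` is the percentage of encapsulated dye
    lost at the 20-min readout.
    """

    urease_fold: float
    gaoa_fold: float
    leakage_pct: float
    lysed: bool = False

    def __post_init__(self) -> None:
        if self.urease_fold < 0 or self.gaoa_fold < 0:
            raise ValueError("sensor fold changes must be >= 0")
        if not (-5.0 <= self.leakage_pct <= 105.0):
            raise ValueError("leakage_pct must lie in [-5, 105]")


@dataclass(frozen=True)
class FateThresholds:
    """Readout cutoffs separating 'high' sensor response and 'leaky' GUVs."""

    urease_fold: float = 2.0
    gaoa_fold: float = 2.0
    leakage_pct: float = 20.0


def apply_step(state: FateState, ionophore: str) -> FateState:
    """Advance the state machine by one ionophore addition.

    Lysed and third-step states are absorbing: the input is recorded but the
    label does not change and the state is marked terminally locked.
    Re-adding an ionophore already in the history is rejected.
    """
    if ionophore not in IONOPHORES:
        raise ValueError(f"unknown ionophore {ionophore!r}; expected one of A, B, C")
    if ionophore in state.history:
        raise ValueError(f"ionophore {ionophore} already applied (history {state.history})")
    history = state.history + (ionophore,)
    if state.terminal_locked or state.lysed or len(state.history) >= 2:
        return replace(state, history=history, terminal_locked=True)
    if state.label == "pluripotent":
        return FateState(label=ionophore, history=history,
                         terminal_locked=ionophore == "C")
    key = (state.label, ionophore)
    if key in _SECOND_STEP:
        return FateState(label=_SECOND_STEP[key], history=history)
    raise ValueError(f"no transition from {state.label!r} with ionophore {ionophore}")


def classify_fate(sequence: Sequence[str]) -> FateState:
    """Left-fold of :func:`apply_step` from the pluripotent state."""
    state = FateState()
    for ion in sequence:
        state = apply_step(state, ion)
    return state


def enumerate_fates() -> tuple[dict[tuple[str, ...], str], int]:
    """Terminal fate of every full ionophore ordering, plus distinct count."""
    mapping = {
        perm: classify_fate(perm).label for perm in permutations(IONOPHORES)
    }
    return mapping, len(set(mapping.values()))


def classify_from_readouts(
    readout: SensorReadout,
    thresholds: FateThresholds | None = None,
) -> str:
    """Assign a terminal fate label from a sensor readout panel.

    Partition: lysed GUVs are fate C (unless they paradoxically show strong
    enzyme sensors, which is flagged as unclassified); among intact GUVs a
    high urease response marks the A branch and a high oxidase response the
    B branch, with leakage separating the -c (Ca-ionophore second, leaky)
    from the -b/-a (tight) sub-fates.  Anything ambiguous — both branches
    high, or no sensor above threshold — is returned as ``"unclassified"``.
    """
    thr = thresholds or FateThresholds()
    urease_high = readout.urease_fold >= thr.urease_fold
    gaoa_high = readout.gaoa_fold >= thr.gaoa_fold
    leaky = readout.leakage_pct >= thr.leakage_pct
    if readout.lysed:
        return "C" if not (urease_high or gaoa_high) else "unclassified"
    if urease_high and not gaoa_high:
        return "A-c" if leaky else "A-b"
    if gaoa_high and not urease_high:
        return "B-c" if leaky else "B-a"
    return "unclassified"
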