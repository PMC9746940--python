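"""Constrained pseudo-random trial sequences for sequential grip-lift experiments.

A participant lifts a light (105 g) or heavy (525 g) cube — occasionally a
317 g "dummy" — with the left or right hand, cued on every trial.  The unit
of analysis is the *transition* between two consecutive lifts: previous
weight (L/H) x current weight (L/H) x hand order (same/different), giving
8 conditions.  Only trials whose current lift uses the group's analysis
hand count; dummy trials, trials following a dummy, wrong-hand trials and
the very first trial are discarded.

The generator here builds sequences that satisfy the hard design counts by
construction:

* same-hand condition pairs are realised as a random Eulerian circuit over
  the two-object transition multigraph (10 edges per ordered object pair),
  so 41 analysis-hand trials yield exactly 40 same-hand transitions;
* each different-hand condition is realised as an atomic (other-hand setup,
  analysis-hand lift) pair, inserted at gaps where the insertion cannot
  disturb an existing transition;
* each dummy trial is inserted together with a clone of its left neighbour,
  so the trial after the clone keeps its original previous-lift state (the
  clone itself is always discarded as "follows dummy").

For the default specification this gives 41 + 80 + 30 = 151 trials with
exactly 15 dummies, exactly 10 analyzable trials per condition (80 total)
and exactly 40 wrong-hand trials.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "TrialSlot",
    "TrialLabel",
    "GROUPS",
    "analysis_hand",
    "handedness",
    "sensor_weight",
    "generate_sequence",
    "practice_block",
    "label_trials",
    "sequence_frame",
]

LIGHT, HEAVY, DUMMY, PRACTICE = "light", "heavy", "dummy", "practice"
LEFT, RIGHT = "left", "right"

#: group -> (handedness, analysis hand)
GROUPS: dict[str, tuple[str, str]] = {
    "RH-right": ("right", "right"),
    "RH-left": ("right", "left"),
    "LH-right": ("left", "right"),
    "LH-left": ("left", "left"),
}


def analysis_hand(group: str) -> str:
    """Hand whose current-lift trials are analysed for ``group``."""
    return GROUPS[group][1]


def handedness(group: str) -> str:
    """Handedness (dominance) of participants in ``group``."""
    return GROUPS[group][0]


@dataclass(frozen=True)
class DesignSpec:
    """Object masses and sequence counts for one participant's session.

    Masses are in grams; ``gravity`` in m/s^2.  The defaults reproduce the
    published design: 8 transition conditions x 10 repetitions plus 15
    dummy lifts in a 151-trial sequence.
    """

    light_mass: float = 105.0
    heavy_mass: float = 525.0
    dummy_mass: float = 317.0
    practice_mass: float = 260.0
    manipulandum_mass: float = 120.0
    reps_per_condition: int = 10
    n_conditions: int = 8
    n_dummy: int = 15
    n_total: int = 151
    group: str = "RH-right"
    gravity: float = 9.81

    def __post_init__(self) -> None:
        masses = (self.light_mass, self.dummy_mass, self.heavy_mass,
                  self.practice_mass, self.manipulandum_mass)
        if any(m <= 0 for m in masses[:4]) or self.manipulandum_mass < 0:
            raise ValueError("object masses must be strictly positive")
        if not self.light_mass < self.dummy_mass < self.heavy_mass:
            raise ValueError("expected heavy > dummy > light masses")
        if self.n_conditions != 8:
            raise ValueError("the transition design has exactly 8 conditions "
                             "(2 previous x 2 current weights x 2 hand orders)")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; one of {sorted(GROUPS)}")
        if abs(self.n_dummy - 0.1 * self.n_total) > 1.0 + 0.05 * self.n_total:
            raise ValueError("dummy trials should make up about 10% of the sequence")
        if self.n_total < self.min_length():
            raise ValueError(
                f"n_total={self.n_total} cannot hold {self.n_conditions} x "
                f"{self.reps_per_condition} conditions plus {self.n_dummy} dummy "
                f"trials (need at least {self.min_length()})")

    def min_length(self) -> int:
        """Smallest sequence length the constructive generator can emit."""
        r = self.reps_per_condition
        # Eulerian same-hand chain + atomic different-hand pairs + dummy pairs
        return (4 * r + 1) + 2 * (4 * r) + 2 * self.n_dummy

    def object_mass(self, obj: str) -> float:
        return {LIGHT: self.light_mass, HEAVY: self.heavy_mass,
                DUMMY: self.dummy_mass, PRACTICE: self.practice_mass}[obj]

    def object_weight(self, obj: str) -> float:
        """Sensor-measured weight (N) of ``obj`` inside the manipulandum."""
        return sensor_weight(self.object_mass(obj), self)


@dataclass(frozen=True)
class TrialSlot:
    index: int          # 1-based position in the sequence
    object: str         # light / heavy / dummy
    cued_hand: str      # left / right


@dataclass(frozen=True)
class TrialLabel:
    index: int
    previous_weight: str   # 'L', 'H' or 'none'
    current_weight: str    # 'L', 'H' or 'dummy'
    hand_order: str        # 'same', 'different' or 'n/a'
    condition: str | None  # e.g. 'HLS'; None when not analyzable
    analyzable: bool
    discard_reason: str    # first_trial / dummy / follows_dummy / wrong_hand_order / none


def sensor_weight(mass_obj: float, spec: DesignSpec | None = None) -> float:
    """Weight (N) seen by the force sensors for an object of ``mass_obj`` grams.

    The manipulandum carrying the sensors adds its own mass, so the lifted
    weight is ``(mass_obj + manipulandum_mass) / 1000 * g``.
    """
    spec = spec or DesignSpec()
    if mass_obj <= 0:
        raise ValueError("object mass must be strictly positive")
    return (mass_obj + spec.manipulandum_mass) / 1000.0 * spec.gravity


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------

def _eulerian_objects(rng: np.random.Generator, reps: int) -> list[str]:
    """Random Eulerian circuit over the {light, heavy} transition multigraph.

    Each ordered object pair contributes ``reps`` edges; all vertices have
    even degree, so a circuit exists.  Hierholzer's algorithm with shuffled
    adjacency lists yields a uniformly scrambled circuit of 4*reps edges,
    i.e. a list of 4*reps + 1 objects.
    """
    adj = {
        LIGHT: [LIGHT] * reps + [HEAVY] * reps,
        HEAVY: [LIGHT] * reps + [HEAVY] * reps,
    }
    for lst in adj.values():
        rng.shuffle(lst)
    start = [LIGHT, HEAVY][rng.integers(2)]
    stack, circuit = [start], []
    while stack:
        v = stack[-1]
        if adj[v]:
            stack.append(adj[v].pop())
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    return circuit


def generate_sequence(spec: DesignSpec | None = None, seed: int = 0) -> list[TrialSlot]:
    """Generate one participant's pseudo-randomized trial sequence.

    The returned sequence has exactly ``spec.n_total`` trials and
    ``spec.n_dummy`` dummy trials, and after :func:`label_trials` every one
    of the 8 transition conditions has at least ``spec.reps_per_condition``
    analyzable trials.  Sequences differ across seeds.
    """
    spec = spec or DesignSpec()
    rng = np.random.default_rng(seed)
    a_hand = analysis_hand(spec.group)
    o_hand = LEFT if a_hand == RIGHT else RIGHT
    reps = spec.reps_per_condition

    # 1. same-hand chain: units are single analysis-hand trials
    chain = _eulerian_objects(rng, reps)
    units: list[dict] = [{"kind": "S", "trials": [(obj, a_hand)]} for obj in chain]

    # 2. insert each different-hand condition as an atomic (setup, lift) pair.
    # A gap before an S-unit requires the new pair's last object to equal the
    # current left neighbour's last object, so the S trial keeps its
    # previous-lift state; gaps before D-units or at the end are free.
    d_tokens = [(p, c) for p in (LIGHT, HEAVY) for c in (LIGHT, HEAVY)] * reps
    rng.shuffle(d_tokens)
    for prev_obj, cur_obj in d_tokens:
        gaps = []
        for g in range(1, len(units) + 1):
            if g == len(units) or units[g]["kind"] == "D":
                gaps.append(g)
            elif units[g - 1]["trials"][-1][0] == cur_obj:
                gaps.append(g)
        g = gaps[rng.integers(len(gaps))]
        units.insert(g, {"kind": "D",
                         "trials": [(prev_obj, o_hand), (cur_obj, a_hand)]})

    trials: list[tuple[str, str]] = [t for u in units for t in u["trials"]]

    # 3. pad with filler lifts if the design spec asks for a longer sequence
    n_filler = spec.n_total - 2 * spec.n_dummy - len(trials)
    for _ in range(n_filler):
        obj = [LIGHT, HEAVY][rng.integers(2)]
        hand = [LEFT, RIGHT][rng.integers(2)]
        trials.append((obj, hand))

    # 4. insert dummies, each followed by a clone of its left neighbour so the
    # next trial's previous-lift state is preserved (the clone itself is
    # discarded as a dummy follower)
    for _ in range(spec.n_dummy):
        while True:
            pos = int(rng.integers(1, len(trials) + 1))
            if trials[pos - 1][0] != DUMMY:
                break
        clone = trials[pos - 1]
        d_hand = [LEFT, RIGHT][rng.integers(2)]
        trials[pos:pos] = [(DUMMY, d_hand), clone]

    if len(trials) != spec.n_total:  # pragma: no cover - guarded by min_length
        raise RuntimeError("constructive sequence generation failed")
    return [TrialSlot(i + 1, obj, hand) for i, (obj, hand) in enumerate(trials)]


def practice_block(spec: DesignSpec | None = None, seed: int = 0) -> list[TrialSlot]:
    """Ten familiarization lifts of the 260 g practice object, 5 per hand."""
    spec = spec or DesignSpec()
    rng = np.random.default_rng(seed)
    hands = [LEFT] * 5 + [RIGHT] * 5
    rng.shuffle(hands)
    return [TrialSlot(i + 1, PRACTICE, h) for i, h in enumerate(hands)]


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

_WCODE = {LIGHT: "L", HEAVY: "H"}


def label_trials(sequence: list[TrialSlot], group: str) -> list[TrialLabel]:
    """Classify every trial into a transition condition or a discard category.

    Deterministic and total over valid slots: exactly one label per slot.
    A trial is analyzable when its current lift uses the group's analysis
    hand, both it and its predecessor are light/heavy objects, and it is
    neither the first trial nor the successor of a dummy lift.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    a_hand = analysis_hand(group)
    labels = []
    for i, slot in enumerate(sequence):
        prev = sequence[i - 1] if i > 0 else None
        cur_w = _WCODE.get(slot.object, DUMMY)
        prev_w = _WCODE.get(prev.object, "none") if prev else "none"
        hand_order = "n/a" if prev is None else (
            "same" if prev.cued_hand == slot.cued_hand else "different")

        if prev is None:
            reason = "first_trial"
        elif slot.object == DUMMY:
            reason = "dummy"
        elif prev.object == DUMMY:
            reason = "follows_dummy"
        elif slot.cued_hand != a_hand:
            reason = "wrong_hand_order"
        else:
            reason = "none"

        analyzable = reason == "none"
        condition = None
        if analyzable:
            condition = prev_w + cur_w + ("S" if hand_order == "same" else "D")
        labels.append(TrialLabel(slot.index, prev_w, cur_w, hand_order,
                                 condition, analyzable, reason))
    return labels


def sequence_frame(sequence: list[TrialSlot],
                   labels: list[TrialLabel] | None = None,
                   group: str | None = None) -> pd.DataFrame:
    """Tidy table of a labeled sequence (one row per trial)."""
    if labels is None:
        if group is None:
            raise ValueError("need labels or a group to label with")
        labels = label_trials(sequence, group)
    rows = []
    for slot, lab in zip(sequence, labels, strict=True):
        rows.append({
            "index": slot.index,
            "object": slot.object,
            "cued_hand": slot.cued_hand,
            "previous_weight": lab.previous_weight,
            "current_weight": lab.current_weight,
            "hand_order": lab.hand_order,
            "condition": lab.condition if lab.condition else "",
            "analyzable": lab.analyzable,
            "discard_reason": lab.discard_reason,
        })
    return pd.DataFrame(rows)
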