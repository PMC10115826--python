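"""Truth-table scoring of translational logic circuits.

A 2-input circuit is measured in the four input states [0,0], [1,0],
[0,1], [1,1] (fixed order).  Two metrics compare the observed per-state
normalized intensities (NI) with the ideal truth table:

* **net fold-change** — mean NI over ON states divided by mean NI over OFF
  states (the single-ON AND case reduces to NI([1,1]) / mean of the rest);
* **vector proximity angle** — the angle theta between the ideal 0/1
  truth-table vector and the observed NI vector, 0 deg (best) to 90 deg
  (worst) for nonnegative observations.  Circuits with theta at or below a
  cutoff (default 20 deg) count as functional.

The module also enumerates all 2-input AND circuit role assignments over a
switch set (unordered input pair + distinct mediator) and scores the two
outputs of a half-subtractor (difference = XOR, borrow = NIMPLY).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateMeasurementError,
    DivisionDomainError,
    InvalidParameterError,
)

__all__ = [
    "TruthTable", "GateMeasurement", "GateScore", "truth_table",
    "net_fold_change", "vector_proximity_angle", "evaluate_gate_panel",
    "enumerate_and_gate_assignments", "evaluate_half_subtractor",
    "cascade_expected_levels", "ANGLE_CUTOFF_DEG", "STATE_ORDER_2",
]

ANGLE_CUTOFF_DEG = 20.0
STATE_ORDER_2 = ((0, 0), (1, 0), (0, 1), (1, 1))

# canonical outputs in STATE_ORDER_2; NIMPLY(A, B) = A AND NOT B
_GATES_2 = {
    "AND": (0, 0, 0, 1),
    "NAND": (1, 1, 1, 0),
    "OR": (0, 1, 1, 1),
    "NOR": (1, 0, 0, 0),
    "XOR": (0, 1, 1, 0),
    "NIMPLY": (0, 1, 0, 0),
}


@dataclass(frozen=True)
class TruthTable:
    name: str
    n_inputs: int
    states: tuple[tuple[int, ...], ...]
    outputs: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.states) != 2 ** self.n_inputs or len(self.outputs) != len(self.states):
            raise InvalidParameterError("truth table must cover all 2^n input states")
        if not (0 in self.outputs and 1 in self.outputs):
            raise InvalidParameterError(
                "a scoreable truth table needs at least one ON and one OFF state"
            )

    @property
    def on_states(self) -> tuple[int, ...]:
        return tuple(i for i, o in enumerate(self.outputs) if o == 1)

    @property
    def off_states(self) -> tuple[int, ...]:
        return tuple(i for i, o in enumerate(self.outputs) if o == 0)


def truth_table(name: str, n_inputs: int = 2) -> TruthTable:
    """Canonical 2-input truth table by gate name."""
    if n_inputs != 2:
        raise InvalidParameterError("only 2-input tables are defined here")
    key = name.upper()
    if key not in _GATES_2:
        raise InvalidParameterError(
            f"unknown gate {name!r}; known: {sorted(_GATES_2)}"
        )
    return TruthTable(name=key, n_inputs=2, states=STATE_ORDER_2, outputs=_GATES_2[key])


@dataclass(frozen=True)
class GateMeasurement:
    """Observed per-state NIs of one circuit, in the fixed state order."""

    circuit_id: str
    ni: tuple[float, ...]
    inputs: tuple[str, ...] = ()
    mediator: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.ni, dtype=float)
        if (arr < 0).any():
            raise InvalidParameterError(f"{self.circuit_id}: NIs must be >= 0")
        if not (arr > 0).any():
            raise DegenerateMeasurementError(f"{self.circuit_id}: all-zero NI vector")


@dataclass(frozen=True)
class GateScore:
    circuit_id: str
    net_fold_change: float
    theta_deg: float
    passed: bool


def _observed(m) -> np.ndarray:
    vec = np.asarray(m.ni if isinstance(m, GateMeasurement) else m, dtype=float)
    if (vec < 0).any():
        raise InvalidParameterError("observed NIs must be >= 0")
    if not (vec > 0).any():
        raise DegenerateMeasurementError("all-zero observed vector")
    return vec


def net_fold_change(m, table: TruthTable) -> float:
    """Mean ON-state NI over mean OFF-state NI."""
    vec = _observed(m)
    if len(vec) != len(table.outputs):
        raise InvalidParameterError("state count does not match the truth table")
    off_mean = float(vec[list(table.off_states)].mean())
    if off_mean <= 0:
        raise DivisionDomainError("mean OFF-state NI is zero")
    return float(vec[list(table.on_states)].mean()) / off_mean


def vector_proximity_angle(m, table: TruthTable) -> float:
    """Angle in degrees between the truth-table vector and the observed
    NI vector; the cosine is clipped to [-1, 1] before arccos."""
    vec = _observed(m)
    truth = np.asarray(table.outputs, dtype=float)
    if len(vec) != len(truth):
        raise InvalidParameterError("state count does not match the truth table")
    cos = float(np.dot(truth, vec) / (np.linalg.norm(truth) * np.linalg.norm(vec)))
    return math.degrees(math.acos(min(1.0, max(-1.0, cos))))


def evaluate_gate_panel(
    measurements: Sequence[GateMeasurement],
    table: TruthTable,
    angle_cutoff: float = ANGLE_CUTOFF_DEG,
) -> tuple[list[GateScore], int]:
    """Score every circuit; pass = theta <= cutoff (boundary inclusive).

    Returns the scores and the pass count.
    """
    scores = []
    for m in measurements:
        theta = vector_proximity_angle(m, table)
        scores.append(
            GateScore(
                circuit_id=m.circuit_id,
                net_fold_change=net_fold_change(m, table),
                theta_deg=theta,
                passed=theta <= angle_cutoff,
            )
        )
    return scores, sum(s.passed for s in scores)


def enumerate_and_gate_assignments(
    switch_ids: Sequence[str],
) -> list[tuple[tuple[str, str], str]]:
    """All 2-input AND circuits over a switch set.

    Each circuit is an unordered input pair {A, B} plus a distinct mediator
    C, giving C(k, 2) x (k - 2) circuits, in deterministic lexicographic
    order of ((A, B), C).
    """
    ids = sorted(set(switch_ids))
    if len(ids) < 3:
        raise InvalidParameterError("need at least 3 distinct switches for an AND circuit")
    out = []
    for a, b in itertools.combinations(ids, 2):
        for c in ids:
            if c != a and c != b:
                out.append(((a, b), c))
    return out


def cascade_expected_levels(
    n_stages: int, repression: float = 0.1, on_level: float = 10.0
) -> list[float]:
    """Expected reporter levels of a translational repression cascade as
    stages are inserted between the input and the reporter.

    Each stage is a translational repressor acting on the next stage's
    switch, so adding one stage inverts the reporter's response: an even
    number of intervening repressors leaves the reporter ON (``on_level``),
    an odd number represses it multiplicatively to
    ``on_level * repression``.  Returns the level for 0..n_stages stages —
    the alternation downstream analyses check against measured NIs.
    """
    if n_stages < 1:
        raise InvalidParameterError("n_stages must be >= 1")
    if not 0.0 < repression < 1.0:
        raise InvalidParameterError("repression factor must be in (0, 1)")
    if on_level <= 0:
        raise InvalidParameterError("on_level must be > 0")
    return [on_level * (repression if k % 2 else 1.0) for k in range(n_stages + 1)]


def evaluate_half_subtractor(
    d_measurement,
    bo_measurement,
    subtrahend: str = "second",
    angle_cutoff: float = ANGLE_CUTOFF_DEG,
) -> tuple[GateScore, GateScore]:
    """Score a half-subtractor's two outputs over the four input states.

    The difference D is scored against XOR; the borrow Bo against NIMPLY
    oriented by ``subtrahend``: with inputs ordered (A, B) and
    ``subtrahend="second"`` the circuit computes A - B, so Bo is ON only in
    state [0,1] (B alone); ``"first"`` flips the orientation.  Per-state
    NIs are first normalized to the [0,0] state, which requires a nonzero
    [0,0] NI (the angle itself is scale-invariant, the normalization is
    applied for reporting consistency with the imaging convention).
    """
    if subtrahend not in ("first", "second"):
        raise InvalidParameterError("subtrahend must be 'first' or 'second'")
    xor = truth_table("XOR")
    nimply = truth_table("NIMPLY")  # A AND NOT B: ON in [1,0]
    if subtrahend == "second":
        nimply = TruthTable(
            name="NIMPLY_BA", n_inputs=2, states=STATE_ORDER_2, outputs=(0, 0, 1, 0)
        )

    def normalize(m) -> np.ndarray:
        vec = _observed(m)
        if len(vec) != 4:
            raise InvalidParameterError("half-subtractor needs the four 2-input states")
        if vec[0] <= 0:
            raise DivisionDomainError("[0,0]-state NI is zero; cannot normalize")
        return vec / vec[0]

    def score(m, table: TruthTable, label: str) -> GateScore:
        vec = normalize(m)
        cid = m.circuit_id if isinstance(m, GateMeasurement) else label
        theta = vector_proximity_angle(vec, table)
        return GateScore(
            circuit_id=cid,
            net_fold_change=net_fold_change(vec, table),
            theta_deg=theta,
            passed=theta <= angle_cutoff,
        )

    return score(d_measurement, xor, "D"), score(bo_measurement, nimply, "Bo")
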