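"""Synthetic flow-cytometry data with planted ground truth.

The generator emulates the raw material of a switch x trigger orthogonality
screen: per-cell event tables (forward/side scatter, a fluorescent reporter
and a co-transfected reference channel) for every combination of a
Cas-responsive switch and a trigger protein, plus mock (untransfected)
samples used to place gates downstream.

The planted model is deliberately simple and steady-state: each trigger
multiplies the reporter expression of each switch by a fixed factor
(< 1 for repression on an OFF switch, > 1 for activation on an ON switch,
1 for no interaction).  Cells are drawn from a log-normal fluorescence
model; a configurable fraction of events are debris (low scatter),
transfection-negative (autofluorescence only) or clamped to the channel
limits (edge events), so every downstream gating step has a well-defined
target.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "NO_GRNA",
    "GroundTruthPanel",
    "CellPopulationModel",
    "EventTable",
    "ScreenDataset",
    "build_ground_truth_panel",
    "build_planted_screen_panel",
    "simulate_sample",
    "simulate_mock_sample",
    "simulate_orthogonality_screen",
    "simulate_gate_panel",
    "expected_fc_matrix",
    "noisy_fc_matrix",
    "subseed",
]

#: Identifier of the control switch that carries no gRNA insert and is
#: therefore blind to every trigger; it is the normalization reference.
NO_GRNA = "NoGRNA"

EVENT_COLUMNS = ["event_id", "fsc", "ssc", "reporter", "reference"]
SAMPLE_SHEET_COLUMNS = [
    "sample_id", "switch_id", "trigger_id", "condition", "replicate", "role",
]


def subseed(master_seed: int, sample_id: str) -> int:
    """Stable per-sample sub-seed derived from (master seed, sample id).

    Uses SHA-256 so adding or re-ordering samples never perturbs the events
    of existing ones.  The result fits in a signed 32-bit integer.
    """
    digest = hashlib.sha256(f"{master_seed}:{sample_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthPanel:
    """Planted multiplicative effect matrix of a switch x trigger screen.

    ``effect`` is indexed by trigger (rows) and switch (columns) and holds
    the factor by which the trigger scales the switch's reporter output.
    The ``NoGRNA`` control column is identically 1.
    """

    trigger_ids: tuple[str, ...]
    switch_ids: tuple[str, ...]
    switch_types: Mapping[str, str]          # switch id -> "OFF" | "ON"
    effect: pd.DataFrame                     # triggers x switches, > 0
    basal_reporter: Mapping[str, float]      # switch id -> a.u.

    def __post_init__(self) -> None:
        eff = self.effect
        if eff.shape != (len(self.trigger_ids), len(self.switch_ids)):
            raise InvalidParameterError(
                f"effect matrix shape {eff.shape} does not match "
                f"{len(self.trigger_ids)} triggers x {len(self.switch_ids)} switches"
            )
        if (eff.to_numpy() <= 0).any():
            raise InvalidParameterError("all effects must be > 0")
        if NO_GRNA in eff.columns and not (eff[NO_GRNA] == 1.0).all():
            raise InvalidParameterError(f"{NO_GRNA} column must be identically 1")

    @property
    def measurement_switch_ids(self) -> tuple[str, ...]:
        """Switch ids excluding the No-gRNA control."""
        return tuple(s for s in self.switch_ids if s != NO_GRNA)

    def matched_switch(self, trigger_id: str) -> str:
        """Switch paired with a trigger (positional pairing T_k <-> S_k)."""
        i = self.trigger_ids.index(trigger_id)
        return self.measurement_switch_ids[i]

    def to_json(self) -> str:
        payload = {
            "trigger_ids": list(self.trigger_ids),
            "switch_ids": list(self.switch_ids),
            "switch_types": dict(self.switch_types),
            "basal_reporter": dict(self.basal_reporter),
            "effect": {t: self.effect.loc[t].to_dict() for t in self.trigger_ids},
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthPanel":
        d = json.loads(text)
        eff = pd.DataFrame(d["effect"]).T.reindex(
            index=d["trigger_ids"], columns=d["switch_ids"]
        )
        return cls(
            trigger_ids=tuple(d["trigger_ids"]),
            switch_ids=tuple(d["switch_ids"]),
            switch_types=d["switch_types"],
            effect=eff,
            basal_reporter=d["basal_reporter"],
        )


def build_ground_truth_panel(
    n_triggers: int,
    switch_types: Sequence[str] | str = "OFF",
    on_target_effect: float | Sequence[float] = 0.1,
    crosstalk_spec: Iterable[tuple[str, str, float]] = (),
    basal_reporter: float = 1000.0,
) -> GroundTruthPanel:
    """Construct a planted trigger x switch effect panel.

    Trigger ``T<k>`` is paired with switch ``S<k>``; the matched (diagonal)
    entry is ``on_target_effect`` (scalar, or one value per switch), every
    other entry is 1 except those listed in ``crosstalk_spec`` as
    ``(trigger_id, switch_id, factor)``.  A ``NoGRNA`` control column with
    all-1 effects is appended.
    """
    if n_triggers < 1:
        raise InvalidParameterError("n_triggers must be >= 1")
    width = len(str(n_triggers))
    trigger_ids = tuple(f"T{k + 1:0{width}d}" for k in range(n_triggers))
    switch_ids = tuple(f"S{k + 1:0{width}d}" for k in range(n_triggers))

    if isinstance(switch_types, str):
        types = {s: switch_types for s in switch_ids}
    else:
        if len(switch_types) != n_triggers:
            raise InvalidParameterError("switch_types length must equal n_triggers")
        types = dict(zip(switch_ids, switch_types))
    for s, t in types.items():
        if t not in ("OFF", "ON"):
            raise InvalidParameterError(f"switch type of {s} must be OFF or ON, got {t!r}")

    if np.isscalar(on_target_effect):
        on_target = {s: float(on_target_effect) for s in switch_ids}
    else:
        on_target = {s: float(v) for s, v in zip(switch_ids, on_target_effect)}
    if any(v <= 0 for v in on_target.values()):
        raise InvalidParameterError("on-target effects must be > 0")

    eff = pd.DataFrame(1.0, index=list(trigger_ids), columns=list(switch_ids))
    for t, s in zip(trigger_ids, switch_ids):
        eff.loc[t, s] = on_target[s]

    seen: set[tuple[str, str]] = set()
    for trig, sw, factor in crosstalk_spec:
        if factor <= 0:
            raise InvalidParameterError(f"crosstalk factor for ({trig},{sw}) must be > 0")
        if (trig, sw) in seen:
            raise InvalidParameterError(f"duplicate crosstalk entry ({trig},{sw})")
        if trig not in eff.index or sw not in eff.columns:
            raise InvalidParameterError(f"unknown crosstalk pair ({trig},{sw})")
        if sw == NO_GRNA:
            raise InvalidParameterError("crosstalk onto the No-gRNA control is not allowed")
        seen.add((trig, sw))
        eff.loc[trig, sw] = float(factor)

    eff[NO_GRNA] = 1.0
    all_switches = switch_ids + (NO_GRNA,)
    types[NO_GRNA] = "OFF"
    basal = {s: float(basal_reporter) for s in all_switches}
    return GroundTruthPanel(
        trigger_ids=trigger_ids,
        switch_ids=all_switches,
        switch_types=types,
        effect=eff,
        basal_reporter=basal,
    )


def build_planted_screen_panel(
    n_triggers: int = 16,
    n_promiscuous: int = 3,
    on_target_effect: float = 0.1,
    crosstalk_effect: float = 0.5,
    switch_types: str = "OFF",
) -> tuple[GroundTruthPanel, tuple[str, ...], tuple[tuple[str, str, float], ...]]:
    """Planted screen panel with a structurally unique orthogonal subset.

    The last ``n_promiscuous`` triggers are promiscuous: each cross-reacts
    with the switches of *two* distinct clean partners at
    ``crosstalk_effect``.  Because keeping a promiscuous trigger in a subset
    forces both of its partners out (two exclusions instead of one), the
    unique best subset of size ``n_triggers - n_promiscuous`` is exactly the
    clean trigger set, independent of noise realization.

    Returns ``(panel, clean_trigger_ids, crosstalk_entries)``.
    """
    if n_triggers - n_promiscuous < 2 * n_promiscuous:
        raise InvalidParameterError("not enough clean partners for the promiscuous triggers")
    width = len(str(n_triggers))
    ids = [f"T{k + 1:0{width}d}" for k in range(n_triggers)]
    n_clean = n_triggers - n_promiscuous
    clean, promiscuous = ids[:n_clean], ids[n_clean:]
    crosstalk = []
    for j, bad in enumerate(promiscuous):
        for partner in (clean[2 * j], clean[2 * j + 1]):
            crosstalk.append((bad, partner.replace("T", "S"), crosstalk_effect))
    panel = build_ground_truth_panel(
        n_triggers,
        switch_types=switch_types,
        on_target_effect=on_target_effect,
        crosstalk_spec=crosstalk,
    )
    return panel, tuple(clean), tuple(crosstalk)


# ---------------------------------------------------------------------------
# per-cell event model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellPopulationModel:
    """Distributional model of one cytometry sample.

    Fluorescence channels are log-normal; the reporter of a transfected cell
    is ``basal x effect x dose x noise`` where ``dose`` is the cell's
    reference intensity relative to the population median, so reporter and
    reference co-vary with transfection dose and their ratio isolates the
    planted effect.  Scatter separates intact cells from debris.
    All channel values are clipped to ``[channel_min, channel_max]``; a
    fraction of events is clamped exactly to the limits (edge events).
    """

    ref_log10_mean: float = 4.0
    ref_log10_sd: float = 0.4
    reporter_log10_noise_sd: float = 0.1
    transfected_fraction: float = 0.7
    debris_fraction: float = 0.05
    edge_fraction: float = 0.01
    channel_min: float = 1.0
    channel_max: float = 16_777_215.0
    auto_log10_mean: float = 2.0
    auto_log10_sd: float = 0.3
    fsc_log10_mean: float = 5.0
    fsc_log10_sd: float = 0.10
    ssc_log10_mean: float = 4.7
    ssc_log10_sd: float = 0.12
    debris_fsc_log10_mean: float = 3.3
    debris_fsc_log10_sd: float = 0.25
    debris_ssc_log10_mean: float = 3.0
    debris_ssc_log10_sd: float = 0.30

    def __post_init__(self) -> None:
        if not (0.0 < self.transfected_fraction <= 1.0):
            raise InvalidParameterError("transfected_fraction must be in (0, 1]")
        if not (0.0 <= self.debris_fraction < 1.0):
            raise InvalidParameterError("debris_fraction must be in [0, 1)")
        if not (0.0 <= self.edge_fraction < 1.0):
            raise InvalidParameterError("edge_fraction must be in [0, 1)")
        if not self.channel_max > self.channel_min:
            raise InvalidParameterError("channel_max must exceed channel_min")

    def with_(self, **kwargs) -> "CellPopulationModel":
        return replace(self, **kwargs)


@dataclass
class EventTable:
    """Per-cell events of one sample plus its sample-sheet metadata."""

    events: pd.DataFrame
    sample_id: str
    switch_id: str | None = None
    trigger_id: str | None = None
    condition: str = ""
    replicate: int = 1
    role: str = "measurement"   # measurement | mock | no_gRNA_control

    def sheet_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "switch_id": self.switch_id or "",
            "trigger_id": self.trigger_id or "",
            "condition": self.condition,
            "replicate": self.replicate,
            "role": self.role,
        }


def _draw_events(
    pop: CellPopulationModel,
    n_events: int,
    rng: np.random.Generator,
    basal: float,
    effect: float,
    transfected_fraction: float | None = None,
) -> pd.DataFrame:
    """Draw one sample's events.  Draw order is fixed for determinism."""
    n = int(n_events)
    tf = pop.transfected_fraction if transfected_fraction is None else transfected_fraction

    is_debris = rng.random(n) < pop.debris_fraction
    is_transfected = (~is_debris) & (rng.random(n) < tf)

    ref_pos = 10.0 ** rng.normal(pop.ref_log10_mean, pop.ref_log10_sd, n)
    ref_auto = 10.0 ** rng.normal(pop.auto_log10_mean, pop.auto_log10_sd, n)
    rep_auto = 10.0 ** rng.normal(pop.auto_log10_mean, pop.auto_log10_sd, n)
    noise = 10.0 ** rng.normal(0.0, pop.reporter_log10_noise_sd, n)

    reference = np.where(is_transfected, ref_pos, ref_auto)
    dose = ref_pos / 10.0 ** pop.ref_log10_mean
    reporter = np.where(is_transfected, basal * effect * dose * noise, rep_auto)

    fsc_intact = 10.0 ** rng.normal(pop.fsc_log10_mean, pop.fsc_log10_sd, n)
    ssc_intact = 10.0 ** rng.normal(pop.ssc_log10_mean, pop.ssc_log10_sd, n)
    fsc_debris = 10.0 ** rng.normal(pop.debris_fsc_log10_mean, pop.debris_fsc_log10_sd, n)
    ssc_debris = 10.0 ** rng.normal(pop.debris_ssc_log10_mean, pop.debris_ssc_log10_sd, n)
    fsc = np.where(is_debris, fsc_debris, fsc_intact)
    ssc = np.where(is_debris, ssc_debris, ssc_intact)

    # edge events: detector saturation, clamped exactly to a channel limit
    edge_draw = rng.random(n)
    edge_hi = edge_draw < pop.edge_fraction / 2.0
    edge_lo = (edge_draw >= pop.edge_fraction / 2.0) & (edge_draw < pop.edge_fraction)
    reporter = np.where(edge_hi, pop.channel_max, reporter)
    reference = np.where(edge_lo, pop.channel_max, reference)

    reporter = np.clip(reporter, pop.channel_min, pop.channel_max)
    reference = np.clip(reference, pop.channel_min, pop.channel_max)
    fsc = np.clip(fsc, pop.channel_min, pop.channel_max)
    ssc = np.clip(ssc, pop.channel_min, pop.channel_max)

    return pd.DataFrame(
        {
            "event_id": np.arange(n, dtype=np.int64),
            "fsc": fsc,
            "ssc": ssc,
            "reporter": reporter,
            "reference": reference,
        }
    )


def simulate_sample(
    panel: GroundTruthPanel,
    switch_id: str,
    trigger_id: str | None,
    pop: CellPopulationModel,
    n_events: int,
    seed: int,
    sample_id: str | None = None,
    replicate: int = 1,
) -> EventTable:
    """Simulate the event table of one (switch, trigger) sample.

    ``trigger_id=None`` is the trigger-minus condition (effect 1).
    """
    if n_events < 1:
        raise InvalidParameterError("n_events must be >= 1")
    if switch_id not in panel.switch_ids:
        raise KeyError(f"unknown switch {switch_id!r}")
    if trigger_id is None:
        effect = 1.0
    else:
        if trigger_id not in panel.trigger_ids:
            raise KeyError(f"unknown trigger {trigger_id!r}")
        effect = float(panel.effect.loc[trigger_id, switch_id])

    sid = sample_id or f"{trigger_id or 'none'}_{switch_id}_r{replicate}"
    rng = np.random.default_rng(seed)
    events = _draw_events(pop, n_events, rng, float(panel.basal_reporter[switch_id]), effect)
    role = "no_gRNA_control" if switch_id == NO_GRNA else "measurement"
    return EventTable(
        events=events,
        sample_id=sid,
        switch_id=switch_id,
        trigger_id=trigger_id,
        condition="trigger+" if trigger_id else "trigger-",
        replicate=replicate,
        role=role,
    )


def simulate_mock_sample(
    pop: CellPopulationModel,
    n_events: int,
    seed: int,
    sample_id: str = "mock_r1",
    replicate: int = 1,
) -> EventTable:
    """Untransfected (mock) sample: autofluorescence only, used for gating."""
    if n_events < 1:
        raise InvalidParameterError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    events = _draw_events(pop, n_events, rng, basal=0.0, effect=1.0, transfected_fraction=0.0)
    return EventTable(
        events=events,
        sample_id=sample_id,
        condition="mock",
        replicate=replicate,
        role="mock",
    )


# ---------------------------------------------------------------------------
# screen- and panel-level datasets
# ---------------------------------------------------------------------------

@dataclass
class ScreenDataset:
    """A set of simulated samples plus the sample sheet describing them."""

    tables: dict[str, EventTable]
    sample_sheet: pd.DataFrame
    panel: GroundTruthPanel | None = None
    extra: dict = field(default_factory=dict)

    def mock_ids(self) -> list[str]:
        sheet = self.sample_sheet
        return list(sheet.loc[sheet["role"] == "mock", "sample_id"])


def simulate_orthogonality_screen(
    panel: GroundTruthPanel,
    pop: CellPopulationModel,
    n_events: int = 5000,
    replicates: int = 3,
    seed: int = 0,
) -> ScreenDataset:
    """Simulate the full switch x trigger screen.

    For every trigger, every switch (including the No-gRNA control), both
    trigger conditions and every replicate, one event table; plus one mock
    sample per replicate.  Per-sample seeds are derived from
    ``(seed, sample_id)`` so the dataset is stable under extension.
    """
    if replicates < 1:
        raise InvalidParameterError("replicates must be >= 1")
    tables: dict[str, EventTable] = {}
    rows = []
    for rep in range(1, replicates + 1):
        sid = f"mock_r{rep}"
        tbl = simulate_mock_sample(pop, n_events, subseed(seed, sid), sid, rep)
        tables[sid] = tbl
        rows.append(tbl.sheet_row())
    for trig in panel.trigger_ids:
        for sw in panel.switch_ids:
            for cond, trig_id in (("plus", trig), ("minus", None)):
                for rep in range(1, replicates + 1):
                    sid = f"{trig}_{sw}_{cond}_r{rep}"
                    tbl = simulate_sample(
                        panel, sw, trig_id, pop, n_events,
                        subseed(seed, sid), sample_id=sid, replicate=rep,
                    )
                    tables[sid] = tbl
                    rows.append(tbl.sheet_row())
    sheet = pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS)
    return ScreenDataset(tables=tables, sample_sheet=sheet, panel=panel)


@dataclass(frozen=True)
class GateSpec:
    """Planted behavior of one logic circuit: expected normalized intensity
    (NI) per input state — ``on_level`` in ON states, one leak level per OFF
    state."""

    circuit_id: str
    outputs: tuple[int, ...]          # ideal truth-table outputs, state order
    on_level: float
    leak_levels: tuple[float, ...]    # one per OFF state, state order

    def expected_levels(self) -> tuple[float, ...]:
        if self.on_level <= 0:
            raise InvalidParameterError("on_level must be > 0")
        if any(l < 0 for l in self.leak_levels):
            raise InvalidParameterError("leak levels must be >= 0")
        n_off = sum(1 for o in self.outputs if o == 0)
        if len(self.leak_levels) != n_off:
            raise InvalidParameterError(
                f"{self.circuit_id}: {n_off} OFF states but "
                f"{len(self.leak_levels)} leak levels"
            )
        levels, leaks = [], list(self.leak_levels)
        for o in self.outputs:
            levels.append(self.on_level if o == 1 else leaks.pop(0))
        return tuple(levels)


def simulate_gate_panel(
    gate_specs: Sequence[GateSpec],
    pop: CellPopulationModel,
    n_events: int = 2000,
    seed: int = 0,
    state_labels: Sequence[str] = ("0,0", "1,0", "0,1", "1,1"),
) -> ScreenDataset:
    """Simulate one event table per circuit and input state.

    The basal reporter level of each state is chosen so that the expected
    downstream NI equals the planted level; a mock sample is included for
    gating.  Raises if a spec's leak count does not match its truth table.
    """
    for spec in gate_specs:
        if len(spec.outputs) != len(state_labels):
            raise InvalidParameterError(
                f"{spec.circuit_id}: truth table arity mismatch "
                f"({len(spec.outputs)} outputs, {len(state_labels)} states)"
            )
    tables: dict[str, EventTable] = {}
    rows = []
    sid = "mock_r1"
    mock = simulate_mock_sample(pop, n_events, subseed(seed, sid), sid)
    tables[sid] = mock
    rows.append(mock.sheet_row())
    for spec in gate_specs:
        levels = spec.expected_levels()
        for label, level in zip(state_labels, levels):
            # NI = 1000 * basal / 10**ref_log10_mean  =>  invert for basal
            basal = max(level, 1e-9) * 10.0 ** pop.ref_log10_mean / 1000.0
            one_switch = GroundTruthPanel(
                trigger_ids=("Tnone",),
                switch_ids=("Sout",),
                switch_types={"Sout": "OFF"},
                effect=pd.DataFrame([[1.0]], index=["Tnone"], columns=["Sout"]),
                basal_reporter={"Sout": basal},
            )
            sample_id = f"{spec.circuit_id}_state_{label.replace(',', '')}"
            tbl = simulate_sample(
                one_switch, "Sout", None, pop, n_events,
                subseed(seed, sample_id), sample_id=sample_id,
            )
            tbl.switch_id = spec.circuit_id
            tbl.condition = label
            tables[sample_id] = tbl
            rows.append(tbl.sheet_row())
    sheet = pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS)
    return ScreenDataset(
        tables=tables, sample_sheet=sheet,
        extra={"gate_specs": list(gate_specs), "state_labels": tuple(state_labels)},
    )


# ---------------------------------------------------------------------------
# fold-change matrices straight from the ground truth
# ---------------------------------------------------------------------------

def expected_fc_matrix(panel: GroundTruthPanel) -> pd.DataFrame:
    """Noise-free fold-change matrix implied by the planted effects.

    Relative reporter expression of trigger i on switch j converges to
    ``effect(i, j)`` under the generator's model, so the expected matrix is
    the effect matrix without the No-gRNA control column.
    """
    return panel.effect[list(panel.measurement_switch_ids)].copy()


def noisy_fc_matrix(
    panel: GroundTruthPanel,
    cv: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Fold-change matrix with multiplicative log-normal measurement noise.

    Each replicate draws ``effect x exp(N(0, ln(1+cv)))`` per entry; the
    returned matrix is the replicate mean — a fast stand-in for running the
    full event-level pipeline when only the orthogonality stage is studied.
    """
    if cv < 0:
        raise InvalidParameterError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    base = expected_fc_matrix(panel).to_numpy()
    sigma = np.log1p(cv)
    draws = base[None, :, :] * np.exp(
        rng.normal(0.0, sigma, size=(replicates,) + base.shape)
    )
    mean = draws.mean(axis=0)
    return pd.DataFrame(
        mean, index=list(panel.trigger_ids), columns=list(panel.measurement_switch_ids)
    )
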