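"""End-to-end orchestration: simulate -> gate -> summarize -> orthogonality
-> gate scoring -> provenance report.

The stage functions operate on in-memory datasets and are what the tests,
the analysis drivers and the CLI all call; :func:`run_pipeline` chains them
from a single :class:`RunConfig` and writes every artifact (TSV tables plus
a provenance JSON) into one output directory.  Reruns with an identical
config reproduce identical numbers.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import InsufficientDataError, SwitchScreenError
from .gates import (
    ANGLE_CUTOFF_DEG,
    GateMeasurement,
    enumerate_and_gate_assignments,
    evaluate_gate_panel,
    truth_table,
)
from .gating import GateConfig, apply_standard_gating
from .io import write_json, write_matrix, write_screen_dataset
from .metrics import (
    normalized_intensity,
    relative_intensity,
    relative_reporter_expression,
    fold_change,
    summarize_replicates,
)
from .orthogonality import (
    ORTHOGONALITY_THRESHOLD,
    FoldChangeMatrix,
    classify_orthogonal,
    pairwise_distance_matrix,
    sweep_best_combinations,
)
from .simulate import (
    NO_GRNA,
    CellPopulationModel,
    GateSpec,
    ScreenDataset,
    build_planted_screen_panel,
    simulate_gate_panel,
    simulate_orthogonality_screen,
)

__all__ = [
    "RunConfig", "summarize_screen", "ScreenSummary", "summarize_gate_panel",
    "build_demo_gate_specs", "run_pipeline",
]


@dataclass
class RunConfig:
    """Everything a full demo run needs; round-trips through JSON."""

    seed: int = 0
    outdir: str = "results/pipeline"
    # planted screen
    n_triggers: int = 16
    n_promiscuous: int = 3
    on_target_effect: float = 0.1
    crosstalk_effect: float = 0.5
    switch_type: str = "OFF"
    n_events: int = 5000
    replicates: int = 3
    reporter_noise_log10_sd: float = 0.1
    # orthogonality
    n_min: int = 3
    n_max: int = 13
    threshold: float = ORTHOGONALITY_THRESHOLD
    profile_mode: str = "full"
    # logic-gate panel
    gate_switches: int = 6
    gate_on_level: float = 10.0
    gate_low_leak: float = 0.5
    gate_high_leak: float = 3.0
    gate_n_low: int = 21
    gate_events: int = 2000
    angle_cutoff: float = ANGLE_CUTOFF_DEG
    gating: dict = field(default_factory=dict)   # GateConfig overrides

    def gate_config(self) -> GateConfig:
        return GateConfig(**self.gating)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


@dataclass
class ScreenSummary:
    """Stage outputs of gating + normalization over a screen dataset."""

    ni_table: pd.DataFrame          # sample_id, n_cells, NI
    comparison_table: pd.DataFrame  # per (trigger, switch): RI, rel. expression, FC, mean, sd
    fc_matrix: pd.DataFrame         # trigger x switch relative reporter expression
    gating_report: list[dict]


def _mock_for(dataset: ScreenDataset, replicate: int):
    sid = f"mock_r{replicate}"
    if sid in dataset.tables:
        return dataset.tables[sid]
    mocks = dataset.mock_ids()
    if not mocks:
        raise InsufficientDataError("dataset has no mock sample to gate against")
    return dataset.tables[mocks[0]]


def summarize_screen(dataset: ScreenDataset, cfg: GateConfig | None = None) -> ScreenSummary:
    """Gate every sample against its replicate's mock and compute the full
    normalization chain down to the trigger x switch fold-change matrix.

    The fold-change matrix holds the replicate-mean relative reporter
    expression with the No-gRNA control column dropped (it is the
    normalizer and identically 1).
    """
    cfg = cfg or GateConfig()
    panel = dataset.panel
    ni: dict[str, float] = {}
    ni_rows, reports = [], []
    for sid, tbl in dataset.tables.items():
        if tbl.role == "mock":
            continue
        gated = apply_standard_gating(tbl, _mock_for(dataset, tbl.replicate), cfg)
        reports.append(gated.report())
        summ = normalized_intensity(gated)
        ni[sid] = summ.ni
        ni_rows.append({"sample_id": sid, "n_cells": summ.n_cells, "NI": summ.ni})
    ni_table = pd.DataFrame(ni_rows, columns=["sample_id", "n_cells", "NI"])

    sheet = dataset.sample_sheet
    meas = sheet[sheet["role"] != "mock"]
    triggers = [t for t in meas["trigger_id"].unique() if t]
    switches = list(dict.fromkeys(s for s in meas["switch_id"] if s))
    replicates = sorted(meas["replicate"].unique())

    def _ri(trig: str, sw: str, rep: int) -> float:
        return relative_intensity(
            ni[f"{trig}_{sw}_plus_r{rep}"], ni[f"{trig}_{sw}_minus_r{rep}"]
        )

    rows = []
    rel_by_pair: dict[tuple[str, str], list[float]] = {}
    for trig in triggers:
        for sw in switches:
            ris, rels = [], []
            for rep in replicates:
                ri = _ri(trig, sw, rep)
                rel = relative_reporter_expression(ri, _ri(trig, NO_GRNA, rep))
                ris.append(ri)
                rels.append(rel)
            rel_by_pair[(trig, sw)] = rels
            mean_rel, sd_rel = summarize_replicates(rels)
            mean_ri, _ = summarize_replicates(ris)
            stype = panel.switch_types.get(sw, "OFF") if panel else "OFF"
            rows.append(
                {
                    "switch_id": sw,
                    "trigger_id": trig,
                    "RI": mean_ri,
                    "relative_reporter_expression": mean_rel,
                    "fold_change": fold_change(mean_ri, stype),
                    "mean": mean_rel,
                    "sd": sd_rel,
                }
            )
    comparison = pd.DataFrame(rows)

    fc_switches = [s for s in switches if s != NO_GRNA]
    fc = pd.DataFrame(
        [[np.mean(rel_by_pair[(t, s)]) for s in fc_switches] for t in triggers],
        index=triggers,
        columns=fc_switches,
    )
    return ScreenSummary(
        ni_table=ni_table,
        comparison_table=comparison,
        fc_matrix=fc,
        gating_report=reports,
    )


def summarize_gate_panel(dataset: ScreenDataset, cfg: GateConfig | None = None) -> list[GateMeasurement]:
    """Gate and normalize a simulated logic-gate dataset into per-circuit
    GateMeasurements (state order as simulated)."""
    cfg = cfg or GateConfig()
    state_labels = dataset.extra.get("state_labels", ("0,0", "1,0", "0,1", "1,1"))
    mock = dataset.tables[dataset.mock_ids()[0]]
    sheet = dataset.sample_sheet
    meas = sheet[sheet["role"] != "mock"]
    out = []
    for cid in dict.fromkeys(meas["switch_id"]):
        nis = []
        for label in state_labels:
            sid = f"{cid}_state_{label.replace(',', '')}"
            gated = apply_standard_gating(dataset.tables[sid], mock, cfg)
            nis.append(normalized_intensity(gated).ni)
        out.append(GateMeasurement(circuit_id=cid, ni=tuple(nis)))
    return out


def build_demo_gate_specs(config: RunConfig) -> list[GateSpec]:
    """AND-gate panel over ``gate_switches`` switches with a planted number
    of low-leak (functional) circuits; the rest leak high.  Which circuits
    are low-leak is drawn deterministically from the run seed."""
    and_outputs = truth_table("AND").outputs
    circuits = enumerate_and_gate_assignments(
        [f"S{i + 1}" for i in range(config.gate_switches)]
    )
    if config.gate_n_low > len(circuits):
        raise SwitchScreenError(
            f"cannot plant {config.gate_n_low} low-leak circuits among {len(circuits)}"
        )
    rng = np.random.default_rng(config.seed + 1)
    low_idx = set(rng.choice(len(circuits), size=config.gate_n_low, replace=False).tolist())
    specs = []
    for k, ((a, b), c) in enumerate(circuits):
        leak = config.gate_low_leak if k in low_idx else config.gate_high_leak
        specs.append(
            GateSpec(
                circuit_id=f"{a}-{b}_via_{c}",
                outputs=and_outputs,
                on_level=config.gate_on_level,
                leak_levels=(leak,) * 3,
            )
        )
    return specs


def run_pipeline(config: RunConfig, write_events: bool = False) -> dict:
    """Run the demo pipeline end to end and write all artifacts.

    Returns the provenance report (also written as ``report.json``).
    Event-level CSVs are only written when ``write_events`` is set; they
    are bulky and every summary is derived from them deterministically.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        panel, clean, crosstalk = build_planted_screen_panel(
            n_triggers=config.n_triggers,
            n_promiscuous=config.n_promiscuous,
            on_target_effect=config.on_target_effect,
            crosstalk_effect=config.crosstalk_effect,
            switch_types=config.switch_type,
        )
        pop = CellPopulationModel(reporter_log10_noise_sd=config.reporter_noise_log10_sd)

        stage = "simulate"
        dataset = simulate_orthogonality_screen(
            panel, pop, n_events=config.n_events,
            replicates=config.replicates, seed=config.seed,
        )
        (out / "ground_truth.json").write_text(panel.to_json() + "\n")
        if write_events:
            write_screen_dataset(dataset, out / "screen")

        stage = "gate+summarize"
        cfg = config.gate_config()
        summary = summarize_screen(dataset, cfg)
        summary.ni_table.to_csv(out / "ni_per_sample.tsv", sep="\t", index=False,
                                float_format="%.17g")
        summary.comparison_table.to_csv(out / "comparisons.tsv", sep="\t", index=False,
                                        float_format="%.17g")
        write_matrix(summary.fc_matrix, out / "fc_matrix.tsv")
        write_json({"samples": summary.gating_report}, out / "gating_report.json")

        stage = "orthogonality"
        fcm = FoldChangeMatrix.from_frame(summary.fc_matrix)
        write_matrix(pairwise_distance_matrix(fcm), out / "pair_distances.tsv")
        sweep = sweep_best_combinations(
            fcm, n_min=config.n_min, n_max=config.n_max,
            profile_mode=config.profile_mode,
        )
        sweep_df = pd.DataFrame(
            {
                "N": [s.size for s in sweep],
                "distance": [s.distance for s in sweep],
                "orthogonal": [classify_orthogonal(s, config.threshold) for s in sweep],
                "combination": [",".join(s.combination) for s in sweep],
                "argmin_pair": ["|".join(s.argmin_pair) for s in sweep],
            }
        )
        sweep_df.to_csv(out / "best_combinations.tsv", sep="\t", index=False,
                        float_format="%.17g")

        stage = "gates"
        specs = build_demo_gate_specs(config)
        gate_ds = simulate_gate_panel(
            specs, pop, n_events=config.gate_events, seed=config.seed + 2
        )
        measurements = summarize_gate_panel(gate_ds, cfg)
        scores, n_pass = evaluate_gate_panel(
            measurements, truth_table("AND"), angle_cutoff=config.angle_cutoff
        )
        pd.DataFrame(
            {
                "circuit_id": [s.circuit_id for s in scores],
                "net_fold_change": [s.net_fold_change for s in scores],
                "theta_deg": [s.theta_deg for s in scores],
                "pass": [s.passed for s in scores],
            }
        ).to_csv(out / "gate_scores.tsv", sep="\t", index=False, float_format="%.17g")

        stage = "report"
        report = {
            "package": "switchscreen",
            "version": __version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "config": json.loads(config.to_json()),
            "planted": {
                "clean_triggers": list(clean),
                "crosstalk_entries": [list(c) for c in crosstalk],
            },
            "counts": {
                "samples": int(len(dataset.sample_sheet)),
                "events_per_sample": config.n_events,
                "circuits": len(specs),
                "circuits_passing": int(n_pass),
            },
            "best_combination_per_N": {
                int(s.size): {"distance": s.distance, "combination": list(s.combination)}
                for s in sweep
            },
        }
        write_json(report, out / "report.json")
        (out / "config.json").write_text(config.to_json() + "\n")
        return report
    except SwitchScreenError as err:
        raise SwitchScreenError(f"pipeline stage {stage!r} failed: {err}") from err
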