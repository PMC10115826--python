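"""Event-level preprocessing: debris, edge and reference-positive gates.

The three gates mirror the standard manual workflow on a cytometer:

1. debris removal on the forward/side-scatter plot (rectangular lower
   bounds),
2. removal of events clamped to a channel limit in the reporter/reference
   plot (detector saturation, "chart edge" events),
3. a reference-positive gate whose threshold is a high percentile of the
   reference channel in a mock (untransfected) sample, so only successfully
   transfected cells enter the median-ratio statistics.

Gates only drop rows; channel values are never modified, and the fixed
order debris -> edge -> reference is applied by :func:`apply_standard_gating`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientDataError, SchemaError
from .simulate import EventTable

__all__ = ["GateConfig", "GatedEvents", "remove_debris", "remove_edge_events",
           "reference_positive_gate", "apply_standard_gating"]


@dataclass(frozen=True)
class GateConfig:
    """Parameters of the three gating steps.

    The mock percentile (default 99.9) sets the reference-positive
    threshold; events must exceed it strictly.  Channel limits must match
    the acquisition settings (here: the generator's).
    """

    fsc_min: float = 2.0e4
    ssc_min: float = 1.0e4
    channel_min: float = 1.0
    channel_max: float = 16_777_215.0
    mock_percentile: float = 99.9
    debris_gate: bool = True
    edge_gate: bool = True
    reference_gate: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.mock_percentile < 100.0):
            raise ConfigError("mock_percentile must be in (0, 100)")
        if not (np.isfinite(self.fsc_min) and np.isfinite(self.ssc_min)):
            raise ConfigError("scatter bounds must be finite")
        if not self.channel_max > self.channel_min:
            raise ConfigError("channel_max must exceed channel_min")


@dataclass
class GatedEvents:
    """Surviving events plus per-step removal bookkeeping."""

    events: pd.DataFrame
    n_input: int
    n_debris_removed: int = 0
    n_edge_removed: int = 0
    n_reference_negative: int = 0
    reference_threshold: float | None = None
    sample_id: str | None = None

    @property
    def n_surviving(self) -> int:
        return len(self.events)

    def report(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "n_input": self.n_input,
            "n_debris_removed": self.n_debris_removed,
            "n_edge_removed": self.n_edge_removed,
            "n_reference_negative": self.n_reference_negative,
            "n_surviving": self.n_surviving,
            "reference_threshold": self.reference_threshold,
        }


def _frame(events) -> pd.DataFrame:
    return events.events if isinstance(events, EventTable) else events


def _require(df: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"event table is missing columns {missing}")


def remove_debris(events, cfg: GateConfig) -> pd.DataFrame:
    """Keep events with fsc >= fsc_min and ssc >= ssc_min, order preserved."""
    df = _frame(events)
    _require(df, ("fsc", "ssc"))
    keep = (df["fsc"].to_numpy() >= cfg.fsc_min) & (df["ssc"].to_numpy() >= cfg.ssc_min)
    return df.loc[keep]


def remove_edge_events(events, cfg: GateConfig) -> pd.DataFrame:
    """Drop events whose reporter or reference sits exactly on a channel limit."""
    df = _frame(events)
    _require(df, ("reporter", "reference"))
    rep = df["reporter"].to_numpy()
    ref = df["reference"].to_numpy()
    on_edge = (
        (rep == cfg.channel_min) | (rep == cfg.channel_max)
        | (ref == cfg.channel_min) | (ref == cfg.channel_max)
    )
    return df.loc[~on_edge]


def mock_reference_threshold(mock, cfg: GateConfig) -> float:
    """Reference-positive threshold: the mock's stated reference percentile."""
    mock_df = _frame(mock)
    _require(mock_df, ("reference",))
    if len(mock_df) == 0:
        raise InsufficientDataError("mock sample is empty; cannot place the reference gate")
    return float(np.percentile(mock_df["reference"].to_numpy(), cfg.mock_percentile))


def reference_positive_gate(events, mock, cfg: GateConfig) -> GatedEvents:
    """Keep events whose reference strictly exceeds the mock-derived threshold."""
    df = _frame(events)
    _require(df, ("reference",))
    threshold = mock_reference_threshold(mock, cfg)
    keep = df["reference"].to_numpy() > threshold
    out = df.loc[keep]
    return GatedEvents(
        events=out,
        n_input=len(df),
        n_reference_negative=int(len(df) - len(out)),
        reference_threshold=threshold,
        sample_id=getattr(events, "sample_id", None),
    )


def apply_standard_gating(events, mock, cfg: GateConfig) -> GatedEvents:
    """Debris -> edge -> reference-positive, with per-step counts.

    The mock sample is passed through the same debris and edge gates before
    its reference percentile is taken, mirroring how mock-derived gates are
    drawn on already-cleaned dot plots (edge-clamped mock events would
    otherwise drag the threshold to the channel maximum).
    """
    df = _frame(events)
    mock_df = _frame(mock)
    if cfg.debris_gate:
        mock_df = remove_debris(mock_df, cfg)
    if cfg.edge_gate:
        mock_df = remove_edge_events(mock_df, cfg)
    n_input = len(df)
    n_debris = n_edge = n_refneg = 0
    threshold = None
    if cfg.debris_gate:
        kept = remove_debris(df, cfg)
        n_debris = n_input - len(kept)
        df = kept
    if cfg.edge_gate:
        kept = remove_edge_events(df, cfg)
        n_edge = len(df) - len(kept)
        df = kept
    if cfg.reference_gate:
        gated = reference_positive_gate(df, mock_df, cfg)
        threshold = gated.reference_threshold
        n_refneg = gated.n_reference_negative
        df = gated.events
    return GatedEvents(
        events=df,
        n_input=n_input,
        n_debris_removed=n_debris,
        n_edge_removed=n_edge,
        n_reference_negative=n_refneg,
        reference_threshold=threshold,
        sample_id=getattr(events, "sample_id", None),
    )
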