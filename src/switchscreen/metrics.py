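"""Median-ratio normalization chain for cytometry and imaging readouts.

Flow cytometry:

    NI  = 1000 x median over cells of (reporter / reference)
    RI  = NI(trigger+) / NI(trigger-)
    relative reporter expression = RI / RI(No-gRNA sample)
    fold change FC = RI for an ON switch, 1/RI for an OFF switch
    fold activation = RI / RI(baseline sample)

Imaging (per reference-positive region):

    DV  = median of per-cell reporter/reference
    RV  = DV(trigger+) / DV(trigger-)
    NFC = RV / RV(No-gRNA sample)
    NFI = DV(condition) / DV(control condition)

Zero denominators raise :class:`~switchscreen.errors.DivisionDomainError`
rather than returning infinities, so degenerate samples surface loudly.
Medians of even-length samples are the mean of the two central order
statistics.  Replicates are summarized as mean +/- sample SD (n-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DivisionDomainError, InsufficientDataError, InvalidParameterError
from .gating import GatedEvents

__all__ = [
    "SampleSummary", "normalized_intensity", "relative_intensity",
    "relative_reporter_expression", "fold_change", "fold_activation",
    "imaging_defined_value", "imaging_relative_value",
    "imaging_normalized_fold_change", "normalized_fluorescence_intensity",
    "summarize_replicates",
]

NI_SCALE = 1000.0


@dataclass(frozen=True)
class SampleSummary:
    """Normalized intensity of one gated sample."""

    sample_id: str
    ni: float
    n_cells: int
    metadata: dict = field(default_factory=dict)


def _value(x) -> float:
    """Accept a SampleSummary or a bare number."""
    return float(x.ni) if isinstance(x, SampleSummary) else float(x)


def normalized_intensity(gated, sample_id: str | None = None, **metadata) -> SampleSummary:
    """NI = 1000 x median per-cell reporter/reference ratio."""
    if isinstance(gated, GatedEvents):
        df = gated.events
        sample_id = sample_id or gated.sample_id or ""
    else:
        df = gated
        sample_id = sample_id or ""
    if len(df) == 0:
        raise InsufficientDataError(f"sample {sample_id!r}: no surviving events")
    ref = df["reference"].to_numpy(dtype=float)
    if (ref <= 0).any():
        raise DivisionDomainError(f"sample {sample_id!r}: non-positive reference values")
    ratio = df["reporter"].to_numpy(dtype=float) / ref
    return SampleSummary(
        sample_id=sample_id,
        ni=NI_SCALE * float(np.median(ratio)),
        n_cells=len(df),
        metadata=metadata,
    )


def relative_intensity(ni_plus, ni_minus) -> float:
    """RI: trigger-plus NI over trigger-minus NI."""
    denom = _value(ni_minus)
    if denom <= 0:
        raise DivisionDomainError("trigger-minus NI must be > 0")
    return _value(ni_plus) / denom


def relative_reporter_expression(ri: float, ri_no_grna: float) -> float:
    """RI normalized by the No-gRNA control's RI; the control maps to 1."""
    if ri_no_grna <= 0:
        raise DivisionDomainError("No-gRNA RI must be > 0")
    return float(ri) / float(ri_no_grna)


def fold_change(ri: float, switch_type: str) -> float:
    """Orient RI so that FC >= 1 means switching in the expected direction:
    FC = RI for an ON switch, 1/RI for an OFF switch."""
    if ri <= 0:
        raise DivisionDomainError("RI must be > 0")
    if switch_type == "ON":
        return float(ri)
    if switch_type == "OFF":
        return 1.0 / float(ri)
    raise InvalidParameterError(f"switch_type must be OFF or ON, got {switch_type!r}")


def fold_activation(ri_sample: float, ri_baseline: float) -> float:
    """RI of a sample over the RI of the stated all-off baseline sample."""
    if ri_baseline <= 0:
        raise DivisionDomainError("baseline RI must be > 0")
    return float(ri_sample) / float(ri_baseline)


# -- imaging analogues -------------------------------------------------------

def imaging_defined_value(pixel_pairs: pd.DataFrame) -> float:
    """DV: median reporter/reference over records of a reference-positive area."""
    if len(pixel_pairs) == 0:
        raise InsufficientDataError("empty reference-positive area")
    ref = pixel_pairs["reference"].to_numpy(dtype=float)
    if (ref <= 0).any():
        raise DivisionDomainError("non-positive reference values in area")
    return float(np.median(pixel_pairs["reporter"].to_numpy(dtype=float) / ref))


def imaging_relative_value(dv_plus: float, dv_minus: float) -> float:
    """RV = DV(trigger+) / DV(trigger-)."""
    if dv_minus <= 0:
        raise DivisionDomainError("trigger-minus DV must be > 0")
    return float(dv_plus) / float(dv_minus)


def imaging_normalized_fold_change(rv: float, rv_no_grna: float) -> float:
    """NFC = RV / RV(No-gRNA sample); the control sample maps to 1."""
    if rv_no_grna <= 0:
        raise DivisionDomainError("No-gRNA RV must be > 0")
    return float(rv) / float(rv_no_grna)


def normalized_fluorescence_intensity(dv_condition: float, dv_control: float) -> float:
    """NFI = DV(condition) / DV(control condition); the control maps to 1."""
    if dv_control <= 0:
        raise DivisionDomainError("control DV must be > 0")
    return float(dv_condition) / float(dv_control)


def summarize_replicates(values: Sequence[float]) -> tuple[float, float | None]:
    """Mean and sample SD (n-1 denominator); SD is None for a single value."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("no replicate values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return mean, sd
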