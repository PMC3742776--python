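"""Raw-measurement preprocessing: qPCR spike-in normalisation and WMIS scoring.

Circulating miRNA levels are quantified by SYBR-green qPCR against a mix of
three synthetic C. elegans spike-in miRNAs added before RNA extraction.
Expression is the exponentiated cycle-threshold difference
``2^(mean(spike Ct) - target Ct)`` — one cycle fewer for the target doubles
the reported level.  The wall motion index score averages per-segment
contractility scores (0 hyperkinetic, 1 normal, 2 hypokinetic, 3 akinetic,
4 dyskinetic) over the up-to-16 analysed LV segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError

VALID_SEGMENT_SCORES = frozenset({0, 1, 2, 3, 4})


@dataclass(frozen=True)
class QpcrSample:
    """Cycle thresholds for one target miRNA and its three spike-in controls."""

    ct_target: float
    ct_spikes: tuple[float, float, float]

    def __post_init__(self):
        if len(self.ct_spikes) != 3:
            raise InputError(f"expected exactly 3 spike-in Ct values, got {len(self.ct_spikes)}")
        vals = (self.ct_target, *self.ct_spikes)
        if not all(np.isfinite(v) and v > 0 for v in vals):
            raise InputError(f"Ct values must be finite and positive, got {vals}")


@dataclass(frozen=True)
class SegmentScores:
    """Per-segment LV contractility scores, each in {0..4}."""

    scores: tuple[int, ...]

    def __post_init__(self):
        if not self.scores:
            raise InputError("no segment scores")
        bad = [s for s in self.scores if s not in VALID_SEGMENT_SCORES]
        if bad:
            raise InputError(f"segment scores must be in 0..4, got {bad}")


def expression_from_ct(sample: QpcrSample) -> float:
    """Spike-in-normalised expression: ``2^(mean(ct_spikes) - ct_target)``."""
    return float(2.0 ** (np.mean(sample.ct_spikes) - sample.ct_target))


def wmis_from_segments(segments: SegmentScores) -> float:
    """Wall motion index score: mean segment score (higher = more impaired)."""
    return float(np.mean(segments.scores))


def dichotomize_wmis(wmis: float, threshold: float = 1.2) -> int:
    """1 if ``wmis`` is strictly above ``threshold`` (impaired), else 0."""
    if not (0.0 <= wmis <= 4.0):
        raise InputError(f"WMIS {wmis} outside [0, 4]")
    return int(wmis > threshold)


def expressions_from_ct_table(ct_table: pd.DataFrame, log2: bool = True) -> pd.DataFrame:
    """Convert a long raw-Ct table into a wide patient x marker expression table.

    ``ct_table`` needs columns ``patient_id, marker, ct_target, ct_spike1,
    ct_spike2, ct_spike3``.  Returns one row per patient with one column per
    marker (log2 expression by default, matching the cohort convention).
    """
    required = {"patient_id", "marker", "ct_target", "ct_spike1", "ct_spike2", "ct_spike3"}
    missing = required - set(ct_table.columns)
    if missing:
        raise InputError(f"raw Ct table missing columns {sorted(missing)}")
    out = {}
    for rec in ct_table.to_dict("records"):
        sample = QpcrSample(
            float(rec["ct_target"]),
            (float(rec["ct_spike1"]), float(rec["ct_spike2"]), float(rec["ct_spike3"])),
        )
        level = expression_from_ct(sample)
        out.setdefault(rec["patient_id"], {})[rec["marker"]] = (
            float(np.log2(level)) if log2 else level
        )
    wide = pd.DataFrame.from_dict(out, orient="index").sort_index()
    wide.index.name = "patient_id"
    return wide
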