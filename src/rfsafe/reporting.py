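"""Report assembly: tier tables, difference histograms, audit trails.

Rendering is a pure function of its inputs; re-rendering the JSON report
produces an identical document.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .safety_tiers import TierAssessment
from .validation import ModelingUncertaintyResult, modeling_uncertainty

__all__ = ["render_report", "histogram_summary", "report_to_csv", "report_to_json"]

# printed precision mirrors conventional safety reports:
# percentages to 0 decimals, safety factors / pSAR / power to 1
_COLUMNS = [
    "label",
    "tier",
    "modeling_pct",
    "intersubject_pct",
    "power_monitoring_pct",
    "safety_factor",
    "buffer",
    "psar_sim_mean",
    "corrected_psar",
    "total_power_limit",
    "per_channel_power_limit",
]


def _fmt_pct(x: "float | None") -> str:
    return "-" if x is None else f"{x * 100:.0f}%"


def _fmt1(x: "float | None") -> str:
    return "-" if x is None else f"{x:.1f}"


def _row(a: TierAssessment) -> dict:
    b = a.budget
    return {
        "label": a.config.label or f"tier {a.config.tier}",
        "tier": a.config.tier,
        "modeling_pct": _fmt_pct(b.modeling if b else None),
        "intersubject_pct": _fmt_pct(b.intersubject if b else None),
        "power_monitoring_pct": _fmt_pct(b.power_monitoring if b else None),
        "safety_factor": _fmt1(a.safety_factor),
        "buffer": _fmt1(a.config.buffer) if a.config.tier == 2 else "-",
        "psar_sim_mean": _fmt1(a.config.psar_sim_mean),
        "corrected_psar": _fmt1(a.corrected_psar),
        "total_power_limit": _fmt1(a.total_power_limit),
        "per_channel_power_limit": f"{a.per_channel_power_limit:.3f}"
        if a.config.tier == 1
        else _fmt1(a.per_channel_power_limit),
    }


def render_report(
    assessments: Sequence[TierAssessment],
    uncertainty_results: Iterable[ModelingUncertaintyResult] = (),
    fit_reports: Iterable[dict] = (),
) -> dict:
    """Assemble a report document: one table row per assessment plus the
    full-precision audit payload.

    Returns a JSON-serializable dict with ``table`` (rounded, table-shaped
    rows) and ``assessments`` (full precision + provenance).
    """
    assessments = list(assessments)
    if not assessments:
        raise ValueError("need at least one assessment")
    units = {a.config.sar_limit for a in assessments}
    if len({a.config.rounding_mode for a in assessments}) > 1:
        raise ValueError("assessments mix rounding modes; render them separately")
    table = [_row(a) for a in assessments]
    doc = {
        "table": table,
        "assessments": [a.to_dict() for a in assessments],
        "modeling_uncertainty": [
            {
                "final": r.final,
                "quantile": r.quantile,
                "worst": {
                    "shim": r.worst.shim_name,
                    "modality": r.worst.modality.value,
                },
                "per_comparison": [
                    {
                        "shim": c.shim_name,
                        "modality": c.modality.value,
                        "uncertainty": c.uncertainty,
                        "raw_quantile": c.raw_quantile,
                        "n_voxels": c.n_voxels,
                    }
                    for c in r.per_comparison
                ],
            }
            for r in uncertainty_results
        ],
        "population_fits": list(fit_reports),
        "sar_limits_w_per_kg": sorted(units),
    }
    return doc


def report_to_csv(doc: dict, path: "str | Path") -> Path:
    path = Path(path)
    pd.DataFrame(doc["table"], columns=_COLUMNS).to_csv(path, index=False)
    return path


def report_to_json(doc: dict, path: "str | Path") -> Path:
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True))
    return path


def histogram_summary(
    diffs: np.ndarray, n_bins: int = 50, quantile: float = 0.999
) -> dict:
    """Histogram of a signed-difference grid plus the quantile marker.

    The marker equals ``modeling_uncertainty`` (unclamped) on the same data,
    i.e. the red-line position in a difference histogram.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = np.asarray(diffs, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite values to histogram")
    counts, edges = np.histogram(values, bins=n_bins)
    marker = modeling_uncertainty(values, quantile, clamp=False)
    return {
        "bin_edges": edges.tolist(),
        "counts": counts.tolist(),
        "n": int(values.size),
        "quantile": quantile,
        "quantile_marker": marker,
    }
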