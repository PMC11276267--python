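"""JSON serialization of systems and CSV serialization of tradeoff curves."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .curve import RBCurve, per_source_curves
from .discrete import Channel, DiscreteDistribution, SourceSystem
from .errors import ValidationError

__all__ = [
    "system_to_dict",
    "system_from_dict",
    "save_system",
    "load_system",
    "curve_to_frame",
    "save_curve",
    "load_curve_frame",
]


def system_to_dict(system: SourceSystem) -> dict:
    """JSON-ready description: target marginal, weights and source channels."""
    return {
        "y_outcomes": list(system.p_y.outcomes),
        "p_y": [float(p) for p in system.p_y.probs],
        "nu_s": [float(p) for p in system.nu_s.probs],
        "sources": [
            {
                "name": name,
                "outcomes": list(ch.output_outcomes),
                "channel": [[float(p) for p in row] for row in ch.probs],
            }
            for name, ch in system.sources
        ],
    }


def system_from_dict(doc: dict) -> SourceSystem:
    try:
        p_y_probs = doc["p_y"]
        sources_doc = doc["sources"]
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"system document missing required key: {exc}") from exc
    y_outcomes = doc.get("y_outcomes") or [str(i) for i in range(len(p_y_probs))]
    p_y = DiscreteDistribution(y_outcomes, p_y_probs)
    sources = []
    for i, src in enumerate(sources_doc):
        try:
            name = src.get("name", f"X{i + 1}")
            ch = Channel(y_outcomes, src["outcomes"], src["channel"])
        except KeyError as exc:
            raise ValidationError(f"source {i}: missing key {exc}") from exc
        sources.append((name, ch))
    nu = doc.get("nu_s")
    nu_s = None if nu is None else DiscreteDistribution(
        [name for name, _ in sources], nu)
    return SourceSystem(p_y, sources, nu_s)


def save_system(system: SourceSystem, path) -> None:
    Path(path).write_text(json.dumps(system_to_dict(system), indent=2) + "\n")


def load_system(path) -> SourceSystem:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"invalid JSON in {path}: {exc}") from exc
    return system_from_dict(doc)


def curve_to_frame(curve: RBCurve) -> pd.DataFrame:
    """One row per beta: totals plus per-source prediction/compression columns."""
    traces = per_source_curves(curve)
    data = {
        "beta": curve.betas,
        "prediction_bits": curve.predictions,
        "compression_bits": curve.compressions,
        "objective_bits": np.array([p.objective for p in curve.points]),
        "converged": np.array([p.converged for p in curve.points]),
        "n_iter": np.array([p.n_iter for p in curve.points]),
    }
    for name, trace in traces.items():
        data[f"pred_src_{name}"] = trace[:, 1]
        data[f"comp_src_{name}"] = trace[:, 0]
    return pd.DataFrame(data)


def save_curve(curve: RBCurve, path) -> None:
    curve_to_frame(curve).to_csv(path, index=False, float_format="%.12g")


def load_curve_frame(path) -> pd.DataFrame:
    return pd.read_csv(path)
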