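"""Turn predicted DVHs into optimizer-ready objective sets.

The strategy switch: by default each OAR's objectives are read off the lower
bound of the 95% prediction band (the aggressive, RapidPlan-style choice that
maximizes sparing pressure).  For advanced T3/T4 cases, OARs adjacent to or
overlapping the target area — optic chiasm, optic nerve, pituitary, and inner
ear — instead use the predicted mean, trading a little sparing pressure for
achievable target coverage.  The per-structure choice is recorded in the
strategy log.  Target objectives are emitted from the prescription
configuration, not predicted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .dvh_model import PredictedDVH, T_STAGES
from .histograms import CumulativeCurve

__all__ = [
    "Objective",
    "ObjectiveSet",
    "default_adjacent_oars",
    "generate_objectives",
    "DEFAULT_SAMPLE_VOLUMES",
    "DEFAULT_PRIORITIES",
]

ObjectiveKind = Literal["upper_dvh_point", "lower_dvh_point", "max_dose", "mean_dose"]
Strategy = Literal["mean", "lower95"]

_ADJACENT_OARS = frozenset({"optic_chiasm", "optic_nerve", "pituitary", "inner_ear"})

DEFAULT_SAMPLE_VOLUMES = (2.0, 30.0, 50.0, 70.0)

# 3-tier priority scheme keyed to the quality-metric organ levels
DEFAULT_PRIORITIES = {"targets": 100, "critical": 80, "subcritical": 60, "other": 40}


def default_adjacent_oars() -> frozenset[str]:
    """OARs adjacent to or overlapping the target area that switch to the
    predicted-mean strategy in advanced T3/T4 cases."""
    return _ADJACENT_OARS


@dataclass(frozen=True)
class Objective:
    structure: str
    kind: ObjectiveKind
    dose_gy: float
    volume_pct: float | None = None
    priority: int = 40

    def __post_init__(self) -> None:
        if self.dose_gy < 0:
            raise ValueError("objective dose must be >= 0")
        if self.kind in ("upper_dvh_point", "lower_dvh_point"):
            if self.volume_pct is None or not 0 < self.volume_pct < 100:
                raise ValueError("DVH-point objectives need volume in (0, 100)%")
        if self.priority <= 0:
            raise ValueError("priority must be a positive integer")


@dataclass
class ObjectiveSet:
    entries: list[Objective]
    strategy_log: dict[str, Strategy] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "structure": e.structure,
                    "kind": e.kind,
                    "dose_Gy": e.dose_gy,
                    "volume_pct": e.volume_pct,
                    "priority": e.priority,
                    "strategy": self.strategy_log.get(e.structure, ""),
                }
                for e in self.entries
            ]
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "entries": self.to_dataframe().to_dict(orient="records"),
                "strategy_log": dict(self.strategy_log),
            },
            indent=2,
        )


def dose_at_volume_pct(curve: CumulativeCurve, volume_pct: float) -> float:
    """Dose (Gy) at a given cumulative volume on a non-increasing DVH, by
    linear interpolation (largest dose whose ordinate still reaches it)."""
    o, a = curve.ordinate, curve.abscissa
    if volume_pct >= o[0]:
        return float(a[0])
    if volume_pct <= o[-1]:
        return float(a[-1])
    idx = int(np.nonzero(o >= volume_pct)[0][-1])
    if o[idx] == volume_pct:
        return float(a[idx])
    # o[idx] > volume_pct > o[idx + 1]
    t = (o[idx] - volume_pct) / (o[idx] - o[idx + 1])
    return float(a[idx] + t * (a[idx + 1] - a[idx]))


def generate_objectives(
    predictions: dict[str, PredictedDVH],
    t_stage: str,
    adjacent_oars: frozenset[str] | set[str] | None = None,
    sample_volumes: tuple[float, ...] = DEFAULT_SAMPLE_VOLUMES,
    priorities: dict[str, int] | None = None,
    oar_levels: dict[str, str] | None = None,
    target_prescriptions: dict[str, tuple[float, float]] | None = None,
) -> ObjectiveSet:
    """Build the starting objective set from per-OAR DVH predictions.

    For each OAR the source curve is the predicted mean when
    ``t_stage in {T3, T4}`` and the OAR is in the adjacent set, otherwise the
    lower bound of the 95% band; upper DVH-point objectives are read off that
    curve at each sample volume.  ``target_prescriptions`` maps target name to
    ``(prescription_gy, coverage_pct)`` and emits lower DVH-point objectives.
    """
    if not predictions:
        raise ValueError("predictions must be non-empty")
    if t_stage not in T_STAGES:
        raise ValueError(f"unknown t_stage {t_stage!r}; expected one of {T_STAGES}")
    adjacent = _ADJACENT_OARS if adjacent_oars is None else frozenset(adjacent_oars)
    prio = dict(DEFAULT_PRIORITIES)
    if priorities:
        prio.update(priorities)
    levels = oar_levels or {}

    entries: list[Objective] = []
    strategy_log: dict[str, Strategy] = {}
    if target_prescriptions:
        for name, (rx, coverage) in target_prescriptions.items():
            entries.append(
                Objective(
                    structure=name,
                    kind="lower_dvh_point",
                    dose_gy=rx,
                    volume_pct=coverage,
                    priority=prio["targets"],
                )
            )

    for name in sorted(predictions):
        pred = predictions[name]
        use_mean = t_stage in ("T3", "T4") and _base_name(name) in adjacent
        source = pred.mean if use_mean else pred.lower95
        strategy_log[name] = "mean" if use_mean else "lower95"
        level = levels.get(name, _default_level(name))
        priority = prio.get(level, prio["other"])
        for v in sample_volumes:
            entries.append(
                Objective(
                    structure=name,
                    kind="upper_dvh_point",
                    dose_gy=dose_at_volume_pct(source, v),
                    volume_pct=float(v),
                    priority=priority,
                )
            )
    return ObjectiveSet(entries=entries, strategy_log=strategy_log)


def _base_name(name: str) -> str:
    """Strip a laterality suffix so paired organs match the adjacent set."""
    for suffix in ("_l", "_r", "_left", "_right"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


_CRITICAL = {"brainstem", "spinal_cord", "optic_chiasm", "optic_nerve", "temporal_lobe"}
_SUBCRITICAL = {"mandible", "tmj", "parotid", "lens", "pituitary"}


def _default_level(name: str) -> str:
    base = _base_name(name)
    if base in _CRITICAL:
        return "critical"
    if base in _SUBCRITICAL:
        return "subcritical"
    return "other"
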