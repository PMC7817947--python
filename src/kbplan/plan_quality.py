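"""Dosimetric indices and the 200-point NPC plan-quality metric.

Indices
-------
- ``CI`` (Paddick conformity index): ``(V_Tref/V_T) * (V_Tref/V_ref)`` where
  ``V_Tref`` is the target volume covered by the reference isodose, ``V_T``
  the target volume, ``V_ref`` the reference-isodose volume; 1 is perfect.
- ``HI`` (homogeneity index): ``(D_2% - D_98%) / D_50%``; 0 is perfectly
  homogeneous.
- ``D_x%`` (dose to the hottest x% of volume), ``D_1cc``, ``D_max``
  (true maximum), ``D_mean``, ``V_x`` (percent of volume receiving at least
  x Gy) and target ``V_x%`` (x percent of that target's prescription).

Scoring
-------
The default table awards up to 200 points over four levels: targets (100),
critical organs (60), sub-critical organs (25), other normal organs (15).
Band thresholds are strict inequalities; a value exactly on a threshold falls
into the next (worse) band, and the last band of each entry acts as a
catch-all.  Paired organs (parotid, lens, eye, inner ear, TMJ, temporal lobe,
optic nerve) are scored per side and the entry receives the mean of the two
side scores (a worst-side mode is available).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core_grid import DoseGrid, StructureMask, structure_volume
from .histograms import CumulativeCurve, compute_dvh
from .objectives import dose_at_volume_pct

__all__ = [
    "conformity_index",
    "conformity_index_from_grids",
    "homogeneity_index",
    "extract_index",
    "ScoreEntry",
    "ScoreTableConfig",
    "PQMResult",
    "default_score_table",
    "score_plan",
    "PlanMetrics",
    "compute_plan_metrics",
]

logger = logging.getLogger(__name__)

Level = Literal["targets", "critical", "subcritical", "other"]

LEVEL_MAXIMA = {"targets": 100, "critical": 60, "subcritical": 25, "other": 15}


# ---------------------------------------------------------------------------
# indices

def conformity_index(v_tref: float, v_t: float, v_ref: float) -> float:
    """Paddick CI = (V_Tref/V_T) * (V_Tref/V_ref)."""
    if v_t <= 0 or v_ref <= 0:
        raise ValueError("CI undefined: target and reference-isodose volumes must be > 0")
    if not -1e-9 <= v_tref <= min(v_t, v_ref) + 1e-9:
        raise ValueError("V_Tref must lie within [0, min(V_T, V_ref)]")
    return (v_tref / v_t) * (v_tref / v_ref)


def conformity_index_from_grids(
    target: StructureMask, dose: DoseGrid, reference_dose_gy: float | None = None
) -> float:
    """CI evaluated directly on the grids; the reference isodose defaults to
    the plan prescription."""
    if target.grid != dose.grid:
        raise ValueError("target and dose must live on the same grid")
    if target.is_empty():
        raise ValueError("CI undefined for empty target")
    ref = dose.prescription if reference_dose_gy is None else reference_dose_gy
    covered = dose.dose >= ref
    vox_cc = target.grid.voxel_volume_cc
    v_t = target.voxel_count * vox_cc
    v_ref = int(np.count_nonzero(covered)) * vox_cc
    v_tref = int(np.count_nonzero(covered & target.occupancy)) * vox_cc
    return conformity_index(v_tref, v_t, v_ref)


def _dose_at_volume_step(curve: CumulativeCurve, volume_pct: float) -> float:
    """Right-continuous inverse of a cumulative DVH on its own grid: the
    largest sampled dose whose ordinate still reaches ``volume_pct``.

    For histograms of voxel data this is exact whenever the voxel doses lie
    on bin edges (plateau edges are read exactly, e.g. D_x% of a uniform
    dose is that dose); otherwise it is within one bin width.
    """
    idx = np.nonzero(curve.ordinate >= volume_pct)[0]
    return float(curve.abscissa[idx[-1]]) if idx.size else float(curve.abscissa[0])


def homogeneity_index(dvh: CumulativeCurve) -> float:
    """HI = (D_2% - D_98%) / D_50% from a target DVH."""
    d50 = _dose_at_volume_step(dvh, 50.0)
    if d50 <= 0:
        raise ValueError("HI undefined: D_50% is zero")
    return (_dose_at_volume_step(dvh, 2.0) - _dose_at_volume_step(dvh, 98.0)) / d50


_INDEX_RE = re.compile(
    r"^(?:"
    r"(?P<dmax>Dmax)|(?P<dmean>Dmean)|(?P<d1cc>D1cc)|"
    r"D(?P<dpct>[0-9.]+)%|"
    r"V(?P<vgy>[0-9.]+)Gy|"
    r"V(?P<vrel>[0-9.]+)%(?:Rx)?"
    r")$"
)


def extract_index(
    dvh: CumulativeCurve, index_spec: str, prescription_gy: float | None = None
) -> float:
    """Evaluate a dosimetric index named like ``Dmax``, ``D1cc``, ``Dmean``,
    ``D1%``, ``V60Gy`` or ``V98%`` (percent of prescription) on a cumulative
    DVH.

    ``D_1cc`` on a structure smaller than 1 cc falls back to ``Dmax`` with a
    logged warning.  ``D_mean`` integrates the differential histogram, exact
    to within half a bin width.
    """
    m = _INDEX_RE.match(index_spec)
    if m is None:
        raise ValueError(f"unrecognized index spec {index_spec!r}")
    o, a = dvh.ordinate, dvh.abscissa
    if m.group("dmax"):
        hot = np.nonzero(o > 1e-9)[0]
        return float(a[hot[-1]]) if hot.size else float(a[0])
    if m.group("dmean"):
        drop = (o[:-1] - o[1:]) / 100.0
        mids = (a[:-1] + a[1:]) / 2.0
        return float((drop * mids).sum() + o[-1] / 100.0 * a[-1])
    if m.group("d1cc"):
        if dvh.total_volume_cc < 1.0:
            logger.warning(
                "structure %s is %.3f cc < 1 cc; D_1cc falls back to D_max",
                dvh.structure_name,
                dvh.total_volume_cc,
            )
            return extract_index(dvh, "Dmax")
        return _dose_at_volume_step(dvh, 100.0 * (1.0 / dvh.total_volume_cc))
    if m.group("dpct"):
        return _dose_at_volume_step(dvh, float(m.group("dpct")))
    if m.group("vgy"):
        return float(np.interp(float(m.group("vgy")), a, o))
    if m.group("vrel"):
        if prescription_gy is None:
            raise ValueError(f"{index_spec!r} needs the target prescription dose")
        level = float(m.group("vrel")) / 100.0 * prescription_gy
        return float(np.interp(level, a, o))
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# score table

Comparator = Literal["<", ">"]


@dataclass(frozen=True)
class ScoreEntry:
    structure: str
    index: str
    bands: tuple[tuple[Comparator, float], ...]
    points: tuple[float, ...]
    level: Level

    def __post_init__(self) -> None:
        if len(self.bands) != len(self.points):
            raise ValueError(
                f"{self.structure}/{self.index}: {len(self.bands)} bands but "
                f"{len(self.points)} point values"
            )
        if any(c not in ("<", ">") for c, _ in self.bands):
            raise ValueError("band comparators must be '<' or '>'")
        if self.level not in LEVEL_MAXIMA:
            raise ValueError(f"unknown level {self.level!r}")

    @property
    def best_points(self) -> float:
        return max(self.points)

    def score_value(self, value: float) -> tuple[float, str]:
        """Points for a value: first satisfied band wins; strict comparisons,
        last band is the catch-all."""
        for (cmp_, thr), pts in zip(self.bands, self.points):
            if (cmp_ == "<" and value < thr) or (cmp_ == ">" and value > thr):
                return pts, f"{cmp_}{thr:g}"
        return self.points[-1], f"{self.bands[-1][0]}{self.bands[-1][1]:g} (catch-all)"


@dataclass
class ScoreTableConfig:
    entries: list[ScoreEntry]
    level_maxima: dict[str, int] = field(default_factory=lambda: dict(LEVEL_MAXIMA))
    paired_mode: Literal["average", "worst"] = "average"
    paired_suffixes: tuple[str, str] = ("_l", "_r")
    missing_policy: Literal["zero", "error"] = "zero"

    def validate_maxima(self) -> None:
        sums: dict[str, float] = {}
        for e in self.entries:
            sums[e.level] = sums.get(e.level, 0.0) + e.best_points
        for level, expected in self.level_maxima.items():
            if abs(sums.get(level, 0.0) - expected) > 1e-9:
                raise ValueError(
                    f"level {level!r} best-band sum {sums.get(level, 0.0)} != {expected}"
                )

    def level_best_sums(self) -> dict[str, float]:
        sums: dict[str, float] = {}
        for e in self.entries:
            sums[e.level] = sums.get(e.level, 0.0) + e.best_points
        return sums

    def to_json(self) -> str:
        return json.dumps(
            {
                "level_maxima": self.level_maxima,
                "paired_mode": self.paired_mode,
                "paired_suffixes": list(self.paired_suffixes),
                "missing_policy": self.missing_policy,
                "entries": [
                    {
                        "structure": e.structure,
                        "index": e.index,
                        "bands": [[c, t] for c, t in e.bands],
                        "points": list(e.points),
                        "level": e.level,
                    }
                    for e in self.entries
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScoreTableConfig":
        d = json.loads(text)
        entries = [
            ScoreEntry(
                structure=e["structure"],
                index=e["index"],
                bands=tuple((c, float(t)) for c, t in e["bands"]),
                points=tuple(e["points"]),
                level=e["level"],
            )
            for e in d["entries"]
        ]
        return cls(
            entries=entries,
            level_maxima=d.get("level_maxima", dict(LEVEL_MAXIMA)),
            paired_mode=d.get("paired_mode", "average"),
            paired_suffixes=tuple(d.get("paired_suffixes", ("_l", "_r"))),
            missing_policy=d.get("missing_policy", "zero"),
        )


def _e(structure, index, bands, points, level) -> ScoreEntry:
    return ScoreEntry(structure, index, tuple(bands), tuple(points), level)


def default_score_table() -> ScoreTableConfig:
    """The built-in 200-point NPC quality-metric table.

    Note the temporal-lobe D_max row: the printed bands are <60 / >60 / >65,
    whose middle band is read as the 60-65 Gy range and encoded accordingly
    (<60, then <65, then the >65 catch-all).
    """
    entries = [
        # targets (100)
        _e("pgtv", "V98%", [(">", 98), (">", 95), ("<", 95)], [10, 6, 0], "targets"),
        _e("pgtv", "V110%", [("<", 10), ("<", 20), (">", 20)], [10, 6, 0], "targets"),
        _e("pgtv", "CI", [(">", 0.8), (">", 0.6), ("<", 0.6)], [10, 6, 3], "targets"),
        _e("pgtv", "HI", [("<", 0.05), ("<", 0.10), (">", 0.10)], [10, 6, 3], "targets"),
        _e("ptv1", "V98%", [(">", 98), (">", 95), ("<", 95)], [10, 6, 3], "targets"),
        _e("ptv1", "CI", [(">", 0.8), (">", 0.6), ("<", 0.6)], [10, 6, 3], "targets"),
        _e("ptv1", "HI", [("<", 0.05), ("<", 0.10), (">", 0.10)], [10, 6, 3], "targets"),
        _e("ptv2", "V98%", [(">", 98), (">", 95), ("<", 95)], [10, 6, 3], "targets"),
        _e("ptv2", "CI", [(">", 0.8), (">", 0.6), ("<", 0.6)], [10, 6, 3], "targets"),
        _e("ptv2", "HI", [("<", 0.05), ("<", 0.10), (">", 0.10)], [10, 6, 3], "targets"),
        # critical organs (60)
        _e("brainstem", "D1cc", [("<", 54), ("<", 60), (">", 60)], [12, 6, 0], "critical"),
        _e("spinal_cord", "D1cc", [("<", 35), ("<", 45), ("<", 50), (">", 50)], [12, 6, 3, 0], "critical"),
        _e("optic_chiasm", "D1%", [("<", 54), ("<", 60), (">", 60)], [12, 6, 0], "critical"),
        _e("optic_nerve", "D1%", [("<", 54), ("<", 60), (">", 60)], [12, 6, 0], "critical"),
        _e("temporal_lobe", "V60Gy", [("<", 10), (">", 10)], [4, 2], "critical"),
        _e("temporal_lobe", "Dmax", [("<", 60), ("<", 65), (">", 65)], [4, 2, 0], "critical"),
        _e("temporal_lobe", "Dmean", [("<", 36), (">", 36)], [4, 2], "critical"),
        # sub-critical organs (25)
        _e("mandible", "Dmax", [("<", 70), ("<", 75), (">", 75)], [5, 3, 1], "subcritical"),
        _e("tmj", "Dmax", [("<", 70), ("<", 75), (">", 75)], [5, 3, 1], "subcritical"),
        _e("parotid", "Dmean", [("<", 26), (">", 26)], [2, 0], "subcritical"),
        _e("parotid", "V50Gy", [("<", 30), (">", 30)], [3, 1], "subcritical"),
        _e("lens", "D1%", [("<", 6), ("<", 10), (">", 10)], [5, 3, 1], "subcritical"),
        _e("pituitary", "D1%", [("<", 60), ("<", 65), (">", 65)], [5, 3, 1], "subcritical"),
        # other normal organs (15)
        _e("eye", "D1%", [("<", 50), (">", 50)], [1, 0], "other"),
        _e("eye", "Dmean", [("<", 35), (">", 35)], [2, 1], "other"),
        _e("inner_ear", "Dmean", [("<", 50), (">", 50)], [4, 2], "other"),
        _e("larynx", "Dmean", [("<", 45), (">", 45)], [4, 2], "other"),
        _e("tongue", "Dmean", [("<", 55), (">", 55)], [4, 2], "other"),
    ]
    table = ScoreTableConfig(entries=entries)
    table.validate_maxima()
    return table


# ---------------------------------------------------------------------------
# scoring

@dataclass
class PlanMetrics:
    """Per-structure map of index name -> value (paired organs appear once
    per side, e.g. ``parotid_l`` and ``parotid_r``)."""

    values: dict[str, dict[str, float]]

    def get(self, structure: str, index: str) -> float | None:
        return self.values.get(structure, {}).get(index)


@dataclass
class PQMResult:
    rows: list[dict]
    subtotals: dict[str, float]
    total: float

    def to_json(self) -> str:
        return json.dumps(
            {"rows": self.rows, "subtotals": self.subtotals, "total": self.total},
            indent=2,
        )

    def to_text(self) -> str:
        lines = [f"{'structure':<16} {'index':<8} {'value':>10} {'band':>18} {'points':>7}"]
        for r in self.rows:
            val = "missing" if r["value"] is None else f"{r['value']:.3f}"
            lines.append(
                f"{r['structure']:<16} {r['index']:<8} {val:>10} {r['band']:>18} {r['points']:>7.1f}"
            )
        lines.append("-" * 62)
        for level, sub in self.subtotals.items():
            lines.append(f"{level:<25} {sub:>7.1f}")
        lines.append(f"{'TOTAL':<25} {self.total:>7.1f}")
        return "\n".join(lines)


def _entry_sides(metrics: PlanMetrics, entry: ScoreEntry, table: ScoreTableConfig):
    """Resolve the metric value(s) for an entry: a direct structure match, or
    the paired left/right sides."""
    direct = metrics.get(entry.structure, entry.index)
    if direct is not None:
        return [(entry.structure, direct)]
    sides = []
    for suffix in table.paired_suffixes:
        v = metrics.get(entry.structure + suffix, entry.index)
        if v is not None:
            sides.append((entry.structure + suffix, v))
    return sides


def score_plan(metrics: PlanMetrics, table: ScoreTableConfig) -> PQMResult:
    """Score a plan against a banded table.

    The result is deterministic and independent of entry ordering; a missing
    metric scores 0 with a warning unless ``missing_policy`` is ``error``.
    """
    rows: list[dict] = []
    subtotals = {level: 0.0 for level in table.level_maxima}
    for entry in table.entries:
        sides = _entry_sides(metrics, entry, table)
        if not sides:
            msg = f"no metric for {entry.structure}/{entry.index}"
            if table.missing_policy == "error":
                raise ValueError(msg)
            logger.warning("%s; scored 0", msg)
            rows.append(
                {
                    "structure": entry.structure,
                    "index": entry.index,
                    "value": None,
                    "band": "missing",
                    "points": 0.0,
                    "level": entry.level,
                    "sides": [],
                }
            )
            continue
        scored = [(name, v, *entry.score_value(v)) for name, v in sides]
        pts = [s[2] for s in scored]
        points = float(np.mean(pts)) if table.paired_mode == "average" else float(min(pts))
        rows.append(
            {
                "structure": entry.structure,
                "index": entry.index,
                "value": float(np.mean([s[1] for s in scored])),
                "band": scored[0][3] if len(scored) == 1 else "paired",
                "points": points,
                "level": entry.level,
                "sides": [
                    {"structure": n, "value": v, "band": b, "points": p}
                    for n, v, p, b in scored
                ],
            }
        )
        subtotals[entry.level] = subtotals.get(entry.level, 0.0) + points
    total = float(sum(subtotals.values()))
    return PQMResult(rows=rows, subtotals=subtotals, total=total)


def compute_plan_metrics(
    masks: dict[str, StructureMask],
    dose: DoseGrid,
    table: ScoreTableConfig,
    prescriptions: dict[str, float],
    bin_width: float = 0.1,
) -> PlanMetrics:
    """Evaluate every index a score table needs from masks and dose.

    ``prescriptions`` maps target-structure names to their prescription dose
    in Gy (used for CI reference isodoses and the relative V_x% levels).
    DVHs are computed once per structure and reused across indices.
    """
    dvh_cache: dict[str, CumulativeCurve] = {}

    def _dvh(name: str) -> CumulativeCurve:
        if name not in dvh_cache:
            dvh_cache[name] = compute_dvh(masks[name], dose, bin_width=bin_width)
        return dvh_cache[name]

    values: dict[str, dict[str, float]] = {}
    for entry in table.entries:
        candidates = [entry.structure] + [
            entry.structure + s for s in table.paired_suffixes
        ]
        for name in candidates:
            if name not in masks:
                continue
            rx = prescriptions.get(entry.structure)
            if entry.index == "CI":
                if rx is None:
                    raise ValueError(f"CI for {name} needs a prescription dose")
                v = conformity_index_from_grids(masks[name], dose, reference_dose_gy=rx)
            elif entry.index == "HI":
                v = homogeneity_index(_dvh(name))
            else:
                v = extract_index(_dvh(name), entry.index, prescription_gy=rx)
            values.setdefault(name, {})[entry.index] = float(v)
    return PlanMetrics(values=values)
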