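"""Cumulative dose-volume (DVH) and distance-to-target (DTH) histograms.

Both share one curve container: ordinate is percent of structure volume, the
abscissa is Gy for DVHs and signed mm for DTHs.  The DVH uses the
"dose-at-least" convention (ordinate at d = % of volume receiving >= d, hence
non-increasing); the DTH is the fraction of OAR volume within each signed
distance of the target surface (non-decreasing).  Distances are negative
inside the target, zero on its surface voxels, positive outside.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .core_grid import (
    DoseGrid,
    StructureMask,
    signed_distance_to_surface,
    structure_volume,
)

__all__ = [
    "CumulativeCurve",
    "compute_dvh",
    "compute_dth",
    "resample_curve",
    "write_curve_csv",
    "read_curve_csv",
]

CurveKind = Literal["dvh", "dth"]

_MONOTONE_TOL = 1e-9


@dataclass
class CumulativeCurve:
    """Cumulative histogram curve.

    ``ordinate[i]`` is the percent of the structure volume receiving at least
    ``abscissa[i]`` (dvh) or lying within signed distance ``abscissa[i]`` of
    the target surface (dth).
    """

    abscissa: np.ndarray
    ordinate: np.ndarray
    kind: CurveKind
    structure_name: str = ""
    total_volume_cc: float = 0.0

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.ordinate = np.asarray(self.ordinate, dtype=float)
        if self.abscissa.ndim != 1 or self.abscissa.shape != self.ordinate.shape:
            raise ValueError("abscissa and ordinate must be matching 1-D arrays")
        if self.abscissa.size < 2:
            raise ValueError("a curve needs at least two points")
        if np.any(np.diff(self.abscissa) < 0):
            raise ValueError("abscissa must be sorted ascending")
        if self.kind not in ("dvh", "dth"):
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if self.ordinate.min() < -_MONOTONE_TOL or self.ordinate.max() > 100 + _MONOTONE_TOL:
            raise ValueError("ordinate must lie within [0, 100]")
        steps = np.diff(self.ordinate)
        if self.kind == "dvh" and np.any(steps > _MONOTONE_TOL):
            raise ValueError("dvh ordinate must be monotone non-increasing")
        if self.kind == "dth" and np.any(steps < -_MONOTONE_TOL):
            raise ValueError("dth ordinate must be monotone non-decreasing")

    def copy(self) -> "CumulativeCurve":
        return replace(self, abscissa=self.abscissa.copy(), ordinate=self.ordinate.copy())


def compute_dvh(mask: StructureMask, dose: DoseGrid, bin_width: float = 0.1) -> CumulativeCurve:
    """Cumulative DVH of ``mask`` on ``dose`` with edges at multiples of
    ``bin_width`` from 0 to just past the maximum structure dose."""
    if mask.grid != dose.grid:
        raise ValueError("mask and dose must live on the same grid")
    if mask.is_empty():
        raise ValueError(f"DVH undefined for empty structure {mask.name!r}")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    d = np.sort(dose.dose[mask.occupancy])
    n = d.size
    n_edges = int(np.floor(d[-1] / bin_width)) + 2
    edges = bin_width * np.arange(n_edges)
    # count of voxels with dose >= edge, exactly as the per-voxel definition
    ordinate = (n - np.searchsorted(d, edges, side="left")) * 100.0 / n
    return CumulativeCurve(
        abscissa=edges,
        ordinate=ordinate,
        kind="dvh",
        structure_name=mask.name,
        total_volume_cc=structure_volume(mask),
    )


def compute_dth(
    oar: StructureMask,
    target: StructureMask,
    bin_width: float = 1.0,
    signed: bool = True,
) -> CumulativeCurve:
    """Cumulative DTH: percent of OAR volume within each signed distance (mm)
    of the target surface.

    ``signed=False`` clips distances at zero inside the target (an OAR voxel
    inside the target then counts as distance 0).
    """
    if oar.grid != target.grid:
        raise ValueError("oar and target must live on the same grid")
    if target.is_empty():
        raise ValueError("DTH undefined: target mask is empty")
    if oar.is_empty():
        raise ValueError(f"DTH undefined for empty OAR {oar.name!r}")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    sd = signed_distance_to_surface(target)
    dist = np.sort(sd[oar.occupancy])
    if not signed:
        dist = np.maximum(dist, 0.0)
    n = dist.size
    first = int(np.floor(dist[0] / bin_width)) - 1
    last = int(np.floor(dist[-1] / bin_width)) + 1
    edges = bin_width * np.arange(first, last + 1)
    ordinate = np.searchsorted(dist, edges, side="right") * 100.0 / n
    return CumulativeCurve(
        abscissa=edges,
        ordinate=ordinate,
        kind="dth",
        structure_name=oar.name,
        total_volume_cc=structure_volume(oar),
    )


def resample_curve(curve: CumulativeCurve, grid: np.ndarray) -> CumulativeCurve:
    """Linear interpolation of a curve onto a new sorted abscissa.

    Points beyond the curve support clamp to the terminal ordinate values.
    """
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size < 2:
        raise ValueError("grid must be a 1-D array with at least two points")
    if np.any(np.diff(g) < 0):
        raise ValueError("grid must be sorted ascending")
    ordinate = np.interp(g, curve.abscissa, curve.ordinate)
    return replace(curve, abscissa=g, ordinate=ordinate)


def write_curve_csv(curve: CumulativeCurve, path_or_buf) -> None:
    """CSV serialization: header ``structure,kind,total_volume_cc`` then
    ``abscissa,ordinate`` rows at 6 significant digits."""

    def _write(fh) -> None:
        w = csv.writer(fh)
        w.writerow(["structure", "kind", "total_volume_cc"])
        w.writerow([curve.structure_name, curve.kind, f"{curve.total_volume_cc:.6g}"])
        w.writerow(["abscissa", "ordinate"])
        for a, o in zip(curve.abscissa, curve.ordinate):
            w.writerow([f"{a:.6g}", f"{o:.6g}"])

    if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
        with open(path_or_buf, "w", newline="") as fh:
            _write(fh)
    else:
        _write(path_or_buf)


def read_curve_csv(path_or_buf) -> CumulativeCurve:
    """Inverse of :func:`write_curve_csv`."""
    if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
        with open(path_or_buf, newline="") as fh:
            rows = list(csv.reader(fh))
    else:
        rows = list(csv.reader(path_or_buf))
    if rows[0] != ["structure", "kind", "total_volume_cc"]:
        raise ValueError("not a curve CSV: bad header")
    name, kind, vol = rows[1]
    data = np.array([[float(a), float(o)] for a, o in rows[3:]], dtype=float)
    return CumulativeCurve(
        abscissa=data[:, 0],
        ordinate=data[:, 1],
        kind=kind,  # type: ignore[arg-type]
        structure_name=name,
        total_volume_cc=float(vol),
    )


def curve_to_string(curve: CumulativeCurve) -> str:
    buf = io.StringIO()
    write_curve_csv(curve, buf)
    return buf.getvalue()
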