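"""Principal-component parameterization of DVH/DTH curve families.

A family of cumulative curves sampled on one common abscissa is summarized by
its mean curve plus a small orthonormal basis of shape components.  Between
one and four components are retained, the smallest number whose cumulative
explained-variance fraction reaches the target (default 0.97); if four do not
suffice, four are kept and the achieved fraction is recorded.  Scores are the
inner products of a centered curve with the retained components; curves are
rebuilt from scores and then projected back onto the set of valid cumulative
curves (clipped to [0, 100] and monotonized).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .histograms import CumulativeCurve, CurveKind

__all__ = ["CurveEmbedding", "fit_embedding", "project", "reconstruct"]

_ZERO_VARIANCE = 1e-18


@dataclass
class CurveEmbedding:
    """PCA basis for a family of curves on a common abscissa."""

    abscissa: np.ndarray
    mean_curve: np.ndarray
    components: np.ndarray  # (n_components, n_points), orthonormal rows
    explained_fraction: np.ndarray
    kind: CurveKind = "dvh"
    achieved_fraction: float = 1.0
    n_curves: int = 0

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.mean_curve = np.asarray(self.mean_curve, dtype=float)
        self.components = np.atleast_2d(np.asarray(self.components, dtype=float))
        self.explained_fraction = np.asarray(self.explained_fraction, dtype=float)
        if self.components.shape[1] != self.abscissa.size:
            raise ValueError("component length must match abscissa length")
        if self.mean_curve.shape != self.abscissa.shape:
            raise ValueError("mean curve length must match abscissa length")
        if self.explained_fraction.size != self.n_components:
            raise ValueError("one explained fraction per component")
        if np.any(np.diff(self.explained_fraction) > 1e-12):
            raise ValueError("explained fractions must be non-increasing")
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise ValueError("components must be mutually orthonormal")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "abscissa": self.abscissa.tolist(),
                "mean_curve": self.mean_curve.tolist(),
                "components": self.components.tolist(),
                "explained_fraction": self.explained_fraction.tolist(),
                "achieved_fraction": self.achieved_fraction,
                "n_curves": self.n_curves,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CurveEmbedding":
        d = json.loads(text)
        return cls(
            abscissa=np.array(d["abscissa"]),
            mean_curve=np.array(d["mean_curve"]),
            components=np.array(d["components"]),
            explained_fraction=np.array(d["explained_fraction"]),
            kind=d["kind"],
            achieved_fraction=d["achieved_fraction"],
            n_curves=d["n_curves"],
        )


def _common_abscissa(curves: list[CumulativeCurve]) -> np.ndarray:
    ref = curves[0].abscissa
    for c in curves[1:]:
        if c.abscissa.shape != ref.shape or not np.array_equal(c.abscissa, ref):
            raise ValueError("all curves must share an identical abscissa")
    return ref


def fit_embedding(
    curves: list[CumulativeCurve],
    variance_target: float = 0.97,
    max_components: int = 4,
) -> CurveEmbedding:
    """Fit a PCA embedding to a family of curves on one abscissa.

    Retains the smallest ``k <= max_components`` with cumulative explained
    fraction >= ``variance_target``; if no ``k`` reaches the target,
    ``max_components`` are kept and ``achieved_fraction`` records the deficit.
    A zero-variance family (all curves identical) degenerates to a single
    component carrying no variance.
    """
    if len(curves) < 2:
        raise ValueError("fit_embedding needs at least 2 curves")
    abscissa = _common_abscissa(curves)
    y = np.stack([c.ordinate for c in curves])
    n_max = min(max_components, len(curves) - 1, abscissa.size)
    pca = PCA(n_components=n_max, svd_solver="full")
    pca.fit(y)
    centered = y - y.mean(axis=0)
    total_var = float((centered**2).sum() / max(len(curves) - 1, 1))

    if total_var < _ZERO_VARIANCE:
        # degenerate family: one nominal component, zero spread
        comp = pca.components_[:1]
        return CurveEmbedding(
            abscissa=abscissa,
            mean_curve=y.mean(axis=0),
            components=comp,
            explained_fraction=np.array([1.0]),
            kind=curves[0].kind,
            achieved_fraction=1.0,
            n_curves=len(curves),
        )

    frac = pca.explained_variance_ / total_var
    cum = np.cumsum(frac)
    reaching = np.nonzero(cum >= variance_target - 1e-12)[0]
    k = int(reaching[0]) + 1 if reaching.size else n_max
    return CurveEmbedding(
        abscissa=abscissa,
        mean_curve=pca.mean_,
        components=pca.components_[:k],
        explained_fraction=frac[:k],
        kind=curves[0].kind,
        achieved_fraction=float(cum[k - 1]),
        n_curves=len(curves),
    )


def project(embedding: CurveEmbedding, curve: CumulativeCurve) -> np.ndarray:
    """Scores of a curve: inner products of (curve - mean) with the retained
    components."""
    if curve.abscissa.shape != embedding.abscissa.shape or not np.array_equal(
        curve.abscissa, embedding.abscissa
    ):
        raise ValueError("curve abscissa does not match embedding abscissa")
    return embedding.components @ (curve.ordinate - embedding.mean_curve)


def _monotonize(ordinate: np.ndarray, kind: CurveKind) -> np.ndarray:
    if kind == "dvh":
        # non-increasing: running max from the right
        return np.maximum.accumulate(ordinate[::-1])[::-1]
    return np.maximum.accumulate(ordinate)


def postprocess_ordinate(ordinate: np.ndarray, kind: CurveKind) -> np.ndarray:
    """Project a raw ordinate vector onto valid cumulative curves: clip to
    [0, 100] then restore monotonicity by a running maximum."""
    return _monotonize(np.clip(ordinate, 0.0, 100.0), kind)


def reconstruct(
    embedding: CurveEmbedding,
    scores: np.ndarray,
    structure_name: str = "",
    total_volume_cc: float = 0.0,
) -> CumulativeCurve:
    """Rebuild a curve from scores: mean + sum(score_j * component_j), clipped
    to [0, 100] and monotonized for the curve kind."""
    s = np.asarray(scores, dtype=float).ravel()
    if s.size != embedding.n_components:
        raise ValueError(
            f"expected {embedding.n_components} scores, got {s.size}"
        )
    raw = embedding.mean_curve + s @ embedding.components
    return CumulativeCurve(
        abscissa=embedding.abscissa.copy(),
        ordinate=postprocess_ordinate(raw, embedding.kind),
        kind=embedding.kind,
        structure_name=structure_name,
        total_volume_cc=total_volume_cc,
    )
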