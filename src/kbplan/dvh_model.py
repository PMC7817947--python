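"""Per-OAR achievable-DVH prediction: anatomical features -> epsilon-SVR on
principal-component scores -> predicted DVH with a 95% band.

For each OAR, planned DVHs of prior cases are resampled onto a common
relative-dose axis (0 to 110% of the prescription, 101 points) and
parameterized by PCA.  Anatomical features are the structure volumes, the
OAR/PTV overlap fraction, the OAR-to-body volume ratio, and the
principal-component scores of the OAR's distance-to-target histogram.
Features with a statistically significant coefficient in an ordinary
multivariate linear regression are kept per DVH score, and one epsilon-SVR
(RBF kernel) is fitted per retained score on standardized features and
responses.  The 95% band comes from the empirical 2.5/97.5% quantiles of the
training residuals (or +-1.96 SD for small cohorts), mapped pointwise onto
the curve through the component basis so that lower95 <= mean <= upper95 by
construction.

Database refinement is flag-only: a prior plan whose planned DVH exceeds the
predicted upper95 by more than a margin over more than a fraction of the
dose axis is reported for external re-optimization; the toolkit never edits
doses itself.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from sklearn.svm import SVR

from .core_grid import StructureMask, mask_union, structure_volume
from .curve_embedding import (
    CurveEmbedding,
    fit_embedding,
    postprocess_ordinate,
    project,
)
from .histograms import CumulativeCurve, compute_dth, resample_curve

__all__ = [
    "FeatureVector",
    "TrainConfig",
    "DVHModel",
    "PredictedDVH",
    "build_features",
    "select_features",
    "train",
    "predict",
    "flag_suboptimal",
    "default_dth_grid",
    "relative_dose_grid",
]

logger = logging.getLogger(__name__)

T_STAGES = ("T1", "T2", "T3", "T4")

VOLUMETRIC_FEATURES = (
    "oar_volume_cc",
    "target_volume_cc",
    "overlap_fraction",
    "oar_to_body_fraction",
)

_CONSTANT_SD = 1e-12


def relative_dose_grid(n_points: int = 101, rel_max: float = 1.1) -> np.ndarray:
    """Common DVH abscissa in units of the prescription dose (0 .. rel_max)."""
    return np.linspace(0.0, rel_max, n_points)


def default_dth_grid(n_points: int = 101, lo: float = -25.0, hi: float = 80.0) -> np.ndarray:
    """Common DTH abscissa in mm (signed distance to the target surface)."""
    return np.linspace(lo, hi, n_points)


@dataclass
class FeatureVector:
    """Anatomical features of one OAR in one case: volumetric information
    plus DTH principal-component scores, with case metadata."""

    oar_volume_cc: float
    target_volume_cc: float
    overlap_fraction: float
    oar_to_body_fraction: float
    dth_scores: np.ndarray
    t_stage: str = "T2"
    prescription_gy: float = 70.0

    def __post_init__(self) -> None:
        self.dth_scores = np.asarray(self.dth_scores, dtype=float).ravel()
        if self.dth_scores.size > 4:
            raise ValueError("at most 4 DTH scores")
        for attr in ("overlap_fraction", "oar_to_body_fraction"):
            v = getattr(self, attr)
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError(f"{attr} must lie in [0, 1], got {v}")
        if self.t_stage not in T_STAGES:
            raise ValueError(f"t_stage must be one of {T_STAGES}, got {self.t_stage!r}")

    def names(self) -> list[str]:
        return list(VOLUMETRIC_FEATURES) + [
            f"dth_score_{i + 1}" for i in range(self.dth_scores.size)
        ]

    def values(self) -> np.ndarray:
        return np.concatenate(
            [
                [
                    self.oar_volume_cc,
                    self.target_volume_cc,
                    self.overlap_fraction,
                    self.oar_to_body_fraction,
                ],
                self.dth_scores,
            ]
        )


def build_features(
    oar: StructureMask,
    targets: list[StructureMask],
    body: StructureMask,
    dth_embedding: CurveEmbedding,
    t_stage: str = "T2",
    prescription_gy: float = 70.0,
    dth_bin_width: float = 1.0,
    signed: bool = True,
    target_index: int | None = None,
) -> FeatureVector:
    """Deterministic feature extraction for one OAR.

    The DTH is computed against the union of all targets by default; pass
    ``target_index`` to use a single PTV instead.
    """
    if oar.is_empty():
        raise ValueError(f"OAR {oar.name!r} is empty")
    if not targets or any(t.is_empty() for t in targets):
        raise ValueError("targets must be non-empty")
    tgt = targets[target_index] if target_index is not None else mask_union(targets, "ptv_union")
    dth = compute_dth(oar, tgt, bin_width=dth_bin_width, signed=signed)
    dth = resample_curve(dth, dth_embedding.abscissa)
    scores = project(dth_embedding, dth)
    overlap = np.count_nonzero(oar.occupancy & tgt.occupancy) / oar.voxel_count
    body_vol = structure_volume(body)
    return FeatureVector(
        oar_volume_cc=structure_volume(oar),
        target_volume_cc=structure_volume(tgt),
        overlap_fraction=float(overlap),
        oar_to_body_fraction=float(structure_volume(oar) / body_vol) if body_vol else 0.0,
        dth_scores=scores,
        t_stage=t_stage,
        prescription_gy=prescription_gy,
    )


def _usable_columns(x: np.ndarray, names: list[str]) -> list[int]:
    """Drop constant columns and later near-duplicates of earlier columns."""
    keep: list[int] = []
    for j in range(x.shape[1]):
        col = x[:, j]
        if col.std() < _CONSTANT_SD:
            logger.warning("feature %s is constant; dropped from selection", names[j])
            continue
        duplicate = False
        for k in keep:
            c = np.corrcoef(col, x[:, k])[0, 1]
            if abs(c) > 1 - 1e-10:
                logger.warning(
                    "feature %s is collinear with %s; dropped", names[j], names[k]
                )
                duplicate = True
                break
        if not duplicate:
            keep.append(j)
    return keep


def select_features(
    features: list[FeatureVector],
    responses: np.ndarray,
    alpha: float = 0.05,
    force_nonempty: bool = True,
) -> list[list[str]]:
    """Per response component, keep features whose OLS coefficient has
    p < alpha; if none qualify (and ``force_nonempty``), keep the single
    best one.

    ``responses`` has shape (n_cases, n_components).  Constant or collinear
    feature columns are dropped with a logged warning before the regression.
    """
    if len(features) < 10:
        raise ValueError(f"select_features needs >= 10 cases, got {len(features)}")
    names = features[0].names()
    x = np.stack([f.values() for f in features])
    y = np.atleast_2d(np.asarray(responses, dtype=float))
    if y.shape[0] != x.shape[0]:
        raise ValueError("responses must have one row per case")
    cols = _usable_columns(x, names)
    if not cols:
        raise ValueError("no usable (non-constant) features")
    xs = sm.add_constant(x[:, cols])
    selected: list[list[str]] = []
    for j in range(y.shape[1]):
        yj = y[:, j]
        if yj.std() < _CONSTANT_SD:
            raise ValueError(f"response component {j} is constant")
        fit = sm.OLS(yj, xs).fit()
        pvals = fit.pvalues[1:]  # skip intercept
        chosen = [names[cols[k]] for k in range(len(cols)) if pvals[k] < alpha]
        if not chosen and force_nonempty:
            chosen = [names[cols[int(np.argmin(pvals))]]]
        selected.append(chosen)
    return selected


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the DVH model, fully config-exposed (the method
    itself prescribes none).

    Defaults: epsilon is kept small (0.01 on the standardized score) so the
    insensitive tube does not itself become a systematic prediction error,
    and the DVH curve family keeps its full four-component parameterization
    (``variance_target=1.0``; trailing zero-variance components are trimmed
    automatically) because truncating at the embedding-selection threshold
    leaves reconstruction error of the same size as the model's accuracy.
    ``always_keep_dth`` retains the DTH shape scores in every regression —
    they are the spatial signal the model exists for, and a linear
    significance screen can discard them when their effect on a curve score
    is strong but non-monotone.
    """

    svr_c: float = 10.0
    svr_epsilon: float = 0.01  # in units of the standardized score
    svr_kernel: str = "rbf"
    svr_gamma: str | float = "scale"
    svr_tol: float = 1e-8
    variance_target: float = 1.0
    max_components: int = 4
    alpha: float = 0.05
    always_keep_dth: bool = True
    standardize: bool = True
    min_cases: int = 10
    quantile_band_min_n: int = 40  # below this, fall back to +-1.96 SD
    cv_folds: int = 5  # residual band uses out-of-fold residuals
    dvh_points: int = 101
    dvh_rel_max: float = 1.1


@dataclass
class _ScoreRegressor:
    """One epsilon-SVR for one DVH score, with its feature/response scalers."""

    feature_names: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    svr: SVR | None  # None when the response is constant
    band: tuple[float, float]  # residual quantiles on the raw score scale

    def predict_one(self, x_raw: np.ndarray) -> float:
        if self.svr is None:
            return self.y_mean
        z = (x_raw - self.x_mean) / self.x_sd
        return float(self.svr.predict(z.reshape(1, -1))[0] * self.y_sd + self.y_mean)


@dataclass
class DVHModel:
    """Trained per-OAR model: embeddings, selected features, one regressor
    per retained DVH score, and the residual band."""

    oar_name: str
    dvh_embedding: CurveEmbedding
    regressors: list[_ScoreRegressor]
    training_n: int
    config: TrainConfig = field(default_factory=TrainConfig)
    dth_embedding: CurveEmbedding | None = None

    @property
    def selected_features(self) -> list[list[str]]:
        return [r.feature_names for r in self.regressors]

    def to_json(self) -> str:
        def _reg(r: _ScoreRegressor) -> dict:
            d = {
                "feature_names": r.feature_names,
                "x_mean": r.x_mean.tolist(),
                "x_sd": r.x_sd.tolist(),
                "y_mean": r.y_mean,
                "y_sd": r.y_sd,
                "band": list(r.band),
                "svr": None,
            }
            if r.svr is not None:
                d["svr"] = {
                    "support_vectors": r.svr.support_vectors_.tolist(),
                    "dual_coef": r.svr.dual_coef_.ravel().tolist(),
                    "intercept": float(r.svr.intercept_[0]),
                    "gamma": float(r.svr._gamma),
                    "kernel": r.svr.kernel,
                }
            return d

        return json.dumps(
            {
                "oar_name": self.oar_name,
                "training_n": self.training_n,
                "config": self.config.__dict__,
                "dvh_embedding": json.loads(self.dvh_embedding.to_json()),
                "dth_embedding": (
                    json.loads(self.dth_embedding.to_json())
                    if self.dth_embedding is not None
                    else None
                ),
                "regressors": [_reg(r) for r in self.regressors],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DVHModel":
        d = json.loads(text)
        regs = []
        for rd in d["regressors"]:
            svr = None
            if rd["svr"] is not None:
                svr = _FrozenSVR(
                    support_vectors=np.array(rd["svr"]["support_vectors"]),
                    dual_coef=np.array(rd["svr"]["dual_coef"]),
                    intercept=rd["svr"]["intercept"],
                    gamma=rd["svr"]["gamma"],
                    kernel=rd["svr"]["kernel"],
                )
            regs.append(
                _ScoreRegressor(
                    feature_names=rd["feature_names"],
                    x_mean=np.array(rd["x_mean"]),
                    x_sd=np.array(rd["x_sd"]),
                    y_mean=rd["y_mean"],
                    y_sd=rd["y_sd"],
                    svr=svr,
                    band=tuple(rd["band"]),
                )
            )
        return cls(
            oar_name=d["oar_name"],
            dvh_embedding=CurveEmbedding.from_json(json.dumps(d["dvh_embedding"])),
            regressors=regs,
            training_n=d["training_n"],
            config=TrainConfig(**d["config"]),
            dth_embedding=(
                CurveEmbedding.from_json(json.dumps(d["dth_embedding"]))
                if d["dth_embedding"] is not None
                else None
            ),
        )


class _FrozenSVR:
    """Deserialized epsilon-SVR decision function (RBF or linear)."""

    def __init__(self, support_vectors, dual_coef, intercept, gamma, kernel):
        self.support_vectors_ = np.asarray(support_vectors, dtype=float)
        self._dual = np.asarray(dual_coef, dtype=float).ravel()
        self._b = float(intercept)
        self._gamma = float(gamma)
        self.kernel = kernel

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        if self.kernel == "rbf":
            d2 = ((x[:, None, :] - self.support_vectors_[None, :, :]) ** 2).sum(axis=2)
            k = np.exp(-self._gamma * d2)
        elif self.kernel == "linear":
            k = x @ self.support_vectors_.T
        else:
            raise ValueError(f"unsupported serialized kernel {self.kernel!r}")
        return k @ self._dual + self._b


@dataclass
class PredictedDVH:
    """Predicted achievable DVH with its 95% band; at every abscissa
    lower95 <= mean <= upper95 by construction."""

    mean: CumulativeCurve
    lower95: CumulativeCurve
    upper95: CumulativeCurve

    def __post_init__(self) -> None:
        tol = 1e-9
        if np.any(self.lower95.ordinate > self.mean.ordinate + tol) or np.any(
            self.mean.ordinate > self.upper95.ordinate + tol
        ):
            raise ValueError("band ordering violated: need lower95 <= mean <= upper95")


def _feature_matrix(features: list[FeatureVector]) -> tuple[np.ndarray, list[str]]:
    names = features[0].names()
    for f in features[1:]:
        if f.names() != names:
            raise ValueError("all feature vectors must have identical feature names")
    return np.stack([f.values() for f in features]), names


def _canonical_order(x: np.ndarray) -> np.ndarray:
    """Stable lexicographic ordering of training cases so that training is
    exactly invariant to input order."""
    return np.lexsort(np.round(x, 12).T[::-1])


def train(
    cases: list[tuple[FeatureVector, CumulativeCurve]],
    config: TrainConfig | None = None,
    oar_name: str = "",
    dth_embedding: CurveEmbedding | None = None,
) -> DVHModel:
    """Fit the per-OAR model from (features, planned DVH) pairs.

    Planned DVHs (in Gy) are resampled onto the common relative-dose axis
    using each case's prescription before the curve PCA.
    """
    config = config or TrainConfig()
    if len(cases) < config.min_cases:
        raise ValueError(
            f"training needs at least {config.min_cases} cases, got {len(cases)}"
        )
    feats = [c[0] for c in cases]
    curves = [c[1] for c in cases]
    x, names = _feature_matrix(feats)
    order = _canonical_order(x)
    feats = [feats[i] for i in order]
    curves = [curves[i] for i in order]
    x = x[order]

    rel = relative_dose_grid(config.dvh_points, config.dvh_rel_max)
    rel_curves = []
    for f, c in zip(feats, curves):
        rc = resample_curve(c, rel * f.prescription_gy)
        rel_curves.append(
            CumulativeCurve(
                abscissa=rel,
                ordinate=rc.ordinate,
                kind="dvh",
                structure_name=c.structure_name,
                total_volume_cc=c.total_volume_cc,
            )
        )
    dvh_embedding = fit_embedding(
        rel_curves, variance_target=config.variance_target, max_components=config.max_components
    )
    scores = np.stack([project(dvh_embedding, rc) for rc in rel_curves])

    # feature selection; a fully constant response family (identical curves)
    # bypasses the regression and freezes the prediction at the constant.
    constant_response = scores.std(axis=0).max() < _CONSTANT_SD
    if constant_response:
        selected = [[names[0]] for _ in range(dvh_embedding.n_components)]
    else:
        try:
            selected = select_features(feats, scores, alpha=config.alpha)
        except ValueError as exc:
            if "non-constant" not in str(exc):
                raise
            # fully degenerate anatomy (every feature constant): fall back to
            # intercept-only regressors; the band then reflects the raw
            # score spread, e.g. dose-noise-driven DVH variability
            logger.warning("all features constant; predicting the cohort mean DVH")
            selected = [[] for _ in range(dvh_embedding.n_components)]
        if config.always_keep_dth:
            dth_names = [
                nm for nm in names
                if nm.startswith("dth_score_")
                and np.std([f.values()[names.index(nm)] for f in feats]) >= _CONSTANT_SD
            ]
            selected = [
                s + [nm for nm in dth_names if nm not in s] for s in selected
            ]

    name_to_col = {nm: j for j, nm in enumerate(names)}
    regressors: list[_ScoreRegressor] = []
    for j in range(dvh_embedding.n_components):
        cols = [name_to_col[nm] for nm in selected[j]]
        xj = x[:, cols]
        yj = scores[:, j]
        if config.standardize:
            x_mean, x_sd = xj.mean(axis=0), xj.std(axis=0)
        else:
            x_mean, x_sd = np.zeros(xj.shape[1]), np.ones(xj.shape[1])
        x_sd = np.where(x_sd < _CONSTANT_SD, 1.0, x_sd)
        y_mean, y_sd = float(yj.mean()), float(yj.std())
        if y_sd < _CONSTANT_SD:
            regressors.append(
                _ScoreRegressor(selected[j], x_mean, x_sd, y_mean, 1.0, None, (0.0, 0.0))
            )
            continue
        if not cols:  # intercept-only: band carries the raw score spread
            resid = yj - y_mean
            if len(cases) >= config.quantile_band_min_n:
                lo, hi = np.quantile(resid, [0.025, 0.975])
            else:
                sd = float(resid.std())
                lo, hi = -1.96 * sd, 1.96 * sd
            regressors.append(
                _ScoreRegressor(
                    [], x_mean, x_sd, y_mean, 1.0, None,
                    (min(float(lo), 0.0), max(float(hi), 0.0)),
                )
            )
            continue
        z = (xj - x_mean) / x_sd
        t = (yj - y_mean) / y_sd

        def _fit(zf: np.ndarray, tf: np.ndarray) -> SVR:
            svr = SVR(
                kernel=config.svr_kernel,
                C=config.svr_c,
                epsilon=config.svr_epsilon,
                gamma=config.svr_gamma,
                tol=config.svr_tol,
            )
            svr.fit(zf, tf)
            return svr

        svr = _fit(z, t)
        # honest residuals for the band: out-of-fold predictions, so that a
        # flexible fit cannot shrink the band by memorizing its training data
        n_cases = len(cases)
        k_folds = min(config.cv_folds, n_cases)
        resid = np.empty(n_cases)
        fold_ids = np.arange(n_cases) % k_folds
        for fold in range(k_folds):
            held = fold_ids == fold
            fit_fold = _fit(z[~held], t[~held])
            resid[held] = yj[held] - (fit_fold.predict(z[held]) * y_sd + y_mean)
        if len(cases) >= config.quantile_band_min_n:
            lo, hi = np.quantile(resid, [0.025, 0.975])
        else:
            sd = float(resid.std())
            lo, hi = -1.96 * sd, 1.96 * sd
        band = (min(float(lo), 0.0), max(float(hi), 0.0))
        regressors.append(
            _ScoreRegressor(selected[j], x_mean, x_sd, y_mean, y_sd, svr, band)
        )

    return DVHModel(
        oar_name=oar_name or curves[0].structure_name,
        dvh_embedding=dvh_embedding,
        regressors=regressors,
        training_n=len(cases),
        config=config,
        dth_embedding=dth_embedding,
    )


def _raw_features_for(model_names: list[str], features: FeatureVector) -> np.ndarray:
    available = dict(zip(features.names(), features.values()))
    missing = [nm for nm in model_names if nm not in available]
    if missing:
        raise ValueError(f"feature vector is missing selected feature(s): {missing}")
    return np.array([available[nm] for nm in model_names])


def predict(model: DVHModel, features: FeatureVector) -> PredictedDVH:
    """Predicted achievable DVH (Gy axis) with its 95% band for one case."""
    emb = model.dvh_embedding
    scores = np.array(
        [r.predict_one(_raw_features_for(r.feature_names, features)) for r in model.regressors]
    )
    raw = emb.mean_curve + scores @ emb.components
    # pointwise band envelope over the per-score residual box
    delta_lo = np.zeros_like(raw)
    delta_hi = np.zeros_like(raw)
    for j, r in enumerate(model.regressors):
        lo_j, hi_j = r.band
        comp = emb.components[j]
        delta_lo += np.minimum(lo_j * comp, hi_j * comp)
        delta_hi += np.maximum(lo_j * comp, hi_j * comp)

    abscissa_gy = emb.abscissa * features.prescription_gy

    def _curve(ordinate: np.ndarray) -> CumulativeCurve:
        return CumulativeCurve(
            abscissa=abscissa_gy,
            ordinate=ordinate,
            kind="dvh",
            structure_name=model.oar_name,
        )

    # band edges are projected *outward* onto valid curves (lower: running
    # min, upper: running max) so post-processing never narrows the band
    mean_ord = postprocess_ordinate(raw, "dvh")
    lower_ord = np.minimum.accumulate(np.clip(raw + delta_lo, 0.0, 100.0))
    upper_ord = np.maximum.accumulate(np.clip(raw + delta_hi, 0.0, 100.0)[::-1])[::-1]
    return PredictedDVH(
        mean=_curve(mean_ord), lower95=_curve(lower_ord), upper95=_curve(upper_ord)
    )


def _exceeds(pred: PredictedDVH, planned: CumulativeCurve, margin: float, fraction: float) -> bool:
    planned_on_grid = resample_curve(planned, pred.upper95.abscissa)
    excess = planned_on_grid.ordinate - pred.upper95.ordinate
    return bool(np.mean(excess > margin) > fraction)


def flag_suboptimal(
    model: DVHModel,
    cases: list[tuple[FeatureVector, CumulativeCurve]],
    margin: float = 5.0,
    fraction: float = 0.2,
    case_ids: list | None = None,
    self_check: bool = True,
) -> list:
    """Identify prior plans whose planned DVH exceeds the predicted upper95
    by more than ``margin`` percentage points of volume over more than
    ``fraction`` of the dose axis.  Returns the flagged case ids
    (defaulting to list indices); deterministic.

    With ``self_check`` (the database-refinement use, where ``cases`` are the
    model's own training plans) each case is predicted by a model refit with
    that case's fold held out: a flexible regressor can otherwise memorize
    the very plan it is supposed to judge.  Pass ``self_check=False`` to
    screen plans that were not part of training.
    """
    ids = list(case_ids) if case_ids is not None else list(range(len(cases)))
    if len(ids) != len(cases):
        raise ValueError("case_ids must match cases in length")

    preds: list[PredictedDVH]
    k = min(model.config.cv_folds, len(cases) // model.config.min_cases)
    if self_check and k >= 2:
        # deterministic folds over the canonical case order
        x, _ = _feature_matrix([c[0] for c in cases])
        order = _canonical_order(x)
        rank = np.empty(len(cases), dtype=int)
        rank[order] = np.arange(len(cases))
        fold_of = rank % k
        preds = [None] * len(cases)  # type: ignore[list-item]
        for fold in range(k):
            held = [i for i in range(len(cases)) if fold_of[i] == fold]
            rest = [cases[i] for i in range(len(cases)) if fold_of[i] != fold]
            fold_model = train(
                rest, config=model.config, oar_name=model.oar_name,
                dth_embedding=model.dth_embedding,
            )
            for i in held:
                preds[i] = predict(fold_model, cases[i][0])
    else:
        preds = [predict(model, f) for f, _ in cases]

    return [
        cid
        for cid, (f, planned), pred in zip(ids, cases, preds)
        if _exceeds(pred, planned, margin, fraction)
    ]
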