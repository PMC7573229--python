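"""OPLS-DA with VIP scoring and the differential-metabolite gate.

Orthogonal partial least squares discriminant analysis separates the
between-class (predictive) variation of an intensity matrix from the
class-orthogonal variation. For a two-class problem the response is a
centered +/-1 dummy vector y; each orthogonal component is estimated from
the part of the X loading orthogonal to the predictive weight and deflated
from X before the single predictive component is fitted (NIPALS-style —
for a single response column the weight solves in one step, so the fit is
fully deterministic).

Variable importance in projection (VIP) is computed from the predictive
component only (the common OPLS-DA convention):

    VIP_j = sqrt( p * sum_a w_ja^2 * SSY_a / sum_a SSY_a )

with one predictive component this reduces to sqrt(p) * |w_j| for the
normalized weight vector, so the mean of VIP^2 over metabolites is exactly
1. The screen keeps metabolites with VIP >= 1 and a raw group-mean
fold-change >= 2 (up) or <= 0.5 (down).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessRecord",
    "OplsdaModel",
    "MetaboliteScreenResult",
    "preprocess",
    "fit_oplsda",
    "vip_scores",
    "fold_change",
    "screen_metabolites",
    "permutation_r2y",
    "split_matrix",
]

_EPS = 1e-12


@dataclass(frozen=True)
class PreprocessRecord:
    log_transform: bool
    scaling: str
    center: np.ndarray
    scale: np.ndarray


@dataclass
class OplsdaModel:
    """Fitted OPLS-DA model for a two-class intensity matrix."""

    feature_names: tuple[str, ...]
    classes: tuple[str, str]
    weights: np.ndarray           # predictive weight vector w (p,), unit norm
    scores: np.ndarray            # predictive scores t (n,)
    loadings: np.ndarray          # predictive X-loadings (p,)
    y_loading: float              # q, regression of y on t
    orthogonal_scores: np.ndarray     # (n, n_orthogonal)
    orthogonal_loadings: np.ndarray   # (p, n_orthogonal)
    orthogonal_weights: np.ndarray    # (p, n_orthogonal)
    r2y: float                    # Y-variance explained by the predictive component
    vip: pd.Series
    preprocessing: PreprocessRecord
    n_orthogonal: int

    def validate(self, tol: float = 1e-8) -> None:
        for a in range(self.orthogonal_scores.shape[1]):
            t_o = self.orthogonal_scores[:, a]
            if abs(float(self.scores @ t_o)) > tol * max(
                1.0, np.linalg.norm(self.scores) * np.linalg.norm(t_o)
            ):
                raise AssertionError("predictive and orthogonal scores not orthogonal")
        if abs(float((self.vip.to_numpy() ** 2).mean()) - 1.0) > 1e-6:
            raise AssertionError("mean squared VIP deviates from 1")


def split_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Split a matrix whose first column is the sample group label."""
    if "group" not in matrix.columns:
        raise ValueError("matrix needs a 'group' column (sample class labels)")
    groups = matrix["group"]
    X = matrix.drop(columns="group")
    return X, groups


def preprocess(
    X: pd.DataFrame, log_transform: bool = True, scaling: str = "uv"
) -> tuple[np.ndarray, PreprocessRecord]:
    """Log-transform and column-scale an intensity matrix.

    ``scaling`` is ``"uv"`` (unit variance), ``"pareto"`` (sqrt of the
    standard deviation) or ``"none"``; all options mean-center. The log
    transform requires strictly positive intensities.
    """
    vals = X.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("intensity matrix contains missing values; impute first")
    if log_transform:
        if (vals <= 0).any():
            raise ValueError("log transform requires strictly positive intensities")
        vals = np.log(vals)
    center = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    if scaling == "uv":
        scale = sd.copy()
    elif scaling == "pareto":
        scale = np.sqrt(sd)
    elif scaling == "none":
        scale = np.ones_like(sd)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    if scaling != "none" and (scale <= _EPS).any():
        bad = list(X.columns[scale <= _EPS])
        raise ValueError(f"constant feature(s) cannot be variance-scaled: {bad[:5]}")
    return (vals - center) / scale, PreprocessRecord(log_transform, scaling, center, scale)


def _encode_classes(groups: Sequence[str]) -> tuple[np.ndarray, tuple[str, str]]:
    labels = pd.Series(list(groups))
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError(f"each class needs >= 2 samples, got {counts.to_dict()}")
    y = np.where(labels.to_numpy() == classes[1], 1.0, -1.0)
    return y, (classes[0], classes[1])


def fit_oplsda(
    matrix: pd.DataFrame,
    groups: Sequence[str] | None = None,
    n_orthogonal: int = 1,
    log_transform: bool = True,
    scaling: str = "uv",
) -> OplsdaModel:
    """Fit an OPLS-DA model with one predictive and ``n_orthogonal`` components.

    ``matrix`` is samples x metabolites; pass ``groups`` separately or as a
    leading ``group`` column. With ``n_orthogonal=0`` the model coincides
    with a one-component PLS-DA fit.
    """
    if groups is None:
        X_df, groups = split_matrix(matrix)
    else:
        X_df = matrix
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")
    y_raw, classes = _encode_classes(groups)
    X, record = preprocess(X_df, log_transform=log_transform, scaling=scaling)
    y = y_raw - y_raw.mean()
    ssy_total = float(y @ y)
    if ssy_total <= _EPS:
        raise ValueError("degenerate class vector")

    n, p = X.shape

    def predictive_weight(Xc: np.ndarray) -> np.ndarray:
        w = Xc.T @ y
        norm = np.linalg.norm(w)
        if norm <= _EPS:
            raise ValueError("degenerate model: X carries no class covariance")
        return w / norm

    T_o = np.zeros((n, n_orthogonal))
    P_o = np.zeros((p, n_orthogonal))
    W_o = np.zeros((p, n_orthogonal))
    Xd = X.copy()
    for a in range(n_orthogonal):
        w = predictive_weight(Xd)
        t = Xd @ w
        p_load = Xd.T @ t / float(t @ t)
        w_orth = p_load - float(w @ p_load) * w
        norm = np.linalg.norm(w_orth)
        if norm <= 1e-10:
            raise ValueError(
                f"no orthogonal variation left for component {a + 1}; "
                "reduce n_orthogonal (matrix rank exhausted)"
            )
        w_orth /= norm
        t_orth = Xd @ w_orth
        p_orth = Xd.T @ t_orth / float(t_orth @ t_orth)
        Xd = Xd - np.outer(t_orth, p_orth)
        T_o[:, a], P_o[:, a], W_o[:, a] = t_orth, p_orth, w_orth

    w = predictive_weight(Xd)
    t = Xd @ w
    p_load = Xd.T @ t / float(t @ t)
    q = float(y @ t / (t @ t))
    r2y = float(q**2 * (t @ t) / ssy_total)

    vip = pd.Series(
        np.sqrt(p) * np.abs(w), index=X_df.columns, name="VIP"
    )
    model = OplsdaModel(
        feature_names=tuple(X_df.columns),
        classes=classes,
        weights=w,
        scores=t,
        loadings=p_load,
        y_loading=q,
        orthogonal_scores=T_o,
        orthogonal_loadings=P_o,
        orthogonal_weights=W_o,
        r2y=r2y,
        vip=vip,
        preprocessing=record,
        n_orthogonal=n_orthogonal,
    )
    model.validate()
    return model


def vip_scores(model: OplsdaModel) -> pd.Series:
    """Per-metabolite VIP from the fitted model's predictive component."""
    if model.r2y <= 0:
        raise ValueError("degenerate model: no explained Y-variance")
    return model.vip.copy()


def fold_change(
    matrix: pd.DataFrame,
    groups: Sequence[str] | None = None,
    order: tuple[str, str] | None = None,
) -> pd.Series:
    """Raw-scale fold change, mean(treated) / mean(control), per metabolite.

    ``order`` is (control, treated); by default the lexicographically first
    class is the control. A zero control mean yields an explicit +inf flag
    (logged), never a silent NaN.
    """
    if groups is None:
        X, groups = split_matrix(matrix)
    else:
        X = matrix
    labels = pd.Series(list(groups), index=X.index)
    classes = sorted(labels.unique())
    if order is None:
        order = (classes[0], classes[1])
    if sorted(order) != classes:
        raise ValueError(f"order {order} does not match classes {classes}")
    control, treated = order
    mean_c = X[labels == control].mean(axis=0)
    mean_t = X[labels == treated].mean(axis=0)
    zero = mean_c == 0
    if zero.any():
        logger.warning("fold_change: %d metabolites with zero control mean -> inf", int(zero.sum()))
    fc = mean_t / mean_c.replace(0, np.nan)
    fc[zero] = np.inf
    fc.name = "fold_change"
    return fc


@dataclass
class MetaboliteScreenResult:
    """Verdict table and summary counts of the differential screen."""

    table: pd.DataFrame
    counts: dict[str, int]
    class_counts: pd.DataFrame | None = None

    @property
    def differential(self) -> tuple[str, ...]:
        mask = self.table["verdict"] != "not-differential"
        return tuple(self.table.index[mask])


def screen_metabolites(
    vip: pd.Series,
    fc: pd.Series,
    vip_threshold: float = 1.0,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    annotations: pd.Series | None = None,
) -> MetaboliteScreenResult:
    """Apply the VIP >= 1 and fold-change >= 2 / <= 0.5 gate.

    ``annotations`` optionally maps metabolite id to a compound class
    (amino acid, lipid, ...) for per-class direction counts.
    """
    if not vip.index.equals(fc.index):
        vip, fc = vip.align(fc, join="inner")
        if vip.empty:
            raise ValueError("VIP and fold-change indexes share no metabolites")
    verdict = np.where(
        (vip >= vip_threshold) & (fc >= fc_up),
        "up",
        np.where((vip >= vip_threshold) & (fc <= fc_down), "down", "not-differential"),
    )
    table = pd.DataFrame({"fold_change": fc, "VIP": vip, "verdict": verdict})
    counts = table["verdict"].value_counts().to_dict()
    for key in ("up", "down", "not-differential"):
        counts.setdefault(key, 0)
    class_counts = None
    if annotations is not None:
        table["class"] = annotations.reindex(table.index).fillna("unannotated")
        class_counts = (
            table.groupby(["class", "verdict"], sort=True).size().unstack(fill_value=0)
        )
    return MetaboliteScreenResult(table=table, counts=counts, class_counts=class_counts)


def permutation_r2y(
    matrix: pd.DataFrame,
    groups: Sequence[str] | None = None,
    n_permutations: int = 100,
    n_orthogonal: int = 0,
    seed: int = 0,
    **fit_kwargs,
) -> np.ndarray:
    """Explained Y-variance of the predictive component under label shuffles.

    A sanity diagnostic: on real class structure the permuted R2Y values
    should fall well below the observed one.
    """
    if groups is None:
        X, groups = split_matrix(matrix)
    else:
        X = matrix
    rng = np.random.default_rng(seed)
    labels = np.asarray(list(groups))
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(labels)
        try:
            out[i] = fit_oplsda(
                X, groups=perm, n_orthogonal=n_orthogonal, **fit_kwargs
            ).r2y
        except ValueError:
            out[i] = 0.0
    return out
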