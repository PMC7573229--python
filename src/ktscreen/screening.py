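"""Comprehensive low-K tolerance evaluation of a germplasm panel.

The screening chain turns a replicate-level trait panel measured under
control (CK) and low-potassium (LK) treatments into a single tolerance
score per genotype:

1. per-trait low-K tolerance coefficients, LK mean / CK mean;
2. PCA of the standardized coefficient matrix, giving "comprehensive
   indices" (component scores X_j) with contribution rates P_j;
3. a fuzzy membership rescaling U(X_j) = (X_j - min_j) / (max_j - min_j);
4. weights W_j = P_j / sum(P_j) over retained components;
5. the comprehensive evaluation value D = sum_j U(X_j) * W_j in [0, 1],
   higher D = more tolerant;
6. hierarchical clustering of D into tolerance classes and percentile
   selection of the extreme genotypes, plus cross-stage consensus.

Component signs are fixed so that each loading vector's largest-magnitude
entry is positive; the membership step is not sign-invariant, so the
convention is recorded in run manifests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)

__all__ = [
    "ComprehensiveEvaluation",
    "ToleranceClassification",
    "SelectionResult",
    "CLASS_LABELS",
    "summarize_traits",
    "tolerance_coefficients",
    "comprehensive_pca",
    "membership",
    "weights",
    "d_value",
    "evaluate",
    "classify",
    "select_extremes",
    "cross_stage_consensus",
]

CLASS_LABELS = ("tolerant", "moderately tolerant", "moderately sensitive", "sensitive")

_PANEL_COLUMNS = ("genotype", "trait", "treatment", "value")
_TREATMENTS = ("CK", "LK")


def _check_panel(panel: pd.DataFrame) -> None:
    missing = [c for c in _PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"trait panel is missing columns {missing}")
    bad = set(panel["treatment"].unique()) - set(_TREATMENTS)
    if bad:
        raise ValueError(f"unknown treatment labels {sorted(bad)}; expected CK/LK")
    if not np.isfinite(panel["value"].to_numpy(dtype=float)).all():
        raise ValueError("trait panel contains non-finite values")


def summarize_traits(panel: pd.DataFrame, trait_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Descriptive statistics per (trait, treatment) across genotypes.

    Replicates are averaged per genotype first; mean, max, min, SD
    (n-1 denominator) and CV% = 100*SD/mean are then computed over the
    genotype means. A zero mean makes the CV undefined; it is reported as
    missing with a warning.
    """
    _check_panel(panel)
    geno_means = (
        panel.groupby(["trait", "treatment", "genotype"], sort=False)["value"]
        .mean()
        .reset_index()
    )
    counts = geno_means.groupby(["trait", "treatment"])["genotype"].nunique()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"need >= 2 genotypes per (trait, treatment); offending: {bad}")

    rows = []
    order = list(trait_order) if trait_order is not None else list(
        panel["trait"].drop_duplicates()
    )
    for trait in order:
        for treatment in _TREATMENTS:
            vals = geno_means.query(
                "trait == @trait and treatment == @treatment"
            )["value"].to_numpy()
            if vals.size == 0:
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1))
            if mean == 0:
                logger.warning("CV undefined for %s/%s: mean is zero", trait, treatment)
                cv = np.nan
            else:
                cv = 100.0 * sd / mean
            rows.append(
                {
                    "trait": trait,
                    "treatment": treatment,
                    "mean": mean,
                    "max": float(vals.max()),
                    "min": float(vals.min()),
                    "sd": sd,
                    "cv_pct": cv,
                }
            )
    return pd.DataFrame(rows)


def tolerance_coefficients(panel: pd.DataFrame) -> pd.DataFrame:
    """Low-K tolerance coefficient per genotype and trait.

    Replicate means are taken per (genotype, trait, treatment) first; the
    coefficient is then LK mean / CK mean. Genotypes missing a treatment
    for any trait, or with a zero CK mean, raise with the offending
    genotype and trait named.
    """
    _check_panel(panel)
    means = panel.groupby(["genotype", "trait", "treatment"], sort=False)["value"].mean()
    wide = means.unstack("treatment")
    for treatment in _TREATMENTS:
        if treatment not in wide.columns or wide[treatment].isna().any():
            missing = (
                wide.index[wide[treatment].isna()].tolist()
                if treatment in wide.columns
                else wide.index.tolist()
            )
            raise ValueError(
                f"missing {treatment} measurements for (genotype, trait) cells: "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
    zero_ck = wide.index[wide["CK"] == 0].tolist()
    if zero_ck:
        g, t = zero_ck[0]
        raise ValueError(f"CK mean is zero for genotype {g!r}, trait {t!r}")
    coeff = (wide["LK"] / wide["CK"]).unstack("trait")
    trait_order = list(panel["trait"].drop_duplicates())
    genotype_order = list(panel["genotype"].drop_duplicates())
    return coeff.loc[genotype_order, trait_order]


@dataclass
class ComprehensiveEvaluation:
    """PCA result plus the membership/weight/D chain for one panel.

    ``scores`` holds the retained comprehensive indices X_j (genotypes x n),
    ``contributions`` the per-component contribution rates P_j in percent,
    ``membership_values``/``weights_``/``d`` the Eq. 1-3 chain once
    :func:`evaluate` has filled them in.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    eigenvalues: np.ndarray
    contributions: np.ndarray
    contributions_all: np.ndarray
    cumulative_contribution: float
    n_retained: int
    retention_rule: str
    membership_values: pd.DataFrame | None = None
    weights_: np.ndarray | None = None
    d: pd.Series | None = None

    def validate(self) -> None:
        if np.any(self.contributions <= 0):
            raise AssertionError("contribution rates must be positive")
        if np.any(np.diff(self.contributions) > 1e-12):
            raise AssertionError("contribution rates must be non-increasing")
        if self.cumulative_contribution > 100 + 1e-9:
            raise AssertionError("cumulative contribution exceeds 100%")
        if self.membership_values is not None:
            u = self.membership_values.to_numpy()
            if u.min() < -1e-12 or u.max() > 1 + 1e-12:
                raise AssertionError("membership values outside [0, 1]")
        if self.weights_ is not None and abs(self.weights_.sum() - 1.0) > 1e-9:
            raise AssertionError("weights do not sum to 1")
        if self.d is not None and (
            self.d.min() < -1e-12 or self.d.max() > 1 + 1e-12
        ):
            raise AssertionError("D values outside [0, 1]")


def _sign_flip(v: np.ndarray, rtol: float = 1e-9) -> bool:
    """True when the loading vector's anchor entry is negative.

    The anchor is the first entry whose magnitude is within ``rtol`` of the
    maximum, making the convention robust to last-ulp magnitude ties.
    """
    a = np.abs(v)
    i = int(np.flatnonzero(a >= a.max() * (1 - rtol))[0])
    return bool(v[i] < 0)


def comprehensive_pca(
    coeff: pd.DataFrame,
    retention_rule: str = "kaiser",
    cumulative_threshold: float = 85.0,
    n_components: int | None = None,
) -> ComprehensiveEvaluation:
    """PCA of the standardized tolerance-coefficient matrix.

    Columns (traits) are standardized to zero mean and unit variance over
    genotypes, so the decomposition is of their correlation structure.
    Contribution rates are P_j = 100 * eigenvalue_j / sum(eigenvalues),
    components ordered by decreasing eigenvalue. Retention rules:
    ``"kaiser"`` keeps eigenvalues > 1 (at least one), ``"cumulative"``
    keeps the smallest set reaching ``cumulative_threshold`` percent,
    ``"fixed"`` keeps ``n_components``.
    """
    if coeff.shape[1] < 2:
        raise ValueError("need at least 2 traits for PCA")
    X = coeff.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        logger.warning("fewer genotypes (%d) than traits (%d); PCA may be unstable", n, p)
    sd = X.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(
            f"constant trait column(s) (zero variance): {list(coeff.columns[constant])}"
        )
    Z = (X - X.mean(axis=0)) / sd

    # SVD of the standardized matrix: eigenvalues of the correlation matrix
    # are s^2/(n-1), scores are U*s, loadings the right singular vectors.
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = s**2 / (n - 1)
    # Sign convention: largest-|entry| of each loading vector is positive
    # (ties broken at the lowest index, within a relative tolerance so the
    # choice is stable under rounding).
    for j in range(Vt.shape[0]):
        if _sign_flip(Vt[j]):
            Vt[j] *= -1
            U[:, j] *= -1
    scores_all = U * s

    contributions_all = 100.0 * eig / eig.sum()
    if retention_rule == "kaiser":
        m = max(1, int(np.sum(eig > 1.0)))
    elif retention_rule == "cumulative":
        m = int(np.searchsorted(np.cumsum(contributions_all), cumulative_threshold) + 1)
        m = min(m, len(eig))
    elif retention_rule == "fixed":
        if n_components is None or not (1 <= n_components <= len(eig)):
            raise ValueError("retention_rule='fixed' requires a valid n_components")
        m = int(n_components)
    else:
        raise ValueError(f"unknown retention rule {retention_rule!r}")

    comp_names = [f"PC{j + 1}" for j in range(m)]
    result = ComprehensiveEvaluation(
        loadings=pd.DataFrame(Vt[:m].T, index=coeff.columns, columns=comp_names),
        scores=pd.DataFrame(scores_all[:, :m], index=coeff.index, columns=comp_names),
        eigenvalues=eig,
        contributions=contributions_all[:m],
        contributions_all=contributions_all,
        cumulative_contribution=float(contributions_all[:m].sum()),
        n_retained=m,
        retention_rule=retention_rule,
    )
    result.validate()
    return result


def membership(scores: pd.DataFrame) -> pd.DataFrame:
    """Fuzzy membership U(X_j) = (X_j - min_j)/(max_j - min_j) per component.

    The genotype achieving a component's minimum maps to 0, the maximum to
    1. A degenerate component (max == min) is an error.
    """
    lo = scores.min(axis=0)
    hi = scores.max(axis=0)
    degenerate = hi[hi == lo].index.tolist()
    if degenerate:
        raise ValueError(f"degenerate component(s) with max == min: {degenerate}")
    return (scores - lo) / (hi - lo)


def weights(contributions: Sequence[float] | np.ndarray) -> np.ndarray:
    """Weights W_j = P_j / sum(P_j) over the retained components."""
    p = np.asarray(contributions, dtype=float)
    if p.size == 0:
        raise ValueError("no contribution rates supplied")
    if np.any(p <= 0):
        raise ValueError("contribution rates must all be positive")
    return p / p.sum()


def d_value(membership_values: pd.DataFrame, w: np.ndarray) -> pd.Series:
    """Comprehensive evaluation value D(g) = sum_j U(g, j) * W_j."""
    w = np.asarray(w, dtype=float)
    if membership_values.shape[1] != w.size:
        raise ValueError(
            f"membership has {membership_values.shape[1]} components but "
            f"{w.size} weights were supplied"
        )
    d = pd.Series(
        membership_values.to_numpy() @ w, index=membership_values.index, name="D"
    )
    return d


def evaluate(
    coeff: pd.DataFrame,
    retention_rule: str = "kaiser",
    cumulative_threshold: float = 85.0,
    n_components: int | None = None,
) -> ComprehensiveEvaluation:
    """Run the full coefficient -> PCA -> U -> W -> D chain."""
    ev = comprehensive_pca(coeff, retention_rule, cumulative_threshold, n_components)
    ev.membership_values = membership(ev.scores)
    ev.weights_ = weights(ev.contributions)
    ev.d = d_value(ev.membership_values, ev.weights_)
    ev.validate()
    return ev


@dataclass
class ToleranceClassification:
    """k-class partition of genotypes by their D values."""

    labels: pd.Series
    class_counts: dict[str, int]
    class_mean_d: dict[str, float]
    k: int
    method: str


def classify(d: pd.Series, k: int = 4, method: str = "average") -> ToleranceClassification:
    """Cluster the one-dimensional D values into k tolerance classes.

    Agglomerative hierarchical clustering (Euclidean distance, ``method``
    linkage — SPSS-style average by default, Ward available) cut at k
    clusters; clusters are labeled tolerant -> sensitive by descending
    mean D. For k=4 the canonical class names are used.
    """
    n = len(d)
    if k > n:
        raise ValueError(f"classify: k={k} exceeds the number of genotypes ({n})")
    if k < 1:
        raise ValueError("classify: k must be >= 1")
    values = d.to_numpy(dtype=float)
    if np.ptp(values) == 0:
        raise ValueError("classify: all D values identical (degenerate input)")
    Z = linkage(values.reshape(-1, 1), method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    found = np.unique(raw)
    if len(found) < k:
        logger.warning(
            "classify: only %d distinct clusters found for k=%d", len(found), k
        )
    # Order clusters by descending mean D; ties broken by cluster id.
    means = {c: values[raw == c].mean() for c in found}
    ordered = sorted(found, key=lambda c: (-means[c], c))
    names = (
        list(CLASS_LABELS)
        if len(ordered) == 4
        else [f"class_{i + 1}" for i in range(len(ordered))]
    )
    mapping = {c: names[i] for i, c in enumerate(ordered)}
    labels = pd.Series([mapping[c] for c in raw], index=d.index, name="class")
    return ToleranceClassification(
        labels=labels,
        class_counts={names[i]: int((raw == c).sum()) for i, c in enumerate(ordered)},
        class_mean_d={names[i]: float(means[c]) for i, c in enumerate(ordered)},
        k=k,
        method=method,
    )


@dataclass
class SelectionResult:
    """Extreme genotypes selected from the empirical D distribution."""

    tolerant: tuple[str, ...]
    sensitive: tuple[str, ...]
    upper_threshold: float
    lower_threshold: float
    universe: tuple[str, ...] = ()


def select_extremes(
    d: pd.Series, upper_pct: float = 99.0, lower_pct: float = 1.0
) -> SelectionResult:
    """Genotypes strictly above/below the empirical D percentiles.

    Percentiles use linear (type-7) interpolation; selection is by strict
    inequality, so ``lower_pct=0`` yields an empty sensitive set.
    """
    if upper_pct <= lower_pct:
        raise ValueError("upper_pct must exceed lower_pct")
    if len(d) < 100:
        logger.warning("select_extremes on only %d genotypes; percentiles are coarse", len(d))
    values = d.to_numpy(dtype=float)
    hi = float(np.percentile(values, upper_pct))
    lo = float(np.percentile(values, lower_pct))
    tolerant = d.index[values > hi]
    sensitive = d.index[values < lo]
    return SelectionResult(
        tolerant=tuple(tolerant),
        sensitive=tuple(sensitive),
        upper_threshold=hi,
        lower_threshold=lo,
        universe=tuple(d.index),
    )


def cross_stage_consensus(
    selections: Mapping[str, SelectionResult],
) -> dict[str, pd.DataFrame]:
    """Genotypes extreme in two or more growth stages.

    Returns, per direction ('tolerant', 'sensitive'), a membership table
    with one boolean column per stage, a 'stages' count, and a 'consensus'
    flag for genotypes selected in >= 2 stages. Mismatched genotype
    universes are warned about; membership is evaluated on the union.
    """
    if len(selections) < 2:
        raise ValueError("need selections from at least 2 stages")
    universes = {s: set(sel.universe) for s, sel in selections.items() if sel.universe}
    if len({frozenset(u) for u in universes.values()}) > 1:
        logger.warning("cross_stage_consensus: stage genotype universes differ; using the union")
    out: dict[str, pd.DataFrame] = {}
    for direction in ("tolerant", "sensitive"):
        sets = {s: set(getattr(sel, direction)) for s, sel in selections.items()}
        ids = sorted(set().union(*sets.values()))
        table = pd.DataFrame(
            {stage: [g in sets[stage] for g in ids] for stage in selections},
            index=pd.Index(ids, name="genotype"),
        )
        table["stages"] = table.sum(axis=1).astype(int)
        table["consensus"] = table["stages"] >= 2
        out[direction] = table
    return out
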