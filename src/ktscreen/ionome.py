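"""Ionome response arithmetic and K-utilization-efficiency indices.

Works on long-format elemental-concentration tables (tissue, treatment,
genotype, element, concentration, unit, significance letters). Percent
changes between the low-K (LK) and control (CK) treatments are the core
quantity; genotype contrasts report which genotype responded more per
(tissue, element). K content and K utilization efficiency follow the
biomass-per-unit-K convention whose printed unit is mg^2 dry weight per
ug K content, i.e. KUE = DW^2 / K content.
"""

from __future__ import annotations

import logging
import re
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ELEMENT_UNITS

logger = logging.getLogger(__name__)

__all__ = [
    "read_ionome_csv",
    "write_ionome_csv",
    "load_reference_ionome",
    "percent_change",
    "response_extremes",
    "k_content",
    "concentration_from_content",
    "kue",
    "genotype_contrast",
]

_CELL_RE = re.compile(r"^\s*([0-9][0-9.eE+-]*)\s*([A-Za-z]*)\s*$")
_HEADER_RE = re.compile(r"^(?P<element>\w+)\s*\((?P<unit>[^)]+)\)$")
_ELEMENT_ORDER = tuple(ELEMENT_UNITS)


def read_ionome_csv(path: str | Path) -> pd.DataFrame:
    """Read a wide ionome CSV into long format.

    Expected layout: columns ``tissue, treatment, genotype`` followed by
    one column per element with its unit in the header, e.g. ``K (g/kg)``.
    Cell values may carry trailing significance letters (``29.58Aa``),
    which are split off and kept as annotations, never computed on.
    """
    wide = pd.read_csv(path, dtype=str)
    for col in ("tissue", "treatment", "genotype"):
        if col not in wide.columns:
            raise ValueError(f"ionome CSV is missing column {col!r}")
    records = []
    for col in wide.columns[3:]:
        m = _HEADER_RE.match(col.strip())
        if not m:
            raise ValueError(f"element column {col!r} lacks a '(unit)' suffix")
        element, unit = m.group("element"), m.group("unit")
        for _, row in wide.iterrows():
            cell = str(row[col])
            cm = _CELL_RE.match(cell)
            if not cm:
                raise ValueError(f"cannot parse concentration cell {cell!r} in {col!r}")
            records.append(
                {
                    "tissue": row["tissue"],
                    "treatment": row["treatment"],
                    "genotype": row["genotype"],
                    "element": element,
                    "concentration": float(cm.group(1)),
                    "unit": unit,
                    "letters": cm.group(2),
                }
            )
    table = pd.DataFrame.from_records(records)
    _check_units(table)
    return table


def _check_units(table: pd.DataFrame) -> None:
    per_element = table.groupby("element")["unit"].nunique()
    mixed = per_element[per_element > 1].index.tolist()
    if mixed:
        raise ValueError(f"element(s) with inconsistent units: {mixed}")
    if (table["concentration"] < 0).any():
        raise ValueError("negative concentrations in ionome table")


def write_ionome_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format ionome table back to the wide CSV layout."""
    _check_units(table)
    units = table.groupby("element")["unit"].first()
    elements = [e for e in _ELEMENT_ORDER if e in units.index] + [
        e for e in units.index if e not in _ELEMENT_ORDER
    ]
    t = table.copy()
    t["cell"] = t["concentration"].map(lambda v: f"{v:g}") + t["letters"].fillna("")
    wide = t.pivot_table(
        index=["tissue", "treatment", "genotype"],
        columns="element",
        values="cell",
        aggfunc="first",
        sort=False,
    ).reset_index()
    wide = wide[["tissue", "treatment", "genotype"] + elements]
    wide.columns = ["tissue", "treatment", "genotype"] + [
        f"{e} ({units[e]})" for e in elements
    ]
    wide.to_csv(path, index=False)


def load_reference_ionome() -> pd.DataFrame:
    """Load the packaged KN9204/BN207 shoot+root elemental-content table."""
    with resources.as_file(
        resources.files("ktscreen.data").joinpath("table5_ionome.csv")
    ) as p:
        return read_ionome_csv(p)


def percent_change(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(tissue, genotype, element) percent change from CK to LK.

    percent change = (LK - CK) / CK * 100, retained at full precision with
    a 2-decimal reporting column. Each row carries a direction label and a
    rank of |percent change| within its (tissue, genotype) (1 = largest).
    Cells with CK = 0 or a missing treatment are flagged, not fabricated.
    """
    pivot = table.pivot_table(
        index=["tissue", "genotype", "element"],
        columns="treatment",
        values="concentration",
        aggfunc="first",
        sort=False,
    )
    for treatment in ("CK", "LK"):
        if treatment not in pivot.columns:
            pivot[treatment] = np.nan
    resp = pivot.reset_index()
    missing = resp["CK"].isna() | resp["LK"].isna()
    zero_ck = resp["CK"] == 0
    if missing.any():
        logger.warning("percent_change: %d cells missing a treatment", int(missing.sum()))
    if zero_ck.any():
        logger.warning("percent_change: %d cells with CK = 0", int(zero_ck.sum()))
    valid = ~(missing | zero_ck)
    resp["percent_change"] = np.where(
        valid, (resp["LK"] - resp["CK"]) / resp["CK"] * 100.0, np.nan
    )
    resp["percent_change_2dp"] = resp["percent_change"].round(2)
    resp["direction"] = pd.cut(
        resp["percent_change"],
        bins=[-np.inf, -1e-300, 1e-300, np.inf],
        labels=["decrease", "unchanged", "increase"],
    ).astype(object)
    resp.loc[resp["percent_change"] == 0, "direction"] = "unchanged"
    resp.loc[~valid, "direction"] = "undefined"
    resp["flag"] = np.select(
        [missing, zero_ck], ["missing-treatment", "zero-control"], default=""
    )
    resp["magnitude_rank"] = (
        resp["percent_change"]
        .abs()
        .groupby([resp["tissue"], resp["genotype"]])
        .rank(ascending=False, method="min")
    )
    return resp


def response_extremes(resp: pd.DataFrame) -> pd.DataFrame:
    """Largest/smallest decreases and increases per (tissue, genotype)."""
    rows = []
    for (tissue, genotype), grp in resp.groupby(["tissue", "genotype"], sort=False):
        for direction in ("decrease", "increase"):
            sub = grp[grp["direction"] == direction]
            if sub.empty:
                continue
            mags = sub["percent_change"].abs()
            for kind, idx in (("largest", mags.idxmax()), ("smallest", mags.idxmin())):
                rows.append(
                    {
                        "tissue": tissue,
                        "genotype": genotype,
                        "direction": direction,
                        "extreme": kind,
                        "element": sub.loc[idx, "element"],
                        "percent_change": sub.loc[idx, "percent_change"],
                    }
                )
    return pd.DataFrame(rows)


def k_content(
    dry_weight: float | np.ndarray,
    k_concentration: float | np.ndarray,
    dry_weight_unit: str = "mg",
    concentration_unit: str = "g/kg",
) -> float | np.ndarray:
    """K content (mg/plant) from dry weight (mg/plant) and K concentration (g/kg).

    content = DW [mg] * concentration [g/kg] * 1e-3; g/kg is mg/g, so the
    factor converts the per-gram concentration to the mg biomass scale.
    """
    if dry_weight_unit != "mg":
        raise ValueError(f"unsupported dry-weight unit {dry_weight_unit!r} (expected 'mg')")
    if concentration_unit != "g/kg":
        raise ValueError(
            f"unsupported concentration unit {concentration_unit!r} (expected 'g/kg')"
        )
    dw = np.asarray(dry_weight, dtype=float)
    conc = np.asarray(k_concentration, dtype=float)
    if (dw < 0).any() or (conc < 0).any():
        raise ValueError("dry weight and concentration must be nonnegative")
    out = dw * conc * 1e-3
    return float(out) if out.ndim == 0 else out


def concentration_from_content(
    k_content_mg: float | np.ndarray, dry_weight_mg: float | np.ndarray
) -> float | np.ndarray:
    """Invert :func:`k_content`: concentration (g/kg) from content and DW."""
    content = np.asarray(k_content_mg, dtype=float)
    dw = np.asarray(dry_weight_mg, dtype=float)
    if (dw <= 0).any():
        raise ValueError("dry weight must be positive to recover a concentration")
    out = content / dw * 1e3
    return float(out) if out.ndim == 0 else out


def kue(
    dry_weight_mg: float | np.ndarray,
    k_content_mg: float | np.ndarray,
    formula: str = "quadratic",
) -> float | np.ndarray:
    """K utilization efficiency from dry weight (mg) and K content (mg).

    The default ``"quadratic"`` form is DW^2 / content with content in ug,
    the only form consistent with the mg^2 DW per ug K unit; the
    ``"linear"`` alternative DW / content (mg biomass per ug K) is offered
    behind this switch.
    """
    dw = np.asarray(dry_weight_mg, dtype=float)
    content_ug = np.asarray(k_content_mg, dtype=float) * 1e3
    if (content_ug <= 0).any():
        raise ValueError("K content must be positive to compute KUE")
    if formula == "quadratic":
        out = dw**2 / content_ug
    elif formula == "linear":
        out = dw / content_ug
    else:
        raise ValueError(f"unknown KUE formula {formula!r}")
    return float(out) if out.ndim == 0 else out


def genotype_contrast(
    resp: pd.DataFrame, tolerant: str, sensitive: str
) -> pd.DataFrame:
    """Per-(tissue, element) comparison of low-K responses of two genotypes.

    The verdict names the genotype with the larger |percent change| and
    whether it was the greater decrease or increase; exactly equal changes
    are reported as a tie.
    """
    present = set(resp["genotype"].unique())
    for g in (tolerant, sensitive):
        if g not in present:
            raise ValueError(f"genotype {g!r} absent from the response table")
    a = resp[resp["genotype"] == tolerant].set_index(["tissue", "element"])
    b = resp[resp["genotype"] == sensitive].set_index(["tissue", "element"])
    idx = a.index.intersection(b.index)
    pc_a = a.loc[idx, "percent_change"]
    pc_b = b.loc[idx, "percent_change"]
    out = pd.DataFrame(
        {
            f"pct_{tolerant}": pc_a,
            f"pct_{sensitive}": pc_b,
        },
        index=idx,
    ).reset_index()
    abs_a, abs_b = pc_a.abs().to_numpy(), pc_b.abs().to_numpy()
    bigger = np.select(
        [abs_a > abs_b, abs_b > abs_a], [tolerant, sensitive], default="tie"
    )
    sign = np.where(
        np.where(abs_a >= abs_b, pc_a.to_numpy(), pc_b.to_numpy()) < 0,
        "decrease",
        "increase",
    )
    out["greater_change_in"] = bigger
    out["verdict"] = np.where(
        bigger == "tie", "tie", np.char.add("greater ", np.char.add(sign, " in "))
    )
    out.loc[out["greater_change_in"] != "tie", "verdict"] = (
        out.loc[out["greater_change_in"] != "tie", "verdict"]
        + out.loc[out["greater_change_in"] != "tie", "greater_change_in"]
    )
    return out
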