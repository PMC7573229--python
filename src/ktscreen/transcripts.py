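"""DEG direction calls, cross-genotype Venn partition and pattern selection.

Consumes per-gene differential-statistics tables (gene, log2 fold-change,
p-value) for two genotype contrasts — typically a low-K-tolerant and a
low-K-sensitive genotype, each LK vs CK. A gene is called up (down) when
its |log2 fold-change| clears the threshold in the corresponding direction
and its p-value is below alpha; otherwise it is unchanged. The boundary is
inclusive (>= theta) by default. Calls from the two contrasts are crossed
into a full 3x3 direction-pair table, from which the Venn counts and the
cross-genotype selection pattern — up in the tolerant contrast while down
or unchanged in the sensitive one, or unchanged in the tolerant contrast
while down in the sensitive one — are read off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import DIRECTIONS

logger = logging.getLogger(__name__)

__all__ = [
    "VennPartition",
    "PatternSelection",
    "DEFAULT_PATTERNS",
    "call_directions",
    "venn_partition",
    "select_pattern_genes",
]

#: Direction pairs (tolerant contrast, sensitive contrast) carried forward
#: to enrichment analysis.
DEFAULT_PATTERNS: tuple[tuple[str, str], ...] = (
    ("up", "down"),
    ("up", "unchanged"),
    ("unchanged", "down"),
)


def call_directions(
    table: pd.DataFrame,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    inclusive: bool = True,
    adjust: str = "none",
) -> pd.Series:
    """Per-gene direction call from log2 fold-change and p-value.

    up: log2FC >= +theta (or > when ``inclusive=False``) and p < alpha;
    down symmetric; everything else unchanged. ``adjust="bh"`` applies
    Benjamini-Hochberg correction to the p-values before gating (default
    off: raw p-values are the conventional input to this screen).
    Duplicate gene records are rejected.
    """
    for col in ("gene", "log2fc", "pvalue"):
        if col not in table.columns:
            raise ValueError(f"differential table is missing column {col!r}")
    if table["gene"].duplicated().any():
        dup = table.loc[table["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate record for gene {dup!r}")
    pvals = table["pvalue"].to_numpy(dtype=float)
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if adjust == "bh":
        from scipy.stats import false_discovery_control

        pvals = false_discovery_control(pvals, method="bh")
    elif adjust != "none":
        raise ValueError(f"unknown p-value adjustment {adjust!r}")
    lfc = table["log2fc"].to_numpy(dtype=float)
    if not np.isfinite(lfc).all():
        raise ValueError("log2 fold-changes must be finite")
    sig = pvals < alpha
    if inclusive:
        up = sig & (lfc >= lfc_threshold)
        down = sig & (lfc <= -lfc_threshold)
    else:
        up = sig & (lfc > lfc_threshold)
        down = sig & (lfc < -lfc_threshold)
    calls = np.where(up, "up", np.where(down, "down", "unchanged"))
    return pd.Series(calls, index=pd.Index(table["gene"], name="gene"), name="direction")


@dataclass
class VennPartition:
    """Cross-classification of direction calls between two contrasts."""

    table: pd.DataFrame  # 3x3 counts, rows = contrast A, cols = contrast B
    universe_size: int

    @property
    def up_common(self) -> int:
        return int(self.table.loc["up", "up"])

    @property
    def down_common(self) -> int:
        return int(self.table.loc["down", "down"])

    @property
    def up_only_a(self) -> int:
        return int(self.table.loc["up", ["down", "unchanged"]].sum())

    @property
    def up_only_b(self) -> int:
        return int(self.table.loc[["down", "unchanged"], "up"].sum())

    @property
    def down_only_a(self) -> int:
        return int(self.table.loc["down", ["up", "unchanged"]].sum())

    @property
    def down_only_b(self) -> int:
        return int(self.table.loc[["up", "unchanged"], "down"].sum())

    def counts(self) -> dict[str, int]:
        return {
            "up_common": self.up_common,
            "up_only_a": self.up_only_a,
            "up_only_b": self.up_only_b,
            "down_common": self.down_common,
            "down_only_a": self.down_only_a,
            "down_only_b": self.down_only_b,
            "universe": self.universe_size,
        }

    def validate(self) -> None:
        if int(self.table.to_numpy().sum()) != self.universe_size:
            raise AssertionError("3x3 partition does not sum to the gene universe")


def _align_calls(
    calls_a: pd.Series, calls_b: pd.Series
) -> tuple[pd.Series, pd.Series]:
    universe = calls_a.index.union(calls_b.index)
    if len(universe) == 0:
        raise ValueError("empty gene universe")
    absent = len(universe) - len(calls_a.index.intersection(calls_b.index))
    if absent:
        logger.warning(
            "%d genes absent from one contrast; treated as 'unchanged' there", absent
        )
    a = calls_a.reindex(universe, fill_value="unchanged")
    b = calls_b.reindex(universe, fill_value="unchanged")
    return a, b


def venn_partition(calls_a: pd.Series, calls_b: pd.Series) -> VennPartition:
    """Full 3x3 direction-pair contingency table between two contrasts.

    Genes present in only one contrast count as unchanged in the other
    (outer join with explicit handling, logged).
    """
    a, b = _align_calls(calls_a, calls_b)
    table = (
        pd.crosstab(a, b)
        .reindex(index=DIRECTIONS, columns=DIRECTIONS, fill_value=0)
        .astype(int)
    )
    table.index.name, table.columns.name = "contrast_a", "contrast_b"
    part = VennPartition(table=table, universe_size=len(a))
    part.validate()
    return part


@dataclass
class PatternSelection:
    """Genes matching the cross-genotype selection patterns."""

    genes: tuple[str, ...]
    pattern_counts: dict[tuple[str, str], int]

    @property
    def n_selected(self) -> int:
        return len(self.genes)


def select_pattern_genes(
    calls_tolerant: pd.Series,
    calls_sensitive: pd.Series,
    patterns: tuple[tuple[str, str], ...] = DEFAULT_PATTERNS,
) -> PatternSelection:
    """Genes whose (tolerant, sensitive) direction pair matches a pattern.

    The default patterns are (up, down), (up, unchanged) and
    (unchanged, down): genes induced in the tolerant genotype but not in
    the sensitive one, or repressed only in the sensitive one.
    """
    a, b = _align_calls(calls_tolerant, calls_sensitive)
    selected: list[str] = []
    counts: dict[tuple[str, str], int] = {}
    for pattern in patterns:
        mask = (a == pattern[0]) & (b == pattern[1])
        counts[pattern] = int(mask.sum())
        selected.extend(a.index[mask])
    return PatternSelection(genes=tuple(sorted(selected)), pattern_counts=counts)
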