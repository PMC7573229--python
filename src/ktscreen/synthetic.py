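"""Synthetic data generators for the low-K screening pipeline.

Every downstream stage of the pipeline (germplasm screening, ionome
responses, metabolite screen, DEG set algebra) consumes tabular input
that in a real study comes from phenotyping and omics platforms. The
generators here emit tables with the statistical structure those stages
assume — a latent tolerance factor driving genotype-specific low-K/control
trait ratios, multiplicative treatment effects on elemental concentrations,
log-normal metabolite intensities with planted group shifts, and per-gene
differential statistics with planted direction patterns — together with a
:class:`SyntheticTruth` sidecar recording exactly what was planted. Truth
is returned alongside the data, never embedded in it, so parameter-recovery
tests can compare estimates against ground truth.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitDescriptor",
    "TraitGenSpec",
    "SyntheticTruth",
    "SEEDLING_TRAITS",
    "DEFAULT_TIERS_543",
    "ELEMENT_UNITS",
    "DIRECTIONS",
    "generate_trait_panel",
    "generate_ionome_table",
    "generate_metabolite_matrix",
    "generate_deg_table",
]

DIRECTIONS = ("up", "down", "unchanged")

#: Units of the ten elements assayed in the ionome stage.
ELEMENT_UNITS = {
    "N": "g/kg",
    "P": "g/kg",
    "K": "g/kg",
    "Ca": "g/kg",
    "Mg": "g/kg",
    "Na": "g/kg",
    "Fe": "mg/kg",
    "Mn": "mg/kg",
    "Cu": "mg/kg",
    "Zn": "mg/kg",
}

# Typical control-level concentrations used when drawing synthetic ionomes.
_ELEMENT_BASE = {
    "N": 25.0,
    "P": 5.0,
    "K": 15.0,
    "Ca": 2.0,
    "Mg": 1.0,
    "Na": 2.5,
    "Fe": 20.0,
    "Mn": 7.0,
    "Cu": 4.0,
    "Zn": 32.0,
}


@dataclass(frozen=True)
class TraitDescriptor:
    """One measured seedling/mature-stage index.

    Parameters
    ----------
    name:
        Trait label, e.g. ``"SL"`` for shoot length.
    unit:
        Measurement unit carried through to the emitted panel.
    control_mean:
        Population mean under the control (CK) treatment; must be > 0.
    control_cv:
        Genotype-level coefficient of variation under CK, as a fraction.
    direction:
        Whether low-K stress typically decreases or increases the trait.
    lk_ck_ratio:
        Population-mean ratio of LK to CK trait means; must be > 0.
    ratio_dispersion:
        Relative spread of the per-genotype LK/CK ratio around its mean,
        scaled by the tolerance loading and the latent tolerance score.
    """

    name: str
    unit: str
    control_mean: float
    control_cv: float
    direction: str
    lk_ck_ratio: float
    ratio_dispersion: float = 0.15

    def __post_init__(self) -> None:
        if self.control_mean <= 0:
            raise ValueError(
                f"trait {self.name!r}: control mean must be positive, got {self.control_mean}"
            )
        if self.lk_ck_ratio <= 0:
            raise ValueError(
                f"trait {self.name!r}: mean LK/CK ratio must be positive, got {self.lk_ck_ratio}"
            )
        if self.direction not in ("decrease", "increase"):
            raise ValueError(
                f"trait {self.name!r}: direction must be 'decrease' or 'increase'"
            )
        if self.control_cv < 0 or self.ratio_dispersion < 0:
            raise ValueError(f"trait {self.name!r}: dispersions must be nonnegative")


#: The thirteen seedling-stage indices with means, genotype CVs and mean
#: LK/CK ratios calibrated to a 543-genotype hydroponic panel. RSDW is the
#: root-to-shoot dry-weight ratio, essentially unchanged by the stress.
SEEDLING_TRAITS: tuple[TraitDescriptor, ...] = (
    TraitDescriptor("LL", "cm", 13.07, 0.3246, "decrease", 10.21 / 13.07),
    TraitDescriptor("LA", "cm^2", 2.99, 0.3667, "decrease", 2.09 / 2.99),
    TraitDescriptor("SL", "cm", 18.01, 0.2671, "decrease", 14.89 / 18.01),
    TraitDescriptor("SDW", "mg/plant", 21.36, 0.2709, "decrease", 17.22 / 21.36),
    TraitDescriptor("RDW", "mg/plant", 11.35, 0.3320, "decrease", 9.18 / 11.35),
    TraitDescriptor("TDW", "mg/plant", 32.41, 0.2625, "decrease", 26.39 / 32.41),
    TraitDescriptor("RSDW", "ratio", 0.53, 0.20, "increase", 1.00),
    TraitDescriptor("SKCe", "g/kg", 24.44, 0.3431, "decrease", 6.93 / 24.44),
    TraitDescriptor("RKCe", "g/kg", 7.72, 0.5189, "decrease", 3.05 / 7.72),
    TraitDescriptor("SKC", "mg/plant", 1.02, 0.4602, "decrease", 0.28 / 1.02),
    TraitDescriptor("RKC", "mg/plant", 0.08, 0.5379, "decrease", 0.03 / 0.08),
    TraitDescriptor("SKUE", "mg^2/ug", 0.99, 0.5033, "increase", 2.61 / 0.99),
    TraitDescriptor("RKUE", "mg^2/ug", 1.95, 0.6550, "increase", 3.52 / 1.95),
)

#: Default planted tolerance tiers for a 543-genotype panel: (size, latent
#: center, within-tier sd). Sizes follow the canonical tolerant /
#: moderately tolerant / moderately sensitive / sensitive split; centers
#: are separated far beyond the within-tier spread so tier recovery is a
#: property of the pipeline, not of luck.
DEFAULT_TIERS_543: tuple[tuple[int, float, float], ...] = (
    (7, 3.0, 0.25),
    (50, 1.5, 0.25),
    (238, 0.0, 0.25),
    (248, -1.2, 0.25),
)


@dataclass(frozen=True)
class TraitGenSpec:
    """Specification for a synthetic genotype x trait x treatment panel.

    ``tolerance_loading`` links the latent per-genotype tolerance score z
    to the per-genotype LK/CK ratio of each trait:

        ratio_t(g) = clip( r_t * (1 + loading_t * dispersion_t * z_g), >0 )

    where r_t is the trait's mean LK/CK ratio. A positive loading on a
    "decrease" trait means tolerant genotypes lose less of the trait under
    stress. ``noise_sd`` is the replicate measurement noise expressed as a
    fraction of the genotype's control mean.
    """

    n_genotypes: int
    traits: Sequence[TraitDescriptor] = SEEDLING_TRAITS
    n_replicates: int = 3
    tolerance_loading: float | Sequence[float] = 0.8
    noise_sd: float = 0.10
    seed: int = 0
    tolerance_tiers: Sequence[tuple[int, float, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_genotypes < 1:
            raise ValueError("n_genotypes must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not self.traits:
            raise ValueError("at least one trait descriptor is required")
        loadings = self.loading_array()
        if np.any(np.abs(loadings) > 1):
            raise ValueError("tolerance_loading entries must lie in [-1, 1]")
        if self.tolerance_tiers is not None:
            sizes = [int(s) for s, _, _ in self.tolerance_tiers]
            if any(s < 1 for s in sizes):
                raise ValueError("tier sizes must be positive")
            if sum(sizes) != self.n_genotypes:
                raise ValueError(
                    f"tier sizes sum to {sum(sizes)}, expected n_genotypes={self.n_genotypes}"
                )

    def loading_array(self) -> np.ndarray:
        arr = np.asarray(self.tolerance_loading, dtype=float)
        if arr.ndim == 0:
            arr = np.full(len(self.traits), float(arr))
        if arr.shape != (len(self.traits),):
            raise ValueError(
                f"tolerance_loading must be scalar or length {len(self.traits)}"
            )
        return arr


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator, kept apart from the data.

    Only the fields relevant to the generator that produced the object are
    populated; the rest stay ``None``.
    """

    latent_tolerance: dict[str, float] | None = None
    tier_labels: dict[str, int] | None = None
    planted_differential_features: dict[str, float] | None = None
    planted_gene_patterns: dict[str, tuple[str, str]] | None = None

    def to_json(self, path: str | Path) -> None:
        """Write the truth object as a JSON sidecar file."""
        payload = {
            "latent_tolerance": self.latent_tolerance,
            "tier_labels": self.tier_labels,
            "planted_differential_features": self.planted_differential_features,
            "planted_gene_patterns": (
                {g: list(p) for g, p in self.planted_gene_patterns.items()}
                if self.planted_gene_patterns is not None
                else None
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        patterns = payload.get("planted_gene_patterns")
        if patterns is not None:
            patterns = {g: tuple(p) for g, p in patterns.items()}
        return cls(
            latent_tolerance=payload.get("latent_tolerance"),
            tier_labels=payload.get("tier_labels"),
            planted_differential_features=payload.get("planted_differential_features"),
            planted_gene_patterns=patterns,
        )


def _latent_scores(
    spec: TraitGenSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray | None]:
    if spec.tolerance_tiers is None:
        return rng.standard_normal(spec.n_genotypes), None
    parts, labels = [], []
    for tier_idx, (size, center, sd) in enumerate(spec.tolerance_tiers):
        parts.append(rng.normal(center, sd, int(size)))
        labels.extend([tier_idx] * int(size))
    return np.concatenate(parts), np.asarray(labels)


def generate_trait_panel(spec: TraitGenSpec) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a replicate-level trait panel under CK and LK treatments.

    Returns a long-format DataFrame with columns ``genotype, trait,
    treatment, replicate, value, unit`` (one record per genotype x trait x
    treatment x replicate) and the :class:`SyntheticTruth` holding each
    genotype's latent tolerance score (and tier label when tiers were
    requested). Replicate noise is Gaussian with sd equal to
    ``spec.noise_sd`` times the genotype's control mean, with negative
    draws censored at zero.
    """
    rng = np.random.default_rng(spec.seed)
    z, tiers = _latent_scores(spec, rng)
    genotypes = np.array([f"G{i + 1:04d}" for i in range(spec.n_genotypes)])
    loadings = spec.loading_array()

    n_g, n_r = spec.n_genotypes, spec.n_replicates
    frames = []
    for t_idx, trait in enumerate(spec.traits):
        ctrl_g = trait.control_mean * np.clip(
            rng.normal(1.0, trait.control_cv, n_g), 0.05, None
        )
        ratio_g = np.clip(
            trait.lk_ck_ratio
            * (1.0 + loadings[t_idx] * trait.ratio_dispersion * z),
            1e-6,
            None,
        )
        for treatment, mean_g in (("CK", ctrl_g), ("LK", ctrl_g * ratio_g)):
            noise = rng.normal(0.0, 1.0, (n_g, n_r)) * (
                spec.noise_sd * ctrl_g[:, None]
            )
            values = np.clip(mean_g[:, None] + noise, 0.0, None)
            frames.append(
                pd.DataFrame(
                    {
                        "genotype": np.repeat(genotypes, n_r),
                        "trait": trait.name,
                        "treatment": treatment,
                        "replicate": np.tile(np.arange(1, n_r + 1), n_g),
                        "value": values.ravel(),
                        "unit": trait.unit,
                    }
                )
            )
    panel = pd.concat(frames, ignore_index=True)
    truth = SyntheticTruth(
        latent_tolerance=dict(zip(genotypes.tolist(), z.astype(float).tolist())),
        tier_labels=(
            dict(zip(genotypes.tolist(), tiers.astype(int).tolist()))
            if tiers is not None
            else None
        ),
    )
    return panel, truth


def generate_ionome_table(
    elements: Sequence[str] | None = None,
    tissues: Sequence[str] = ("shoot", "root"),
    genotypes: Sequence[str] = ("KN9204", "BN207"),
    effect_map: Mapping[tuple[str, str, str], float] | None = None,
    seed: int = 0,
    concentration_cv: float = 0.25,
) -> pd.DataFrame:
    """Generate a long-format ionome table under CK and LK treatments.

    CK concentrations are drawn log-normally around element-typical levels;
    the LK concentration of each (tissue, genotype, element) cell equals
    its CK concentration times the multiplicative effect supplied in
    ``effect_map`` (keyed ``(tissue, genotype, element)``; missing keys
    default to 1.0, i.e. no response). Effects must be strictly positive.
    """
    if elements is None:
        elements = list(ELEMENT_UNITS)
    unknown = [e for e in elements if e not in ELEMENT_UNITS]
    if unknown:
        raise ValueError(f"unknown elements (no unit declared): {unknown}")
    effect_map = dict(effect_map or {})
    for key, eff in effect_map.items():
        if eff <= 0:
            raise ValueError(f"multiplicative LK effect must be > 0, got {eff} for {key}")

    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + concentration_cv**2))
    records = []
    for tissue in tissues:
        for genotype in genotypes:
            for element in elements:
                base = _ELEMENT_BASE[element]
                ck = float(base * rng.lognormal(-0.5 * sigma**2, sigma))
                lk = ck * effect_map.get((tissue, genotype, element), 1.0)
                for treatment, conc in (("CK", ck), ("LK", lk)):
                    records.append(
                        {
                            "tissue": tissue,
                            "treatment": treatment,
                            "genotype": genotype,
                            "element": element,
                            "concentration": conc,
                            "unit": ELEMENT_UNITS[element],
                            "letters": "",
                        }
                    )
    return pd.DataFrame.from_records(records)


def generate_metabolite_matrix(
    n_samples_per_group: int = 3,
    n_features: int = 200,
    n_differential: int = 20,
    fc_range: tuple[float, float] = (2.5, 8.0),
    noise_sd: float = 0.2,
    seed: int = 0,
    group_labels: tuple[str, str] = ("CK", "LK"),
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a two-class metabolite intensity matrix with planted effects.

    Intensities are log-normal: feature j has a latent log-intensity mu_j,
    samples add Gaussian noise with sd ``noise_sd`` on the log scale, and
    planted differential features shift the second group's mean by
    log(true fold-change). Fold changes are drawn from ``fc_range`` (which
    must not intrude into the non-differential band (0.5, 2)) and inverted
    to 1/fc for a random half of the planted features, so both directions
    occur. The truth object maps planted metabolite ids to their true
    group-mean ratio (group 2 over group 1).
    """
    if n_samples_per_group < 2:
        raise ValueError("need >= 2 samples per group (discriminant model undefined)")
    if n_differential > n_features:
        raise ValueError("n_differential cannot exceed n_features")
    lo, hi = fc_range
    if not (lo <= hi) or lo < 2.0:
        raise ValueError(
            "fc_range must lie within [2, inf) so planted fold-changes "
            "(or their reciprocals) clear the differential gate"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")

    rng = np.random.default_rng(seed)
    features = np.array([f"M{j + 1:04d}" for j in range(n_features)])
    mu = rng.normal(13.0, 1.0, n_features)

    planted_idx = rng.choice(n_features, size=n_differential, replace=False)
    fc = rng.uniform(lo, hi, n_differential)
    invert = rng.random(n_differential) < 0.5
    true_fc = np.where(invert, 1.0 / fc, fc)

    n = n_samples_per_group
    shift = np.zeros(n_features)
    shift[planted_idx] = np.log(true_fc)
    log_means = np.vstack([np.tile(mu, (n, 1)), np.tile(mu + shift, (n, 1))])
    X = np.exp(log_means + rng.normal(0.0, noise_sd, (2 * n, n_features)))

    samples = [f"{group_labels[0]}_{i + 1}" for i in range(n)] + [
        f"{group_labels[1]}_{i + 1}" for i in range(n)
    ]
    matrix = pd.DataFrame(X, index=pd.Index(samples, name="sample"), columns=features)
    matrix.insert(0, "group", [group_labels[0]] * n + [group_labels[1]] * n)

    order = np.argsort(planted_idx)
    truth = SyntheticTruth(
        planted_differential_features={
            features[planted_idx[i]]: float(true_fc[i]) for i in order
        }
    )
    return matrix, truth


#: Default per-gene probabilities over (tolerant-contrast, sensitive-contrast)
#: direction pairs; most genes respond in neither contrast.
DEFAULT_PATTERN_PROBS: dict[tuple[str, str], float] = {
    ("up", "up"): 0.02,
    ("up", "down"): 0.01,
    ("up", "unchanged"): 0.02,
    ("down", "up"): 0.01,
    ("down", "down"): 0.03,
    ("down", "unchanged"): 0.02,
    ("unchanged", "up"): 0.03,
    ("unchanged", "down"): 0.04,
    ("unchanged", "unchanged"): 0.82,
}


def generate_deg_table(
    n_genes: int = 10000,
    pattern_probabilities: Mapping[tuple[str, str], float] | None = None,
    effect_size_model: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    contrasts: tuple[str, str] = ("tolerant", "sensitive"),
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate two per-gene differential tables with planted patterns.

    Each gene is assigned a direction pair over the two genotype contrasts
    by a multinomial draw from ``pattern_probabilities`` (9 pairs over
    {up, down, unchanged}^2, summing to 1 within 1e-9). log2 fold-changes
    and p-values are then drawn so the planted direction is what the
    standard gate (|log2FC| >= 1, p < 0.05) recovers: changed genes get
    |log2FC| in [1.5, 5] and p ~ U(0, 0.04); unchanged genes get |log2FC|
    <= 0.5 and p ~ U(0.1, 1). ``effect_size_model`` can override those
    ranges with keys ``"changed_lfc"``, ``"unchanged_lfc"``,
    ``"changed_p"``, ``"unchanged_p"``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    probs = dict(pattern_probabilities or DEFAULT_PATTERN_PROBS)
    pairs = [(a, b) for a in DIRECTIONS for b in DIRECTIONS]
    unknown = set(probs) - set(pairs)
    if unknown:
        raise ValueError(f"unknown direction pairs: {sorted(unknown)}")
    p = np.array([probs.get(pair, 0.0) for pair in pairs], dtype=float)
    if np.any(p < 0):
        raise ValueError("pattern probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"pattern probabilities sum to {p.sum():.12f}, expected 1")

    ranges = {
        "changed_lfc": (1.5, 5.0),
        "unchanged_lfc": (0.0, 0.5),
        "changed_p": (0.0, 0.04),
        "unchanged_p": (0.1, 1.0),
    }
    ranges.update(effect_size_model or {})

    rng = np.random.default_rng(seed)
    genes = np.array([f"gene{g + 1:05d}" for g in range(n_genes)])
    pattern_idx = rng.choice(len(pairs), size=n_genes, p=p / p.sum())

    tables = []
    for side, contrast in enumerate(contrasts):
        direction = np.array([pairs[i][side] for i in pattern_idx])
        lfc = np.empty(n_genes)
        pval = np.empty(n_genes)
        changed = direction != "unchanged"
        n_changed = int(changed.sum())
        mag = rng.uniform(*ranges["changed_lfc"], n_changed)
        sign = np.where(direction[changed] == "up", 1.0, -1.0)
        lfc[changed] = sign * mag
        pval[changed] = rng.uniform(*ranges["changed_p"], n_changed)
        n_unch = n_genes - n_changed
        lfc[~changed] = rng.uniform(
            -ranges["unchanged_lfc"][1], ranges["unchanged_lfc"][1], n_unch
        )
        pval[~changed] = rng.uniform(*ranges["unchanged_p"], n_unch)
        tables.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "log2fc": lfc,
                    "pvalue": pval,
                    "contrast": contrast,
                }
            )
        )

    truth = SyntheticTruth(
        planted_gene_patterns={
            genes[g]: pairs[pattern_idx[g]] for g in range(n_genes)
        }
    )
    return tables[0], tables[1], truth
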