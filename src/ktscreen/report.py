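"""Pipeline orchestration, run manifests and the human-readable report.

`run_pipeline` drives the stages in dependency order (synthetic inputs ->
germplasm screening -> ionome -> metabolite screen -> DEG screen), writes
every artifact as plain CSV/JSON/text, and records a manifest with the
fully-resolved configuration (defaults echoed), its hash, the per-stage
convention decisions, input checksums and derived seeds — enough to
reproduce deterministic stages bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from . import ionome as ion
from . import metabolomics as met
from . import screening as scr
from . import synthetic as syn
from . import transcripts as tra

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "StageError", "resolve_config", "run_pipeline", "render_report"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "stages": {
        "screening": True,
        "ionome": True,
        "metabolites": True,
        "degs": True,
    },
    "synthetic": {
        "n_genotypes": 543,
        "n_replicates": 3,
        "tolerance_loading": 0.8,
        "noise_sd": 0.10,
        "tiered": True,
        "metabolites": {
            "n_samples_per_group": 3,
            "n_features": 200,
            "n_differential": 20,
            "fc_range": [2.5, 8.0],
            "noise_sd": 0.2,
        },
        "degs": {"n_genes": 10000},
    },
    "screening": {
        "retention_rule": "kaiser",
        "cumulative_threshold": 85.0,
        "k": 4,
        "cluster_method": "average",
        "upper_pct": 99.0,
        "lower_pct": 1.0,
    },
    "ionome": {
        "contrast": ["KN9204", "BN207"],
        "kue_formula": "quadratic",
    },
    "metabolites": {
        "n_orthogonal": 1,
        "scaling": "uv",
        "log_transform": True,
        "vip_threshold": 1.0,
        "fc_up": 2.0,
        "fc_down": 0.5,
    },
    "degs": {
        "lfc_threshold": 1.0,
        "alpha": 0.05,
        "inclusive_boundary": True,
    },
}

#: Convention decisions surfaced in every manifest (no silent defaults).
DECISIONS = {
    "pca_sign_convention": "largest-|loading| entry of each component made positive",
    "pca_standardization": "columns standardized (correlation-matrix PCA), sd with n-1",
    "percentile_convention": "linear interpolation (type 7), strict inequality for selection",
    "tolerance_coefficient": "replicate means per genotype first, then LK/CK ratio",
    "kue_coefficient_inversion": "traits with coefficient > 1 under stress are not inverted",
    "deg_boundary": "|log2FC| >= threshold (inclusive), raw p-values (no FDR)",
    "vip_source": "predictive component only (orthogonal variation excluded)",
    "fold_change_scale": "raw (unlogged) group means",
    "noise_truncation": "Gaussian replicate noise censored at 0",
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


def _merge(defaults: Mapping[str, Any], override: Mapping[str, Any], path: str = "") -> dict:
    out = dict(defaults)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key {where!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, Mapping):
                raise ValueError(f"config key {where!r} must be a mapping")
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = value
    return out


def resolve_config(config: Mapping[str, Any] | None = None) -> dict:
    """Merge a partial config over the defaults, rejecting unknown keys."""
    return _merge(DEFAULT_CONFIG, config or {})


def _config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    # Fan one global seed out to independent per-stage substreams, keeping
    # each derived seed below 2^31 so it round-trips through any RNG API.
    state = np.random.SeedSequence(seed).generate_state(4)
    names = ("traits", "ionome", "metabolites", "degs")
    return {name: int(s % (2**31)) for name, s in zip(names, state)}


def run_pipeline(
    config: Mapping[str, Any] | None,
    outdir: str | Path,
    panel: pd.DataFrame | None = None,
    ionome_table: pd.DataFrame | None = None,
) -> dict[str, Any]:
    """Run the configured stages end to end, writing artifacts to ``outdir``.

    When ``panel``/``ionome_table`` are not supplied, synthetic inputs are
    generated from the per-stage seed substreams. Returns the manifest
    (also written to ``manifest.json``).
    """
    cfg = resolve_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(cfg["seed"]))
    manifest: dict[str, Any] = {
        "package": "ktscreen",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "decisions": DECISIONS,
        "stage_seeds": seeds,
        "inputs": {},
        "stages_run": [],
    }

    if cfg["stages"]["screening"]:
        _run_screening(cfg, out, seeds["traits"], panel, manifest)
    if cfg["stages"]["ionome"]:
        _run_ionome(cfg, out, seeds["ionome"], ionome_table, manifest)
    if cfg["stages"]["metabolites"]:
        _run_metabolites(cfg, out, seeds["metabolites"], manifest)
    if cfg["stages"]["degs"]:
        _run_degs(cfg, out, seeds["degs"], manifest)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    render_report(out)
    return manifest


def _run_screening(cfg, out: Path, seed: int, panel, manifest) -> None:
    try:
        s = cfg["synthetic"]
        if panel is None:
            spec = syn.TraitGenSpec(
                n_genotypes=s["n_genotypes"],
                n_replicates=s["n_replicates"],
                tolerance_loading=s["tolerance_loading"],
                noise_sd=s["noise_sd"],
                seed=seed,
                tolerance_tiers=(
                    syn.DEFAULT_TIERS_543
                    if s["tiered"] and s["n_genotypes"] == 543
                    else None
                ),
            )
            panel, truth = syn.generate_trait_panel(spec)
            truth.to_json(out / "trait_truth.json")
            panel.to_csv(out / "trait_panel.csv", index=False)
        summary = scr.summarize_traits(panel)
        summary.to_csv(out / "trait_summary.csv", index=False)
        coeff = scr.tolerance_coefficients(panel)
        coeff.to_csv(out / "tolerance_coefficients.csv")
        p = cfg["screening"]
        ev = scr.evaluate(
            coeff,
            retention_rule=p["retention_rule"],
            cumulative_threshold=p["cumulative_threshold"],
        )
        evaluation = ev.scores.copy()
        evaluation.columns = [f"score_{c}" for c in evaluation.columns]
        for j, c in enumerate(ev.membership_values.columns):
            evaluation[f"U_{c}"] = ev.membership_values[c]
        evaluation["D"] = ev.d
        evaluation.to_csv(out / "evaluation.csv")
        pd.DataFrame(
            {
                "component": ev.scores.columns,
                "eigenvalue": ev.eigenvalues[: ev.n_retained],
                "contribution_pct": ev.contributions,
                "weight": ev.weights_,
            }
        ).to_csv(out / "components.csv", index=False)
        cls = scr.classify(ev.d, k=p["k"], method=p["cluster_method"])
        cls.labels.to_frame().assign(D=ev.d).to_csv(out / "classification.csv")
        sel = scr.select_extremes(ev.d, p["upper_pct"], p["lower_pct"])
        pd.DataFrame(
            {
                "genotype": list(sel.tolerant) + list(sel.sensitive),
                "direction": ["tolerant"] * len(sel.tolerant)
                + ["sensitive"] * len(sel.sensitive),
            }
        ).to_csv(out / "extremes.csv", index=False)
        manifest["stages_run"].append("screening")
        manifest["screening_summary"] = {
            "n_genotypes": int(coeff.shape[0]),
            "n_traits": int(coeff.shape[1]),
            "n_components_retained": ev.n_retained,
            "cumulative_contribution_pct": ev.cumulative_contribution,
            "class_counts": cls.class_counts,
            "class_mean_d": cls.class_mean_d,
            "n_tolerant_selected": len(sel.tolerant),
            "n_sensitive_selected": len(sel.sensitive),
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("screening", exc) from exc


def _run_ionome(cfg, out: Path, seed: int, table, manifest) -> None:
    try:
        if table is None:
            table = ion.load_reference_ionome()
            manifest["inputs"]["ionome"] = "packaged reference table"
        resp = ion.percent_change(table)
        resp.to_csv(out / "ionome_response.csv", index=False)
        ion.response_extremes(resp).to_csv(out / "ionome_extremes.csv", index=False)
        a, b = cfg["ionome"]["contrast"]
        contrast = ion.genotype_contrast(resp, a, b)
        contrast.to_csv(out / "ionome_contrast.csv", index=False)
        manifest["stages_run"].append("ionome")
        manifest["ionome_summary"] = {
            "n_cells": int(len(resp)),
            "contrast": [a, b],
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("ionome", exc) from exc


def _run_metabolites(cfg, out: Path, seed: int, manifest) -> None:
    try:
        s = cfg["synthetic"]["metabolites"]
        matrix, truth = syn.generate_metabolite_matrix(
            n_samples_per_group=s["n_samples_per_group"],
            n_features=s["n_features"],
            n_differential=s["n_differential"],
            fc_range=tuple(s["fc_range"]),
            noise_sd=s["noise_sd"],
            seed=seed,
        )
        matrix.to_csv(out / "metabolite_matrix.csv")
        truth.to_json(out / "metabolite_truth.json")
        m = cfg["metabolites"]
        X, groups = met.split_matrix(matrix)
        model = met.fit_oplsda(
            X,
            groups=groups,
            n_orthogonal=m["n_orthogonal"],
            log_transform=m["log_transform"],
            scaling=m["scaling"],
        )
        fc = met.fold_change(X, groups=groups)
        screen = met.screen_metabolites(
            met.vip_scores(model),
            fc,
            vip_threshold=m["vip_threshold"],
            fc_up=m["fc_up"],
            fc_down=m["fc_down"],
        )
        screen.table.to_csv(out / "metabolite_screen.csv")
        (out / "oplsda_model.json").write_text(
            json.dumps(
                {
                    "classes": list(model.classes),
                    "n_orthogonal": model.n_orthogonal,
                    "r2y_predictive": model.r2y,
                    "scaling": model.preprocessing.scaling,
                    "log_transform": model.preprocessing.log_transform,
                    "mean_vip_sq": float((model.vip**2).mean()),
                },
                indent=1,
            )
        )
        manifest["stages_run"].append("metabolites")
        manifest["metabolites_summary"] = {
            "n_features": int(X.shape[1]),
            "r2y_predictive": model.r2y,
            "screen_counts": screen.counts,
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("metabolites", exc) from exc


def _run_degs(cfg, out: Path, seed: int, manifest) -> None:
    try:
        table_a, table_b, truth = syn.generate_deg_table(
            n_genes=cfg["synthetic"]["degs"]["n_genes"], seed=seed
        )
        table_a.to_csv(out / "degs_tolerant.csv", index=False)
        table_b.to_csv(out / "degs_sensitive.csv", index=False)
        truth.to_json(out / "deg_truth.json")
        d = cfg["degs"]
        calls_a = tra.call_directions(
            table_a, d["lfc_threshold"], d["alpha"], d["inclusive_boundary"]
        )
        calls_b = tra.call_directions(
            table_b, d["lfc_threshold"], d["alpha"], d["inclusive_boundary"]
        )
        part = tra.venn_partition(calls_a, calls_b)
        (out / "venn_counts.json").write_text(json.dumps(part.counts(), indent=1))
        part.table.to_csv(out / "venn_table.csv")
        sel = tra.select_pattern_genes(calls_a, calls_b)
        (out / "selected_genes.txt").write_text("\n".join(sel.genes) + "\n")
        manifest["stages_run"].append("degs")
        manifest["degs_summary"] = {
            "venn": part.counts(),
            "n_selected": sel.n_selected,
            "pattern_counts": {f"{a}/{b}": n for (a, b), n in sel.pattern_counts.items()},
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("degs", exc) from exc


def _section(lines: list[str], title: str) -> None:
    lines.append(f"\n## {title}\n")


def render_report(artifacts_dir: str | Path) -> Path:
    """Assemble a markdown report from whatever stage artifacts exist.

    Idempotent: regenerating over the same artifacts produces the same
    report. Raises if the directory holds no known artifacts.
    """
    d = Path(artifacts_dir)
    lines = ["# Low-K tolerance screening report"]
    found = False

    if (d / "trait_summary.csv").exists():
        found = True
        _section(lines, "Trait summary (per trait and treatment)")
        lines.append(pd.read_csv(d / "trait_summary.csv").round(2).to_markdown(index=False))
    if (d / "components.csv").exists():
        found = True
        _section(lines, "Comprehensive indices (retained components)")
        lines.append(pd.read_csv(d / "components.csv").round(4).to_markdown(index=False))
    if (d / "classification.csv").exists():
        found = True
        cls = pd.read_csv(d / "classification.csv", index_col=0)
        _section(lines, "Tolerance classification")
        counts = cls["class"].value_counts()
        means = cls.groupby("class")["D"].mean()
        summary = pd.DataFrame({"count": counts, "mean_D": means.round(3)})
        lines.append(summary.to_markdown())
    if (d / "extremes.csv").exists():
        found = True
        _section(lines, "Extreme genotypes (percentile selection)")
        lines.append(pd.read_csv(d / "extremes.csv").to_markdown(index=False))
    if (d / "ionome_response.csv").exists():
        found = True
        _section(lines, "Ionome responses (percent change, LK vs CK)")
        resp = pd.read_csv(d / "ionome_response.csv")
        wide = resp.pivot_table(
            index=["tissue", "genotype"],
            columns="element",
            values="percent_change_2dp",
            sort=False,
        )
        lines.append(wide.to_markdown())
    if (d / "metabolite_screen.csv").exists():
        found = True
        _section(lines, "Metabolite screen (VIP >= 1 and FC >= 2 or <= 0.5)")
        screen = pd.read_csv(d / "metabolite_screen.csv", index_col=0)
        lines.append(screen["verdict"].value_counts().to_frame("count").to_markdown())
        hits = screen[screen["verdict"] != "not-differential"].round(3)
        if not hits.empty:
            lines.append("")
            lines.append(hits.sort_values("VIP", ascending=False).head(20).to_markdown())
    if (d / "venn_counts.json").exists():
        found = True
        _section(lines, "DEG cross-genotype partition")
        counts = json.loads((d / "venn_counts.json").read_text())
        lines.append(
            pd.Series(counts, name="count").to_frame().to_markdown()
        )
        selected = d / "selected_genes.txt"
        if selected.exists():
            n = len([ln for ln in selected.read_text().splitlines() if ln.strip()])
            lines.append(f"\nSelected cross-genotype pattern genes: {n}")

    if not found:
        raise ValueError(f"no pipeline artifacts found in {d}")
    path = d / "report.md"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
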