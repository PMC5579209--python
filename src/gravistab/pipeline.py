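"""Pipeline orchestration: simulate/load → normalize → screen → rank → enrich.

``run_pipeline`` chains the analysis stages deterministically from a single
configuration (a dict, typically loaded from YAML) and writes per-stage
outputs plus a machine-readable ``summary.json``. Given identical inputs and
seed the summary is byte-identical across runs: the JSON is written with
sorted keys and Python's deterministic float repr.

Configuration keys (all optional except one input source)::

    seed: 0
    simulate: {n_genes: 5000, ...}        # SimConfig overrides, or
    inputs:                               # pre-existing files
      matrices: {PFC: pfc.tsv, ...}
      scale: log2                         # or linear
      samples: samples.csv
      annotation: annotation.tsv
    screen: {alpha: 0.05, fc_stable: 1.1, fc_changed: 1.3,
             comparisons: {PFC: [[ug, 1g_IF], ...], ...}, p_mode: tukey}
    rank: {panel: [GAPDH, ...]}           # defaults to the simulated panel
    enrich: {band: 11p15.4}
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import refrank, region, screen, simdata
from .matrixio import (
    ExpressionMatrix,
    GeneAnnotation,
    SampleSheet,
    ValidationError,
    align_annotation,
    read_annotation,
    read_matrix,
    read_sample_sheet,
    validate_matrix_sheet,
    write_matrix,
)
from .normalize import log2_transform, quantile_normalize

__all__ = ["run_pipeline", "SUMMARY_SCHEMA_VERSION"]

SUMMARY_SCHEMA_VERSION = 1

log = logging.getLogger("gravistab")


def _setup_logging(level: str = "INFO") -> None:
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        log.addHandler(handler)
    log.setLevel(level.upper())


def _json_default(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _load_inputs(config: Mapping[str, Any]):
    """Return (matrices, sheet, annotation, dataset-or-None)."""
    if "simulate" in config:
        overrides = dict(config.get("simulate") or {})
        sim_config = simdata.default_config(
            seed=int(config.get("seed", 0)), **overrides
        )
        dataset = simdata.generate_dataset(sim_config)
        return dataset.matrices, dataset.samples, dataset.annotation, dataset
    if "inputs" not in config:
        raise ValidationError("config needs either a 'simulate' or an 'inputs' section")
    inputs = config["inputs"]
    if "samples" not in inputs:
        raise ValidationError("inputs.samples (sample sheet path) is required")
    scale = inputs.get("scale", "log2")
    matrices = {
        name: read_matrix(path, scale=scale)
        for name, path in inputs["matrices"].items()
    }
    sheet = read_sample_sheet(inputs["samples"])
    annotation = (
        read_annotation(inputs["annotation"]) if "annotation" in inputs else None
    )
    return matrices, sheet, annotation, None


def _recovery_metrics(
    dataset: simdata.SimulatedDataset,
    tables_by_platform: Mapping[str, Mapping[screen.ComparisonSpec, pd.DataFrame]],
    stable_sets: Mapping[str, set[str]],
    changed_delta: float = np.log2(1.5),
) -> dict:
    """Parameter recovery against the planted truth.

    * stable sensitivity: fraction of true-null genes (zero effect
      everywhere) recovered in each platform's stable set, averaged over
      platforms;
    * changed sensitivity: fraction of genes planted with
      |delta| >= ``changed_delta`` on a platform's microgravity comparison
      that the screen bins as ``changed`` there, averaged over platforms.
    """
    truth = dataset.truth
    null_genes = set(truth.index[truth["true_null"]])
    per_platform_stable = []
    for platform, sset in stable_sets.items():
        if null_genes:
            per_platform_stable.append(len(null_genes & sset) / len(null_genes))
    changed_rates = []
    for p in dataset.config.platforms:
        col = f"delta_{p.name}_{p.microgravity}"
        if col not in truth.columns:
            continue
        planted = truth.index[np.abs(truth[col]) >= changed_delta - 1e-12]
        if not len(planted):
            continue
        tables = tables_by_platform[p.name]
        spec = next(
            s for s in tables if s.test == p.microgravity and s.reference == p.baseline
        )
        bins = tables[spec].loc[planted, "bin"]
        changed_rates.append(float((bins == "changed").mean()))
    out = {}
    if per_platform_stable:
        out["stable_sensitivity"] = float(np.mean(per_platform_stable))
        out["stable_sensitivity_per_platform"] = {
            k: float(len(null_genes & s) / len(null_genes))
            for k, s in stable_sets.items()
        }
    if changed_rates:
        out["changed_sensitivity"] = float(np.mean(changed_rates))
    return out


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> dict:
    """Run every configured stage; return (and write) the summary dict."""
    _setup_logging(str(config.get("log_level", "INFO")))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    matrices, sheet, annotation, dataset = _load_inputs(config)
    for matrix in matrices.values():
        validate_matrix_sheet(matrix, sheet)
    log.info("inputs: %d platform(s), stage took %.2fs", len(matrices), time.perf_counter() - t0)

    summary: dict[str, Any] = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": int(config.get("seed", 0)),
        "platforms": sorted(matrices),
    }

    # --- normalize ---------------------------------------------------------
    t = time.perf_counter()
    normalized: dict[str, ExpressionMatrix] = {}
    for name, matrix in matrices.items():
        if matrix.scale == "linear":
            matrix = log2_transform(matrix)
        normalized[name] = quantile_normalize(matrix)
        write_matrix(normalized[name], out_dir / f"normalized_{name}.tsv")
    log.info("normalize: %.2fs", time.perf_counter() - t)

    # --- screen ------------------------------------------------------------
    t = time.perf_counter()
    screen_cfg = dict(config.get("screen") or {})
    comparisons = screen_cfg.get("comparisons")
    if comparisons is not None:
        comparisons = {p: tuple(map(tuple, pairs)) for p, pairs in comparisons.items()}
    kwargs = dict(
        fc_stable=float(screen_cfg.get("fc_stable", screen.FC_STABLE)),
        fc_changed=float(screen_cfg.get("fc_changed", screen.FC_CHANGED)),
        alpha=float(screen_cfg.get("alpha", screen.ALPHA)),
        p_mode=screen_cfg.get("p_mode", "tukey"),
    )
    tables_by_platform: dict[str, dict[screen.ComparisonSpec, pd.DataFrame]] = {}
    stable_sets: dict[str, set[str]] = {}
    summary["screen"] = {"parameters": kwargs, "platforms": {}}
    for name in sorted(normalized):
        table_map = screen.screen_platform(
            normalized[name], sheet, name, comparisons=comparisons, **kwargs
        )
        tables_by_platform[name] = table_map
        stable_sets[name] = screen.platform_stable_set(table_map)
        platform_summary: dict[str, Any] = {
            "stable_set_size": len(stable_sets[name]),
            "stable_set_percent": screen.percent_of_array(
                len(stable_sets[name]), normalized[name].n_genes, 1
            ),
            "comparisons": {},
        }
        for spec, table in table_map.items():
            table.to_csv(
                out_dir / f"comparison_{spec.label.replace(':', '_')}.tsv",
                sep="\t",
                float_format="%.12g",
            )
            platform_summary["comparisons"][spec.label] = screen.census(table)
        (out_dir / f"stable_set_{name}.txt").write_text(
            "\n".join(sorted(stable_sets[name])) + "\n"
        )
        summary["screen"]["platforms"][name] = platform_summary

    if len(stable_sets) >= 2:
        cross, venn = screen.intersect_sets(stable_sets)
        n_genes = next(iter(normalized.values())).n_genes
        summary["screen"]["cross_platform"] = {
            "intersection_size": len(cross),
            "intersection_percent": screen.percent_of_array(len(cross), n_genes, 1),
            "venn": venn,
        }
        (out_dir / "stable_set_cross_platform.txt").write_text(
            "\n".join(sorted(cross)) + "\n"
        )
        (out_dir / "venn.json").write_text(
            json.dumps(venn, indent=2, sort_keys=True) + "\n"
        )
    else:
        cross = next(iter(stable_sets.values()))
    log.info("screen: %.2fs", time.perf_counter() - t)

    # --- reference-gene ranking --------------------------------------------
    t = time.perf_counter()
    rank_cfg = dict(config.get("rank") or {})
    panel = rank_cfg.get("panel")
    if panel is None and dataset is not None:
        panel = dataset.panel_ids
    if panel:
        consensus = {}
        for name in sorted(normalized):
            table = refrank.rank_table(
                normalized[name], panel, sheet=sheet, platform=name
            )
            table.to_csv(
                out_dir / f"rank_table_{name}.tsv", sep="\t", float_format="%.12g"
            )
            consensus[name] = table["consensus_rank"]
        global_table = refrank.global_ranking(consensus)
        global_table.to_csv(
            out_dir / "rank_global.tsv", sep="\t", float_format="%.12g"
        )
        survivors, grid = refrank.stable_reference_genes(tables_by_platform, panel)
        grid.to_csv(out_dir / "panel_stability_grid.tsv", sep="\t")
        summary["rank"] = {
            "panel_size": len(panel),
            "global_order": list(global_table.index),
            "stable_reference_genes": survivors,
        }
    log.info("rank: %.2fs", time.perf_counter() - t)

    # --- band enrichment ----------------------------------------------------
    t = time.perf_counter()
    enrich_cfg = dict(config.get("enrich") or {})
    band = enrich_cfg.get("band")
    if band is None and dataset is not None and dataset.config.band_size > 0:
        band = dataset.config.band_label
    if band and annotation is not None:
        universe = next(iter(normalized.values())).gene_ids
        annotation_aligned = align_annotation(next(iter(normalized.values())), annotation)
        result = region.band_enrichment(cross, annotation_aligned, band, universe)
        (out_dir / "enrichment.json").write_text(
            json.dumps(result.as_dict(), indent=2, sort_keys=True) + "\n"
        )
        summary["enrichment"] = result.as_dict()
    log.info("enrich: %.2fs", time.perf_counter() - t)

    # --- truth-based recovery (synthetic runs only) -------------------------
    if dataset is not None:
        summary["recovery"] = _recovery_metrics(
            dataset, tables_by_platform, stable_sets
        )

    summary_path = out_dir / "summary.json"
    summary_path.write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    log.info("pipeline done in %.2fs -> %s", time.perf_counter() - t0, summary_path)
    return summary
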