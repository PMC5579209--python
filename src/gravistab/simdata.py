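"""Synthetic multi-platform expression datasets with known ground truth.

The generator emulates the three experimental platforms of the study design:
a parabolic-flight campaign (PFC: 1 g in-flight control, microgravity,
1.8 g hypergravity, 1 g hardware ground control; 6 replicates per group), a
suborbital ballistic rocket (TX: 1 g in-flight, microgravity, launch
baseline, 1 g hardware control; 7–9 replicates), and ground-based facilities
(GBF: 1 g control, clinostat simulated microgravity, 9 g centrifugation; 6
replicates). Expression is additive Gaussian on the log2 scale (log-normal
intensities): ``value(gene, sample in condition c) ~ N(mu_g + delta_{g,c},
sigma_g)``, where the baseline condition of each platform always has
``delta = 0``.

Ground truth is planted per gene:

* ``global_stable`` genes have zero effect everywhere,
* ``responsive`` genes carry a signed log2 effect on the microgravity-like
  condition (or a configured condition), with default effect sizes
  bracketing the screen's log2(1.1) and log2(1.3) thresholds,
* ``minimal`` genes get a uniform effect inside the minimal-change FC band,
* a candidate reference-gene panel with per-gene noise overrides, and
* one cytogenetic band whose truly stable fraction equals
  ``band_stable_frac`` exactly by construction (stratified assignment, not
  sampling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrixio import (
    ExpressionMatrix,
    GeneAnnotation,
    SampleSheet,
    ValidationError,
    write_annotation,
    write_matrix,
    write_sample_sheet,
)

__all__ = [
    "PlatformSpec",
    "EffectSpec",
    "PanelGene",
    "SimConfig",
    "SimulatedDataset",
    "default_platforms",
    "default_effects",
    "default_panel",
    "default_config",
    "generate_dataset",
    "write_fixture",
    "read_fixture",
]

LOG2_1_1 = math.log2(1.1)
LOG2_1_3 = math.log2(1.3)


@dataclass(frozen=True)
class PlatformSpec:
    """One experimental platform: its condition groups and replicate counts.

    ``baseline`` is the platform's 1 g control (always zero effect);
    ``microgravity`` is the condition that default planted effects attach to.
    """

    name: str
    replicates: Mapping[str, int]
    baseline: str
    microgravity: str

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.replicates)

    def validate(self) -> None:
        if len(self.replicates) < 2:
            raise ValidationError(
                f"platform {self.name!r} needs >= 2 condition groups"
            )
        for cond, n in self.replicates.items():
            if n < 2:
                raise ValidationError(
                    f"platform {self.name!r}, condition {cond!r}: "
                    f"needs >= 2 replicates (got {n})"
                )
        for attr in ("baseline", "microgravity"):
            if getattr(self, attr) not in self.replicates:
                raise ValidationError(
                    f"platform {self.name!r}: {attr} condition "
                    f"{getattr(self, attr)!r} not among its groups"
                )


@dataclass(frozen=True)
class EffectSpec:
    """A planted signed log2 effect attached to a condition group.

    ``platforms=None`` applies the effect on every platform (using each
    platform's microgravity-like condition when ``condition`` is ``None``).
    ``n_genes`` is the number of genes planted with exactly this effect.
    """

    delta: float
    n_genes: int
    condition: str | None = None
    platforms: tuple[str, ...] | None = None


@dataclass(frozen=True)
class PanelGene:
    """A candidate reference gene with an optional noise/effect override."""

    gene_id: str
    sd: float | None = None
    delta: float = 0.0
    condition: str | None = None
    platforms: tuple[str, ...] | None = None


def default_platforms() -> tuple[PlatformSpec, ...]:
    return (
        PlatformSpec(
            "PFC",
            {"1g_IF": 6, "ug": 6, "1.8g": 6, "1g_HW": 6},
            baseline="1g_IF",
            microgravity="ug",
        ),
        PlatformSpec(
            "TX",
            {"1g_IF": 9, "ug": 9, "BL": 7, "1g_HW": 7},
            baseline="1g_IF",
            microgravity="ug",
        ),
        PlatformSpec(
            "GBF",
            {"1g_GBF": 6, "sim_ug": 6, "9g": 6},
            baseline="1g_GBF",
            microgravity="sim_ug",
        ),
    )


def default_effects(n_genes: int) -> tuple[EffectSpec, ...]:
    """Planted responsive effects bracketing the 1.1 and 1.3 FC thresholds.

    2.5% of genes up and 2.5% down at FC 1.05 (inside the stable band),
    1.5% up and 1.5% down at FC 1.5 (clearly changed); the remaining
    unassigned genes become the minimal-change background.
    """

    def count(frac: float) -> int:
        return int(round(frac * n_genes))

    return (
        EffectSpec(delta=+math.log2(1.05), n_genes=count(0.025)),
        EffectSpec(delta=-math.log2(1.05), n_genes=count(0.025)),
        EffectSpec(delta=+math.log2(1.5), n_genes=count(0.015)),
        EffectSpec(delta=-math.log2(1.5), n_genes=count(0.015)),
    )


#: Candidate reference panel modelled on widely used housekeeping genes;
#: noise overrides spread the panel across the stability range, and two
#: candidates carry a planted effect so the panel is not uniformly stable.
def default_panel() -> tuple[PanelGene, ...]:
    quiet = [
        ("GAPDH", 0.05),
        ("ABCA5", 0.06),
        ("HPRT1", 0.07),
        ("RPL13A", 0.07),
        ("PLA2G4A", 0.08),
        ("ACTB", 0.09),
        ("B2M", 0.10),
        ("PPIA", 0.11),
        ("TBP", 0.12),
        ("UBC", 0.13),
        ("YWHAZ", 0.14),
        ("SDHA", 0.15),
        ("POLR2A", 0.16),
        ("GUSB", 0.17),
        ("HMBS", 0.18),
        ("RPLP0", 0.19),
        ("ALB", 0.22),
        ("B4GALT6", 0.25),
    ]
    genes = [PanelGene(g, sd=s) for g, s in quiet]
    genes.append(PanelGene("TUBA1A", sd=0.12, delta=math.log2(1.4), platforms=("TX",)))
    genes.append(PanelGene("HSP90AA1", sd=0.12, delta=-math.log2(1.35), platforms=("PFC",)))
    return tuple(genes)


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic multi-platform dataset."""

    n_genes: int = 5000
    platforms: tuple[PlatformSpec, ...] = field(default_factory=default_platforms)
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    gene_sd_range: tuple[float, float] = (0.1, 0.1)
    frac_global_stable: float = 0.35
    responsive_effects: tuple[EffectSpec, ...] | None = None
    minimal_effect_range: tuple[float, float] = (math.log2(1.12), math.log2(1.28))
    panel_genes: tuple[PanelGene, ...] = field(default_factory=default_panel)
    band_label: str = "11p15.4"
    band_size: int = 200
    band_stable_frac: float = 0.90
    frac_annotated: float = 0.85
    seed: int = 0

    def effects(self) -> tuple[EffectSpec, ...]:
        if self.responsive_effects is not None:
            return self.responsive_effects
        return default_effects(self.n_genes)

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValidationError("n_genes must be >= 0")
        for name in ("frac_global_stable", "band_stable_frac", "frac_annotated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1] (got {v})")
        if self.band_size > self.n_genes:
            raise ValidationError(
                f"band_size ({self.band_size}) exceeds n_genes ({self.n_genes})"
            )
        lo, hi = self.gene_sd_range
        if lo < 0 or hi < lo:
            raise ValidationError("gene_sd_range must satisfy 0 <= lo <= hi")
        lo, hi = self.baseline_mean_range
        if hi < lo:
            raise ValidationError("baseline_mean_range must satisfy lo <= hi")
        if not self.platforms:
            raise ValidationError("at least one platform is required")
        names = [p.name for p in self.platforms]
        if len(set(names)) != len(names):
            raise ValidationError("platform names must be unique")
        for p in self.platforms:
            p.validate()
        for pg in self.panel_genes:
            if pg.sd is not None and pg.sd < 0:
                raise ValidationError(f"panel gene {pg.gene_id!r}: sd must be >= 0")
        n_special = len(self.panel_genes) + sum(e.n_genes for e in self.effects())
        n_stable = int(round(self.frac_global_stable * self.n_genes))
        if n_special + n_stable > self.n_genes:
            raise ValidationError(
                "frac_global_stable, responsive_effects and panel_genes "
                "together exceed n_genes"
            )


@dataclass
class SimulatedDataset:
    """Generated matrices plus sample sheet, annotation and truth table."""

    config: SimConfig
    matrices: dict[str, ExpressionMatrix]
    samples: SampleSheet
    annotation: GeneAnnotation
    truth: pd.DataFrame  # indexed by gene_id

    @property
    def panel_ids(self) -> list[str]:
        return [p.gene_id for p in self.config.panel_genes]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _effect_targets(
    effect: EffectSpec | PanelGene, platforms: Sequence[PlatformSpec]
) -> list[tuple[str, str]]:
    """(platform, condition) pairs an effect applies to."""
    out = []
    for p in platforms:
        if effect.platforms is not None and p.name not in effect.platforms:
            continue
        cond = effect.condition or p.microgravity
        if cond == p.baseline:
            raise ValidationError(
                f"effects may not attach to the baseline condition {cond!r}"
            )
        if cond in p.replicates:
            out.append((p.name, cond))
    return out


def generate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate one expression matrix per platform plus metadata and truth.

    Identical configs (including the seed) produce bit-identical output; a
    single generator instance drives every random draw.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    panel_ids = [p.gene_id for p in config.panel_genes]
    width = max(5, len(str(max(n, 1))))
    gene_ids = panel_ids + [
        f"G{i:0{width}d}" for i in range(1, n - len(panel_ids) + 1)
    ]

    # per-gene baseline mean and noise SD, shared across platforms
    mu = rng.uniform(*config.baseline_mean_range, size=n)
    sd = rng.uniform(*config.gene_sd_range, size=n)
    for idx, pg in enumerate(config.panel_genes):
        if pg.sd is not None:
            sd[idx] = pg.sd

    # --- assign classes -----------------------------------------------------
    gene_class = np.array(["minimal"] * n, dtype=object)
    gene_class[: len(panel_ids)] = "panel"
    effect_cols: dict[tuple[str, str], np.ndarray] = {
        (p.name, c): np.zeros(n)
        for p in config.platforms
        for c in p.conditions
        if c != p.baseline
    }

    free = np.arange(len(panel_ids), n)
    n_stable = int(round(config.frac_global_stable * n))
    n_stable = min(n_stable, len(free))
    stable_idx = free[:n_stable]
    gene_class[stable_idx] = "global_stable"
    cursor = len(panel_ids) + n_stable

    for effect in config.effects():
        take = np.arange(cursor, cursor + effect.n_genes)
        if take.size and take[-1] >= n:
            raise ValidationError("responsive effects exceed available genes")
        cursor += effect.n_genes
        gene_class[take] = "responsive"
        for target in _effect_targets(effect, config.platforms):
            effect_cols[target][take] += effect.delta

    minimal_idx = np.arange(cursor, n)
    if minimal_idx.size:
        lo, hi = config.minimal_effect_range
        magnitude = rng.uniform(lo, hi, size=minimal_idx.size)
        sign = rng.choice([-1.0, 1.0], size=minimal_idx.size)
        for p in config.platforms:
            effect_cols[(p.name, p.microgravity)][minimal_idx] = sign * magnitude

    for idx, pg in enumerate(config.panel_genes):
        if pg.delta:
            for target in _effect_targets(pg, config.platforms):
                effect_cols[target][idx] += pg.delta

    deltas = (
        np.column_stack(list(effect_cols.values()))
        if effect_cols
        else np.zeros((n, 0))
    )
    true_null = (deltas == 0).all(axis=1)
    true_fc_stable = (np.abs(deltas) <= LOG2_1_1 + 1e-12).all(axis=1)

    # --- band membership: stratified so the band's truly stable fraction ---
    # equals band_stable_frac exactly (construction, not sampling)
    in_band = np.zeros(n, dtype=bool)
    if config.band_size:
        eligible = np.arange(len(panel_ids), n)
        stable_pool = eligible[true_fc_stable[eligible]]
        unstable_pool = eligible[~true_fc_stable[eligible]]
        n_band_stable = int(round(config.band_stable_frac * config.band_size))
        n_band_unstable = config.band_size - n_band_stable
        if n_band_stable > stable_pool.size or n_band_unstable > unstable_pool.size:
            raise ValidationError(
                "band_stable_frac is infeasible for this gene-class mix"
            )
        chosen = np.concatenate(
            [
                rng.choice(stable_pool, size=n_band_stable, replace=False),
                rng.choice(unstable_pool, size=n_band_unstable, replace=False),
            ]
        )
        in_band[chosen] = True

    # --- sample values ------------------------------------------------------
    matrices: dict[str, ExpressionMatrix] = {}
    sheet_rows = []
    for p in config.platforms:
        columns = {}
        for cond in p.conditions:
            delta = (
                effect_cols[(p.name, cond)]
                if cond != p.baseline
                else np.zeros(n)
            )
            for rep in range(1, p.replicates[cond] + 1):
                sid = f"{p.name}_{cond}_r{rep}"
                noise = rng.normal(0.0, 1.0, size=n) * sd
                columns[sid] = mu + delta + noise
                sheet_rows.append(
                    {
                        "sample_id": sid,
                        "platform": p.name,
                        "condition": cond,
                        "replicate": rep,
                    }
                )
        df = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
        matrices[p.name] = ExpressionMatrix(data=df, scale="log2")

    samples = SampleSheet(pd.DataFrame(sheet_rows)) if sheet_rows else SampleSheet(
        pd.DataFrame(columns=["sample_id", "platform", "condition", "replicate"])
    )

    # --- annotation ---------------------------------------------------------
    # leading chromosome token of e.g. "11p15.4" -> "11"
    lead = ""
    for ch in config.band_label:
        if ch in "pq":
            break
        lead += ch
    chrom_of_band = lead or "11"
    chroms, bands, annotated = [], [], []
    for i in range(n):
        if in_band[i]:
            chroms.append(chrom_of_band)
            bands.append(config.band_label)
            annotated.append(True)
        else:
            c = str((i % 22) + 1)
            chroms.append(c)
            bands.append(f"{c}q{(i % 3) + 1}1.{(i % 4) + 1}")
            annotated.append(
                True
                if gene_class[i] == "panel"
                else bool(rng.random() < config.frac_annotated)
            )
    annotation = GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": gene_ids,
                "symbol": [
                    g if gene_class[i] == "panel" else ""
                    for i, g in enumerate(gene_ids)
                ],
                "chromosome": chroms,
                "band": bands,
                "annotated": annotated,
            }
        )
    )

    # --- truth table --------------------------------------------------------
    final_class = gene_class.copy()
    final_class[in_band] = "band_member"
    truth = pd.DataFrame(
        {
            "gene_class": final_class,
            "stratum": gene_class,
            "in_band": in_band,
            "true_null": true_null,
            "true_fc_stable": true_fc_stable,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    for (pname, cond), col in effect_cols.items():
        truth[f"delta_{pname}_{cond}"] = col

    return SimulatedDataset(
        config=config,
        matrices=matrices,
        samples=samples,
        annotation=annotation,
        truth=truth,
    )


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The default study-condition configuration with a chosen seed."""
    return replace(SimConfig(), seed=seed, **overrides)


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------


def write_fixture(dataset: SimulatedDataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset as plain-text files that round-trip losslessly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, matrix in dataset.matrices.items():
        paths[f"matrix_{name}"] = write_matrix(matrix, directory / f"{name}_matrix.tsv")
    paths["samples"] = write_sample_sheet(dataset.samples, directory / "samples.csv")
    paths["annotation"] = write_annotation(
        dataset.annotation, directory / "annotation.tsv"
    )
    truth_path = directory / "truth.tsv"
    dataset.truth.to_csv(truth_path, sep="\t", float_format="%.12g")
    paths["truth"] = truth_path
    return paths


def read_fixture(directory: str | Path) -> dict:
    """Read back a written fixture (matrices, samples, annotation, truth)."""
    from .matrixio import read_annotation, read_matrix, read_sample_sheet

    directory = Path(directory)
    matrices = {
        p.stem.removesuffix("_matrix"): read_matrix(p, scale="log2")
        for p in sorted(directory.glob("*_matrix.tsv"))
    }
    out = {
        "matrices": matrices,
        "samples": read_sample_sheet(directory / "samples.csv"),
        "annotation": read_annotation(directory / "annotation.tsv"),
    }
    truth_path = directory / "truth.tsv"
    if truth_path.exists():
        out["truth"] = pd.read_csv(truth_path, sep="\t", index_col=0)
    return out
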