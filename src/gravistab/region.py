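"""Chromosomal-band stability enrichment.

Compares the share of stably expressed genes inside one cytogenetic band
(e.g. ``11p15.4``, home of the OR51/OR52 olfactory-receptor clusters) to the
genome-wide share, reporting the fold enrichment and, as a clearly labelled
statistical extension, a hypergeometric upper-tail probability.

Band membership is an exact string match on the annotation's ``band`` column
restricted to ``annotated=True`` genes; no base-pair interval arithmetic is
performed. Fractions are rounded only for presentation — the fold is always
computed from the unrounded fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

from scipy import stats

from .matrixio import GeneAnnotation, ValidationError
from .screen import percent_of_array

__all__ = ["EnrichmentResult", "band_enrichment", "hypergeometric_tail"]


@dataclass
class EnrichmentResult:
    band_label: str
    n_band: int
    n_band_stable: int
    n_genome: int
    n_genome_stable: int
    band_fraction: float  # percent, rounded half-up to 1 decimal
    genome_fraction: float  # percent, rounded half-up to 1 decimal
    fold_enrichment: float  # unrounded ratio of the unrounded fractions
    fold_label: str  # nearest-integer presentation, e.g. "3-fold"
    p_hyper: float  # hypergeometric tail (extension; the fold is the headline)

    def as_dict(self) -> dict:
        return asdict(self)


def hypergeometric_tail(
    n_band_stable: int, n_band: int, n_genome_stable: int, n_genome: int
) -> float:
    """P(X >= n_band_stable) drawing n_band genes from the genome without
    replacement, with n_genome_stable stable genes among n_genome."""
    if not (
        0 <= n_band_stable <= n_band <= n_genome
        and 0 <= n_genome_stable <= n_genome
        and n_band_stable <= n_genome_stable
    ):
        raise ValidationError(
            f"inconsistent counts: {n_band_stable}/{n_band} stable in band, "
            f"{n_genome_stable}/{n_genome} in genome"
        )
    return float(stats.hypergeom.sf(n_band_stable - 1, n_genome, n_genome_stable, n_band))


def band_enrichment(
    stable_set: Iterable[str],
    annotation: GeneAnnotation,
    band_label: str,
    genome_genes: Iterable[str] | None = None,
) -> EnrichmentResult:
    """Stable-gene enrichment of one cytogenetic band.

    ``stable_set`` is the screen's (typically cross-platform) stable gene
    set. The genome universe defaults to every annotation gene; pass
    ``genome_genes`` to restrict it (e.g. to the transcripts on the array).
    """
    stable = set(stable_set)
    if genome_genes is None:
        genome = list(annotation.gene_ids)
    else:
        genome = list(dict.fromkeys(genome_genes))
    n_genome = len(genome)
    if n_genome == 0:
        raise ValidationError("empty genome universe")
    band_genes = [g for g in annotation.genes_in_band(band_label) if g in set(genome)]
    if not band_genes:
        raise ValidationError(
            f"band {band_label!r} has no annotated gene in the universe"
        )
    n_band = len(band_genes)
    n_band_stable = sum(1 for g in band_genes if g in stable)
    n_genome_stable = sum(1 for g in genome if g in stable)
    if n_genome_stable == 0:
        raise ValidationError("genome stable fraction is zero; fold undefined")

    band_frac = n_band_stable / n_band
    genome_frac = n_genome_stable / n_genome
    fold = band_frac / genome_frac
    return EnrichmentResult(
        band_label=band_label,
        n_band=n_band,
        n_band_stable=n_band_stable,
        n_genome=n_genome,
        n_genome_stable=n_genome_stable,
        band_fraction=percent_of_array(n_band_stable, n_band, 1),
        genome_fraction=percent_of_array(n_genome_stable, n_genome, 1),
        fold_enrichment=fold,
        fold_label=(
            f"{int(Decimal(fold).quantize(Decimal(1), rounding=ROUND_HALF_UP))}-fold"
        ),
        p_hyper=hypergeometric_tail(n_band_stable, n_band, n_genome_stable, n_genome),
    )
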