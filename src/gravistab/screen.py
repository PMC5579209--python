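"""The expression-stability screen.

For each within-platform comparison (test condition vs. reference condition)
every gene gets a mean log2 difference ``d``, a signed linear fold change
``fc`` (``|fc| = 2**|d|``, sign of ``d``, ``+1`` at ``d = 0``), a one-way
ANOVA omnibus p across the platform's compared groups, and a Tukey-adjusted
pairwise p for the specific pair.

Two distinct notions are derived from these:

* the *stable set* criterion — ``|fc| <= 1.1`` **and** ``p > alpha`` — used
  for per-platform and cross-platform intersections of stably expressed
  genes, and
* the *FC-bin census* — ``stable`` (|fc| <= 1.1), ``changed`` (|fc| >= 1.3)
  and ``minimal`` in between — which partitions all transcripts by fold
  change alone so the three bins always sum to 100%.

Tukey–Kramer pairwise p-values come from the studentized-range tail with the
pooled within-group variance; large batches are evaluated through an
exact-grid + monotone-interpolation scheme (see :class:`StudentizedRangeTail`)
because direct quadrature of the studentized-range distribution is far too
slow for tens of thousands of genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .matrixio import ExpressionMatrix, SampleSheet, ValidationError

__all__ = [
    "DegenerateDataError",
    "ComparisonSpec",
    "AnovaTukeyResult",
    "signed_fold_change",
    "anova_tukey",
    "classify_transcripts",
    "run_comparison_set",
    "screen_platform",
    "platform_stable_set",
    "intersect_sets",
    "census",
    "percent_of_array",
    "DEFAULT_COMPARISONS",
    "FC_STABLE",
    "FC_CHANGED",
    "ALPHA",
]

FC_STABLE = 1.1
FC_CHANGED = 1.3
ALPHA = 0.05

#: Fig-8-style default comparison sets: each platform's test conditions are
#: compared against its in-flight / ground 1 g control.
DEFAULT_COMPARISONS: Mapping[str, tuple[tuple[str, str], ...]] = {
    "PFC": (("ug", "1g_IF"), ("1.8g", "1g_IF"), ("1g_HW", "1g_IF")),
    "TX": (("ug", "1g_IF"), ("BL", "1g_IF"), ("1g_HW", "1g_IF")),
    "GBF": (("sim_ug", "1g_GBF"), ("9g", "1g_GBF")),
}


class DegenerateDataError(ValueError):
    """Raised when a test is requested on data with no usable variance."""


@dataclass(frozen=True)
class ComparisonSpec:
    """One within-platform group comparison (test vs. reference)."""

    platform: str
    test: str
    reference: str

    @property
    def label(self) -> str:
        return f"{self.platform}:{self.test}_vs_{self.reference}"


def signed_fold_change(d):
    """Signed linear fold change from a mean log2 difference.

    ``fc = 2**d`` for ``d >= 0`` and ``-2**(-d)`` for ``d < 0``, so
    down-regulation maps to the conventional negative ratio and
    ``fc ∈ (-inf, -1] ∪ [+1, inf)`` with ``fc = +1`` exactly at ``d = 0``.
    """
    d = np.asarray(d, dtype=float)
    fc = np.where(d >= 0, np.exp2(d), -np.exp2(-d))
    return fc if fc.ndim else float(fc)


# ---------------------------------------------------------------------------
# studentized range tail
# ---------------------------------------------------------------------------


class StudentizedRangeTail:
    """Upper-tail probability of the studentized range, fast for batches.

    For small batches the exact scipy quadrature is used directly. For large
    batches (the per-gene screen) exact values are computed once on a dense
    q grid for the given (k, df) and evaluated in between by monotone PCHIP
    interpolation of log(sf); the absolute interpolation error is ~1e-6,
    orders of magnitude below any decision threshold applied to these
    p-values.
    """

    #: batches up to this size go straight to scipy's quadrature
    EXACT_LIMIT = 64

    def __init__(self) -> None:
        self._grids: dict[tuple[int, int], tuple[np.ndarray, PchipInterpolator]] = {}

    def _grid(self, k: int, df: int):
        key = (k, df)
        if key not in self._grids:
            q = np.concatenate(
                [np.linspace(1e-3, 8.0, 257), np.linspace(8.05, 20.0, 96)]
            )
            sf = stats.studentized_range.sf(q, k, df)
            sf = np.clip(sf, 1e-300, 1.0)
            # enforce strict monotonicity for PCHIP
            sf = np.minimum.accumulate(sf)
            interp = PchipInterpolator(q, np.log(sf))
            self._grids[key] = (q, interp)
        return self._grids[key]

    def sf(self, q, k: int, df: int) -> np.ndarray:
        q = np.atleast_1d(np.asarray(q, dtype=float))
        if q.size <= self.EXACT_LIMIT:
            return np.clip(stats.studentized_range.sf(q, k, df), 0.0, 1.0)
        grid_q, interp = self._grid(k, df)
        out = np.empty_like(q)
        low = q <= grid_q[0]
        high = q >= grid_q[-1]
        mid = ~(low | high)
        out[low] = 1.0
        out[high] = 0.0
        out[mid] = np.exp(interp(q[mid]))
        return np.clip(out, 0.0, 1.0)


_SR_TAIL = StudentizedRangeTail()


# ---------------------------------------------------------------------------
# one-way ANOVA with Tukey's multiple-comparison test
# ---------------------------------------------------------------------------


@dataclass
class AnovaTukeyResult:
    """Vectorized result of a one-way ANOVA with Tukey's post test.

    ``means`` is genes × groups; ``p_pairs[(i, j)]`` holds the Tukey-adjusted
    p for each gene for the group pair (i, j) in the order groups were given.
    """

    group_names: tuple[str, ...]
    means: np.ndarray
    p_omnibus: np.ndarray
    p_pairs: dict[tuple[int, int], np.ndarray]
    msw: np.ndarray
    df_within: int

    def pair_p(self, a: str, b: str) -> np.ndarray:
        i, j = self.group_names.index(a), self.group_names.index(b)
        return self.p_pairs[(min(i, j), max(i, j))]


def anova_tukey(
    groups: Sequence[np.ndarray],
    group_names: Sequence[str] | None = None,
) -> AnovaTukeyResult:
    """One-way ANOVA omnibus p plus Tukey-adjusted p for every group pair.

    Each element of ``groups`` is an array of replicate values, either 1-D
    (one gene) or 2-D genes × replicates; all elements must agree on the
    number of genes. Unequal replicate counts use the Tukey–Kramer standard
    error ``sqrt(MSW/2 * (1/n_i + 1/n_j))``.

    A gene whose pooled within-group variance is zero is degenerate: if its
    group means also all coincide (every value identical) there is no
    evidence of change and ``p = 1`` is assigned throughout; if the means
    differ, :class:`DegenerateDataError` is raised — a zero-variance contrast
    is not evidence at ``p = 0``.
    """
    arrays = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValidationError("need at least 2 groups")
    n_genes = arrays[0].shape[0]
    if any(a.shape[0] != n_genes for a in arrays):
        raise ValidationError("all groups must cover the same genes")
    ns = np.array([a.shape[1] for a in arrays])
    if ns.min() < 2:
        raise ValidationError("each group needs at least 2 replicates")
    names = tuple(group_names) if group_names else tuple(f"g{i}" for i in range(k))

    n_total = int(ns.sum())
    means = np.column_stack([a.mean(axis=1) for a in arrays])
    ssw = np.zeros(n_genes)
    for a, m in zip(arrays, means.T):
        ssw += ((a - m[:, None]) ** 2).sum(axis=1)
    df_within = n_total - k
    msw = ssw / df_within

    grand = (means * ns).sum(axis=1) / n_total
    ssb = (ns * (means - grand[:, None]) ** 2).sum(axis=1)
    msb = ssb / (k - 1)

    # variance at float-rounding scale (relative to the data magnitude) is
    # indistinguishable from zero; comparing dust against dust would yield
    # arbitrary F statistics
    tiny = (1e-10 * np.maximum(1.0, np.abs(grand))) ** 2
    zero_var = msw <= tiny
    flat = zero_var & (ssb <= tiny * (k - 1))
    bad = zero_var & ~flat
    if bad.any():
        idx = int(np.argmax(bad))
        raise DegenerateDataError(
            f"zero within-group variance with differing group means "
            f"(gene index {idx}); cannot test"
        )

    p_omnibus = np.ones(n_genes)
    ok = ~zero_var
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = np.where(ok, msb / np.where(ok, msw, 1.0), 0.0)
    p_omnibus[ok] = stats.f.sf(f_stat[ok], k - 1, df_within)

    p_pairs: dict[tuple[int, int], np.ndarray] = {}
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(msw * 0.5 * (1.0 / ns[i] + 1.0 / ns[j]))
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(ok, np.abs(means[:, i] - means[:, j]) / np.where(ok, se, 1.0), 0.0)
        p = np.ones(n_genes)
        p[ok] = _SR_TAIL.sf(q[ok], k, df_within)
        p_pairs[(i, j)] = p

    return AnovaTukeyResult(
        group_names=names,
        means=means,
        p_omnibus=p_omnibus,
        p_pairs=p_pairs,
        msw=msw,
        df_within=df_within,
    )


def pooled_t_pvalue(
    groups: Sequence[np.ndarray], i: int, j: int, msw: np.ndarray, df_within: int
) -> np.ndarray:
    """Unadjusted two-sample p using the pooled within-group variance."""
    a = np.atleast_2d(np.asarray(groups[i], dtype=float))
    b = np.atleast_2d(np.asarray(groups[j], dtype=float))
    se = np.sqrt(msw * (1.0 / a.shape[1] + 1.0 / b.shape[1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (a.mean(axis=1) - b.mean(axis=1)) / np.where(se > 0, se, 1.0), 0.0)
    return 2.0 * stats.t.sf(np.abs(t), df_within)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_transcripts(
    table: pd.DataFrame,
    fc_stable: float = FC_STABLE,
    fc_changed: float = FC_CHANGED,
    alpha: float = ALPHA,
    p_column: str = "p_adj",
) -> pd.DataFrame:
    """Add ``bin`` and ``is_stable`` columns to a comparison table.

    ``bin`` partitions by |fc| alone: ``stable`` (|fc| <= fc_stable),
    ``changed`` (|fc| >= fc_changed), ``minimal`` in between; both boundary
    values are inclusive. ``is_stable`` additionally requires the pairwise
    p to exceed ``alpha``, so a tight-but-significant gene can sit in the
    stable *bin* while being excluded from the stable *set*.
    """
    out = table.copy()
    abs_fc = out["fc"].abs()
    bins = np.where(
        abs_fc <= fc_stable, "stable", np.where(abs_fc >= fc_changed, "changed", "minimal")
    )
    out["bin"] = bins
    out["is_stable"] = (abs_fc <= fc_stable) & (out[p_column] > alpha)
    return out


def run_comparison_set(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    comparisons: Sequence[ComparisonSpec],
    fc_stable: float = FC_STABLE,
    fc_changed: float = FC_CHANGED,
    alpha: float = ALPHA,
    p_mode: str = "tukey",
) -> dict[ComparisonSpec, pd.DataFrame]:
    """Evaluate a platform's comparisons from one shared ANOVA.

    All conditions named by the platform's comparisons enter a single
    per-gene one-way ANOVA; each comparison's table then reports that
    omnibus p plus the Tukey-adjusted p of its own pair (or, with
    ``p_mode="pooled_t"``, the unadjusted pooled-variance two-sample p).
    """
    if not comparisons:
        raise ValidationError("no comparisons given")
    platforms = {c.platform for c in comparisons}
    if len(platforms) != 1:
        raise ValidationError("comparisons in one set must share a platform")
    platform = platforms.pop()
    if matrix.scale != "log2":
        raise ValidationError("screen operates on log2-scale matrices")

    conditions: list[str] = []
    for c in comparisons:
        for cond in (c.test, c.reference):
            if cond not in conditions:
                conditions.append(cond)
    groups = []
    for cond in conditions:
        ids = sheet.samples_for(platform, cond)
        if len(ids) < 2:
            raise ValidationError(
                f"condition {cond!r} on platform {platform!r} has "
                f"{len(ids)} sample(s); need >= 2"
            )
        missing = [s for s in ids if s not in matrix.data.columns]
        if missing:
            raise ValidationError(f"matrix lacks sample(s) {missing[:5]}")
        groups.append(matrix.data[ids].to_numpy(dtype=float))

    result = anova_tukey(groups, conditions)
    tables: dict[ComparisonSpec, pd.DataFrame] = {}
    for spec in comparisons:
        i = conditions.index(spec.test)
        j = conditions.index(spec.reference)
        d = result.means[:, i] - result.means[:, j]
        if p_mode == "tukey":
            p_adj = result.p_pairs[(min(i, j), max(i, j))]
        elif p_mode == "pooled_t":
            p_adj = pooled_t_pvalue(groups, i, j, result.msw, result.df_within)
        else:
            raise ValidationError(f"unknown p_mode {p_mode!r}")
        table = pd.DataFrame(
            {
                "d": d,
                "fc": signed_fold_change(d),
                "p_omnibus": result.p_omnibus,
                "p_adj": p_adj,
            },
            index=pd.Index(matrix.gene_ids, name="gene_id"),
        )
        tables[spec] = classify_transcripts(
            table, fc_stable=fc_stable, fc_changed=fc_changed, alpha=alpha
        )
    return tables


def screen_platform(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    platform: str,
    comparisons: Mapping[str, Sequence[tuple[str, str]]] | None = None,
    **kwargs,
) -> dict[ComparisonSpec, pd.DataFrame]:
    """Run the default (or given) comparison set for one platform."""
    pairs = (comparisons or DEFAULT_COMPARISONS)[platform]
    specs = [ComparisonSpec(platform, t, r) for t, r in pairs]
    return run_comparison_set(matrix, sheet, specs, **kwargs)


# ---------------------------------------------------------------------------
# set algebra and census
# ---------------------------------------------------------------------------


def platform_stable_set(tables: Mapping[ComparisonSpec, pd.DataFrame]) -> set[str]:
    """Genes stable (``is_stable``) in every one of a platform's comparisons."""
    if not tables:
        raise ValidationError("no comparison tables given")
    sets = [set(t.index[t["is_stable"]]) for t in tables.values()]
    return set.intersection(*sets)


def intersect_sets(named_sets: Mapping[str, set[str]]):
    """Exact intersection of named gene sets plus exclusive Venn counts.

    Returns ``(intersection, venn)`` where ``venn`` maps each non-empty
    membership pattern (set names joined by ``&``) to the number of genes in
    exactly that combination of sets; the region counts sum to |union|.
    """
    if len(named_sets) < 2:
        raise ValidationError("need at least 2 sets to intersect")
    names = list(named_sets)
    union: set[str] = set().union(*named_sets.values())
    venn: dict[str, int] = {}
    for gene in union:
        pattern = "&".join(n for n in names if gene in named_sets[n])
        venn[pattern] = venn.get(pattern, 0) + 1
    intersection = set.intersection(*[named_sets[n] for n in names])
    return intersection, dict(sorted(venn.items()))


def census(
    table: pd.DataFrame,
    decimals_stable: int = 1,
    decimals_changed: int = 2,
) -> dict:
    """Count and express as percentages the FC bins of one comparison.

    The three bins partition the transcript total by construction. Stable
    and minimal fractions are printed with 1 decimal, changed fractions with
    2 (configurable), matching the different precisions used when reporting
    large stable shares vs. small changed shares.
    """
    total = len(table)
    counts = {b: int((table["bin"] == b).sum()) for b in ("stable", "minimal", "changed")}
    percentages = {
        "stable": percent_of_array(counts["stable"], total, decimals_stable),
        "minimal": percent_of_array(counts["minimal"], total, decimals_stable),
        "changed": percent_of_array(counts["changed"], total, decimals_changed),
    }
    return {"total": total, "counts": counts, "percent": percentages}


def percent_of_array(count: int, total: int, decimals: int = 1) -> float:
    """Percentage of ``count`` over ``total``, rounded half-up.

    This is the single rounding rule used by every report in the package, so
    a share printed by the screen and the band-enrichment stage can never
    disagree in their last digit.
    """
    if total <= 0:
        raise ValidationError("total must be positive")
    if not 0 <= count <= total:
        raise ValidationError(f"count {count} outside [0, {total}]")
    value = Decimal(count) * 100 / Decimal(total)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))
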