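"""Reference-gene stability evaluation and consensus ranking.

Candidate reference (housekeeping) genes are scored on log2 expression by
five criteria:

* coefficient of variation (CV%, a stand-alone screening criterion — a
  candidate is conventionally acceptable below ~25%),
* the comparative ΔCt method (mean SD of all pairwise log2 differences),
* BestKeeper (per-gene SD and CV of log2 values plus Pearson correlation
  with the BestKeeper index, the per-sample mean of the candidates' log2
  values — i.e. the geometric mean on the linear scale),
* geNorm (the same pairwise-SD M value, ranked by iterative exclusion of the
  least stable gene until a final pair remains), and
* NormFinder (variability of sample-centered expression, optionally
  decomposed into intra- and intergroup components when condition groups are
  known).

The four algorithmic scores (ΔCt, BestKeeper, geNorm, NormFinder) are
combined into a consensus by the geometric mean of their ranks; the lowest
geometric mean is the most stable candidate. CV stays outside the consensus.
A global cross-platform ordering takes the geometric mean of the per-platform
consensus ranks.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrixio import ExpressionMatrix, SampleSheet, ValidationError
from .screen import ComparisonSpec

__all__ = [
    "coefficient_of_variation",
    "delta_ct_stability",
    "bestkeeper_stats",
    "genorm_ranking",
    "normfinder_stability",
    "reffinder_consensus",
    "rank_table",
    "global_ranking",
    "stable_reference_genes",
]


def _candidate_frame(matrix_or_frame, candidates=None) -> pd.DataFrame:
    if isinstance(matrix_or_frame, ExpressionMatrix):
        df = matrix_or_frame.data
    else:
        df = matrix_or_frame
    if candidates is not None:
        missing = [g for g in candidates if g not in df.index]
        if missing:
            raise ValidationError(f"candidate gene(s) absent from matrix: {missing}")
        df = df.loc[list(candidates)]
    return df.astype(float)


def coefficient_of_variation(matrix_or_frame, candidates=None, linear: bool = False) -> pd.Series:
    """CV% per gene: 100 · sample SD / mean of its values.

    Computed on the log2 values as retrieved from the array console by
    default; ``linear=True`` first maps back to the linear scale.
    """
    df = _candidate_frame(matrix_or_frame, candidates)
    if df.shape[1] < 2:
        raise ValidationError("CV needs at least 2 samples")
    if linear:
        df = np.exp2(df)
    mean = df.mean(axis=1)
    if (mean == 0).any():
        raise ValidationError(
            f"zero mean for gene {mean.index[(mean == 0).argmax()]!r}: CV undefined"
        )
    return (100.0 * df.std(axis=1, ddof=1) / mean).rename("cv_percent")


def _pairwise_sd_mean(df: pd.DataFrame) -> pd.Series:
    """Mean over partners of the sample-SD of pairwise log2 differences."""
    genes = list(df.index)
    values = df.to_numpy()
    scores = np.empty(len(genes))
    for i in range(len(genes)):
        diffs = values[i][None, :] - np.delete(values, i, axis=0)
        scores[i] = diffs.std(axis=1, ddof=1).mean()
    return pd.Series(scores, index=df.index)


def delta_ct_stability(matrix_or_frame, candidates=None) -> pd.Series:
    """Comparative ΔCt score: mean SD of a gene's pairwise differences."""
    df = _candidate_frame(matrix_or_frame, candidates)
    if df.shape[0] < 2:
        raise ValidationError("ΔCt method needs at least 2 candidate genes")
    return _pairwise_sd_mean(df).rename("delta_ct")


def bestkeeper_stats(matrix_or_frame, candidates=None) -> pd.DataFrame:
    """BestKeeper per-gene SD, CV and correlation with the index.

    The index is the per-sample arithmetic mean of the candidates' log2
    values. A zero-variance gene still gets its SD/CV but its correlation is
    reported as NaN (not computable).
    """
    df = _candidate_frame(matrix_or_frame, candidates)
    if df.shape[0] < 2:
        raise ValidationError("BestKeeper needs at least 2 candidate genes")
    if df.shape[1] < 3:
        raise ValidationError("BestKeeper needs at least 3 samples")
    index = df.mean(axis=0)
    sd = df.std(axis=1, ddof=1)
    cv = 100.0 * sd / df.mean(axis=1)
    centered = df.sub(df.mean(axis=1), axis=0)
    idx_centered = index - index.mean()
    denom = np.sqrt((centered**2).sum(axis=1) * (idx_centered**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (centered @ idx_centered) / denom
    r[sd == 0] = np.nan
    return pd.DataFrame({"bk_sd": sd, "bk_cv": cv, "bk_r": r})


def genorm_ranking(matrix_or_frame, candidates=None) -> pd.DataFrame:
    """geNorm M values and the rank from iterative exclusion.

    ``genorm_m`` is the full-panel M value (identical, by definition, to the
    ΔCt score). The iterative procedure repeatedly removes the gene with the
    highest M among the remaining candidates — ties broken towards the later
    gene in input order, deterministically — until two genes remain; those
    two share rank 1.5 and the gene excluded at step t (counting from the
    end) gets rank t + 2.
    """
    df = _candidate_frame(matrix_or_frame, candidates)
    n = df.shape[0]
    if n < 3:
        raise ValidationError("geNorm needs at least 3 candidate genes")
    m_full = _pairwise_sd_mean(df).rename("genorm_m")

    remaining = list(df.index)
    rank = pd.Series(index=df.index, dtype=float, name="rank_genorm")
    next_rank = float(n)
    while len(remaining) > 2:
        m = _pairwise_sd_mean(df.loc[remaining])
        # idxmax on the reversed order → later input gene wins ties
        worst = m.iloc[::-1].idxmax()
        rank[worst] = next_rank
        next_rank -= 1.0
        remaining.remove(worst)
    rank[remaining] = 1.5
    return pd.DataFrame({"genorm_m": m_full, "rank_genorm": rank})


def normfinder_stability(
    matrix_or_frame,
    candidates=None,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.Series:
    """NormFinder stability of sample-centered expression.

    Let ``z_i = x_i − per-sample mean over candidates``. Ungrouped, the score
    is simply the sample SD of ``z_i``. With condition groups, the score is a
    transparent intra/intergroup decomposition: the mean absolute intergroup
    deviation of the group means of ``z_i`` plus the mean standard error of
    ``z_i`` within the groups — no shrinkage of the group deviations is
    applied.
    """
    df = _candidate_frame(matrix_or_frame, candidates)
    if df.shape[0] < 3:
        raise ValidationError("NormFinder needs at least 3 candidate genes")
    z = df.sub(df.mean(axis=0), axis=1)
    if groups is None:
        return z.std(axis=1, ddof=1).rename("normfinder_s")

    group_items = list(groups.items())
    for name, ids in group_items:
        if len(ids) < 2:
            raise ValidationError(f"group {name!r} has {len(ids)} sample(s); need >= 2")
        missing = [s for s in ids if s not in z.columns]
        if missing:
            raise ValidationError(f"group {name!r} names unknown sample(s) {missing}")
    m = np.column_stack([z[list(ids)].mean(axis=1) for _, ids in group_items])
    v = np.column_stack([z[list(ids)].var(axis=1, ddof=1) for _, ids in group_items])
    n_g = np.array([len(ids) for _, ids in group_items])
    d = m - m.mean(axis=1, keepdims=True)
    score = np.abs(d).mean(axis=1) + np.sqrt(v / n_g).mean(axis=1)
    return pd.Series(score, index=df.index, name="normfinder_s")


def _midrank(scores: pd.Series) -> pd.Series:
    return pd.Series(
        stats.rankdata(scores.to_numpy(), method="average"),
        index=scores.index,
    )


def reffinder_consensus(ranks: pd.DataFrame) -> pd.DataFrame:
    """Geometric-mean consensus of four per-method rank columns.

    Returns ``consensus_score`` (the geometric mean itself) and
    ``consensus_rank`` (mid-ranked ascending order of the scores).
    """
    if ranks.shape[1] != 4:
        raise ValidationError("consensus expects exactly four method rank columns")
    if ranks.isna().any().any():
        raise ValidationError("method ranks cover different candidate sets")
    score = np.exp(np.log(ranks.astype(float)).mean(axis=1))
    return pd.DataFrame(
        {"consensus_score": score, "consensus_rank": _midrank(score)}
    )


def rank_table(
    matrix: ExpressionMatrix,
    panel: Sequence[str],
    sheet: SampleSheet | None = None,
    platform: str | None = None,
    bestkeeper_rank_by: str = "bk_sd",
    cv_linear: bool = False,
) -> pd.DataFrame:
    """Full stability rank table for a candidate panel on one platform.

    Columns: CV%, the four method scores, per-method ranks, and the
    geometric-mean consensus. BestKeeper is ranked by SD by default
    (``bestkeeper_rank_by`` accepts ``bk_sd`` or ``bk_cv``).
    """
    df = _candidate_frame(matrix, panel)
    groups = None
    if sheet is not None and platform is not None:
        groups = {
            cond: sheet.samples_for(platform, cond)
            for cond in sheet.conditions(platform)
        }
        groups = {c: [s for s in ids if s in df.columns] for c, ids in groups.items()}
        groups = {c: ids for c, ids in groups.items() if len(ids) >= 2}

    out = pd.DataFrame(index=df.index)
    out["cv_percent"] = coefficient_of_variation(df, linear=cv_linear)
    out["delta_ct"] = delta_ct_stability(df)
    out = out.join(bestkeeper_stats(df))
    gn = genorm_ranking(df)
    out["genorm_m"] = gn["genorm_m"]
    out["normfinder_s"] = normfinder_stability(df, groups=groups)

    out["rank_cv"] = _midrank(out["cv_percent"])
    out["rank_dct"] = _midrank(out["delta_ct"])
    if bestkeeper_rank_by not in ("bk_sd", "bk_cv"):
        raise ValidationError("bestkeeper_rank_by must be 'bk_sd' or 'bk_cv'")
    out["rank_bk"] = _midrank(out[bestkeeper_rank_by])
    out["rank_gn"] = gn["rank_genorm"]
    out["rank_nf"] = _midrank(out["normfinder_s"])

    consensus = reffinder_consensus(out[["rank_dct", "rank_bk", "rank_gn", "rank_nf"]])
    out["consensus_score"] = consensus["consensus_score"]
    out["consensus_rank"] = consensus["consensus_rank"]
    return out


def global_ranking(consensus_by_platform: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Cross-platform ordering: geometric mean of per-platform consensus ranks."""
    if not consensus_by_platform:
        raise ValidationError("no per-platform rankings given")
    frame = pd.DataFrame(dict(consensus_by_platform))
    if frame.isna().any().any():
        gene = frame.index[frame.isna().any(axis=1).argmax()]
        raise ValidationError(f"gene {gene!r} missing from at least one platform")
    score = np.exp(np.log(frame.astype(float)).mean(axis=1))
    out = pd.DataFrame({"global_score": score, "global_rank": _midrank(score)})
    return out.sort_values("global_score")


def stable_reference_genes(
    tables_by_platform: Mapping[str, Mapping[ComparisonSpec, pd.DataFrame]],
    panel: Sequence[str],
) -> tuple[list[str], pd.DataFrame]:
    """Panel genes stable in every comparison of every platform.

    Returns the surviving subset (in panel order) and a gene × comparison
    grid of ``stable`` / ``altered`` labels suitable for printing.
    """
    columns: dict[str, pd.Series] = {}
    for platform, tables in tables_by_platform.items():
        for spec, table in tables.items():
            missing = [g for g in panel if g not in table.index]
            if missing:
                raise ValidationError(
                    f"panel gene(s) absent from {spec.label}: {missing}"
                )
            columns[spec.label] = table.loc[list(panel), "is_stable"]
    if not columns:
        raise ValidationError("no screen results given")
    grid_bool = pd.DataFrame(columns, index=pd.Index(list(panel), name="gene_id"))
    grid = grid_bool.map(lambda b: "stable" if b else "altered")
    survivors = [g for g in panel if bool(grid_bool.loc[g].all())]
    return survivors, grid
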