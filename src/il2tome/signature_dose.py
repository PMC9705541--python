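"""Day-55 signature scores, Δ-scores, dose-response regression and the
participant-level concordant-discordant PCA axis.

For each pseudo-bulk dataset (one cell group x stimulation status), the
signature score of a sample is the sum of per-gene z-scores of normalized
expression over the upregulated signature genes minus that over the
downregulated ones; z-scores are taken across all samples of the dataset
jointly.  Δ-scores are differences from the participant's Day-0 score; their
mean over cell groups is regressed on IL-2 dose (ordinary least squares,
two-sided t-test on the slope).  Participant-specific Day-27 fold-change
profiles of the signature genes are summarized by PC1 of a centred PCA,
oriented so that higher scores mean concordance with the Day-55 direction.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def normalize_pseudobulk(counts, size_factors) -> pd.DataFrame:
    """Normalized pseudo-bulk expression: ln(1 + count / size_factor)."""
    K = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, float)
    s = np.asarray(size_factors, dtype=float)
    if np.any(s <= 0):
        raise ValueError("size factors must be positive")
    norm = np.log1p(K / s[:, None])
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(norm, index=counts.index, columns=counts.columns)
    return pd.DataFrame(norm)


def signature_score(
    norm_expr: pd.DataFrame,
    up_genes: list[str],
    down_genes: list[str],
) -> pd.Series:
    """Per-sample signature score S = sum_z(up) - sum_z(down).

    z-scores use the sample standard deviation (ddof=1) across the samples of
    the dataset.  Genes absent from the matrix are skipped with a warning;
    constant genes contribute zero.  Empty sets give S = 0 (flagged).
    """
    if set(up_genes) & set(down_genes):
        raise ValueError("up and down gene sets must not overlap")
    if not up_genes and not down_genes:
        logger.warning("empty signature gene sets; scores are all zero")
        return pd.Series(0.0, index=norm_expr.index)

    def z_sum(genes: list[str]) -> np.ndarray:
        total = np.zeros(len(norm_expr))
        for gene in genes:
            if gene not in norm_expr.columns:
                logger.warning("signature gene %s absent from matrix; skipped", gene)
                continue
            x = norm_expr[gene].to_numpy(dtype=float)
            sd = x.std(ddof=1)
            if sd > 0:
                total += (x - x.mean()) / sd
        return total

    return pd.Series(z_sum(up_genes) - z_sum(down_genes), index=norm_expr.index)


def delta_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Δ-scores per participant x cell group x contrast, plus their mean over
    cell groups.

    ``scores`` has columns participant, visit, cell_group, score (and
    optionally dose, carried through).  Participants missing Day 0 in a cell
    group are dropped from that group with a warning.
    """
    wide = scores.pivot_table(
        index=["participant", "cell_group"], columns="visit", values="score",
        aggfunc="first",
    )
    if 0 not in wide.columns:
        raise ValueError("no Day-0 scores available")
    missing = wide[0].isna()
    if missing.any():
        logger.warning("dropping %d participant/cell-group pairs without Day 0",
                       int(missing.sum()))
        wide = wide[~missing]
    out = []
    for visit in wide.columns:
        if visit == 0:
            continue
        delta = (wide[visit] - wide[0]).dropna()
        frame = delta.rename("delta").reset_index()
        frame["contrast"] = f"d{visit}_vs_d0"
        out.append(frame)
    deltas = pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["participant", "cell_group", "delta", "contrast"]
    )
    if "dose" in scores.columns:
        doses = scores.drop_duplicates("participant").set_index("participant")["dose"]
        deltas["dose"] = deltas["participant"].map(doses)
    mean_delta = (
        deltas.groupby(["participant", "contrast"])
        .agg(mean_delta=("delta", "mean"), n_groups=("delta", "size"),
             **({"dose": ("dose", "first")} if "dose" in deltas else {}))
        .reset_index()
    )
    return deltas, mean_delta


class PairedTResult(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool


def paired_t_test(x, y) -> PairedTResult:
    """Classical two-tailed paired t-test (df = n - 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need >= 2 pairs of equal length")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        return PairedTResult(np.nan, np.nan, True)
    t, p = stats.ttest_rel(x, y)
    return PairedTResult(float(t), float(p), False)


class DoseRegressionResult(NamedTuple):
    slope: float
    intercept: float
    pvalue: float
    n: int


def dose_regression(mean_delta, dose) -> DoseRegressionResult:
    """OLS of mean Δ signature score on IL-2 dose; two-sided t-test on the
    slope (no multiple-comparison adjustment)."""
    y = np.asarray(mean_delta, dtype=float)
    d = np.asarray(dose, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 participants for dose regression")
    if np.unique(d).size < 2:
        raise ValueError("need at least 2 distinct doses")
    fit = stats.linregress(d, y)
    return DoseRegressionResult(float(fit.slope), float(fit.intercept),
                                float(fit.pvalue), y.size)


class ParticipantPCA(NamedTuple):
    scores: pd.Series              # PC1 score per participant
    loadings: pd.Series            # PC1 loading per gene
    explained_variance_ratio: float


def participant_pca(
    fc_profiles: pd.DataFrame,
    up_genes: list[str] | None = None,
    down_genes: list[str] | None = None,
) -> ParticipantPCA:
    """PC1 of centred participant x gene Day-27 fold-change profiles.

    Sign convention: PC1 is oriented to correlate positively with the Day-55
    direction (up-genes positive, down-genes negative) when gene sets are
    given, else so the largest-magnitude loading is positive.
    """
    if len(fc_profiles) < 2:
        raise ValueError("need at least 2 participants for PCA")
    X = fc_profiles.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    pc1 = vt[0]
    scores = X @ pc1
    if up_genes or down_genes:
        direction = np.zeros(X.shape[1])
        cols = list(fc_profiles.columns)
        for g in up_genes or []:
            if g in cols:
                direction[cols.index(g)] = 1.0
        for g in down_genes or []:
            if g in cols:
                direction[cols.index(g)] = -1.0
        sign = np.sign(pc1 @ direction) or 1.0
    else:
        sign = np.sign(pc1[np.abs(pc1).argmax()]) or 1.0
    evr = float(s[0] ** 2 / np.sum(s**2)) if np.sum(s**2) > 0 else 0.0
    return ParticipantPCA(
        scores=pd.Series(sign * scores, index=fc_profiles.index),
        loadings=pd.Series(sign * pc1, index=fc_profiles.columns),
        explained_variance_ratio=evr,
    )


def participant_fold_changes(
    norm_expr: pd.DataFrame,
    sample_meta: pd.DataFrame,
    genes: list[str],
    contrast: tuple[int, int] = (27, 0),
) -> pd.DataFrame:
    """Participant-specific log2 fold changes computed directly from the
    normalized pseudo-bulk expression (ln-scale difference / ln 2)."""
    t1, t0 = contrast
    meta = sample_meta.reset_index(drop=True)
    expr = norm_expr.reset_index(drop=True)
    rows = {}
    for participant, idx in meta.groupby("participant").groups.items():
        sub = meta.loc[idx]
        i1 = sub.index[sub["visit"] == t1]
        i0 = sub.index[sub["visit"] == t0]
        if len(i1) != 1 or len(i0) != 1:
            continue
        diff = (expr.loc[i1[0], genes] - expr.loc[i0[0], genes]) / np.log(2.0)
        rows[participant] = diff
    return pd.DataFrame(rows).T
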