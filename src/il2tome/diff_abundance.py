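"""Gate-stratified differential abundance testing.

Cell-type frequencies are computed within (participant, visit, stimulation,
sorting gate) strata — the gate is the denominator because the sorted
populations were pooled at designated, biologically arbitrary proportions.
Visit contrasts (Day 27 vs 0, Day 55 vs 0) are tested with an exact paired
two-sided Wilcoxon signed-rank test (sign-assignment enumeration for small
n, tie-/continuity-corrected normal approximation beyond), with
Benjamini-Hochberg correction applied after pooling all resulting p-values.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

STRATA = ["participant", "visit", "stimulation", "gate"]


def compute_frequencies(annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum cell-type frequencies.

    ``annotations`` needs one row per cell with columns participant, visit,
    stimulation, gate and cell_type; optional boolean columns
    ``sample_excluded`` (low-yield samples, dropped) and ``gate_mismatch``
    (cells clustered away from their sorting gate, excluded from both
    numerator and denominator).
    """
    df = annotations
    if "sample_excluded" in df:
        df = df[~df["sample_excluded"].astype(bool)]
    if "gate_mismatch" in df:
        df = df[~df["gate_mismatch"].astype(bool)]
    if df.empty:
        logger.warning("no cells left after exclusions; empty frequency table")
        return pd.DataFrame(
            columns=STRATA + ["cell_type", "frequency", "n_cells", "n_gate"]
        )
    denom = df.groupby(STRATA).size().rename("n_gate")
    numer = df.groupby(STRATA + ["cell_type"]).size().rename("n_cells")
    out = numer.reset_index().merge(denom.reset_index(), on=STRATA)
    out["frequency"] = out["n_cells"] / out["n_gate"]
    return out[STRATA + ["cell_type", "frequency", "n_cells", "n_gate"]]


class WilcoxonResult(NamedTuple):
    statistic: float      # W+ (sum of positive-difference ranks)
    pvalue: float
    n_effective: int

    @property
    def degenerate(self) -> bool:
        return self.n_effective == 0


def _exact_wilcoxon_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over all sign assignments via the distribution of
    2*W+ (doubling makes tied average ranks integral)."""
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2 * w_plus))
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_signed_rank(
    x, y, exact_max_n: int = 25
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are discarded (classic treatment).  For effective n up
    to ``exact_max_n`` the p-value is exact over the 2^n sign assignments;
    beyond that a normal approximation with tie correction and continuity
    correction is used.  n = 0 is degenerate: W = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _exact_wilcoxon_p(ranks, w_plus)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        delta = w_plus - mean
        correction = 0.5 * np.sign(delta)
        z = (delta - correction) / np.sqrt(var) if var > 0 else 0.0
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return WilcoxonResult(w_plus, p, n)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity enforcement."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def paired_log2_fc(
    frequencies: pd.DataFrame,
    contrast: tuple[int, int] = (27, 0),
    pseudo: float | None = None,
) -> pd.DataFrame:
    """Per-participant log2 fold change of frequencies between two visits.

    Participants missing either visit are dropped.  Zero frequencies are
    handled by adding half the smallest nonzero frequency in the table (to
    both members of the affected pair); pairs that are zero at both visits
    are omitted.
    """
    t1, t0 = contrast
    if pseudo is None:
        nonzero = frequencies.loc[frequencies["frequency"] > 0, "frequency"]
        pseudo = 0.5 * nonzero.min() if len(nonzero) else 0.0
    keys = ["stimulation", "gate", "cell_type", "participant"]
    wide = frequencies.pivot_table(
        index=keys, columns="visit", values="frequency", aggfunc="first"
    )
    if t1 not in wide.columns or t0 not in wide.columns:
        return pd.DataFrame(columns=keys + ["log2fc"])
    wide = wide.dropna(subset=[t1, t0])
    both_zero = (wide[t1] == 0) & (wide[t0] == 0)
    if both_zero.any():
        logger.warning("omitting %d pairs with zero frequency at both visits",
                       int(both_zero.sum()))
        wide = wide[~both_zero]
    f1, f0 = wide[t1].to_numpy(), wide[t0].to_numpy()
    zero = (f1 == 0) | (f0 == 0)
    f1 = np.where(zero, f1 + pseudo, f1)
    f0 = np.where(zero, f0 + pseudo, f0)
    out = wide.reset_index()[keys]
    out["log2fc"] = np.log2(f1 / f0)
    return out


def abundance_tests(
    frequencies: pd.DataFrame,
    contrasts: tuple = ((27, 0), (55, 0)),
    exact_max_n: int = 25,
) -> pd.DataFrame:
    """Paired Wilcoxon tests of cell-type frequencies for each visit contrast,
    with BH correction pooled over all cell types and contrasts."""
    rows = []
    for (stim, gate, cell_type), sub in frequencies.groupby(
        ["stimulation", "gate", "cell_type"]
    ):
        wide = sub.pivot_table(index="participant", columns="visit",
                               values="frequency", aggfunc="first")
        for t1, t0 in contrasts:
            if t1 not in wide.columns or t0 not in wide.columns:
                continue
            paired = wide[[t1, t0]].dropna()
            if len(paired) < 2:
                continue
            res = wilcoxon_signed_rank(
                paired[t1].to_numpy(), paired[t0].to_numpy(), exact_max_n
            )
            fcs = paired_log2_fc(sub, contrast=(t1, t0))
            rows.append(
                {
                    "stimulation": stim,
                    "gate": gate,
                    "cell_type": cell_type,
                    "contrast": f"d{t1}_vs_d{t0}",
                    "n_pairs": len(paired),
                    "statistic": res.statistic,
                    "pvalue": res.pvalue,
                    "median_log2fc": float(fcs["log2fc"].median()) if len(fcs) else np.nan,
                }
            )
    result = pd.DataFrame(rows)
    if len(result):
        result["padj"] = bh_adjust(result["pvalue"].to_numpy())
    return result


DEFAULT_IL21_CLUSTERS = ("CXCR5+ Tcm", "CXCR5low IL21+", "CD25+ TFH")


def stratify_il21(
    dataset,
    threshold: int = 1,
    cluster_labels: tuple = DEFAULT_IL21_CLUSTERS,
) -> pd.DataFrame:
    """IL-21+ cell fraction per participant x visit within each T_FH-like
    cluster of the stimulated dataset (raw IL21 count >= threshold)."""
    meta = dataset.cell_meta
    if "cluster_label" not in meta:
        raise KeyError("dataset must carry cluster_label annotations")
    il21 = dataset.rna_counts[:, dataset.gene_index("IL21")].toarray().ravel()
    df = pd.DataFrame(
        {
            "participant": meta["participant"],
            "visit": meta["visit"],
            "cluster_label": meta["cluster_label"],
            "positive": il21 >= threshold,
        }
    )
    if "sample_excluded" in meta:
        df = df[~meta["sample_excluded"].astype(bool).to_numpy()]
    df = df[df["cluster_label"].isin(cluster_labels)]
    out = (
        df.groupby(["participant", "visit", "cluster_label"])["positive"]
        .agg(fraction="mean", n_cells="size")
        .reset_index()
    )
    return out


def il21_tests(fractions: pd.DataFrame, contrasts=((27, 0), (55, 0))) -> pd.DataFrame:
    """Wilcoxon contrasts of IL-21+ fractions, BH-pooled like abundance_tests."""
    renamed = fractions.rename(columns={"cluster_label": "cell_type", "fraction": "frequency"})
    renamed["stimulation"] = "stim"
    renamed["gate"] = "il21"
    return abundance_tests(renamed, contrasts=contrasts)
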