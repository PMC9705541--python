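"""Pseudo-bulk negative-binomial differential expression.

Cells from the same participant, visit and stimulation status (within one
cell group, after dropping cells not sorted from the corresponding gate) are
summed into pseudo-bulk samples.  Size factors use the median-of-ratios
method.  Per gene, a negative binomial GLM (log link, size-factor offsets) is
fitted by IRLS for a full model (visit as a 2-df factor + participant) and a
reduced model (participant only); the likelihood-ratio statistic is referred
to a chi-square with 2 df, so the test detects any visit effect while
per-contrast fold changes come from the visit coefficients.  The gene-wise
dispersion is estimated by maximum likelihood (method-of-moments start,
floor 1e-8) and held fixed across both models.  Fold changes are optionally
shrunk by a MAP estimate under a heavy-tailed (Cauchy) zero-centred prior
whose scale is estimated from the raw estimates — an analog of standard
effect-size shrinkage for small panels, not a reimplementation of any
specific package.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy import optimize, special, stats

from .config import DEConfig
from .datamodel_io import MultiomicsDataset
from .diff_abundance import bh_adjust

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# Aggregation and size factors
# ---------------------------------------------------------------------------

def aggregate_pseudobulk(
    dataset: MultiomicsDataset,
    modality: str = "rna",
    min_cells: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum raw counts into (participant x visit x gate x stimulation) samples.

    Cells flagged ``gate_mismatch`` or belonging to excluded (low-yield)
    samples are dropped first.  Returns ``(counts, sample_meta)``; samples
    with fewer than ``min_cells`` cells are flagged (``low_cell_flag``) and
    excluded from design matrices downstream.
    """
    meta = dataset.cell_meta
    keep = np.ones(len(meta), dtype=bool)
    if "gate_mismatch" in meta:
        keep &= ~meta["gate_mismatch"].astype(bool).to_numpy()
    if "sample_excluded" in meta:
        keep &= ~meta["sample_excluded"].astype(bool).to_numpy()
    if not keep.any():
        logger.warning("no cells to aggregate; returning empty table")
        return pd.DataFrame(), pd.DataFrame()

    matrix = dataset.rna_counts if modality == "rna" else dataset.protein_counts
    names = dataset.gene_names if modality == "rna" else dataset.protein_names
    sub = meta.loc[keep, ["participant", "visit", "gate", "stimulation"]].copy()
    if "dose" in meta:
        sub["dose"] = meta.loc[keep, "dose"]
    sub["cell_group"] = sub["gate"]
    key_cols = ["participant", "visit", "cell_group", "stimulation"]
    keys, inverse = np.unique(
        sub[key_cols].astype(str).agg("|".join, axis=1), return_inverse=True
    )
    indicator = sp.csr_matrix(
        (np.ones(len(sub)), (inverse, np.arange(len(sub)))),
        shape=(len(keys), len(sub)),
    )
    counts = np.asarray((indicator @ matrix[keep]).todense()).astype(np.int64)
    sample_meta = (
        sub.assign(_key=inverse)
        .groupby("_key")
        .agg({c: "first" for c in sub.columns} | {"cell_group": "first"})
        .assign(n_cells=np.bincount(inverse))
        .reset_index(drop=True)
    )
    sample_meta["low_cell_flag"] = sample_meta["n_cells"] < min_cells
    return pd.DataFrame(counts, columns=names), sample_meta


def estimate_size_factors(counts) -> np.ndarray:
    """Median-of-ratios size factors normalized to geometric mean 1.

    Falls back to total-count ratios when no gene is positive in every sample.
    """
    K = np.asarray(counts, dtype=float)
    if K.ndim != 2 or K.shape[0] < 2:
        raise ValueError("need at least 2 samples to estimate size factors")
    positive = (K > 0).all(axis=0)
    if positive.any():
        logK = np.log(K[:, positive])
        log_ref = logK.mean(axis=0)
        s = np.exp(np.median(logK - log_ref, axis=1))
    else:
        logger.warning("no gene positive in all samples; using total-count ratios")
        totals = K.sum(axis=1)
        if np.any(totals <= 0):
            raise ValueError("cannot size-factor samples with zero totals")
        s = totals
    return s / np.exp(np.log(s).mean())


# ---------------------------------------------------------------------------
# NB likelihood machinery
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """Negative binomial log-likelihood, variance mu + alpha mu^2.

    Evaluated as Poisson in the alpha -> 0 limit, where the gammaln terms
    would otherwise lose double precision.
    """
    mu = np.maximum(mu, 1e-12)
    if alpha < 1e-9:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    r = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _ml_dispersion(
    y: np.ndarray, mu: np.ndarray, floor: float = 1e-8, X: np.ndarray | None = None
) -> float:
    """Maximize the NB likelihood in alpha with the fitted means held fixed.

    When the design matrix is supplied the likelihood is Cox-Reid adjusted
    (-0.5 log det X'WX): plain ML dispersion is biased low when many mean
    parameters are fitted from few samples, which would inflate the LRT.
    """
    resid = np.sum((y - mu) ** 2 - mu)
    denom = np.sum(mu**2)
    start = max(resid / denom if denom > 0 else floor, floor)

    def objective(la: float) -> float:
        alpha = np.exp(la)
        ll = _nb_loglik(y, mu, alpha)
        if X is not None:
            w = mu / (1.0 + alpha * mu)  # GLM weights, log link
            _, logdet = np.linalg.slogdet(X.T * w @ X)
            ll -= 0.5 * logdet
        return -ll if np.isfinite(ll) else 1e300

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize_scalar(
            objective,
            bounds=(np.log(floor), np.log(100.0)),
            method="bounded",
            options={"xatol": 1e-6},
        )
    alpha = float(np.exp(res.x)) if res.success else start
    return max(alpha, floor)


def _fit_glm(y, X, offset, alpha):
    family = (
        sm.families.Poisson()
        if alpha <= 1e-8
        else sm.families.NegativeBinomial(alpha=alpha)
    )
    model = sm.GLM(y, X, family=family, offset=offset)
    with warnings.catch_warnings():
        # near-saturated genes at small n trip benign separation warnings
        warnings.simplefilter("ignore")
        return model.fit(maxiter=100, tol=1e-8)


def _design_matrices(meta: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    visits = sorted(meta["visit"].unique())
    baseline = visits[0]
    visit_dummies = pd.get_dummies(
        pd.Categorical(meta["visit"], categories=visits), drop_first=True, dtype=float
    )
    part_dummies = pd.get_dummies(meta["participant"], drop_first=True, dtype=float)
    ones = np.ones((len(meta), 1))
    full = np.column_stack([ones, visit_dummies.to_numpy(), part_dummies.to_numpy()])
    reduced = np.column_stack([ones, part_dummies.to_numpy()])
    contrast_names = [f"d{v}_vs_d{baseline}" for v in visits[1:]]
    return full, reduced, contrast_names


def fit_nb_lrt(
    counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    size_factors: np.ndarray | None = None,
    config: DEConfig | None = None,
    fixed_dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-gene NB LRT of visit effect (full: visit + participant; reduced:
    participant only) for one cell group x stimulation dataset.

    Returns a long frame with one row per gene x visit contrast; the LRT
    statistic and p-value are shared across a gene's contrasts.
    """
    config = config or DEConfig()
    meta = sample_meta.reset_index(drop=True)
    usable = ~meta["low_cell_flag"].to_numpy() if "low_cell_flag" in meta else np.ones(len(meta), bool)
    meta = meta[usable].reset_index(drop=True)
    K = counts.to_numpy()[usable]
    if size_factors is None:
        size_factors = estimate_size_factors(K)
    else:
        size_factors = np.asarray(size_factors)[usable] if len(size_factors) == len(usable) else np.asarray(size_factors)
    offset = np.log(size_factors)
    X_full, X_red, contrast_names = _design_matrices(meta)
    df_diff = X_full.shape[1] - X_red.shape[1]
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("full design matrix is rank deficient")

    rows = []
    for gi, gene in enumerate(counts.columns):
        y = K[:, gi].astype(float)
        record = {
            "feature": gene,
            "stat": np.nan,
            "df": df_diff,
            "pvalue": np.nan,
            "alpha": np.nan,
            "converged": False,
            "base_mean": float(np.mean(y / size_factors)),
        }
        coefs = {c: np.nan for c in contrast_names}
        ses = {c: np.nan for c in contrast_names}
        if np.count_nonzero(y) >= 3:
            try:
                if fixed_dispersion is None:
                    pois = _fit_glm(y, X_full, offset, 0.0)
                    alpha = _ml_dispersion(y, pois.fittedvalues,
                                           config.dispersion_floor, X_full)
                    fit_full = _fit_glm(y, X_full, offset, alpha)
                    alpha = _ml_dispersion(y, fit_full.fittedvalues,
                                           config.dispersion_floor, X_full)
                else:
                    alpha = max(fixed_dispersion, 0.0)
                fit_full = _fit_glm(y, X_full, offset, alpha)
                fit_red = _fit_glm(y, X_red, offset, alpha)
                ll_full = _nb_loglik(y, fit_full.fittedvalues, max(alpha, 1e-12))
                ll_red = _nb_loglik(y, fit_red.fittedvalues, max(alpha, 1e-12))
                lam = max(0.0, 2.0 * (ll_full - ll_red))
                record.update(
                    stat=lam,
                    pvalue=float(stats.chi2.sf(lam, df_diff)),
                    alpha=alpha,
                    converged=bool(fit_full.converged and fit_red.converged),
                )
                for ci, cname in enumerate(contrast_names):
                    coefs[cname] = float(fit_full.params[1 + ci] / LN2)
                    ses[cname] = float(fit_full.bse[1 + ci] / LN2)
            except Exception as err:  # non-convergence: flagged, excluded from FDR
                logger.warning("NB fit failed for %s: %s", gene, err)
        for cname in contrast_names:
            rows.append(
                record
                | {"contrast": cname, "log2fc": coefs[cname], "lfc_se": ses[cname]}
            )

    result = pd.DataFrame(rows)
    ok = result["pvalue"].notna() & result["converged"]
    result["padj"] = np.nan
    # each gene contributes one p-value; adjust on unique genes then broadcast
    first = result[ok].drop_duplicates("feature")
    padj = pd.Series(bh_adjust(first["pvalue"].to_numpy()), index=first["feature"])
    result.loc[ok, "padj"] = result.loc[ok, "feature"].map(padj).to_numpy()
    if config.shrink:
        result = shrink_lfc(result)
    else:
        result["log2fc_shrunk"] = result["log2fc"]
    result["tier"] = assign_tiers(result, config)
    return result


def shrink_lfc(de: pd.DataFrame, prior_scale: float | None = None) -> pd.DataFrame:
    """MAP fold-change shrinkage under a zero-centred Cauchy prior.

    The normal approximation N(log2fc, lfc_se^2) stands in for the per-gene
    likelihood; the prior scale is estimated from the spread of the raw
    estimates in excess of their sampling noise.  High-information genes are
    left nearly untouched; noisy ones are pulled toward zero.
    """
    de = de.copy()
    shrunk = np.full(len(de), np.nan)
    for contrast, idx in de.groupby("contrast").groups.items():
        sub = de.loc[idx]
        ok = sub["log2fc"].notna() & sub["lfc_se"].notna() & (sub["lfc_se"] > 0)
        b = sub.loc[ok, "log2fc"].to_numpy()
        se = sub.loc[ok, "lfc_se"].to_numpy()
        if prior_scale is None:
            excess = np.mean(b**2) - np.mean(se**2) if len(b) else 0.0
            scale = float(np.sqrt(max(excess, 1e-4)))
        else:
            scale = prior_scale
        values = np.array([_map_shrink(bi, si, scale) for bi, si in zip(b, se)])
        out = np.full(len(sub), np.nan)
        out[np.flatnonzero(ok.to_numpy())] = values
        shrunk[de.index.get_indexer(idx)] = out
    de["log2fc_shrunk"] = shrunk
    return de


def _map_shrink(b_hat: float, se: float, scale: float) -> float:
    if b_hat == 0.0:
        return 0.0

    def grad(b: float) -> float:
        return (b - b_hat) / se**2 + 2.0 * b / (scale**2 + b**2)

    lo, hi = (0.0, b_hat) if b_hat > 0 else (b_hat, 0.0)
    if grad(lo) == 0.0:
        return lo
    return float(optimize.brentq(grad, lo, hi, xtol=1e-10))


def assign_tiers(de: pd.DataFrame, config: DEConfig | None = None) -> pd.Series:
    """Two-tier significance: tier-FC (|log2FC| >= 0.4 and FDR < 0.01) or
    tier-P (FDR < 1e-10)."""
    config = config or DEConfig()
    # The fold-change threshold applies to the maximum-likelihood estimate;
    # shrunken values are for reporting and direction calls.
    lfc = de["log2fc"].abs()
    tier_fc = (lfc >= config.fc_cut) & (de["padj"] < config.fdr_cut)
    tier_p = de["padj"] < config.p_cut
    return pd.Series(
        np.where(tier_fc, "tier-FC", np.where(tier_p, "tier-P", "none")),
        index=de.index,
    )


# ---------------------------------------------------------------------------
# Signature-gene selection
# ---------------------------------------------------------------------------

def select_signature_genes(
    results_by_population: dict[str, pd.DataFrame],
    contrast: str,
    fc_cut: float = 0.4,
    fdr_cut: float = 0.01,
    p_cut: float = 1e-10,
) -> tuple[list[str], list[str]]:
    """Signature genes: selected when, in at least one cell population,
    |log2FC| >= fc_cut with FDR < fdr_cut, or FDR < p_cut.  Direction by the
    sign of the (shrunken) fold change in qualifying populations; conflicts
    resolved by majority, ties flagged and dropped."""
    votes: dict[str, list[float]] = {}
    for pop, de in results_by_population.items():
        sub = de[(de["contrast"] == contrast) & de["padj"].notna()]
        raw = sub["log2fc"]
        shrunk = sub["log2fc_shrunk"].where(sub["log2fc_shrunk"].notna(), raw) \
            if "log2fc_shrunk" in sub else raw
        selected = ((raw.abs() >= fc_cut) & (sub["padj"] < fdr_cut)) | (
            sub["padj"] < p_cut
        )
        for gene, fc in zip(sub.loc[selected, "feature"], shrunk[selected]):
            votes.setdefault(gene, []).append(np.sign(fc))
    up, down = [], []
    for gene, signs in sorted(votes.items()):
        s = np.sum(signs)
        if s > 0:
            up.append(gene)
        elif s < 0:
            down.append(gene)
        else:
            logger.warning("gene %s has tied direction votes; dropped", gene)
    return up, down


def select_de_genes_fig3(
    results_by_population: dict[str, pd.DataFrame],
    contrast: str,
    fc_cut: float = 1.2,
    fdr_cut: float = 0.01,
) -> list[str]:
    """Single-tier selection: |log2FC| >= fc_cut and FDR < fdr_cut in at
    least one cluster."""
    genes = set()
    for de in results_by_population.values():
        sub = de[(de["contrast"] == contrast) & de["padj"].notna()]
        hit = (sub["log2fc"].abs() >= fc_cut) & (sub["padj"] < fdr_cut)
        genes.update(sub.loc[hit, "feature"])
    return sorted(genes)
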