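"""Absolute subset counts and the Treg suppression-assay statistic.

Absolute numbers of Treg subsets in circulation are inferred by scaling the
whole-blood FACS count of the parent population (cells/ul) by the within-gate
relative frequency of each subset from the single-cell data.  The in vitro
suppression assay reports percent suppression per Treg:Teff ratio from
replicate-averaged tritiated-thymidine CPM readings, with participant-visits
whose Teff-alone proliferation falls below 1,000 CPM excluded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel_io import validate_facs_counts

logger = logging.getLogger(__name__)

TEFF_ALONE = "0:1"
DEFAULT_MIN_TEFF_CPM = 1000.0


def absolute_subset_counts(
    facs: pd.DataFrame,
    frequencies: pd.DataFrame,
    parent_gates: dict[str, str] | None = None,
) -> pd.DataFrame:
    """count(subset) = N_FACS(parent) x f(subset | parent gate).

    ``parent_gates`` maps each FACS parent subset name to the sorting gate
    whose frequencies partition it (default: identity for gates present in
    both tables).  Participant-visits without a FACS record are omitted with
    a warning.
    """
    facs = validate_facs_counts(facs)
    if parent_gates is None:
        shared = set(facs["subset"]) & set(frequencies["gate"])
        parent_gates = {s: s for s in sorted(shared)}
    rows = []
    for parent, gate in parent_gates.items():
        sub = frequencies[frequencies["gate"] == gate]
        parent_counts = facs[facs["subset"] == parent].set_index(["participant", "visit"])["count"]
        for (participant, visit), grp in sub.groupby(["participant", "visit"]):
            key = (participant, visit)
            if key not in parent_counts.index:
                logger.warning("no FACS record for %s day %s (%s); omitted",
                               participant, visit, parent)
                continue
            n_parent = parent_counts.loc[key]
            for _, row in grp.iterrows():
                rows.append(
                    {
                        "participant": participant,
                        "visit": visit,
                        "parent": parent,
                        "subset": row["cell_type"],
                        "absolute_count": n_parent * row["frequency"],
                    }
                )
    return pd.DataFrame(rows, columns=["participant", "visit", "parent", "subset",
                                       "absolute_count"])


def percent_suppression(cpm_with: float, cpm_without: float) -> float:
    """percent suppression = 100 - (CPM_with_Tregs / CPM_without_Tregs) x 100.

    Values below 0 (proliferation enhancement) are permitted and logged.
    """
    if cpm_without <= 0:
        raise ValueError("Teff-alone CPM must be positive")
    value = 100.0 - (cpm_with / cpm_without) * 100.0
    if value < 0:
        logger.info("negative suppression (%.1f%%): proliferation enhanced", value)
    return value


def summarize_suppression(
    assay: pd.DataFrame,
    min_teff_cpm: float = DEFAULT_MIN_TEFF_CPM,
) -> pd.DataFrame:
    """Percent suppression per participant x visit x ratio.

    Replicate CPMs are arithmetically averaged per condition.  Any
    participant-visit whose Teff-alone (0:1) mean is below ``min_teff_cpm``
    is excluded entirely (``excluded`` = True, suppression NaN); remaining
    ratios are converted against the same visit's 0:1 mean.
    """
    required = {"participant", "visit", "ratio", "cpm"}
    missing = required - set(assay.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    means = (
        assay.groupby(["participant", "visit", "ratio"])["cpm"]
        .agg(mean_cpm="mean", n_replicates="size")
        .reset_index()
    )
    few = means["n_replicates"] < 5
    for _, row in means[few].iterrows():
        logger.warning("only %d replicates for %s day %s ratio %s",
                       row["n_replicates"], row["participant"], row["visit"], row["ratio"])
    rows = []
    for (participant, visit), grp in means.groupby(["participant", "visit"]):
        teff = grp[grp["ratio"] == TEFF_ALONE]
        if teff.empty:
            logger.warning("missing Teff-alone condition for %s day %s; excluded",
                           participant, visit)
            excluded, teff_mean = True, np.nan
        else:
            teff_mean = float(teff["mean_cpm"].iloc[0])
            excluded = teff_mean < min_teff_cpm
            if excluded:
                logger.warning("%s day %s excluded: Teff-alone mean %.0f CPM < %.0f",
                               participant, visit, teff_mean, min_teff_cpm)
        for _, row in grp.iterrows():
            if row["ratio"] == TEFF_ALONE:
                continue
            rows.append(
                {
                    "participant": participant,
                    "visit": visit,
                    "ratio": row["ratio"],
                    "mean_cpm": row["mean_cpm"],
                    "teff_alone_cpm": teff_mean,
                    "excluded": excluded,
                    "percent_suppression": (
                        np.nan if excluded
                        else percent_suppression(row["mean_cpm"], teff_mean)
                    ),
                }
            )
    return pd.DataFrame(rows)
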