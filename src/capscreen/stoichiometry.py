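"""iBAQ-based relative copy-number ratios within each IP experiment.

iBAQ divides a protein's summed intensity by its number of theoretically
observable peptides, so within one run the ratio of two proteins' iBAQ values
proxies their relative copy number. Ratios are reported as log2 values per
experiment; any per-run global scaling (capture efficiency, loading) cancels,
so no tag normalization is applied on this path. Cells left unquantified stay
undefined — no imputation by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ingest import ExperimentDesign, IntensityMatrix


def ibaq_ratio(m: IntensityMatrix, a: str, b: str, experiment: str) -> float:
    """log2(iBAQ_a / iBAQ_b) in one experiment; NaN when either is unquantified."""
    if m.layer != "iBAQ" or m.scale != "linear":
        raise ValueError("ibaq_ratio expects the linear iBAQ layer")
    va = m.values.at[a, experiment]
    vb = m.values.at[b, experiment]
    if np.isnan(va) or np.isnan(vb):
        return float("nan")
    return float(np.log2(va / vb))


def stoichiometry_table(
    m: IntensityMatrix,
    pairs: list[tuple[str, str]],
    design: ExperimentDesign,
    case_only: bool = True,
) -> pd.DataFrame:
    """One row per (pair, experiment) where the ratio is defined.

    Pairs are (numerator, denominator) accessions; unknown proteins raise.
    Rows carry the bait target for display grouping.
    """
    if m.layer != "iBAQ" or m.scale != "linear":
        raise ValueError("stoichiometry_table expects the linear iBAQ layer")
    for a, b in pairs:
        for prot in (a, b):
            if prot not in m.values.index:
                raise KeyError(f"protein {prot!r} not present in the iBAQ table")
    dt = design.table
    rows = []
    for _, run in dt.iterrows():
        if case_only and run["role"] != "case":
            continue
        exp = run["experiment_id"]
        if exp not in m.values.columns:
            continue
        for a, b in pairs:
            r = ibaq_ratio(m, a, b, exp)
            if not np.isnan(r):
                rows.append(
                    {
                        "experiment_id": exp,
                        "bait": run["bait"],
                        "target_set": run["target_set"],
                        "condition_id": run["condition_id"],
                        "pair": f"{a}/{b}",
                        "log2_ratio": r,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "experiment_id",
            "bait",
            "target_set",
            "condition_id",
            "pair",
            "log2_ratio",
        ],
    )


def summarize_pairs(table: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of the log2 ratio per pair (optionally group beforehand)."""
    if table.empty:
        return pd.DataFrame(columns=["pair", "n", "median_log2_ratio", "iqr"])
    g = table.groupby("pair")["log2_ratio"]
    return pd.DataFrame(
        {
            "pair": g.median().index,
            "n": g.size().to_numpy(),
            "median_log2_ratio": g.median().to_numpy(),
            "iqr": (g.quantile(0.75) - g.quantile(0.25)).to_numpy(),
        }
    ).reset_index(drop=True)
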