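"""Case-vs-control significance testing across the imputation ensemble.

Each (target set, condition) family is tested by unpaired two-sample t-tests
(Welch by default) between the bait-capture runs and the tag-only controls,
with Benjamini-Hochberg control across the proteins of that family. A protein
counts as significant in one imputation trial when its BH-adjusted p-value is
<= alpha (0.05) and its log2 fold-change (case minus control on the log2
scale) is >= fc_min (1). To suppress calls that depend on lucky completions
of missing cells, only proteins significant in at least ``min_trials`` of the
``n_trials`` completions (60 of 100 by default) are retained — the
imputation-stability filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ingest import ExperimentDesign, IntensityMatrix
from .impute import ImputationEnsemble


@dataclass(frozen=True)
class DifferentialParams:
    alpha: float = 0.05
    fc_min: float = 1.0
    min_trials: int = 60
    equal_var: bool = False  # False = Welch; True = pooled-variance

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_trials < 1:
            raise ValueError("min_trials must be >= 1")


def welch_ttest(case: np.ndarray, control: np.ndarray, equal_var: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise unpaired t-test; returns (log2FC, p).

    Degenerate rows (zero variance on both sides) get p = 1 when the means
    are equal and p = 0 otherwise.
    """
    case = np.atleast_2d(case)
    control = np.atleast_2d(control)
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("need >=2 replicates on each side")
    fc = case.mean(axis=1) - control.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant rows (e.g. the tag protein after self-normalization) are
        # resolved by the degenerate-row convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(case, control, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        p = p.copy()
        p[degenerate & (fc == 0)] = 1.0
        p[degenerate & (fc != 0)] = 0.0
    return fc, p


def test_condition(
    trial: IntensityMatrix,
    design: ExperimentDesign,
    target_set: str,
    condition_id: str,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-protein (log2FC, p) for one completed matrix and one condition."""
    if trial.scale != "log2":
        raise ValueError("test_condition expects a completed log2 matrix")
    case_cols = design.case_experiments(target_set, condition_id)
    ctrl_cols = design.control_experiments(target_set, condition_id)
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError(
            f"(target_set={target_set!r}, condition={condition_id!r}) has "
            f"{len(case_cols)} case / {len(ctrl_cols)} control columns; need >=2 each"
        )
    fc, p = welch_ttest(
        trial.values[case_cols].to_numpy(dtype=float),
        trial.values[ctrl_cols].to_numpy(dtype=float),
        equal_var=equal_var,
    )
    return pd.DataFrame({"log2FC": fc, "p": p}, index=trial.values.index)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved, capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d vector")
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def ensemble_tests(
    ensemble: ImputationEnsemble,
    design: ExperimentDesign,
    params: DifferentialParams = DifferentialParams(),
) -> dict[tuple[str, str], tuple[pd.Index, np.ndarray, np.ndarray]]:
    """Per-trial (log2FC, BH-adjusted p) arrays for every testable condition.

    Returns, keyed by (target_set, condition_id), the protein index and two
    (proteins x trials) arrays. BH is applied per trial across the proteins
    of the condition's family.
    """
    first = ensemble.trials[0]
    proteins = first.values.index
    out: dict[tuple[str, str], tuple[pd.Index, np.ndarray, np.ndarray]] = {}
    for ts, cond in design.testable_conditions():
        case_cols = design.case_experiments(ts, cond)
        ctrl_cols = design.control_experiments(ts, cond)
        n_trials = ensemble.n_trials
        fc_trials = np.empty((len(proteins), n_trials))
        adj_trials = np.empty((len(proteins), n_trials))
        for k, trial in enumerate(ensemble.trials):
            fc, p = welch_ttest(
                trial.values[case_cols].to_numpy(dtype=float),
                trial.values[ctrl_cols].to_numpy(dtype=float),
                equal_var=params.equal_var,
            )
            fc_trials[:, k] = fc
            adj_trials[:, k] = bh_adjust(p)
        out[(ts, cond)] = (proteins, fc_trials, adj_trials)
    return out


def run_differential(
    ensemble: ImputationEnsemble,
    design: ExperimentDesign,
    params: DifferentialParams = DifferentialParams(),
) -> pd.DataFrame:
    """Full ensemble testing with the stability filter.

    Returns one row per protein x target_set x condition with the median
    log2FC and median BH-adjusted p across trials, the count of trials in
    which the protein met both thresholds, and the pass flag
    (n_significant_trials >= min_trials).
    """
    frames = []
    for (ts, cond), (proteins, fc_trials, adj_trials) in ensemble_tests(
        ensemble, design, params
    ).items():
        n_trials = fc_trials.shape[1]
        sig = (adj_trials <= params.alpha) & (fc_trials >= params.fc_min)
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": proteins,
                    "target_set": ts,
                    "condition_id": cond,
                    "log2FC_median": np.median(fc_trials, axis=1),
                    "adjp_median": np.median(adj_trials, axis=1),
                    "n_significant_trials": sig.sum(axis=1),
                    "n_trials": n_trials,
                }
            )
        )
    results = pd.concat(frames, ignore_index=True)
    results["pass"] = results["n_significant_trials"] >= params.min_trials
    return results


def stability_filter(
    per_trial_fc: np.ndarray,
    per_trial_adjp: np.ndarray,
    params: DifferentialParams = DifferentialParams(),
) -> pd.DataFrame:
    """Aggregate per-trial (log2FC, adjusted p) arrays of shape (proteins, trials)."""
    if per_trial_fc.shape != per_trial_adjp.shape:
        raise ValueError("trial count mismatch between fold-changes and p-values")
    sig = (per_trial_adjp <= params.alpha) & (per_trial_fc >= params.fc_min)
    n_sig = sig.sum(axis=1)
    return pd.DataFrame(
        {
            "log2FC_median": np.median(per_trial_fc, axis=1),
            "adjp_median": np.median(per_trial_adjp, axis=1),
            "n_significant_trials": n_sig,
            "pass": n_sig >= params.min_trials,
        }
    )


def collate_significant(results: pd.DataFrame) -> pd.DataFrame:
    """Union of passing proteins with their per-protein tally of passed tests.

    The tally counts (target_set, condition) combinations in which the protein
    passed; a protein passing nothing is excluded.
    """
    passed = results[results["pass"]]
    tally = (
        passed.groupby("protein_id")
        .agg(
            n_tests_passed=("condition_id", "size"),
            target_sets=("target_set", lambda s: ";".join(sorted(set(s)))),
        )
        .reset_index()
    )
    return tally.sort_values(
        ["n_tests_passed", "protein_id"], ascending=[False, True]
    ).reset_index(drop=True)


def significant_proteins(results: pd.DataFrame, target_set: str | None = None) -> set[str]:
    """Proteins passing in >=1 condition, optionally restricted to one target set."""
    sub = results[results["pass"]]
    if target_set is not None:
        sub = sub[sub["target_set"] == target_set]
    return set(sub["protein_id"])
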