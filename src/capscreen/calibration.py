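"""Closed-loop benchmarks of the pipeline against generator ground truth.

Three standard experiments:

* **null calibration** — screens with no true interactors quantify the
  pipeline's type-I behaviour: the fraction of background proteins that pass
  the full filter chain (BH <= alpha, log2FC >= fc_min, stability >=
  min_trials/n_trials) should stay at or below alpha, and below what any
  single imputation trial would pass on its own;
* **sensitivity** — screens with interactors spiked at a known log2 effect
  measure recall and fold-change recovery;
* **stoichiometry** — proteins pinned at a known copy ratio check iBAQ-ratio
  recovery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import normalize as norm
from .differential import DifferentialParams, ensemble_tests
from .impute import ImputationEnsemble, ImputationParams, impute_ensemble
from .ingest import filter_records, protein_groups_from_frame
from .pipeline import RunConfig, analyze_screen
from .stoichiometry import stoichiometry_table
from .synthetic import GFP_ID, SyntheticConfig, TargetSpec, generate_screen, null_screen


def _normalized_ensemble(design, frame, imp: ImputationParams) -> ImputationEnsemble:
    records, lfq, ibaq = protein_groups_from_frame(frame, design)
    records, (lfq, ibaq), _ = filter_records(records, [lfq, ibaq])
    ens = impute_ensemble(norm.log2_transform(lfq), design, imp)
    trials = [norm.normalize_to_reference(t, GFP_ID) for t in ens.trials]
    return ImputationEnsemble(trials=trials, seeds=ens.seeds)


def null_screen_pass_fractions(
    cfg: SyntheticConfig,
    n_trials: int = 100,
    params: DifferentialParams = DifferentialParams(),
) -> tuple[float, float]:
    """(stability pass fraction, median single-trial pass fraction) over
    background proteins of one null screen.

    A background protein "passes" when it clears the per-condition thresholds
    in at least one condition; the single-trial figure applies the same
    per-trial thresholds without the stability requirement and takes the
    median across trials.
    """
    design, frame, truth = null_screen(cfg)
    ens = _normalized_ensemble(
        design, frame, ImputationParams(n_trials=n_trials, base_seed=cfg.seed + 1)
    )
    tests = ensemble_tests(ens, design, params)
    background = truth.background_proteins()
    any_sig = None  # proteins x trials, True when significant in >=1 condition
    stable_pass = None
    for (_ts, _cond), (proteins, fc, adjp) in tests.items():
        sig = (adjp <= params.alpha) & (fc >= params.fc_min)
        loc = pd.Index(proteins).get_indexer(background)
        loc = loc[loc >= 0]
        sig_bg = sig[loc]
        cond_pass = sig_bg.sum(axis=1) >= params.min_trials
        any_sig = sig_bg if any_sig is None else (any_sig | sig_bg)
        stable_pass = cond_pass if stable_pass is None else (stable_pass | cond_pass)
    stability_fraction = float(stable_pass.mean())
    single_trial_fraction = float(np.median(any_sig.mean(axis=0)))
    return stability_fraction, single_trial_fraction


def null_calibration(
    n_screens: int = 20,
    seed: int = 0,
    n_trials: int = 100,
    n_background: int = 500,
    params: DifferentialParams = DifferentialParams(),
) -> pd.DataFrame:
    """Type-I calibration over seeded null screens (4 conditions x 4+4 runs)."""
    rows = []
    for i in range(n_screens):
        cfg = SyntheticConfig(n_background=n_background, seed=seed + 1000 * (i + 1))
        stab, single = null_screen_pass_fractions(cfg, n_trials=n_trials, params=params)
        rows.append(
            {"screen": i, "seed": cfg.seed, "stability_pass_fraction": stab,
             "single_trial_pass_fraction": single}
        )
    return pd.DataFrame(rows)


def sensitivity_benchmark(
    seed: int = 0,
    effect: float = 4.0,
    n_interactors: int = 20,
    n_background: int = 500,
    noise_sd: float = 0.3,
    n_trials: int = 100,
) -> dict:
    """Recall and log2FC recovery on a spiked screen.

    Sensitivity counts (interactor, condition) pairs that pass the full
    pipeline; fold-change error compares the median estimated log2FC of those
    pairs with the spiked effect.
    """
    cfg = SyntheticConfig(
        n_background=n_background,
        n_interactors=n_interactors,
        effect_range=(effect, effect),
        noise_sd=noise_sd,
        seed=seed,
    )
    design, frame, truth = generate_screen(cfg)
    analysis = analyze_screen(
        design, frame, RunConfig(n_trials=n_trials, base_seed=seed + 1)
    )
    interactors = {p for ps in truth.interactors.values() for p in ps}
    sub = analysis.results[analysis.results["protein_id"].isin(interactors)]
    sensitivity = float(sub["pass"].mean())
    median_fc = float(sub["log2FC_median"].median())
    return {
        "sensitivity": sensitivity,
        "median_log2fc": median_fc,
        "true_effect": effect,
        "median_log2fc_error": median_fc - effect,
        "n_pairs": int(len(sub)),
        "results": analysis.results,
        "truth": truth,
    }


def stoichiometry_benchmark(seed: int = 0, copy_ratio: float = 2.0) -> dict:
    """iBAQ recovery of a known copy ratio over >= 20 case experiments."""
    cfg = SyntheticConfig(
        targets=(
            TargetSpec("NCBP1", ("7", "10", "12", "18"), 4, 4),
            TargetSpec("NCBP2", ("7", "10", "12", "18"), 4, 4),
        ),
        n_background=30,
        n_interactors=0,
        noise_sd=0.2,
        copy_numbers=(("STOICH_A", copy_ratio), ("STOICH_B", 1.0)),
        seed=seed,
    )
    design, frame, _ = generate_screen(cfg)
    _, _, ibaq = protein_groups_from_frame(frame, design)
    table = stoichiometry_table(ibaq, [("STOICH_A", "STOICH_B")], design)
    return {
        "median_log2_ratio": float(table["log2_ratio"].median()),
        "true_log2_ratio": float(np.log2(copy_ratio)),
        "n_experiments": int(len(table)),
        "table": table,
    }
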