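"""Decision-tree multiple imputation of missing log2 intensities.

Missingness in label-free AP-MS is dominated by left censoring: low-abundance
proteins fall below the detection limit (missing not at random). The imputer
treats each protein within one replicate group — the runs sharing a target
set, condition and case/control role — and applies one of three branches
depending on how much evidence the group retains:

* fully observed: nothing to do;
* partially missing with at least two observed replicates: the protein was
  demonstrably detectable there, so missing cells are drawn from a normal
  centred on the observed replicate mean, with the observed spread (floored to
  avoid degenerate draws);
* no usable within-group evidence (zero or one observed replicate): missing
  cells are drawn per experiment from a down-shifted, narrowed normal in the
  tail of that column's observed intensity distribution — the standard
  left-censoring model with the Perseus-style constants (shift 1.8 sd, width
  0.3 sd) as defaults.

The whole completion is repeated over many seeds (100 by default); every
downstream statistic is aggregated across the resulting ensemble, and the
stability filter in :mod:`capscreen.differential` discards calls that only an
unlucky completion supports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import ExperimentDesign, IntensityMatrix


@dataclass(frozen=True)
class ImputationParams:
    """Constants of the three-branch imputation scheme.

    downshift and width are in multiples of the per-column observed standard
    deviation; sd_floor is in log2 units and floors the replicate-group sd
    used by the partially-missing branch.
    """

    n_trials: int = 100
    downshift: float = 1.8
    width: float = 0.3
    sd_floor: float = 0.2
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")

    def seeds(self) -> list[int]:
        return [int(self.base_seed) + i for i in range(self.n_trials)]


@dataclass
class ImputationEnsemble:
    """A list of seeded completions; observed cells identical across trials."""

    trials: list[IntensityMatrix]
    seeds: list[int]

    def __post_init__(self) -> None:
        if len(self.trials) != len(self.seeds):
            raise ValueError("one seed per trial required")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def stack(self) -> np.ndarray:
        """trials x proteins x experiments array."""
        return np.stack([t.values.to_numpy(dtype=float) for t in self.trials])

    def mean_matrix(self) -> IntensityMatrix:
        """Cell-wise ensemble mean (observed cells come back exactly)."""
        first = self.trials[0]
        mean = self.stack().mean(axis=0)
        return IntensityMatrix(
            pd.DataFrame(mean, index=first.values.index, columns=first.values.columns),
            first.layer,
            first.scale,
        )


def _column_stats(values: np.ndarray, min_observed: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Observed mean and sd per column; error when a column is too sparse."""
    obs = ~np.isnan(values)
    n = obs.sum(axis=0)
    if np.any(n < min_observed):
        bad = np.nonzero(n < min_observed)[0]
        raise ValueError(
            f"column(s) at position(s) {bad.tolist()} have fewer than {min_observed} "
            "observed values; cannot estimate the censoring distribution"
        )
    mu = np.nanmean(values, axis=0)
    sigma = np.nanstd(values, axis=0, ddof=1)
    return mu, sigma


def impute_once(
    m: IntensityMatrix,
    design: ExperimentDesign,
    seed: int,
    params: ImputationParams = ImputationParams(),
) -> IntensityMatrix:
    """One seeded completion of ``m`` (log2 scale).

    Deterministic given ``seed``: replicate groups are visited in design
    order and draws are made with a single generator.
    """
    if m.scale != "log2":
        raise ValueError("imputation operates on the log2 scale")
    rng = np.random.default_rng(seed)
    values = m.values.to_numpy(dtype=float).copy()
    col_index = {c: i for i, c in enumerate(m.values.columns)}
    mu_col, sd_col = _column_stats(m.values.to_numpy(dtype=float))

    for (_ts, _cond, _role), exp_ids in design.replicate_groups():
        cols = np.array([col_index[e] for e in exp_ids if e in col_index], dtype=int)
        if cols.size == 0:
            continue
        block = values[:, cols]
        miss = np.isnan(block)
        n_obs = (~miss).sum(axis=1)
        any_miss = miss.any(axis=1)

        # branch B: replicate-informed draw around the observed group mean
        rows_b = np.nonzero(any_miss & (n_obs >= 2))[0]
        if rows_b.size:
            sub = block[rows_b]
            means = np.nanmean(sub, axis=1)
            sds = np.maximum(np.nanstd(sub, axis=1, ddof=1), params.sd_floor)
            for j, r in enumerate(rows_b):
                holes = cols[np.isnan(values[r, cols])]
                values[r, holes] = rng.normal(means[j], sds[j], size=holes.size)

        # branch C: column-wise down-shifted draw (left-censoring model)
        rows_c = np.nonzero(any_miss & (n_obs < 2))[0]
        if rows_c.size:
            for c in cols:
                holes = rows_c[np.isnan(values[rows_c, c])]
                if holes.size:
                    values[holes, c] = rng.normal(
                        mu_col[c] - params.downshift * sd_col[c],
                        params.width * sd_col[c],
                        size=holes.size,
                    )

    out = pd.DataFrame(values, index=m.values.index, columns=m.values.columns)
    if out.isna().any().any():
        # cells in experiments not covered by the design's replicate groups
        raise ValueError("matrix contains missing cells outside any replicate group")
    return IntensityMatrix(out, m.layer, "log2")


def impute_ensemble(
    m: IntensityMatrix,
    design: ExperimentDesign,
    params: ImputationParams = ImputationParams(),
) -> ImputationEnsemble:
    """``params.n_trials`` seeded completions (seeds = base_seed + trial index)."""
    seeds = params.seeds()
    trials = [impute_once(m, design, s, params) for s in seeds]
    return ImputationEnsemble(trials=trials, seeds=seeds)
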