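"""Synthetic affinity-capture screens with known ground truth.

The generator emulates the statistical structure of a tagged-bait IP-MS
screen: a bait protein captured at high abundance in its own runs, a GFP tag
present in every experiment (tag-only controls included), true interactors
elevated over control by condition-dependent log2 effects, a large background
of proteins identically distributed between case and control, log-normal
baseline abundances with replicate noise, and intensity-dependent missingness
— a logistic detection curve in log2 intensity (left censoring, MNAR) plus a
small completely-at-random dropout. An iBAQ layer is derived from LFQ through
a per-protein "observable peptides" size factor so that iBAQ ratios track the
simulated copy numbers.

Everything is deterministic given the seed, and the generator returns the
full ground truth (baselines, effects, size factors, per-cell censoring
labels) for closed-loop testing of the downstream pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import DESIGN_COLUMNS, ExperimentDesign

GFP_ID = "GFP"


@dataclass(frozen=True)
class TargetSpec:
    """One screen: a bait, its extraction conditions and replicate counts."""

    name: str
    conditions: tuple[str, ...] = ("7", "10", "12", "18")
    n_case_replicates: int = 4
    n_control_replicates: int = 4
    vessel: str = "multiwell"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a generated screen.

    Abundances are on the log2 LFQ scale. Defaults mirror a single-bait screen
    with 4 extraction conditions in quadruplicate against quadruplicate
    tag-only controls, 500 background proteins, 20 interactors enriched by
    2-6 log2 units, replicate noise of 0.3 log2 units, and a logistic
    detection model (midpoint 21, slope 1.2) that leaves roughly a fifth of
    background cells censored, plus 2% random dropout.
    """

    targets: tuple[TargetSpec, ...] = (TargetSpec("NCBP1"),)
    n_background: int = 500
    n_interactors: int = 20
    effect_range: tuple[float, float] = (2.0, 6.0)
    baseline_mean: float = 24.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.3
    mnar_midpoint: float = 21.0
    mnar_slope: float = 1.2
    mcar_rate: float = 0.02
    gfp_log2: float = 26.0
    bait_log2: float = 27.0
    size_factor_range: tuple[float, float] = (5.0, 60.0)
    copy_numbers: tuple[tuple[str, float], ...] = ()  # (protein, true copies)
    copy_offset: float = 20.0  # log2 iBAQ at one copy; keeps pinned proteins detectable
    n_decoys: int = 0
    n_contaminants: int = 0
    n_low_evidence: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mcar_rate <= 1:
            raise ValueError("mcar_rate must lie in [0, 1]")
        if self.noise_sd <= 0 or self.baseline_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if self.n_background < 0 or self.n_interactors < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class SyntheticTruth:
    """Ground truth for one generated screen."""

    baseline_log2: dict[str, float]
    size_factor: dict[str, float]
    interactors: dict[str, list[str]]  # target -> interactor ids
    effects: dict[str, dict[str, dict[str, float]]]  # target -> condition -> protein -> effect
    true_log2_lfq: pd.DataFrame  # pre-censoring log2 LFQ (NaN = truly absent)
    censored: pd.DataFrame  # "observed" | "mnar" | "mcar" | "absent"
    copy_number: dict[str, float]

    def background_proteins(self) -> list[str]:
        interactors = {p for ps in self.interactors.values() for p in ps}
        special = interactors | set(self.interactors) | {GFP_ID}
        return [p for p in self.true_log2_lfq.index if p not in special]


def _build_design(cfg: SyntheticConfig) -> ExperimentDesign:
    rows = []
    for t in cfg.targets:
        for cond in t.conditions:
            for r in range(1, t.n_case_replicates + 1):
                rows.append((f"{t.name}_c{cond}_r{r}", t.name, t.name, cond, r, t.vessel, "case"))
            for r in range(1, t.n_control_replicates + 1):
                rows.append((f"{t.name}_c{cond}_ctl{r}", "control", t.name, cond, r, t.vessel, "control"))
    return ExperimentDesign(pd.DataFrame(rows, columns=list(DESIGN_COLUMNS)))


def generate_screen(
    cfg: SyntheticConfig,
) -> tuple[ExperimentDesign, pd.DataFrame, SyntheticTruth]:
    """Generate one screen: design, protein-groups table, ground truth.

    The table is in the dialect :func:`capscreen.ingest.read_protein_groups`
    reads: censored cells are written as intensity 0.
    """
    rng = np.random.default_rng(cfg.seed)
    design = _build_design(cfg)
    dt = design.table

    proteins: list[str] = [GFP_ID]
    baits = [t.name for t in cfg.targets]
    proteins += baits
    interactors: dict[str, list[str]] = {}
    for t in cfg.targets:
        ids = [f"INT_{t.name}_{i:03d}" for i in range(1, cfg.n_interactors + 1)]
        interactors[t.name] = ids
        proteins += ids
    background = [f"BG{i:04d}" for i in range(1, cfg.n_background + 1)]
    proteins += background
    for p, _copies in cfg.copy_numbers:
        if p not in proteins:
            proteins.append(p)

    baseline = {GFP_ID: cfg.gfp_log2}
    for b in baits:
        baseline[b] = cfg.bait_log2
    for p in proteins:
        if p not in baseline:
            baseline[p] = float(rng.normal(cfg.baseline_mean, cfg.baseline_sd))

    size_factor = {
        p: float(np.exp(rng.uniform(*np.log(cfg.size_factor_range)))) for p in proteins
    }
    copy_number = {}
    for p, copies in cfg.copy_numbers:
        copy_number[p] = float(copies)
        # pin log2 iBAQ = log2(copies) + offset, i.e. log2 LFQ = that + log2(size factor)
        baseline[p] = float(np.log2(copies) + cfg.copy_offset + np.log2(size_factor[p]))

    effects: dict[str, dict[str, dict[str, float]]] = {}
    for t in cfg.targets:
        effects[t.name] = {}
        per_protein = {
            p: float(rng.uniform(*cfg.effect_range)) for p in interactors[t.name]
        }
        for cond in t.conditions:
            effects[t.name][cond] = dict(per_protein)

    exp_ids = design.experiment_ids
    n, m = len(proteins), len(exp_ids)
    true_log2 = np.full((n, m), np.nan)
    p_index = {p: i for i, p in enumerate(proteins)}
    for j, (_, run) in enumerate(dt.iterrows()):
        ts, cond, role, bait = run["target_set"], run["condition_id"], run["role"], run["bait"]
        for p in proteins:
            if p in baits:
                # the tagged bait is expressed only in its own case runs
                if not (role == "case" and bait == p):
                    continue
            x = baseline[p]
            if role == "case" and p in effects.get(ts, {}).get(cond, {}):
                x += effects[ts][cond][p]
            true_log2[p_index[p], j] = x + rng.normal(0.0, cfg.noise_sd)

    # detection: logistic in log2 intensity, then MCAR; the tag is always kept
    detect_p = 1.0 / (1.0 + np.exp(-cfg.mnar_slope * (true_log2 - cfg.mnar_midpoint)))
    u_mnar = rng.uniform(size=true_log2.shape)
    u_mcar = rng.uniform(size=true_log2.shape)
    absent = np.isnan(true_log2)
    mnar = ~absent & (u_mnar > detect_p)
    mcar = ~absent & ~mnar & (u_mcar < cfg.mcar_rate)
    gfp_row = p_index[GFP_ID]
    mnar[gfp_row, :] = False
    mcar[gfp_row, :] = False

    labels = np.where(absent, "absent", np.where(mnar, "mnar", np.where(mcar, "mcar", "observed")))
    observed_log2 = np.where(labels == "observed", true_log2, np.nan)

    idx = pd.Index(proteins, name="protein_id")
    truth = SyntheticTruth(
        baseline_log2=baseline,
        size_factor=size_factor,
        interactors=interactors,
        effects=effects,
        true_log2_lfq=pd.DataFrame(true_log2, index=idx, columns=exp_ids),
        censored=pd.DataFrame(labels, index=idx, columns=exp_ids),
        copy_number=copy_number,
    )

    lfq_linear = np.exp2(observed_log2)
    sf = np.array([size_factor[p] for p in proteins])[:, None]
    ibaq_linear = lfq_linear / sf

    table = {
        "Majority protein IDs": list(proteins),
        "Gene names": list(proteins),
        "Peptide counts (razor + unique)": [
            str(int(rng.integers(2, 41))) for _ in proteins
        ],
        "Reverse": ["" for _ in proteins],
        "Potential contaminant": ["" for _ in proteins],
    }
    intensity_cols = {}
    for j, e in enumerate(exp_ids):
        intensity_cols[f"LFQ intensity {e}"] = np.nan_to_num(lfq_linear[:, j], nan=0.0)
        intensity_cols[f"iBAQ {e}"] = np.nan_to_num(ibaq_linear[:, j], nan=0.0)
    frame = pd.concat([pd.DataFrame(table), pd.DataFrame(intensity_cols)], axis=1)
    frame = _inject_junk_rows(frame, cfg, rng, exp_ids)
    return design, frame, truth


def _inject_junk_rows(
    frame: pd.DataFrame, cfg: SyntheticConfig, rng: np.random.Generator, exp_ids: list[str]
) -> pd.DataFrame:
    """Optional decoy / contaminant / single-peptide rows for filter exercises."""
    extra = []
    def _row(pid: str, reverse: str, contam: str, counts: str) -> dict:
        row = {
            "Majority protein IDs": pid,
            "Gene names": pid,
            "Peptide counts (razor + unique)": counts,
            "Reverse": reverse,
            "Potential contaminant": contam,
        }
        for e in exp_ids:
            v = float(np.exp2(rng.normal(22.0, 1.0)))
            row[f"LFQ intensity {e}"] = v
            row[f"iBAQ {e}"] = v / 10.0
        return row

    for i in range(cfg.n_decoys):
        extra.append(_row(f"REV{i:03d}", "+", "", str(int(rng.integers(1, 20)))))
    for i in range(cfg.n_contaminants):
        extra.append(_row(f"CON{i:03d}", "", "+", str(int(rng.integers(2, 30)))))
    for i in range(cfg.n_low_evidence):
        extra.append(_row(f"LOW{i:03d}", "", "", "1"))
    if extra:
        frame = pd.concat([frame, pd.DataFrame(extra)], ignore_index=True)
    return frame


def null_screen(cfg: SyntheticConfig) -> tuple[ExperimentDesign, pd.DataFrame, SyntheticTruth]:
    """A screen with no true interactors (bait and tag constructs unchanged)."""
    from dataclasses import replace

    return generate_screen(replace(cfg, n_interactors=0))


def write_protein_groups(
    design: ExperimentDesign,
    frame: pd.DataFrame,
    truth: SyntheticTruth | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the proteinGroups-dialect TSV, the design TSV and the truth JSON.

    The written tables round-trip exactly through :mod:`capscreen.ingest`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "protein_groups": out / "proteinGroups.txt",
        "design": out / "design.tsv",
    }
    # %.17g guarantees bit-exact float round-trip through the text format
    frame.to_csv(paths["protein_groups"], sep="\t", index=False, float_format="%.17g")
    design.table.to_csv(paths["design"], sep="\t", index=False)
    if truth is not None:
        paths["truth"] = out / "truth.json"
        payload = {
            "baseline_log2": truth.baseline_log2,
            "size_factor": truth.size_factor,
            "interactors": truth.interactors,
            "effects": truth.effects,
            "copy_number": truth.copy_number,
            "censored": truth.censored.to_dict(orient="index"),
        }
        paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths
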