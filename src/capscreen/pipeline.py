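"""End-to-end orchestration of the screen analysis.

Stage order follows the processing scheme: ingest and filter -> homolog merge
-> log2 -> multiple imputation -> tag (GFP) normalization -> range-restoring
rescale -> per-condition differential testing with the stability filter ->
complex enrichment, stoichiometry and MDS embedding. A machine-readable
report records parameters, seeds, per-stage record counts and wall-clock so
identical inputs and seeds reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import complexes as cx
from . import differential as diff
from . import embedding as emb
from . import normalize as norm
from . import stoichiometry as stoich
from .impute import ImputationEnsemble, ImputationParams, impute_ensemble
from .ingest import (
    DEFAULT_MERGE_GROUPS,
    ExperimentDesign,
    IntensityMatrix,
    ProteinRecord,
    filter_records,
    merge_homologs,
    protein_groups_from_frame,
    read_design,
)
from .synthetic import GFP_ID


@dataclass
class RunConfig:
    """One configuration bundle; defaults are the screen's stated constants."""

    protein_groups: str | Path | None = None
    design: str | Path | None = None
    catalog: str | Path | None = None
    out_dir: str | Path | None = None
    reference_protein: str = GFP_ID
    alpha: float = 0.05
    fc_min: float = 1.0
    n_trials: int = 100
    min_trials: int = 60
    imputation_downshift: float = 1.8
    imputation_width: float = 0.3
    imputation_sd_floor: float = 0.2
    base_seed: int = 0
    equal_var: bool = False
    min_peptides: int = 2
    apply_rescale: bool = True
    merge_groups: dict | None = None
    stoich_pairs: tuple[tuple[str, str], ...] = ()
    mds_min_tests: int = 1
    mds_dims: int = 3

    def imputation_params(self) -> ImputationParams:
        return ImputationParams(
            n_trials=self.n_trials,
            downshift=self.imputation_downshift,
            width=self.imputation_width,
            sd_floor=self.imputation_sd_floor,
            base_seed=self.base_seed,
        )

    def differential_params(self) -> diff.DifferentialParams:
        return diff.DifferentialParams(
            alpha=self.alpha,
            fc_min=self.fc_min,
            min_trials=self.min_trials,
            equal_var=self.equal_var,
        )


@dataclass
class ScreenAnalysis:
    """All in-memory stage outputs of one pipeline run."""

    design: ExperimentDesign
    records: list[ProteinRecord]
    lfq_linear: IntensityMatrix
    ibaq_linear: IntensityMatrix
    ensemble: ImputationEnsemble
    normalized_mean: IntensityMatrix
    rescale_coefficient: float
    results: pd.DataFrame
    tally: pd.DataFrame
    drop_log: dict[str, int]


def analyze_screen(
    design: ExperimentDesign,
    protein_groups: pd.DataFrame,
    cfg: RunConfig = RunConfig(),
) -> ScreenAnalysis:
    """Run ingest -> differential on an in-memory protein-groups table."""
    records, lfq, ibaq = protein_groups_from_frame(protein_groups, design)
    records, (lfq, ibaq), drop_log = filter_records(records, [lfq, ibaq], cfg.min_peptides)
    merge_groups = cfg.merge_groups if cfg.merge_groups is not None else DEFAULT_MERGE_GROUPS
    lfq, ibaq = merge_homologs([lfq, ibaq], merge_groups, records)

    log2_lfq = norm.log2_transform(lfq)
    ensemble = impute_ensemble(log2_lfq, design, cfg.imputation_params())

    c = norm.compute_rescale_coefficient(lfq) if cfg.apply_rescale else 1.0
    normalized_trials = [
        norm.apply_rescale(norm.normalize_to_reference(t, cfg.reference_protein), c)
        for t in ensemble.trials
    ]
    normalized = ImputationEnsemble(trials=normalized_trials, seeds=ensemble.seeds)

    results = diff.run_differential(normalized, design, cfg.differential_params())
    passed = results[results["pass"]]
    tally = diff.collate_significant(results) if len(passed) else pd.DataFrame(
        columns=["protein_id", "n_tests_passed", "target_sets"]
    )
    return ScreenAnalysis(
        design=design,
        records=records,
        lfq_linear=lfq,
        ibaq_linear=ibaq,
        ensemble=normalized,
        normalized_mean=normalized.mean_matrix(),
        rescale_coefficient=c,
        results=results,
        tally=tally,
        drop_log=drop_log,
    )


def qc_summary(design: ExperimentDesign, lfq: IntensityMatrix, reference: str = GFP_ID) -> pd.DataFrame:
    """Per-experiment quantification counts, missingness and tag intensity."""
    rows = []
    for _, run in design.table.iterrows():
        e = run["experiment_id"]
        col = lfq.values[e]
        n_quant = int(col.notna().sum())
        ref_val = float(col.get(reference, np.nan)) if reference in lfq.values.index else np.nan
        flags = []
        if n_quant == 0:
            flags.append("no_detections")
        if np.isnan(ref_val):
            flags.append("tag_missing")
        rows.append(
            {
                "experiment_id": e,
                "target_set": run["target_set"],
                "role": run["role"],
                "proteins_quantified": n_quant,
                "missing_fraction": float(col.isna().mean()),
                "tag_intensity": ref_val,
                "median_intensity": float(col.median()),
                "qc_flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """File-to-file pipeline run; returns the JSON-able run report.

    Validates the configuration before any compute, writes every stage table
    under ``cfg.out_dir`` and a ``report.json`` beside them.
    """
    if cfg.protein_groups is None or cfg.design is None or cfg.out_dir is None:
        raise ValueError("protein_groups, design and out_dir paths are required")
    pg_path, design_path = Path(cfg.protein_groups), Path(cfg.design)
    for p in (pg_path, design_path):
        if not p.exists():
            raise FileNotFoundError(f"input not found: {p}")
    catalog = None
    if cfg.catalog is not None:
        cat_path = Path(cfg.catalog)
        if not cat_path.exists():
            raise FileNotFoundError(f"catalog not found: {cat_path}")
        catalog = cx.read_complex_catalog(cat_path)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "inputs": {
            "protein_groups": {"path": str(pg_path), "sha256": _sha256(pg_path)},
            "design": {"path": str(design_path), "sha256": _sha256(design_path)},
        },
        "parameters": {
            k: v
            for k, v in asdict(cfg).items()
            if k not in ("protein_groups", "design", "catalog", "out_dir")
        },
        "stages": {},
    }

    def _stage(name: str, fn):
        t0 = time.perf_counter()
        value = fn()
        report["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        return value

    design = _stage("read_design", lambda: read_design(design_path))
    frame = pd.read_csv(pg_path, sep="\t", dtype=str)
    analysis = _stage("analyze", lambda: analyze_screen(design, frame, cfg))
    report["stages"]["analyze"].update(
        {
            "proteins_retained": len(analysis.lfq_linear.proteins),
            "dropped": analysis.drop_log,
            "n_trials": analysis.ensemble.n_trials,
            "rescale_coefficient": analysis.rescale_coefficient,
            "n_passing": int(analysis.results["pass"].sum()),
        }
    )

    qc = _stage("qc", lambda: qc_summary(design, analysis.lfq_linear, cfg.reference_protein))
    qc.to_csv(out / "qc_summary.tsv", sep="\t", index=False)
    analysis.results.to_csv(out / "differential.tsv", sep="\t", index=False)
    analysis.tally.to_csv(out / "significant_tally.tsv", sep="\t", index=False)

    if catalog is not None:
        def _complexes():
            sig = {
                ts: diff.significant_proteins(analysis.results, ts)
                for ts in design.target_sets
            }
            display = {
                ts: norm.control_subtract_linear(analysis.lfq_linear, design, ts)
                for ts in design.target_sets
            }
            return cx.enrich_complexes(catalog, sig, display)

        enr = _stage("complexes", _complexes)
        enr.to_csv(out / "complexes.tsv", sep="\t", index=False)
        report["stages"]["complexes"]["n_included"] = int(enr["included"].sum())

    if cfg.stoich_pairs:
        st = _stage(
            "stoichiometry",
            lambda: stoich.stoichiometry_table(
                analysis.ibaq_linear, list(cfg.stoich_pairs), design
            ),
        )
        st.to_csv(out / "stoichiometry.tsv", sep="\t", index=False)

    if len(analysis.tally):
        def _mds():
            profiles = emb.build_profile_matrix(
                analysis.normalized_mean, design, analysis.results, cfg.mds_min_tests
            )
            coords, eigvals = emb.classical_mds(
                emb.euclidean_distances(profiles), cfg.mds_dims
            )
            return profiles, coords, eigvals

        profiles, coords, eigvals = _stage("embedding", _mds)
        coords.to_csv(out / "mds_coordinates.tsv", sep="\t")
        report["stages"]["embedding"].update(
            {"n_dimensions_before_reduction": int(profiles.shape[1]),
             "n_proteins_embedded": int(profiles.shape[0])}
        )

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
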