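"""capscreen: quantitative affinity-capture (AP-MS) screen analysis.

Tag-based IP-MS screens compare bait captures against tag-only controls under
several extraction conditions. This package implements the full
post-identification analysis: protein-group ingestion and filtering, log2 /
GFP-tag normalization, left-censored multiple imputation, per-condition
differential enrichment with an imputation-stability filter, complex-centric
scoring against a CORUM-style catalog, iBAQ stoichiometry ratios, and
classical-MDS interactome embedding — plus a ground-truth synthetic screen
generator for closed-loop validation.
"""

from importlib.resources import files
from pathlib import Path

from .differential import (
    DifferentialParams,
    bh_adjust,
    collate_significant,
    run_differential,
    significant_proteins,
    test_condition,
)
from .impute import ImputationEnsemble, ImputationParams, impute_ensemble, impute_once
from .ingest import (
    ExperimentDesign,
    IntensityMatrix,
    ProteinRecord,
    filter_records,
    merge_homologs,
    read_design,
    read_protein_groups,
)
from .pipeline import RunConfig, ScreenAnalysis, analyze_screen, qc_summary, run_pipeline
from .synthetic import SyntheticConfig, TargetSpec, generate_screen, null_screen

__version__ = "0.1.0"


def ncbp_design_path() -> Path:
    """Path to the packaged NCBP screen design registry (synthetic reconstruction).

    Matches the screen's printed per-target case-IP totals — 23 NCBP1, 22
    NCBP2 and 12 NCBP3 runs, 57 in all — with matched tag-only controls; the
    per-condition replicate split is reconstructed, not transcribed.
    """
    return Path(str(files("capscreen").joinpath("data/synthetic_ncbp_design.tsv")))


def toy_catalog_path() -> Path:
    """Path to the packaged toy complex catalog (test fixture)."""
    return Path(str(files("capscreen").joinpath("data/toy_complexes.tsv")))
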