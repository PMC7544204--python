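"""Log transformation, bait-tag normalization, rescaling and control subtraction.

Capture efficiency varies between IP runs, so intensities are made comparable
by dividing each run's values by that run's intensity of the affinity tag
(GFP), which is present in every experiment — tag-only controls included. On
the log2 scale this is a per-column subtraction. Because the division shrinks
the numeric range, a single multiplicative coefficient — the mean of the
smallest and largest pre-normalization intensity — restores the original range
(an additive shift on the log scale that cancels in every two-sample
comparison).

Control subtraction produces display-layer values: per condition, the mean
control LFQ intensity is subtracted from the mean case intensity on the linear
scale and the difference is log10-transformed when positive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ingest import ExperimentDesign, IntensityMatrix


def log2_transform(m: IntensityMatrix) -> IntensityMatrix:
    """log2 each present cell; mask untouched; scale tag flips to log2."""
    if m.scale != "linear":
        raise ValueError("log2_transform expects a linear-scale matrix")
    return IntensityMatrix(np.log2(m.values), m.layer, "log2")


def linear_transform(m: IntensityMatrix) -> IntensityMatrix:
    """Inverse of :func:`log2_transform`."""
    if m.scale != "log2":
        raise ValueError("linear_transform expects a log2-scale matrix")
    return IntensityMatrix(np.exp2(m.values), m.layer, "linear")


def normalize_to_reference(m: IntensityMatrix, reference: str = "GFP") -> IntensityMatrix:
    """Subtract the reference (tag) protein's log2 value from each column.

    Equivalent to dividing every linear intensity by the run's GFP intensity;
    the reference row becomes identically zero. The reference must be
    quantified in every column (guaranteed after imputation).
    """
    if m.scale != "log2":
        raise ValueError("normalize_to_reference operates on the log2 scale")
    if reference not in m.values.index:
        raise KeyError(f"reference protein {reference!r} not present in matrix")
    ref = m.values.loc[reference]
    missing = ref.index[ref.isna()]
    if len(missing):
        raise ValueError(
            f"reference {reference!r} not quantified in experiment(s) {list(missing)}"
        )
    return IntensityMatrix(m.values.sub(ref, axis=1), m.layer, "log2")


def compute_rescale_coefficient(m_before: IntensityMatrix) -> float:
    """Mean of the smallest and largest present linear intensity.

    Computed globally over the pre-normalization matrix; multiplying the
    normalized values by this coefficient restores the data's original range.
    """
    if m_before.scale != "linear":
        raise ValueError("rescale coefficient is defined on the linear scale")
    arr = m_before.values.to_numpy(dtype=float)
    present = arr[~np.isnan(arr)]
    if present.size == 0:
        raise ValueError("cannot compute rescale coefficient of an empty matrix")
    return float((present.min() + present.max()) / 2.0)


def apply_rescale(m: IntensityMatrix, coefficient: float) -> IntensityMatrix:
    """Multiply by ``coefficient`` (adds log2(c) on the log2 scale)."""
    if coefficient <= 0:
        raise ValueError("rescale coefficient must be positive")
    if m.scale == "log2":
        return IntensityMatrix(m.values + np.log2(coefficient), m.layer, "log2")
    return IntensityMatrix(m.values * coefficient, m.layer, "linear")


def control_subtract(
    m: IntensityMatrix,
    design: ExperimentDesign,
    target_set: str,
) -> pd.DataFrame:
    """Control-subtracted log10 display intensities, per protein x condition.

    For each condition of ``target_set``: mean linear case intensity minus mean
    linear control intensity, missing cells entering the means as 0 (a protein
    never detected in controls contributes background 0). The difference is
    log10-transformed when positive and NaN ("undefined/grey") otherwise.
    """
    if m.scale != "linear" or m.layer != "LFQ":
        raise ValueError("control_subtract expects the linear LFQ layer")
    out = {}
    for cond in design.conditions(target_set):
        case_cols = design.case_experiments(target_set, cond)
        ctrl_cols = design.control_experiments(target_set, cond)
        case_mean = m.values[case_cols].fillna(0.0).mean(axis=1)
        ctrl_mean = m.values[ctrl_cols].fillna(0.0).mean(axis=1)
        diff = case_mean - ctrl_mean
        out[cond] = np.log10(diff.where(diff > 0))
    return pd.DataFrame(out, index=m.values.index)


def control_subtract_linear(
    m: IntensityMatrix,
    design: ExperimentDesign,
    target_set: str,
) -> pd.DataFrame:
    """Linear-scale control-subtracted means (may be <= 0), per protein x condition."""
    if m.scale != "linear" or m.layer != "LFQ":
        raise ValueError("control_subtract expects the linear LFQ layer")
    out = {}
    for cond in design.conditions(target_set):
        case_cols = design.case_experiments(target_set, cond)
        ctrl_cols = design.control_experiments(target_set, cond)
        out[cond] = (
            m.values[case_cols].fillna(0.0).mean(axis=1)
            - m.values[ctrl_cols].fillna(0.0).mean(axis=1)
        )
    return pd.DataFrame(out, index=m.values.index)
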