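"""Complex-centric enrichment against a CORUM-style catalog.

A complex is summarized per target by its *protein ratio* — the fraction of
its annotated subunits that passed the differential screen — and included in
the enrichment display when at least half its subunits pass (complexes with
three or more members) or both subunits pass (two-member complexes). The
relative abundance of an included complex is the log10 of the mean
control-subtracted linear LFQ intensity over its qualifying members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ProteinComplex:
    complex_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"complex {self.complex_id!r} has an empty member set")


@dataclass
class ComplexCatalog:
    complexes: list[ProteinComplex]

    def __post_init__(self) -> None:
        ids = [c.complex_id for c in self.complexes]
        if len(ids) != len(set(ids)):
            raise ValueError("complex ids must be unique")

    def __iter__(self):
        return iter(self.complexes)

    def __len__(self) -> int:
        return len(self.complexes)

    def redundant_pairs(self) -> list[tuple[str, str]]:
        """Pairs of catalog entries with identical member sets (kept, flagged)."""
        seen: dict[frozenset[str], str] = {}
        out = []
        for c in self.complexes:
            if c.members in seen:
                out.append((seen[c.members], c.complex_id))
            else:
                seen[c.members] = c.complex_id
        return out


# CORUM coreComplexes.txt column holding the semicolon-separated accessions
_CORUM_SUBUNIT_COL = "subunits(UniProt IDs)"


def read_complex_catalog(path) -> ComplexCatalog:
    """Parse a CORUM coreComplexes dialect or a minimal 3-column TSV.

    The minimal dialect is ``complex_id <tab> name <tab> members`` with
    members semicolon-separated; duplicated accessions within a row are
    deduplicated, rows with no members are skipped with a warning.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if _CORUM_SUBUNIT_COL in table.columns:
        id_col, name_col, mem_col = "ComplexID", "ComplexName", _CORUM_SUBUNIT_COL
    else:
        id_col, name_col, mem_col = table.columns[:3]
    complexes = []
    for _, row in table.iterrows():
        raw = row[mem_col]
        members = frozenset(
            m.strip() for m in str(raw).split(";") if isinstance(raw, str) and m.strip()
        )
        if not members:
            warnings.warn(f"complex {row[id_col]!r} has no members; skipped", stacklevel=2)
            continue
        complexes.append(
            ProteinComplex(str(row[id_col]), str(row[name_col]), members)
        )
    return ComplexCatalog(complexes)


def protein_ratio(cx: ProteinComplex, significant: set[str]) -> float:
    """Fraction of the complex's subunits in the significant set."""
    return len(cx.members & significant) / len(cx.members)


def is_included(cx: ProteinComplex, ratio: float) -> bool:
    """Inclusion rule: ratio >= 0.5 for >=3 members; both members for pairs."""
    if len(cx.members) >= 3:
        return ratio >= 0.5
    return ratio == 1.0


def enrich_complexes(
    catalog: ComplexCatalog,
    significant_by_target: dict[str, set[str]],
    display_values: dict[str, pd.DataFrame],
    log_then_mean: bool = False,
) -> pd.DataFrame:
    """Per complex x target: ratio, inclusion and control-subtracted intensity.

    ``display_values[target]`` is the *linear* control-subtracted per-protein
    x condition frame from :func:`capscreen.normalize.control_subtract_linear`.
    A member qualifies for the intensity summary when its across-condition mean
    subtracted intensity is positive; the complex intensity is the log10 of the
    mean over qualifying members (or, with ``log_then_mean``, the mean of their
    log10 values). NaN when no member qualifies.
    """
    rows = []
    for target, significant in significant_by_target.items():
        disp = display_values.get(target)
        member_means = None
        if disp is not None:
            member_means = disp.mean(axis=1)  # across conditions, linear scale
        for cx in catalog:
            ratio = protein_ratio(cx, significant)
            included = is_included(cx, ratio)
            intensity = np.nan
            contributing: list[str] = []
            if member_means is not None:
                vals = member_means.reindex(sorted(cx.members)).dropna()
                vals = vals[vals > 0]
                if len(vals):
                    contributing = list(vals.index)
                    if log_then_mean:
                        intensity = float(np.log10(vals).mean())
                    else:
                        intensity = float(np.log10(vals.mean()))
            rows.append(
                {
                    "complex_id": cx.complex_id,
                    "name": cx.name,
                    "target_set": target,
                    "n_members": len(cx.members),
                    "n_significant": len(cx.members & significant),
                    "protein_ratio": ratio,
                    "included": included,
                    "log10_intensity": intensity,
                    "contributing_members": ";".join(contributing),
                }
            )
    return pd.DataFrame(rows)
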