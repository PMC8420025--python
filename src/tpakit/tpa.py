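"""Absolute quantification by the Total Protein Approach (TPA).

TPA converts raw MS intensities into absolute concentrations without labels or
spike-in standards: within one run,

    c(i) = intensity(i) / (total intensity * MW(i))   [mol / g total protein]

so that mass is conserved by construction — summing c(i)*MW(i) over all
quantified proteins gives exactly 1 g of protein per g of total protein.
Concentrations are reported in pmol per mg total protein (factor 1e9 from
mol/g).  Molecular weights use average (isotope-abundance-weighted) residue
masses, the appropriate scale for whole proteins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from types import MappingProxyType
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_tables import IntensityMatrix, ProteinRecord, SampleAnnotation

__all__ = [
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "TPAMatrix",
    "molecular_weight",
    "tpa_concentrations",
    "dynamic_range",
    "group_concentration_ranges",
]

#: average residue (amino acid minus water) masses, g/mol (Expasy values)
AVERAGE_RESIDUE_MASS = MappingProxyType(
    {
        "A": 71.0788,
        "R": 156.1875,
        "N": 114.1038,
        "D": 115.0886,
        "C": 103.1388,
        "E": 129.1155,
        "Q": 128.1307,
        "G": 57.0519,
        "H": 137.1411,
        "I": 113.1594,
        "L": 113.1594,
        "K": 128.1741,
        "M": 131.1926,
        "F": 147.1766,
        "P": 97.1167,
        "S": 87.0782,
        "T": 101.1051,
        "W": 186.2132,
        "Y": 163.1760,
        "V": 99.1326,
    }
)

WATER_MASS = 18.0153  # g/mol

#: substitute mass for ambiguous residues (B/J/X/Z) under the lenient policy:
#: the unweighted mean of the 20 canonical residue masses
AMBIGUOUS_RESIDUE_MASS = sum(AVERAGE_RESIDUE_MASS.values()) / len(AVERAGE_RESIDUE_MASS)

_AMBIGUOUS = set("BJXZ")


def molecular_weight(sequence: str, on_ambiguous: str = "error") -> float:
    """Average molecular weight of a protein sequence in g/mol.

    Sum of average residue masses plus one water.  ``on_ambiguous`` controls
    the handling of B/J/X/Z: ``"error"`` (default) raises; ``"average"``
    substitutes the mean canonical residue mass with a warning.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if on_ambiguous not in ("error", "average"):
        raise ValueError("on_ambiguous must be 'error' or 'average'")
    total = WATER_MASS
    n_ambiguous = 0
    for pos, aa in enumerate(sequence.upper()):
        mass = AVERAGE_RESIDUE_MASS.get(aa)
        if mass is None:
            if aa in _AMBIGUOUS and on_ambiguous == "average":
                total += AMBIGUOUS_RESIDUE_MASS
                n_ambiguous += 1
                continue
            raise ValueError(f"non-canonical residue {aa!r} at position {pos}")
        total += mass
    if n_ambiguous:
        warnings.warn(
            f"{n_ambiguous} ambiguous residues assigned the average canonical mass",
            stacklevel=2,
        )
    return total


@dataclass
class TPAMatrix:
    """Protein x run absolute concentrations in pmol per mg total protein."""

    concentrations: pd.DataFrame
    mw_used: pd.Series  # g/mol, aligned with the protein index
    total_signal: pd.Series  # per-run sum of raw intensities

    @property
    def protein_ids(self) -> list[str]:
        return list(self.concentrations.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.concentrations.columns)


def _resolve_mw(
    protein_id: str, by_accession: dict[str, ProteinRecord], on_ambiguous: str
) -> Optional[float]:
    # protein groups list accessions ';'-separated; the leading (majority)
    # accession carries the group's molecular weight
    lead = protein_id.split(";")[0]
    rec = by_accession.get(lead)
    if rec is None:
        return None
    if rec.mw is not None:
        return rec.mw
    if rec.sequence:
        return molecular_weight(rec.sequence, on_ambiguous=on_ambiguous)
    return None


def tpa_concentrations(
    matrix: IntensityMatrix,
    records: Sequence[ProteinRecord],
    restrict_to: Optional[Iterable[str]] = None,
    on_ambiguous: str = "error",
) -> TPAMatrix:
    """Compute TPA concentrations (pmol/mg) from raw intensities.

    The per-run denominator sums raw intensity over every included protein
    (missing treated as 0).  By default that is the full quantified table
    after decoy/contaminant removal; pass ``restrict_to`` to limit both the
    numerators and the total to a protein subset (e.g. the presence-filtered
    set).  Proteins without a resolvable molecular weight are excluded with a
    warning.
    """
    raw = matrix.raw
    if restrict_to is not None:
        keep = [p for p in raw.index if p in set(restrict_to)]
        raw = raw.loc[keep]
    by_accession = {r.accession: r for r in records}
    mw_vals: dict[str, float] = {}
    unresolved: list[str] = []
    for pid in raw.index:
        mw = _resolve_mw(pid, by_accession, on_ambiguous)
        if mw is None:
            unresolved.append(pid)
        else:
            mw_vals[pid] = mw
    if unresolved:
        warnings.warn(
            f"excluding {len(unresolved)} proteins without molecular weight "
            f"(first: {unresolved[0]!r})",
            stacklevel=2,
        )
        raw = raw.drop(index=unresolved)
    if raw.empty:
        raise ValueError("no proteins with resolvable molecular weight")

    mw = pd.Series(mw_vals).loc[raw.index]
    total = raw.sum(axis=0, skipna=True)  # missing counts as 0 signal
    zero = total[total == 0]
    if not zero.empty:
        raise ValueError(f"run(s) with zero total signal: {list(zero.index)}")

    conc_mol_per_g = raw.div(total, axis=1).div(mw, axis=0)
    return TPAMatrix(
        concentrations=conc_mol_per_g * 1e9,  # mol/g -> pmol/mg
        mw_used=mw,
        total_signal=total,
    )


def dynamic_range(tpa: TPAMatrix) -> tuple[pd.Series, float]:
    """Orders of magnitude spanned by positive concentrations.

    Returns ``(per_run, overall)`` where each value is log10(max/min) over
    the positive entries of a run (or the whole matrix).
    """
    conc = tpa.concentrations

    def decades(values: np.ndarray) -> float:
        pos = values[np.isfinite(values) & (values > 0)]
        if pos.size < 2:
            return float("nan")
        return float(math.log10(pos.max() / pos.min()))

    per_run = conc.apply(lambda col: decades(col.to_numpy()), axis=0)
    overall = decades(conc.to_numpy().ravel())
    return per_run, overall


def group_concentration_ranges(
    tpa: TPAMatrix,
    annotation: SampleAnnotation,
    proteins: Sequence[str],
) -> pd.DataFrame:
    """Per-group min/median/max concentration for selected proteins.

    Technical replicates of a biological sample are averaged first; the
    summaries are then taken over biological samples.
    """
    missing = [p for p in proteins if p not in tpa.concentrations.index]
    if missing:
        raise ValueError(f"proteins absent from TPA matrix: {missing}")
    annotation.validate_runs(tpa.run_ids)
    conc = tpa.concentrations.loc[list(proteins)]
    sample_ids = annotation.table.loc[conc.columns, "biological_sample_id"]
    by_sample = conc.T.groupby(sample_ids.to_numpy()).mean().T
    sample_group = annotation.sample_to_group
    groups = pd.Series({s: sample_group[s] for s in by_sample.columns})

    rows = []
    for pid in conc.index:
        for group in annotation.groups:
            vals = by_sample.loc[pid, groups[groups == group].index].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            rows.append(
                {
                    "protein": pid,
                    "group": group,
                    "min": np.min(vals) if vals.size else np.nan,
                    "median": np.median(vals) if vals.size else np.nan,
                    "max": np.max(vals) if vals.size else np.nan,
                    "n_samples": int(vals.size),
                }
            )
    return pd.DataFrame(rows).set_index(["protein", "group"])
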