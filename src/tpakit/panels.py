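"""Subtype biomarker panels from differential proteins and TPA concentrations.

The selection workflow: from the ANOVA-significant protein set, a protein is
assigned to subtype s when its per-biological-sample TPA concentration differs
from *every* other group (pairwise Mann-Whitney, p <= 0.01 by default) with a
consistent direction — higher in s than everywhere else ("up") or lower
("down").  Each subtype's panel is then shortlisted by fold change of the
median concentration in s over the median across all other samples, with
published per-subtype thresholds (ccRCC >= 5, pRCC >= 9, chRCC >= 4, RO >= 3)
and the top k = 6 kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import SampleAnnotation
from .tpa import TPAMatrix

__all__ = [
    "BiomarkerPanel",
    "FC_THRESHOLDS",
    "assign_one_vs_rest",
    "shortlist_by_fold_change",
]

#: published fold-change thresholds per subtype
FC_THRESHOLDS: dict[str, float] = {"ccRCC": 5.0, "pRCC": 9.0, "chRCC": 4.0, "RO": 3.0}


@dataclass
class BiomarkerPanel:
    """One subtype's candidate markers with directions and fold changes.

    ``members`` is indexed by protein id with columns ``direction``
    (up/down), ``fold_change`` (>= 1, inverted for down markers),
    ``median_target`` and ``median_rest`` (pmol/mg).
    """

    subtype: str
    members: pd.DataFrame
    shortlist: list[str]


def _per_sample_concentrations(
    tpa: TPAMatrix, annotation: SampleAnnotation
) -> tuple[pd.DataFrame, pd.Series]:
    """Average technical replicates: proteins x biological samples."""
    annotation.validate_runs(tpa.run_ids)
    conc = tpa.concentrations
    sample_ids = annotation.table.loc[conc.columns, "biological_sample_id"]
    by_sample = conc.T.groupby(sample_ids.to_numpy(), sort=False).mean().T
    groups = pd.Series(annotation.sample_to_group)[by_sample.columns]
    return by_sample, groups


def _pairwise_mw_pvalues(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Mann-Whitney p; exact when tie-free and small."""
    n = A.shape[1] + B.shape[1]
    method = "exact" if n <= 16 else "asymptotic"
    try:
        res = stats.mannwhitneyu(A, B, alternative="two-sided", method=method, axis=1)
        return np.minimum(res.pvalue, 1.0)
    except ValueError:
        # exact path rejects ties; fall back row by row
        pvals = np.empty(A.shape[0])
        for i in range(A.shape[0]):
            row_method = method
            pooled = np.concatenate([A[i], B[i]])
            if np.unique(pooled).size < pooled.size:
                row_method = "asymptotic"
            pvals[i] = stats.mannwhitneyu(
                A[i], B[i], alternative="two-sided", method=row_method
            ).pvalue
        return np.minimum(pvals, 1.0)


def assign_one_vs_rest(
    significant_proteins: Sequence[str],
    tpa: TPAMatrix,
    annotation: SampleAnnotation,
    subtypes: Optional[Sequence[str]] = None,
    p_threshold: float = 0.01,
) -> dict[str, BiomarkerPanel]:
    """Assign differential proteins to disjoint one-vs-rest subtype panels.

    ``subtypes`` are the candidate panel labels (default: every group except
    ``NAT``); the "rest" in each comparison includes all other groups, NAT
    included.  A protein joins subtype s only if it is significantly
    different from each other group individually with one consistent sign.
    A protein qualifying for two subtypes (up in one, down in another) is
    kept only in the panel with the larger |log2 fold change|, preserving
    disjointness.
    """
    proteins = [p for p in significant_proteins if p in tpa.concentrations.index]
    if not proteins:
        raise ValueError("no significant proteins present in the TPA matrix")
    by_sample, groups = _per_sample_concentrations(tpa, annotation)
    all_groups = list(dict.fromkeys(groups))
    if subtypes is None:
        subtypes = [g for g in all_groups if g != "NAT"]
    for g in all_groups:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 biological samples")

    # NaN concentrations (dropout) are treated as 0 for ranking purposes:
    # "not quantified" is biologically "below detection"
    values = by_sample.loc[proteins].fillna(0.0)

    candidate: dict[str, dict[str, dict]] = {s: {} for s in subtypes}
    for s in subtypes:
        target_cols = groups[groups == s].index
        T = values[target_cols].to_numpy(float)
        all_pass = np.ones(len(proteins), dtype=bool)
        sign_up = np.ones(len(proteins), dtype=bool)
        sign_down = np.ones(len(proteins), dtype=bool)
        for g in all_groups:
            if g == s:
                continue
            other_cols = groups[groups == g].index
            O = values[other_cols].to_numpy(float)
            pvals = _pairwise_mw_pvalues(T, O)
            all_pass &= pvals <= p_threshold
            delta = np.median(T, axis=1) - np.median(O, axis=1)
            sign_up &= delta > 0
            sign_down &= delta < 0
        passed = all_pass & (sign_up | sign_down)

        rest_cols = groups[groups != s].index
        R = values[rest_cols].to_numpy(float)
        med_t = np.median(T, axis=1)
        med_r = np.median(R, axis=1)
        for i, pid in enumerate(proteins):
            if not passed[i]:
                continue
            up = bool(sign_up[i])
            fc = _fold_change(med_t[i], med_r[i], up)
            candidate[s][pid] = {
                "direction": "up" if up else "down",
                "fold_change": fc,
                "median_target": med_t[i],
                "median_rest": med_r[i],
            }

    # disjointness: a protein in several panels keeps only its strongest one
    owner: dict[str, str] = {}
    for s in subtypes:
        for pid, info in candidate[s].items():
            if pid not in owner or (
                candidate[s][pid]["fold_change"]
                > candidate[owner[pid]][pid]["fold_change"]
            ):
                owner[pid] = s

    panels: dict[str, BiomarkerPanel] = {}
    for s in subtypes:
        rows = {
            pid: info
            for pid, info in candidate[s].items()
            if owner.get(pid) == s
        }
        members = pd.DataFrame.from_dict(rows, orient="index")
        if members.empty:
            members = pd.DataFrame(
                columns=["direction", "fold_change", "median_target", "median_rest"]
            )
        panels[s] = BiomarkerPanel(subtype=s, members=members, shortlist=[])
    return panels


def _fold_change(med_target: float, med_rest: float, up: bool) -> float:
    """Ratio of medians, inverted for down markers; infinite when the
    denominator is 0 (marker absent outside/inside the subtype)."""
    num, den = (med_target, med_rest) if up else (med_rest, med_target)
    if den == 0:
        return float("inf") if num > 0 else float("nan")
    return num / den


def shortlist_by_fold_change(
    panel: BiomarkerPanel,
    fc_threshold: Optional[float] = None,
    k: int = 6,
) -> BiomarkerPanel:
    """Keep panel members with FC >= threshold, ranked by FC, top k.

    Ties in fold change break by concentration magnitude (median in the
    subtype), then accession lexicographically.  The threshold defaults to
    the subtype's published value (1, i.e. no filtering, for subtypes
    without one).
    """
    if fc_threshold is None:
        fc_threshold = FC_THRESHOLDS.get(panel.subtype, 1.0)
    if k < 0:
        raise ValueError("k must be >= 0")
    members = panel.members
    if members.empty:
        return BiomarkerPanel(panel.subtype, members, [])
    eligible = members[members["fold_change"] >= fc_threshold]
    ranked = eligible.sort_values(
        by=["fold_change", "median_target"],
        ascending=[False, False],
        kind="stable",
    )
    # lexicographic accession as the final tie-break
    ranked = ranked.loc[
        sorted(
            ranked.index,
            key=lambda pid: (
                -ranked.at[pid, "fold_change"],
                -ranked.at[pid, "median_target"],
                pid,
            ),
        )
    ]
    return BiomarkerPanel(panel.subtype, members, list(ranked.index[:k]))
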