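"""Self-contained validation experiments on synthetic cohorts.

Each function builds its own inputs with the synthetic generator, runs the
relevant pipeline stages end to end, and returns the measured quantity.  They
are used by the test suite and by ``scripts/acceptance.py``; problem sizes are
chosen to finish in seconds to minutes on one CPU (the methods note states
them).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diagnostics import evaluate_marker
from .diffstats import anova_permutation_fdr
from .panels import assign_one_vs_rest
from .preprocess import (
    LogMatrix,
    filter_by_group_presence,
    impute_downshifted_gaussian,
    log2_transform,
    zscore_rows,
)
from .structure import cut_tree, hierarchical_cluster
from .synthetic import CohortConfig, MarkerSpec, generate_cohort, generate_ihc_scores
from .tpa import dynamic_range, tpa_concentrations

__all__ = [
    "tma_diagnostics",
    "tpa_mass_balance",
    "tpa_two_protein_example",
    "cohort_dynamic_range",
    "null_anova_calibration",
    "marker_recovery",
    "metagroup_split",
    "imputation_moments",
]

FIVE_GROUPS = (("ccRCC", 5), ("pRCC", 5), ("chRCC", 5), ("RO", 5), ("NAT", 5))
TUMOR_SUBTYPES = ("ccRCC", "pRCC", "chRCC", "RO")


def _subseed(seed: int, offset: int) -> int:
    return (seed * 1009 + offset) % (2**31 - 1)


def tma_diagnostics(seed: int = 0) -> dict[str, dict[str, float]]:
    """Sensitivity/specificity/PPV/NPV for the four TMA markers.

    Uses the deterministic score generator, so the 2x2 counts follow exactly
    from the cohort design (40/26/12/30 tumor cases).
    """
    table = generate_ihc_scores(seed=seed, mode="deterministic")
    out = {}
    for marker in ("PLIN2", "TUBB3", "LAMP1", "HK1"):
        ct, m = evaluate_marker(table, marker)
        out[marker] = {
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "ppv": m.ppv,
            "npv": m.npv,
            "counts": (ct.tp, ct.fp, ct.fn, ct.tn),
        }
    return out


def tpa_mass_balance(seed: int = 0, n_cohorts: int = 3, n_proteins: int = 400) -> float:
    """Max relative deviation of per-run Sum c_i * MW_i from 1 g/g."""
    worst = 0.0
    for i in range(n_cohorts):
        cfg = CohortConfig(
            n_proteins=n_proteins, groups=FIVE_GROUPS, seed=_subseed(seed, i)
        )
        matrix, _, records, _ = generate_cohort(cfg)
        t = tpa_concentrations(matrix, records)
        mass = (t.concentrations / 1e9).mul(t.mw_used, axis=0).sum(axis=0, skipna=True)
        worst = max(worst, float(np.abs(mass - 1.0).max()))
    return worst


def tpa_two_protein_example() -> tuple[float, float]:
    """Closed-form check: equal signal, MW 50 kDa and 100 kDa -> 1e4 and 5e3 pmol/mg."""
    from .io_tables import ProteinRecord

    raw = pd.DataFrame({"run1": [3e7, 3e7]}, index=["P1", "P2"])
    flags = pd.DataFrame(
        False, index=raw.index, columns=["reverse", "site_only", "contaminant"]
    )
    from .io_tables import IntensityMatrix

    m = IntensityMatrix(
        raw=raw, lfq=raw.copy(), flags=flags, gene_names=pd.Series(["", ""], index=raw.index)
    )
    t = tpa_concentrations(
        m, [ProteinRecord("P1", mw=5e4), ProteinRecord("P2", mw=1e5)]
    )
    return float(t.concentrations.iloc[0, 0]), float(t.concentrations.iloc[1, 0])


def cohort_dynamic_range(seed: int = 0, n_proteins: int = 1000) -> float:
    """Overall orders of magnitude spanned by TPA concentrations of a default cohort."""
    cfg = CohortConfig(n_proteins=n_proteins, seed=seed)
    matrix, _, records, _ = generate_cohort(cfg)
    _, overall = dynamic_range(tpa_concentrations(matrix, records))
    return overall


def _preprocess(matrix, annotation, seed):
    logm = log2_transform(matrix, basis="lfq")
    filtered = filter_by_group_presence(logm, annotation, 0.70)
    return impute_downshifted_gaussian(filtered, seed=seed)


def null_anova_calibration(
    seed: int = 0, n_seeds: int = 20, n_proteins: int = 500
) -> float:
    """Mean fraction of ANOVA-significant proteins at FDR 1% on global-null cohorts.

    Full pipeline per cohort: MNAR dropout, 70% filter, down-shifted
    imputation, permutation ANOVA over biological samples.
    """
    fractions = []
    for i in range(n_seeds):
        s = _subseed(seed, 100 + i)
        cfg = CohortConfig(n_proteins=n_proteins, groups=FIVE_GROUPS, seed=s)
        matrix, annotation, _, _ = generate_cohort(cfg)
        imputed = _preprocess(matrix, annotation, s)
        res = anova_permutation_fdr(imputed, annotation, target_fdr=0.01, seed=s)
        fractions.append(float(res["significant"].mean()))
    return float(np.mean(fractions))


def _planted_markers(n_per_subtype: int = 8) -> list[MarkerSpec]:
    """Half up-, half down-regulated markers (|log2FC| = 2) per tumor subtype."""
    markers = []
    idx = 0
    for g in TUMOR_SUBTYPES:
        for j in range(n_per_subtype):
            effect = 2.0 if j < n_per_subtype // 2 else -2.0
            markers.append(MarkerSpec(idx, g, effect))
            idx += 1
    return markers


def marker_recovery(
    seed: int = 0, n_seeds: int = 20, n_proteins: int = 500
) -> tuple[float, float]:
    """Power of the ANOVA + panel pipeline on planted subtype markers.

    Complete-data power experiment (no dropout): markers shifted by |log2FC|=2
    with sigma_bio = 0.3.  Returns (fraction of planted markers that are both
    ANOVA-significant and assigned to their own subtype panel, fraction of
    null proteins assigned to any panel).
    """
    markers = _planted_markers()
    n_markers = len(markers)
    marker_ids = {f"SYN{m.protein:04d}": m.group for m in markers}
    recovered, null_assigned = [], []
    for i in range(n_seeds):
        s = _subseed(seed, 200 + i)
        cfg = CohortConfig(
            n_proteins=n_proteins,
            groups=FIVE_GROUPS,
            sigma_bio=0.3,
            sigma_tech=0.1,
            mnar_slope=0.0,
            markers=markers,
            seed=s,
        )
        matrix, annotation, records, _ = generate_cohort(cfg)
        imputed = _preprocess(matrix, annotation, s)
        res = anova_permutation_fdr(imputed, annotation, target_fdr=0.01, seed=s)
        sig = list(res.index[res["significant"]])
        t = tpa_concentrations(matrix, records)
        panels = assign_one_vs_rest(sig, t, annotation) if sig else {}
        correct = 0
        nulls = 0
        for subtype, panel in panels.items():
            for pid in panel.members.index:
                if marker_ids.get(pid) == subtype:
                    correct += 1
                elif pid not in marker_ids:
                    nulls += 1
        recovered.append(correct / n_markers)
        null_assigned.append(nulls / (n_proteins - n_markers))
    return float(np.mean(recovered)), float(np.mean(null_assigned))


def metagroup_split(
    seed: int = 0, n_seeds: int = 20, n_proteins: int = 300
) -> int:
    """How often the k=2 tree cut separates the two tumor meta-groups.

    Cohorts carry a shared proximal-type shift (ccRCC + pRCC) plus modest
    subtype-specific markers; runs are clustered on z-scored significant
    proteins and the 2-cluster cut is compared with the
    {ccRCC, pRCC} vs {chRCC, RO, NAT} partition.
    """
    successes = 0
    for i in range(n_seeds):
        s = _subseed(seed, 300 + i)
        markers = []
        for p in range(60):  # shared proximal-type program
            markers += [MarkerSpec(p, "ccRCC", 1.5), MarkerSpec(p, "pRCC", 1.5)]
        for gi, g in enumerate(TUMOR_SUBTYPES):  # subtype-specific accents
            markers += [MarkerSpec(60 + gi * 10 + j, g, 1.5) for j in range(10)]
        cfg = CohortConfig(
            n_proteins=n_proteins,
            groups=FIVE_GROUPS,
            sigma_bio=0.5,
            sigma_tech=0.2,
            markers=markers,
            seed=s,
        )
        matrix, annotation, _, _ = generate_cohort(cfg)
        imputed = _preprocess(matrix, annotation, s)
        res = anova_permutation_fdr(imputed, annotation, target_fdr=0.01, seed=s)
        sig = res.index[res["significant"]]
        if len(sig) < 2:
            continue
        zs = zscore_rows(LogMatrix(values=imputed.values.loc[sig]))
        labels = cut_tree(hierarchical_cluster(zs, axis="runs"), 2)
        meta = annotation.table["group"].map(
            lambda g: "proximal" if g in ("ccRCC", "pRCC") else "distal"
        )
        tab = pd.crosstab(labels[annotation.run_ids].to_numpy(), meta.to_numpy())
        if tab.shape == (2, 2) and tab.max(axis=1).sum() == len(meta) :
            successes += 1
    return successes


def imputation_moments(seed: int = 0, n_missing: int = 100_000) -> tuple[float, float]:
    """Empirical mean/SD of imputed values in a column with mu=20, sd=2.

    Target distribution: Normal(20 - 1.8*2, (0.5*2)^2) = Normal(16.4, 1.0).
    """
    col = np.full(n_missing + 2, np.nan)
    col[:2] = [20 - np.sqrt(2.0), 20 + np.sqrt(2.0)]  # mean 20, sample SD 2
    lm = LogMatrix(values=pd.DataFrame({"run": col}))
    out = impute_downshifted_gaussian(lm, width=0.5, downshift=1.8, seed=seed)
    vals = out.values["run"].to_numpy()[2:]
    return float(vals.mean()), float(vals.std(ddof=0))
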