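"""End-to-end orchestration of the analysis stages with a run manifest.

Stage order follows the analysis workflow: flag removal -> log2 transform ->
70% group-presence filter -> run correlation / PCA -> down-shifted imputation
-> ANOVA with permutation FDR (plus optional two-sample volcanoes) -> z-score
and hierarchical clustering -> TPA absolute quantification -> subtype panels
-> IHC diagnostics (when a score table is provided).  Every stage writes a
TSV/JSON snapshot into the output directory and is listed in ``manifest.json``
together with the parameter echo and seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, diffstats, io_tables, panels, preprocess, structure, tpa

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    intensity_table: str
    annotation: str
    fasta: str
    output_dir: str
    ihc_table: Optional[str] = None

    min_fraction: float = 0.70
    impute_width: float = 0.5
    impute_downshift: float = 1.8
    s0: float = 0.1
    volcano_fdr: float = 0.01
    anova_fdr: float = 0.01
    n_perm: int = 250
    panel_p_threshold: float = 0.01
    fc_thresholds: dict = field(default_factory=lambda: dict(panels.FC_THRESHOLDS))
    shortlist_k: int = 6
    linkage: str = "average"
    remove_contaminants: bool = True
    volcano_pairs: list = field(default_factory=list)  # [(group_a, group_b), ...]
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        flat: dict = {}
        for section in ("paths", "parameters"):
            flat.update(data.pop(section, {}) or {})
        flat.update(data)
        return cls(**flat)

    def validate(self) -> None:
        if not 0 < self.min_fraction <= 1:
            raise ValueError(f"min_fraction={self.min_fraction} outside (0, 1]")
        for name in ("volcano_fdr", "anova_fdr", "panel_p_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} outside (0, 1)")
        if self.s0 < 0 or self.impute_width < 0 or self.impute_downshift < 0:
            raise ValueError("s0, impute_width and impute_downshift must be >= 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.shortlist_k < 0:
            raise ValueError("shortlist_k must be >= 0")
        for s, fc in self.fc_thresholds.items():
            if fc < 1:
                raise ValueError(f"fold-change threshold for {s} must be >= 1")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": asdict(config), "seed": config.seed, "stages": {}}
    artifacts: list[str] = []

    def write_tsv(df: pd.DataFrame, name: str, stage: str, **kw) -> None:
        path = out / name
        df.to_csv(path, sep="\t", na_rep="", **kw)
        manifest["stages"].setdefault(stage, []).append(name)
        artifacts.append(name)

    def write_json(obj, name: str, stage: str) -> None:
        path = out / name
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)
        manifest["stages"].setdefault(stage, []).append(name)
        artifacts.append(name)

    # --- load
    matrix = io_tables.read_protein_table(config.intensity_table)
    annotation = io_tables.read_annotation(config.annotation)
    records = io_tables.read_fasta(config.fasta)

    # --- flag removal
    matrix = io_tables.remove_flagged(
        matrix, remove_contaminants=config.remove_contaminants
    )
    manifest["stages"]["remove_flagged"] = [f"{matrix.n_proteins} proteins retained"]

    # --- log2 + filter (LFQ track)
    logm = preprocess.log2_transform(matrix, basis="lfq")
    filtered = preprocess.filter_by_group_presence(
        logm, annotation, min_fraction=config.min_fraction
    )
    write_tsv(filtered.values, "filtered_log2_lfq.tsv", "filter")

    # --- correlation on filtered (pre-imputation) values
    corr = preprocess.pearson_correlation_matrix(filtered)
    write_tsv(corr, "pearson_correlation.tsv", "correlation")

    # --- imputation
    imputed = preprocess.impute_downshifted_gaussian(
        filtered,
        width=config.impute_width,
        downshift=config.impute_downshift,
        seed=config.seed,
    )
    write_tsv(imputed.values, "imputed_log2_lfq.tsv", "impute")

    # --- PCA
    n_comp = min(5, imputed.values.shape[0], imputed.values.shape[1])
    pca_res = structure.pca(imputed, n_components=n_comp)
    write_tsv(pca_res.scores, "pca_scores.tsv", "pca")
    write_json(
        {"explained_variance_fraction": pca_res.explained_variance_fraction.tolist()},
        "pca_summary.json",
        "pca",
    )

    # --- differential testing
    anova = diffstats.anova_permutation_fdr(
        imputed,
        annotation,
        target_fdr=config.anova_fdr,
        n_perm=config.n_perm,
        seed=config.seed,
    )
    write_tsv(anova, "anova_results.tsv", "anova")
    for pair in config.volcano_pairs:
        a, b = pair
        res = diffstats.permutation_fdr_two_sample(
            imputed,
            annotation,
            a,
            b,
            s0=config.s0,
            target_fdr=config.volcano_fdr,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        write_tsv(res, f"volcano_{a}_vs_{b}.tsv", "volcano")

    # --- clustering of runs on z-scored significant proteins
    sig = anova.index[anova["significant"]]
    if len(sig) >= 2:
        zs = preprocess.zscore_rows(
            preprocess.LogMatrix(
                values=imputed.values.loc[sig], basis="lfq", transformed=True
            )
        )
        tree = structure.hierarchical_cluster(zs, axis="runs", linkage=config.linkage)
        (out / "cluster_runs.nwk").write_text(structure.to_newick(tree))
        manifest["stages"]["cluster"] = ["cluster_runs.nwk"]
        artifacts.append("cluster_runs.nwk")
    else:
        warnings.warn("fewer than 2 significant proteins; clustering skipped")

    # --- TPA (raw-intensity track, full quantified table as denominator)
    tpa_mat = tpa.tpa_concentrations(matrix, records)
    write_tsv(tpa_mat.concentrations, "tpa_pmol_per_mg.tsv", "tpa")
    per_run, overall = tpa.dynamic_range(tpa_mat)
    write_json(
        {
            "total_signal": {k: float(v) for k, v in tpa_mat.total_signal.items()},
            "dynamic_range_decades": {k: float(v) for k, v in per_run.items()},
            "overall_decades": overall,
        },
        "tpa_summary.json",
        "tpa",
    )

    # --- panels
    if len(sig) > 0:
        subtype_panels = panels.assign_one_vs_rest(
            list(sig),
            tpa_mat,
            annotation,
            p_threshold=config.panel_p_threshold,
        )
        report = {}
        for s, panel in subtype_panels.items():
            short = panels.shortlist_by_fold_change(
                panel,
                fc_threshold=config.fc_thresholds.get(s),
                k=config.shortlist_k,
            )
            members = panel.members.replace([np.inf, -np.inf], "inf")
            report[s] = {
                "n_members": int(len(panel.members)),
                "members": members.to_dict(orient="index"),
                "shortlist": short.shortlist,
            }
        write_json(report, "panels.json", "panels")

    # --- diagnostics
    if config.ihc_table:
        table = io_tables.read_ihc_scores(config.ihc_table)
        rows = []
        for marker in table.markers:
            if marker not in diagnostics.MARKER_RULES:
                warnings.warn(f"no dichotomization rule for marker {marker!r}; skipped")
                continue
            ct, m = diagnostics.evaluate_marker(table, marker)
            rows.append(
                {
                    "marker": marker,
                    "target_subtype": diagnostics.MARKER_TARGETS[marker],
                    "TP": ct.tp,
                    "FP": ct.fp,
                    "FN": ct.fn,
                    "TN": ct.tn,
                    "sensitivity_pct": m.sensitivity,
                    "specificity_pct": m.specificity,
                    "ppv_pct": m.ppv,
                    "npv_pct": m.npv,
                }
            )
        write_tsv(pd.DataFrame(rows).set_index("marker"), "ihc_metrics.tsv", "diagnostics")

    manifest["artifacts"] = artifacts
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
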