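"""Synthetic renal-cohort generator with the statistical structure of LFQ data.

The generator emulates a five-group tissue study (four tumor subtypes plus
normal adjacent tissue, 5-7 biological samples each, technical duplicates)
with ~2,500 proteins whose linear intensities span about seven orders of
magnitude.  The hierarchical noise model is, on the log2 scale,

    log2 I = base(protein) + effect(protein, group)
             + N(0, sigma_bio) per biological sample
             + N(0, sigma_tech) per technical replicate,

with sigma_tech < sigma_bio so that technical replicates correlate more
strongly than biological replicates of the same group.  Dropout is
missing-not-at-random: a cell is censored with probability
expit(mnar_slope * (mnar_midpoint - log2 I)), so low-abundance proteins go
missing more often.  Default MNAR parameters yield roughly 30% overall
missingness, enough to exercise the 70% presence filter non-trivially.

A companion generator emits IHC score tables for a tissue-microarray
validation cohort, either stochastically (multinomial per subtype/marker) or
deterministically (largest-remainder rounding of the score distribution),
the latter reproducing worked examples exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .diagnostics import IHCScoreTable
from .io_tables import IntensityMatrix, ProteinRecord, SampleAnnotation
from .tpa import AVERAGE_RESIDUE_MASS

__all__ = [
    "MarkerSpec",
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_ihc_scores",
    "RENAL_TMA_COHORT",
    "RENAL_TMA_RULES",
]

#: the study design: (group label, number of biological samples)
DEFAULT_GROUPS: tuple[tuple[str, int], ...] = (
    ("ccRCC", 7),
    ("pRCC", 5),
    ("chRCC", 5),
    ("RO", 5),
    ("NAT", 5),
)

_AA = sorted(AVERAGE_RESIDUE_MASS)


@dataclass(frozen=True)
class MarkerSpec:
    """A planted group-specific effect: protein index, target group, log2 shift."""

    protein: int
    group: str
    log2_effect: float


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort; defaults mirror the study design."""

    n_proteins: int = 2500
    groups: Sequence[tuple[str, int]] = DEFAULT_GROUPS
    n_tech_reps: int = 2
    #: base log10 intensity drawn uniformly on center +/- span/2 (log-uniform
    #: linear intensities spanning `span` orders of magnitude)
    base_log10_center: float = 7.5
    base_log10_span: float = 7.0
    markers: Sequence[MarkerSpec] = field(default_factory=tuple)
    sigma_bio: float = 1.0  # log2 SD between biological samples
    sigma_tech: float = 0.25  # log2 SD between technical replicates
    #: MNAR dropout: P(missing) = expit(slope * (midpoint - log2 intensity));
    #: slope = 0 disables dropout entirely
    mnar_midpoint: float = 20.0
    mnar_slope: float = 0.5
    #: per-run log2 scale jitter applied to LFQ values (0 = LFQ == raw)
    lfq_scale_jitter: float = 0.0
    #: when set, marker proteins draw their base log10 abundance uniformly
    #: from [marker_log10_min, top of range] — markers model quantifiable
    #: proteins, not ones lost to dropout
    marker_log10_min: Optional[float] = None
    mean_protein_length: int = 450  # residues; ~50 kDa proteins
    sd_protein_length: int = 150
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        if self.sigma_bio <= 0:
            raise ValueError("sigma_bio must be > 0")
        if self.sigma_tech < 0:
            raise ValueError("sigma_tech must be >= 0")
        if self.sigma_tech >= self.sigma_bio:
            raise ValueError(
                "sigma_tech must be < sigma_bio (technical replicates must be "
                "more correlated than biological replicates)"
            )
        if self.mnar_slope < 0:
            raise ValueError("mnar_slope must be >= 0")
        if self.base_log10_span <= 0:
            raise ValueError("base_log10_span must be > 0")
        group_labels = [g for g, _ in self.groups]
        if len(set(group_labels)) != len(group_labels):
            raise ValueError("duplicate group labels")
        seen = set()
        for m in self.markers:
            if not 0 <= m.protein < self.n_proteins:
                raise ValueError(f"marker protein index {m.protein} out of range")
            if m.group not in group_labels:
                raise ValueError(f"marker group {m.group!r} not in design")
            if not math.isfinite(m.log2_effect):
                raise ValueError("marker effect sizes must be finite")
            key = (m.protein, m.group)
            if key in seen:
                raise ValueError(f"duplicate marker spec for {key}")
            seen.add(key)


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    group_means_log2: pd.DataFrame  # proteins x groups, base + effect
    markers: tuple[MarkerSpec, ...]
    dropout: pd.DataFrame  # proteins x runs boolean

    def markers_of_group(self, group: str) -> list[int]:
        return [m.protein for m in self.markers if m.group == group]


def generate_cohort(
    config: CohortConfig,
) -> tuple[IntensityMatrix, SampleAnnotation, list[ProteinRecord], GroundTruth]:
    """Draw a full synthetic cohort; bit-reproducible under ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    ids = [f"SYN{i:04d}" for i in range(n)]
    genes = [f"GENE{i}" for i in range(n)]
    group_labels = [g for g, _ in config.groups]

    lo = config.base_log10_center - config.base_log10_span / 2
    hi = config.base_log10_center + config.base_log10_span / 2
    base_log10 = rng.uniform(lo, hi, n)
    if config.marker_log10_min is not None and config.markers:
        marker_idx = sorted({m.protein for m in config.markers})
        base_log10[marker_idx] = rng.uniform(
            config.marker_log10_min, hi, len(marker_idx)
        )
    base_log2 = base_log10 * math.log2(10)

    effects = pd.DataFrame(0.0, index=ids, columns=group_labels)
    for m in config.markers:
        effects.iloc[m.protein, group_labels.index(m.group)] += m.log2_effect

    run_ids: list[str] = []
    meta_rows = []
    columns_log2 = []
    for group, n_samples in config.groups:
        for s in range(1, n_samples + 1):
            sample_id = f"{group}{s}"
            bio = rng.normal(0.0, config.sigma_bio, n)
            for r in range(1, config.n_tech_reps + 1):
                tech = (
                    rng.normal(0.0, config.sigma_tech, n)
                    if config.sigma_tech > 0
                    else np.zeros(n)
                )
                run_ids.append(f"{sample_id}.{r}")
                meta_rows.append((sample_id, group, r))
                columns_log2.append(
                    base_log2 + effects[group].to_numpy() + bio + tech
                )

    log2_vals = np.column_stack(columns_log2)
    intensity = np.exp2(log2_vals)

    if config.mnar_slope > 0:
        p_missing = expit(config.mnar_slope * (config.mnar_midpoint - log2_vals))
    else:
        p_missing = np.zeros_like(log2_vals)
    dropout = rng.random(log2_vals.shape) < p_missing
    raw = np.where(dropout, np.nan, intensity)

    if config.lfq_scale_jitter > 0:
        scale = np.exp2(rng.normal(0.0, config.lfq_scale_jitter, len(run_ids)))
        lfq = raw * scale[None, :]
    else:
        lfq = raw.copy()

    raw_df = pd.DataFrame(raw, index=ids, columns=run_ids)
    lfq_df = pd.DataFrame(lfq, index=ids, columns=run_ids)
    flags = pd.DataFrame(
        False, index=ids, columns=["reverse", "site_only", "contaminant"]
    )
    matrix = IntensityMatrix(
        raw=raw_df, lfq=lfq_df, flags=flags, gene_names=pd.Series(genes, index=ids)
    )

    annotation = SampleAnnotation(
        pd.DataFrame(
            meta_rows,
            index=pd.Index(run_ids, name="run_id"),
            columns=["biological_sample_id", "group", "technical_replicate"],
        )
    )

    lengths = np.maximum(
        50,
        rng.normal(config.mean_protein_length, config.sd_protein_length, n).astype(int),
    )
    records = [
        ProteinRecord(
            accession=ids[i],
            gene=genes[i],
            sequence="".join(rng.choice(_AA, lengths[i])),
        )
        for i in range(n)
    ]

    truth = GroundTruth(
        group_means_log2=effects.add(base_log2, axis=0),
        markers=tuple(config.markers),
        dropout=pd.DataFrame(dropout, index=ids, columns=run_ids),
    )
    return matrix, annotation, records, truth


# ---------------------------------------------------------------------------
# IHC score tables

#: TMA validation cohort sizes (tumor cases only, as used in the 2x2 tables)
RENAL_TMA_COHORT: dict[str, int] = {"ccRCC": 40, "pRCC": 26, "chRCC": 12, "RO": 30}

#: score distributions per marker and subtype shaped after the validation
#: cohort's staining patterns (PLIN2 positive in 90% of ccRCC; TUBB3 in ~54%
#: of pRCC; diffuse LAMP1 in 11/12 chRCC; abundant HK1 in 29/30 RO with a
#: single chRCC false positive)
RENAL_TMA_RULES: dict[str, dict[str, dict[str, float]]] = {
    "PLIN2": {
        "ccRCC": {"0": 0.05, "1": 0.05, "2": 0.50, "3": 0.40},
        "pRCC": {"0": 0.9, "1": 0.1},
        "chRCC": {"0": 0.9, "1": 0.1},
        "RO": {"0": 0.9, "1": 0.1},
    },
    "TUBB3": {
        "ccRCC": {"0": 1.0},
        "pRCC": {"0": 8 / 26, "1": 4 / 26, "2": 8 / 26, "3": 6 / 26},
        "chRCC": {"0": 0.7, "1": 0.3},
        "RO": {"0": 0.8, "1": 0.2},
    },
    "LAMP1": {
        "ccRCC": {"N": 1.0},
        "pRCC": {"N": 1.0},
        "chRCC": {"D": 11 / 12, "A": 1 / 12},
        "RO": {"A": 0.5, "F": 0.4, "N": 0.1},
    },
    "HK1": {
        "ccRCC": {"0": 0.8, "1": 0.2},
        "pRCC": {"0": 0.9, "1": 0.1},
        "chRCC": {"0": 4 / 12, "1": 4 / 12, "2": 3 / 12, "3": 1 / 12},
        "RO": {"3": 29 / 30, "2": 1 / 30},
    },
}


def _largest_remainder_counts(probs: dict[str, float], n: int) -> dict[str, int]:
    """Apportion n cases to score categories by largest-remainder rounding."""
    scores = list(probs)
    quotas = np.array([probs[s] * n for s in scores], dtype=float)
    floors = np.floor(quotas + 1e-9).astype(int)
    remainder = n - int(floors.sum())
    if remainder < 0:
        raise ValueError("probabilities sum to more than 1")
    frac = quotas - np.floor(quotas + 1e-9)
    order = np.argsort(-frac, kind="stable")
    counts = floors.copy()
    for i in order[:remainder]:
        counts[i] += 1
    return dict(zip(scores, counts.tolist()))


def generate_ihc_scores(
    rules: Optional[dict[str, dict[str, dict[str, float]]]] = None,
    cohort_sizes: Optional[dict[str, int]] = None,
    seed: Optional[int] = None,
    mode: str = "stochastic",
) -> IHCScoreTable:
    """Generate a TMA score table from per-marker, per-subtype distributions.

    ``mode="stochastic"`` draws each case's score from the distribution
    (multinomial under ``seed``); ``mode="deterministic"`` emits the exact
    largest-remainder counts, which makes worked examples reproducible by
    hand.
    """
    if rules is None:
        rules = RENAL_TMA_RULES
    if cohort_sizes is None:
        cohort_sizes = RENAL_TMA_COHORT
    if mode not in ("stochastic", "deterministic"):
        raise ValueError("mode must be 'stochastic' or 'deterministic'")
    rng = np.random.default_rng(seed)

    rows = []
    for subtype, n_cases in cohort_sizes.items():
        case_ids = [f"{subtype}_{i:03d}" for i in range(1, n_cases + 1)]
        for marker, by_subtype in rules.items():
            if subtype not in by_subtype:
                continue
            dist = by_subtype[subtype]
            probs = np.array(list(dist.values()), dtype=float)
            if (probs < 0).any():
                raise ValueError(f"negative probability for {marker}/{subtype}")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"probabilities for {marker}/{subtype} sum to {probs.sum():g}, not 1"
                )
            scores = list(dist)
            if mode == "deterministic":
                counts = _largest_remainder_counts(dist, n_cases)
                assigned = [s for s in scores for _ in range(counts[s])]
            else:
                assigned = list(rng.choice(scores, size=n_cases, p=probs))
            for case_id, score in zip(case_ids, assigned):
                rows.append((case_id, subtype, marker, score))

    return IHCScoreTable(
        pd.DataFrame(rows, columns=["case_id", "subtype", "marker", "score"])
    )
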