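"""Differential-abundance statistics with permutation-based FDR control.

Three test families:

* an S0-moderated two-sample t statistic (SAM style): the usual pooled-t
  denominator is inflated by a constant ``s0`` so that tiny-variance,
  tiny-effect proteins do not dominate the top of the volcano plot;
* a one-way ANOVA F statistic across all groups;
* the Mann-Whitney U test for non-parametric pairwise comparisons.

Significance for the first two is decided by a permutation-based FDR: group
labels are permuted over *biological samples* — technical replicates always
carry their sample's label, preserving the replicate randomization structure —
and for a statistic threshold t the FDR is estimated as the mean number of
null exceedances per permutation divided by the observed exceedance count
(plain SAM ratio, no pi0 correction, clipped to [0, 1]).  A protein's q-value
is the smallest such estimate over all thresholds that would reject it, making
q monotone in the statistic; the significant set at a target FDR is then the
largest threshold set whose estimate is below the target.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import SampleAnnotation
from .preprocess import LogMatrix

__all__ = [
    "moderated_t",
    "permutation_fdr_two_sample",
    "anova_permutation_fdr",
    "mann_whitney",
]


# ---------------------------------------------------------------------------
# moderated t


def _pooled_sd(x: np.ndarray, y: np.ndarray, axis: int = -1) -> np.ndarray:
    n1 = x.shape[axis]
    n2 = y.shape[axis]
    v1 = x.var(axis=axis, ddof=1)
    v2 = y.var(axis=axis, ddof=1)
    return np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))


def _moderated_t_rows(X: np.ndarray, Y: np.ndarray, s0: float) -> np.ndarray:
    """Row-wise moderated t for proteins x runs blocks."""
    n1, n2 = X.shape[1], Y.shape[1]
    sp = _pooled_sd(X, Y)
    diff = X.mean(axis=1) - Y.mean(axis=1)
    denom = sp * math.sqrt(1.0 / n1 + 1.0 / n2) + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        return diff / denom


def moderated_t(
    x: Sequence[float], y: Sequence[float], s0: float = 0.1
) -> tuple[float, float]:
    """S0-moderated two-sample t statistic and its parametric reference p.

    d = (mean(x) - mean(y)) / (sp*sqrt(1/n1 + 1/n2) + s0), sp the pooled SD.
    The returned p-value is the classical two-tailed Student p at s0=0
    (n1+n2-2 df), reported for volcano axes; significance calls should come
    from the permutation procedure.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    sp = _pooled_sd(x, y)
    se = sp * math.sqrt(1.0 / x.size + 1.0 / y.size)
    diff = x.mean() - y.mean()
    if se == 0 and s0 == 0:
        raise ValueError("zero variance in both groups with s0=0")
    d = diff / (se + s0)
    if se == 0:
        warnings.warn("zero variance in both groups; parametric p undefined", stacklevel=2)
        p = float("nan")
    else:
        t0 = diff / se
        p = 2.0 * stats.t.sf(abs(t0), x.size + y.size - 2)
    return float(d), float(p)


# ---------------------------------------------------------------------------
# permutation FDR machinery


def _sample_distinct_permutations(
    rng: np.random.Generator, draw, n_perm: int
) -> list[np.ndarray]:
    """Draw ``n_perm`` *distinct* label assignments via rejection sampling.

    ``draw()`` must return an array; distinctness is judged on its tuple.
    The caller guarantees that more than ``n_perm`` distinct assignments
    exist.
    """
    seen: set[tuple] = set()
    out: list[np.ndarray] = []
    while len(out) < n_perm:
        a = draw()
        key = tuple(a.tolist())
        if key not in seen:
            seen.add(key)
            out.append(a)
    return out


def _fdr_from_permutations(
    observed: np.ndarray, null_stats: np.ndarray, n_perm: int, target_fdr: float
) -> tuple[np.ndarray, np.ndarray]:
    """q-values and significance calls from observed and pooled null statistics.

    ``observed``: |statistic| per protein.  ``null_stats``: flat array of all
    |statistic| values across permutations.  For each candidate threshold (the
    observed values), FDR-hat = (mean null exceedances) / (observed
    exceedances); q_i = min FDR-hat over thresholds <= |d_i|.
    """
    m = observed.size
    order = np.argsort(-observed)  # descending
    sorted_obs = observed[order]
    null_sorted = np.sort(null_stats)
    # null exceedances >= t for each observed threshold
    null_ge = null_stats.size - np.searchsorted(null_sorted, sorted_obs, side="left")
    # ties in observed values: every tied protein shares the deepest rank
    # (count of observed >= its value)
    obs_ge = np.searchsorted(-sorted_obs, -sorted_obs, side="right").astype(float)
    fdr_hat = np.clip((null_ge / n_perm) / obs_ge, 0.0, 1.0)
    # monotone q: best (smallest) estimate over any threshold at or below |d_i|
    q_sorted = np.minimum.accumulate(fdr_hat[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    significant = q <= target_fdr
    return q, significant


def _group_run_indices(
    matrix: LogMatrix, annotation: SampleAnnotation
) -> tuple[list[str], dict[str, list[int]], dict[str, str]]:
    """Biological samples, their run column indices, and sample->group map."""
    annotation.validate_runs(matrix.run_ids)
    col_of = {run: i for i, run in enumerate(matrix.run_ids)}
    samples: list[str] = []
    run_idx: dict[str, list[int]] = {}
    for run in matrix.run_ids:
        sample = annotation.table.loc[run, "biological_sample_id"]
        if sample not in run_idx:
            samples.append(sample)
            run_idx[sample] = []
        run_idx[sample].append(col_of[run])
    return samples, run_idx, annotation.sample_to_group


def permutation_fdr_two_sample(
    matrix: LogMatrix,
    annotation: SampleAnnotation,
    group_a: str,
    group_b: str,
    s0: float = 0.1,
    target_fdr: float = 0.01,
    n_perm: int = 250,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Volcano-style two-sample test with S0 moderation and permutation FDR.

    Returns a DataFrame indexed by protein with columns ``statistic``,
    ``p_value`` (parametric, s0=0), ``log2_fc`` (mean_a - mean_b),
    ``q_value`` and ``significant``.
    """
    if not matrix.is_complete:
        raise ValueError("permutation test requires a complete (imputed) matrix")
    samples, run_idx, sample_group = _group_run_indices(matrix, annotation)
    samples_ab = [s for s in samples if sample_group[s] in (group_a, group_b)]
    if not samples_ab:
        raise ValueError(f"groups {group_a!r}/{group_b!r} not found")
    labels = np.array([sample_group[s] == group_a for s in samples_ab])
    if labels.sum() == 0 or (~labels).sum() == 0:
        raise ValueError("both groups must be present")

    V = matrix.values.to_numpy(dtype=float)

    def block_stat(assignment: np.ndarray) -> np.ndarray:
        cols_a = [c for s, in_a in zip(samples_ab, assignment) for c in (run_idx[s] if in_a else [])]
        cols_b = [c for s, in_a in zip(samples_ab, assignment) for c in (run_idx[s] if not in_a else [])]
        return _moderated_t_rows(V[:, cols_a], V[:, cols_b], s0)

    observed_d = block_stat(labels)
    n_a = int(labels.sum())

    # distinct relabelings = choices of which samples carry group_a's label
    total = math.comb(len(samples_ab), n_a)
    rng = np.random.default_rng(seed)
    if total <= n_perm:
        if total < n_perm:
            warnings.warn(
                f"only {total} distinct permutations exist; enumerating all",
                stacklevel=2,
            )
        assignments = []
        for combo in combinations(range(len(samples_ab)), n_a):
            a = np.zeros(len(samples_ab), dtype=bool)
            a[list(combo)] = True
            assignments.append(a)
    else:
        assignments = _sample_distinct_permutations(
            rng, lambda: rng.permutation(labels), n_perm
        )

    null_abs = np.concatenate([np.abs(block_stat(a)) for a in assignments])
    q, significant = _fdr_from_permutations(
        np.abs(observed_d), null_abs, len(assignments), target_fdr
    )

    cols_a = [c for s in samples_ab if sample_group[s] == group_a for c in run_idx[s]]
    cols_b = [c for s in samples_ab if sample_group[s] == group_b for c in run_idx[s]]
    Xa, Xb = V[:, cols_a], V[:, cols_b]
    log2_fc = Xa.mean(axis=1) - Xb.mean(axis=1)
    sp = _pooled_sd(Xa, Xb)
    se = sp * math.sqrt(1.0 / Xa.shape[1] + 1.0 / Xb.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = log2_fc / se
    p = 2.0 * stats.t.sf(np.abs(t0), Xa.shape[1] + Xb.shape[1] - 2)

    return pd.DataFrame(
        {
            "statistic": observed_d,
            "p_value": p,
            "log2_fc": log2_fc,
            "q_value": q,
            "significant": significant,
        },
        index=matrix.values.index,
    )


def _anova_f_rows(V: np.ndarray, group_cols: list[np.ndarray]) -> np.ndarray:
    """Row-wise one-way F statistic; runs are the observations."""
    n_total = sum(len(c) for c in group_cols)
    k = len(group_cols)
    grand = V[:, np.concatenate(group_cols)].mean(axis=1)
    ssb = np.zeros(V.shape[0])
    ssw = np.zeros(V.shape[0])
    for cols in group_cols:
        block = V[:, cols]
        gmean = block.mean(axis=1)
        ssb += len(cols) * (gmean - grand) ** 2
        ssw += ((block - gmean[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ssb / (k - 1)) / (ssw / (n_total - k))


def anova_permutation_fdr(
    matrix: LogMatrix,
    annotation: SampleAnnotation,
    target_fdr: float = 0.01,
    n_perm: int = 250,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Multi-group one-way ANOVA with permutation FDR over biological samples.

    Permutations shuffle the sample->group assignment; both technical
    replicates of a sample always move together, preserving the replicate
    randomization.  Returns a DataFrame with ``statistic`` (F), ``p_value``
    (parametric F reference), ``q_value`` and ``significant``.
    """
    if not matrix.is_complete:
        raise ValueError("permutation test requires a complete (imputed) matrix")
    samples, run_idx, sample_group = _group_run_indices(matrix, annotation)
    groups = list(dict.fromkeys(sample_group[s] for s in samples))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        n_bio = sum(1 for s in samples if sample_group[s] == g)
        if n_bio < 2:
            raise ValueError(f"group {g!r} has fewer than 2 biological samples")

    V = matrix.values.to_numpy(dtype=float)
    sample_labels = np.array([groups.index(sample_group[s]) for s in samples])

    def group_cols(lbls: np.ndarray) -> list[np.ndarray]:
        out = []
        for gi in range(len(groups)):
            cols = [c for s, l in zip(samples, lbls) if l == gi for c in run_idx[s]]
            if len(cols) < 2:
                raise ValueError(f"group {groups[gi]!r} reduced to < 2 runs")
            out.append(np.array(cols))
        return out

    observed_f = _anova_f_rows(V, group_cols(sample_labels))

    counts = np.bincount(sample_labels)
    total = math.factorial(len(samples))
    for c in counts:
        total //= math.factorial(int(c))
    rng = np.random.default_rng(seed)
    if total <= n_perm:
        from sympy.utilities.iterables import multiset_permutations

        if total < n_perm:
            warnings.warn(
                f"only {total} distinct permutations exist; enumerating all",
                stacklevel=2,
            )
        label_sets = [np.array(p) for p in multiset_permutations(sample_labels.tolist())]
    else:
        label_sets = _sample_distinct_permutations(
            rng, lambda: rng.permutation(sample_labels), n_perm
        )

    null_f = np.concatenate([_anova_f_rows(V, group_cols(l)) for l in label_sets])
    q, significant = _fdr_from_permutations(
        observed_f, null_f, len(label_sets), target_fdr
    )

    n_total = V.shape[1]
    k = len(groups)
    p = stats.f.sf(observed_f, k - 1, n_total - k)

    return pd.DataFrame(
        {
            "statistic": observed_f,
            "p_value": p,
            "q_value": q,
            "significant": significant,
        },
        index=matrix.values.index,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (U reported for the first sample).

    Exact p by enumeration when n1+n2 <= 16 and there are no ties; otherwise
    the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 16 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
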