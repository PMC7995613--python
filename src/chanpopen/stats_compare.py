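"""Randomization (permutation) statistics for group comparisons.

Two-tailed unpaired test on the absolute difference of group means: group
labels are permuted (sampling without replacement) and the observed
statistic is referred to the permutation distribution.  When the number of
distinct label assignments is no larger than the requested iteration count
the test enumerates all of them and reports the exact p-value; otherwise a
Monte-Carlo sample is drawn and the add-one convention
p = (#{permuted ≥ observed} + 1)/(n_iter + 1) keeps p away from zero.

Comparisons across many construct/agonist pairs use a Bonferroni-style
family threshold: alpha_family/n_comparisons (0.05/10 = 0.005 for the ten
comparisons typical of a four-agonist, multi-construct study).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .cluster_popen import select_group

__all__ = [
    "RandomizationResult",
    "randomization_test",
    "multiple_comparison_threshold",
    "compare_table",
    "type_i_error_rate",
]

N_ITER_DEFAULT = 10_000
ALPHA_DEFAULT = 0.005  # 0.05 family-wise over 10 comparisons

_TIE_EPS = 1e-12  # float-safe ">= observed" comparison


@dataclass(frozen=True)
class RandomizationResult:
    """Outcome of one two-tailed unpaired randomization test."""

    observed_stat: float
    p_value: float
    n_iterations: int
    exhaustive: bool
    seed: int | None


def randomization_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_iter: int = N_ITER_DEFAULT,
    seed: int | None = None,
) -> RandomizationResult:
    """Two-tailed unpaired permutation test on |mean(A) − mean(B)|.

    Enumerates all C(nA+nB, nA) assignments when that count does not exceed
    ``n_iter`` (exact, seed-independent p); otherwise draws ``n_iter``
    random assignments and applies the add-one convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size + b.size < 4:
        warnings.warn(
            "fewer than 4 observations in total: the permutation distribution "
            "is too granular for meaningful p-values",
            stacklevel=2,
        )
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    observed = abs(a.mean() - b.mean())
    total = pooled.sum()
    n_splits = comb(n, na)

    if n_splits <= n_iter:
        count = 0
        for idx in combinations(range(n), na):
            sum_a = pooled[list(idx)].sum()
            stat = abs(sum_a / na - (total - sum_a) / (n - na))
            if stat >= observed - _TIE_EPS:
                count += 1
        return RandomizationResult(
            observed_stat=observed,
            p_value=count / n_splits,
            n_iterations=n_splits,
            exhaustive=True,
            seed=None,
        )

    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(n_iter, int(2e7) // n))
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        # random nA-subsets via argpartition of uniform keys
        keys = rng.random((m, n))
        idx_a = np.argpartition(keys, na - 1, axis=1)[:, :na]
        sum_a = pooled[idx_a].sum(axis=1)
        stats = np.abs(sum_a / na - (total - sum_a) / (n - na))
        count += int(np.count_nonzero(stats >= observed - _TIE_EPS))
        done += m
    return RandomizationResult(
        observed_stat=observed,
        p_value=(count + 1) / (n_iter + 1),
        n_iterations=n_iter,
        exhaustive=False,
        seed=seed,
    )


def multiple_comparison_threshold(
    alpha_family: float = 0.05, n_comparisons: int = 10
) -> float:
    """Bonferroni per-test threshold alpha_family/n_comparisons."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be at least 1")
    if not 0 < alpha_family < 1:
        raise ValueError("alpha_family must lie in (0, 1)")
    return alpha_family / n_comparisons


def type_i_error_rate(
    n_replicates: int = 1000,
    n_per_group: int = 10,
    n_iter: int = 2000,
    alpha: float = ALPHA_DEFAULT,
    seed: int = 0,
) -> float:
    """Empirical false-positive rate of the test under an exact null.

    Draws ``n_replicates`` pairs of groups from the same standard normal
    distribution, runs the randomization test on each, and returns the
    fraction rejected at ``alpha``.  A well-calibrated test returns a value
    near ``alpha``.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    rejections = 0
    for rep_seed in ss.spawn(n_replicates):
        x = rng.standard_normal(n_per_group)
        y = rng.standard_normal(n_per_group)
        sub_seed = int(rep_seed.generate_state(1)[0] % (2**31))
        res = randomization_test(x, y, n_iter=n_iter, seed=sub_seed)
        if res.p_value < alpha:
            rejections += 1
    return rejections / n_replicates


def _parse_contrast(contrast) -> tuple:
    if isinstance(contrast, str):
        parts = contrast.split(" vs ")
        if len(parts) != 2:
            raise ValueError(f"cannot parse contrast {contrast!r}; use 'A vs B'")
        return parts[0].strip(), parts[1].strip()
    g1, g2 = contrast
    return g1, g2


def compare_table(
    clusters: pd.DataFrame,
    contrasts: Sequence,
    n_iter: int = N_ITER_DEFAULT,
    seed: int = 0,
    alpha: float = ALPHA_DEFAULT,
    value_col: str = "popen",
    by_patch: bool = False,
) -> pd.DataFrame:
    """Run one randomization test per contrast on a cluster table.

    ``contrasts`` holds ``"group1 vs group2"`` strings (group syntax as in
    :func:`chanpopen.cluster_popen.select_group`) or pairs of group
    selectors.  The sampling unit is the cluster; ``by_patch=True``
    aggregates to patch means first.  Each row records the statistic,
    p-value, iteration count, exhaustiveness, seed and a significance flag
    at ``alpha``.
    """
    contrasts = list(contrasts)
    ss = np.random.SeedSequence(seed)
    rows = []
    for contrast, child in zip(contrasts, ss.spawn(len(contrasts))):
        g1, g2 = _parse_contrast(contrast)
        v1 = select_group(clusters, g1)
        v2 = select_group(clusters, g2)
        if by_patch:
            x1 = v1.groupby("patch_id")[value_col].mean().to_numpy()
            x2 = v2.groupby("patch_id")[value_col].mean().to_numpy()
        else:
            x1 = v1[value_col].to_numpy(float)
            x2 = v2[value_col].to_numpy(float)
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        res = randomization_test(x1, x2, n_iter=n_iter, seed=sub_seed)
        rows.append(
            {
                "group_a": str(g1),
                "group_b": str(g2),
                "n_a": x1.size,
                "n_b": x2.size,
                "mean_a": float(np.mean(x1)),
                "mean_b": float(np.mean(x2)),
                "observed_stat": res.observed_stat,
                "p_value": res.p_value,
                "n_iterations": res.n_iterations,
                "exhaustive": res.exhaustive,
                "seed": res.seed,
                "significant": res.p_value < alpha,
                "alpha": alpha,
                "unit": "patch" if by_patch else "cluster",
            }
        )
    return pd.DataFrame(rows)
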