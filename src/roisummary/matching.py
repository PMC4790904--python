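"""Covariate-matched subset selection and matched-resampling evaluation.

``covariate_match`` selects a pool subset whose covariates are statistically
indistinguishable from a reference group (every two-sample t test p > 0.2 by
default; binary covariates are coded 0/1 and t-tested the same way).  The
search is rejection sampling over random subsets with greedy single-swap
refinement — the matching procedure itself is a design choice, the p > 0.2
criterion is the contract.

``replicate_comparison`` repeats draw-and-match many times (1000 by default)
and aggregates, per measure, the mean Cohen's d and the fraction of
replicates with t-test p below 0.05 / 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import cohens_d, two_sample_t

__all__ = ["MatchFailureError", "covariate_match", "replicate_comparison"]


class MatchFailureError(RuntimeError):
    """No matched subset found within the iteration budget."""


def _match_pvalues(
    ref: np.ndarray, pool: np.ndarray, subset: np.ndarray
) -> np.ndarray:
    """Per-covariate two-sample t p values between reference and subset."""
    out = np.empty(ref.shape[1])
    for j in range(ref.shape[1]):
        x, y = ref[:, j], pool[subset, j]
        try:
            _, p = two_sample_t(x, y)
        except ValueError:  # zero pooled variance with unequal means
            p = 0.0
        out[j] = p
    return out


def covariate_match(
    reference: pd.DataFrame,
    pool: pd.DataFrame,
    covariates: Sequence[str],
    n: int,
    p_min: float = 0.2,
    max_iter: int = 10_000,
    seed: int | np.random.Generator = 0,
    n_swaps: int = 200,
) -> pd.DataFrame:
    """Select ``n`` pool rows matched to ``reference`` on every covariate.

    Success means every covariate's two-sample t test (reference vs subset)
    has p > ``p_min``.  Deterministic under ``seed``.  Raises
    :class:`MatchFailureError` when ``max_iter`` candidate evaluations pass
    without success.
    """
    if len(pool) < n:
        raise ValueError("pool smaller than requested subset")
    for c in covariates:
        if reference[c].isna().any() or pool[c].isna().any():
            raise ValueError(f"covariate {c!r} has missing values")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ref = reference[list(covariates)].to_numpy(dtype=float)
    pl = pool[list(covariates)].to_numpy(dtype=float)
    n_pool = len(pool)

    iters = 0
    while iters < max_iter:
        subset = rng.choice(n_pool, size=n, replace=False)
        pvals = _match_pvalues(ref, pl, subset)
        iters += 1
        if pvals.min() > p_min:
            return pool.iloc[np.sort(subset)]
        # greedy single-swap refinement on the worst covariate's p value
        for _ in range(n_swaps):
            if iters >= max_iter:
                break
            out_pos = int(rng.integers(n))
            candidates = np.setdiff1d(np.arange(n_pool), subset, assume_unique=False)
            new_member = int(rng.choice(candidates))
            trial = subset.copy()
            trial[out_pos] = new_member
            trial_p = _match_pvalues(ref, pl, trial)
            iters += 1
            if trial_p.min() > pvals.min():
                subset, pvals = trial, trial_p
                if pvals.min() > p_min:
                    return pool.iloc[np.sort(subset)]
    raise MatchFailureError(
        f"no matched subset of size {n} found in {max_iter} iterations"
    )


@dataclass(frozen=True)
class ReplicateSummary:
    """Aggregate of the matched-resampling evaluation."""

    per_measure: pd.DataFrame  # measure, mean_d, frac_p05, frac_p01
    n_replicates: int
    n_match_failures: int


def replicate_comparison(
    table: pd.DataFrame,
    measures: Sequence[str],
    covariates: Sequence[str],
    group_col: str = "group",
    n_draw: int = 50,
    n_rep: int = 1000,
    p_min: float = 0.2,
    max_iter: int = 10_000,
    seed: int = 0,
) -> ReplicateSummary:
    """Matched-resampling sensitivity evaluation.

    Per replicate: draw ``n_draw`` subjects from the first group without
    replacement, covariate-match ``n_draw`` from the second, then compute
    Cohen's d and the t-test p for every measure on that subset (one shared
    draw per replicate, reused by all measures).  Replicates whose matching
    fails are redrawn and counted; more failures than successful replicates
    aborts with a diagnostic.
    """
    labels = list(pd.unique(table[group_col]))
    if len(labels) != 2:
        raise ValueError("replicate_comparison needs exactly 2 groups")
    g1 = table[table[group_col] == labels[0]].reset_index(drop=True)
    g2 = table[table[group_col] == labels[1]].reset_index(drop=True)
    if len(g1) <= n_draw or len(g2) <= n_draw:
        raise ValueError("both groups must be larger than n_draw")

    rng = np.random.default_rng(seed)
    d_acc = {m: [] for m in measures}
    p_acc = {m: [] for m in measures}
    failures = 0
    done = 0
    while done < n_rep:
        if failures > n_rep // 2 and failures > done:
            raise MatchFailureError(
                f"aborting: {failures} match failures against {done} successes"
            )
        ref_idx = rng.choice(len(g1), size=n_draw, replace=False)
        ref = g1.iloc[ref_idx]
        try:
            matched = covariate_match(
                ref, g2, covariates, n_draw, p_min=p_min, max_iter=max_iter, seed=rng
            )
        except MatchFailureError:
            failures += 1
            continue
        for m in measures:
            x = ref[m].dropna().to_numpy()
            y = matched[m].dropna().to_numpy()
            if len(x) < 2 or len(y) < 2:
                d_acc[m].append(np.nan)
                p_acc[m].append(np.nan)
                continue
            d_acc[m].append(cohens_d(x, y))
            p_acc[m].append(two_sample_t(x, y)[1])
        done += 1

    per_measure = pd.DataFrame(
        {
            "measure": list(measures),
            "mean_d": [float(np.nanmean(d_acc[m])) for m in measures],
            "frac_p05": [float(np.nanmean(np.asarray(p_acc[m]) < 0.05)) for m in measures],
            "frac_p01": [float(np.nanmean(np.asarray(p_acc[m]) < 0.01)) for m in measures],
        }
    )
    return ReplicateSummary(per_measure, n_replicates=done, n_match_failures=failures)
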