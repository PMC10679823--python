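"""Randomization inference: max-statistic multiple-comparison correction,
condition permutation contrasts, per-frequency rank-sum tests, and equal-weight
across-subject combination.

The max-based correction controls the family-wise error rate across a
comparison dimension (usually frequency): each randomization contributes only
the minimum and maximum of the recomputed statistic, and the 2.5th percentile
of the min distribution / 97.5th percentile of the max distribution bound a
two-sided 5% family-wise test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

__all__ = [
    "RandomizationResult",
    "nearest_rank_percentile",
    "max_corrected_randomization",
    "max_corrected_from_null",
    "condition_permutation_test",
    "per_frequency_condition_test",
    "combine_subjects",
]


def nearest_rank_percentile(x: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the ceil(q/100 * n)-th smallest value."""
    x = np.sort(np.asarray(x))
    n = len(x)
    rank = int(np.ceil(q / 100.0 * n))
    return float(x[min(max(rank, 1), n) - 1])


@dataclass
class RandomizationResult:
    observed: np.ndarray
    null_min: np.ndarray
    null_max: np.ndarray
    lo_threshold: float
    hi_threshold: float
    significant: np.ndarray
    n_randomizations: int

    def __post_init__(self):
        expect = (self.observed < self.lo_threshold) | \
                 (self.observed > self.hi_threshold)
        if not np.array_equal(expect, self.significant):
            raise ValueError("significance must match the thresholds")


def max_corrected_from_null(observed: np.ndarray,
                            null_stats: np.ndarray) -> RandomizationResult:
    """Thresholds and per-point significance from precomputed null statistics
    (n_randomizations x n_points)."""
    null_stats = np.asarray(null_stats)
    if null_stats.shape[0] < 100:
        raise ValueError("need at least 100 randomizations for stable "
                         "percentile thresholds")
    null_min = null_stats.min(axis=1)
    null_max = null_stats.max(axis=1)
    lo = nearest_rank_percentile(null_min, 2.5)
    hi = nearest_rank_percentile(null_max, 97.5)
    observed = np.asarray(observed)
    sig = (observed < lo) | (observed > hi)
    return RandomizationResult(observed=observed, null_min=null_min,
                               null_max=null_max, lo_threshold=lo,
                               hi_threshold=hi, significant=sig,
                               n_randomizations=null_stats.shape[0])


def max_corrected_randomization(data, statistic_fn, relabel_fn,
                                n_rand: int = 1000,
                                rng: np.random.Generator | None = None
                                ) -> RandomizationResult:
    """Max-statistic randomization test.

    ``statistic_fn(data)`` maps the data to a vector over comparison points;
    ``relabel_fn(data, rng)`` returns a relabeled copy drawn from the null
    (RT shuffling, condition permutation, or trial shuffling, depending on
    the analysis — the scheme must be exchangeable under the null).
    """
    if n_rand < 100:
        raise ValueError("n_rand below 100 gives unstable percentiles")
    rng = np.random.default_rng() if rng is None else rng
    observed = np.atleast_1d(np.asarray(statistic_fn(data), dtype=float))
    null = np.empty((n_rand, observed.shape[0]))
    for i in range(n_rand):
        null[i] = np.atleast_1d(statistic_fn(relabel_fn(data, rng)))
    return max_corrected_from_null(observed, null)


def condition_permutation_test(statistic_fn, labels: np.ndarray,
                               n_rand: int = 1000,
                               rng: np.random.Generator | None = None,
                               conditions: tuple = ("IN", "OUT"),
                               p_method: str = "z"
                               ) -> tuple[float, float, float]:
    """Observed IN-OUT difference versus a trial-permutation null.

    ``statistic_fn(indices)`` evaluates the statistic on a subset of trials.
    Returns (observed difference, z relative to the null distribution, p).
    ``p_method='z'`` gives the two-sided normal p of the z score;
    ``p_method='empirical'`` the exact two-sided permutation p-value
    (1 + exceedances) / (n_rand + 1), which is valid by construction.
    """
    labels = np.asarray(labels)
    idx_a = np.flatnonzero(labels == conditions[0])
    idx_b = np.flatnonzero(labels == conditions[1])
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("need at least 2 trials per condition")
    rng = np.random.default_rng() if rng is None else rng
    obs = statistic_fn(idx_a) - statistic_fn(idx_b)
    pool = np.concatenate([idx_a, idx_b])
    na = len(idx_a)
    null = np.empty(n_rand)
    for i in range(n_rand):
        perm = rng.permutation(pool)
        null[i] = statistic_fn(perm[:na]) - statistic_fn(perm[na:])
    sd = null.std()
    if sd == 0:
        return float(obs), 0.0, 1.0
    z = (obs - null.mean()) / sd
    if p_method == "empirical":
        # the permutation null of a condition difference is symmetric about 0
        p = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (n_rand + 1.0)
    elif p_method == "z":
        p = 2.0 * _stats.norm.sf(abs(z))
    else:
        raise ValueError("p_method must be 'z' or 'empirical'")
    return float(obs), float(z), float(p)


def per_frequency_condition_test(values_in: np.ndarray, values_out: np.ndarray,
                                 alpha: float = 0.05) -> dict:
    """Wilcoxon rank-sum test per frequency across site pairs, Bonferroni
    corrected by the number of frequencies."""
    values_in = np.asarray(values_in)
    values_out = np.asarray(values_out)
    if values_in.shape[0] < 2 or values_out.shape[0] < 2:
        raise ValueError("need at least 2 site pairs per group")
    n_freq = values_in.shape[1]
    p = np.empty(n_freq)
    for f in range(n_freq):
        a, b = values_in[:, f], values_out[:, f]
        if np.ptp(np.concatenate([a, b])) == 0:
            p[f] = 1.0
        else:
            p[f] = _stats.ranksums(a, b).pvalue
    threshold = alpha / n_freq
    return {"p": p, "significant": p < threshold,
            "bonferroni_threshold": threshold}


def combine_subjects(per_subject_results: list) -> np.ndarray:
    """Equal-weight combination: average within each subject over its units
    (site pairs), then unweighted average across subjects.

    Each entry is an array whose first axis indexes that subject's units
    (scalars are taken as already averaged); all unit-averaged results must
    share a (peak-aligned) shape.
    """
    if not per_subject_results:
        raise ValueError("no subjects")
    means = []
    for res in per_subject_results:
        res = np.asarray(res, dtype=float)
        means.append(res.mean(axis=0) if res.ndim >= 1 else res)
    shapes = {m.shape for m in means}
    if len(shapes) > 1:
        raise ValueError("subjects must share an aligned frequency axis")
    return np.mean(means, axis=0)
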