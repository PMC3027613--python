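"""Shannon diversity and analytic (hypergeometric) rarefaction.

Diversity is computed over genus-level marker-gene assignments that
pass the 80% classifier-confidence filter.  Because datasets of unequal
size are not directly comparable, the Shannon index can also be
computed as the average over many uniform without-replacement
subsamples matched to the smaller dataset's size.  Rarefaction curves
give the closed-form expected number of categories (genera, protein
families) observed in subsamples of increasing size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .taxonomy import AbundanceProfile


class DiversityError(ValueError):
    pass


def shannon_index(profile: AbundanceProfile | dict[str, int] | Sequence[int],
                  base: float | None = None) -> float:
    """H = -sum p_i log p_i over category relative abundances.

    Natural log by default (the conventional ecological choice); pass
    ``base`` for another logarithm base.  Zero-count categories are
    excluded; at least one non-zero count is required.
    """
    if isinstance(profile, AbundanceProfile):
        counts = np.array(list(profile.counts.values()), dtype=float)
    elif isinstance(profile, dict):
        counts = np.array(list(profile.values()), dtype=float)
    else:
        counts = np.asarray(profile, dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise DiversityError("Shannon index of an empty profile is undefined")
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def subsampled_shannon(
    assignments: pd.DataFrame,
    subsample_size: int,
    iterations: int = 5000,
    seed: int | np.random.Generator = 0,
    min_conf: float = 0.80,
    mode: str = "read",
    taxon_col: str = "taxon",
    conf_col: str = "confidence",
) -> float:
    """Mean Shannon index over uniform without-replacement subsamples.

    ``assignments`` holds one row per classified read (taxon +
    classifier confidence).  In ``mode="read"`` each iteration draws
    ``subsample_size`` reads, re-applies the confidence filter to the
    subsample and computes the genus Shannon index.  ``mode="category"``
    is a distributionally equivalent fast path: rows are first reduced
    to category counts (confidence-failing reads pooled into one
    below-threshold category that never contributes to the index) and
    each iteration draws from the multivariate hypergeometric
    distribution over those counts.
    """
    n = len(assignments)
    if subsample_size > n:
        raise DiversityError(
            f"subsample size {subsample_size} exceeds dataset size {n}"
        )
    if subsample_size < 1:
        raise DiversityError("subsample size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    passing = assignments[conf_col].to_numpy() >= min_conf
    taxa = assignments[taxon_col].to_numpy()
    # integer-code taxa; failing reads get code -1 (excluded from H)
    codes, _ = pd.factorize(taxa)
    codes = np.where(passing, codes, -1)

    if subsample_size == n:
        counts = np.bincount(codes[codes >= 0])
        return shannon_index(counts[counts > 0])

    if mode == "read":
        values = np.empty(iterations)
        for i in range(iterations):
            idx = rng.choice(n, size=subsample_size, replace=False)
            sub = codes[idx]
            sub = sub[sub >= 0]
            counts = np.bincount(sub)
            values[i] = shannon_index(counts[counts > 0])
        return float(values.mean())
    if mode == "category":
        ncat = codes.max() + 1
        full = np.bincount(codes + 1, minlength=ncat + 1)  # slot 0 = failing
        values = np.empty(iterations)
        for i in range(iterations):
            draw = rng.multivariate_hypergeometric(full, subsample_size)
            counts = draw[1:]
            values[i] = shannon_index(counts[counts > 0])
        return float(values.mean())
    raise DiversityError(f"unknown mode {mode!r}")


@dataclass
class RarefactionCurve:
    """Expected category richness E[S_n] over a grid of sample sizes."""

    sample_sizes: np.ndarray
    expected_richness: np.ndarray
    total_items: int
    category_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_size": self.sample_sizes, "expected_richness": self.expected_richness}
        )


def _log_choose(a: np.ndarray, b: int) -> np.ndarray:
    """log C(a, b) elementwise, -inf where a < b."""
    a = np.asarray(a, dtype=float)
    out = np.full(a.shape, -np.inf)
    ok = a >= b
    out[ok] = gammaln(a[ok] + 1) - gammaln(b + 1) - gammaln(a[ok] - b + 1)
    return out


def expected_richness(category_counts: Sequence[int], n: int) -> float:
    """Closed-form E[S_n] for a without-replacement subsample of size n.

    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)], the hypergeometric
    probability that category i appears at least once; C(a, b) = 0 when
    a < b.  Computed via log-gamma for stability at large N.
    """
    counts = np.asarray(category_counts, dtype=int)
    if np.any(counts < 1):
        raise DiversityError("all category counts must be >= 1")
    total = int(counts.sum())
    if n > total:
        raise DiversityError(f"sample size {n} exceeds total items {total}")
    if n < 0:
        raise DiversityError("sample size must be >= 0")
    if n == 0:
        return 0.0
    log_denom = _log_choose(np.array([total]), n)[0]
    log_num = _log_choose(total - counts, n)
    return float(np.sum(1.0 - np.exp(log_num - log_denom)))


def rarefaction_curve(
    category_counts: Sequence[int],
    sample_sizes: Sequence[int] | None = None,
    grid_points: int = 50,
) -> RarefactionCurve:
    """Analytic rarefaction curve over a grid of sample sizes.

    Default grid: ``grid_points`` sizes evenly spaced from 1 to the
    total number of items.
    """
    counts = np.asarray(category_counts, dtype=int)
    total = int(counts.sum())
    if sample_sizes is None:
        sizes = np.unique(np.linspace(1, total, min(grid_points, total)).astype(int))
    else:
        sizes = np.asarray(sample_sizes, dtype=int)
    richness = np.array([expected_richness(counts, int(n)) for n in sizes])
    return RarefactionCurve(
        sample_sizes=sizes,
        expected_richness=richness,
        total_items=total,
        category_counts=counts,
    )
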