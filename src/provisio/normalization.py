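"""Expression-level filtering and TMM library-size normalization.

Filtering follows the counts-per-million rule tied to the median library
size and the smallest group size; normalization is the trimmed mean of
M-values (TMM): a doubly trimmed, precision-weighted mean of per-feature
log ratios against a reference sample, rescaled to geometric mean one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class NormFactors:
    """Per-sample TMM scale factors (geometric mean 1) and the reference."""

    factors: pd.Series
    reference: str

    def __post_init__(self):
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")


def _library_sizes(counts: pd.DataFrame) -> pd.Series:
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("all-zero library in count matrix")
    return lib


def filter_by_expression(
    counts: pd.DataFrame,
    group: pd.Series,
    min_count: float = 10.0,
    min_total: float = 15.0,
) -> pd.Index:
    """Features worth keeping for differential analysis.

    A feature is retained iff its CPM is at least ``min_count / median
    library size * 1e6`` in at least k samples (k = size of the smallest
    group) and its total count across all samples reaches ``min_total``.
    Returns retained feature identifiers in input order.
    """
    group = group.reindex(counts.columns)
    if group.isna().any():
        raise ValueError("every sample needs a group label")
    sizes = group.value_counts()
    if (sizes == 0).any() or sizes.empty:
        raise ValueError("empty groups")
    k = int(sizes.min())

    lib = _library_sizes(counts)
    cutoff = min_count / float(np.median(lib)) * 1e6
    cpm = counts.to_numpy(float) / lib.to_numpy()[None, :] * 1e6
    # tiny tolerance so a feature sitting exactly at the cutoff is kept
    enough_samples = (cpm >= cutoff * (1 - 1e-10)).sum(axis=1) >= k
    enough_total = counts.sum(axis=1).to_numpy() >= min_total
    return counts.index[enough_samples & enough_total]


def _choose_reference(counts: np.ndarray, lib: np.ndarray) -> int:
    """Sample whose upper-quartile CPM is closest to the mean upper-quartile."""
    uq = np.array(
        [np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])]
    )
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    abs_trim: float,
) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2^f)."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValueError("no co-expressed features between sample and reference")
    o, r = obs[pos].astype(float), ref[pos].astype(float)
    po, pr = o / n_obs, r / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic (1-p)/(n p) binomial variance, summed over both samples
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    n = m.size
    if n == 0:
        raise ValueError("no usable features for TMM")
    # double trim by rank: central (1 - 2*trim) of M and of A
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * abs_trim) + 1, n + 1 - np.floor(n * abs_trim)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    w = 1.0 / v[keep]
    f = float(np.sum(w * m[keep]) / np.sum(w))
    if not np.isfinite(f):
        return 1.0
    return 2.0 ** f


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> NormFactors:
    """Trimmed-mean-of-M-values scale factors for every sample.

    The reference is the sample whose upper-quartile CPM is closest to the
    mean upper-quartile (ties broken by input order).  Factors are rescaled
    so their geometric mean is one.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    x = counts.to_numpy(float)
    lib = _library_sizes(counts).to_numpy()
    ref_idx = _choose_reference(x, lib)
    factors = np.array(
        [
            _tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx],
                      logratio_trim, abs_trim)
            for j in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(
        factors=pd.Series(factors, index=counts.columns, name="tmm"),
        reference=str(counts.columns[ref_idx]),
    )


def log_cpm(
    counts: pd.DataFrame,
    factors: NormFactors | None = None,
    prior: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million with a prior count and effective library sizes.

    value = log2((count + prior) / (library * factor + 2 * prior) * 1e6)
    """
    lib = _library_sizes(counts)
    f = factors.factors.reindex(counts.columns) if factors is not None else 1.0
    eff = lib * f
    if np.any(np.asarray(eff) <= 0):
        raise ValueError("non-positive effective library size")
    x = counts.to_numpy(float)
    out = np.log2((x + prior) / (np.asarray(eff, float)[None, :] + 2 * prior) * 1e6)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)
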