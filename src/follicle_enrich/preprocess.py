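"""Low-expression filtering and TMM between-sample normalization.

Filtering keeps genes with at least ``min_rpm`` reads per million in at
least ``min_samples`` samples, with RPM computed against the library sizes
fixed at load time (full sequencing depth, not post-filter sums).

Normalization implements the trimmed mean of M-values (TMM) estimator:
for each sample against a reference sample, per-gene log2 expression
ratios (M) are trimmed at the extremes of both M and average log
expression (A), and the surviving ratios are averaged with inverse
asymptotic-variance (precision) weights. The resulting per-sample scaling
factors are rescaled to geometric mean 1, and effective library sizes are
raw depth times factor.
"""

from __future__ import annotations

import warnings

import numpy as np

from .model import CountMatrix, FilterReport, NormalizationFactors, ValidationError


def compute_rpm(counts: CountMatrix) -> np.ndarray:
    """Reads per million: count * 1e6 / library size, per sample."""
    lib = counts.library_sizes.astype(float)
    if np.any(lib <= 0):
        bad = [counts.sample_ids[i] for i in np.flatnonzero(lib <= 0)]
        raise ValidationError(f"zero library size for sample(s) {bad}")
    return counts.counts * 1e6 / lib[np.newaxis, :]


def filter_low_expression(
    counts: CountMatrix, min_rpm: float = 1.0, min_samples: int = 2
) -> tuple[CountMatrix, FilterReport]:
    """Retain genes with RPM >= ``min_rpm`` in >= ``min_samples`` samples.

    Library sizes are carried through unchanged so that downstream RPM
    still refers to the original sequencing depth.
    """
    if min_samples > counts.n_samples:
        raise ValidationError(
            f"min_samples={min_samples} exceeds the {counts.n_samples} samples present"
        )
    rpm = compute_rpm(counts)
    keep = (rpm >= min_rpm).sum(axis=1) >= min_samples
    report = FilterReport(
        n_input_genes=counts.n_genes,
        n_retained_genes=int(keep.sum()),
        min_rpm=float(min_rpm),
        min_samples=int(min_samples),
    )
    return counts.subset_genes(keep), report


def select_reference_sample(counts: CountMatrix) -> str:
    """Reference column for TMM: the sample whose 75th percentile of RPM
    (over its nonzero genes) is closest to the across-sample mean of that
    statistic; ties break to the lowest sample index."""
    if counts.n_samples < 1:
        raise ValidationError("need at least one sample")
    rpm = compute_rpm(counts)
    stats = np.empty(counts.n_samples)
    for j in range(counts.n_samples):
        nz = rpm[:, j][counts.counts[:, j] > 0]
        if nz.size == 0:
            stats[j] = np.nan
        else:
            stats[j] = np.percentile(nz, 75)
    if np.all(np.isnan(stats)):
        raise ValidationError("all-zero count matrix: no reference sample exists")
    mean = np.nanmean(stats)
    dist = np.abs(stats - mean)
    dist[np.isnan(dist)] = np.inf
    return counts.sample_ids[int(np.argmin(dist))]


def _trim_keep_mask(values: np.ndarray, trim: float) -> np.ndarray:
    """Keep ranks strictly inside the lower/upper ``trim`` fractions.

    Rank-based (average ranks for ties) so exactly floor(n*trim) values are
    shed from each end for distinct values.
    """
    n = values.size
    # average ranks, 1-based
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    # resolve ties to average rank
    vals_sorted = values[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and vals_sorted[j + 1] == vals_sorted[i]:
            j += 1
        if j > i:
            ranks[order[i : j + 1]] = (i + 1 + j + 1) / 2.0
        i = j + 1
    lo = np.floor(n * trim) + 1
    hi = n + 1 - lo
    return (ranks >= lo) & (ranks <= hi)


def compute_tmm_factors(
    counts: CountMatrix,
    reference: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    min_genes: int = 10,
) -> NormalizationFactors:
    """Weighted doubly-trimmed mean of per-gene log ratios against a reference.

    For sample k vs reference r over genes with nonzero counts in both:
    M_g = log2((y_gk/N_k)/(y_gr/N_r)), A_g = 0.5*log2((y_gk/N_k)*(y_gr/N_r)),
    precision weight w_g = inverse of (N_k-y_gk)/(N_k y_gk) + (N_r-y_gr)/(N_r y_gr).
    The top and bottom ``trim_m`` fraction by M and ``trim_a`` fraction by A
    are dropped (union of drops); factor_k = 2**(sum w M / sum w). Factors
    are rescaled to geometric mean 1. Samples with fewer than ``min_genes``
    genes surviving trimming get factor 1 with a warning.
    """
    if reference is None:
        reference = select_reference_sample(counts)
    r = counts.sample_index(reference)
    y = counts.counts.astype(float)
    N = counts.library_sizes.astype(float)
    factors = np.ones(counts.n_samples)
    for k in range(counts.n_samples):
        if k == r:
            continue
        shared = (y[:, k] > 0) & (y[:, r] > 0)
        yk, yr = y[shared, k], y[shared, r]
        if yk.size < min_genes:
            warnings.warn(
                f"sample {counts.sample_ids[k]!r}: only {yk.size} genes shared with "
                "the reference survive; TMM factor set to 1",
                stacklevel=2,
            )
            continue
        pk, pr = yk / N[k], yr / N[r]
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        w = 1.0 / ((N[k] - yk) / (N[k] * yk) + (N[r] - yr) / (N[r] * yr))
        keep = _trim_keep_mask(m, trim_m) & _trim_keep_mask(a, trim_a)
        if keep.sum() < min_genes:
            warnings.warn(
                f"sample {counts.sample_ids[k]!r}: fewer than {min_genes} genes "
                "survive trimming; TMM factor set to 1",
                stacklevel=2,
            )
            continue
        factors[k] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        sample_ids=counts.sample_ids,
        factor=factors,
        effective_library_size=N * factors,
        reference_sample=reference,
    )
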