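"""Probe-level expression preprocessing.

Background correction follows the normal-background + exponential-signal
convolution ("normexp") model: observed intensity X = B + S with
B ~ N(mu, sigma^2) and S ~ Exp(rate).  Each value is replaced by the
posterior mean E[S | X = x], which is strictly positive and monotone in x.
Quantile normalization forces every array onto the rank-wise mean
distribution; present/absent filtering then drops probes that the platform's
detection rule calls absent.

Beadchip inputs are assumed already background-subtracted by the vendor
software; an offset before log2 (default 16) guards against non-positive
values in that case.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import ExpressionMatrix

logger = logging.getLogger("retroarray")


@dataclass(frozen=True)
class NormexpParams:
    """Per-array convolution parameters.

    bg_mean/bg_sd parameterise the normal background; signal_rate is the
    exponential rate (1/mean) of the true signal.
    """

    bg_mean: float
    bg_sd: float
    signal_rate: float

    def __post_init__(self):
        if self.signal_rate <= 0:
            raise ValueError("signal rate must be positive")
        if self.bg_sd < 0:
            raise ValueError("background sd must be non-negative")


def normexp_posterior_mean(x, params: NormexpParams):
    """E[signal | observed x] under the normexp convolution model."""
    x = np.asarray(x, dtype=float)
    alpha = 1.0 / params.signal_rate  # signal mean
    sigma = params.bg_sd
    mu_sf = x - params.bg_mean - sigma ** 2 / alpha
    if sigma == 0:
        # degenerate background: signal is max(x - mu, 0) but keep positivity
        return np.maximum(mu_sf, np.finfo(float).tiny)
    z = mu_sf / sigma
    # sigma * phi(z)/Phi(z) computed in log space for stability in the far tail
    log_ratio = norm.logpdf(z) - norm.logcdf(z)
    return mu_sf + sigma * np.exp(log_ratio)


def estimate_normexp_params(column) -> NormexpParams:
    """Moments-based estimate of per-array normexp parameters.

    Matches the first three moments of X = B + S: E[X] = mu + alpha,
    Var[X] = sigma^2 + alpha^2, third central moment = 2 alpha^3.
    """
    x = np.asarray(column, dtype=float)
    m, v = x.mean(), x.var()
    m3 = np.mean((x - m) ** 3)
    alpha = (max(m3, 1e-12) / 2.0) ** (1.0 / 3.0)
    sigma_sq = v - alpha ** 2
    if sigma_sq <= 0:
        # nearly pure exponential signal: keep a token background spread
        sigma_sq = 0.01 * v if v > 0 else 1e-6
        alpha = math.sqrt(max(v - sigma_sq, 1e-12))
    mu = m - alpha
    return NormexpParams(bg_mean=mu, bg_sd=math.sqrt(sigma_sq), signal_rate=1.0 / alpha)


def normexp_background_correct(
    matrix: ExpressionMatrix,
    params: Optional[Dict[str, NormexpParams]] = None,
) -> ExpressionMatrix:
    """Background-correct a raw-scale matrix column by column.

    ``params`` maps sample id -> NormexpParams; missing entries are estimated
    from that array by the moments method.
    """
    if matrix.scale != "raw":
        raise ValueError("background correction expects a raw-scale matrix")
    params = params or {}
    corrected = {}
    for sample in matrix.values.columns:
        col = matrix.values[sample].to_numpy(dtype=float)
        p = params.get(sample) or estimate_normexp_params(col)
        corrected[sample] = normexp_posterior_mean(col, p)
    out = pd.DataFrame(corrected, index=matrix.values.index)
    return matrix.with_values(out, "raw")


def log2_transform(matrix: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """log2(value + offset); flips the scale flag to 'log2'."""
    if matrix.scale != "raw":
        raise ValueError("matrix is already log2 scale")
    shifted = matrix.values.to_numpy(dtype=float) + offset
    if (shifted <= 0).any():
        raise ValueError(
            "non-positive values after offset; increase the log2 offset"
        )
    out = pd.DataFrame(
        np.log2(shifted), index=matrix.values.index, columns=matrix.values.columns
    )
    return matrix.with_values(out, "log2")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column onto the rank-wise mean distribution.

    After normalization the sorted values of every column are identical.
    Ties within a column receive the mean of the reference values their ranks
    span.  A single-column matrix is returned unchanged.
    """
    values = matrix.values.to_numpy(dtype=float)
    n_probes, n_samples = values.shape
    if n_samples < 2:
        return matrix
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        sort_idx = order[:, j]
        rank_of = np.empty(n_probes, dtype=int)
        rank_of[sort_idx] = np.arange(n_probes)
        # a tie group takes the mean of the reference values its ranks span
        _, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        ref_sums = np.bincount(inverse, weights=reference[rank_of])
        out[:, j] = (ref_sums / counts)[inverse]
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(df)


def filter_absent_illumina(
    matrix: ExpressionMatrix, detection_alpha: float = 0.01
) -> ExpressionMatrix:
    """Drop probes called absent in every sample.

    Detection values may be p-values (present iff p < detection_alpha) or
    0/1 booleans.  Retained rows keep their order and values.
    """
    if matrix.detection is None:
        raise ValueError("no detection matrix attached")
    det = matrix.detection.to_numpy(dtype=float)
    if ((det == 0) | (det == 1)).all():
        present = det.astype(bool)
    else:
        present = det < detection_alpha
    keep = present.any(axis=1)
    removed = int((~keep).sum())
    if removed:
        logger.info("removed %d probes absent in all samples", removed)
    return matrix.subset(matrix.values.index[keep])


def filter_present_affymetrix(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Keep probes above the per-array median in at least half of one
    condition's arrays.

    "Above" is strict; "half" rounds up for odd array counts.
    """
    groups = matrix.condition_samples()
    for cond, samples in groups.items():
        if not samples:
            raise ValueError(f"condition {cond!r} has no samples")
    values = matrix.values
    above = values.gt(values.median(axis=0), axis=1)  # per-array medians
    keep = np.zeros(len(values), dtype=bool)
    for cond, samples in groups.items():
        need = math.ceil(len(samples) / 2)
        keep |= (above[samples].sum(axis=1) >= need).to_numpy()
    removed = int((~keep).sum())
    if removed:
        logger.info("removed %d probes failing the present filter", removed)
    return matrix.subset(values.index[keep])


def preprocess_illumina(
    matrix: ExpressionMatrix, log2_offset: float = 16.0, detection_alpha: float = 0.01
) -> ExpressionMatrix:
    """Beadchip route: offset log2 transform, quantile normalize, drop
    probes absent everywhere."""
    out = log2_transform(matrix, offset=log2_offset)
    out = quantile_normalize(out)
    if out.detection is not None:
        out = filter_absent_illumina(out, detection_alpha)
    return out


def preprocess_affymetrix(
    matrix: ExpressionMatrix,
    normexp: Optional[Dict[str, NormexpParams]] = None,
) -> ExpressionMatrix:
    """GeneChip route: normexp background correction, log2, quantile
    normalize, median present filter.  Probeset summarisation is deliberately
    skipped; everything stays at probe level."""
    out = normexp_background_correct(matrix, normexp)
    out = log2_transform(out)
    out = quantile_normalize(out)
    return filter_present_affymetrix(out)
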