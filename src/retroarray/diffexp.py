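"""Two-condition probe-level differential expression.

The model is the standard empirical-Bayes moderated t: per-probe pooled
variances s2 with df residual degrees of freedom are assumed to follow a
scaled-F prior, s2 ~ s0^2 F(df, d0).  The prior (d0, s0^2) is estimated by
matching the moments of log(s2); posterior variances

    s2_post = (d0 * s0^2 + df * s2) / (d0 + df)

shrink each probe's variance toward the prior, and the moderated t-statistic
t = log_fc / sqrt(s2_post * (1/n1 + 1/n2)) is referred to a t distribution
with df + d0 degrees of freedom.  Multiple testing is controlled by
Benjamini-Hochberg step-up adjustment, and probes are called up/down when the
fold change passes the threshold (inclusive) and the adjusted p-value the
significance level (strict by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import norm, t as t_dist

from .model import ExpressionMatrix, Parameters, RepeatProbeAnnotation, percent

logger = logging.getLogger("retroarray")

#: estimated prior df above this are treated as infinite
D0_CAP = 500.0


@dataclass(frozen=True)
class ModerationFit:
    """Estimated variance prior: d0 prior degrees of freedom (may be inf),
    s0_sq prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not self.d0 >= 0:
            raise ValueError("d0 must be >= 0")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be > 0")


def fit_two_group(
    matrix: ExpressionMatrix, case: str, control: str
) -> pd.DataFrame:
    """Per-probe two-group statistics on a log2-scale matrix.

    Returns a DataFrame indexed by probe id with columns log_fc (case minus
    control, log2), A (grand mean), s2 (pooled within-group variance), df,
    n_case, n_control.
    """
    if matrix.scale != "log2":
        raise ValueError("differential expression expects a log2-scale matrix")
    groups = matrix.condition_samples()
    for label in (case, control):
        if label not in groups or not groups[label]:
            raise ValueError(f"condition {label!r} has no samples")
    x1 = matrix.values[groups[case]].to_numpy(dtype=float)
    x0 = matrix.values[groups[control]].to_numpy(dtype=float)
    n1, n0 = x1.shape[1], x0.shape[1]
    if min(n1, n0) < 2:
        warnings.warn(
            "a condition has a single sample; variance pooled from the other group"
        )
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x0 - m0[:, None]) ** 2).sum(axis=1)
    df = n1 + n0 - 2
    s2 = ss / df if df > 0 else np.zeros_like(ss)
    grand = np.hstack([x1, x0]).mean(axis=1)
    return pd.DataFrame(
        {
            "log_fc": m1 - m0,
            "A": grand,
            "s2": s2,
            "df": float(df),
            "n_case": n1,
            "n_control": n0,
        },
        index=matrix.values.index.rename("probe_id"),
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on a decreasing function)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> ModerationFit:
    """Moment-matching fit of the scaled-F variance prior from log(s2)."""
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2 or df <= 0:
        raise ValueError("need >=2 positive variances with df > 0")
    z = np.log(positive)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = e.mean()
    n = e.size
    e_var = ((e - e_bar) ** 2).sum() / (n - 1) - polygamma(1, df / 2.0)
    if e_var <= 0:
        return ModerationFit(d0=np.inf, s0_sq=float(np.exp(e_bar)))
    d0 = 2.0 * _trigamma_inverse(float(e_var))
    if d0 > D0_CAP:
        return ModerationFit(d0=np.inf, s0_sq=float(np.exp(e_bar)))
    s0_sq = np.exp(e_bar + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return ModerationFit(d0=float(d0), s0_sq=float(s0_sq))


def moderate(
    fit: pd.DataFrame, prior: Optional[ModerationFit] = None
) -> Tuple[ModerationFit, pd.DataFrame]:
    """Shrink variances and compute moderated t and two-sided p per probe.

    ``fit`` is the output of :func:`fit_two_group`.  ``prior`` overrides the
    estimated prior (d0=0 reproduces the ordinary pooled t; d0=inf gives all
    probes the common denominator s0_sq).  Probes with no residual degrees of
    freedom and no prior information get p = 1.
    """
    s2 = fit["s2"].to_numpy(dtype=float)
    df = float(fit["df"].iloc[0])
    n1 = int(fit["n_case"].iloc[0])
    n0 = int(fit["n_control"].iloc[0])
    if prior is None:
        if df <= 0 or not (s2 > 0).any():
            warnings.warn("no usable variances; falling back to ordinary t")
            prior = ModerationFit(d0=0.0, s0_sq=1.0) if df > 0 else None
            if prior is None:
                out = fit.copy()
                out["s2_post"] = s2
                out["t_mod"] = 0.0
                out["p"] = 1.0
                return ModerationFit(d0=0.0, s0_sq=1.0), out
        else:
            prior = estimate_prior(s2, df)
    d0, s0_sq = prior.d0, prior.s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    elif d0 == 0:
        s2_post = s2.copy()
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    log_fc = fit["log_fc"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log_fc / np.where(se > 0, se, 1.0), 0.0)
    total_df = df + d0
    if total_df <= 0:
        p = np.ones_like(t_mod)
    elif np.isinf(total_df):
        p = 2.0 * norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * t_dist.sf(np.abs(t_mod), total_df)
    p = np.where(se > 0, p, 1.0)
    out = fit.copy()
    out["s2_post"] = s2_post
    out["t_mod"] = t_mod
    out["p"] = p
    return prior, out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def call_changed(results: pd.DataFrame, params: Parameters) -> pd.DataFrame:
    """Add the up/down/unchanged call column.

    Fold-change threshold is inclusive ("at least n fold"); the significance
    cut is strict (adj_p < alpha) unless params.alpha_inclusive.
    """
    if "adj_p" not in results.columns:
        raise ValueError("adjusted p-values not computed; run bh_adjust first")
    log_cut = np.log2(params.fold_threshold)
    if params.alpha_inclusive:
        significant = results["adj_p"] <= params.alpha
    else:
        significant = results["adj_p"] < params.alpha
    call = np.where(
        significant & (results["log_fc"] >= log_cut), "up",
        np.where(significant & (results["log_fc"] <= -log_cut), "down", "unchanged"),
    )
    out = results.copy()
    out["call"] = call
    return out


def run_de(
    matrix: ExpressionMatrix,
    case: str,
    control: str,
    params: Optional[Parameters] = None,
    prior: Optional[ModerationFit] = None,
) -> Tuple[ModerationFit, pd.DataFrame]:
    """fit_two_group -> moderate -> bh_adjust -> call_changed in one step."""
    params = params or Parameters()
    fit = fit_two_group(matrix, case, control)
    prior, results = moderate(fit, prior)
    results["adj_p"] = bh_adjust(results["p"].to_numpy())
    results = call_changed(results, params)
    return prior, results


def summarize_by_element(
    results: pd.DataFrame, annotations: List[RepeatProbeAnnotation]
) -> Tuple[pd.DataFrame, dict]:
    """Per-element change counts over sense-detecting repeat probes.

    Returns (table, totals).  The table has one row per element with columns
    element, family, class, n_probes_expressed, n_up, n_down.  Totals report
    the changed/expressed repeat probe counts and their percentage share.
    Every probe in ``results`` must have an annotation record.
    """
    by_id = {a.probe_id: a for a in annotations}
    missing = [pid for pid in results.index if pid not in by_id]
    if missing:
        raise ValueError(f"probes without annotation record: {missing[:5]}")
    if "call" not in results.columns:
        raise ValueError("calls not computed; run call_changed first")
    rows: dict = {}
    n_sense = 0
    n_changed = 0
    for pid, row in results.iterrows():
        a = by_id[pid]
        if not (a.is_repeat and a.detects_sense):
            continue
        n_sense += 1
        entry = rows.setdefault(
            a.element,
            {"family": a.family, "class": a.repeat_class,
             "n_probes_expressed": 0, "n_up": 0, "n_down": 0},
        )
        entry["n_probes_expressed"] += 1
        if row["call"] == "up":
            entry["n_up"] += 1
            n_changed += 1
        elif row["call"] == "down":
            entry["n_down"] += 1
            n_changed += 1
    table = pd.DataFrame(
        [
            {"element": el, **v}
            for el, v in sorted(rows.items())
        ],
        columns=["element", "family", "class", "n_probes_expressed", "n_up", "n_down"],
    )
    totals = {
        "n_expressed_repeat_probes": n_sense,
        "n_changed_repeat_probes": n_changed,
        "pct_changed_repeat_probes": (
            percent(n_changed, n_sense) if n_sense else 0.0
        ),
    }
    return table, totals
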