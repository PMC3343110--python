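"""Population-level comparison of probe groups.

The central question is whether a set of repeat probes (one element, family
or class) behaves as a distinct population from the expressed non-repeat
probes in the same experiment, judged on log fold changes (the M axis of an
MA plot).  Comparison is by the two-sided Wilcoxon-Mann-Whitney rank-sum
test: exact by dynamic programming over the midrank distribution for small
totals, and a tie- and continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .model import RepeatProbeAnnotation

logger = logging.getLogger("retroarray")

#: largest pooled sample size for which the exact null distribution is used
EXACT_LIMIT = 30


@dataclass(frozen=True)
class PopulationTestResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    U: float
    p_two_sided: float
    method: str  # 'exact' or 'normal_approx'

    def __post_init__(self):
        if not 0 <= self.U <= self.n_a * self.n_b:
            raise ValueError("U outside [0, n_a * n_b]")


@dataclass(frozen=True)
class GroupSpec:
    """Selector for a probe population: exactly one of element / family /
    repeat_class set."""

    element: Optional[str] = None
    family: Optional[str] = None
    repeat_class: Optional[str] = None

    def __post_init__(self):
        if sum(x is not None for x in (self.element, self.family, self.repeat_class)) != 1:
            raise ValueError("set exactly one of element, family, repeat_class")

    @property
    def label(self) -> str:
        return self.element or self.family or self.repeat_class


def ma_table(results: pd.DataFrame) -> pd.DataFrame:
    """The numeric table behind an MA plot: probe_id, A, M."""
    out = pd.DataFrame(
        {"A": results["A"], "M": results["log_fc"]}, index=results.index
    )
    return out.rename_axis("probe_id")


def _exact_ranksum_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Exact two-sided p for the rank sum of a uniformly chosen subset.

    DP over the midrank multiset (doubled to stay integral); p is the
    doubled smaller tail, capped at 1.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    n = len(r2)
    # dp[k, s] = number of size-k subsets with doubled rank sum s
    dp = np.zeros((n_a + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for val in r2:
        for k in range(min(n_a, n) - 1, -1, -1):
            row = dp[k]
            nz = np.nonzero(row)[0]
            if nz.size:
                dp[k + 1, nz + val] += row[nz]
    counts = dp[n_a]
    denom = counts.sum()
    w2 = int(np.rint(2.0 * w_obs))
    lower = counts[: w2 + 1].sum() / denom
    upper = counts[w2:].sum() / denom
    return float(min(1.0, 2.0 * min(lower, upper)))


def rank_sum_test(values_a: Sequence[float], values_b: Sequence[float]) -> PopulationTestResult:
    """Two-sided Wilcoxon-Mann-Whitney test with midranks for ties.

    Exact (subset enumeration via dynamic programming) when
    n_a + n_b <= 30, else a normal approximation with tie and continuity
    corrections.  Identical pooled values give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups need at least one value")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    w_a = ranks[:n_a].sum()
    u = w_a - n_a * (n_a + 1) / 2.0
    if np.all(pooled == pooled[0]):
        return PopulationTestResult("a", "b", n_a, n_b, float(u), 1.0, "exact")
    if n <= EXACT_LIMIT:
        p = _exact_ranksum_p(ranks, n_a, w_a)
        method = "exact"
    else:
        mean_u = n_a * n_b / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1.0))
        var_u = n_a * n_b / 12.0 * (n + 1.0 - tie_term)
        if var_u <= 0:
            p = 1.0
        else:
            z = (abs(u - mean_u) - 0.5) / np.sqrt(var_u)
            p = float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))
        method = "normal_approx"
    return PopulationTestResult("a", "b", n_a, n_b, float(u), p, method)


def density_estimate(
    values: Sequence[float],
    bandwidth="auto",
    grid_size: int = 512,
) -> pd.DataFrame:
    """Gaussian-kernel density on a regular grid spanning data +/- 3 bandwidths.

    ``bandwidth='auto'`` applies Silverman's rule of thumb.  Returns a
    DataFrame with columns x and density; the trapezoid integral is within
    1e-3 of 1.
    """
    x = np.asarray(values, dtype=float)
    if bandwidth == "auto":
        if x.size < 2:
            raise ValueError("auto bandwidth needs at least 2 values")
        sd = x.std(ddof=1)
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        if spread == 0:
            raise ValueError("degenerate data: zero spread")
        bandwidth = 0.9 * spread * x.size ** (-0.2)
    bandwidth = float(bandwidth)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(x.min() - 3 * bandwidth, x.max() + 3 * bandwidth, grid_size)
    dens = norm.pdf((grid[:, None] - x[None, :]) / bandwidth).mean(axis=1) / bandwidth
    return pd.DataFrame({"x": grid, "density": dens})


def compare_probe_populations(
    results: pd.DataFrame,
    annotations: List[RepeatProbeAnnotation],
    group_specs: Sequence[GroupSpec],
) -> List[PopulationTestResult]:
    """Rank-sum tests of selected repeat-probe populations on M values.

    Each selected group (sense-detecting repeat probes matching the selector) is
    tested against the expressed non-repeat probes; an element-level group is
    additionally tested against the rest of its family and of its class.
    Empty groups are skipped with a warning.
    """
    by_id = {a.probe_id: a for a in annotations}
    ann = [by_id[pid] for pid in results.index if pid in by_id]
    m = results["log_fc"]

    def m_of(pids):
        return m.loc[[p for p in pids if p in m.index]].to_numpy()

    nonrepeat = [a.probe_id for a in ann if not a.is_repeat]
    baseline = m_of(nonrepeat)
    sense = [a for a in ann if a.is_repeat and a.detects_sense]
    out = []
    for spec in group_specs:
        if spec.element is not None:
            members = [a for a in sense if a.element == spec.element]
        elif spec.family is not None:
            members = [a for a in sense if a.family == spec.family]
        else:
            members = [a for a in sense if a.repeat_class == spec.repeat_class]
        if not members:
            logger.warning("group %s matched no expressed probes; skipped", spec.label)
            continue
        group_m = m_of([a.probe_id for a in members])
        contrasts: List[Tuple[str, np.ndarray]] = [("non-repeat", baseline)]
        if spec.element is not None:
            family = members[0].family
            cls = members[0].repeat_class
            fam_rest = [a for a in sense if a.family == family and a.element != spec.element]
            cls_rest = [a for a in sense if a.repeat_class == cls and a.element != spec.element]
            contrasts.append((f"other {family}", m_of([a.probe_id for a in fam_rest])))
            contrasts.append((f"other {cls}", m_of([a.probe_id for a in cls_rest])))
        for name, other in contrasts:
            if other.size == 0:
                logger.warning(
                    "contrast %s vs %s has an empty comparison group; skipped",
                    spec.label, name,
                )
                continue
            r = rank_sum_test(group_m, other)
            out.append(
                PopulationTestResult(
                    spec.label, name, r.n_a, r.n_b, r.U, r.p_two_sided, r.method
                )
            )
    return out


def population_tests_table(tests: List[PopulationTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": t.group_a, "group_b": t.group_b,
                "n_a": t.n_a, "n_b": t.n_b,
                "U": t.U, "p_two_sided": t.p_two_sided, "method": t.method,
            }
            for t in tests
        ],
        columns=["group_a", "group_b", "n_a", "n_b", "U", "p_two_sided", "method"],
    )
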