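"""Paired cohort comparison statistics and the equivalence-design sample size.

The initial-vs-synthetic endpoint series are paired (the same cases underlie
both), so the paired two-sided t-test is the default; an unpaired mode is
available. The equivalence sample size follows the two one-sided tests
(TOST) normal-approximation formula

    n per group = ceil( 2 sigma^2 (z_{1-alpha} + z_{1-beta/2})^2 / delta^2 )

with alpha the one-sided level of each of the two tests (5% for a stated
two-sided 5% design) and beta = 1 - power; the total is twice the per-group
size. Alternative z-quantile conventions are selectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSeries",
    "EquivalenceDesign",
    "TTestResult",
    "SpearmanResult",
    "t_test_two_sided",
    "spearman",
    "equivalence_sample_size",
]


@dataclass
class PairedSeries:
    """Two equal-length per-case value series: a = initial, b = synthetic."""

    labels: tuple
    a: np.ndarray
    b: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.labels = tuple(self.labels)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("PairedSeries: a and b must be equal-length 1D series")
        if len(self.labels) != self.a.size:
            raise ValueError("PairedSeries: one label per case required")
        if self.a.size < 2:
            raise ValueError("PairedSeries: at least two cases required")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("PairedSeries: values must be finite")


@dataclass
class EquivalenceDesign:
    """Equivalence-trial design parameters.

    sigma: expected SD of the outcome (same units as the margin);
    delta: equivalence margin; alpha: two-sided level; power: 1 - beta.
    """

    sigma: float
    delta: float
    alpha: float = 0.05
    power: float = 0.95

    def __post_init__(self):
        if self.sigma <= 0 or self.delta <= 0 or self.alpha <= 0:
            raise ValueError("EquivalenceDesign: sigma, delta and alpha must be > 0")
        if not (0.0 < self.power < 1.0):
            raise ValueError("EquivalenceDesign: power must lie in (0, 1)")


@dataclass
class TTestResult:
    t: float
    p: float
    mean_difference: float  # sign convention: synthetic - initial (b - a)
    df: float
    degenerate: bool = False  # identical series: t/p undefined


@dataclass
class SpearmanResult:
    rho: float
    p: float
    degenerate: bool = False  # constant series: rho undefined


def t_test_two_sided(series: PairedSeries, paired: bool = True) -> TTestResult:
    """Two-sided t-test of b vs a (paired by default)."""
    diff = series.b - series.a
    mean_diff = float(diff.mean())
    if paired:
        if np.allclose(diff, diff[0]) and np.isclose(diff.std(ddof=1), 0.0):
            return TTestResult(
                t=float("nan"), p=float("nan"), mean_difference=mean_diff,
                df=diff.size - 1, degenerate=True,
            )
        res = sps.ttest_rel(series.b, series.a)
        df = diff.size - 1
    else:
        if np.isclose(series.a.std(ddof=1), 0.0) and np.isclose(series.b.std(ddof=1), 0.0):
            return TTestResult(
                t=float("nan"), p=float("nan"), mean_difference=mean_diff,
                df=2 * series.a.size - 2, degenerate=True,
            )
        res = sps.ttest_ind(series.b, series.a)
        df = float(res.df)
    return TTestResult(
        t=float(res.statistic), p=float(res.pvalue), mean_difference=mean_diff, df=df
    )


def spearman(series: PairedSeries) -> SpearmanResult:
    """Spearman rank correlation (average ranks on ties, t-approximation p)."""
    if series.a.size < 3:
        raise ValueError("spearman: at least three cases required")
    if np.all(series.a == series.a[0]) or np.all(series.b == series.b[0]):
        return SpearmanResult(rho=float("nan"), p=float("nan"), degenerate=True)
    res = sps.spearmanr(series.a, series.b)
    return SpearmanResult(rho=float(res.statistic), p=float(res.pvalue))


def equivalence_sample_size(
    design: EquivalenceDesign, convention: str = "tost"
) -> int:
    """Total number of participants for a two-group equivalence design.

    ``convention`` selects the z-quantile pairing:

    * ``"tost"`` (default): z_{1-alpha} and z_{1-beta/2} — each one-sided
      test at the stated level, power split across the two tests;
    * ``"half-alpha"``: z_{1-alpha/2} and z_{1-beta} — the plain
      two-sample-difference formula applied to the margin.
    """
    beta = 1.0 - design.power
    if convention == "tost":
        z_a = sps.norm.ppf(1.0 - design.alpha)
        z_b = sps.norm.ppf(1.0 - beta / 2.0)
    elif convention == "half-alpha":
        z_a = sps.norm.ppf(1.0 - design.alpha / 2.0)
        z_b = sps.norm.ppf(1.0 - beta)
    else:
        raise ValueError(f"equivalence_sample_size: unknown convention {convention!r}")
    n_per_group = math.ceil(2.0 * design.sigma**2 * (z_a + z_b) ** 2 / design.delta**2)
    return 2 * max(n_per_group, 1)
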