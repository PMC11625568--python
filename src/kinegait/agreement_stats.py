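"""Method-comparison statistics between a test and a reference system.

Given paired per-trial parameter values — ``measured`` from the system under
test and ``actual`` from the reference — the module computes the standard
agreement battery used in concurrent-validity studies:

* Kolmogorov–Smirnov normality check (Lilliefors variant by default, since
  the normal parameters are estimated from the data);
* two-sided paired t-test for a systematic difference;
* accuracy as 100% − MAPE, where MAPE = mean(|measured − actual| / |actual|);
* Pearson product-moment correlation with its two-sided p-value;
* RMSE of the paired differences;
* Bland–Altman analysis: mean difference and limits of agreement (LoA) at
  mean ± 1.96 × sample SD of the differences.

Differences are oriented ``measured − actual`` throughout.  No
multiple-testing correction is applied; p-values are raw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "BlandAltman",
    "AgreementResult",
    "ks_normality",
    "paired_t",
    "accuracy_mape",
    "pearson",
    "rmse",
    "bland_altman",
    "agreement_table",
    "plot_bland_altman",
]


def _pair(measured, actual) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(measured, dtype=float)
    a = np.asarray(actual, dtype=float)
    if m.shape != a.shape or m.ndim != 1:
        raise ValueError("measured and actual must be 1-D of equal length")
    if not (np.isfinite(m).all() and np.isfinite(a).all()):
        raise ValueError("non-finite values in the pair table")
    return m, a


def ks_normality(values, variant: str = "lilliefors") -> float:
    """p-value of a one-sample normality test.

    ``variant="lilliefors"`` (default) uses the Lilliefors correction for
    mean and SD estimated from the sample; ``variant="ks"`` runs the classic
    Kolmogorov–Smirnov test against a normal law with the sample moments
    plugged in as if known (anti-conservative; kept for comparability).
    Constant input has no defined normality and raises.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations for a normality test")
    if np.std(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    if variant == "lilliefors":
        _, p = lilliefors(x, dist="norm")
        return float(p)
    if variant == "ks":
        _, p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        return float(p)
    raise ValueError(f"unknown variant {variant!r}")


def paired_t(measured, actual) -> tuple[float, float]:
    """Two-sided paired t-test on the differences measured − actual.

    Identical vectors return (0.0, 1.0) by convention; nonzero differences
    with zero variance have an infinite t-statistic and raise instead of
    returning a misleading number.
    """
    m, a = _pair(measured, actual)
    if m.size < 2:
        raise ValueError("need at least 2 pairs")
    d = m - a
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, 1.0
        raise ValueError("degenerate: infinite t (constant nonzero differences)")
    t, p = stats.ttest_rel(m, a)
    return float(t), float(p)


def accuracy_mape(measured, actual) -> float:
    """Accuracy in percent: 100 − mean(|measured − actual| / |actual|) × 100."""
    m, a = _pair(measured, actual)
    zero = np.flatnonzero(a == 0)
    if zero.size:
        raise ValueError(
            f"reference value is zero at pair index {zero[0]}: "
            "percentage error undefined"
        )
    mape = float(np.mean(np.abs(m - a) / np.abs(a)) * 100.0)
    return 100.0 - mape


def pearson(measured, actual) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p-value."""
    m, a = _pair(measured, actual)
    if m.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(m) == 0 or np.std(a) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(m, a)
    return float(r), float(p)


def rmse(measured, actual) -> float:
    """Root mean square of the paired differences."""
    m, a = _pair(measured, actual)
    if m.size < 1:
        raise ValueError("need at least 1 pair")
    return float(np.sqrt(np.mean((m - a) ** 2)))


@dataclass
class BlandAltman:
    """Bland–Altman summary: differences against pair means."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray = field(repr=False)
    diffs: np.ndarray = field(repr=False)

    @property
    def inside_fraction(self) -> float:
        """Fraction of points falling inside the limits of agreement."""
        inside = (self.diffs >= self.loa_low) & (self.diffs <= self.loa_high)
        return float(inside.mean())


def bland_altman(measured, actual) -> BlandAltman:
    """Mean difference and ±1.96 × sample-SD limits of agreement."""
    m, a = _pair(measured, actual)
    if m.size < 2:
        raise ValueError("need at least 2 pairs")
    d = m - a
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        mean_diff=mean_diff,
        sd_diff=sd,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
        means=0.5 * (m + a),
        diffs=d,
    )


@dataclass
class AgreementResult:
    """Per-parameter method-comparison summary for one group of pairs."""

    parameter: str
    group: str
    n: int
    mean_measured: float
    sd_measured: float
    mean_actual: float
    sd_actual: float
    t_p: float
    accuracy_pct: float
    pearson_r: float
    r_p: float
    r_significant: bool
    rmse: float
    ba_mean_diff: float
    ba_loa_low: float
    ba_loa_high: float


def _cell_result(parameter: str, group: str, m, a) -> AgreementResult:
    _, t_p = paired_t(m, a)
    r, r_p = pearson(m, a)
    ba = bland_altman(m, a)
    return AgreementResult(
        parameter=parameter,
        group=group,
        n=len(m),
        mean_measured=float(np.mean(m)),
        sd_measured=float(np.std(m, ddof=1)),
        mean_actual=float(np.mean(a)),
        sd_actual=float(np.std(a, ddof=1)),
        t_p=t_p,
        accuracy_pct=accuracy_mape(m, a),
        pearson_r=r,
        r_p=r_p,
        r_significant=bool(r_p < 0.05),
        rmse=rmse(m, a),
        ba_mean_diff=ba.mean_diff,
        ba_loa_low=ba.loa_low,
        ba_loa_high=ba.loa_high,
    )


def agreement_table(pairs: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Full agreement battery per (parameter × group) cell.

    ``pairs`` is tidy with columns parameter, measured, actual and
    optionally group.  For each parameter the statistics are computed on the
    pooled data ("all") and, when group labels exist, separately per group.
    Cells with fewer than ``min_pairs`` pairs are omitted with a warning.
    """
    required = {"parameter", "measured", "actual"}
    if not required.issubset(pairs.columns):
        raise ValueError(f"pair table must have columns {sorted(required)}")
    groups = (
        sorted(pairs["group"].dropna().unique()) if "group" in pairs.columns else []
    )
    results: list[AgreementResult] = []
    for parameter, sub in pairs.groupby("parameter", sort=False):
        cells = [("all", sub)] + [
            (g, sub[sub["group"] == g]) for g in groups
        ]
        for gname, cell in cells:
            if len(cell) < min_pairs:
                warnings.warn(
                    f"cell ({parameter!r}, {gname!r}) has {len(cell)} pairs "
                    f"(< {min_pairs}); omitted",
                    stacklevel=2,
                )
                continue
            results.append(
                _cell_result(
                    str(parameter),
                    gname,
                    cell["measured"].to_numpy(float),
                    cell["actual"].to_numpy(float),
                )
            )
    return pd.DataFrame([vars(r) for r in results])


def plot_bland_altman(ba: BlandAltman, ax=None, title: str | None = None):
    """Standard Bland–Altman scatter with mean-difference and LoA lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(ba.means, ba.diffs, s=18, alpha=0.7)
    ax.axhline(ba.mean_diff, color="k", lw=1.2)
    for loa in (ba.loa_low, ba.loa_high):
        ax.axhline(loa, color="k", lw=1.0, ls="--")
    ax.set_xlabel("mean of the two systems")
    ax.set_ylabel("difference (test − reference)")
    if title:
        ax.set_title(title)
    return ax
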