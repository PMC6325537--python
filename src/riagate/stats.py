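"""Estimation statistics: Bayesian-bootstrap means, effect-size CIs,
regression and one-way F tests, Bonferroni correction.

The estimation approach reports effect sizes rather than bare p values: a
comparison is summarized by the observed mean difference, its 95%
percentile confidence interval, and the full bootstrap distribution of
the mean.  The bootstrap weights each observation by a gamma draw with
shape (n - 1)/n and scale 1, normalized to sum to one per replicate; the
canonical Bayesian bootstrap (unit-exponential weights, i.e. flat
Dirichlet) is available behind a flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sps


def bayesian_bootstrap_means(
    values,
    n_boot: int = 2500,
    seed: int | np.random.Generator = 0,
    canonical: bool = False,
) -> np.ndarray:
    """Distribution of weighted means under the Bayesian bootstrap.

    For each of ``n_boot`` replicates, one weight per observation is drawn
    from gamma(shape=(n-1)/n, scale=1) (or exponential(1) when
    ``canonical``), the weights are normalized to sum to one, and the
    weighted mean recorded.  A single observation yields a degenerate
    distribution at its value.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise ValueError("values must be a non-empty 1-D array")
    if not np.all(np.isfinite(values)):
        raise ValueError("values contain non-finite entries")
    n = len(values)
    if n == 1:
        return np.full(n_boot, values[0])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = 1.0 if canonical else (n - 1) / n
    w = rng.gamma(shape, 1.0, size=(n_boot, n))
    w /= w.sum(axis=1, keepdims=True)
    return w @ values


@dataclass
class EstimationResult:
    """Mean difference with its bootstrap distribution and 95% CI."""

    mean_test: float
    mean_control: float
    sd_test: float
    sd_control: float
    mean_difference: float
    ci_low: float
    ci_high: float
    n_test: int
    n_control: int
    paired: bool
    n_boot: int
    seed: int
    bootstrap: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("bootstrap")
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def save_bootstrap_csv(self, path) -> None:
        np.savetxt(path, self.bootstrap, header="bootstrap_mean_difference", comments="")

    def excludes_zero(self) -> bool:
        return (self.ci_low > 0.0) or (self.ci_high < 0.0)


def estimation_difference(
    test_values,
    control_values,
    paired: bool = False,
    n_boot: int = 2500,
    seed: int = 0,
    canonical: bool = False,
) -> EstimationResult:
    """Estimation-plot comparison of a test group against a control.

    Unpaired: the difference of independently bootstrapped group means.
    Paired: the bootstrap of the per-pair differences (the within-group
    difference).  The CI is the 2.5/97.5 percentile interval of the
    bootstrap distribution.
    """
    test = np.asarray(test_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if paired and len(test) != len(control):
        raise ValueError("paired comparison requires equal lengths")
    rng = np.random.default_rng(seed)
    if paired:
        boot = bayesian_bootstrap_means(test - control, n_boot, rng, canonical)
    else:
        boot_test = bayesian_bootstrap_means(test, n_boot, rng, canonical)
        boot_control = bayesian_bootstrap_means(control, n_boot, rng, canonical)
        boot = boot_test - boot_control
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return EstimationResult(
        mean_test=float(test.mean()),
        mean_control=float(control.mean()),
        sd_test=float(test.std(ddof=1)) if len(test) > 1 else 0.0,
        sd_control=float(control.std(ddof=1)) if len(control) > 1 else 0.0,
        mean_difference=float(test.mean() - control.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_test=len(test),
        n_control=len(control),
        paired=paired,
        n_boot=n_boot,
        seed=int(seed),
        bootstrap=boot,
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    F: float
    df: tuple
    p: float
    perfect_fit: bool = False


def regression_F(x, y) -> RegressionResult:
    """Ordinary least-squares line with the regression F test.

    F = MS_regression / MS_residual on (1, n - 2) degrees of freedom.  A
    perfect fit (zero residual sum of squares) reports infinite F with the
    ``perfect_fit`` flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")
    fit = sps.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    ss_res = float(resid @ resid)
    ss_reg = float(np.sum((fit.intercept + fit.slope * x - y.mean()) ** 2))
    df = (1, n - 2)
    scale = max(ss_reg + ss_res, 1.0)
    if ss_res <= 1e-14 * scale:
        return RegressionResult(fit.slope, fit.intercept, np.inf, df, 0.0, True)
    F = ss_reg / (ss_res / df[1])
    p = float(sps.f.sf(F, *df))
    return RegressionResult(float(fit.slope), float(fit.intercept), float(F), df, p)


def oneway_F(groups) -> tuple[float, tuple, float]:
    """One-way ANOVA across groups: returns (F, (df_between, df_within), p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need at least two groups of at least two values")
    F, p = sps.f_oneway(*groups)
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    return float(F), (k - 1, n_total - k), float(p)


def bonferroni_adjust(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni-corrected p values: min(1, m * p)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = len(p)
    return np.minimum(1.0, m * p)


def plot_estimation(result: EstimationResult, ax=None, label: str = ""):
    """Basic estimation plot: the bootstrap distribution with the CI and mean."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 4))
    ax.violinplot([result.bootstrap], positions=[0], showextrema=False)
    ax.plot(0, result.mean_difference, "ko")
    ax.vlines(0, result.ci_low, result.ci_high, colors="k", linewidth=2)
    ax.axhline(0.0, color="gray", linewidth=0.5, linestyle="--")
    ax.set_xticks([0])
    ax.set_xticklabels([label or "difference"])
    ax.set_ylabel("mean difference")
    return ax
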