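"""Linear regression, Bland-Altman agreement, and paired comparisons.

Conventions: differences are first-argument-minus-second throughout, and the
limits of agreement use the fixed 1.96 multiplier on the sample standard
deviation (n−1 denominator) — no small-sample t correction — matching the
structure ``bias ± 1.96·SD`` used when agreement is reported alongside a fitted
model.  A model refit by ordinary least squares with an intercept has zero mean
residual by construction, which is why a fitted-vs-observed Bland-Altman bias of
exactly 0 is expected on the fitting cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

LOA_MULTIPLIER = 1.96


class AgreementError(ValueError):
    pass


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    pearson_r: float
    n: int
    degenerate: bool = False  # constant y: slope 0, r reported as 0

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, float) + self.intercept


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement between two paired series; differences are a − b."""

    bias: float
    loa_lower: float
    loa_upper: float
    sd_diff: float
    n: int


@dataclass(frozen=True)
class PairedTestResult:
    t_statistic: float
    p_value: float
    mean_difference: float  # a − b
    n: int


def fit_linear(x, y) -> LinearFit:
    """Ordinary least squares with intercept, plus Pearson r on the same pairs.

    A constant ``y`` is a documented degenerate case (slope 0, r reported as 0
    with ``degenerate=True``); a constant ``x`` is an error.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise AgreementError("x and y must be equal-length 1D series")
    if len(x) < 2:
        raise AgreementError("need at least 2 pairs")
    if np.ptp(x) == 0:
        raise AgreementError("x is constant; slope undefined")
    if np.ptp(y) == 0:
        return LinearFit(
            slope=0.0, intercept=float(y[0]), pearson_r=0.0, n=len(x), degenerate=True
        )
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        n=len(x),
    )


def bland_altman(a, b) -> BlandAltmanResult:
    """Bias and 1.96·SD limits of agreement of the paired differences a − b."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise AgreementError("series must be equal-length 1D arrays")
    if len(a) < 2:
        raise AgreementError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_lower=bias - LOA_MULTIPLIER * sd,
        loa_upper=bias + LOA_MULTIPLIER * sd,
        sd_diff=sd,
        n=len(a),
    )


def paired_t(a, b) -> PairedTestResult:
    """Two-sided paired Student's t-test on the differences a − b."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise AgreementError("series must be equal-length 1D arrays")
    if len(a) < 2:
        raise AgreementError("need at least 2 pairs")
    d = a - b
    if np.ptp(d) == 0:
        raise AgreementError("zero-variance differences: paired t undefined")
    res = stats.ttest_rel(a, b)
    return PairedTestResult(
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_difference=float(d.mean()),
        n=len(a),
    )


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def scatter_with_fit(x, y, fit: LinearFit, xlabel: str, ylabel: str, path) -> None:
    """Scatter of (x, y) with the fitted line and r annotation, saved to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, color="tab:blue")
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, fit.predict(xs), "k-", lw=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    sign = "+" if fit.intercept >= 0 else "−"
    ax.set_title(
        f"y = {fit.slope:.3g}x {sign} {abs(fit.intercept):.3g}   r = {fit.pearson_r:.2f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def bland_altman_plot(a, b, result: BlandAltmanResult, label_a: str, label_b: str, path) -> None:
    """Bland-Altman plot (mean vs difference a − b) with bias and LOA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2, a - b, color="tab:blue")
    for yv, style in (
        (result.bias, "k-"),
        (result.loa_lower, "k--"),
        (result.loa_upper, "k--"),
    ):
        ax.axhline(yv, ls=style[1:], color="k", lw=1)
    ax.set_xlabel(f"mean of {label_a} and {label_b}")
    ax.set_ylabel(f"{label_a} − {label_b}")
    ax.set_title(
        f"bias {result.bias:.2f}, LOA [{result.loa_lower:.2f}, {result.loa_upper:.2f}]"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
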