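"""Human-vs-automated agreement statistics.

For each periocular metric, agreement between two raters (e.g. a human
annotator and the automated pipeline) is summarised three ways:

- mean absolute error (MAE) of the paired differences, with the sample SD of
  the absolute differences;
- Bland-Altman analysis: bias = mean difference, limits of agreement (LoA) =
  bias +/- 1.96 * SD of the differences, with t-based 95% confidence
  intervals for the bias (SE = s/sqrt(n)) and for each LoA (the standard
  SE approximation s * sqrt(3/n));
- intraclass correlation ICC(A,1): single measures, absolute agreement,
  two-way model, from the subjects-by-raters ANOVA decomposition, with the
  F-based confidence interval of McGraw & Wong and an F test of ICC = 0.

Bilateral metrics (MRD1, MRD2, PFH, HPA) are pooled across eyes — each face
contributes a right-eye and a left-eye pair — while the central distances
(IPD, IICD, OICD) contribute one pair per face. Pooled pairs are treated as
independent observations, matching common clinical practice even though the
two eyes of one face are correlated; pass per-face records directly for a
sensitivity analysis without pooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateIccError, ValidationError
from .measure import BILATERAL_METRICS, CENTRAL_METRICS, MeasurementRecord

ALL_METRICS = BILATERAL_METRICS + CENTRAL_METRICS

#: Reliability interpretation thresholds for ICC point estimates.
ICC_BANDS = ((0.5, "poor"), (0.75, "moderate"), (0.9, "good"), (np.inf, "excellent"))


@dataclass
class PairedMeasurements:
    """Aligned (rater_A, rater_B) values for one metric, in mm."""

    metric: str
    a: np.ndarray
    b: np.ndarray
    pooling: str = "per-face"  # "per-eye" for bilateral metrics

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValidationError(
                f"paired arrays must be equal-length 1D; got {self.a.shape} vs {self.b.shape}"
            )
        if np.isnan(self.a).any() or np.isnan(self.b).any():
            raise ValidationError(f"missing entries in pairs for {self.metric!r}")

    @property
    def n(self) -> int:
        return len(self.a)


def pool_bilateral(
    records_a: Sequence[MeasurementRecord],
    records_b: Sequence[MeasurementRecord],
) -> dict[str, PairedMeasurements]:
    """Build per-metric pairs from two index-aligned record lists.

    Bilateral metrics emit two pairs per face (right then left eye);
    central metrics emit one.
    """
    if len(records_a) != len(records_b):
        raise ValidationError(
            f"misaligned record lists: {len(records_a)} vs {len(records_b)}"
        )
    if not records_a:
        raise ValidationError("no records to pool")
    out: dict[str, PairedMeasurements] = {}
    for metric in BILATERAL_METRICS:
        a = [r.value(metric, side) for r in records_a for side in ("right", "left")]
        b = [r.value(metric, side) for r in records_b for side in ("right", "left")]
        out[metric] = PairedMeasurements(metric, np.array(a), np.array(b), "per-eye")
    for metric in CENTRAL_METRICS:
        a = [r.value(metric) for r in records_a]
        b = [r.value(metric) for r in records_b]
        out[metric] = PairedMeasurements(metric, np.array(a), np.array(b), "per-face")
    return out


def mean_absolute_error(pairs: PairedMeasurements) -> tuple[float, float]:
    """MAE of the paired differences and the sample SD of |A - B|."""
    if pairs.n < 1:
        raise ValidationError("MAE requires at least one pair")
    abs_diff = np.abs(pairs.a - pairs.b)
    sd = float(abs_diff.std(ddof=1)) if pairs.n > 1 else 0.0
    return float(abs_diff.mean()), sd


@dataclass
class BlandAltmanResult:
    bias: float
    bias_ci: tuple[float, float]
    loa_lower: float
    loa_lower_ci: tuple[float, float]
    loa_upper: float
    loa_upper_ci: tuple[float, float]
    sd_diff: float
    n: int
    means: np.ndarray  # per-pair (A+B)/2, for plotting
    diffs: np.ndarray  # per-pair A-B, for plotting


def bland_altman(pairs: PairedMeasurements, ci_level: float = 0.95) -> BlandAltmanResult:
    """Bias and 1.96-SD limits of agreement with t-based confidence intervals."""
    if pairs.n < 3:
        raise ValidationError("Bland-Altman requires at least 3 pairs")
    d = pairs.a - pairs.b
    n = len(d)
    bias = float(d.mean())
    s = float(d.std(ddof=1))
    tcrit = float(stats.t.ppf(0.5 + ci_level / 2.0, n - 1))
    se_bias = s / np.sqrt(n)
    se_loa = s * np.sqrt(3.0 / n)
    lower, upper = bias - 1.96 * s, bias + 1.96 * s
    return BlandAltmanResult(
        bias=bias,
        bias_ci=(bias - tcrit * se_bias, bias + tcrit * se_bias),
        loa_lower=lower,
        loa_lower_ci=(lower - tcrit * se_loa, lower + tcrit * se_loa),
        loa_upper=upper,
        loa_upper_ci=(upper - tcrit * se_loa, upper + tcrit * se_loa),
        sd_diff=s,
        n=n,
        means=(pairs.a + pairs.b) / 2.0,
        diffs=d,
    )


def icc_band(icc: float) -> str:
    for upper, name in ICC_BANDS:
        if icc < upper:
            return name
    return "excellent"


@dataclass
class IccResult:
    icc: float
    ci: tuple[float, float]
    p_value: float
    band: str
    msr: float
    msc: float
    mse: float
    n: int
    k: int = 2


def icc_absolute_single(
    pairs: PairedMeasurements, ci_level: float = 0.95
) -> IccResult:
    """ICC(A,1): single measures, absolute agreement, two-way model.

    Mean squares come from the subjects-by-raters two-way ANOVA: MSR (rows =
    subjects), MSC (columns = raters), MSE (interaction/residual). The point
    estimate is (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE)); the
    confidence interval follows McGraw & Wong's F-based procedure, and the
    p-value tests ICC = 0 with F = MSR/MSE on (n-1, (n-1)(k-1)) df.
    """
    if pairs.n < 3:
        raise ValidationError("ICC requires at least 3 subjects")
    y = np.column_stack([pairs.a, pairs.b])
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or np.isclose(msr, 0.0):
        raise DegenerateIccError(
            "no between-subject variance; ICC(A,1) is undefined"
        )
    icc = (msr - mse) / denom

    alpha = 1.0 - ci_level
    if np.isclose(mse, 0.0) and np.isclose(msc, mse):
        ci = (icc, icc)  # perfect agreement: interval collapses
        p = 0.0
    else:
        # McGraw & Wong CI for ICC(A,1)
        fj = msc / mse if mse > 0 else np.inf
        a_ = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
        b_ = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
        if np.isfinite(a_) and np.isfinite(fj):
            v = ((a_ * fj + b_) ** 2) / (
                (a_**2 * fj**2) / (k - 1) + b_**2 / (n - 1)
            )
        else:
            v = n - 1
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = (
            n * (msr - f_l * mse)
            / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
        upper = (
            n * (f_u * msr - mse)
            / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
        )
        ci = (float(lower), float(upper))
        f_stat = msr / mse if mse > 0 else np.inf
        p = float(stats.f.sf(f_stat, n - 1, (n - 1) * (k - 1)))

    return IccResult(
        icc=float(icc),
        ci=ci,
        p_value=p,
        band=icc_band(float(icc)),
        msr=float(msr),
        msc=float(msc),
        mse=float(mse),
        n=n,
        k=k,
    )


@dataclass
class AgreementReport:
    """All agreement statistics for one metric."""

    metric: str
    n: int
    mae: float
    mae_sd: float
    bland_altman: BlandAltmanResult
    icc: IccResult


def agreement_report(pairs: PairedMeasurements, ci_level: float = 0.95) -> AgreementReport:
    mae, mae_sd = mean_absolute_error(pairs)
    return AgreementReport(
        metric=pairs.metric,
        n=pairs.n,
        mae=mae,
        mae_sd=mae_sd,
        bland_altman=bland_altman(pairs, ci_level),
        icc=icc_absolute_single(pairs, ci_level),
    )


def plot_bland_altman(result: BlandAltmanResult, metric: str, path) -> None:
    """Write a Bland-Altman scatter with bias and LoA lines to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.diffs, s=8, alpha=0.6)
    ax.axhline(result.bias, ls="--", color="0.3", label=f"bias {result.bias:.2f}")
    for v in (result.loa_lower, result.loa_upper):
        ax.axhline(v, ls="--", color="k")
    ax.set_xlabel(f"mean of raters ({metric}, mm)")
    ax.set_ylabel("difference A - B (mm)")
    ax.set_title(f"Bland-Altman: {metric}")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
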