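"""Agreement statistics: pooling, MAE, Bland-Altman, ICC(A,1)."""

import numpy as np
import pytest

import periopix as pp
from periopix.agreement import (
    PairedMeasurements,
    bland_altman,
    icc_absolute_single,
    icc_band,
    mean_absolute_error,
    pool_bilateral,
)
from periopix.errors import DegenerateIccError, ValidationError
from periopix.measure import MeasurementRecord


def icc_a1_oracle(a, b):
    """Independent variance-components computation of ICC(A,1), k=2.

    Written directly from the two-way ANOVA sums of squares, no shared code
    with the implementation.
    """
    y = np.column_stack([a, b])
    n, k = y.shape
    xbar = y.mean()
    ss_total = ((y - xbar) ** 2).sum()
    ss_rows = k * ((y.mean(axis=1) - xbar) ** 2).sum()
    ss_cols = n * ((y.mean(axis=0) - xbar) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def _record(vals):
    return MeasurementRecord(*vals, mm_per_px=0.25)


def _random_records(rng, n):
    out = []
    for _ in range(n):
        m1r, m1l = rng.normal(3.7, 0.9, 2)
        m2r, m2l = rng.normal(5.2, 1.2, 2)
        hr, hl = rng.normal(25.3, 2.1, 2)
        ipd, iicd = rng.normal(61, 3.7), rng.normal(33.3, 3.4)
        out.append(
            _record([m1r, m1l, m2r, m2l, m1r + m2r, m1l + m2l, hr, hl, ipd, iicd, iicd + hr + hl])
        )
    return out


def test_pooling_counts_per_metric(rng):
    a = _random_records(rng, 3)
    b = _random_records(rng, 3)
    pairs = pool_bilateral(a, b)
    assert pairs["mrd1"].n == 6 and pairs["mrd1"].pooling == "per-eye"
    assert pairs["ipd"].n == 3 and pairs["ipd"].pooling == "per-face"
    one = pool_bilateral(a[:1], b[:1])
    assert one["mrd1"].n == 2 and one["ipd"].n == 1


def test_pooled_mean_matches_flattened_values(rng):
    a = _random_records(rng, 10)
    b = _random_records(rng, 10)
    pairs = pool_bilateral(a, b)
    naive = [v for r in a for v in (r.mrd1_right, r.mrd1_left)]
    assert pairs["mrd1"].a.mean() == pytest.approx(np.mean(naive), abs=1e-12)


def test_misaligned_lists_rejected(rng):
    with pytest.raises(ValidationError):
        pool_bilateral(_random_records(rng, 3), _random_records(rng, 4))


def test_mae_exact_and_oracle(rng):
    same = PairedMeasurements("m", [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert mean_absolute_error(same) == (0.0, 0.0)
    two = PairedMeasurements("m", [1.0, 3.0], [2.0, 1.0])
    mae, _ = mean_absolute_error(two)
    assert mae == pytest.approx(1.5)
    a = rng.normal(size=1000)
    b = rng.normal(size=1000)
    mae, sd = mean_absolute_error(PairedMeasurements("m", a, b))
    diffs = [abs(x - y) for x, y in zip(a, b)]
    assert mae == pytest.approx(sum(diffs) / 1000, abs=1e-12)
    assert sd == pytest.approx(np.std(diffs, ddof=1), abs=1e-12)


def test_bland_altman_degenerate_cases():
    same = PairedMeasurements("m", [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    r = bland_altman(same)
    assert r.bias == 0.0 and r.loa_lower == 0.0 and r.loa_upper == 0.0
    assert r.bias_ci == (0.0, 0.0)
    const = PairedMeasurements("m", [1.0, 2.0, 3.0], [0.6, 1.6, 2.6])
    r = bland_altman(const)
    assert r.bias == pytest.approx(0.4)
    assert r.sd_diff == pytest.approx(0.0, abs=1e-12)
    assert r.loa_lower == pytest.approx(r.loa_upper)


def test_bland_altman_formulas(rng):
    from scipy import stats

    a = rng.normal(10, 1, 40)
    b = a - rng.normal(0.3, 0.5, 40)
    r = bland_altman(PairedMeasurements("m", a, b))
    d = a - b
    s = d.std(ddof=1)
    t = stats.t.ppf(0.975, 39)
    assert r.bias == pytest.approx(d.mean())
    assert r.loa_upper == pytest.approx(d.mean() + 1.96 * s)
    assert r.bias_ci[1] - r.bias_ci[0] == pytest.approx(2 * t * s / np.sqrt(40))
    assert r.loa_upper_ci[1] - r.loa_upper_ci[0] == pytest.approx(
        2 * t * s * np.sqrt(3 / 40)
    )


def test_icc_perfect_agreement_is_one(rng):
    a = rng.normal(10, 2, 12)
    r = icc_absolute_single(PairedMeasurements("m", a, a.copy()))
    assert r.icc == pytest.approx(1.0)
    assert r.band == "excellent"


def test_icc_matches_handwritten_anova():
    a = np.array([1.0, 2, 3, 4, 5, 6])
    b = a + 0.5
    r = icc_absolute_single(PairedMeasurements("m", a, b))
    assert r.icc == pytest.approx(icc_a1_oracle(a, b), abs=1e-8)


def test_icc_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(5)
    a = rng.normal(10, 2, 25)
    b = a + rng.normal(0.4, 0.7, 25)
    ours = icc_absolute_single(PairedMeasurements("m", a, b))
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(25), 2),
            "rater": np.tile([0, 1], 25),
            "score": np.column_stack([a, b]).ravel(),
        }
    )
    ref = pingouin.intraclass_corr(df, "subject", "rater", "score")
    mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
    row = ref[mask].iloc[0]
    ci = row["CI95%"] if "CI95%" in ref.columns else row["CI95"]
    assert ours.icc == pytest.approx(row["ICC"], abs=1e-8)
    assert ours.ci[0] == pytest.approx(ci[0], abs=0.01)  # pingouin rounds CIs
    assert ours.ci[1] == pytest.approx(ci[1], abs=0.01)
    assert ours.p_value == pytest.approx(row["pval"], rel=1e-6)


def test_icc_interpretation_bands():
    assert icc_band(0.843) == "good"
    assert icc_band(0.906) == "excellent"
    assert icc_band(0.3) == "poor"
    assert icc_band(0.6) == "moderate"


def test_icc_shift_invariance_and_offset_penalty(rng):
    a = rng.normal(10, 2, 30)
    b = a + rng.normal(0, 0.5, 30)
    base = icc_absolute_single(PairedMeasurements("m", a, b)).icc
    both = icc_absolute_single(PairedMeasurements("m", a + 5, b + 5)).icc
    assert both == pytest.approx(base, abs=1e-10)
    one_side = icc_absolute_single(PairedMeasurements("m", a, b + 2.0)).icc
    assert one_side < base


def test_icc_degenerate_subject_variance():
    a = np.full(8, 3.0)
    b = np.full(8, 3.0)
    with pytest.raises(DegenerateIccError):
        icc_absolute_single(PairedMeasurements("m", a, b))


def test_mae_bounds_bias(rng):
    for _ in range(20):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0, 1, 15)
        pm = PairedMeasurements("m", a, b)
        mae, _ = mean_absolute_error(pm)
        assert mae >= abs(np.mean(a - b)) - 1e-12
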