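"""Method-agreement statistics for paired measurement series.

Given the same parameter (EDV, ESV or EF) measured by two methods on the
same subjects, this module computes Pearson's r, a two-tailed paired t-test,
a Lilliefors-style Kolmogorov-Smirnov normality check per series, and the
Bland-Altman bias with 95% limits of agreement (bias +/- 1.96 SD of the
differences, sample SD with n-1 denominator). A mean difference of at least
10 mL for volumes, or 3 percentage points for EF, is flagged as clinically
relevant.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import CardiosegError, DegenerateSeriesError
from .types import AgreementReport, PairedSeries

#: Clinical-relevance thresholds on |bias| (inclusive).
CLINICAL_THRESHOLDS = {"EDV": 10.0, "ESV": 10.0, "EF": 3.0}

_KS_MC_REPS = 10_000
_KS_MC_SEED = 20130327  # fixed: the Monte-Carlo p is stochastic but reproducible


def pearson_r(series: PairedSeries) -> float:
    """Product-moment correlation between the two series."""
    a, b = series.values_a, series.values_b
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateSeriesError("correlation undefined for a constant series")
    return float(stats.pearsonr(a, b).statistic)


def paired_t(series: PairedSeries) -> tuple:
    """Two-tailed paired t-test on the differences a - b.

    Returns ``(t, p_two_tailed, df)`` with ``df = n - 1`` and the sample
    (n-1 denominator) standard deviation.
    """
    d = series.differences
    n = d.size
    if n < 2:
        raise CardiosegError("paired t-test needs n >= 2")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateSeriesError("paired t-test undefined: zero-variance differences")
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, p, df


def ks_normality(values, rng_seed: int = _KS_MC_SEED, n_reps: int = _KS_MC_REPS) -> float:
    """One-sample KS test against a normal with estimated mean and SD.

    Because the parameters are estimated from the sample (Lilliefors
    situation), the p-value comes from a Monte-Carlo null distribution of the
    same statistic on standard-normal samples of the same size, with a fixed
    seed for reproducibility.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 3:
        raise CardiosegError("normality test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateSeriesError("normality test undefined for zero-variance data")

    def lilliefors_stat(sample):
        z = np.sort((sample - sample.mean(axis=-1, keepdims=True))
                    / sample.std(axis=-1, ddof=1, keepdims=True), axis=-1)
        n = z.shape[-1]
        cdf = stats.norm.cdf(z)
        i = np.arange(1, n + 1, dtype=float)
        d_plus = (i / n - cdf).max(axis=-1)
        d_minus = (cdf - (i - 1) / n).max(axis=-1)
        return np.maximum(d_plus, d_minus)

    d_obs = float(lilliefors_stat(x[None, :])[0])
    rng = np.random.default_rng(rng_seed)
    sims = lilliefors_stat(rng.standard_normal((n_reps, x.size)))
    return float((1 + np.sum(sims >= d_obs)) / (1 + n_reps))


def bland_altman(series: PairedSeries) -> dict:
    """Bias, SD of differences, 95% limits of agreement and their coverage.

    ``loa = bias +/- 1.96 * sd_diff``; ``coverage_fraction`` is the fraction
    of observed differences inside the closed interval.
    """
    d = series.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    loa_low = bias - 1.96 * sd
    loa_high = bias + 1.96 * sd
    coverage = float(np.mean((d >= loa_low) & (d <= loa_high)))
    return {
        "bias": bias,
        "sd_diff": sd,
        "loa_low": loa_low,
        "loa_high": loa_high,
        "coverage_fraction": coverage,
    }


def clinical_relevance(bias: float, label: str) -> bool:
    """True iff |bias| reaches the label's clinical threshold (inclusive)."""
    key = label.upper()
    if key not in CLINICAL_THRESHOLDS:
        raise CardiosegError(f"unknown parameter label {label!r}; expected EDV, ESV or EF")
    return abs(bias) >= CLINICAL_THRESHOLDS[key]


def compare_series(series: PairedSeries) -> AgreementReport:
    """Full agreement analysis of one paired parameter series."""
    t, p, df = paired_t(series)
    ba = bland_altman(series)
    return AgreementReport(
        label=series.label,
        units=series.units,
        n=series.n,
        r=pearson_r(series),
        t_stat=t,
        p_two_tailed=p,
        df=df,
        ks_p_a=ks_normality(series.values_a),
        ks_p_b=ks_normality(series.values_b),
        clinically_relevant=clinical_relevance(ba["bias"], series.label),
        **ba,
    )


def compare_tables(table_a, table_b) -> dict:
    """Agreement reports for the standard EDV/ESV/EF columns of two tables.

    ``table_a``/``table_b`` are mappings (e.g. DataFrames) with columns
    ``EDV_ml``, ``ESV_ml``, ``EF_percent`` aligned row-by-row (same patients,
    same order).
    """
    spec = [("EDV", "EDV_ml", "mL"), ("ESV", "ESV_ml", "mL"), ("EF", "EF_percent", "%")]
    out = {}
    for label, column, units in spec:
        series = PairedSeries(
            np.asarray(table_a[column], dtype=float),
            np.asarray(table_b[column], dtype=float),
            label=label,
            units=units,
        )
        out[label] = compare_series(series)
    return out
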