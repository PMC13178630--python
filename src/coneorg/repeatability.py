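"""Test-retest repeatability statistics for per-cone response parameters.

Two levels of analysis mirror how repeated optoretinography trials are
summarized:

* single-cone: for each cone present in every trial, the coefficient of
  variation (CoV, %) of its parameter across trials, aggregated over cones
  by root-mean-square (and, for comparison, by arithmetic mean), plus the
  single-measure intraclass correlation ICC(2,1) from a two-way ANOVA with
  an F-based 95% confidence interval;

* pooled: per-trial mean and standard deviation over all retained cones
  (the cone subsets may differ between trials), with the CoV of the
  per-trial means and of the per-trial SDs quantifying the stability of the
  pooled response and of the inter-cone dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "cov",
    "aggregate_cov",
    "IccResult",
    "icc_2_1",
    "pooled_stats",
    "repeatability_report",
]


def cov(values) -> float:
    """Coefficient of variation in percent: 100 * sample SD / mean.

    Uses the n-1 denominator. Requires n >= 2 and a positive mean (the
    parameters this is applied to are nonnegative by construction).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CoV needs at least two values")
    m = x.mean()
    if m <= 0:
        raise ValueError("CoV undefined for non-positive mean")
    return float(100.0 * x.std(ddof=1) / m)


def aggregate_cov(per_cone_covs, method: str = "rms") -> float:
    """Aggregate per-cone CoV values across the mosaic.

    ``rms`` (the default) weights larger per-cone variabilities more than
    the arithmetic ``mean`` and is never smaller than it.
    """
    x = np.asarray(per_cone_covs, dtype=float)
    if x.size == 0:
        raise ValueError("no CoV values to aggregate")
    if method == "rms":
        return float(np.sqrt(np.mean(x**2)))
    if method == "mean":
        return float(np.mean(x))
    raise ValueError(f"unknown aggregation method {method!r}")


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    degenerate: bool = False   # zero error mean square; CI meaningless


def _anova_ms(x: np.ndarray):
    """Mean squares of the two-way crossed design (rows x columns, one
    observation per cell)."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_2_1(matrix, alpha: float = 0.05) -> IccResult:
    """Single-measure intraclass correlation from a two-way ANOVA.

    ``matrix`` is cones x trials, complete cases only. The estimator is the
    Shrout-Fleiss ICC(2,1) (absolute agreement, single measure):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with rows = cones, columns = trials. The confidence interval uses the
    F-distribution method of McGraw & Wong (1996) for this case. Negative
    estimates are reported as computed. A degenerate ANOVA (zero error mean
    square, i.e. perfect agreement) returns ICC 1 with a flagged CI.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (cones x trials)")
    if np.isnan(x).any():
        raise ValueError("complete cases only: matrix contains NaN")
    n, k = x.shape
    if n < 5 or k < 2:
        raise ValueError("need at least 5 cones and 2 trials")

    msr, msc, mse = _anova_ms(x)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    # mse at rounding-noise level relative to the row variance is treated as
    # exact agreement (noise-free replicates differ only in the last bits)
    if mse <= 0 or denom <= 0 or mse < 1e-12 * msr:
        return IccResult(icc=1.0, ci_low=1.0, ci_high=1.0, degenerate=True)
    icc = (msr - mse) / denom

    # McGraw & Wong F-based CI for the two-way, absolute-agreement,
    # single-measure case (Satterthwaite df for the mixture of MSC and MSE)
    f_obs = msr / mse
    a = k * icc / (n * (1.0 - icc))
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (n * (msr - f_l * mse)
             / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
    upper = (n * (f_u * msr - mse)
             / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
    return IccResult(icc=float(icc), ci_low=float(lower),
                     ci_high=float(upper))


def pooled_stats(per_trial_values) -> dict:
    """Per-trial pooled mean and SD, and the stability of both across trials.

    ``per_trial_values`` is a sequence of 1-D arrays, one per trial; the
    cone subsets need not coincide between trials. Returns per-trial means
    and SDs, the CoV (%) of the means and the CoV (%) of the SDs.
    """
    arrays = [np.asarray(v, dtype=float) for v in per_trial_values]
    if len(arrays) < 2:
        raise ValueError("pooled repeatability needs at least two trials")
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise ValueError(f"trial {i} has fewer than 2 retained cones")
    means = np.array([a.mean() for a in arrays])
    stds = np.array([a.std(ddof=1) for a in arrays])
    return {
        "trial_means": means.tolist(),
        "trial_stds": stds.tolist(),
        "mean_of_means": float(means.mean()),
        "sd_of_means": float(means.std(ddof=1)),
        "mean_of_stds": float(stds.mean()),
        "sd_of_stds": float(stds.std(ddof=1)),
        "cov_of_means": cov(means),
        "cov_of_stds": cov(stds),
        "n_per_trial": [int(a.size) for a in arrays],
    }


def repeatability_report(fit_table,
                         params=("dopl_max_nm", "dopl_fit_max_nm", "tau_a"),
                         aggregation: str = "rms") -> dict:
    """Full repeatability summary from a per-(cone, trial) fit table.

    Single-cone statistics use only cones retained in every trial
    (complete cases); pooled statistics use all retained cones per trial.
    Cones whose parameter row has non-positive mean are flagged and dropped
    from CoV aggregation.
    """
    df = fit_table[fit_table["retained"]].copy()
    trials = sorted(df["trial_id"].unique())
    k = len(trials)
    report: dict = {"n_trials": k, "params": {}}
    if k < 2:
        raise ValueError("repeatability needs >= 2 trials with retained cones")

    counts = df.groupby("cone_id")["trial_id"].nunique()
    complete = counts[counts == k].index

    for param in params:
        wide = (df[df["cone_id"].isin(complete)]
                .pivot(index="cone_id", columns="trial_id", values=param)
                .sort_index())
        mat = wide.to_numpy()
        per_cone, flagged = [], 0
        for row in mat:
            try:
                per_cone.append(cov(row))
            except ValueError:
                flagged += 1
        icc = icc_2_1(mat) if mat.shape[0] >= 5 else None
        per_trial = [df.loc[df["trial_id"] == tr, param].to_numpy()
                     for tr in trials]
        report["params"][param] = {
            "n_complete_cones": int(mat.shape[0]),
            "n_cov_flagged": flagged,
            "cov_rms": aggregate_cov(per_cone, "rms") if per_cone else None,
            "cov_mean": aggregate_cov(per_cone, "mean") if per_cone else None,
            "cov_aggregated": (aggregate_cov(per_cone, aggregation)
                               if per_cone else None),
            "icc": None if icc is None else icc.icc,
            "icc_ci95": None if icc is None else [icc.ci_low, icc.ci_high],
            "icc_degenerate": None if icc is None else icc.degenerate,
            "pooled": pooled_stats(per_trial),
        }
    return report
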