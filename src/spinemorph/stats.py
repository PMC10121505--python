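"""Agreement and diagnostic-performance statistics.

Implements the study-style statistical layer: intraclass correlation
(two-way random-effects, absolute agreement, single measures by default,
with the F-distribution confidence interval), Cohen's kappa, Bland-Altman
limits of agreement, and sensitivity/specificity/accuracy with exact
(Clopper-Pearson) binomial confidence intervals.  Two point estimates are
declared significantly different only when their 95% CIs are disjoint
(touching endpoints count as overlapping).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "AgreementReport",
    "ContingencyCounts",
    "BlandAltman",
    "icc",
    "cohens_kappa",
    "kappa_from_table",
    "bland_altman",
    "diagnostic_metrics",
    "ci_overlap_significant",
    "koo_band",
    "landis_koch_band",
]


@dataclass(frozen=True)
class AgreementReport:
    """One statistic with its 95% CI and sample size."""

    name: str
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    band: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isnan(self.ci_low)
                or self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12):
            raise ValueError(
                f"{self.name}: CI ({self.ci_low}, {self.ci_high}) does not "
                f"contain the estimate {self.estimate}"
            )


def koo_band(icc_value: float) -> str:
    """Qualitative ICC interpretation (poor/moderate/good/excellent)."""
    if icc_value < 0.5:
        return "poor"
    if icc_value < 0.75:
        return "moderate"
    if icc_value <= 0.9:
        return "good"
    return "excellent"


def landis_koch_band(kappa: float) -> str:
    if kappa < 0.0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

_ICC_FORMS = ("ICC1", "ICC2", "ICC3", "ICC1k", "ICC2k", "ICC3k")


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float, float]:
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = (ss_total - ss_rows) / (n * (k - 1))
    return msr, msc, mse, msw


def icc(ratings: np.ndarray, form: str = "ICC2",
        alpha: float = 0.05) -> AgreementReport:
    """Intraclass correlation of an (n subjects x k raters) table.

    ``form`` selects the model: ICC1 (one-way random), ICC2 (two-way
    random, absolute agreement — the default), ICC3 (two-way mixed,
    consistency); the 'k' suffix gives the average-measures variant.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D (subjects x raters) table")
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 raters")
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if np.isnan(x).any():
        raise ValueError("ratings contain missing values; align them first")
    if form not in _ICC_FORMS:
        raise ValueError(f"unknown ICC form {form!r}; expected one of {_ICC_FORMS}")
    if np.var(x.mean(axis=1)) == 0.0:
        raise ValueError("zero between-subject variance: ICC undefined")

    msr, msc, mse, msw = _anova_mean_squares(x)

    with np.errstate(divide="ignore", invalid="ignore"):
        if form in ("ICC1", "ICC1k"):
            est_single = (msr - msw) / (msr + (k - 1) * msw)
            f_stat = msr / msw if msw > 0 else np.inf
            fl = f_stat / sps.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
            fu = f_stat * sps.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
            lo = (fl - 1) / (fl + (k - 1))
            hi = (fu - 1) / (fu + (k - 1))
        elif form in ("ICC3", "ICC3k"):
            if mse == 0:
                est_single, lo, hi = 1.0, 1.0, 1.0
            else:
                est_single = (msr - mse) / (msr + (k - 1) * mse)
                f_stat = msr / mse
                fl = f_stat / sps.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
                fu = f_stat * sps.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
                lo = (fl - 1) / (fl + k - 1)
                hi = (fu - 1) / (fu + k - 1)
        else:  # ICC2 family
            est_single = (msr - mse) / (msr + (k - 1) * mse
                                        + k * (msc - mse) / n)
            if mse == 0 and msc == 0:
                lo = hi = 1.0
            else:
                fj = msc / mse if mse > 0 else np.inf
                icc2 = est_single
                vn = ((k - 1) * (n - 1)
                      * (k * icc2 * fj + n * (1 + (k - 1) * icc2)
                         - k * icc2) ** 2)
                vd = ((n - 1) * k ** 2 * icc2 ** 2 * fj ** 2
                      + (n * (1 + (k - 1) * icc2) - k * icc2) ** 2)
                v = vn / vd
                f2u = sps.f.ppf(1 - alpha / 2, n - 1, v)
                f2l = sps.f.ppf(1 - alpha / 2, v, n - 1)
                lo = (n * (msr - f2u * mse)
                      / (f2u * (k * msc + (k * n - k - n) * mse) + n * msr))
                hi = (n * (f2l * msr - mse)
                      / (k * msc + (k * n - k - n) * mse + n * f2l * msr))

        if form.endswith("k"):
            def to_avg(v: float) -> float:
                if not np.isfinite(v):
                    return v
                denom = 1 + (k - 1) * v
                return k * v / denom if denom != 0 else 1.0

            est = to_avg(est_single)
            lo, hi = to_avg(lo), to_avg(hi)
        else:
            est = est_single

    est = float(np.clip(est, -1.0, 1.0))
    lo = float(np.clip(lo, -1.0, est))
    hi = float(np.clip(hi, est, 1.0))
    return AgreementReport(name=form, estimate=est, ci_low=lo, ci_high=hi,
                           n=n, band=koo_band(est),
                           extra={"raters": k, "msr": msr, "msc": msc,
                                  "mse": mse, "msw": msw})


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------


def cohens_kappa(a, b, alpha: float = 0.05) -> AgreementReport:
    """Chance-corrected categorical agreement between two raters."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and equally long")
    n = len(a)
    if n == 0:
        raise ValueError("empty label vectors")
    categories = np.union1d(a, b)
    po = float((a == b).mean())
    pe = 0.0
    for cat in categories:
        pe += float((a == cat).mean()) * float((b == cat).mean())
    if pe >= 1.0 - 1e-15:
        raise ValueError("expected agreement is 1 (both raters constant): "
                         "kappa undefined")
    kappa = (po - pe) / (1.0 - pe)
    se = math.sqrt(po * (1 - po) / n) / (1 - pe)
    z = sps.norm.ppf(1 - alpha / 2)
    lo = max(kappa - z * se, -1.0)
    hi = min(kappa + z * se, 1.0)
    return AgreementReport(name="kappa", estimate=float(kappa), ci_low=lo,
                           ci_high=hi, n=n, band=landis_koch_band(kappa),
                           extra={"po": po, "pe": pe})


def kappa_from_table(table: np.ndarray, alpha: float = 0.05) -> AgreementReport:
    """Kappa from a square agreement table (rows: rater A, cols: rater B)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("agreement table must be square")
    n = t.sum()
    a_idx, b_idx = [], []
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            cnt = int(t[i, j])
            a_idx += [i] * cnt
            b_idx += [j] * cnt
    return cohens_kappa(np.array(a_idx), np.array(b_idx), alpha=alpha)


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlandAltman:
    """Mean difference (first minus second argument) and limits of agreement."""

    mean_diff: float
    sd_diff: float
    loa_halfwidth: float
    loa_low: float
    loa_high: float
    n: int

    def __str__(self) -> str:  # the "mean +/- LoA half-width" report style
        return (f"mean difference of {self.mean_diff:.1f} with LoA of "
                f"± {self.loa_halfwidth:.1f}")


def bland_altman(a, b, z: float = 1.96) -> BlandAltman:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("measurement vectors must be 1-D and equally long")
    if len(a) < 2:
        raise ValueError("Bland-Altman needs at least 2 paired measurements")
    diff = a - b
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    half = z * sd
    return BlandAltman(mean_diff=mean_diff, sd_diff=sd, loa_halfwidth=half,
                       loa_low=mean_diff - half, loa_high=mean_diff + half,
                       n=len(a))


def bland_altman_plot(a, b, ax=None, label: str = ""):
    """Optional rendering of the agreement plot."""
    import matplotlib.pyplot as plt

    ba = bland_altman(a, b)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((a + b) / 2.0, a - b, s=12, alpha=0.7)
    for y, style in ((ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (first - second)")
    if label:
        ax.set_title(label)
    return ax


# ---------------------------------------------------------------------------
# diagnostic performance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyCounts:
    """TP/FP/TN/FN for one stratum of the fracture-detection evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int
    stratum: str = ""

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total == 0:
            raise ValueError("contingency counts sum to zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _proportion_ci(count: int, nobs: int, alpha: float,
                   method: str) -> tuple[float, float]:
    from statsmodels.stats.proportion import proportion_confint

    sm_method = {"clopper-pearson": "beta", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method=sm_method)
    return float(lo), float(hi)


def diagnostic_metrics(
    counts: ContingencyCounts,
    alpha: float = 0.05,
    method: str = "clopper-pearson",
) -> dict[str, AgreementReport]:
    """Sensitivity, specificity and accuracy with binomial CIs.

    A metric with a zero denominator is returned with NaN estimate and an
    'undefined' note instead of failing the others.
    """
    out: dict[str, AgreementReport] = {}
    spec_pairs = {
        "sensitivity": (counts.tp, counts.tp + counts.fn),
        "specificity": (counts.tn, counts.tn + counts.fp),
        "accuracy": (counts.tp + counts.tn, counts.total),
    }
    for name, (num, den) in spec_pairs.items():
        if den == 0:
            out[name] = AgreementReport(
                name=name, estimate=float("nan"), ci_low=float("nan"),
                ci_high=float("nan"), n=0,
                extra={"note": "undefined: zero denominator",
                       "stratum": counts.stratum})
            continue
        est = num / den
        lo, hi = _proportion_ci(num, den, alpha, method)
        out[name] = AgreementReport(name=name, estimate=est, ci_low=lo,
                                    ci_high=hi, n=den,
                                    extra={"stratum": counts.stratum,
                                           "method": method})
    return out


def ci_overlap_significant(a: AgreementReport, b: AgreementReport) -> bool:
    """True iff the two 95% CIs are disjoint (touching = not significant)."""
    for rep in (a, b):
        if math.isnan(rep.ci_low) or math.isnan(rep.ci_high):
            raise ValueError(f"{rep.name}: CI undefined")
    return a.ci_high < b.ci_low or b.ci_high < a.ci_low
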