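"""Accuracy and precision statistics for the quantification study.

Accuracy is scored with Lin's Concordance Correlation Coefficient (CCC),
which penalizes both correlation loss and location/scale bias:

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (x_bar - y_bar)^2)

with population (1/n) moments and a Fisher-z confidence interval.  Precision
is scored with Pearson's r and an ordinary least-squares fit of the measured
index on the achieved truth (t-based 95 % CIs), plus the coefficient of
determination rho^2.  ``evaluate_study`` assembles these per method and
compartment into the study's agreement report: CCC within each activity
level (high / intermediary / low) plus pooled regression statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CccResult",
    "OlsResult",
    "lin_ccc",
    "pearson_r",
    "ols_fit",
    "evaluate_study",
    "write_report",
    "format_report",
]

ACTIVITY_LEVELS = ("high", "intermediary", "low")


@dataclass
class CccResult:
    value: float
    ci_low: float
    ci_high: float


@dataclass
class OlsResult:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]


def _check_xy(x, y, min_n=3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} points")
    return x, y


def lin_ccc(x, y, bias: str = "population", alpha: float = 0.05) -> CccResult:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    ``bias='population'`` uses 1/n moments (Lin's original definition);
    ``bias='sample'`` uses 1/(n-1) moments, which differs appreciably at the
    per-level group sizes of this study (n = 7-9).
    """
    x, y = _check_xy(x, y)
    ddof = 0 if bias == "population" else 1
    if bias not in ("population", "sample"):
        raise ValueError("bias must be 'population' or 'sample'")
    n = x.size
    sx2 = x.var(ddof=ddof)
    sy2 = y.var(ddof=ddof)
    if sx2 == 0 or sy2 == 0:
        raise ValueError("zero variance in x or y")
    sxy = ((x - x.mean()) * (y - y.mean())).sum() / (n - ddof)
    dmean = x.mean() - y.mean()
    ccc = 2.0 * sxy / (sx2 + sy2 + dmean ** 2)

    r = sxy / math.sqrt(sx2 * sy2)
    if abs(ccc) >= 1.0 - 1e-12 or r == 0:
        return CccResult(value=float(ccc), ci_low=float(ccc), ci_high=float(ccc))
    # Lin (1989) asymptotic variance of the z-transformed CCC
    u2 = dmean ** 2 / math.sqrt(sx2 * sy2)
    c1 = (1.0 - r ** 2) * ccc ** 2 / ((1.0 - ccc ** 2) * r ** 2)
    c2 = 2.0 * ccc ** 3 * (1.0 - ccc) * u2 / (r * (1.0 - ccc ** 2) ** 2)
    c3 = ccc ** 4 * u2 ** 2 / (2.0 * r ** 2 * (1.0 - ccc ** 2) ** 2)
    var_z = max((c1 + c2 - c3) / (n - 2), 0.0)
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    z = math.atanh(ccc)
    half = zcrit * math.sqrt(var_z)
    return CccResult(
        value=float(ccc),
        ci_low=float(math.tanh(z - half)),
        ci_high=float(math.tanh(z + half)),
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-tailed p-value."""
    x, y = _check_xy(x, y)
    if x.var() == 0 or y.var() == 0:
        raise ValueError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def ols_fit(x, y, alpha: float = 0.05) -> OlsResult:
    """Ordinary least squares of y on x with t-based confidence intervals."""
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0:
        raise ValueError("degenerate x (all values equal)")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=alpha)
    return OlsResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_se=float(model.bse[1]),
        intercept_se=float(model.bse[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
    )


def _level_ccc(sub: pd.DataFrame, bias: str) -> CccResult | None:
    if len(sub) < 3:
        return None
    try:
        return lin_ccc(sub["truth"].to_numpy(), sub["value"].to_numpy(), bias=bias)
    except ValueError:
        return None


def evaluate_study(results: pd.DataFrame, ccc_bias: str = "population") -> pd.DataFrame:
    """Agreement report per (method, compartment).

    ``results`` must carry columns method, compartment, index_type, value,
    truth, activity_level.  Levels with fewer than three points get an
    undefined (NaN) CCC rather than an error.
    """
    required = {"method", "compartment", "index_type", "value", "truth",
                "activity_level"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table lacks columns {sorted(missing)}")
    rows = []
    for (method, compartment, index_type), grp in results.groupby(
        ["method", "compartment", "index_type"], sort=True
    ):
        x = grp["truth"].to_numpy(dtype=float)
        y = grp["value"].to_numpy(dtype=float)
        fit = ols_fit(x, y)
        r, p = pearson_r(x, y)
        row = {
            "method": method,
            "compartment": compartment,
            "index_type": index_type,
            "n": len(grp),
            "intercept": fit.intercept,
            "intercept_se": fit.intercept_se,
            "intercept_lo": fit.intercept_ci[0],
            "intercept_hi": fit.intercept_ci[1],
            "slope": fit.slope,
            "slope_se": fit.slope_se,
            "slope_lo": fit.slope_ci[0],
            "slope_hi": fit.slope_ci[1],
            "pearson_r": r,
            "pearson_p": p,
            "cod": r ** 2,
        }
        for level in ACTIVITY_LEVELS:
            ccc = _level_ccc(grp[grp["activity_level"] == level], ccc_bias)
            row[f"ccc_{level}"] = ccc.value if ccc else float("nan")
            row[f"ccc_{level}_lo"] = ccc.ci_low if ccc else float("nan")
            row[f"ccc_{level}_hi"] = ccc.ci_high if ccc else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> str:
    """Pretty text table: CCC per level, regression coefficients, r, rho^2."""
    lines = [
        f"{'method':<14}{'comp':<6}{'index':<6}"
        f"{'CCC high':<22}{'CCC interm.':<22}{'CCC low':<22}"
        f"{'intercept (CI)':<26}{'slope (CI)':<26}{'r':>7}{'rho2':>7}"
    ]
    for _, row in report.iterrows():
        def ccc_txt(level):
            v = row[f"ccc_{level}"]
            if np.isnan(v):
                return "undefined"
            return f"{v:.3f} ({row[f'ccc_{level}_lo']:.3f};{row[f'ccc_{level}_hi']:.3f})"

        ic = f"{row['intercept']:.3f} ({row['intercept_lo']:.3f};{row['intercept_hi']:.3f})"
        sl = f"{row['slope']:.3f} ({row['slope_lo']:.3f};{row['slope_hi']:.3f})"
        lines.append(
            f"{row['method']:<14}{row['compartment']:<6}{row['index_type']:<6}"
            f"{ccc_txt('high'):<22}{ccc_txt('intermediary'):<22}{ccc_txt('low'):<22}"
            f"{ic:<26}{sl:<26}{row['pearson_r']:>7.3f}{row['cod']:>7.3f}"
        )
    return "\n".join(lines)


def write_report(report: pd.DataFrame, out_dir, stem: str = "agreement") -> dict[str, Path]:
    """Write the report as CSV, JSON and pretty text."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "csv": out_dir / f"{stem}.csv",
        "json": out_dir / f"{stem}.json",
        "txt": out_dir / f"{stem}.txt",
    }
    report.to_csv(paths["csv"], index=False)
    paths["json"].write_text(json.dumps(report.to_dict(orient="records"), indent=2))
    paths["txt"].write_text(format_report(report) + "\n")
    return paths
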