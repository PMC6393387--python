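"""Level-specific association tests on per-sample data.

Two classical tests, shared by the Monte-Carlo machinery and by
user-supplied tables:

* the t-test for the slope of a one-predictor least-squares regression
  (simple random sampling), and
* the pooled-variance two-sample t-test comparing an omics level between
  the upper and lower trait tails (extreme phenotype sampling).

Both carry df = n_total - 2, which is what the analytic power engine
assumes.  A Welch option is available for data analysis but is not used
by the power calculations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .power import DesignSpec

__all__ = ["TestResult", "slope_t_test", "two_sample_t_test", "level_scan"]

_RESID_TOL = 1e-12

REQUIRED_COLUMNS = ("genotype", "rna", "prt", "trait")


@dataclass(frozen=True)
class TestResult:
    estimate: float
    t_stat: float
    df: int
    p_value: float
    level: str | None = None
    scheme: str | None = None
    degenerate: bool = False
    reject: bool | None = None


def _p_value(t_stat: float, df: int, sides: int) -> float:
    if sides == 2:
        return float(2.0 * t_dist.sf(abs(t_stat), df))
    return float(t_dist.sf(t_stat, df))


def slope_t_test(x, y, sides: int = 2) -> TestResult:
    """Classical t-test for the slope of y on x.

    Zero residual variance with a non-zero slope (a perfect fit) is
    reported with the ``degenerate`` flag and p-value 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("x is constant; slope undefined")
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    slope = sxy / sxx
    df = n - 2
    sse = max(syy - slope * sxy, 0.0)
    scale = max(syy, sxx, 1.0)
    if sse <= _RESID_TOL * scale:
        if slope == 0.0:  # constant y: no association, no evidence
            return TestResult(0.0, 0.0, df, 1.0 if sides == 2 else 0.5)
        return TestResult(slope, np.inf, df, 0.0, degenerate=True)
    se = np.sqrt(sse / df / sxx)
    t_stat = slope / se
    return TestResult(slope, float(t_stat), df, _p_value(t_stat, df, sides))


def two_sample_t_test(upper, lower, sides: int = 2, welch: bool = False) -> TestResult:
    """t-test for a difference in means, pooled variance by default.

    The pooled version with df = n_u + n_l - 2 matches the convention of
    the analytic EPS power formulas; Welch's unequal-variance form is
    offered for data analysis.
    """
    upper = np.asarray(upper, dtype=float)
    lower = np.asarray(lower, dtype=float)
    if upper.size < 2 or lower.size < 2:
        raise ValueError("each group needs at least 2 observations")
    nu, nl = upper.size, lower.size
    diff = float(upper.mean() - lower.mean())
    vu = float(upper.var(ddof=1))
    vl = float(lower.var(ddof=1))
    if welch:
        se_sq = vu / nu + vl / nl
        df = int((se_sq**2 / ((vu / nu) ** 2 / (nu - 1) + (vl / nl) ** 2 / (nl - 1))))
        df = max(df, 1)
    else:
        pooled = ((nu - 1) * vu + (nl - 1) * vl) / (nu + nl - 2)
        se_sq = pooled * (1.0 / nu + 1.0 / nl)
        df = nu + nl - 2
    if se_sq <= _RESID_TOL:
        if diff == 0.0:
            return TestResult(0.0, 0.0, df, 1.0 if sides == 2 else 0.5)
        return TestResult(diff, np.inf, df, 0.0, degenerate=True)
    t_stat = diff / np.sqrt(se_sq)
    return TestResult(diff, float(t_stat), df, _p_value(t_stat, df, sides))


def level_scan(
    table: pd.DataFrame,
    design: DesignSpec,
    sig_level: float | None = None,
) -> list[TestResult]:
    """Run the three level-trait association tests on a per-sample table.

    ``table`` must carry columns genotype (0/1/2 minor-allele counts),
    rna, prt and trait.  Under SRS each level is regressed against the
    trait; under EPS each level is compared between the upper and lower
    trait tails, taken from a ``tail_label`` column when present and
    otherwise from the table's own empirical ``design.trunc_alpha``
    quantiles.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing required column(s): {missing}")
    geno = table["genotype"].to_numpy()
    if not np.isin(geno, (0, 1, 2)).all():
        raise ValueError("genotype values must be in {0, 1, 2}")
    if sig_level is None:
        sig_level = design.sig_level

    results = []
    levels = {"SNP": "genotype", "RNA": "rna", "PRT": "prt"}
    if design.scheme == "SRS":
        y = table["trait"].to_numpy(dtype=float)
        for level, col in levels.items():
            res = slope_t_test(table[col].to_numpy(dtype=float), y, design.sides)
            results.append(_finalize(res, level, design, sig_level))
    else:
        if "tail_label" in table.columns:
            upper_mask = table["tail_label"].to_numpy() == "upper"
            lower_mask = table["tail_label"].to_numpy() == "lower"
        else:
            trait = table["trait"].to_numpy(dtype=float)
            k = max(int(round(design.trunc_alpha * len(trait))), 2)
            order = np.argsort(trait, kind="stable")
            lower_mask = np.zeros(len(trait), dtype=bool)
            upper_mask = np.zeros(len(trait), dtype=bool)
            lower_mask[order[:k]] = True
            upper_mask[order[-k:]] = True
        for level, col in levels.items():
            vals = table[col].to_numpy(dtype=float)
            res = two_sample_t_test(vals[upper_mask], vals[lower_mask], design.sides)
            results.append(_finalize(res, level, design, sig_level))
    return results


def _finalize(res: TestResult, level: str, design: DesignSpec, sig: float) -> TestResult:
    return TestResult(
        estimate=res.estimate,
        t_stat=res.t_stat,
        df=res.df,
        p_value=res.p_value,
        level=level,
        scheme=design.scheme,
        degenerate=res.degenerate,
        reject=bool(res.p_value < sig),
    )
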