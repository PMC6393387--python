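"""Analytic power and minimal sample size for level-trait association tests.

Two sampling designs are covered.

Simple random sampling (SRS)
    The association between an omics level and the trait is tested by
    the classical t-test for the slope of a one-predictor regression.
    For a squared population correlation ``rho^2`` between level and
    trait, the t statistic at total sample size n is approximately
    non-central t with df = n - 2 and non-centrality
    ``delta = sqrt(n) * rho / sqrt(1 - rho^2)``.

Extreme phenotype sampling (EPS)
    Equal groups of n/2 subjects are drawn from the top and bottom
    100*alpha% tails of the trait and the level is compared between
    tails with a pooled two-sample t-test (df = n - 2).  The between-tail
    mean separation of the standardised level is 2*rho*lam(alpha) and
    the within-tail standard deviation is
    ``sigma_tail = sqrt(1 - rho^2 (1 - tail_var(alpha)))``, giving
    ``delta = rho * lam * sqrt(n) / sigma_tail``.

Power is the non-central-t mass beyond the central-t critical value;
sample size inversion is an integer bisection exploiting the strict
monotonicity of power in n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import nct, norm, t as t_dist

from .core import MediateCorrelations, scale_to_heritability, trait_correlations
from .trunc import tail_moments

__all__ = [
    "LEVELS",
    "SCHEMES",
    "DesignSpec",
    "PowerResult",
    "SampleSizeResult",
    "srs_ncp",
    "eps_ncp",
    "power_from_ncp",
    "level_power",
    "sample_size",
    "power_curve",
]

LEVELS = ("SNP", "RNA", "PRT")
SCHEMES = ("SRS", "EPS")

_N_MAX = 2**26  # sample-size search ceiling (~6.7e7 subjects)


@dataclass(frozen=True)
class DesignSpec:
    """Sampling scheme and test specification.

    The default significance level 2.5e-6 is the Bonferroni-style
    genome-wide gene-based threshold 0.05 / 20,000 protein-coding genes.
    """

    scheme: str = "SRS"
    trunc_alpha: float = 0.2
    sig_level: float = 2.5e-6
    sides: int = 2
    normal_approx: bool = False
    tail_shrinkage: bool = True

    def __post_init__(self) -> None:
        scheme = self.scheme.upper()
        if scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        object.__setattr__(self, "scheme", scheme)
        if not 0.0 < self.sig_level < 1.0:
            raise ValueError(f"sig_level must be in (0, 1), got {self.sig_level}")
        if self.sides not in (1, 2):
            raise ValueError(f"sides must be 1 or 2, got {self.sides}")
        if scheme == "EPS" and not 0.0 < self.trunc_alpha <= 0.5:
            raise ValueError(
                f"trunc_alpha must be in (0, 0.5] under EPS, got {self.trunc_alpha}"
            )

    @property
    def n_step(self) -> int:
        """Admissible sample sizes: any n under SRS, even n under EPS."""
        return 2 if self.scheme == "EPS" else 1


@dataclass(frozen=True)
class PowerResult:
    level: str
    scheme: str
    n: int
    ncp: float
    df: int
    power: float


@dataclass(frozen=True)
class SampleSizeResult:
    level: str
    scheme: str
    target_power: float
    n_required: int
    achieved_power: float


def srs_ncp(rho_sq: float, n: int) -> float:
    """Non-centrality of the SRS slope t-test: sqrt(n)*rho/sqrt(1-rho^2)."""
    _check_rho_sq(rho_sq)
    if n < 4:
        raise ValueError(f"n must be >= 4, got {n}")
    return math.sqrt(n * rho_sq / (1.0 - rho_sq))


def eps_ncp(rho_sq: float, n: int, trunc_alpha: float, tail_shrinkage: bool = True) -> float:
    """Non-centrality of the EPS two-sample t-test on n/2 + n/2 tails.

    ``tail_shrinkage=False`` drops the within-tail variance reduction
    (sigma_tail := 1), a cruder reconstruction kept for comparison.
    """
    _check_rho_sq(rho_sq)
    if n < 4:
        raise ValueError(f"n must be >= 4, got {n}")
    if n % 2:
        raise ValueError(f"EPS requires an even total sample size, got {n}")
    tm = tail_moments(trunc_alpha)
    sigma_tail = 1.0
    if tail_shrinkage:
        sigma_tail = math.sqrt(1.0 - rho_sq * (1.0 - tm.tail_var))
    return math.sqrt(rho_sq) * tm.lam * math.sqrt(n) / sigma_tail


def power_from_ncp(
    ncp: float,
    df: int,
    sig_level: float,
    sides: int = 2,
    normal_approx: bool = False,
) -> float:
    """Rejection probability of the t-test at non-centrality ``ncp``.

    Two-sided: mass of the noncentral t beyond +/- the central critical
    value; the lower-tail term is evaluated as ``nct.sf(tcrit, df, -ncp)``
    (exact by symmetry), which stays numerically stable at large df where
    ``nct.cdf(-tcrit, df, ncp)`` can fail.  At ncp = 0 both conventions
    reduce to the size, returned exactly.
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if not 0.0 < sig_level < 1.0:
        raise ValueError(f"sig_level must be in (0, 1), got {sig_level}")
    if ncp == 0.0:
        return sig_level
    tail = sig_level / sides
    if normal_approx:
        zc = norm.ppf(1.0 - tail)
        power = norm.sf(zc - ncp)
        if sides == 2:
            power += norm.cdf(-zc - ncp)
        return float(power)
    tcrit = t_dist.ppf(1.0 - tail, df)
    power = nct.sf(tcrit, df, ncp)
    if sides == 2:
        power += nct.sf(tcrit, df, -ncp)
    return float(min(power, 1.0))


def level_power(
    level: str,
    correlations: MediateCorrelations,
    design: DesignSpec,
    n: int,
) -> PowerResult:
    """Power of the chosen level's association test at total sample size n."""
    rho_sq = _level_rho_sq(level, correlations)
    if design.scheme == "SRS":
        ncp = srs_ncp(rho_sq, n)
    else:
        ncp = eps_ncp(rho_sq, n, design.trunc_alpha, design.tail_shrinkage)
    df = n - 2
    power = power_from_ncp(ncp, df, design.sig_level, design.sides, design.normal_approx)
    return PowerResult(level=level.upper(), scheme=design.scheme, n=n,
                       ncp=ncp, df=df, power=power)


def sample_size(
    level: str,
    correlations: MediateCorrelations,
    design: DesignSpec,
    target_power: float = 0.8,
) -> SampleSizeResult:
    """Smallest admissible total n with power >= ``target_power``.

    Brackets by doubling from n = 16, then bisects on the integer grid
    (even integers under EPS).  Strict monotonicity of power in n makes
    the bracket invariant exact: power(n_required) >= target and power at
    the previous admissible n falls below target.
    """
    rho_sq = _level_rho_sq(level, correlations)
    if rho_sq <= 0.0:
        raise ValueError(
            f"{level} has zero correlation with the trait; target power unattainable"
        )
    if not design.sig_level < target_power < 1.0:
        raise ValueError(
            f"target_power must be in (sig_level, 1), got {target_power}"
        )
    step = design.n_step

    def power_at(n: int) -> float:
        return level_power(level, correlations, design, n).power

    lo, hi = 4, 16
    while power_at(hi) < target_power:
        lo, hi = hi, hi * 2
        if hi > _N_MAX:
            raise ValueError("sample-size search exceeded ceiling; effect too small")
    # invariant: power(lo) < target <= power(hi); shrink to adjacent grid points
    while hi - lo > step:
        mid = (lo + hi) // 2
        mid -= mid % step
        if mid <= lo:
            mid = lo + step
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return SampleSizeResult(
        level=level.upper(),
        scheme=design.scheme,
        target_power=target_power,
        n_required=hi,
        achieved_power=power_at(hi),
    )


def power_curve(
    mode: str,
    anchor: MediateCorrelations,
    designs: Sequence[DesignSpec] | DesignSpec,
    grid: Iterable[float],
    n: int | None = None,
    target_power: float = 0.8,
    levels: Sequence[str] = LEVELS,
) -> pd.DataFrame:
    """Long-format table of power or required sample size over a grid.

    Modes
    -----
    ``power_vs_h2``
        ``grid`` holds heritability values; the anchor correlations are
        rescaled along the common-factor path at each point and power is
        computed at fixed total ``n``.
    ``power_vs_n``
        ``grid`` holds sample sizes (rounded up to even under EPS) at
        the fixed anchor correlations.
    ``n_vs_h2``
        ``grid`` holds heritability values; reports the sample size
        achieving ``target_power``.
    """
    if isinstance(designs, DesignSpec):
        designs = [designs]
    rows: list[dict] = []
    for design in designs:
        for level in levels:
            for g in grid:
                if mode == "power_vs_h2":
                    if n is None:
                        raise ValueError("mode 'power_vs_h2' requires n")
                    mc = scale_to_heritability(anchor, g)
                    n_used = n + n % design.n_step
                    value = level_power(level, mc, design, n_used).power
                    rows.append({"scheme": design.scheme, "level": level.upper(),
                                 "h2": g, "n": n_used, "power": value})
                elif mode == "power_vs_n":
                    n_used = int(g)
                    n_used += n_used % design.n_step
                    value = level_power(level, anchor, design, n_used).power
                    rows.append({"scheme": design.scheme, "level": level.upper(),
                                 "h2": anchor.h2, "n": n_used, "power": value})
                elif mode == "n_vs_h2":
                    mc = scale_to_heritability(anchor, g)
                    res = sample_size(level, mc, design, target_power)
                    rows.append({"scheme": design.scheme, "level": level.upper(),
                                 "h2": g, "n": res.n_required,
                                 "power": res.achieved_power})
                else:
                    raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows)


def _level_rho_sq(level: str, correlations: MediateCorrelations) -> float:
    lc = trait_correlations(correlations)
    try:
        return {"SNP": lc.snp, "RNA": lc.rna, "PRT": lc.prt}[level.upper()]
    except KeyError:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}") from None


def _check_rho_sq(rho_sq: float) -> None:
    if not 0.0 <= rho_sq < 1.0:
        raise ValueError(f"rho_sq must be in [0, 1), got {rho_sq}")
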