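"""Truncated standard-normal tail moments for extreme phenotype sampling.

Under extreme phenotype sampling (EPS) with per-tail truncation fraction
``alpha``, equal numbers of subjects are drawn from the top and bottom
100*alpha% tails of the (standardised) trait distribution.  Everything
the design's power depends on reduces to a handful of moments of the
standard normal conditional on the tail:

* ``z`` — upper tail threshold, the (1 - alpha) quantile;
* ``lam`` — the tail mean factor, phi(z)/alpha, i.e. E[Y | Y > z]
  (the "selection differential" of quantitative genetics);
* ``tail_var`` — var(Y | Y > z) = 1 + z*lam - lam^2;
* ``sel_m2`` — E[Y^2 | |Y| >= z] = 1 + z*lam for the symmetric two-tail
  selection.

A predictor W standardised to unit variance with population correlation
``rho`` to the trait satisfies, within the upper/lower tail,
E[W | tail] = +/- rho*lam and var(W | tail) = 1 - rho^2 (1 - tail_var).

The same machinery converts a reported between-tail fold change of a
positive intensity (e.g. a protein abundance) to the squared
protein-trait correlation: modelling log intensity as standard bivariate
normal with the trait, the expected between-tail difference in log
intensity is 2*r*lam, hence fc = exp(2*r*lam).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = [
    "TailMoments",
    "tail_moments",
    "eps_predictor_moments",
    "fold_change_to_r3sq",
    "r3sq_to_fold_change",
]


@dataclass(frozen=True)
class TailMoments:
    alpha: float
    z: float
    lam: float
    tail_var: float
    sel_m2: float


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha <= 0.5:
        raise ValueError(f"per-tail truncation fraction must be in (0, 0.5], got {alpha}")


def tail_moments(alpha: float) -> TailMoments:
    """Moments of the standard normal conditional on the upper tail.

    ``alpha`` is the per-tail fraction, so a symmetric two-tail design
    retains 2*alpha of the population; ``alpha = 0.5`` is a median split.
    """
    _check_alpha(alpha)
    z = norm.ppf(1.0 - alpha)
    lam = norm.pdf(z) / alpha
    tail_var = 1.0 + z * lam - lam * lam
    sel_m2 = 1.0 + z * lam
    return TailMoments(alpha=alpha, z=z, lam=lam, tail_var=tail_var, sel_m2=sel_m2)


def eps_predictor_moments(rho: float, alpha: float) -> tuple[float, float, float]:
    """Conditional moments of a correlated standardised predictor under EPS.

    Returns ``(mean_upper, mean_lower, within_var)`` for a predictor with
    population correlation ``rho`` to the trait, conditional on the trait
    falling in the upper / lower selected tail.  Writing
    W = rho*Y + sqrt(1-rho^2)*e with e independent standard normal gives
    the means +/- rho*lam and the common within-tail variance
    1 - rho^2 (1 - tail_var).
    """
    if not -1.0 < rho < 1.0:
        raise ValueError(f"rho must be in (-1, 1), got {rho}")
    tm = tail_moments(alpha)
    mean_upper = rho * tm.lam
    within_var = 1.0 - rho * rho * (1.0 - tm.tail_var)
    return mean_upper, -mean_upper, within_var


def fold_change_to_r3sq(fc: float, alpha: float) -> float:
    """Convert a between-tail fold change to a squared trait correlation.

    ``fc`` is the ratio of (geometric mean) intensity between the upper
    and lower EPS tails; log intensity is modelled as standard bivariate
    normal with the trait.  Solving fc = exp(2*r*lam) for r gives
    r = ln(fc) / (2*lam); the square is returned.
    """
    _check_alpha(alpha)
    if fc < 1.0:
        raise ValueError(f"fold change must be >= 1, got {fc}")
    lam = tail_moments(alpha).lam
    r = math.log(fc) / (2.0 * lam)
    if r >= 1.0:
        raise ValueError(
            f"fold change {fc} at alpha={alpha} implies correlation {r:.4f} >= 1"
        )
    return r * r


def r3sq_to_fold_change(r3sq: float, alpha: float) -> float:
    """Inverse of :func:`fold_change_to_r3sq`: fc = exp(2*sqrt(r3sq)*lam)."""
    _check_alpha(alpha)
    if not 0.0 <= r3sq < 1.0:
        raise ValueError(f"r3sq must be in [0, 1), got {r3sq}")
    lam = tail_moments(alpha).lam
    return math.exp(2.0 * math.sqrt(r3sq) * lam)
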