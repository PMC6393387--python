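"""Seeded Monte-Carlo machinery for the causal chain.

Generates per-sample data under the structural model — genotype drawn
Binomial(2, maf) under Hardy-Weinberg equilibrium, Gaussian exogenous
errors pushed down the chain — and serves as the simulation oracle for
every analytic quantity in the package: population moments, level-trait
correlations, and empirical power under both sampling designs.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; identical seeds give bit-identical output.
Replicated studies inside :func:`empirical_power` are generated as one
replicate-by-sample block from that stream and tested with vectorised
closed forms of the same statistics computed by :mod:`mcmpower.assoc`
(agreement between the two routes is asserted in the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .core import MCMParams
from .power import DesignSpec

__all__ = ["SimDataset", "EmpiricalPower", "simulate_cohort", "eps_select",
           "empirical_power"]


@dataclass(frozen=True)
class SimDataset:
    """Per-sample realisation of the chain.

    ``tail_label`` is None for a plain cohort; for an EPS pool it marks
    each sample ``upper``, ``lower`` or ``none`` (not selected).
    """

    x1: np.ndarray
    x2: np.ndarray
    x3: np.ndarray
    y: np.ndarray
    seed: int
    params: MCMParams
    tail_label: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.x1.size
        if not (self.x2.size == self.x3.size == self.y.size == n):
            raise ValueError("all sample vectors must have equal length")
        if self.tail_label is not None and self.tail_label.size != n:
            raise ValueError("tail_label length mismatch")

    @property
    def n(self) -> int:
        return self.x1.size

    def selected(self) -> "SimDataset":
        """Restrict an EPS pool to the labelled tail samples."""
        if self.tail_label is None:
            return self
        keep = self.tail_label != "none"
        return SimDataset(self.x1[keep], self.x2[keep], self.x3[keep],
                          self.y[keep], self.seed, self.params,
                          self.tail_label[keep])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "sample_id": np.arange(self.n),
            "genotype": self.x1.astype(int),
            "rna": self.x2,
            "prt": self.x3,
            "trait": self.y,
        })
        if self.tail_label is not None:
            df["tail_label"] = self.tail_label
        return df


@dataclass(frozen=True)
class EmpiricalPower:
    level: str
    scheme: str
    n: int
    reps: int
    rejections: int
    power_hat: float
    mc_se: float


# hook for robustness experiments: any callable (rng, size) -> standard errors
ErrorSampler = Callable[[np.random.Generator, tuple[int, ...]], np.ndarray]


def _gaussian(rng: np.random.Generator, size) -> np.ndarray:
    return rng.standard_normal(size)


def _draw_chain(params: MCMParams, rng: np.random.Generator, size,
                error_sampler: ErrorSampler = _gaussian):
    x1 = rng.binomial(2, params.maf, size).astype(float)
    x2 = params.beta1 * x1 + math.sqrt(params.var_e2) * error_sampler(rng, size)
    x3 = params.beta2 * x2 + math.sqrt(params.var_e3) * error_sampler(rng, size)
    y = params.beta3 * x3 + math.sqrt(params.var_e4) * error_sampler(rng, size)
    return x1, x2, x3, y


def simulate_cohort(
    params: MCMParams,
    n: int,
    seed: int,
    error_sampler: ErrorSampler = _gaussian,
) -> SimDataset:
    """Simulate n independent subjects under simple random sampling."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    x1, x2, x3, y = _draw_chain(params, rng, n, error_sampler)
    return SimDataset(x1, x2, x3, y, seed=seed, params=params)


def _pool_size(n_selected: int, trunc_alpha: float) -> int:
    pool = math.ceil(n_selected / (2.0 * trunc_alpha))
    while int(pool * trunc_alpha) < n_selected // 2:
        pool += 1
    return pool


def eps_select(
    params: MCMParams,
    n_selected: int,
    trunc_alpha: float,
    seed: int,
    error_sampler: ErrorSampler = _gaussian,
) -> SimDataset:
    """Simulate an EPS study: screen a pool, keep the trait extremes.

    A pool of ceil(n_selected / (2*alpha)) subjects is simulated (grown
    deterministically if rounding leaves a tail short) and the
    n_selected/2 samples with the largest / smallest trait values are
    labelled ``upper`` / ``lower``.  The returned dataset is the full
    pool with labels; use :meth:`SimDataset.selected` for the retained
    extremes only.
    """
    if n_selected % 2:
        raise ValueError(f"n_selected must be even, got {n_selected}")
    if not 0.0 < trunc_alpha <= 0.5:
        raise ValueError(f"trunc_alpha must be in (0, 0.5], got {trunc_alpha}")
    pool = _pool_size(n_selected, trunc_alpha)
    rng = np.random.default_rng(seed)
    x1, x2, x3, y = _draw_chain(params, rng, pool, error_sampler)
    half = n_selected // 2
    order = np.argsort(y, kind="stable")  # index ties broken by sample order
    labels = np.full(pool, "none", dtype=object)
    labels[order[:half]] = "lower"
    labels[order[-half:]] = "upper"
    return SimDataset(x1, x2, x3, y, seed=seed, params=params,
                      tail_label=np.asarray(labels))


def _slope_t_pvalues(x: np.ndarray, y: np.ndarray, sides: int) -> np.ndarray:
    """Row-wise slope-test p-values; x, y are (reps, n) blocks.

    Uses the identity t = r * sqrt(df) / sqrt(1 - r^2) linking the slope
    t statistic to the sample correlation r.
    """
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", xc, xc)
    syy = np.einsum("ij,ij->i", yc, yc)
    sxy = np.einsum("ij,ij->i", xc, yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_sq = sxy**2 / (sxx * syy)
        r_sq = np.clip(np.nan_to_num(r_sq), 0.0, 1.0 - 1e-15)
        t_sq = r_sq * (n - 2) / (1.0 - r_sq)
    if sides == 2:
        return 2.0 * t_dist.sf(np.sqrt(t_sq), n - 2)
    return t_dist.sf(np.sign(sxy) * np.sqrt(t_sq), n - 2)


def _pooled_t_pvalues(upper: np.ndarray, lower: np.ndarray, sides: int) -> np.ndarray:
    """Row-wise pooled two-sample t p-values; groups are (reps, m) blocks."""
    nu, nl = upper.shape[1], lower.shape[1]
    df = nu + nl - 2
    diff = upper.mean(axis=1) - lower.mean(axis=1)
    pooled = ((nu - 1) * upper.var(axis=1, ddof=1)
              + (nl - 1) * lower.var(axis=1, ddof=1)) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(pooled * (1.0 / nu + 1.0 / nl))
        t = np.nan_to_num(t)
    if sides == 2:
        return 2.0 * t_dist.sf(np.abs(t), df)
    return t_dist.sf(t, df)


_CHUNK_BUDGET = 20_000_000  # samples per generated block, keeps memory modest


def empirical_power(
    params: MCMParams,
    design: DesignSpec,
    n: int,
    reps: int,
    seed: int,
    sig_level: float | None = None,
) -> dict[str, EmpiricalPower]:
    """Monte-Carlo rejection frequency of each level's test.

    Replicated studies of total size ``n`` are generated under
    ``design.scheme``, each level's test is applied at ``sig_level``
    (defaulting to the design's level), and the rejection fraction with
    its binomial standard error is returned per level.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if sig_level is None:
        sig_level = design.sig_level
    eps = design.scheme == "EPS"
    if eps and n % 2:
        raise ValueError(f"EPS requires even n, got {n}")
    per_rep = _pool_size(n, design.trunc_alpha) if eps else n
    rng = np.random.default_rng(seed)
    chunk = max(min(reps, _CHUNK_BUDGET // per_rep), 1)
    rejections = {level: 0 for level in ("SNP", "RNA", "PRT")}
    done = 0
    half = n // 2
    while done < reps:
        r = min(chunk, reps - done)
        x1, x2, x3, y = _draw_chain(params, rng, (r, per_rep))
        if eps:
            order = np.argsort(y, axis=1, kind="stable")
            lo_idx, up_idx = order[:, :half], order[:, -half:]
            for level, block in (("SNP", x1), ("RNA", x2), ("PRT", x3)):
                pv = _pooled_t_pvalues(
                    np.take_along_axis(block, up_idx, axis=1),
                    np.take_along_axis(block, lo_idx, axis=1),
                    design.sides,
                )
                rejections[level] += int((pv < sig_level).sum())
        else:
            for level, block in (("SNP", x1), ("RNA", x2), ("PRT", x3)):
                pv = _slope_t_pvalues(block, y, design.sides)
                rejections[level] += int((pv < sig_level).sum())
        done += r
    out = {}
    for level, rej in rejections.items():
        p_hat = rej / reps
        out[level] = EmpiricalPower(
            level=level, scheme=design.scheme, n=n, reps=reps, rejections=rej,
            power_hat=p_hat, mc_se=math.sqrt(p_hat * (1.0 - p_hat) / reps),
        )
    return out
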