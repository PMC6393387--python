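"""Variance and correlation algebra of the multi-omics causal chain.

The model is a linear structural chain following the central dogma::

    X1 (genotype) --b1--> X2 (RNA) --b2--> X3 (protein) --b3--> Y (trait)

with mutually independent exogenous Gaussian errors e2, e3, e4 added at
each downstream node.  The genotype X1 is the minor-allele count at a
biallelic SNP under Hardy-Weinberg equilibrium, so var(X1) = 2p(1-p) for
minor allele frequency p.

Each link of the chain carries a squared "mediate" correlation

    r1^2 = b1^2 var(X1) / var(X2)        (genotype - RNA)
    r2^2 = b2^2 var(X2) / var(X3)        (RNA - protein)
    r3^2 = b3^2 var(X3) / var(Y)         (protein - trait)

and the SNP heritability of the trait factorises as h^2 = r1^2 r2^2 r3^2.
Because every mediate correlation is below one, the squared correlation
of an omics level with the trait shrinks the further the level sits from
the trait: r3^2 >= r2^2 r3^2 >= h^2.

This module provides the forward map (structural parameters ->
correlations), its inverse (target correlations -> parameters, needed to
place simulations at a requested effect size), and the one-parameter
heritability path used to sweep the chain through a range of h^2 values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "MCMParams",
    "VarianceChain",
    "MediateCorrelations",
    "LevelCorrelations",
    "variance_chain",
    "mediate_correlations",
    "trait_correlations",
    "params_from_correlations",
    "scale_to_heritability",
]

_H2_ATOL = 1e-12


@dataclass(frozen=True)
class MCMParams:
    """Structural parameters of the causal chain.

    Parameters
    ----------
    maf : float
        Minor allele frequency of the causal SNP, in (0, 0.5].
    beta1, beta2, beta3 : float
        Slopes of the three structural equations
        (genotype->RNA, RNA->protein, protein->trait).
    var_e2, var_e3, var_e4 : float, default 1.0
        Variances of the exogenous errors entering RNA, protein and
        trait respectively.  Must be positive.
    """

    maf: float
    beta1: float
    beta2: float
    beta3: float
    var_e2: float = 1.0
    var_e3: float = 1.0
    var_e4: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        for name in ("var_e2", "var_e3", "var_e4"):
            v = getattr(self, name)
            if not v > 0.0:
                raise ValueError(f"{name} must be positive, got {v}")

    @property
    def betas(self) -> tuple[float, float, float]:
        return (self.beta1, self.beta2, self.beta3)


@dataclass(frozen=True)
class VarianceChain:
    """Population variances of genotype, RNA, protein and trait."""

    var_x1: float
    var_x2: float
    var_x3: float
    var_y: float

    def __post_init__(self) -> None:
        for name in ("var_x1", "var_x2", "var_x3", "var_y"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class MediateCorrelations:
    """Squared correlations of consecutive chain links, with h^2 derived.

    ``h2`` is always recomputed as the product ``r1sq * r2sq * r3sq``;
    it is not an independent degree of freedom.
    """

    r1sq: float
    r2sq: float
    r3sq: float
    h2: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("r1sq", "r2sq", "r3sq"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        object.__setattr__(self, "h2", self.r1sq * self.r2sq * self.r3sq)


@dataclass(frozen=True)
class LevelCorrelations:
    """Squared population correlation of each omics level with the trait."""

    snp: float
    rna: float
    prt: float

    def __post_init__(self) -> None:
        if not self.prt >= self.rna >= self.snp:
            raise ValueError("level correlations must satisfy prt >= rna >= snp")


def variance_chain(params: MCMParams) -> VarianceChain:
    """Propagate variances down the chain.

    var(X1) = 2p(1-p) under Hardy-Weinberg equilibrium; each downstream
    variance is slope^2 * upstream variance + error variance.
    """
    p = params.maf
    var_x1 = 2.0 * p * (1.0 - p)
    var_x2 = params.beta1**2 * var_x1 + params.var_e2
    var_x3 = params.beta2**2 * var_x2 + params.var_e3
    var_y = params.beta3**2 * var_x3 + params.var_e4
    return VarianceChain(var_x1, var_x2, var_x3, var_y)


def mediate_correlations(params: MCMParams) -> MediateCorrelations:
    """Squared mediate correlations r_k^2 of the three chain links."""
    vc = variance_chain(params)
    return MediateCorrelations(
        r1sq=params.beta1**2 * vc.var_x1 / vc.var_x2,
        r2sq=params.beta2**2 * vc.var_x2 / vc.var_x3,
        r3sq=params.beta3**2 * vc.var_x3 / vc.var_y,
    )


def trait_correlations(mc: MediateCorrelations) -> LevelCorrelations:
    """Squared correlation of each omics level with the trait.

    Substituting the chain equations into one another shows the trait is
    linear in each level plus independent noise, giving

        snp = r1^2 r2^2 r3^2 = h^2,  rna = r2^2 r3^2,  prt = r3^2,

    so proximity to the trait strictly increases the correlation when
    every mediate correlation lies strictly inside (0, 1).
    """
    return LevelCorrelations(
        snp=mc.h2,
        rna=mc.r2sq * mc.r3sq,
        prt=mc.r3sq,
    )


def params_from_correlations(
    target: MediateCorrelations,
    maf: float = 0.25,
    error_variances: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> MCMParams:
    """Invert :func:`mediate_correlations`.

    Solves for non-negative slopes reproducing the requested squared
    mediate correlations at the given allele frequency and error
    variances.  Signs of the slopes are unidentifiable from squared
    correlations; the positive root is returned.  The solve is exact:
    each link satisfies ``b_k^2 * var_up = r_k^2 * var_down`` and
    ``var_down = b_k^2 * var_up + var_e``, hence
    ``b_k^2 = r_k^2 var_e / ((1 - r_k^2) var_up)``.
    """
    ve2, ve3, ve4 = error_variances
    var_up = 2.0 * maf * (1.0 - maf)
    betas = []
    for r_sq, ve in ((target.r1sq, ve2), (target.r2sq, ve3), (target.r3sq, ve4)):
        if not 0.0 <= r_sq < 1.0:
            raise ValueError(f"squared correlation must be in [0, 1), got {r_sq}")
        b_sq = r_sq * ve / ((1.0 - r_sq) * var_up)
        betas.append(math.sqrt(b_sq))
        var_up = b_sq * var_up + ve
    return MCMParams(maf, *betas, ve2, ve3, ve4)


def scale_to_heritability(
    anchor: MediateCorrelations, h2_target: float
) -> MediateCorrelations:
    """Move along the heritability path through an anchor parameter set.

    All three squared mediate correlations are scaled by the common
    factor ``(h2_target / anchor.h2)**(1/3)``, so their product — the
    heritability — lands exactly on ``h2_target`` while the relative
    make-up of the chain is preserved.  Raises if any scaled squared
    correlation would reach 1.
    """
    if h2_target < 0.0:
        raise ValueError(f"h2_target must be non-negative, got {h2_target}")
    if h2_target == 0.0:
        return MediateCorrelations(0.0, 0.0, 0.0)
    if anchor.h2 <= 0.0:
        raise ValueError("anchor must have positive heritability")
    factor = (h2_target / anchor.h2) ** (1.0 / 3.0)
    scaled = tuple(r * factor for r in (anchor.r1sq, anchor.r2sq, anchor.r3sq))
    if any(r >= 1.0 for r in scaled):
        raise ValueError(
            f"h2_target={h2_target} pushes a squared mediate correlation to >= 1"
        )
    out = MediateCorrelations(*scaled)
    assert abs(out.h2 - h2_target) <= 1e-10 * h2_target + _H2_ATOL
    return out


#: Slopes anchoring the default heritability path: with maf = 0.25 and unit
#: error variances they give h^2 = 1.0% split as
#: (r1^2, r2^2, r3^2) ~= (0.110, 0.367, 0.248).
ANCHOR_BETAS = (0.5744, 0.7183, 0.4564)

#: Default chain parameters used throughout the numerical studies.
ANCHOR_PARAMS = MCMParams(0.25, *ANCHOR_BETAS)

#: Mediate correlations of the anchor chain.
ANCHOR_CORRELATIONS = mediate_correlations(ANCHOR_PARAMS)
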