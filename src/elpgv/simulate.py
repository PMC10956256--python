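"""Quantitative-trait simulation on synthetic marker panels.

The generator emulates a wheat-style inbred panel: 599 lines scored for 1279
dominant presence/absence (0/1) markers.  QTL are drawn uniformly among the
markers, effect magnitudes come from a Gamma(shape 0.4, scale 1.66)
distribution with random sign, and residual noise is scaled against the
empirical variance of the true genetic values so each replicate hits its
target heritability in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .learners import GenotypeMatrix

__all__ = [
    "SimulationDesign",
    "SimulatedTrait",
    "generate_genotypes",
    "simulate_trait",
    "wheat_fixture_genotypes",
]

#: Fixed seed of the bundled synthetic wheat-like genotype fixture.
WHEAT_FIXTURE_SEED = 599_1279


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one simulation scenario.

    The defaults reproduce the 5-QTL, heritability-0.5 scenario on a
    599 x 1279 dominant-marker panel; ``n_qtl`` is typically 5 (oligogenic)
    or 1000 (polygenic) and ``heritability`` 0.2 or 0.5.
    """

    n_individuals: int = 599
    n_markers: int = 1279
    marker_type: str = "binary_dominant"   # or "snp_biallelic"
    freq_range: tuple[float, float] = (0.1, 0.9)
    n_qtl: int = 5
    gamma_shape: float = 0.4
    gamma_scale: float = 1.66
    heritability: float = 0.5
    signed_effects: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if not 0.0 < self.heritability <= 1.0:
            raise ValueError("heritability must lie in (0, 1]")
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("gamma parameters must be positive")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("frequency range must lie inside (0, 1)")
        if self.marker_type not in ("binary_dominant", "snp_biallelic"):
            raise ValueError(f"unknown marker type {self.marker_type!r}")


@dataclass
class SimulatedTrait:
    """One simulated trait replicate with its generating truth."""

    phenotypes: np.ndarray
    genetic_values: np.ndarray
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    residual_variance: float
    realized_heritability: float


def generate_genotypes(
    design: SimulationDesign, rng: np.random.Generator
) -> GenotypeMatrix:
    """Draw a marker panel: Bernoulli presence/absence codes for dominant
    markers, or Hardy-Weinberg 0/1/2 dosages for biallelic SNPs, with
    per-marker frequencies uniform on ``design.freq_range``."""
    lo, hi = design.freq_range
    freqs = rng.uniform(lo, hi, size=design.n_markers)
    if design.marker_type == "binary_dominant":
        codes = (rng.random((design.n_individuals, design.n_markers)) < freqs)
        codes = codes.astype(float)
    else:
        codes = rng.binomial(
            2, freqs, size=(design.n_individuals, design.n_markers)
        ).astype(float)
    ids = np.array([f"ind{i:04d}" for i in range(design.n_individuals)])
    markers = np.array([f"m{k:05d}" for k in range(design.n_markers)])
    return GenotypeMatrix(ids, markers, codes)


def simulate_trait(
    genotypes: GenotypeMatrix,
    design: SimulationDesign,
    rng: np.random.Generator,
) -> SimulatedTrait:
    """Assign QTL and effects, then add normal noise scaled to the target
    heritability.

    Effect magnitudes are Gamma(shape, scale) draws; signs are +/- with equal
    probability unless ``design.signed_effects`` is off.  The residual
    variance is ``Var(g) * (1 - h2) / h2`` with ``Var(g)`` the empirical
    variance of the genetic values in this sample, so the realized
    heritability matches the target in expectation.  If every sampled QTL is
    monomorphic the QTL set is redrawn (at most 10 times).
    """
    Z = genotypes.codes
    for _ in range(10):
        qtl = rng.choice(genotypes.n_markers, size=design.n_qtl, replace=False)
        magnitudes = rng.gamma(design.gamma_shape, design.gamma_scale, design.n_qtl)
        if design.signed_effects:
            effects = magnitudes * rng.choice([-1.0, 1.0], size=design.n_qtl)
        else:
            effects = magnitudes
        g = Z[:, qtl] @ effects
        var_g = float(np.var(g))
        if var_g > 0:
            break
    else:
        raise RuntimeError(
            "all sampled QTL sets were monomorphic; cannot scale heritability"
        )
    h2 = design.heritability
    sigma_e2 = var_g * (1.0 - h2) / h2
    e = rng.normal(0.0, np.sqrt(sigma_e2), size=g.shape) if sigma_e2 > 0 else np.zeros_like(g)
    y = g + e
    realized = var_g / (var_g + float(np.var(e))) if sigma_e2 > 0 else 1.0
    return SimulatedTrait(
        phenotypes=y,
        genetic_values=g,
        qtl_indices=qtl,
        qtl_effects=effects,
        residual_variance=sigma_e2,
        realized_heritability=realized,
    )


def wheat_fixture_genotypes() -> GenotypeMatrix:
    """Deterministic synthetic stand-in for the public wheat panel: a
    599 x 1279 dominant presence/absence matrix generated from a fixed seed.

    It reproduces the panel's shape and marker type only, not its linkage
    structure; supply real genotypes by file where those matter.
    """
    design = SimulationDesign()
    return generate_genotypes(design, np.random.default_rng(WHEAT_FIXTURE_SEED))
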