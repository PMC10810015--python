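"""The semi-empirical lesion model for one voxel traversal.

A single particle track crossing the 36 nm³ voxel produces, on average,
λ_p(L) DNA lesions (strand breaks plus base lesions), where λ_p is a
per-particle quadratic in track-averaged LET anchored exactly on
published per-voxel lesion counts and on the clustered-damage threshold
LET (expected lesions = 2).  The quadratic is decomposed into

* a linear *direct* term — SSBs from DNA cation radicals, at the
  measured yield 2.1×10⁻² per eV deposited in the DNA;
* a linear *indirect* term — SSBs and base lesions from water-radiolysis
  radicals, at 1.2×10⁻² and 1.36×10⁻² per eV deposited in the water;
* a residual *LEE* term — lesions from low-energy electrons, classified
  into strand breaks and base lesions by the measured cross-section
  ratio σ_SB : σ_base = 3.8 : 4.8 (×10⁻² nm²).

Double-strand breaks follow a quadratic-in-SSB pairing form
min(k_D·s²/4, λ/2), with k_D calibrated so the expected DSB count is
exactly one at each particle's published minimum LET.

Stochastic realizations draw Poisson lesion totals, classify each lesion
SSB vs base, assign SSBs to strands, and count opposite-strand pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .config import (
    LET_DOMAIN,
    CalibrationSet,
    calibrate_lambda,
    default_calibration,
)

__all__ = [
    "LesionCounts",
    "LesionDecomposition",
    "calibrate_lambda",
    "mean_lesions",
    "decompose_lesions",
    "mean_dsb",
    "min_let_for",
    "sample_voxel_damage",
]

_PARTICLES = ("alpha", "proton", "electron")


def _check(particle_id: str, let: float) -> None:
    if particle_id not in _PARTICLES:
        raise KeyError(
            f"unknown particle {particle_id!r}; expected one of {_PARTICLES}")
    lo, hi = LET_DOMAIN
    if not (lo <= let <= hi):
        raise ValueError(
            f"LET {let} keV/μm outside the model domain [{lo}, {hi}]")


@dataclass(frozen=True)
class LesionCounts:
    """Sampled lesion tallies for one voxel traversal."""

    ssb: int
    dsb: int
    base: int
    total: int
    direct_part: float
    indirect_part: float
    lee_part: float


@dataclass(frozen=True)
class LesionDecomposition:
    """Mean lesion decomposition at a given particle/LET."""

    linear_direct: float
    linear_indirect: float
    lee_part: float
    ssb_mean: float
    base_mean: float

    @property
    def total(self) -> float:
        return self.linear_direct + self.linear_indirect + self.lee_part


def mean_lesions(
    particle_id: str, let: float, cal: CalibrationSet | None = None
) -> float:
    """Expected total lesions λ_p(L) per voxel traversal (clamped at 0)."""
    _check(particle_id, let)
    cal = cal or default_calibration()
    a, b, c = cal.value(f"lesions.lambda_coeffs.{particle_id}")
    return max(0.0, a * let * let + b * let + c)


def decompose_lesions(
    particle_id: str, let: float, cal: CalibrationSet | None = None
) -> LesionDecomposition:
    """Split λ_p(L) into direct / indirect / LEE parts and SSB / base means."""
    _check(particle_id, let)
    cal = cal or default_calibration()
    lam = mean_lesions(particle_id, let, cal)
    ell = cal.value("voxel.side_length_nm")
    f_dir = cal.value("voxel.direct_fraction")
    y_dir = cal.value("lesions.y_ssb_dir_per_ev")
    y_ind = cal.value("lesions.y_ssb_ind_per_ev")
    y_base = cal.value("lesions.y_base_ind_per_ev")
    lin_dir = ell * let * f_dir * y_dir
    lin_ind = ell * let * (1.0 - f_dir) * (y_ind + y_base)
    lee = max(0.0, lam - lin_dir - lin_ind)
    s = ell * let * (f_dir * y_dir + (1.0 - f_dir) * y_ind) \
        + lee * cal.value("lesions.sb_share")
    return LesionDecomposition(
        linear_direct=lin_dir,
        linear_indirect=lin_ind,
        lee_part=lee,
        ssb_mean=s,
        base_mean=max(0.0, lam - s),
    )


def mean_dsb(
    particle_id: str, let: float, cal: CalibrationSet | None = None
) -> float:
    """Expected DSBs per traversal: min(k_D·s²/4, λ/2)."""
    _check(particle_id, let)
    cal = cal or default_calibration()
    s = decompose_lesions(particle_id, let, cal).ssb_mean
    k_d = cal.value(f"lesions.dsb_scale.{particle_id}")
    lam = mean_lesions(particle_id, let, cal)
    return min(k_d * s * s / 4.0, lam / 2.0)


_QUANTITIES = {"total_lesions": mean_lesions, "dsb": mean_dsb}
_BRACKET = (0.1, 300.0)


def min_let_for(
    particle_id: str,
    quantity: str,
    level: float,
    cal: CalibrationSet | None = None,
    tol: float = 1e-3,
) -> float:
    """Minimum LET at which ``quantity`` reaches ``level`` (bisection).

    ``quantity`` is ``"total_lesions"`` or ``"dsb"``.  The root is
    bracketed on [0.1, 300] keV/μm; both quantities are nondecreasing
    there, which is asserted before solving.
    """
    if quantity not in _QUANTITIES:
        raise KeyError(
            f"unknown quantity {quantity!r}; expected one of "
            f"{sorted(_QUANTITIES)}")
    cal = cal or default_calibration()
    func = _QUANTITIES[quantity]
    lo, hi = _BRACKET
    f_lo = func(particle_id, lo, cal) - level
    f_hi = func(particle_id, hi, cal) - level
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            f"level {level} for {quantity} not attainable on the bracket "
            f"[{lo}, {hi}]: endpoint values "
            f"({f_lo + level:.4g}, {f_hi + level:.4g})")
    grid = np.linspace(lo, hi, 64)
    vals = [func(particle_id, g, cal) for g in grid]
    if any(b < a - 1e-9 for a, b in zip(vals, vals[1:])):
        raise ValueError(
            f"{quantity} is not monotone on the bracket for {particle_id}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if func(particle_id, mid, cal) - level < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sample_voxel_damage(
    particle_id: str,
    let: float,
    seed: int | None = None,
    cal: CalibrationSet | None = None,
    rng: np.random.Generator | None = None,
) -> LesionCounts:
    """One stochastic voxel traversal.

    Total lesions are Poisson(λ); each lesion is an SSB with probability
    s/λ, else a base lesion; SSBs land on either strand with equal
    probability, and the stochastic DSB count is the number of
    opposite-strand pairs, min(strand 1 SSBs, strand 2 SSBs).  The
    direct/indirect/LEE parts report the expected decomposition scaled
    to the sampled total.
    """
    _check(particle_id, let)
    cal = cal or default_calibration()
    if rng is None:
        rng = substream(seed, "lesions")
    lam = mean_lesions(particle_id, let, cal)
    dec = decompose_lesions(particle_id, let, cal)
    total = int(rng.poisson(lam))
    p_ssb = dec.ssb_mean / lam if lam > 0 else 0.0
    ssb = int(rng.binomial(total, p_ssb)) if total else 0
    strand1 = int(rng.binomial(ssb, 0.5)) if ssb else 0
    dsb = min(strand1, ssb - strand1)
    scale = total / lam if lam > 0 else 0.0
    return LesionCounts(
        ssb=ssb,
        dsb=dsb,
        base=total - ssb,
        total=total,
        direct_part=dec.linear_direct * scale,
        indirect_part=dec.linear_indirect * scale,
        lee_part=dec.lee_part * scale,
    )
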