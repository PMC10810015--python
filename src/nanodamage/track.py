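"""Stochastic surrogates for track-structure outputs in the voxel.

Two quantities are modeled per voxel traversal:

* **Ionizations** — the mean count is linear in track-averaged LET,
  a_p + b_p·L, with the published slopes (0.10, 0.11 and 0.14 per
  keV/μm for alpha, proton and electron) and intercepts calibrated so
  the line passes exactly through each particle's published
  maximum-LET count (17.0, 9.4, 4.4).  Per-traversal counts are
  Poisson about the mean.

* **Low-energy electrons (LEEs)** — counts grow quadratically with LET;
  they are obtained from the calibrated total-lesion mean by removing
  the linear (non-LEE) lesion term and dividing by the per-LEE lesion
  probability, which keeps LEE counts and lesion tallies internally
  consistent.  The LEE energy spectrum is a fixed three-component
  mixture on [1, 25] eV — a broad bump near 2–6 eV, a dominant narrow
  peak at 8–11 eV and an exponentially decaying tail beyond 15 eV —
  identical for all particles and LETs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._rng import substream
from .config import LET_DOMAIN, CalibrationSet, default_calibration
from .lesions import mean_lesions

__all__ = [
    "IonizationModel",
    "LEESpectrum",
    "mean_ionizations",
    "sample_ionizations",
    "mean_lee_count",
    "sample_lee_spectrum",
]

_PARTICLES = ("alpha", "proton", "electron")


@dataclass(frozen=True)
class IonizationModel:
    """Per-particle linear ionization model, mean = intercept + slope·L."""

    slopes: dict
    intercepts: dict

    @classmethod
    def from_calibration(cls, cal: CalibrationSet | None = None) -> "IonizationModel":
        cal = cal or default_calibration()
        return cls(
            slopes={p: cal.value(f"ionization.slope.{p}") for p in _PARTICLES},
            intercepts={p: cal.value(f"ionization.intercept.{p}") for p in _PARTICLES},
        )

    def mean(self, particle_id: str, let: float) -> float:
        if particle_id not in self.slopes:
            raise KeyError(
                f"unknown particle {particle_id!r}; expected one of "
                f"{_PARTICLES}")
        lo, hi = LET_DOMAIN
        if not (lo <= let <= hi):
            raise ValueError(
                f"LET {let} keV/μm outside the model domain [{lo}, {hi}]")
        return self.intercepts[particle_id] + self.slopes[particle_id] * let


def mean_ionizations(
    particle_id: str, track_averaged_let: float, cal: CalibrationSet | None = None
) -> float:
    """Mean ionizations per voxel traversal."""
    return IonizationModel.from_calibration(cal).mean(particle_id, track_averaged_let)


def sample_ionizations(
    particle_id: str,
    track_averaged_let: float,
    seed: int | None = None,
    size: int | None = None,
    cal: CalibrationSet | None = None,
    rng: np.random.Generator | None = None,
):
    """Poisson ionization counts per traversal (scalar, or array if ``size``)."""
    mu = mean_ionizations(particle_id, track_averaged_let, cal)
    if rng is None:
        rng = substream(seed, "ionization")
    if size is None:
        return int(rng.poisson(mu))
    return rng.poisson(mu, size=size)


def mean_lee_count(
    particle_id: str, track_averaged_let: float, cal: CalibrationSet | None = None
) -> float:
    """Mean LEEs per traversal, max(0, λ_p(L) − c_lin·L) / p_LEE."""
    cal = cal or default_calibration()
    lam = mean_lesions(particle_id, track_averaged_let, cal)
    c_lin = cal.value("lesions.c_lin_per_kev_um")
    p_lee = cal.value("lesions.p_lee")
    return max(0.0, lam - c_lin * track_averaged_let) / p_lee


class LEESpectrum:
    """Three-component LEE energy spectrum on [1, 25] eV.

    Truncated-normal bump + truncated-normal peak + shifted-exponential
    tail (truncated at the upper support edge); weights sum to one and
    the density is zero outside the support.  Shape parameters are
    assumption-tagged calibration constants — the spectrum is shape-only.
    """

    def __init__(self, cal: CalibrationSet | None = None):
        cal = cal or default_calibration()
        self.support = tuple(cal.value("lee.support_ev"))
        lo, hi = self.support
        b_loc = cal.value("lee.bump_loc_ev")
        b_sc = cal.value("lee.bump_scale_ev")
        p_loc = cal.value("lee.peak_loc_ev")
        p_sc = cal.value("lee.peak_scale_ev")
        t0 = cal.value("lee.tail_start_ev")
        t_sc = cal.value("lee.tail_scale_ev")
        self.weights = np.array(
            [
                cal.value("lee.bump_weight"),
                cal.value("lee.peak_weight"),
                cal.value("lee.tail_weight"),
            ]
        )
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError(
                f"LEE spectrum weights must sum to 1, got {self.weights.sum()}")
        self._components = [
            stats.truncnorm((lo - b_loc) / b_sc, (hi - b_loc) / b_sc,
                            loc=b_loc, scale=b_sc),
            stats.truncnorm((lo - p_loc) / p_sc, (hi - p_loc) / p_sc,
                            loc=p_loc, scale=p_sc),
            stats.truncexpon((hi - t0) / t_sc, loc=t0, scale=t_sc),
        ]

    def pdf(self, energy_ev):
        """Mixture density (zero outside the support)."""
        e = np.asarray(energy_ev, dtype=float)
        lo, hi = self.support
        out = np.zeros_like(e)
        inside = (e >= lo) & (e <= hi)
        for w, comp in zip(self.weights, self._components):
            out = np.where(inside, out + w * comp.pdf(e), out)
        return out if out.ndim else float(out)

    def sample(
        self,
        n: int,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """``n`` LEE energies (eV) drawn from the mixture."""
        if n < 0:
            raise ValueError(f"sample count must be nonnegative, got {n}")
        if rng is None:
            rng = substream(seed, "lee_spectrum")
        if n == 0:
            return np.empty(0)
        which = rng.choice(3, size=n, p=self.weights)
        out = np.empty(n)
        for i, comp in enumerate(self._components):
            mask = which == i
            k = int(mask.sum())
            if k:
                out[mask] = comp.rvs(size=k, random_state=rng)
        return out


def sample_lee_spectrum(
    n: int,
    seed: int | None = None,
    cal: CalibrationSet | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """``n`` LEE energies in eV; the spectrum is particle- and LET-independent."""
    return LEESpectrum(cal).sample(n, seed=seed, rng=rng)
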