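"""LET-dependent water-radiolysis G-values at the 100 ns snapshot.

G-values (species per 100 eV deposited) in the nanometric voxel are
piecewise-linear in track-averaged LET.  The radical species (°OH, eaq−,
H°) rise linearly from a baseline to a species-specific peak LET
(66, 30 and 100 keV/μm) and then decline slowly; hydrogen peroxide is
zero below a 5 keV/μm onset, rises linearly (for alphas up to a
100 keV/μm breakpoint, then at a shallower rate), and passes exactly
through the published maxima — 1.15 (proton) and 1.44 (alpha) per
100 eV at each particle's maximum track-averaged LET.  Beyond a
particle's maximum tabulated LET the curve is held flat, which also
keeps the electron H₂O₂ curve under its 0.3 ceiling everywhere.

Yields are effectively time-independent after ~10 ns, so the module
exposes only the 100 ns snapshot.
"""

from __future__ import annotations

import numpy as np

from .config import LET_DOMAIN, CalibrationSet, default_calibration

__all__ = ["g_value", "peak_let", "oh_rise_rate", "curve_knots"]

RADICALS = ("OH", "e_aq", "H")
SPECIES = RADICALS + ("H2O2",)
_ION_PARTICLES = ("proton", "alpha")


def curve_knots(
    species: str, particle_id: str, cal: CalibrationSet | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Knot points (LET, G) of the piecewise-linear curve."""
    cal = cal or default_calibration()
    lo, hi = LET_DOMAIN
    if species in RADICALS:
        if particle_id not in _ION_PARTICLES:
            raise KeyError(
                f"{species} curve is defined for proton and alpha only, "
                f"not {particle_id!r}")
        g0 = cal.value("radiolysis.g0")
        rate = cal.value(f"radiolysis.rise.{species}.{particle_id}")
        peak = cal.value(f"radiolysis.peak_let.{species}")
        decline = cal.value(f"radiolysis.decline.{species}")
        g_peak = g0 + rate * peak
        g_end = max(0.0, g_peak - decline * (hi - peak))
        return np.array([lo, peak, hi]), np.array([g0, g_peak, g_end])
    if species == "H2O2":
        if particle_id not in _ION_PARTICLES + ("electron",):
            raise KeyError(f"unknown particle {particle_id!r}")
        onset = cal.value("radiolysis.h2o2_onset_let")
        l_max, g_max = cal.value(f"radiolysis.h2o2_max.{particle_id}")
        brk = cal.value("radiolysis.h2o2_breakpoint_let")
        if l_max > brk:
            # rise to the breakpoint, shallower segment to the maximum
            g_brk = cal.value(f"radiolysis.h2o2_breakpoint_value.{particle_id}")
            xs = [lo, onset, brk, l_max, hi]
            ys = [0.0, 0.0, g_brk, g_max, g_max]
        else:
            # the particle's maximum LET sits below the breakpoint:
            # a single linear rise, clamped flat past the maximum
            xs = [lo, onset, l_max, hi]
            ys = [0.0, 0.0, g_max, g_max]
        return np.array(xs), np.array(ys)
    raise KeyError(f"unknown species {species!r}; expected one of {SPECIES}")


def g_value(
    species: str,
    particle_id: str,
    let: float,
    cal: CalibrationSet | None = None,
):
    """G-value (per 100 eV) at 100 ns for the given species/particle/LET."""
    lo, hi = LET_DOMAIN
    lets = np.asarray(let, dtype=float)
    if np.any((lets < lo) | (lets > hi)):
        raise ValueError(f"LET {let} outside the domain [{lo}, {hi}] keV/μm")
    xs, ys = curve_knots(species, particle_id, cal)
    out = np.interp(lets, xs, ys)
    return float(out) if out.ndim == 0 else out


def peak_let(
    species: str, particle_id: str, cal: CalibrationSet | None = None
) -> float:
    """Grid-search argmax of the radical G-curve over [0, 300], 0.1 steps."""
    if species == "H2O2":
        raise KeyError("H2O2 is monotone nondecreasing and has no interior peak")
    grid = np.arange(LET_DOMAIN[0], LET_DOMAIN[1] + 1e-9, 0.1)
    vals = g_value(species, particle_id, grid, cal)
    return float(grid[int(np.argmax(vals))])


def oh_rise_rate(particle_id: str, cal: CalibrationSet | None = None) -> float:
    """OLS slope of the °OH curve over LET 5–60 keV/μm (1 keV/μm grid)."""
    grid = np.arange(5.0, 60.0 + 1e-9, 1.0)
    vals = g_value("OH", particle_id, grid, cal)
    slope, _ = np.polyfit(grid, vals, 1)
    return float(slope)
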