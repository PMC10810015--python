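"""Registry of the simulated particles and their energy–LET tables.

Three particle types are supported — electrons, protons and alpha
particles — each with ten tabulated energies and the corresponding
initial and track-averaged linear energy transfer (LET, keV/μm) through
a 36 nm³ voxel of hydrated DNA.  Track-averaged LET is the quantity all
downstream damage models are parameterised on; initial LET is the LET
of the incident particle at the voxel entrance.

Energies are stored in the unit each table is printed in: MeV for
protons and alphas, keV for electrons (whose tabulated range runs from
0.1 keV to 500 keV).  ``ParticleRecord.energy_unit`` carries the unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ParticleRecord",
    "PARTICLES",
    "lookup_let",
    "let_to_energy",
    "registry_table",
]

# (energy, initial LET, track-averaged LET); energy unit per particle.
_ALPHA_ROWS = (
    (0.75, 233.8, 262.2),
    (1.0, 219.0, 221.7),
    (2.0, 161.4, 162.4),
    (4.0, 101.3, 103.4),
    (7.0, 67.4, 69.5),
    (10.0, 51.5, 53.4),
    (20.0, 30.6, 31.4),
    (50.0, 14.6, 15.2),
    (100.0, 8.1, 8.6),
    (200.0, 4.5, 4.9),
)

_PROTON_ROWS = (
    (0.1, 70.6, 81.5),
    (0.2, 66.0, 66.2),
    (0.5, 41.0, 41.3),
    (1.0, 26.7, 28.0),
    (2.0, 15.9, 16.9),
    (5.0, 7.9, 8.8),
    (10.0, 4.8, 5.0),
    (20.0, 2.6, 2.8),
    (50.0, 1.2, 1.3),
    (100.0, 0.7, 0.7),
)

# electron energies in keV
_ELECTRON_ROWS = (
    (0.1, 28.7, 28.7),
    (0.2, 26.6, 28.5),
    (0.5, 17.0, 18.6),
    (1.0, 11.2, 12.5),
    (2.0, 7.1, 7.3),
    (5.0, 3.6, 3.8),
    (10.0, 2.1, 2.2),
    (50.0, 0.7, 0.7),
    (100.0, 0.4, 0.4),
    (500.0, 0.2, 0.2),
)


@dataclass(frozen=True)
class ParticleRecord:
    """One particle type with its tabulated energy ↔ LET rows."""

    particle_id: str
    energy_unit: str  # unit of the energy column ("MeV" or "keV")
    rows: tuple[tuple[float, float, float], ...] = field(repr=False)

    @property
    def energies(self) -> tuple[float, ...]:
        return tuple(r[0] for r in self.rows)

    @property
    def initial_lets(self) -> tuple[float, ...]:
        return tuple(r[1] for r in self.rows)

    @property
    def track_avg_lets(self) -> tuple[float, ...]:
        return tuple(r[2] for r in self.rows)

    @property
    def energy_range(self) -> tuple[float, float]:
        return self.rows[0][0], self.rows[-1][0]

    @property
    def let_range(self) -> tuple[float, float]:
        """Track-averaged LET range (min, max)."""
        lets = self.track_avg_lets
        return min(lets), max(lets)


PARTICLES: dict[str, ParticleRecord] = {
    "alpha": ParticleRecord("alpha", "MeV", _ALPHA_ROWS),
    "proton": ParticleRecord("proton", "MeV", _PROTON_ROWS),
    "electron": ParticleRecord("electron", "keV", _ELECTRON_ROWS),
}


def _get(particle_id: str) -> ParticleRecord:
    try:
        return PARTICLES[particle_id]
    except KeyError:
        raise KeyError(
            f"unknown particle {particle_id!r}; expected one of "
            f"{sorted(PARTICLES)}"
        ) from None


def _loglog_interp(x: float, x0: float, x1: float, y0: float, y1: float) -> float:
    # linear in log(x)-log(y); LET-energy relations are near power-law
    t = (math.log(x) - math.log(x0)) / (math.log(x1) - math.log(x0))
    return math.exp(math.log(y0) + t * (math.log(y1) - math.log(y0)))


def lookup_let(particle_id: str, energy: float) -> tuple[float, float]:
    """Return (initial LET, track-averaged LET) in keV/μm at ``energy``.

    ``energy`` is in the particle's tabulated unit (MeV for protons and
    alphas, keV for electrons).  Exact row values are returned when the
    energy matches a tabulated row; otherwise both LET columns are
    log-log linearly interpolated between the bracketing rows.
    """
    rec = _get(particle_id)
    lo, hi = rec.energy_range
    if not (lo <= energy <= hi):
        raise ValueError(
            f"energy {energy} {rec.energy_unit} outside the tabulated range "
            f"[{lo}, {hi}] {rec.energy_unit} for {particle_id}"
        )
    rows = rec.rows
    for e, li, lt in rows:
        if energy == e:
            return li, lt
    for (e0, i0, t0), (e1, i1, t1) in zip(rows, rows[1:]):
        if e0 < energy < e1:
            return (
                _loglog_interp(energy, e0, e1, i0, i1),
                _loglog_interp(energy, e0, e1, t0, t1),
            )
    raise AssertionError("unreachable")  # pragma: no cover


def let_to_energy(particle_id: str, track_averaged_let: float) -> float:
    """Inverse of :func:`lookup_let` on the track-averaged LET column.

    Returns the energy (in the particle's tabulated unit) whose
    track-averaged LET equals the argument.  LET decreases strictly with
    energy in every table, so the inverse is single-valued.
    """
    rec = _get(particle_id)
    lets = rec.track_avg_lets
    lo, hi = min(lets), max(lets)
    if not (lo <= track_averaged_let <= hi):
        raise ValueError(
            f"track-averaged LET {track_averaged_let} keV/μm outside the "
            f"tabulated range [{lo}, {hi}] keV/μm for {particle_id}"
        )
    rows = rec.rows
    for e, _li, lt in rows:
        if track_averaged_let == lt:
            return e
    # rows are ordered by increasing energy / decreasing LET
    for (e0, _i0, t0), (e1, _i1, t1) in zip(rows, rows[1:]):
        if t1 < track_averaged_let < t0:
            return _loglog_interp(track_averaged_let, t0, t1, e0, e1)
    # duplicated-LET plateaus (e.g. electron 0.7 at two energies) are
    # caught by the exact match above; anything else is a range error
    raise ValueError(
        f"LET {track_averaged_let} falls on a plateau of the "
        f"{particle_id} table with no unique energy"
    )


def registry_table():
    """The full registry as a pandas DataFrame (CSV column order)."""
    import pandas as pd

    recs = []
    for pid, rec in PARTICLES.items():
        for e, li, lt in rec.rows:
            e_mev = e / 1000.0 if rec.energy_unit == "keV" else e
            recs.append(
                {
                    "particle": pid,
                    "energy_MeV": e_mev,
                    "initial_LET": li,
                    "track_avg_LET": lt,
                }
            )
    return pd.DataFrame.from_records(recs)
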