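"""Hydrated-DNA voxel geometry and deterministic energy bookkeeping.

The scoring volume is a 36.0 nm³ cube holding 15 base pairs of DNA with
its first and second hydration layers (20 water molecules per
nucleotide, 600 waters in total).  A particle traversal deposits
LET × ℓ eV in the voxel (straight chord through a face, using the
identity 1 keV/μm = 1 eV/nm), and the deposit is split half-and-half
between the DNA itself (direct action) and its water (indirect action),
the ratio implied by the relative volumes of the non-hydrated DNA and
the 600 water molecules.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import CalibrationSet, default_calibration

__all__ = ["VoxelGeometry", "energy_deposited_per_traversal", "partition_energy"]


@dataclass(frozen=True)
class VoxelGeometry:
    """Geometry and composition of the hydrated-DNA voxel."""

    volume_nm3: float
    side_length_nm: float
    base_pairs: int
    waters_per_nucleotide: int
    water_count: int
    water_molecule_volume_nm3: float
    composition: dict
    dna_density_g_cm3: float
    direct_fraction: float

    @classmethod
    def from_calibration(cls, cal: CalibrationSet | None = None) -> "VoxelGeometry":
        cal = cal or default_calibration()
        return cls(
            volume_nm3=cal.value("voxel.volume_nm3"),
            side_length_nm=cal.value("voxel.side_length_nm"),
            base_pairs=cal.value("voxel.base_pairs"),
            waters_per_nucleotide=cal.value("voxel.waters_per_nucleotide"),
            water_count=cal.value("voxel.water_count"),
            water_molecule_volume_nm3=cal.value("voxel.water_molecule_volume_nm3"),
            composition=dict(cal.value("voxel.composition")),
            dna_density_g_cm3=cal.value("voxel.dna_density_g_cm3"),
            direct_fraction=cal.value("voxel.direct_fraction"),
        )

    @property
    def water_volume_nm3(self) -> float:
        return self.water_count * self.water_molecule_volume_nm3

    @property
    def molecule_count(self) -> int:
        """DNA constituent molecules (THF + TMP + PU + PY), excluding water."""
        return sum(self.composition.values())


def energy_deposited_per_traversal(
    track_averaged_let: float, cal: CalibrationSet | None = None
) -> float:
    """Energy (eV) deposited by one straight traversal at the given LET.

    LET is in keV/μm ≡ eV/nm, so the deposit is LET × side length.
    """
    if track_averaged_let < 0:
        raise ValueError(f"LET must be nonnegative, got {track_averaged_let}")
    cal = cal or default_calibration()
    return track_averaged_let * cal.value("voxel.side_length_nm")


def partition_energy(
    energy_ev: float, cal: CalibrationSet | None = None
) -> tuple[float, float]:
    """Split a deposit into (E_DNA, E_water) eV; the sum is conserved exactly."""
    if energy_ev < 0:
        raise ValueError(f"energy must be nonnegative, got {energy_ev}")
    cal = cal or default_calibration()
    f_dir = cal.value("voxel.direct_fraction")
    e_dna = f_dir * energy_ev
    return e_dna, energy_ev - e_dna
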