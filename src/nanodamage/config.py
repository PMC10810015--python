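"""Calibration constants with provenance, and the config file interface.

Every numeric constant of the simulator lives in a :class:`CalibrationSet`:
voxel geometry, ionization-model slopes and intercepts, LEE spectrum shape
parameters, radiolysis G-curve parameters, lesion yields and cross-sections,
the anchored lesion quadratics, DSB scales, and nucleus-scale constants.

Each constant carries exactly one provenance tag:

``paper_printed``
    a number printed verbatim in the source publication's text or tables;
``paper_anchored_fit``
    an anchor list assembled from printed numbers, through which a model
    is fitted exactly;
``derived``
    a value computed from other constants by a stated procedure (these are
    recomputed on every build and cannot be overridden);
``assumption``
    a shape or amplitude the publication does not print numerically,
    chosen here and freely overridable.

A config file is a YAML mapping of constant names to replacement values.
``paper_printed`` constants may only be overridden with ``allow_override``.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from typing import Any, Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "Constant",
    "CalibrationSet",
    "default_calibration",
    "load_config",
    "calibrate_lambda",
    "invert_site_count",
]

PROVENANCE_TAGS = ("paper_printed", "paper_anchored_fit", "derived", "assumption")

#: LET domain (keV/μm) on which every parametric curve is defined.
LET_DOMAIN = (0.0, 300.0)


@dataclass(frozen=True)
class Constant:
    """One calibration constant with provenance."""

    value: Any
    provenance: str
    citation: str = ""

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCE_TAGS:
            raise ValueError(f"unknown provenance tag {self.provenance!r}")
        object.__setattr__(self, "value", _freeze(self.value))


def _freeze(v: Any) -> Any:
    if isinstance(v, (list, tuple)):
        return tuple(_freeze(x) for x in v)
    if isinstance(v, dict):
        return {k: _freeze(x) for k, x in v.items()}
    return v


def _thaw(v: Any) -> Any:
    if isinstance(v, tuple):
        return [_thaw(x) for x in v]
    if isinstance(v, dict):
        return {k: _thaw(x) for k, x in v.items()}
    return v


# --------------------------------------------------------------------------
# calibration math (pure helpers; re-exported by the lesions module)

def calibrate_lambda(anchors) -> tuple[float, float, float]:
    """Exact quadratic a·L² + b·L + c through three (LET, λ) anchors.

    Solves the 3×3 Vandermonde system; raises on duplicate LETs.
    """
    anchors = [(float(L), float(lam)) for L, lam in anchors]
    if len(anchors) != 3:
        raise ValueError("exactly three (LET, lambda) anchors are required")
    lets = [L for L, _ in anchors]
    if len(set(lets)) != 3:
        raise ValueError(f"duplicate anchor LETs: {lets}")
    V = np.array([[L * L, L, 1.0] for L, _ in anchors])
    y = np.array([lam for _, lam in anchors])
    a, b, c = np.linalg.solve(V, y)
    return float(a), float(b), float(c)


def invert_site_count(
    let: float, sites: float, *, energy_kev: float, diameter_um: float, n_v: int
) -> float:
    """Per-voxel lesion mean λ implied by a nucleus damage-site count.

    Inverts sites = n_tracks · N_v · (1 − exp(−N_v·λ)) with
    n_tracks = E / (LET · d).
    """
    n_tracks = energy_kev / (let * diameter_um)
    p = sites / (n_tracks * n_v)
    if not 0.0 < p < 1.0:
        raise ValueError(f"site count {sites} not invertible at LET {let}")
    return -math.log1p(-p) / n_v


# --------------------------------------------------------------------------
# base (settable) constants

def _base_constants() -> dict[str, Constant]:
    P = "paper_printed"
    A = "assumption"
    c: dict[str, Constant] = {}

    def put(name, value, tag, cite):
        c[name] = Constant(value, tag, cite)

    # voxel geometry
    put("voxel.volume_nm3", 36.0, P, "36.0 nm^3 voxel of 15 bp hydrated DNA")
    put("voxel.base_pairs", 15, P, "15 base pairs per voxel")
    put("voxel.waters_per_nucleotide", 20, P, "hydration shell, 20 H2O per nucleotide")
    put("voxel.water_count", 600, P, "600 H2O molecules per voxel")
    put("voxel.water_molecule_volume_nm3", 0.0299, P, "volume of one H2O molecule")
    put("voxel.composition", {"THF": 30, "TMP": 30, "PU": 15, "PY": 15}, P,
        "molecular composition of the 15 bp voxel")
    put("voxel.dna_density_g_cm3", 1.4, P, "DNA density")
    put("voxel.direct_fraction", 0.5, P,
        "fraction of deposited energy assigned to the DNA (direct action)")

    # ionization surrogate: mean = intercept + slope · LET
    for pid, slope in (("alpha", 0.10), ("proton", 0.11), ("electron", 0.14)):
        put(f"ionization.slope.{pid}", slope, P,
            "linear rate of ionizations per keV/um")
    for pid, (L, v) in (
        ("alpha", (162.4, 17.0)),
        ("proton", (81.5, 9.4)),
        ("electron", (28.7, 4.4)),
    ):
        put(f"ionization.anchor.{pid}", (L, v), P,
            "ionizations per traversal at the particle's maximum "
            "track-averaged LET")

    # LEE energy spectrum (shape-only; mixture over [1, 25] eV)
    put("lee.support_ev", (1.0, 25.0), P, "LEE energy range 1-25 eV")
    put("lee.bump_loc_ev", 4.0, A, "broad low-energy bump, 2-6 eV; shape-only")
    put("lee.bump_scale_ev", 1.5, A, "shape-only")
    put("lee.bump_weight", 0.25, A, "shape-only")
    put("lee.peak_loc_ev", 9.5, A, "dominant narrow peak, 8-11 eV; shape-only")
    put("lee.peak_scale_ev", 1.2, A, "shape-only")
    put("lee.peak_weight", 0.60, A, "shape-only")
    put("lee.tail_start_ev", 15.0, A, "rapid decrease beyond 15 eV; shape-only")
    put("lee.tail_scale_ev", 2.5, A, "shape-only")
    put("lee.tail_weight", 0.15, A, "shape-only")

    # radiolysis G-curves at the 100 ns snapshot
    put("radiolysis.g0", 0.5, A,
        "zero-LET baseline G-value for the radical species; amplitude "
        "not numerically readable")
    put("radiolysis.rise.OH.proton", 0.047, P, "OH rise rate, proton")
    put("radiolysis.rise.OH.alpha", 0.054, P, "OH rise rate, alpha")
    put("radiolysis.rise.e_aq.proton", 0.040, A, "amplitude assumption")
    put("radiolysis.rise.e_aq.alpha", 0.045, A, "amplitude assumption")
    put("radiolysis.rise.H.proton", 0.020, A, "amplitude assumption")
    put("radiolysis.rise.H.alpha", 0.025, A, "amplitude assumption")
    put("radiolysis.peak_let.OH", 66.0, P, "OH yield maximal at 66 keV/um")
    put("radiolysis.peak_let.e_aq", 30.0, P, "e_aq yield maximal near 30 keV/um")
    put("radiolysis.peak_let.H", 100.0, P, "H yield maximal near 100 keV/um")
    put("radiolysis.decline.OH", 0.008, A, "slow post-peak decline; shape-only")
    put("radiolysis.decline.e_aq", 0.004, A, "shape-only")
    put("radiolysis.decline.H", 0.003, A, "shape-only")
    put("radiolysis.h2o2_onset_let", 5.0, P,
        "H2O2 negligible below 5 keV/um; modeled as a hard onset")
    put("radiolysis.h2o2_breakpoint_let", 100.0, P,
        "H2O2 rises linearly up to 100 keV/um, then at a lower rate")
    put("radiolysis.h2o2_max.proton", (81.5, 1.15), P,
        "maximum H2O2 G-value at the proton maximum track-averaged LET")
    put("radiolysis.h2o2_max.alpha", (262.2, 1.44), P,
        "maximum H2O2 G-value at the alpha maximum track-averaged LET")
    put("radiolysis.h2o2_breakpoint_value.alpha", 1.0, A,
        "alpha H2O2 G-value at the 100 keV/um breakpoint; shape-only")
    put("radiolysis.h2o2_ceiling.electron", 0.3, P,
        "electron H2O2 yields stay under 0.3 per 100 eV")
    put("radiolysis.h2o2_max.electron", (28.7, 0.25), A,
        "electron H2O2 amplitude at its maximum LET; kept below the "
        "printed 0.3 ceiling")

    # measured lesion yields and cross-sections
    put("lesions.sigma_sb_nm2", 3.8e-2, P, "LEE strand-break cross-section")
    put("lesions.sigma_base_nm2", 4.8e-2, P, "LEE base-lesion cross-section")
    put("lesions.y_ssb_dir_per_ev", 2.1e-2, P,
        "SSB yield of DNA cation radicals (direct) per eV")
    put("lesions.y_ssb_ind_per_ev", 1.2e-2, P,
        "SSB yield of water radicals (indirect) per eV")
    put("lesions.y_base_ind_per_ev", 1.36e-2, P,
        "base-lesion yield of water radicals per eV")

    # total-lesion quadratic anchors (LET, lambda)
    put("lesions.lambda_anchors.alpha",
        ((162.4, 39.8), (103.4, 23.1), (11.5, 2.0)), "paper_anchored_fit",
        "two cluster-size rows plus the clustered-damage threshold LET")
    put("lesions.lambda_anchors.proton",
        ((41.3, 10.8), (26.1, 6.3), (9.4, 2.0)), "paper_anchored_fit",
        "two cluster-size rows plus the clustered-damage threshold LET")
    put("lesions.clustered_anchor.electron", (7.1, 2.0), P,
        "clustered-damage threshold LET for electrons")
    put("lesions.site_anchors.electron", ((0.2, 86.7), (0.4, 67.9)), P,
        "electron nucleus damage-site counts; inverted to low-LET "
        "lambda anchors")

    # DSB model
    for pid, lmin in (("electron", 9.0), ("proton", 11.8), ("alpha", 15.2)):
        put(f"lesions.dsb_lmin.{pid}", lmin, P,
            "minimum track-averaged LET for one DSB per voxel")

    # nucleus
    put("nucleus.diameter_um", 4.0, P, "spherical nucleus diameter")
    put("nucleus.energy_kev", 260.0, P, "fixed deposited energy per nucleus")
    put("nucleus.dose_gy", 2.0, P, "nominal dose equivalent of 260 keV")
    put("nucleus.candidate_voxels", 4, "derived",
        "candidate damaged voxels per track; nucleus-table self-consistency "
        "(sites = 4 x n_tracks for all medium/high-LET rows)")
    return c


# --------------------------------------------------------------------------
# derived constants (always recomputed; never overridable)

def _derive(base: Mapping[str, Constant]) -> dict[str, Constant]:
    D = "derived"
    v = lambda name: base[name].value  # noqa: E731
    out: dict[str, Constant] = {}

    ell = float(v("voxel.volume_nm3")) ** (1.0 / 3.0)
    out["voxel.side_length_nm"] = Constant(ell, D, "cube root of the voxel volume")

    for pid in ("alpha", "proton", "electron"):
        L, val = v(f"ionization.anchor.{pid}")
        slope = v(f"ionization.slope.{pid}")
        out[f"ionization.intercept.{pid}"] = Constant(
            val - slope * L, D, "anchor value minus slope x anchor LET")

    sig_sb = v("lesions.sigma_sb_nm2")
    sig_b = v("lesions.sigma_base_nm2")
    n_a = 60.0 / ell**2
    p_lee = (sig_sb + sig_b) * n_a
    out["lesions.nucleotide_areal_density_per_nm2"] = Constant(
        n_a, D, "60 nucleotide targets over one voxel face")
    out["lesions.p_lee"] = Constant(
        p_lee, D, "per-LEE lesion probability, (sigma_sb + sigma_base) x n_A")
    out["lesions.sb_share"] = Constant(
        sig_sb / (sig_sb + sig_b), D, "strand-break share of LEE lesions")

    f_dir = v("voxel.direct_fraction")
    c_lin = ell * (
        f_dir * v("lesions.y_ssb_dir_per_ev")
        + (1.0 - f_dir) * (v("lesions.y_ssb_ind_per_ev") + v("lesions.y_base_ind_per_ev"))
    )
    out["lesions.c_lin_per_kev_um"] = Constant(
        c_lin, D, "linear (non-LEE) lesion rate per keV/um")

    # electron low-LET lambda anchors from the printed electron site counts
    e_kev = v("nucleus.energy_kev")
    d_um = v("nucleus.diameter_um")
    n_v = v("nucleus.candidate_voxels")
    e_anchors = [tuple(map(float, v("lesions.clustered_anchor.electron")))]
    for L, sites in v("lesions.site_anchors.electron"):
        e_anchors.append(
            (L, invert_site_count(L, sites, energy_kev=e_kev,
                                  diameter_um=d_um, n_v=n_v))
        )
    out["lesions.lambda_anchors.electron"] = Constant(
        tuple(e_anchors), D,
        "clustered threshold plus site-count inversions of the electron rows")

    anchors = {
        "alpha": v("lesions.lambda_anchors.alpha"),
        "proton": v("lesions.lambda_anchors.proton"),
        "electron": tuple(e_anchors),
    }
    coeffs = {}
    for pid, anc in anchors.items():
        coeffs[pid] = calibrate_lambda(anc)
        out[f"lesions.lambda_coeffs.{pid}"] = Constant(
            coeffs[pid], D, "exact quadratic through the three anchors")

    # DSB scale k_D so that mean DSB = 1 at the printed minimum LET
    for pid in ("alpha", "proton", "electron"):
        lmin = v(f"lesions.dsb_lmin.{pid}")
        a, b, c0 = coeffs[pid]
        lam = max(0.0, a * lmin * lmin + b * lmin + c0)
        lee_part = max(0.0, lam - c_lin * lmin)
        s = ell * lmin * (
            f_dir * v("lesions.y_ssb_dir_per_ev")
            + (1.0 - f_dir) * v("lesions.y_ssb_ind_per_ev")
        ) + lee_part * out["lesions.sb_share"].value
        out[f"lesions.dsb_scale.{pid}"] = Constant(
            4.0 / s**2, D, "k_D with mean DSB = k_D s^2 / 4 = 1 at L_min")
    return out


# --------------------------------------------------------------------------

class CalibrationSet:
    """Immutable mapping of constant name → :class:`Constant`.

    Built from the defaults plus optional overrides; derived constants
    are recomputed after every override so the set is always internally
    consistent.
    """

    def __init__(self, base: Mapping[str, Constant] | None = None):
        self._base = dict(base) if base is not None else _base_constants()
        self._derived = _derive(self._base)
        self._data = {**self._base, **self._derived}

    # mapping-ish surface
    def __getitem__(self, name: str) -> Constant:
        try:
            return self._data[name]
        except KeyError:
            raise KeyError(f"unknown calibration constant {name!r}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def __contains__(self, name: str) -> bool:
        return name in self._data

    def value(self, name: str) -> Any:
        return self[name].value

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CalibrationSet):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    @property
    def derived_names(self) -> frozenset[str]:
        return frozenset(self._derived)

    def with_overrides(
        self, overrides: Mapping[str, Any], *, allow_override: bool = False
    ) -> "CalibrationSet":
        """New set with base constants replaced by ``overrides``.

        Derived constants are recomputed; overriding one (or an unknown
        name) is a schema error.  ``paper_printed`` constants require
        ``allow_override=True``.
        """
        base = dict(self._base)
        for name, value in overrides.items():
            if name in self._derived:
                raise ValueError(
                    f"{name}: derived constant, recomputed from its inputs "
                    "and not overridable")
            if name not in base:
                raise ValueError(f"{name}: unknown calibration constant")
            old = base[name]
            if old.provenance == "paper_printed" and not allow_override:
                raise PermissionError(
                    f"{name}: overriding a paper_printed constant requires "
                    "allow_override")
            base[name] = Constant(value, old.provenance, old.citation)
        return CalibrationSet(base)

    def to_dict(self) -> dict[str, dict[str, Any]]:
        return {
            name: {
                "value": _thaw(c.value),
                "provenance": c.provenance,
                "citation": c.citation,
            }
            for name, c in sorted(self._data.items())
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_file(cls, path, *, allow_override: bool = False) -> "CalibrationSet":
        return load_config(path, allow_override=allow_override)


@functools.lru_cache(maxsize=1)
def default_calibration() -> CalibrationSet:
    """The default :class:`CalibrationSet` (cached singleton)."""
    return CalibrationSet()


def load_config(path, *, allow_override: bool = False) -> CalibrationSet:
    """Load a YAML config into a :class:`CalibrationSet`.

    The file is either empty (full defaults), a flat mapping of constant
    name → value, or a full serialized set (mapping of name → {value,
    provenance, citation}), as written by :meth:`CalibrationSet.save`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return CalibrationSet()
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    default = CalibrationSet()
    overrides: dict[str, Any] = {}
    for name, entry in raw.items():
        value = entry["value"] if isinstance(entry, dict) and "value" in entry else entry
        if name in default.derived_names:
            # full serialized sets carry derived entries; accept them only
            # if they match the recomputation
            recomputed = _thaw(default[name].value)
            if not _close(recomputed, value):
                raise ValueError(
                    f"{name}: derived constant disagrees with recomputation")
            continue
        if name not in default:
            raise ValueError(f"{name}: unknown calibration constant")
        if not _close(_thaw(default[name].value), value):
            overrides[name] = value
    return default.with_overrides(overrides, allow_override=allow_override)


def _close(a: Any, b: Any, rtol: float = 1e-12) -> bool:
    if isinstance(a, (list, tuple)) and isinstance(b, (list, tuple)):
        return len(a) == len(b) and all(_close(x, y, rtol) for x, y in zip(a, b))
    if isinstance(a, dict) and isinstance(b, dict):
        return a.keys() == b.keys() and all(_close(a[k], b[k], rtol) for k in a)
    if isinstance(a, (int, float)) and isinstance(b, (int, float)):
        return math.isclose(float(a), float(b), rel_tol=rtol, abs_tol=1e-15)
    return a == b
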