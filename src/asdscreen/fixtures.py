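"""Deterministic synthetic fixtures and packaged pure-component constants.

Everything here is generated locally (no downloads): random but valid
segment cavities, smooth Gaussian-peaked σ-profiles, an analytic symmetric
Margules system for closed-form equilibrium tests, and the fusion-property
table of the seven reference APIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .activity_model import Component, FusionProperties
from .constants import CLASSES, N_BINS, PARAMS_2010, SIGMA_GRID, SIGMA_STEP
from .equilibria import MargulesSystem
from .sigma_io import SegmentSet, SigmaProfile, write_cosmo

__all__ = [
    "FixtureSpec",
    "gen_segment_set",
    "gen_sphere_cavity",
    "gen_gaussian_profile",
    "gen_analytic_system",
    "gen_margules_system",
    "api_fusion_table",
    "API_FV_INPUTS",
    "POLYMER_FV_INPUTS",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic segment cavity; same seed → identical output."""

    seed: int = 0
    n_segments: int = 40
    n_units: int = 1
    atoms_per_unit: int = 2
    sigma_mean: float = 0.0
    sigma_width: float = 0.004
    unit_sigma_offsets: tuple[float, ...] = ()
    area_range: tuple[float, float] = (0.2, 0.6)
    margules_a: float = 0.0

    def __post_init__(self) -> None:
        if self.n_segments < 1 or self.n_units < 1 or self.atoms_per_unit < 1:
            raise ValueError("fixture sizes must be positive")
        if self.unit_sigma_offsets and len(self.unit_sigma_offsets) != self.n_units:
            raise ValueError("one σ offset per unit required")


def gen_segment_set(spec: FixtureSpec, path: str | Path | None = None) -> SegmentSet:
    """Random but valid cavity with atoms grouped into labelled units.

    Atom indices partition into ``n_units`` consecutive blocks of
    ``atoms_per_unit`` (unit u owns atoms u·k … u·k+k−1); segments are
    assigned round-robin to atoms.  If ``path`` is given, a ``.cosmo``
    fixture file is written alongside.
    """
    rng = np.random.default_rng(spec.seed)
    n_atoms = spec.n_units * spec.atoms_per_unit
    elements = [("C", "O", "N")[i % 3] for i in range(n_atoms)]
    atom_xyz = np.zeros((n_atoms, 3))
    atom_xyz[:, 0] = np.arange(n_atoms) * 1.5
    atom_xyz += rng.normal(scale=0.05, size=atom_xyz.shape)

    seg_atom = np.arange(spec.n_segments) % n_atoms
    direction = rng.normal(size=(spec.n_segments, 3))
    direction /= np.linalg.norm(direction, axis=1)[:, None]
    seg_xyz = atom_xyz[seg_atom] + 1.4 * direction
    seg_area = rng.uniform(*spec.area_range, size=spec.n_segments)

    offsets = spec.unit_sigma_offsets or tuple([0.0] * spec.n_units)
    unit_of_atom = np.arange(n_atoms) // spec.atoms_per_unit
    seg_offset = np.array([offsets[unit_of_atom[a]] for a in seg_atom])
    seg_sigma = rng.normal(spec.sigma_mean, spec.sigma_width, spec.n_segments)
    seg_sigma = np.clip(seg_sigma + seg_offset, -0.024, 0.024)

    seg = SegmentSet(
        name=f"fixture-seed{spec.seed}",
        elements=elements,
        atom_xyz=atom_xyz,
        seg_atom=seg_atom,
        seg_xyz=seg_xyz,
        seg_area=seg_area,
        seg_sigma=seg_sigma,
        area=float(seg_area.sum()),
        volume=float(seg_area.sum()) * 1.2,
    )
    if path is not None:
        write_cosmo(seg, path)
    return seg


def gen_sphere_cavity(
    n_segments: int = 200,
    radius: float = 3.0,
    sigma_amplitude: float = 0.01,
    seed: int = 0,
) -> SegmentSet:
    """Closed spherical cavity with equal-area segments and smooth σ.

    Segments sit on a Fibonacci spiral over the sphere; σ varies smoothly
    with latitude.  Useful for charge-conservation checks of the averaging
    step.
    """
    rng = np.random.default_rng(seed)
    i = np.arange(n_segments)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_segments
    r = np.sqrt(1.0 - z * z)
    theta = golden * i
    xyz = radius * np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    area = np.full(n_segments, 4.0 * math.pi * radius**2 / n_segments)
    sigma = sigma_amplitude * (z + 0.3 * np.sin(2.0 * theta) * r)
    sigma += rng.normal(scale=1e-4, size=n_segments)
    return SegmentSet(
        name=f"sphere-{n_segments}",
        elements=["C"],
        atom_xyz=np.zeros((1, 3)),
        seg_atom=np.zeros(n_segments, dtype=int),
        seg_xyz=xyz,
        seg_area=area,
        seg_sigma=sigma,
        area=float(area.sum()),
        volume=4.0 / 3.0 * math.pi * radius**3,
    )


def gen_gaussian_profile(
    name: str,
    area: float,
    volume: float,
    peaks: list[tuple[str, float, float, float]],
) -> SigmaProfile:
    """Smooth σ-profile from Gaussian peaks binned on the standard grid.

    ``peaks`` entries are (class, center σ, width, area fraction); fractions
    must sum to 1.  Bin values are non-negative and sum exactly to ``area``.
    """
    fractions = sum(p[3] for p in peaks)
    if abs(fractions - 1.0) > 1e-9:
        raise ValueError("peak area fractions must sum to 1")
    areas = np.zeros((len(CLASSES), N_BINS))
    for cls, center, width, frac in peaks:
        ci = CLASSES.index(cls)
        weights = np.exp(-0.5 * ((SIGMA_GRID - center) / width) ** 2)
        areas[ci] += frac * area * weights / weights.sum()
    return SigmaProfile(name=name, areas=areas, volume=volume)


def _flat_profile(name: str, area: float, volume: float) -> SigmaProfile:
    areas = np.zeros((len(CLASSES), N_BINS))
    areas[0, N_BINS // 2] = area  # all surface neutral, NHB
    return SigmaProfile(name=name, areas=areas, volume=volume)


def gen_analytic_system(
    a: float,
    fusion: FusionProperties | None = None,
    m: float = 100.0,
) -> tuple[Component, Component]:
    """Two components engineered so total ln γ reduces to the Margules form.

    Identical neutral σ-profiles (residual ≡ 0), equal area/volume (SG ≡ 0)
    and equal free volumes (FV ≡ 0); the dispersion parameters reproduce
    the Margules constant ``a`` exactly through the combining rule.
    """
    w = PARAMS_2010.w_dsp
    eps1 = 2.0 * abs(a) / w
    cls1 = "nhb" if a >= 0 else "cooh"
    profile = _flat_profile("analytic", area=100.0, volume=120.0)
    c1 = Component(
        name="api", profile=profile, m=m, v=100.0, v_hc=50.0,
        eps=eps1, dispersion_class=cls1, fusion=fusion,
    )
    c2 = Component(
        name="poly", profile=_flat_profile("analytic", 100.0, 120.0),
        m=m, v=100.0, v_hc=50.0, eps=0.0, dispersion_class="nhb",
    )
    return c1, c2


def gen_margules_system(
    a: float | None = None,
    c_over_t: float | None = None,
    fusion: FusionProperties | None = None,
    m_api: float = 100.0,
    m_poly: float = 100.0,
) -> MargulesSystem:
    """Analytic binary system with constant or A(T) = c/T Margules constant."""
    if (a is None) == (c_over_t is None):
        raise ValueError("specify exactly one of a or c_over_t")
    a_fun = a if a is not None else (lambda t: c_over_t / t)
    api = Component(name="api", m=m_api, fusion=fusion)
    poly = Component(name="poly", m=m_poly)
    return MargulesSystem(a=a_fun, api=api, polymer=poly)


# ---------------------------------------------------------------------------
# packaged constants: fusion properties of the seven reference APIs
# ---------------------------------------------------------------------------

_API_FUSION_DATA = {
    # name: (M g/mol, T_m K, dh_fus kJ/mol, dcp_a J/K/mol, dcp_b J/K^2/mol)
    "GSF": (352.77, 491.85, 37.90, 93.84, 0.0),
    "IBP": (206.29, 348.55, 26.40, 176.16440, -0.3449480),
    "IMC": (357.79, 433.35, 38.10, 238.18385, -0.2785901),
    "NIF": (346.34, 445.75, 39.30, 121.22, 0.0),
    "NPX": (230.26, 429.25, 32.40, 99.30, 0.0),
    "PCM": (151.16, 442.55, 28.00, 99.80, 0.0),
    "SIM": (418.57, 412.45, 27.75, 278.77100, -0.331300),
}


def api_fusion_table() -> dict[str, Component]:
    """The seven crystallizable reference APIs with their fusion constants."""
    out = {}
    for name, (m, tm, dh, a, b) in _API_FUSION_DATA.items():
        out[name] = Component(
            name=name,
            m=m,
            fusion=FusionProperties(tm=tm, dh_fus=dh, dcp_a=a, dcp_b=b),
        )
    return out


# ---------------------------------------------------------------------------
# reconstructed free-volume inputs for the study species
# ---------------------------------------------------------------------------
# Liquid molar volumes v = M/ρ use amorphous/supercooled-liquid densities at
# 298 K compiled from the open literature (the original per-species volume
# table is not redistributed here); hard-core volumes are computed from the
# molecular structure with the bond/ring-corrected Bondi-increment scheme.

#: API name -> (SMILES, amorphous density g/cm^3 at 298 K)
API_FV_INPUTS = {
    "GSF": ("COC1=CC(=O)C[C@@H](C)[C@]12Oc1c(Cl)c(OC)cc(OC)c1C2=O", 1.351),
    "IBP": ("CC(C)Cc1ccc(cc1)C(C)C(O)=O", 1.05),
    "IMC": ("COc1ccc2c(c1)c(CC(O)=O)c(C)n2C(=O)c1ccc(Cl)cc1", 1.32),
    "NIF": ("COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]", 1.29),
    "NPX": ("COc1ccc2cc(ccc2c1)[C@H](C)C(O)=O", 1.19),
    "PCM": ("CC(=O)Nc1ccc(O)cc1", 1.26),
    "SIM": (
        "CC[C](C)(C)C(=O)O[CH]1C[CH](C)C=C2C=C[CH](C)[CH](CC[CH]3C[CH](O)CC(=O)O3)[CH]12",
        1.14,
    ),
}

#: repeat units: atom counts, (aromatic, non-aromatic) rings, unit molar mass
_UNITS = {
    "VP": ({"C": 6, "H": 9, "N": 1, "O": 1}, (0, 1), 111.142),
    "VA": ({"C": 2, "H": 4, "O": 1}, (0, 0), 44.053),
    "LA": ({"C": 3, "H": 4, "O": 2}, (0, 0), 72.063),
    "GA": ({"C": 2, "H": 2, "O": 2}, (0, 0), 58.036),
    "VAc": ({"C": 4, "H": 6, "O": 2}, (0, 0), 86.090),
    "MAA": ({"C": 4, "H": 6, "O": 2}, (0, 0), 86.090),
    "MMA": ({"C": 5, "H": 8, "O": 2}, (0, 0), 100.117),
}

#: polymer name -> (density g/cm^3 at 298 K, {unit: mole fraction})
POLYMER_FV_INPUTS = {
    "EUD": (1.27, {"MAA": 0.5, "MMA": 0.5}),
    "PDL": (1.25, {"LA": 1.0}),
    "PLGA50": (1.34, {"LA": 0.5, "GA": 0.5}),
    "PLGA75": (1.30, {"LA": 0.75, "GA": 0.25}),
    "PVA": (1.25, {"VA": 1.0}),
    "PVPK12": (1.20, {"VP": 1.0}),
    "PVPK25": (1.20, {"VP": 1.0}),
    "PVPK30": (1.20, {"VP": 1.0}),
    "PVPVAc64": (1.19, {"VP": 0.537, "VAc": 0.463}),
}


def polymer_unit_data(unit: str) -> tuple[dict[str, int], tuple[int, int], float]:
    """Atom counts, (aromatic, non-aromatic) ring counts and mass of a unit."""
    return _UNITS[unit]
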