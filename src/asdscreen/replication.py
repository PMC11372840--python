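"""Virtual-macromolecule σ-profiles from oligomer COSMO data.

A polymer profile is built by replicating the binned contribution of the
central monomer unit(s) of a short oligomer: the resulting profile equals
the oligomer profile plus ``n_rep`` extra copies of each central unit's
segments, and the total surface area and cavity volume accumulate by the
same additive rule.  Because binning is linear, replicating binned per-unit
contributions is equivalent to duplicating the segments themselves.

Unit counts are derived from the target polymer molar mass: a homopolymer
of mass M built from monomers of mass m carries ``round(M / m)`` units;
for copolymers the total count follows from the ratio-weighted mean monomer
mass and is apportioned by the molar unit ratio.  The number of *extra*
copies of a central unit is the target count of that monomer type minus the
number of units of that type already present in the oligomer (edge units
are never replicated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sigma_io import SegmentSet, SigmaProfile, build_profile

__all__ = ["PolymerSpec", "count_units", "replicate_profile", "replicate_area_volume"]


def count_units(
    m_poly: float,
    monomer_masses: dict[str, float] | float,
    ratio: dict[str, float] | None = None,
    rounding=round,
) -> dict[str, int]:
    """Monomer unit counts of a (co)polymer from its molar mass.

    For a homopolymer pass a single mass (or a one-entry dict); for a
    copolymer pass per-type masses plus the molar unit ratio (entries sum
    to 1).  Counts are rounded to the nearest integer by default; the
    rounding rule is overridable.
    """
    if isinstance(monomer_masses, (int, float)):
        monomer_masses = {"A": float(monomer_masses)}
    if any(m <= 0 for m in monomer_masses.values()):
        raise ValueError("monomer masses must be > 0")
    if ratio is None:
        if len(monomer_masses) != 1:
            raise ValueError("copolymer requires an explicit unit ratio")
        ratio = {next(iter(monomer_masses)): 1.0}
    if set(ratio) != set(monomer_masses):
        raise ValueError("ratio keys must match monomer mass keys")
    if abs(sum(ratio.values()) - 1.0) > 1e-9:
        raise ValueError("ratio entries must sum to 1")
    mean_mass = sum(ratio[t] * monomer_masses[t] for t in ratio)
    if m_poly < min(monomer_masses.values()):
        raise ValueError(
            f"polymer mass {m_poly} g/mol is smaller than one monomer"
        )
    n_total = m_poly / mean_mass
    return {t: int(rounding(ratio[t] * n_total)) for t in monomer_masses}


@dataclass
class PolymerSpec:
    """Recipe for building a polymer σ-profile from an oligomer cavity.

    ``unit_atoms`` identifies, per monomer type, the atom indices of the
    central unit to replicate; ``oligomer_unit_counts`` states how many
    units of each type the oligomer already contains (e.g. 3 for a
    homopolymer trimer, 2 and 2 for an alternating tetramer).
    """

    oligomer: SegmentSet
    unit_atoms: dict[str, frozenset[int]]
    monomer_masses: dict[str, float]
    m_poly: float
    oligomer_unit_counts: dict[str, int]
    ratio: dict[str, float] | None = None
    hb_atom_classes: dict[int, str] = field(default_factory=dict)
    unit_volumes: dict[str, float] | None = None  # default: area-proportional

    def __post_init__(self) -> None:
        if not self.oligomer.averaged:
            raise ValueError("oligomer σ must be averaged before replication")
        sets = list(self.unit_atoms.values())
        if any(not s for s in sets):
            raise ValueError("unit atom sets must be non-empty")
        for i, a in enumerate(sets):
            for b in sets[i + 1:]:
                if set(a) & set(b):
                    raise ValueError("unit atom sets must be disjoint")
        counts = self.target_unit_counts()
        for t, n in counts.items():
            if n < self.oligomer_unit_counts.get(t, 0):
                raise ValueError(
                    f"target count {n} for unit {t!r} is below the "
                    f"{self.oligomer_unit_counts.get(t, 0)} units already "
                    "present in the oligomer"
                )

    def target_unit_counts(self) -> dict[str, int]:
        return count_units(self.m_poly, self.monomer_masses, self.ratio)

    def n_rep(self) -> dict[str, int]:
        """Number of *extra* copies of each central unit to add."""
        targets = self.target_unit_counts()
        return {
            t: targets[t] - self.oligomer_unit_counts[t] for t in self.unit_atoms
        }

    def unit_profile(self, unit: str) -> SigmaProfile:
        """Binned σ-profile contribution of one central unit's segments."""
        atoms = self.unit_atoms[unit]
        mask = np.isin(self.oligomer.seg_atom, list(atoms))
        if not mask.any():
            raise ValueError(f"unit {unit!r} owns no surface segments")
        sub = SegmentSet(
            name=f"{self.oligomer.name}:{unit}",
            elements=self.oligomer.elements,
            atom_xyz=self.oligomer.atom_xyz,
            seg_atom=self.oligomer.seg_atom[mask],
            seg_xyz=self.oligomer.seg_xyz[mask],
            seg_area=self.oligomer.seg_area[mask],
            seg_sigma=self.oligomer.seg_sigma[mask],
            area=float(self.oligomer.seg_area[mask].sum()),
            volume=self.unit_volume(unit),
            averaged=True,
        )
        return build_profile(sub, self.hb_atom_classes)

    def unit_volume(self, unit: str) -> float:
        if self.unit_volumes and unit in self.unit_volumes:
            return self.unit_volumes[unit]
        atoms = self.unit_atoms[unit]
        mask = np.isin(self.oligomer.seg_atom, list(atoms))
        frac = float(self.oligomer.seg_area[mask].sum()) / float(
            self.oligomer.seg_area.sum()
        )
        return self.oligomer.volume * frac


def replicate_profile(spec: PolymerSpec, n_rep: dict[str, int] | None = None) -> SigmaProfile:
    """Polymer σ-profile: oligomer profile + n_rep copies of each unit."""
    n_rep = spec.n_rep() if n_rep is None else n_rep
    if any(n < 0 for n in n_rep.values()):
        raise ValueError("replication counts must be >= 0")
    profile = build_profile(spec.oligomer, spec.hb_atom_classes)
    areas = profile.areas.copy()
    volume = profile.volume
    for unit, n in n_rep.items():
        if n == 0:
            continue
        unit_prof = spec.unit_profile(unit)
        areas = areas + n * unit_prof.areas
        volume += n * unit_prof.volume
    return SigmaProfile(name=spec.oligomer.name, areas=areas, volume=volume)


def replicate_area_volume(
    spec: PolymerSpec, n_rep: dict[str, int] | None = None
) -> tuple[float, float]:
    """Total cavity (area, volume) of the virtual polymer molecule."""
    n_rep = spec.n_rep() if n_rep is None else n_rep
    if any(n < 0 for n in n_rep.values()):
        raise ValueError("replication counts must be >= 0")
    area = float(spec.oligomer.seg_area.sum())
    volume = spec.oligomer.volume
    for unit, n in n_rep.items():
        atoms = spec.unit_atoms[unit]
        mask = np.isin(spec.oligomer.seg_atom, list(atoms))
        area += n * float(spec.oligomer.seg_area[mask].sum())
        volume += n * spec.unit_volume(unit)
    return area, volume
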