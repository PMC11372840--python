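"""Parsing of COSMO segment files and construction of σ-profiles.

The entry objects are :class:`SegmentSet` (the raw molecular cavity: atoms
plus surface segments carrying position, area and screening charge density)
and :class:`SigmaProfile` (the 51-bin area-weighted histogram of charge
density, split into the three hydrogen-bonding surface classes NHB/OH/OT).

The supported ``.cosmo`` dialect is a keyword-sectioned text layout
(``$info`` / ``$cosmo_data`` / ``$coord_rad`` / ``$segment_information``)
with lengths either in Angstrom or atomic units as declared in the header.
Other dialects are rejected explicitly rather than guessed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .constants import (
    BOHR_ANGSTROM,
    CLASSES,
    N_BINS,
    PARAMS_2010,
    SIGMA_GRID,
    SIGMA_MAX,
    SIGMA_MIN,
    SIGMA_STEP,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentSet",
    "SigmaProfile",
    "CosmoParseError",
    "SigmaFormatError",
    "parse_cosmo",
    "write_cosmo",
    "average_charge_density",
    "build_profile",
    "read_sigma",
    "write_sigma",
]


class CosmoParseError(ValueError):
    """Raised when a .cosmo file is malformed or of an unsupported dialect."""


class SigmaFormatError(ValueError):
    """Raised when a .sigma file violates the expected text format."""


@dataclass
class SegmentSet:
    """A parsed COSMO cavity: atoms plus charged surface segments.

    All lengths are Angstrom, areas Angstrom^2, charge densities e/Angstrom^2.
    """

    name: str
    elements: list[str]
    atom_xyz: np.ndarray          # (n_atoms, 3)
    seg_atom: np.ndarray          # (n_seg,) 0-based owning atom index
    seg_xyz: np.ndarray           # (n_seg, 3)
    seg_area: np.ndarray          # (n_seg,)
    seg_sigma: np.ndarray         # (n_seg,) charge density
    area: float                   # total cavity area from the file header
    volume: float                 # total cavity volume from the file header
    averaged: bool = False        # whether σ has undergone spatial averaging

    def __post_init__(self) -> None:
        self.atom_xyz = np.asarray(self.atom_xyz, dtype=float).reshape(-1, 3)
        self.seg_atom = np.asarray(self.seg_atom, dtype=int)
        self.seg_xyz = np.asarray(self.seg_xyz, dtype=float).reshape(-1, 3)
        self.seg_area = np.asarray(self.seg_area, dtype=float)
        self.seg_sigma = np.asarray(self.seg_sigma, dtype=float)
        self.validate()

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_segments(self) -> int:
        return self.seg_area.size

    def validate(self) -> None:
        if self.n_segments == 0:
            raise CosmoParseError("segment set contains no segments")
        if np.any(self.seg_area <= 0.0):
            raise ValueError("every segment area must be > 0")
        if self.seg_atom.min() < 0 or self.seg_atom.max() >= self.n_atoms:
            raise ValueError("segment references a non-existing atom index")
        total = float(self.seg_area.sum())
        if self.area > 0 and abs(total - self.area) > 5e-3 * self.area:
            raise ValueError(
                f"segment areas sum to {total:.4f} A^2, header declares "
                f"{self.area:.4f} A^2 (>0.5% mismatch)"
            )


@dataclass
class SigmaProfile:
    """Area-weighted σ-histogram A_i·p_i(σ) on the fixed 51-bin grid.

    ``areas`` has shape (3, 51): one row per surface class in the order
    NHB, OH, OT.  The grid itself is immutable package-level data.
    """

    name: str
    areas: np.ndarray             # (3, 51) A^2 per class and bin
    volume: float                 # total cavity volume, A^3

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (len(CLASSES), N_BINS):
            raise ValueError(f"areas must have shape (3, {N_BINS})")
        if np.any(self.areas < -1e-12):
            raise ValueError("σ-profile bin values must be non-negative")

    @property
    def grid(self) -> np.ndarray:
        return SIGMA_GRID

    @property
    def area(self) -> float:
        """Total molecular surface area (sum over all bins and classes)."""
        return float(self.areas.sum())

    @property
    def total(self) -> np.ndarray:
        """Class-summed profile, shape (51,)."""
        return self.areas.sum(axis=0)

    def normalized(self) -> np.ndarray:
        """p_i(σ) per class, normalized so the grand sum is 1."""
        return self.areas / self.area

    def scaled(self, factor: float) -> "SigmaProfile":
        return SigmaProfile(self.name, self.areas * factor, self.volume * factor)

    def __add__(self, other: "SigmaProfile") -> "SigmaProfile":
        return SigmaProfile(
            self.name, self.areas + other.areas, self.volume + other.volume
        )


# ---------------------------------------------------------------------------
# .cosmo parsing / writing
# ---------------------------------------------------------------------------

_SECTIONS = ("$info", "$cosmo_data", "$coord_rad", "$segment_information")


def parse_cosmo(path: str | Path) -> SegmentSet:
    """Parse a ``.cosmo`` segment file into a :class:`SegmentSet`.

    Header area/volume are taken from the ``$cosmo_data`` section; all
    quantities are converted to Angstrom-based units when the file declares
    atomic units (``length_unit = au``).
    """
    path = Path(path)
    text = path.read_text()
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("$"):
            key = line.split()[0].lower()
            if key not in _SECTIONS:
                raise CosmoParseError(
                    f"{path.name}: unsupported section {key!r}; this reader "
                    f"understands only the {', '.join(_SECTIONS)} dialect"
                )
            current = key
            sections[current] = []
            continue
        if current is not None:
            sections[current].append(line)

    if not sections:
        raise CosmoParseError(f"{path.name}: no recognizable sections found")
    for required in ("$cosmo_data", "$coord_rad", "$segment_information"):
        if required not in sections:
            raise CosmoParseError(f"{path.name}: missing section {required!r}")

    name = sections.get("$info", [path.stem])
    name = name[0] if name else path.stem

    header: dict[str, str] = {}
    for line in sections["$cosmo_data"]:
        if "=" in line:
            key, _, value = line.partition("=")
            header[key.strip().lower()] = value.strip()
    try:
        area = float(header["area"])
        volume = float(header["volume"])
    except KeyError as exc:
        raise CosmoParseError(f"{path.name}: $cosmo_data lacks {exc}") from exc
    unit = header.get("length_unit", "angstrom").lower()
    if unit in ("angstrom", "a", "ang"):
        scale = 1.0
    elif unit in ("au", "bohr"):
        scale = BOHR_ANGSTROM
    else:
        raise CosmoParseError(f"{path.name}: unknown length_unit {unit!r}")

    elements: list[str] = []
    atom_xyz: list[list[float]] = []
    for line in sections["$coord_rad"]:
        if line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 5:
            raise CosmoParseError(f"{path.name}: malformed $coord_rad row: {line!r}")
        atom_xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
        elements.append(parts[4].capitalize())
    if not elements:
        raise CosmoParseError(f"{path.name}: $coord_rad holds no atoms")

    rows = [ln for ln in sections["$segment_information"] if not ln.startswith("#")]
    if not rows:
        raise CosmoParseError(f"{path.name}: $segment_information holds no segments")
    seg_atom, seg_xyz, seg_area, seg_charge = [], [], [], []
    for line in rows:
        parts = line.split()
        if len(parts) < 7:
            raise CosmoParseError(
                f"{path.name}: malformed $segment_information row: {line!r}"
            )
        seg_atom.append(int(parts[1]) - 1)  # file rows are 1-based
        seg_xyz.append([float(parts[2]), float(parts[3]), float(parts[4])])
        seg_charge.append(float(parts[5]))
        seg_area.append(float(parts[6]))

    seg_area_arr = np.asarray(seg_area) * scale**2
    seg_sigma = np.asarray(seg_charge) / seg_area_arr  # e / A^2 after scaling
    return SegmentSet(
        name=name,
        elements=elements,
        atom_xyz=np.asarray(atom_xyz) * scale,
        seg_atom=np.asarray(seg_atom),
        seg_xyz=np.asarray(seg_xyz) * scale,
        seg_area=seg_area_arr,
        seg_sigma=seg_sigma,
        area=area * scale**2,
        volume=volume * scale**3,
    )


def write_cosmo(seg: SegmentSet, path: str | Path) -> None:
    """Write a :class:`SegmentSet` to the supported ``.cosmo`` dialect."""
    path = Path(path)
    lines = ["$info", seg.name, "$cosmo_data",
             f"  area   = {seg.area:.10f}",
             f"  volume = {seg.volume:.10f}",
             "  length_unit = angstrom",
             "$coord_rad",
             "#  n             x               y               z  element"]
    for i, (el, xyz) in enumerate(zip(seg.elements, seg.atom_xyz), start=1):
        lines.append(
            f"{i:4d} {xyz[0]:16.10f} {xyz[1]:16.10f} {xyz[2]:16.10f}  {el.lower()}"
        )
    lines.append("$segment_information")
    lines.append("#  n  atom             x               y               z"
                 "           charge             area")
    for i in range(seg.n_segments):
        charge = seg.seg_sigma[i] * seg.seg_area[i]
        x, y, z = seg.seg_xyz[i]
        lines.append(
            f"{i + 1:5d} {seg.seg_atom[i] + 1:5d} {x:16.10f} {y:16.10f} "
            f"{z:16.10f} {charge:16.12f} {seg.seg_area[i]:16.10f}"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# charge-density averaging
# ---------------------------------------------------------------------------

def average_charge_density(
    raw: SegmentSet,
    r_av: float = PARAMS_2010.r_av,
    f_decay: float = PARAMS_2010.f_decay,
) -> SegmentSet:
    """Spatially average raw segment charge densities.

    Each segment's σ is replaced by a weighted mean over all segments, the
    weight combining the segment size with a Gaussian decay in distance::

        w_mn = (r_n^2 r_av^2 / (r_n^2 + r_av^2))
               * exp(-f_decay d_mn^2 / (r_n^2 + r_av^2))

    with r_n the segment radius from its area (a_n = pi r_n^2).  Areas and
    positions are unchanged.
    """
    if r_av <= 0:
        raise ValueError("r_av must be > 0")
    rn2 = raw.seg_area / math.pi
    rav2 = r_av * r_av
    d2 = cdist(raw.seg_xyz, raw.seg_xyz, metric="sqeuclidean")
    denom = rn2 + rav2  # (n,) per source segment n
    kernel = (rn2 * rav2 / denom) * np.exp(-f_decay * d2 / denom)
    sigma_avg = kernel @ raw.seg_sigma / kernel.sum(axis=1)
    return replace(raw, seg_sigma=sigma_avg, averaged=True)


# ---------------------------------------------------------------------------
# σ-profile construction
# ---------------------------------------------------------------------------

def hb_switching(sigma: np.ndarray, sigma_hb: float = PARAMS_2010.sigma_hb) -> np.ndarray:
    """Probability that a segment of an HB-capable atom is truly HB surface.

    Gaussian switching in |σ| so near-neutral segments count as NHB:
    ``P_hb = 1 - exp(-σ² / (2 σ₀²))``.
    """
    return 1.0 - np.exp(-np.square(sigma) / (2.0 * sigma_hb * sigma_hb))


def build_profile(
    seg: SegmentSet,
    hb_atom_classes: dict[int, str] | None = None,
    sigma_hb: float = PARAMS_2010.sigma_hb,
) -> SigmaProfile:
    """Bin an averaged segment set into a three-class σ-profile.

    ``hb_atom_classes`` maps atom indices to ``"oh"`` (hydroxyl O and its H)
    or ``"ot"`` (other HB-capable N/O/F and their H); unlisted atoms are NHB.
    Each segment area is split linearly between the two neighboring grid
    bins; the HB-class share is weighted by the switching function of |σ|.
    Total area is conserved exactly.
    """
    hb_atom_classes = hb_atom_classes or {}
    for idx, cls in hb_atom_classes.items():
        if cls not in CLASSES:
            raise ValueError(f"unknown HB class {cls!r} for atom {idx}")
        if idx < 0 or idx >= seg.n_atoms:
            raise ValueError(f"HB class refers to non-existing atom {idx}")

    sigma = seg.seg_sigma.copy()
    clipped = (sigma < SIGMA_MIN) | (sigma > SIGMA_MAX)
    if np.any(clipped):
        logger.warning(
            "%s: %d segment σ values outside [%.3f, %.3f] clamped to end bins",
            seg.name, int(clipped.sum()), SIGMA_MIN, SIGMA_MAX,
        )
        sigma = np.clip(sigma, SIGMA_MIN, SIGMA_MAX)

    # two-bin linear interpolation weights
    pos = (sigma - SIGMA_MIN) / SIGMA_STEP
    lo = np.floor(pos).astype(int)
    lo = np.minimum(lo, N_BINS - 2)
    frac = pos - lo

    seg_class = np.array(
        [hb_atom_classes.get(int(a), "nhb") for a in seg.seg_atom]
    )
    p_hb = hb_switching(sigma, sigma_hb)

    areas = np.zeros((len(CLASSES), N_BINS))
    for ci, cls in enumerate(CLASSES):
        if cls == "nhb":
            weight = np.where(seg_class == "nhb", 1.0, 1.0 - p_hb)
        else:
            weight = np.where(seg_class == cls, p_hb, 0.0)
        contrib = seg.seg_area * weight
        np.add.at(areas[ci], lo, contrib * (1.0 - frac))
        np.add.at(areas[ci], lo + 1, contrib * frac)
    return SigmaProfile(name=seg.name, areas=areas, volume=seg.volume)


# ---------------------------------------------------------------------------
# .sigma text format
# ---------------------------------------------------------------------------

def write_sigma(profile: SigmaProfile, path: str | Path, meta: dict | None = None) -> None:
    """Write a σ-profile as commented-header text with 51 four-column rows."""
    path = Path(path)
    lines = [
        f"# name: {profile.name}",
        f"# area[A^2]: {profile.area:.17e}",
        f"# volume[A^3]: {profile.volume:.17e}",
        "# columns: sigma[e/A^2] nhb[A^2] oh[A^2] ot[A^2]",
    ]
    for key, value in (meta or {}).items():
        lines.append(f"# meta:{key}: {value}")
    for j in range(N_BINS):
        lines.append(
            f"{SIGMA_GRID[j]: .4f} {profile.areas[0, j]:.17e} "
            f"{profile.areas[1, j]:.17e} {profile.areas[2, j]:.17e}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_sigma(path: str | Path) -> SigmaProfile:
    """Read a σ-profile text file.

    Both the native 4-column three-class layout and legacy 2-column
    single-class files (all area loaded as NHB) are accepted.  A wrong row
    count or malformed row raises :class:`SigmaFormatError` naming the line.
    """
    path = Path(path)
    name = path.stem
    volume = 0.0
    rows: list[tuple[int, list[str]]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("name:"):
                name = body.partition(":")[2].strip()
            elif body.lower().startswith("volume[a^3]:"):
                volume = float(body.partition(":")[2])
            continue
        rows.append((lineno, line.split()))

    if len(rows) != N_BINS:
        raise SigmaFormatError(
            f"{path.name}: expected {N_BINS} data rows, found {len(rows)}"
        )
    areas = np.zeros((len(CLASSES), N_BINS))
    for j, (lineno, parts) in enumerate(rows):
        if len(parts) not in (2, 4):
            raise SigmaFormatError(
                f"{path.name}: line {lineno}: expected 2 or 4 columns, "
                f"got {len(parts)}"
            )
        try:
            values = [float(p) for p in parts]
        except ValueError as exc:
            raise SigmaFormatError(
                f"{path.name}: line {lineno}: non-numeric field"
            ) from exc
        if abs(values[0] - SIGMA_GRID[j]) > 1e-9:
            raise SigmaFormatError(
                f"{path.name}: line {lineno}: σ value {values[0]} does not "
                f"match grid node {SIGMA_GRID[j]:.4f}"
            )
        if len(values) == 2:
            areas[0, j] = values[1]
        else:
            areas[:, j] = values[1:]
    return SigmaProfile(name=name, areas=areas, volume=volume)
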