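"""Activity coefficients: residual segment model + combinatorial + dispersion.

``ln γ_i`` of each mixture component is assembled as the sum of up to three
contributions,

* a residual (enthalpic) term from the self-consistent interaction of
  σ-profile surface segments (electrostatic misfit plus hydrogen-bond
  exchange energies over the three NHB/OH/OT surface classes),
* a combinatorial (entropic) term — either the Staverman–Guggenheim (SG)
  relation on normalized area/volume parameters or a free-volume (FV)
  Flory–Huggins form built on free volumes ``v^F = v − v^HC``,
* an ad hoc single-constant Margules dispersion term whose constant follows
  from the components' dispersion energy parameters by a combining rule
  with molecule-class sign exceptions.

The six supported model configurations toggle the combinatorial flavor and
the dispersion term; the residual term is always active.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .constants import (
    CLASSES,
    N_BINS,
    PARAMETER_SETS,
    R_KCAL,
    SIGMA_GRID,
    VDW_AROMATIC_RING_CORRECTION,
    VDW_ATOM_INCREMENTS,
    VDW_BOND_CORRECTION,
    VDW_NONAROMATIC_RING_CORRECTION,
    AVOGADRO,
    ParameterSet,
)
from .sigma_io import SigmaProfile

__all__ = [
    "FusionProperties",
    "Component",
    "ModelConfig",
    "ActivityResult",
    "ResidualWorkspace",
    "ConvergenceError",
    "lngamma_residual",
    "lngamma_sg",
    "lngamma_fv",
    "lngamma_dsp",
    "lngamma_total",
    "dispersion_constant",
    "hardcore_volume",
    "hardcore_volume_from_smiles",
    "load_component_table",
    "lngamma_fv_minus_fh",
]

#: molecule classes steering the sign of the dispersion combining rule
DISPERSION_CLASSES = ("nhb", "hb-donor-acceptor", "hb-acceptor", "cooh", "water")


class ConvergenceError(RuntimeError):
    """Segment fixed-point iteration failed; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class FusionProperties:
    """Pure-API fusion data: T_m, Δfus h, and Δfus c_p = a + b·T."""

    tm: float          # K
    dh_fus: float      # kJ/mol
    dcp_a: float = 0.0  # J/(K mol)
    dcp_b: float = 0.0  # J/(K^2 mol)

    def dcp(self, t: float) -> float:
        return self.dcp_a + self.dcp_b * t


@dataclass
class Component:
    """A mixture species: σ-profile plus pure-component properties.

    ``v`` is the liquid molar volume at the 298 K convention, ``v_hc`` the
    molar hard-core (van der Waals) volume, both cm³/mol.  ``eps`` is the
    dispersion energy parameter ε/k_B in K, with ``dispersion_class``
    flagging sign-rule exceptions.  Fusion properties are present only for
    a crystallizable API.
    """

    name: str
    profile: SigmaProfile | None = None
    m: float = 0.0
    v: float = float("nan")
    v_hc: float = float("nan")
    eps: float | None = None
    dispersion_class: str = "nhb"
    fusion: FusionProperties | None = None

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("molar mass must be positive")
        if np.isfinite(self.v) and np.isfinite(self.v_hc):
            if not 0 < self.v_hc < self.v:
                raise ValueError(
                    f"{self.name}: require 0 < v_hc ({self.v_hc}) < v ({self.v})"
                )
        if self.dispersion_class not in DISPERSION_CLASSES:
            raise ValueError(
                f"{self.name}: unknown dispersion class {self.dispersion_class!r}"
            )

    @property
    def v_free(self) -> float:
        """Free molar volume v^F = v − v^HC, cm³/mol."""
        return self.v - self.v_hc

    @property
    def area(self) -> float:
        return self.profile.area

    @property
    def volume(self) -> float:
        return self.profile.volume


class ModelConfig(BaseModel):
    """One of the six model configurations plus solver tolerances."""

    combinatorial: Literal["none", "sg", "fv"] = "fv"
    dispersion: bool = True
    parameter_set: str = "2010"
    gamma_tol: float = Field(1e-8, gt=0)
    gamma_maxiter: int = Field(500, gt=0)
    gamma_damping: float = Field(0.5, ge=0, lt=1)
    diff_step: float = Field(1e-5, gt=0)

    model_config = {"extra": "forbid"}

    @model_validator(mode="after")
    def _check_params(self):
        if self.parameter_set not in PARAMETER_SETS:
            raise ValueError(f"unknown parameter set {self.parameter_set!r}")
        return self

    @property
    def params(self) -> ParameterSet:
        return PARAMETER_SETS[self.parameter_set]

    @property
    def label(self) -> str:
        comb = {"none": "", "sg": "^SG", "fv": "^FV"}[self.combinatorial]
        dsp = "_dsp" if self.dispersion else ""
        return f"CS{dsp}{comb}"

    @classmethod
    def from_label(cls, label: str, **kwargs) -> "ModelConfig":
        """Build from a configuration label such as ``CS_dsp^FV``."""
        key = label.replace("-", "").replace("^", "").replace("_", "").lower()
        table = {
            "cs": ("none", False),
            "cssg": ("sg", False),
            "csfv": ("fv", False),
            "csdsp": ("none", True),
            "csdspsg": ("sg", True),
            "csdspfv": ("fv", True),
        }
        if key not in table:
            raise ValueError(f"unknown model configuration label {label!r}")
        comb, dsp = table[key]
        return cls(combinatorial=comb, dispersion=dsp, **kwargs)


@dataclass
class ActivityResult:
    """Per-component ln γ terms; total is the exact sum of active terms."""

    lngamma_res: np.ndarray
    lngamma_comb: np.ndarray
    lngamma_dsp: np.ndarray
    iterations: int

    @property
    def total(self) -> np.ndarray:
        return self.lngamma_res + self.lngamma_comb + self.lngamma_dsp


@dataclass
class ResidualWorkspace:
    """Converged segment state: mixture profile, Γ fields, ΔW matrix."""

    p_mix: np.ndarray            # (3*N_BINS,) normalized mixture profile
    gamma_mix: np.ndarray        # (3*N_BINS,)
    gamma_pure: list[np.ndarray]
    exchange: np.ndarray         # (3*N_BINS, 3*N_BINS) ΔW in kcal/mol
    iterations: int


# ---------------------------------------------------------------------------
# residual term
# ---------------------------------------------------------------------------

def _exchange_energy(params: ParameterSet, t: float) -> np.ndarray:
    """ΔW(σ_m^t, σ_n^s) on the flattened class×bin grid, kcal/mol units."""
    sig = np.tile(SIGMA_GRID, len(CLASSES))
    cls = np.repeat(np.arange(len(CLASSES)), N_BINS)
    sm, sn = np.meshgrid(sig, sig, indexing="ij")
    cm, cn = np.meshgrid(cls, cls, indexing="ij")

    c_es = params.a_es + params.b_es / (t * t)
    dw = c_es * np.square(sm + sn)

    chb = np.zeros_like(dw)
    oh, ot = 1, 2
    chb[(cm == oh) & (cn == oh)] = params.c_ohoh
    chb[(cm == ot) & (cn == ot)] = params.c_otot
    chb[((cm == oh) & (cn == ot)) | ((cm == ot) & (cn == oh))] = params.c_ohot
    chb = np.where(sm * sn < 0.0, chb, 0.0)
    return dw - chb * np.square(sm - sn)


def _solve_segment_gamma(
    p: np.ndarray,
    boltz: np.ndarray,
    tol: float,
    maxiter: int,
    damping: float,
) -> tuple[np.ndarray, int]:
    """Damped successive substitution for segment activity coefficients Γ."""
    gamma = np.ones_like(p)
    residual = np.inf
    for it in range(1, maxiter + 1):
        denom = boltz @ (p * gamma)
        gamma_new = 1.0 / denom
        residual = float(np.max(np.abs(gamma_new - gamma) / gamma_new))
        gamma = damping * gamma + (1.0 - damping) * gamma_new
        if residual < tol:
            return gamma, it
    raise ConvergenceError(
        f"segment Γ iteration did not converge in {maxiter} steps "
        f"(last residual {residual:.3e})",
        residual,
    )


def residual_workspace(
    components: Sequence[Component],
    x: Sequence[float],
    t: float,
    config: ModelConfig | None = None,
) -> ResidualWorkspace:
    """Solve the segment model for the mixture and every pure component."""
    config = config or ModelConfig()
    params = config.params
    x = np.asarray(x, dtype=float)
    if abs(x.sum() - 1.0) > 1e-9:
        raise ValueError("mole fractions must sum to 1")
    if t <= 0:
        raise ValueError("temperature must be positive")

    profiles = [c.profile.normalized().ravel() for c in components]
    areas = np.array([c.profile.area for c in components])
    weights = x * areas
    p_mix = sum(w * p for w, p in zip(weights, profiles)) / weights.sum()

    dw = _exchange_energy(params, t)
    boltz = np.exp(-dw / (R_KCAL * t))

    gamma_mix, iters = _solve_segment_gamma(
        p_mix, boltz, config.gamma_tol, config.gamma_maxiter, config.gamma_damping
    )
    gamma_pure = []
    for p in profiles:
        g, it = _solve_segment_gamma(
            p, boltz, config.gamma_tol, config.gamma_maxiter, config.gamma_damping
        )
        gamma_pure.append(g)
        iters += it
    return ResidualWorkspace(p_mix, gamma_mix, gamma_pure, dw, iters)


def lngamma_residual(
    components: Sequence[Component],
    x: Sequence[float],
    t: float,
    config: ModelConfig | None = None,
    workspace: ResidualWorkspace | None = None,
) -> np.ndarray:
    """Residual ln γ from area-weighted segment-activity differences."""
    config = config or ModelConfig()
    ws = workspace or residual_workspace(components, x, t, config)
    params = config.params
    out = np.empty(len(components))
    for i, comp in enumerate(components):
        p_i = comp.profile.normalized().ravel()
        n_i = comp.profile.area / params.a_eff
        out[i] = n_i * float(
            np.sum(p_i * (np.log(ws.gamma_mix) - np.log(ws.gamma_pure[i])))
        )
    return out


# ---------------------------------------------------------------------------
# combinatorial terms
# ---------------------------------------------------------------------------

def lngamma_sg(
    components: Sequence[Component],
    x: Sequence[float],
    config: ModelConfig | None = None,
) -> np.ndarray:
    """Staverman–Guggenheim combinatorial term."""
    config = config or ModelConfig()
    params = config.params
    x = np.asarray(x, dtype=float)
    r = np.array([c.profile.volume for c in components]) / params.r0
    q = np.array([c.profile.area for c in components]) / params.q0
    z2 = params.z_coord / 2.0
    phi_over_x = r / float(x @ r)
    theta_over_phi = (q / r) * float(x @ r) / float(x @ q)
    ell = z2 * (r - q) - (r - 1.0)
    return (
        np.log(phi_over_x)
        + z2 * q * np.log(theta_over_phi)
        + ell
        - phi_over_x * float(x @ ell)
    )


def lngamma_fv(
    components: Sequence[Component],
    x: Sequence[float],
    config: ModelConfig | None = None,
) -> np.ndarray:
    """Free-volume combinatorial term.

    Flory–Huggins form with the volume fraction replaced by the free-volume
    fraction ``φ_i^FV = x_i v_i^F / Σ_j x_j v_j^F`` where ``v^F = v − v^HC``.
    """
    x = np.asarray(x, dtype=float)
    vf = np.array([c.v_free for c in components])
    if np.any(~np.isfinite(vf)) or np.any(vf <= 0):
        bad = [c.name for c, f in zip(components, vf) if not (np.isfinite(f) and f > 0)]
        raise ValueError(f"free volume v - v_hc must be positive for: {bad}")
    phi_over_x = vf / float(x @ vf)
    return np.log(phi_over_x) + 1.0 - phi_over_x


def lngamma_fv_minus_fh(
    components: Sequence[Component], x: Sequence[float]
) -> np.ndarray:
    """Closed-form difference between the FV and Flory–Huggins terms.

    ``ln γ_i^FV − ln γ_i^FH = ln(v_i^F v_mix / (v_i v_mix^F))
    + v_i/v_mix − v_i^F/v_mix^F`` with molar averages v_mix = Σ x v and
    v_mix^F = Σ x v^F.  Used as an independent identity check of the two
    term-by-term implementations.
    """
    x = np.asarray(x, dtype=float)
    v = np.array([c.v for c in components])
    vf = np.array([c.v_free for c in components])
    v_mix = float(x @ v)
    vf_mix = float(x @ vf)
    return np.log(vf * v_mix / (v * vf_mix)) + v / v_mix - vf / vf_mix


# ---------------------------------------------------------------------------
# dispersion term
# ---------------------------------------------------------------------------

_NEGATIVE_W_PAIRS = {
    frozenset(("water", "hb-acceptor")),
    frozenset(("cooh", "nhb")),
    frozenset(("cooh", "hb-donor-acceptor")),
    frozenset(("water", "cooh")),
}


def dispersion_constant(
    comp1: Component, comp2: Component, w_dsp: float
) -> float:
    """Margules constant from the combining rule on ε/k_B.

    ``A = w [ (ε₁+ε₂)/2 − sqrt(ε₁ ε₂) ]`` with w positive except for the
    listed molecule-class pairings, where its sign flips.
    """
    for comp in (comp1, comp2):
        if comp.eps is None:
            raise ValueError(
                f"{comp.name}: dispersion parameter ε missing but the "
                "dispersion term is enabled"
            )
    w = w_dsp
    if frozenset((comp1.dispersion_class, comp2.dispersion_class)) in _NEGATIVE_W_PAIRS:
        w = -w_dsp
    e1, e2 = comp1.eps, comp2.eps
    return w * (0.5 * (e1 + e2) - np.sqrt(e1 * e2))


def lngamma_dsp(
    components: Sequence[Component],
    x: Sequence[float],
    config: ModelConfig | None = None,
    a_override: float | None = None,
) -> np.ndarray:
    """Single-constant Margules dispersion term for a binary mixture."""
    config = config or ModelConfig()
    if len(components) != 2:
        raise ValueError("dispersion term is defined for binary mixtures only")
    x = np.asarray(x, dtype=float)
    a = (
        a_override
        if a_override is not None
        else dispersion_constant(components[0], components[1], config.params.w_dsp)
    )
    return np.array([a * x[1] ** 2, a * x[0] ** 2])


# ---------------------------------------------------------------------------
# total
# ---------------------------------------------------------------------------

def lngamma_total(
    components: Sequence[Component],
    x: Sequence[float],
    t: float,
    config: ModelConfig | None = None,
) -> ActivityResult:
    """ln γ per component for the active model configuration.

    Inactive terms are reported as exact zeros; the total is the exact sum
    of the active terms.
    """
    config = config or ModelConfig()
    n = len(components)
    ws = residual_workspace(components, x, t, config)
    res = lngamma_residual(components, x, t, config, workspace=ws)
    if config.combinatorial == "sg":
        comb = lngamma_sg(components, x, config)
    elif config.combinatorial == "fv":
        comb = lngamma_fv(components, x, config)
    else:
        comb = np.zeros(n)
    if config.dispersion:
        dsp = lngamma_dsp(components, x, config)
    else:
        dsp = np.zeros(n)
    return ActivityResult(res, comb, dsp, ws.iterations)


# ---------------------------------------------------------------------------
# hard-core volume
# ---------------------------------------------------------------------------

def hardcore_volume(
    atom_counts: dict[str, int | float],
    n_bonds: float,
    n_aromatic_rings: float = 0,
    n_nonaromatic_rings: float = 0,
) -> float:
    """Molar hard-core (van der Waals) volume in cm³/mol.

    Bondi-radius-based atomic increments minus bond and ring corrections::

        V/A^3 = Σ_atoms ΔV_atom − 5.92 N_bonds − 14.7 R_arom − 3.8 R_nonarom

    converted to molar volume.  Counts may be fractional (useful for
    per-repeat-unit averages of copolymers).
    """
    if n_bonds < 0 or n_aromatic_rings < 0 or n_nonaromatic_rings < 0:
        raise ValueError("counts must be non-negative")
    vol = 0.0
    for element, count in atom_counts.items():
        if count < 0:
            raise ValueError("atom counts must be non-negative")
        try:
            vol += VDW_ATOM_INCREMENTS[element] * count
        except KeyError:
            supported = ", ".join(sorted(VDW_ATOM_INCREMENTS))
            raise ValueError(
                f"unknown element {element!r}; supported: {supported}"
            ) from None
    vol -= VDW_BOND_CORRECTION * n_bonds
    vol -= VDW_AROMATIC_RING_CORRECTION * n_aromatic_rings
    vol -= VDW_NONAROMATIC_RING_CORRECTION * n_nonaromatic_rings
    return vol * AVOGADRO / 1e24  # A^3/molecule -> cm^3/mol


def load_component_table(path, sigma_dir=None) -> dict[str, Component]:
    """Load components from a property CSV plus per-component σ-profiles.

    Expected columns: ``name, M, v, v_hc, eps, dispersion_class, Tm, dHfus,
    dCp_a, dCp_b, sigma_path``.  Empty fusion cells mean the species is not
    crystallizable; an empty ``sigma_path`` leaves the profile unset.
    """
    import math
    from pathlib import Path

    import pandas as pd

    from .sigma_io import read_sigma

    path = Path(path)
    sigma_dir = Path(sigma_dir) if sigma_dir is not None else path.parent
    frame = pd.read_csv(path)
    required = {"name", "M", "v", "v_hc"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"component table lacks columns {sorted(missing)}")

    def _get(row, col, default=None):
        if col not in row or pd.isna(row[col]):
            return default
        return row[col]

    out: dict[str, Component] = {}
    for _, row in frame.iterrows():
        fusion = None
        if _get(row, "Tm") is not None:
            fusion = FusionProperties(
                tm=float(row["Tm"]),
                dh_fus=float(row["dHfus"]),
                dcp_a=float(_get(row, "dCp_a", 0.0)),
                dcp_b=float(_get(row, "dCp_b", 0.0)),
            )
        profile = None
        sigma_path = _get(row, "sigma_path")
        if sigma_path:
            candidate = Path(sigma_path)
            if not candidate.is_absolute():
                candidate = sigma_dir / candidate
            profile = read_sigma(candidate)
        eps = _get(row, "eps")
        out[str(row["name"])] = Component(
            name=str(row["name"]),
            profile=profile,
            m=float(row["M"]),
            v=float(_get(row, "v", math.nan)),
            v_hc=float(_get(row, "v_hc", math.nan)),
            eps=float(eps) if eps is not None else None,
            dispersion_class=str(_get(row, "dispersion_class", "nhb")),
            fusion=fusion,
        )
    return out


def hardcore_volume_from_smiles(smiles: str) -> float:
    """Hard-core molar volume from a SMILES string (requires RDKit)."""
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover
        raise ImportError("hardcore_volume_from_smiles requires rdkit") from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
    n_bonds = mol.GetNumBonds()
    n_arom = 0
    n_nonarom = 0
    ring_info = mol.GetRingInfo()
    for ring in ring_info.BondRings():
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring):
            n_arom += 1
        else:
            n_nonarom += 1
    return hardcore_volume(counts, n_bonds, n_arom, n_nonarom)
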