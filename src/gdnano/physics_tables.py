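"""Physical constants, materials, reaction channels and lookup tables.

Everything downstream — beam transport, nano-target alpha production, dose
and strand-break integration, and the neutron slab model — pulls its physics
from here: elemental compositions and number densities, the four plateau
reaction cross-sections, and the alpha-particle LET(E) / RBE(LET) lookup
table with its interpolation contract.

Cross-sections are plateau values in barns (1 b = 1e-24 cm^2); the
``ReactionChannel`` type also accepts a tabulated sigma(E) for refinement.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib.resources import files

import numpy as np
import yaml

N_AVOGADRO = 6.02214076e23  # 1/mol
BARN_TO_CM2 = 1.0e-24
MEV_PER_U = 931.49410242

#: Atomic rest masses (u) used in reaction kinematics; atomic (not nuclear)
#: masses so that Q-values computed from them are electron-consistent.
PARTICLE_MASS_U = {
    "p": 1.007825,
    "n": 1.008665,
    "alpha": 4.002603,
    "C12": 12.0,
    "O16": 15.994915,
    "F19": 18.998403,
    "Li7": 7.016003,
}

#: Map from target element symbol (as used in material compositions) to the
#: nuclide actually struck in the reaction kinematics.
TARGET_NUCLIDE_MASS_U = {"C": 12.0, "F": 18.998403}


def _data_path(name: str):
    return files("gdnano.data").joinpath(name)


def load_nuclide_data() -> dict:
    """Per-element constants: atomic mass, A, scattering/capture sigmas."""
    with _data_path("nuclides.yaml").open() as fh:
        return yaml.safe_load(fh)


_NUCLIDES = load_nuclide_data()


class InvalidInputError(ValueError):
    """Raised for physically invalid arguments (negative energies etc.)."""


# ---------------------------------------------------------------------------
# Materials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Material:
    """A homogeneous material: name, bulk density and mass fractions."""

    name: str
    density: float  # g/cm^3
    composition: tuple[tuple[str, float], ...]  # (element, mass fraction)

    def __post_init__(self):
        if self.density <= 0:
            raise InvalidInputError(f"density must be > 0, got {self.density}")
        total = sum(f for _, f in self.composition)
        if abs(total - 1.0) > 1e-9:
            raise InvalidInputError(
                f"mass fractions of {self.name!r} sum to {total!r}, not 1.0"
            )
        for el, f in self.composition:
            if f < 0:
                raise InvalidInputError(f"negative mass fraction for {el}")

    def mass_fraction(self, element: str) -> float:
        for el, f in self.composition:
            if el == element:
                return f
        return 0.0


@dataclass(frozen=True)
class NumberDensity:
    element: str
    n: float  # atoms/cm^3

    def __post_init__(self):
        if self.n < 0:
            raise InvalidInputError(f"number density must be >= 0, got {self.n}")


def number_densities(material: Material) -> list[NumberDensity]:
    """Atoms per cm^3 of each element: n_i = rho * w_i / A_i * N_A."""
    out = []
    for el, frac in material.composition:
        if el not in _NUCLIDES:
            raise InvalidInputError(f"unknown element symbol: {el!r}")
        a = _NUCLIDES[el]["atomic_mass"]
        out.append(NumberDensity(el, material.density * frac / a * N_AVOGADRO))
    return out


def number_density_of(material: Material, element: str) -> float:
    """Atoms/cm^3 of one element in a material (0.0 if absent)."""
    for nd in number_densities(material):
        if nd.element == element:
            return nd.n
    if element not in _NUCLIDES:
        raise InvalidInputError(f"unknown element symbol: {element!r}")
    return 0.0


def gd_number_density_from_ppm(ppm_mass: float, host: Material) -> float:
    """157Gd atoms/cm^3 for a mass-ppm loading in a host material.

    ppm is parts per million by mass (the convention in the Gd neutron-capture
    literature); the 157Gd molar mass is taken as 157 g/mol.
    """
    if ppm_mass < 0:
        raise InvalidInputError(f"ppm must be >= 0, got {ppm_mass}")
    a_gd = _NUCLIDES["Gd"]["atomic_mass"]
    return host.density * ppm_mass * 1e-6 / a_gd * N_AVOGADRO


def macroscopic_sigma(n: float, sigma_barn: float) -> float:
    """Macroscopic cross-section Sigma = n * sigma (1/cm)."""
    n = np.asarray(n, dtype=float)
    sigma_barn = np.asarray(sigma_barn, dtype=float)
    if np.any(n < 0) or np.any(sigma_barn < 0):
        raise InvalidInputError("n and sigma must be >= 0")
    out = n * sigma_barn * BARN_TO_CM2
    return float(out) if out.ndim == 0 else out


def load_materials() -> dict[str, Material]:
    with _data_path("materials.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return {
        name: Material(name, m["density"], tuple(m["composition"].items()))
        for name, m in raw.items()
    }


# ---------------------------------------------------------------------------
# Reaction channels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReactionChannel:
    """One nuclear reaction with a plateau (or tabulated) cross-section."""

    name: str
    projectile: str
    target_nuclide: str
    products: tuple[str, ...]
    sigma_barn: float
    alpha_multiplicity: int
    q_value_mev: float
    #: optional tabulated sigma(E): (energies_mev, sigmas_barn)
    sigma_table: tuple[tuple[float, ...], tuple[float, ...]] | None = None

    def __post_init__(self):
        if self.sigma_barn < 0:
            raise InvalidInputError("cross-section must be >= 0")
        n_alpha = sum(1 for pr in self.products if pr == "alpha")
        if n_alpha != self.alpha_multiplicity:
            raise InvalidInputError(
                f"alpha_multiplicity {self.alpha_multiplicity} inconsistent "
                f"with products {self.products}"
            )

    @property
    def threshold_mev(self) -> float:
        """Lab-frame kinetic-energy threshold for the charged-particle channels.

        Endothermic: T_thr = -Q / (1 - m_proj*M_out/M_in^2) in the
        non-relativistic convention used by the event sampler; exothermic: 0.
        """
        if self.q_value_mev >= 0 or self.projectile == "n":
            return 0.0
        m_proj = PARTICLE_MASS_U[self.projectile if self.projectile != "p" else "p"]
        m_tgt = TARGET_NUCLIDE_MASS_U.get(self.target_nuclide)
        if m_tgt is None:
            return 0.0
        m_out = sum(
            PARTICLE_MASS_U[pr] for pr in self.products if pr in PARTICLE_MASS_U
        )
        m_in = m_proj + m_tgt
        return -self.q_value_mev / (1.0 - m_proj * m_out / m_in**2)

    def sigma_at(self, e_mev) -> np.ndarray | float:
        """sigma(E) in barns; 0 below threshold."""
        e = np.asarray(e_mev, dtype=float)
        if self.sigma_table is not None:
            sig = np.interp(e, self.sigma_table[0], self.sigma_table[1])
        else:
            sig = np.full_like(e, self.sigma_barn)
        sig = np.where(e > self.threshold_mev, sig, 0.0)
        return float(sig) if sig.ndim == 0 else sig


def load_reaction_channels() -> dict[str, ReactionChannel]:
    with _data_path("reactions.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return {
        name: ReactionChannel(
            name=name,
            projectile=ch["projectile"],
            target_nuclide=ch["target_nuclide"],
            products=tuple(ch["products"]),
            sigma_barn=ch["sigma_barn"],
            alpha_multiplicity=ch["alpha_multiplicity"],
            q_value_mev=ch["q_value_mev"],
        )
        for name, ch in raw.items()
    }


# ---------------------------------------------------------------------------
# LET / RBE lookup
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LetRbeTable:
    """Tabulated LET(E) for alphas in tissue and RBE(LET) at 10% survival.

    The grid spans 1-12 MeV in 1 MeV steps; LET is strictly decreasing over
    the grid. Lookups are linear between grid points and clamp (with a
    warning) outside the tabulated domain.
    """

    energies: np.ndarray  # MeV
    let_values: np.ndarray  # keV/um
    rbe_values: np.ndarray  # dimensionless

    def __post_init__(self):
        e, l, r = (np.asarray(v, float) for v in
                   (self.energies, self.let_values, self.rbe_values))
        if not (len(e) == len(l) == len(r)):
            raise InvalidInputError("grid length mismatch in LET/RBE table")
        if np.any(l <= 0) or np.any(r <= 0) or np.any(e <= 0):
            raise InvalidInputError("LET/RBE table values must be > 0")
        if np.any(np.diff(l) >= 0):
            raise InvalidInputError("LET must be strictly decreasing in E")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "let_values", l)
        object.__setattr__(self, "rbe_values", r)

    @classmethod
    def from_tsv(cls, path=None) -> "LetRbeTable":
        if path is None:
            path = _data_path("let_rbe.tsv")
        arr = np.loadtxt(path)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2])


_DEFAULT_LET_RBE: LetRbeTable | None = None


def default_let_rbe_table() -> LetRbeTable:
    global _DEFAULT_LET_RBE
    if _DEFAULT_LET_RBE is None:
        _DEFAULT_LET_RBE = LetRbeTable.from_tsv()
    return _DEFAULT_LET_RBE


def _clamped(x, lo, hi, what):
    x = np.asarray(x, dtype=float)
    if np.any(x < lo) or np.any(x > hi):
        warnings.warn(
            f"{what} outside tabulated range [{lo}, {hi}]; clamping",
            stacklevel=3,
        )
    return np.clip(x, lo, hi)


def let_of_energy(e_mev, table: LetRbeTable | None = None):
    """LET (keV/um) of an alpha of kinetic energy ``e_mev`` (MeV)."""
    table = table or default_let_rbe_table()
    e = np.asarray(e_mev, dtype=float)
    if np.any(e <= 0):
        raise InvalidInputError("alpha energy must be > 0")
    e = _clamped(e, table.energies[0], table.energies[-1], "alpha energy")
    out = np.interp(e, table.energies, table.let_values)
    return float(out) if out.ndim == 0 else out


def rbe_of_let(let_kev_um, table: LetRbeTable | None = None):
    """RBE (10% surviving fraction) at a given LET; reporting aid only."""
    table = table or default_let_rbe_table()
    let = np.asarray(let_kev_um, dtype=float)
    if np.any(let <= 0):
        raise InvalidInputError("LET must be > 0")
    lo, hi = table.let_values[-1], table.let_values[0]
    let = _clamped(let, lo, hi, "LET")
    # LET decreases with E, so reverse for ascending-x interpolation.
    out = np.interp(let, table.let_values[::-1], table.rbe_values[::-1])
    return float(out) if out.ndim == 0 else out


MATERIALS = load_materials()
REACTIONS = load_reaction_channels()
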