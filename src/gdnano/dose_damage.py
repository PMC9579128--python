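"""Fluence-weighted dose, strand-break totals and enhancement metrics.

The two effectiveness metrics are plain spectrum-weighted sums over energy
bins, evaluated at bin centers:

    Dose_tot [Gy/proton] = sum_i fluence(E_i) * LET(E_i) * 1.6e-13
    SSB_tot              = sum_i fluence(E_i) * SSB(E_i)
    DSB_tot              = sum_i fluence(E_i) * DSB(E_i)

fluence(E_i) is alphas per incident proton per bin; the 1.6e-13 keV->Gy
conversion is applied verbatim, with the implied area/mass normalization
folded into the synthetic-spectrum calibration (see docs/methods.md).
Enhancement is the percent increase of the with-target value over the
without-target value, under a configurable rounding policy.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files

import numpy as np

from .physics_tables import InvalidInputError, LetRbeTable, default_let_rbe_table, let_of_energy
from .spectrum import EnergySpectrum

#: keV -> Gy conversion applied in the dose sum (per incident proton).
DOSE_CONVERSION = 1.6e-13


@dataclass(frozen=True)
class DamageYieldTable:
    """Per-alpha SSB/DSB yields vs alpha energy on the 1-12 MeV grid.

    The SSB curve peaks at 2 MeV and the DSB curve at 1 MeV; lookups clamp
    outside the grid like the LET table.
    """

    energies: np.ndarray
    ssb_per_alpha: np.ndarray
    dsb_per_alpha: np.ndarray
    source_label: str = "default"

    def __post_init__(self):
        e = np.asarray(self.energies, float)
        s = np.asarray(self.ssb_per_alpha, float)
        d = np.asarray(self.dsb_per_alpha, float)
        if not (len(e) == len(s) == len(d)):
            raise InvalidInputError("damage-yield grids must have equal length")
        if np.any(s < 0) or np.any(d < 0):
            raise InvalidInputError("damage yields must be >= 0")
        if e[np.argmax(s)] != 2.0:
            raise InvalidInputError("SSB yield must peak at 2 MeV")
        if e[np.argmax(d)] != 1.0:
            raise InvalidInputError("DSB yield must peak at 1 MeV")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "ssb_per_alpha", s)
        object.__setattr__(self, "dsb_per_alpha", d)

    @classmethod
    def from_shape(cls, ssb_scale: float = 1.0, dsb_scale: float = 1.0,
                   label: str = "parametric") -> "DamageYieldTable":
        """Skewed-peak parametric table with the canonical argmax positions."""
        e = np.arange(1.0, 13.0)
        return cls(e, ssb_scale * peak_shape(e, 2.0, 1.5),
                   dsb_scale * peak_shape(e, 1.0, 1.2), label)

    @classmethod
    def from_tsv(cls, path=None) -> "DamageYieldTable":
        if path is None:
            path = files("gdnano.data").joinpath("damage_yield.tsv")
        label = "fitted"
        with open(path) as fh:
            for line in fh:
                if line.startswith("#source_label"):
                    label = line.split(None, 1)[1].strip()
        arr = np.loadtxt(path)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], label)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#source_label {self.source_label}\n")
            fh.write("#E_MeV SSB_per_alpha DSB_per_alpha\n")
            for e, s, d in zip(self.energies, self.ssb_per_alpha, self.dsb_per_alpha):
                fh.write(f"{e:g} {s:.10e} {d:.10e}\n")


def peak_shape(e, e_peak: float, skew: float):
    """Gamma-like unimodal shape (E/Ep)^a exp(a (1 - E/Ep)), max 1 at Ep."""
    x = np.asarray(e, float) / e_peak
    return np.power(x, skew) * np.exp(skew * (1.0 - x))


def damage_yield(e_mev, table: DamageYieldTable) -> tuple:
    """Interpolated (SSB, DSB) per alpha at energy ``e_mev`` (clamped)."""
    e = np.asarray(e_mev, dtype=float)
    if np.any(e <= 0):
        raise InvalidInputError("alpha energy must be > 0")
    e = np.clip(e, table.energies[0], table.energies[-1])
    ssb = np.interp(e, table.energies, table.ssb_per_alpha)
    dsb = np.interp(e, table.energies, table.dsb_per_alpha)
    if ssb.ndim == 0:
        return float(ssb), float(dsb)
    return ssb, dsb


@dataclass(frozen=True)
class DoseResult:
    total_dose: float  # Gy per incident proton
    per_bin: np.ndarray
    conversion_constant: float = DOSE_CONVERSION

    def __post_init__(self):
        if self.total_dose < 0 or np.any(self.per_bin < 0):
            raise InvalidInputError("dose must be nonnegative")


@dataclass(frozen=True)
class DamageResult:
    ssb_total: float  # per incident proton
    dsb_total: float

    def __post_init__(self):
        if self.ssb_total < 0 or self.dsb_total < 0:
            raise InvalidInputError("strand-break totals must be nonnegative")


def total_dose(spectrum: EnergySpectrum, let_table: LetRbeTable | None = None) -> DoseResult:
    """Eq.-style fluence x LET dose sum at bin centers."""
    if len(spectrum.fluence) == 0:
        raise InvalidInputError("empty spectrum")
    let_table = let_table or default_let_rbe_table()
    centers = spectrum.bin_centers
    mask = spectrum.fluence > 0
    per_bin = np.zeros_like(spectrum.fluence)
    if mask.any():
        let = let_of_energy(centers[mask], let_table)
        per_bin[mask] = spectrum.fluence[mask] * let * DOSE_CONVERSION
    return DoseResult(float(per_bin.sum()), per_bin)


def total_strand_breaks(spectrum: EnergySpectrum,
                        table: DamageYieldTable) -> DamageResult:
    """Spectrum-weighted SSB and DSB totals per incident proton."""
    if len(spectrum.fluence) == 0:
        raise InvalidInputError("empty spectrum")
    centers = spectrum.bin_centers
    mask = spectrum.fluence > 0
    ssb = dsb = 0.0
    if mask.any():
        s, d = damage_yield(centers[mask], table)
        ssb = float((spectrum.fluence[mask] * s).sum())
        dsb = float((spectrum.fluence[mask] * d).sum())
    return DamageResult(ssb, dsb)


def enhancement_percent(with_value: float, without_value: float,
                        rounding: str | None = "int") -> float:
    """100 * (with - without) / without, rounded per policy.

    rounding: ``"int"`` nearest integer, ``"10"`` nearest ten, ``"2sf"`` two
    significant figures, ``None``/``"raw"`` unrounded.
    """
    if without_value <= 0:
        raise InvalidInputError("without_value must be > 0")
    pct = 100.0 * (with_value - without_value) / without_value
    if rounding in (None, "raw"):
        return pct
    if rounding == "int":
        return float(round(pct))
    if rounding == "10":
        return float(round(pct / 10.0) * 10.0)
    if rounding == "2sf":
        if pct == 0:
            return 0.0
        from math import floor, log10
        ndigits = 1 - int(floor(log10(abs(pct))))
        return float(round(pct, ndigits))
    raise InvalidInputError(f"unknown rounding policy: {rounding!r}")
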