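"""Binned particle-fluence spectra: the pipeline's common currency.

An :class:`EnergySpectrum` holds fluence per incident proton per energy bin,
optionally with the raw sampled counts behind each bin (for counting-error
bars), and round-trips through a commented delimited-text format.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class EnergySpectrum:
    """Particle fluence per incident proton, binned in kinetic energy."""

    bin_edges: np.ndarray  # MeV, strictly increasing, len = nbins + 1
    fluence: np.ndarray  # particles per incident proton per bin
    particle: str = "alpha"
    n_protons: int | None = None  # incident protons behind the statistics
    counts: np.ndarray | None = None  # raw sampled counts per bin
    seed: int | None = None

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        flu = np.asarray(self.fluence, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if len(flu) != len(edges) - 1:
            raise ValueError("fluence length must be len(bin_edges) - 1")
        if np.any(flu < 0):
            raise ValueError("fluence must be >= 0 in every bin")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "fluence", flu)
        if self.counts is not None:
            c = np.asarray(self.counts, dtype=float)
            if len(c) != len(flu):
                raise ValueError("counts length must match fluence")
            object.__setattr__(self, "counts", c)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def total_fluence(self) -> float:
        return float(self.fluence.sum())

    def scaled(self, factor: float) -> "EnergySpectrum":
        return replace(self, fluence=self.fluence * factor, counts=None)

    def __add__(self, other: "EnergySpectrum") -> "EnergySpectrum":
        if not np.array_equal(self.bin_edges, other.bin_edges):
            raise ValueError("cannot add spectra with different binning")
        counts = None
        if self.counts is not None and other.counts is not None:
            counts = self.counts + other.counts
        return replace(self, fluence=self.fluence + other.fluence, counts=counts)

    def band_fluence(self, lo: float, hi: float) -> float:
        """Summed fluence of bins fully inside [lo, hi] MeV."""
        sel = (self.bin_edges[:-1] >= lo - 1e-12) & (self.bin_edges[1:] <= hi + 1e-12)
        return float(self.fluence[sel].sum())

    # -- text serialization -------------------------------------------------

    def save(self, path) -> None:
        counts = self.counts if self.counts is not None else np.full(len(self.fluence), np.nan)
        with open(path, "w") as fh:
            fh.write(f"#particle {self.particle}\n")
            fh.write(f"#n_protons {self.n_protons if self.n_protons is not None else 'NA'}\n")
            fh.write(f"#seed {self.seed if self.seed is not None else 'NA'}\n")
            fh.write("#bin_low_MeV bin_high_MeV fluence_per_proton raw_count\n")
            for lo, hi, f, c in zip(self.bin_edges[:-1], self.bin_edges[1:], self.fluence, counts):
                fh.write(f"{lo:.6g} {hi:.6g} {f:.10e} {c:.10g}\n")

    @classmethod
    def load(cls, path) -> "EnergySpectrum":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    parts = line[1:].split(None, 1)
                    if len(parts) == 2 and parts[0] in ("particle", "n_protons", "seed"):
                        meta[parts[0]] = parts[1]
                    continue
                rows.append([float(x) for x in line.split()])
        arr = np.array(rows)
        edges = np.append(arr[:, 0], arr[-1, 1])
        counts = arr[:, 3]
        counts = None if np.all(np.isnan(counts)) else counts
        def _int_or_none(v):
            return None if v in (None, "NA") else int(float(v))
        return cls(
            bin_edges=edges,
            fluence=arr[:, 2],
            particle=meta.get("particle", "unknown"),
            n_protons=_int_or_none(meta.get("n_protons")),
            counts=counts,
            seed=_int_or_none(meta.get("seed")),
        )


def uniform_edges(emax: float, nbins: int) -> np.ndarray:
    return np.linspace(0.0, emax, nbins + 1)
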