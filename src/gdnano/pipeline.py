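"""End-to-end orchestration: validated config, seeded stages, report tables.

``run_pipeline`` chains beam -> nano-target Monte Carlo -> calibrated
synthetic spectra -> dose/damage -> neutron reduction and collects three
report tables (dose, strand breaks, neutron fluence) whose enhancement
columns are recomputable from the bundled raw values.
"""
from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .physics_tables import InvalidInputError, MATERIALS, default_let_rbe_table
from .beam_transport import build_sobp, in_tumor_proton_spectrum, sobp_flat_region
from .nano_interaction import NanoTargetGeometry, alpha_spectrum_pair
from .dose_damage import enhancement_percent, total_dose, total_strand_breaks
from .synthetic_data import (
    AGENTS,
    expected_alpha_spectrum,
    generate_alpha_spectra,
    generate_neutron_fluxes,
    default_yield_table,
    load_recipe,
)
from .neutron_model import reduction_report

_AGENT_MATERIAL = {"C": "carbon", "GdF4": "gdf4"}


@dataclass
class RunConfig:
    """All pipeline parameters; unknown keys are rejected at validation."""

    # beam stage
    depth_window: tuple = (2.0, 3.0)
    n_peaks: int = 11
    beam_protons: int = 100_000
    beam_seed: int = 11

    # nano-target Monte Carlo stage
    agent: str = "GdF4"  # none | C | GdF4
    thickness_nm: float = 50.0
    micro_events: int = 50_000
    micro_seed: int = 23

    # synthetic calibrated spectra
    synth_protons: int = 100_000_000
    synth_seed: int = 31
    synth_noise: bool = True

    # neutron stage
    gd_ppm: float = 3000.0
    partition_ratio: float = 70.0
    neutron_events: int = 100_000
    neutron_seed: int = 47

    # reporting
    rounding: str = "int"  # int | 10 | 2sf | raw

    def __post_init__(self):
        if self.agent not in AGENTS:
            raise InvalidInputError(f"agent must be one of {AGENTS}, got {self.agent!r}")
        for key in ("thickness_nm",):
            if getattr(self, key) <= 0:
                raise InvalidInputError(f"{key} must be > 0")
        for key in ("gd_ppm", "partition_ratio"):
            if getattr(self, key) < 0:
                raise InvalidInputError(f"{key} must be >= 0")
        for key in ("beam_protons", "micro_events", "synth_protons",
                    "neutron_events", "n_peaks"):
            if getattr(self, key) < 1:
                raise InvalidInputError(f"{key} must be >= 1")
        if self.rounding not in ("int", "10", "2sf", "raw"):
            raise InvalidInputError(f"unknown rounding policy {self.rounding!r}")

    def config_hash(self) -> str:
        canon = yaml.safe_dump(_jsonify(asdict(self)), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def validate_config(raw) -> RunConfig:
    """Parse a YAML document (text, mapping or path) into a typed RunConfig.

    Empty documents yield full defaults; unknown keys and out-of-range
    values raise, naming the key.
    """
    if isinstance(raw, RunConfig):
        return raw
    if (isinstance(raw, (str, Path)) and str(raw).strip()
            and "\n" not in str(raw) and Path(str(raw)).is_file()):
        raw = Path(raw).read_text()
    doc = yaml.safe_load(raw) if isinstance(raw, str) else raw
    doc = doc or {}
    if not isinstance(doc, dict):
        raise InvalidInputError("config document must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
    if "depth_window" in doc:
        doc["depth_window"] = tuple(doc["depth_window"])
    return RunConfig(**doc)


@dataclass
class ReportBundle:
    dose_table: pd.DataFrame
    damage_table: pd.DataFrame
    neutron_table: pd.DataFrame
    micro_summary: dict
    provenance: dict

    def render(self) -> str:
        buf = io.StringIO()
        buf.write("# Proton nano-target effectiveness report\n")
        for key, val in self.provenance.items():
            buf.write(f"# {key}: {val}\n")
        buf.write("\n## Alpha dose (Gy per incident proton)\n")
        buf.write(self.dose_table.to_string(index=False))
        buf.write("\n\n## DNA strand breaks (per incident proton)\n")
        buf.write(self.damage_table.to_string(index=False))
        buf.write("\n\n## Thermal-1 keV neutron fluence (per incident proton)\n")
        buf.write(self.neutron_table.to_string(index=False))
        buf.write("\n\n## Nano-target Monte Carlo summary\n")
        for key, val in self.micro_summary.items():
            buf.write(f"{key}: {val}\n")
        buf.write("\n")
        return buf.getvalue()


def run_pipeline(config: RunConfig | dict | str | None = None,
                 out_dir: str | Path | None = None) -> ReportBundle:
    """Run every stage under one validated config; deterministic per config."""
    cfg = validate_config(config if config is not None else {})
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- beam stage
    beam = build_sobp(depth_window=cfg.depth_window, n_peaks=cfg.n_peaks,
                      n_protons=cfg.beam_protons)
    proton_spec = in_tumor_proton_spectrum(beam, cfg.depth_window,
                                           seed=cfg.beam_seed)
    if out is not None:
        proton_spec.save(out / "proton_spectrum_tumor.txt")

    # --- nano-target Monte Carlo stage
    geometry = None
    if cfg.agent != "none":
        geometry = NanoTargetGeometry(MATERIALS[_AGENT_MATERIAL[cfg.agent]],
                                      cfg.thickness_nm)
    mc_with, mc_without = alpha_spectrum_pair(proton_spec, geometry,
                                              cfg.micro_events, cfg.micro_seed)
    excess = mc_with.fluence - mc_without.fluence
    tot = excess.sum()
    micro_summary = {
        "agent": cfg.agent,
        "alpha_yield_without_target": float(mc_without.total_fluence),
        "alpha_yield_with_target": float(mc_with.total_fluence),
        "excess_fraction_1_6_mev": float(excess[1:6].sum() / tot) if tot > 0 else 0.0,
    }
    if out is not None:
        mc_with.save(out / "mc_alpha_with_target.txt")
        mc_without.save(out / "mc_alpha_without_target.txt")

    # --- calibrated synthetic spectra -> dose & damage tables
    recipe = load_recipe()
    yield_table = default_yield_table()
    let_table = default_let_rbe_table()
    spectra = {
        a: generate_alpha_spectra(recipe, a, seed=cfg.synth_seed + i,
                                  n_protons=cfg.synth_protons,
                                  noise=cfg.synth_noise)
        for i, a in enumerate(AGENTS)
    }
    doses = {a: total_dose(s, let_table).total_dose for a, s in spectra.items()}
    dmg = {a: total_strand_breaks(s, yield_table) for a, s in spectra.items()}

    def enh(with_v, without_v):
        return enhancement_percent(with_v, without_v, cfg.rounding)

    report_agents = ("none",) if cfg.agent == "none" else ("none", cfg.agent)
    dose_rows, dmg_rows = [], []
    for a in report_agents:
        dose_rows.append({
            "agent": "No agent" if a == "none" else a,
            "dose_gy_per_proton": doses[a],
            "enhancement_pct": 0.0 if a == "none" else enh(doses[a], doses["none"]),
        })
        dmg_rows.append({
            "agent": "No agent" if a == "none" else a,
            "ssb_per_proton": dmg[a].ssb_total,
            "ssb_enhancement_pct": 0.0 if a == "none" else enh(dmg[a].ssb_total, dmg["none"].ssb_total),
            "dsb_per_proton": dmg[a].dsb_total,
            "dsb_enhancement_pct": 0.0 if a == "none" else enh(dmg[a].dsb_total, dmg["none"].dsb_total),
        })
    dose_table = pd.DataFrame(dose_rows)
    damage_table = pd.DataFrame(dmg_rows)
    if out is not None:
        for a, s in spectra.items():
            s.save(out / f"synthetic_alpha_{a}.txt")

    # --- neutron stage
    with_gd, without_gd = generate_neutron_fluxes(
        seed=cfg.neutron_seed, gd_ppm=cfg.gd_ppm,
        partition_ratio=cfg.partition_ratio, n_events=cfg.neutron_events)
    red = reduction_report(with_gd, without_gd)
    neutron_rows = []
    for reg in with_gd.regions:
        neutron_rows.append({
            "region": reg,
            "without_gd": red[reg]["without"],
            "with_gd": red[reg]["with"],
            "reduction_pct": red[reg]["reduction_percent"],
            "factor": red[reg]["factor"],
        })
    neutron_table = pd.DataFrame(neutron_rows)

    provenance = {
        "config_hash": cfg.config_hash(),
        "seeds": f"beam={cfg.beam_seed} micro={cfg.micro_seed} "
                 f"synth={cfg.synth_seed} neutron={cfg.neutron_seed}",
        "version": __version__,
    }
    bundle = ReportBundle(dose_table, damage_table, neutron_table,
                          micro_summary, provenance)
    if out is not None:
        (out / "report.txt").write_text(bundle.render())
        dose_table.to_csv(out / "dose_table.csv", index=False)
        damage_table.to_csv(out / "damage_table.csv", index=False)
        neutron_table.to_csv(out / "neutron_table.csv", index=False)
    return bundle
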