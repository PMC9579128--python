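"""Calibrate the synthetic alpha-spectrum recipe and damage-yield table.

Solves the free scale factors (baseline fluence, SSB/DSB yield scales,
per-agent excess shape+scale) so the published per-proton dose and
strand-break values are reproduced, then writes the fitted recipe and yield
table into the package data directory (the shipped fixtures regenerate
bit-identically from this script).
"""
from pathlib import Path

import pandas as pd

from gdnano.synthetic_data import calibrate, save_calibration

PKG_DATA = Path(__file__).resolve().parents[1] / "src" / "gdnano" / "data"
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    result = calibrate()
    save_calibration(result, PKG_DATA / "calibration.yaml",
                     PKG_DATA / "damage_yield.tsv")
    result.achieved.to_csv(OUT / "calibration_residuals.csv", index=False)
    with pd.option_context("display.float_format", "{:.4g}".format):
        print(result.achieved.to_string(index=False))
    print(f"worst relative residual: {result.worst_residual():.2e} "
          f"(tolerance {result.tolerance})")
    print(f"wrote {PKG_DATA / 'calibration.yaml'} and {PKG_DATA / 'damage_yield.tsv'}")


if __name__ == "__main__":
    main()
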