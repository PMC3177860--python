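"""Regenerate the packaged synthetic reference CSVs from the analytic models."""
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from warmcool.colorimetry import DEFAULT_GRID, planckian_spd, synthetic_cone_fundamentals

data_dir = Path(__file__).resolve().parents[1] / "src" / "warmcool" / "data"
data_dir.mkdir(parents=True, exist_ok=True)

ill = planckian_spd(6504.0, DEFAULT_GRID)
with open(data_dir / "illuminant_daylight_synthetic.csv", "w") as fh:
    fh.write("wavelength_nm,relative_power\n")
    for wl, v in zip(ill.wavelengths, ill.values):
        fh.write(f"{wl:.0f},{v:.6f}\n")

fund = synthetic_cone_fundamentals(DEFAULT_GRID)
with open(data_dir / "cone_fundamentals_synthetic.csv", "w") as fh:
    fh.write("wavelength_nm,l,m,s\n")
    for wl, l, m, s in zip(fund.wavelengths, fund.l, fund.m, fund.s):
        fh.write(f"{wl:.0f},{l:.8f},{m:.8f},{s:.8f}\n")

print("wrote", sorted(p.name for p in data_dir.glob("*.csv")))
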