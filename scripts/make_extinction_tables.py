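"""Regenerate the packaged synthetic extinction-coefficient tables.

The curves are monotone-cubic interpolants through landmark anchors placed at
the standard peak/valley positions of the visible-range absorbers used for
breast-tissue diffuse reflectance fitting:

* oxyhemoglobin  — Soret tail below 460 nm, beta/alpha Q-bands at 542/577 nm,
  steep fall-off beyond 585 nm;
* deoxyhemoglobin — Soret tail, single broad Q-band near 556 nm, slow decline
  toward 600 nm (noticeably above oxyhemoglobin there);
* beta-carotene  — broad 440-490 nm band, negligible beyond ~540 nm;
* Lymphazurin (isosulfan blue) — rising flank of the ~640 nm band.

Values are stored as mu_a-per-concentration factors in cm^-1 uM^-1, i.e.
mu_a(lambda) [cm^-1] = epsilon(lambda) * C [uM] (the ln(10) decadic factor is
folded in). Magnitudes are of the right order for the real compounds, but the
tables are synthetic approximations, not digitizations of any measured data
set; the package's simulations and inversions are self-consistent against
whatever basis is loaded.
"""

from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

OUT = Path(__file__).resolve().parents[1] / "src" / "marginspec" / "data"

GRID = np.arange(440.0, 622.0, 2.0)

ANCHORS = {
    "hbo2": [
        (430, 0.60), (440, 0.25), (450, 0.145), (460, 0.095), (470, 0.070),
        (480, 0.058), (490, 0.052), (500, 0.048), (508, 0.046), (516, 0.050),
        (524, 0.058), (532, 0.080), (538, 0.105), (542, 0.122), (546, 0.115),
        (552, 0.092), (560, 0.075), (568, 0.090), (573, 0.110), (577, 0.125),
        (581, 0.100), (585, 0.060), (590, 0.030), (595, 0.015), (600, 0.0074),
        (610, 0.0040), (620, 0.0030), (630, 0.0025),
    ],
    "dhb": [
        (430, 1.20), (440, 0.40), (450, 0.144), (460, 0.075), (470, 0.060),
        (480, 0.052), (490, 0.048), (500, 0.047), (510, 0.048), (520, 0.052),
        (530, 0.060), (540, 0.080), (548, 0.105), (556, 0.123), (564, 0.115),
        (576, 0.085), (584, 0.062), (592, 0.045), (600, 0.034), (610, 0.025),
        (620, 0.020), (630, 0.016),
    ],
    "bcar": [
        (430, 0.24), (440, 0.30), (450, 0.322), (460, 0.330), (470, 0.300),
        (478, 0.310), (486, 0.260), (495, 0.170), (505, 0.090), (515, 0.040),
        (525, 0.015), (535, 0.005), (545, 0.001), (555, 0.0), (570, 0.0),
        (600, 0.0), (630, 0.0),
    ],
    "lymphazurin": [
        (430, 0.0015), (440, 0.002), (460, 0.003), (480, 0.005), (500, 0.008),
        (520, 0.014), (540, 0.025), (560, 0.045), (580, 0.085), (600, 0.160),
        (610, 0.200), (620, 0.230), (630, 0.255),
    ],
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, pts in ANCHORS.items():
        lam = np.array([p[0] for p in pts], dtype=float)
        eps = np.array([p[1] for p in pts], dtype=float)
        curve = np.clip(PchipInterpolator(lam, eps)(GRID), 0.0, None)
        path = OUT / f"{name}_extinction_synthetic.tsv"
        with path.open("w") as fh:
            fh.write("# synthetic extinction table (see data/README.md)\n")
            fh.write("# wavelength_nm\tepsilon_cm-1_uM-1\n")
            for w, e in zip(GRID, curve):
                fh.write(f"{w:.1f}\t{e:.6g}\n")
        print(f"wrote {path} ({len(GRID)} rows)")


if __name__ == "__main__":
    main()
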