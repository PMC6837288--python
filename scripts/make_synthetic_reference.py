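"""Regenerate the bundled synthetic Epas1 sampling-site table.

The original deposited sampling table (per-locality elevations and Epas1
allele frequencies for 266 mice at 23 western-US sites, 10 of which form
the Lincoln -> Mt. Evans transect) is not redistributable here, so the
package bundles a *synthetic* stand-in with the same structure, generated
once by this script from published summary facts: 23 localities spanning
~300-4350 m, 266 mice total, a sigmoid elevational cline centered at
1399.5 m, a high-altitude allele frequency of ~0.83 at the Mt. Evans
summit and a low frequency on the Great Plains.  Binomial sampling noise
uses a fixed seed; the generated file is bit-stable.

Run from the repository root:  python scripts/make_synthetic_reference.py
"""

from pathlib import Path

import numpy as np

from altipop.cline import ClineParams
from altipop.synthetic_data import gen_cline_dataset

SEED = 1008420
CENTER_M = 1399.5   # published cline center used as the generator's truth
WIDTH_M = 800.0     # plausible transect width; see docs/methods.md
PMIN, PMAX = 0.04, 0.86

# (locality, elevation m a.s.l., mice sampled, on transect)
SITES = [
    ("lincoln_ne",      430, 14, True),
    ("plains_low1",     600, 11, False),
    ("plains_mid1",     760, 12, True),
    ("plains_mid2",     950, 12, True),
    ("foothills_1",    1150, 12, True),
    ("foothills_2",    1300, 11, False),
    ("front_range_1",  1450, 12, True),
    ("front_range_2",  1600, 12, True),
    ("front_range_3",  1850, 11, False),
    ("montane_1",      2100, 12, True),
    ("montane_2",      2400, 11, False),
    ("montane_3",      2700, 12, True),
    ("subalpine_1",    3000, 11, False),
    ("subalpine_2",    3300, 12, True),
    ("alpine_1",       3700, 12, False),
    ("mt_evans_co",    4350, 12, True),
    ("great_basin_1",   800, 11, False),
    ("great_basin_2",  1250, 11, False),
    ("wasatch_1",      2000, 11, False),
    ("wasatch_2",      2600, 11, False),
    ("sierra_low",      320, 11, False),
    ("sierra_mid",     1500, 11, False),
    ("sierra_high",    3200, 11, False),
]


def main():
    assert sum(n for _, _, n, _ in SITES) == 266
    assert len(SITES) == 23
    params = ClineParams(center=CENTER_M, width=WIDTH_M, pmin=PMIN, pmax=PMAX)
    elev = np.array([s[1] for s in SITES], dtype=float)
    alleles = np.array([2 * s[2] for s in SITES])
    data = gen_cline_dataset(params, elev, alleles, seed=SEED)
    out = Path(__file__).resolve().parents[1] / "src/altipop/data"
    out.mkdir(parents=True, exist_ok=True)
    path = out / "epas1_cline_synthetic.tsv"
    with open(path, "w") as fh:
        fh.write("# SYNTHETIC stand-in for the deposited Epas1 sampling "
                 "table (regenerate with scripts/make_synthetic_reference.py)\n")
        fh.write(f"# seed={SEED} center={CENTER_M} width={WIDTH_M} "
                 f"pmin={PMIN} pmax={PMAX}\n")
        fh.write("locality\televation_m\tallele_H_count\ttotal_alleles\ttransect\n")
        for (name, e, n, transect), k in zip(SITES, data.k.astype(int)):
            fh.write(f"{name}\t{e}\t{k}\t{2 * n}\t{int(transect)}\n")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
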