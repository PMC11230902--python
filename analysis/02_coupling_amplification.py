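#!/usr/bin/env python
"""Statistical coupling predictions for measured pool enantiopurities.

Takes the enantiopurities a kinetic resolution actually delivers and asks
what the no-induction coupling step makes of them: the near-enantiopure
regime reached from a 96% + 99% e.e. pool pair, and the classic
symmetric-linker (homocoupling) amplification across pool e.e. levels.

Writes results/coupling_predictions.csv and results/horeau_homocoupling.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from stereokin import (
    EnantiomerPool,
    format_dr,
    format_ee_percent,
    horeau_homocoupling,
    statistical_coupling,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)

    pairs = [(0.6233, 0.6233), (0.83, 0.83), (0.96, 0.99), (0.99, 0.99)]
    rows = []
    for a, b in pairs:
        dist = statistical_coupling(
            EnantiomerPool.from_ee(a, 1.0, "intermediate"),
            EnantiomerPool.from_ee(-b, 1.0, "substrate"),
        )
        rows.append(
            {"ee_pool_1": a, "ee_pool_2": b, "ee_hetero": dist.hetero_ee, "dr": dist.dr}
        )
        print(
            f"pools {format_ee_percent(a)} + {format_ee_percent(b)} -> "
            f"heterochiral {format_ee_percent(dist.hetero_ee)}, d.r. {format_dr(dist.dr)}"
        )
    pd.DataFrame(rows).to_csv(OUT / "coupling_predictions.csv", index=False)

    homo = []
    for a in np.linspace(0.0, 1.0, 21):
        dist = horeau_homocoupling(EnantiomerPool.from_ee(a, 1.0))
        homo.append(
            {
                "ee_pool": a,
                "ee_homochiral_dimer": dist.homo_ee if a > 0 else 0.0,
                "meso_fraction": dist.hetero_total / dist.total,
            }
        )
    pd.DataFrame(homo).to_csv(OUT / "horeau_homocoupling.csv", index=False)
    print(f"\nwrote {OUT / 'coupling_predictions.csv'} and {OUT / 'horeau_homocoupling.csv'}")


if __name__ == "__main__":
    main()
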