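#!/usr/bin/env python
"""Sweep the closed-form Riccati release kernel over the published
(omega, r) parameter points, label each regime, and verify the
closed-form invariants.

Writes results/riccati_sweep.csv (tidy omega,r,t,re_z,im_z) and
results/riccati_invariants.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from mfrel import riccati

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    frames = []
    labels = []
    for omega, r in riccati.FIG_SWEEP_PAIRS:
        p = riccati.RiccatiParams(omega=omega, r=r)
        t = np.linspace(0.0, 8 * p.period, 2000)
        z = riccati.z_solution(p, t)
        series = riccati.RegimeSeries(t, z.real, z.imag, p)
        label = riccati.classify_regime(series)
        labels.append({"omega": omega, "r": r, "regime": label})
        # decimate the written table; classification used the dense grid
        sl = slice(None, None, 20)
        frames.append(
            pd.DataFrame(
                {"omega": omega, "r": r, "t": t[sl], "re_z": z.real[sl], "im_z": z.imag[sl]}
            )
        )
    pd.concat(frames).to_csv(OUT / "riccati_sweep.csv", index=False)

    report = riccati.run_invariant_suite()
    (OUT / "riccati_invariants.json").write_text(json.dumps(report, indent=2))

    print(pd.DataFrame(labels).to_string(index=False))
    print(
        "\nRegimes sharpen from near-harmonic oscillation toward spike "
        "trains as the modulation constant r grows; omega sets only the "
        "time scale (period pi/omega)."
    )
    print("\nInvariant suite (closed form vs numerical oracles):")
    for k, v in report.items():
        print(f"  {k}: {v:.3g}" if isinstance(v, float) else f"  {k}: {v}")


if __name__ == "__main__":
    main()
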