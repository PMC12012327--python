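#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes, under results/data/:
  - cumulative-labeling TSVs for a control-like population (T_C 76.6 h,
    T_S 13.5 h) and a slow knockout-like population (T_C 179 h, T_S
    16.7 h), 500 scored cells per timepoint at 3-24 h of label exposure;
  - 4 h pulse-chase count TSVs for both populations;
  - noisy FRAP and FLIP trace CSVs planted at the two DNA-bound
    fractions under study (73% and 33% immobile);
  - motif-annotated foreground/background peak BEDs with planted CTCF,
    SOX10 and E-box frequencies.

Every file gets a sidecar JSON logging the seed and parameters.
"""

import argparse
from pathlib import Path

import opcycle as oc
from opcycle import tables

CONDITIONS = {
    "control": dict(t_c=76.6, t_s=13.5, t_g2=1.8, t_m=3.0),
    "cko": dict(t_c=179.0, t_s=16.7, t_g2=3.0, t_m=3.0),
}
TIMES = [3, 6, 9, 12, 15, 18, 21, 24]
N_CELLS = 500


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    for name, c in CONDITIONS.items():
        t_g1 = c["t_c"] - c["t_s"] - c["t_g2"] - c["t_m"]
        phases = oc.PhaseDurations(t_g1=t_g1, t_s=c["t_s"], t_g2=c["t_g2"], t_m=c["t_m"])
        spec = oc.PopulationSpec.single(phases, 1.0)

        points = []
        for i, t in enumerate(TIMES):  # one independent litter per timepoint
            cohort = oc.simulate_cohort(
                spec, N_CELLS, oc.child_seed(args.seed, f"{name}-lab{i}")
            )
            points.extend(oc.run_cumulative_edu(cohort, spec, [t]))
        lab_path = args.outdir / f"labeling_{name}.tsv"
        tables.write_labeling_tsv(lab_path, points)
        tables.write_sidecar(lab_path, args.seed, {**c, "n_cells": N_CELLS, "times": TIMES})

        cohort = oc.simulate_cohort(spec, 10_000, oc.child_seed(args.seed, f"{name}-pc"))
        obs = oc.run_pulse_chase(cohort, spec, t_chase=4)
        pc_path = args.outdir / f"pulsechase_{name}.tsv"
        tables.write_pulse_chase_tsv(pc_path, [obs])
        tables.write_sidecar(pc_path, args.seed, {**c, "t_chase": 4, "n_cells": 10_000})
        print(f"{name}: labeling L.I. {points[0].li:.3f}..{points[-1].li:.3f}, "
              f"pulse-chase f_ph3 = {obs.f_ph3:.3f}")

    for name, immobile in [("control", 0.73), ("cko", 0.33)]:
        params = oc.FrapSimParams(mobile_fraction=1 - immobile, rate_k=0.1, noise_sd=0.01)
        frap_path = args.outdir / f"frap_{name}.csv"
        tables.write_trace_csv(frap_path, oc.generate_frap_trace(params, oc.child_seed(args.seed, f"fr-{name}")))
        tables.write_sidecar(frap_path, args.seed, params.__dict__)
        flip_path = args.outdir / f"flip_{name}.csv"
        tables.write_trace_csv(flip_path, oc.generate_flip_trace(params, oc.child_seed(args.seed, f"fl-{name}")))
        tables.write_sidecar(flip_path, args.seed, params.__dict__)

    peaks = oc.PeakUniverseParams(n_foreground=2000, n_background=8000)
    fg, bg = oc.generate_peak_universe(peaks, oc.child_seed(args.seed, "peaks"))
    tables.write_peaks_bed(args.outdir / "peaks_down.bed", fg)
    tables.write_peaks_bed(args.outdir / "peaks_other.bed", bg)
    tables.write_sidecar(args.outdir / "peaks_down.bed", args.seed,
                         {"n_foreground": peaks.n_foreground, "n_background": peaks.n_background})
    print(f"peaks: {len(fg)} down-regulated foreground, {len(bg)} background")
    print(f"all inputs written to {args.outdir}")


if __name__ == "__main__":
    main()
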