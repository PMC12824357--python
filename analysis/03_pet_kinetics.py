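#!/usr/bin/env python
"""Reference-tissue kinetic modeling on a simulated PET cohort.

For each subject in the simulated study, generate placebo and
methylphenidate raclopride time-activity curves from the SRTM forward
model (cerebellum-like gamma-variate reference; planted 10-20% D2R BPnd
reductions under MP, matching the dopamine-competition regime), then fit
both models per scan: SRTM (basis-function) for BPnd and the Logan
reference model for DVR, and derive the dopamine increase
delta_DA = BPnd(PL) - BPnd(MP).

Verifies DVR = BPnd + 1 on every fit and writes
results/pet_kinetics.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hiergrad import pet_kinetics as pk
from hiergrad.synthetic import synth_ref_tac

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20250929
N_SUBJECTS = 38


def main() -> None:
    rng = np.random.default_rng(SEED)
    ref = synth_ref_tac(seed=SEED)
    basis = pk.SRTMBasis(ref)
    k2_ref = 0.3  # simulated reference clearance, known here by design

    rows = []
    for s in range(N_SUBJECTS):
        bp_pl = float(rng.uniform(2.0, 3.2))
        reduction = float(rng.uniform(0.10, 0.20))
        bp_mp = bp_pl * (1 - reduction)
        row = {"subject_id": f"sub{s:03d}", "bp_pl_true": bp_pl,
               "bp_mp_true": bp_mp}
        for cond, bp in (("pl", bp_pl), ("mp", bp_mp)):
            target = pk.simulate_srtm_tac(ref, r1=1.0, k2=k2_ref, bpnd=bp)
            noisy = pk.TAC(target.frame_mid_times, target.frame_durations,
                           target.activity *
                           (1 + 0.03 * rng.standard_normal(22)))
            srtm = pk.fit_srtm(noisy, basis=basis)
            logan = pk.logan_dvr(noisy, ref, t_star=20.0, k2_ref=k2_ref)
            row[f"bpnd_{cond}"] = srtm.bpnd
            row[f"dvr_{cond}"] = logan.dvr
        row["delta_da"] = pk.dopamine_increase(row["bpnd_pl"], row["bpnd_mp"])
        row["delta_da_pct"] = pk.dopamine_increase(
            row["bpnd_pl"], row["bpnd_mp"], percent=True)
        rows.append(row)

    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "pet_kinetics.tsv", sep="\t", index=False,
              float_format="%.6g")

    dvr_minus_bp = np.concatenate([
        df["dvr_pl"] - df["bpnd_pl"], df["dvr_mp"] - df["bpnd_mp"],
    ])
    err_pl = (df["bpnd_pl"] - df["bp_pl_true"]).abs() / df["bp_pl_true"]
    print(f"fitted {len(df)} subjects x 2 conditions "
          f"(3% frame noise, t* = 20 min)")
    print(f"BPnd(PL) recovery: median |error| {100 * err_pl.median():.1f}%")
    print(f"DVR - BPnd: mean {dvr_minus_bp.mean():.3f} "
          f"(sd {dvr_minus_bp.std():.3f}; reference-tissue identity: 1.0)")
    print(f"dopamine increase: mean {df['delta_da'].mean():.3f} BPnd units "
          f"= {df['delta_da_pct'].mean():.1f}% "
          f"(planted 10-20% reductions)")


if __name__ == "__main__":
    main()
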