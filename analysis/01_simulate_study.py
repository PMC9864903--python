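#!/usr/bin/env python
"""Generate the synthetic study inputs every later stage consumes.

Emulates the four experimental designs: the 8-time-point rat
biodistribution (2 animals/time, plus a blocked arm at 20 min), the
subcutaneous plasma profile with below-LOD censoring, triplicate
saturation-binding assays, and a cell-pellet autoradiogram with baseline
and blocked pellets.  Writes CSV/JSON under results/simulated/ together
with the generators' truth records.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from gipet import io, reference, simulate


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/simulated"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)
    ga68 = reference.load_nuclide("ga68")

    # rat biodistribution, baseline + blocked arm (no displacement in vivo)
    ds, truth = simulate.simulate_biodistribution(
        simulate.BiodistConfig(noise_cv=0.10), ga68, seed=args.seed,
        blocked_arm=True, blocked_factor=1.0)
    io.write_time_activity_table(ds, out / "biodist_samples.csv",
                                 out / "biodist_injections.csv")
    with open(out / "biodist_truth.json", "w") as fh:
        json.dump({"suv_a_integral_h": truth.suv_a_integral_h}, fh, indent=2)
    print(f"biodistribution: {len(ds.samples)} samples, "
          f"{len(ds.injections)} animals -> {out}/biodist_*.csv")

    # plasma PK
    profile, pk_truth = simulate.simulate_plasma_pk(
        simulate.PKSimConfig(noise_cv=0.0), seed=args.seed)
    pd.DataFrame({
        "time_min": profile.times_min,
        "conc_ng_per_mL": profile.conc_ng_per_ml,
        "censored": profile.censored.astype(int),
    }).to_csv(out / "plasma.csv", index=False)
    with open(out / "plasma_truth.json", "w") as fh:
        json.dump(vars(pk_truth), fh, indent=2)
    n_cens = int(profile.censored.sum())
    print(f"plasma profile: {profile.times_min.size} samples, "
          f"{n_cens} below LOD (assigned zero)")

    # saturation assay
    sat, sat_truth = simulate.simulate_saturation_assay(
        simulate.AssaySimConfig(noise_cv=0.10), seed=args.seed)
    rows = []
    for i, c in enumerate(sat.concentrations_nm):
        for r in range(sat.total_bound.shape[1]):
            rows.append({"conc_nM": c, "replicate": r + 1,
                         "total": sat.total_bound[i, r],
                         "nonspecific": sat.nonspecific_bound[i, r]})
    pd.DataFrame(rows).to_csv(out / "saturation.csv", index=False)
    with open(out / "saturation_truth.json", "w") as fh:
        json.dump({k: v for k, v in sat_truth.items() if np.isscalar(v)},
                  fh, indent=2)
    print(f"saturation assay: {len(rows)} wells over "
          f"{sat.concentrations_nm.size} concentrations")

    # autoradiogram: baseline pellet vs strongly blocked pellet
    img, arg_truth = simulate.simulate_autoradiogram(
        {"baseline": 3.0, "blocked": 0.24}, seed=args.seed)
    np.savetxt(out / "autoradiogram_counts.csv", img.counts,
               delimiter=",", fmt="%.1f")
    roi_ids = np.zeros(img.counts.shape, dtype=int)
    roi_names = {}
    for k, (name, mask) in enumerate(img.rois.items(), start=1):
        roi_ids[mask] = k
        roi_names[str(k)] = name
    np.savetxt(out / "autoradiogram_rois.csv", roi_ids, delimiter=",", fmt="%d")
    with open(out / "autoradiogram_meta.json", "w") as fh:
        json.dump({"roi_labels": roi_names,
                   "pixel_size_mm": img.pixel_size_mm,
                   "reference_activity_bq": img.reference_activity_bq,
                   "molar_activity_bq_per_fmol": img.molar_activity_bq_per_fmol,
                   "truth": arg_truth}, fh, indent=2)
    print(f"autoradiogram: {img.counts.shape} grid, ROIs {list(img.rois)}")


if __name__ == "__main__":
    main()
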