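"""MIRD dosimetry from denoised reduced-count scans.

Quantifies the torso phantom's organ activities at 24/96/168 h by
conjugate view on denoised 30%-count anterior/posterior pairs, checks
the noise-free slab-recovery of the quantification chain (within 5% for
5-20 cm water), integrates the estimated time-activity curves to
cumulated activities, and folds them with the toy S matrix into absorbed
doses.  Writes results/dosimetry/.
"""

import sys
from pathlib import Path

from lu177planar import io as lio
from lu177planar.experiments import slab_recovery
from lu177planar.pipeline import torso_dosimetry

MODEL = Path("results/model/desk_model.npz")
OUT = Path("results/dosimetry")


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    slab = slab_recovery()
    slab.to_csv(OUT / "slab_recovery.csv", index=False)
    print("conjugate-view slab recovery (noise-free):")
    print(slab.round(4).to_string(index=False))

    model = lio.load_model(MODEL)
    dose_df, act_df = torso_dosimetry(model, seed=seed)
    act_df.to_csv(OUT / "organ_activities.csv", index=False)
    dose_df.to_csv(OUT / "dose_report.csv", index=False)
    print("\norgan activities from denoised 30%-count scans:")
    print(act_df.round(3).to_string(index=False))
    print("\nabsorbed doses (toy S matrix):")
    print(dose_df.round(4).to_string(index=False))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
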