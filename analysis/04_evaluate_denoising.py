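"""Evaluate the trained denoiser on held-out scenes.

Denoises held-out reduced-count images at 10-90% count fractions and
reports RMSE / PSNR / SSIM of the outputs against the full-count
references, next to the scale-corrected inputs.  The headline numbers:
mean PSNR improvement at 30% counts and the monotone decrease of output
RMSE with count fraction.
"""

import sys
from pathlib import Path

import pandas as pd

from lu177planar import io as lio
from lu177planar.experiments import heldout_evaluation

MODEL = Path("results/model/desk_model.npz")
OUT = Path("results/evaluation")


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    model = lio.load_model(MODEL)
    ev = heldout_evaluation(model, seed=seed + 1000)
    ev.to_csv(OUT / "heldout_metrics.csv", index=False)
    g = ev.groupby("fraction")[["psnr_in", "psnr_out", "rmse_in",
                                "rmse_out", "ssim_out"]].mean().round(3)
    print(g.to_string())
    gain30 = (ev[ev.fraction == 0.3].psnr_out
              - ev[ev.fraction == 0.3].psnr_in).mean()
    rmse_by_f = g["rmse_out"]
    print(f"\nmean PSNR gain at 30% counts: {gain30:.2f} dB")
    print("output RMSE monotonically non-increasing with fraction:",
          bool(rmse_by_f.is_monotonic_decreasing))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
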