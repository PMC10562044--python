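"""Train the desk-scale denoiser on the synthetic corpus.

30 slice-duplication scenes (96x96) from the two training phantom
families are simulated, thinned to 10-90% counts, cut into 25x25 patch
pairs (scale-corrected input vs full-count label) and used for 2000 Adam
iterations of the reduced dense-skip-connection network.  Writes the
model checkpoint and loss history under results/model/.
"""

import sys
import time
from pathlib import Path

import pandas as pd

from lu177planar import io as lio
from lu177planar.experiments import train_desk_model

OUT = Path("results/model")


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    model, history, dataset = train_desk_model(seed=seed)
    minutes = (time.time() - t0) / 60.0
    lio.save_model(OUT / "desk_model.npz", model)
    pd.DataFrame({"iteration": range(len(history)),
                  "rmse_loss": history}).to_csv(OUT / "loss_history.csv",
                                                index=False)
    print(f"trained on {len(dataset)} patch pairs in {minutes:.1f} min")
    print(f"normalization constant: {model.normalization_constant:.1f} "
          "counts")
    print("loss (normalized RMSE): "
          f"iter 1 {history[0]:.4f} -> iter 2000 {history[-1]:.4f}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
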