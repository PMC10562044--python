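"""Whole-image fidelity metrics: RMSE, PSNR and global SSIM.

All three metrics are computed over the whole image.  The SSIM here is the
*global* form -- one similarity value from whole-image means, standard
deviations and covariance -- rather than the more common windowed mean-SSIM;
a windowed variant (scikit-image) is available behind a flag for
cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class MetricTriple:
    rmse: float
    psnr: float
    ssim: float


def _as_pair(ref, test) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    return ref, test


def rmse(ref, test) -> float:
    """Root-mean-square error over all pixels, in count units."""
    ref, test = _as_pair(ref, test)
    return float(np.sqrt(np.mean((ref - test) ** 2)))


def psnr(ref, test, i_max: float | None = None) -> float:
    """Peak signal-to-noise ratio, dB: ``20 log10(I_max / RMSE)``.

    ``i_max`` defaults to the maximum of the reference image.  Identical
    images have zero RMSE; ``math.inf`` is returned as the defined sentinel.
    """
    ref, test = _as_pair(ref, test)
    if i_max is None:
        i_max = float(ref.max())
    if i_max <= 0:
        raise ValueError("i_max must be positive")
    r = rmse(ref, test)
    if r == 0.0:
        return math.inf
    return float(20.0 * np.log10(i_max / r))


def ssim_global(ref, test, c1: float | None = None, c2: float | None = None,
                windowed: bool = False) -> float:
    """Structural similarity from whole-image statistics.

    ``SSIM = (2 mu_x mu_y + C1)(2 s_xy + C2) /
    ((mu_x^2 + mu_y^2 + C1)(s_x^2 + s_y^2 + C2))`` with sample (n-1)
    moments.  ``C1``/``C2`` default to ``(0.01 L)^2`` and ``(0.03 L)^2``
    with ``L = max(ref)``.  With ``windowed=True`` the scikit-image
    sliding-window mean SSIM is returned instead (cross-check variant).
    """
    ref, test = _as_pair(ref, test)
    L = float(ref.max())
    if c1 is None:
        c1 = (0.01 * L) ** 2
    if c2 is None:
        c2 = (0.03 * L) ** 2
    if windowed:
        from skimage.metrics import structural_similarity
        return float(structural_similarity(
            ref, test, data_range=L if L > 0 else 1.0))
    mx, my = ref.mean(), test.mean()
    n = ref.size
    ddof = 1 if n > 1 else 0
    vx = ref.var(ddof=ddof)
    vy = test.var(ddof=ddof)
    cov = float(((ref - mx) * (test - my)).sum() / max(n - 1, 1))
    num = (2.0 * mx * my + c1) * (2.0 * cov + c2)
    den = (mx**2 + my**2 + c1) * (vx + vy + c2)
    if den == 0.0:
        return 1.0  # both images constant and zero: identical by convention
    return float(num / den)


def metric_triple(ref, test, i_max: float | None = None) -> MetricTriple:
    return MetricTriple(rmse(ref, test), psnr(ref, test, i_max),
                        ssim_global(ref, test))


def metric_report(ref, tests: Mapping[float, np.ndarray] |
                  Sequence[tuple[float, np.ndarray]],
                  image_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """One row of (RMSE, PSNR, SSIM) per test image, ordered by fraction.

    ``tests`` maps retained count fraction -> image (or is a sequence of
    ``(fraction, image)`` pairs).
    """
    items = list(tests.items()) if isinstance(tests, Mapping) else list(tests)
    items.sort(key=lambda kv: kv[0])
    if image_ids is None:
        image_ids = [f"img_{f:g}" for f, _ in items]
    rows = []
    for (f, img), iid in zip(items, image_ids):
        t = metric_triple(ref, img)
        rows.append({"image_id": iid, "fraction": f, "rmse": t.rmse,
                     "psnr_db": t.psnr, "ssim": t.ssim})
    return pd.DataFrame(rows)
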