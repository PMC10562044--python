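"""Desk-scale study conditions: corpus building, training, evaluation.

The emulated study runs at GPU scale (300 scenes of 256x256, a 69-layer
network, 1e5 iterations).  The functions here express the same design at
a size a single CPU handles in minutes: 96x96 training scenes from the
two training phantom families, the reduced network profile
(:data:`lu177planar.denoiser.DESK_SPEC`), 2000 Adam iterations, and
evaluation on the hot-rod and torso phantoms at their physical scale.
Problem sizes are the package's reduced-scale defaults; every constant of
the imaging chain (pixel size, sensitivity, scan time, resolution) stays
at its full value.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import metrics
from .denoiser import (DESK_SPEC, Denoiser, PatchDataset, TrainConfig,
                       build_model, denoise_image, extract_patches, train)
from .dosimetry import ConjugateViewMeasurement, conjugate_view_activity, \
    self_attenuation_factor
from .phantoms import (MU_WATER_208KEV, RodSpec, TrainingCorpusSpec,
                       VoxelPhantom, default_tac, make_anthropomorphic,
                       make_brain_like, make_derenzo, make_shepp_logan,
                       total_activity)
from .projector import (CountImage, ScannerModel, project_expected,
                        sample_counts, simulate_scan, thin_counts)
from .roistats import (embed_mask, organ_rois, percent_difference,
                       project_labels, rod_rois, significance_table)

#: count fractions exercised throughout the reduced-scale experiments
DESK_FRACTIONS = (0.1, 0.3, 0.5, 0.7, 0.9)

#: desk corpus: 15 axial slices per family x 2 families = 30 scenes,
#: 96x96 in-plane, 24 duplicated slices deep.  Per-scene activities are
#: spaced over ranges that preserve the wide brightness span of the
#: full-scale corpus families (factors of ~10x and ~16x), putting
#: full-count foreground levels at ~10-160 counts/pixel so that both the
#: dim late-time-point organs and the bright rods fall inside the
#: training intensity distribution.
DESK_CORPUS = TrainingCorpusSpec(n_slices=15, n_duplicates=24, matrix=96,
                                 activity_range_a=(4.5, 45.0),
                                 activity_range_b=(3.0, 50.0))


def desk_scanner(matrix: tuple[int, int] = (96, 96)) -> ScannerModel:
    """Scanner with full acquisition constants on a reduced matrix."""
    return ScannerModel(matrix=matrix)


def make_desk_scenes(seed: int = 0,
                     spec: TrainingCorpusSpec = DESK_CORPUS
                     ) -> list[VoxelPhantom]:
    """The reduced training corpus: slice-duplication scenes of the
    Shepp-Logan phantom and the brain-like surrogate."""
    small = (spec.matrix, spec.matrix, 64)
    bases = (make_shepp_logan(small), make_brain_like(small, seed=seed))
    from .phantoms import make_training_corpus
    return list(make_training_corpus(spec, seed=seed, bases=bases))


def simulate_training_pairs(scenes: list[VoxelPhantom],
                            scanner: ScannerModel,
                            fractions: tuple[float, ...] = DESK_FRACTIONS,
                            seed: int = 0) -> PatchDataset:
    """Simulate each scene, thin it, and cut scale-corrected patch pairs.

    Inputs are thinned counts divided by their fraction (full-count
    intensity scale); labels are the full-count realization.  One random
    grid offset per (scene, fraction) image.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    parts = []
    for i, scene in enumerate(scenes):
        series = simulate_scan(scene, scanner, fractions, seed=seed * 100003
                               + i, views=("anterior",))["anterior"]
        full = series[1.0].counts.astype(np.float32)
        for f in fractions:
            inp = series[f].counts.astype(np.float32) / f
            part = extract_patches(inp, full, rng=rng,
                                   image_id=f"{scene.name}:{f:g}")
            if len(part):
                parts.append(part)
    return PatchDataset.concatenate(parts)


def train_desk_model(seed: int = 0, scenes: list[VoxelPhantom] | None = None,
                     iterations: int = 2000,
                     fractions: tuple[float, ...] = DESK_FRACTIONS,
                     ) -> tuple[Denoiser, list[float], PatchDataset]:
    """Train the reduced-profile denoiser on the desk corpus."""
    scanner = desk_scanner()
    scenes = scenes or make_desk_scenes(seed=seed)
    dataset = simulate_training_pairs(scenes, scanner, fractions, seed=seed)
    model = build_model(DESK_SPEC, seed=seed)
    cfg = TrainConfig(iterations=iterations, seed=seed)
    model, history = train(model, dataset, cfg)
    return model, history, dataset


def heldout_evaluation(model: Denoiser, seed: int = 1000,
                       n_scenes: int = 20,
                       fractions: tuple[float, ...] = DESK_FRACTIONS
                       ) -> pd.DataFrame:
    """Denoise held-out scenes; PSNR/RMSE of outputs and of the
    scale-corrected inputs against the full-count reference.

    The held-out scenes come from the same two phantom families with a
    different generator seed and slice set.
    """
    spec = replace(DESK_CORPUS, n_slices=(n_scenes + 1) // 2)
    scanner = desk_scanner()
    scenes = make_desk_scenes(seed=seed, spec=spec)[:n_scenes]
    rows = []
    for i, scene in enumerate(scenes):
        series = simulate_scan(scene, scanner, fractions,
                               seed=seed * 99991 + i,
                               views=("anterior",))["anterior"]
        ref = series[1.0].counts.astype(float)
        for f in fractions:
            inp_scaled = series[f].counts.astype(float) / f
            out = denoise_image(model, series[f])
            rows.append({
                "scene": scene.name, "fraction": f,
                "psnr_in": metrics.psnr(ref, inp_scaled),
                "psnr_out": metrics.psnr(ref, out),
                "rmse_in": metrics.rmse(ref, inp_scaled),
                "rmse_out": metrics.rmse(ref, out),
                "ssim_out": metrics.ssim_global(ref, out),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hot-rod phantom evaluation
# ---------------------------------------------------------------------------

def derenzo_experiment(model: Denoiser, tbr: float = 5.0, seed: int = 0,
                       fractions: tuple[float, ...] = DESK_FRACTIONS,
                       alpha: float = 0.01):
    """Simulate, thin and denoise the hot-rod phantom; significance table.

    Returns ``(table, rois, series, outputs)``: the per-ROI table compares
    every reduced-count input and every denoised output against the
    full-count reference, mirroring the tabular analysis of the emulated
    study.
    """
    spec = RodSpec(tbr=tbr)
    phantom, labels = make_derenzo(spec)
    scanner = desk_scanner(matrix=(160, 160))
    series = simulate_scan(phantom, scanner, fractions, seed=seed,
                           views=("anterior",))["anterior"]
    full = series[1.0]
    proj = project_labels(labels, voxel_dy=phantom.voxel_size[1])
    proj = {name: embed_mask(m > 0, scanner.matrix).astype(float)
            for name, m in proj.items()}
    rois = rod_rois(full.counts, proj)
    tests: dict[str, np.ndarray] = {}
    outputs: dict[float, np.ndarray] = {}
    for f in fractions:
        tests[f"input_{int(round(f * 100))}"] = series[f].counts
    for f in fractions:
        out = denoise_image(model, series[f])
        outputs[f] = out
        tests[f"output_{int(round(f * 100))}"] = out
    table = significance_table(full.counts, tests, rois, alpha=alpha)
    return table, rois, series, outputs


# ---------------------------------------------------------------------------
# torso phantom evaluation over time points
# ---------------------------------------------------------------------------

#: retention scaling of the three imaging time points relative to the first
TIMEPOINT_FRACTIONS = {24.0: 1.0, 96.0: 0.6, 168.0: 0.4}


def torso_experiment(model: Denoiser, seed: int = 0,
                     fractions: tuple[float, ...] = DESK_FRACTIONS,
                     alpha: float = 0.01, injected_activity: float = 700.0):
    """Torso phantom at 24/96/168 h; one significance table per time point.

    Later time points are *thinned* versions of the 24 h acquisition
    (retention scaling 0.6 and 0.4), the same reuse the emulated study's
    tables exhibit; each time point then gets its own nested
    reduced-count series and denoised outputs.
    """
    tac = default_tac(injected_activity)
    phantom, labels = make_anthropomorphic(tac=tac, time_h=24.0)
    scanner = desk_scanner(matrix=(176, 176))
    rois = _torso_rois(labels, phantom, scanner)
    base = simulate_scan(phantom, scanner, (), seed=seed,
                         views=("anterior",))["anterior"][1.0]
    tables: dict[float, pd.DataFrame] = {}
    ss = np.random.SeedSequence(seed + 7).spawn(len(TIMEPOINT_FRACTIONS))
    for (time_h, ret), stream in zip(TIMEPOINT_FRACTIONS.items(), ss):
        rngs = stream.spawn(len(fractions))
        if ret == 1.0:
            tp_full = base
        else:
            tp_full = thin_counts(base, ret,
                                  np.random.default_rng(stream))
        # rebook this time point's acquisition as its own full-count scan
        tp_full = CountImage(tp_full.counts, tp_full.view,
                             tp_full.pixel_size, tp_full.duration,
                             fraction=1.0)
        tests: dict[str, np.ndarray] = {}
        prev = tp_full
        for f, frng in zip(sorted(fractions, reverse=True), rngs):
            prev = thin_counts(prev, f, np.random.default_rng(frng))
            tests[f"input_{int(round(f * 100))}"] = prev.counts
            tests[f"output_{int(round(f * 100))}"] = denoise_image(model,
                                                                   prev)
        tables[time_h] = significance_table(tp_full.counts, tests, rois,
                                            alpha=alpha)
    return tables, rois, phantom, labels


def _torso_rois(labels, phantom, scanner):
    rois = organ_rois(labels, voxel_dy=phantom.voxel_size[1])
    embedded = []
    for roi in rois:
        roi.mask = embed_mask(roi.mask, scanner.matrix)
        embedded.append(roi)
    return embedded


# ---------------------------------------------------------------------------
# conjugate-view activity recovery on uniform slabs
# ---------------------------------------------------------------------------

def slab_recovery(thicknesses_cm=(5.0, 10.0, 15.0, 20.0),
                  activity_mbq: float = 10.0,
                  lateral_px: int = 48) -> pd.DataFrame:
    """Noise-free conjugate-view quantification of a uniform water slab.

    A slab of known activity and thickness is projected anterior and
    posterior without noise; the conjugate-view estimate with
    ``T = exp(-mu d)``, the slab self-attenuation factor and the system
    calibration factor is compared to the truth.
    """
    scanner = desk_scanner(matrix=(lateral_px + 16, lateral_px + 16))
    rows = []
    for d_cm in thicknesses_cm:
        d_mm = 10.0 * d_cm
        ny = max(8, int(round(d_mm / 2.2)))
        dy = d_mm / ny
        act = np.zeros((lateral_px, ny, lateral_px))
        act[8:-8, :, 8:-8] = activity_mbq / ((lateral_px - 16) ** 2 * ny)
        atten = np.zeros_like(act)
        atten[8:-8, :, 8:-8] = MU_WATER_208KEV
        slab = VoxelPhantom(act, atten, (2.2, dy, 2.2), f"slab_{d_cm:g}cm")
        ia = project_expected(slab, scanner, "anterior").total \
            / scanner.scan_time
        ip = project_expected(slab, scanner, "posterior").total \
            / scanner.scan_time
        t_factor = float(np.exp(-MU_WATER_208KEV * d_mm))
        f_corr = self_attenuation_factor(MU_WATER_208KEV, d_mm)
        c_cal = scanner.sensitivity / 1e6  # counts/s per Bq
        m = ConjugateViewMeasurement(ia, ip, t_factor, c_cal, f_corr)
        rec_mbq = conjugate_view_activity(m) / 1e6
        rows.append({"thickness_cm": d_cm, "true_mbq": activity_mbq,
                     "recovered_mbq": rec_mbq,
                     "error_pct": 100.0 * abs(rec_mbq - activity_mbq)
                     / activity_mbq})
    return pd.DataFrame(rows)
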