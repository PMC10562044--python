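"""End-to-end pipeline: simulate -> thin -> train -> denoise -> evaluate.

``run_experiment`` executes the whole desk-scale study from one
configuration and writes every artifact (metric report, significance
tables, percent-difference summary, dosimetry report, model checkpoint)
plus a manifest with the configuration, seeds, package versions and a
SHA-256 of each output, so a rerun with the same configuration can be
checked for bit-identity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import experiments as ex
from .denoiser import Denoiser
from .dosimetry import (ConjugateViewMeasurement, SMatrix,
                        conjugate_view_activity, cumulated_activity_set,
                        absorbed_dose, self_attenuation_factor)
from .phantoms import (MU_WATER_208KEV, TimeActivityCurve,
                       default_tac, make_anthropomorphic)
from .projector import project_expected, simulate_scan, thin_counts, \
    CountImage
from .roistats import organ_rois, embed_mask, percent_difference
from . import io as lio

log = logging.getLogger("lu177planar")

#: toy S matrix (Gy per MBq*s) for the four source organs; magnitudes are
#: illustrative of kidney-dominant Lu-177 dosimetry, for exercising the
#: dose arithmetic only -- not published S values.
TOY_S_MATRIX = SMatrix(
    values=np.array([
        # sources: liver, spleen, right_kidney, left_kidney
        [1.2e-9, 2.0e-11, 4.0e-11, 2.0e-11],   # target liver
        [2.0e-11, 6.0e-9, 3.0e-11, 8.0e-11],   # target spleen
        [4.0e-11, 3.0e-11, 1.8e-8, 6.0e-11],   # target right kidney
        [2.0e-11, 8.0e-11, 6.0e-11, 1.8e-8],   # target left kidney
    ]),
    targets=["liver", "spleen", "right_kidney", "left_kidney"],
    sources=["liver", "spleen", "right_kidney", "left_kidney"],
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    fractions: tuple[float, ...] = ex.DESK_FRACTIONS
    iterations: int = 2000
    n_heldout: int = 20
    tbrs: tuple[float, ...] = (5.0, 20.0)
    injected_activity: float = 700.0
    alpha: float = 0.01
    dosimetry_fraction: float = 0.3
    out_dir: str = "results/run"

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = RunConfig(**raw)
        if any(not (0.0 < f <= 1.0) for f in cfg.fractions):
            raise ValueError("fractions must lie in (0, 1]")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fractions"] = list(self.fractions)
        d["tbrs"] = list(self.tbrs)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_experiment(config: RunConfig,
                   model: Denoiser | None = None) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}

    def stage(name):
        t0 = time.time()
        log.info("stage %s started", name)
        return lambda: stages.__setitem__(name, round(time.time() - t0, 2))

    try:
        done = stage("train")
        if model is None:
            model, history, dataset = ex.train_desk_model(
                seed=config.seed, iterations=config.iterations,
                fractions=config.fractions)
            pd.DataFrame({"iteration": np.arange(len(history)),
                          "rmse_loss": history}).to_csv(
                out / "loss_history.csv", index=False)
            lio.save_model(out / "model.npz", model)
        done()

        done = stage("heldout_metrics")
        ev = ex.heldout_evaluation(model, seed=config.seed + 1000,
                                   n_scenes=config.n_heldout,
                                   fractions=config.fractions)
        ev.to_csv(out / "heldout_metrics.csv", index=False)
        done()

        done = stage("derenzo")
        pct_rows = []
        for tbr in config.tbrs:
            table, rois, series, outputs = ex.derenzo_experiment(
                model, tbr=tbr, seed=config.seed,
                fractions=config.fractions, alpha=config.alpha)
            table.to_csv(out / f"derenzo_tbr{tbr:g}.csv", index=False)
            ref_rows = table[table.image_id == "reference"]
            for _, r in table[table.image_id != "reference"].iterrows():
                ref_mean = float(ref_rows[ref_rows.roi == r.roi]["mean"]
                                 .iloc[0])
                pct_rows.append({
                    "phantom": f"derenzo_tbr{tbr:g}", "roi": r.roi,
                    "image_id": r.image_id,
                    "percent_difference":
                        percent_difference(ref_mean, r["mean"])})
        pd.DataFrame(pct_rows).to_csv(out / "percent_differences.csv",
                                      index=False)
        done()

        done = stage("torso")
        tables, rois, phantom, labels = ex.torso_experiment(
            model, seed=config.seed, fractions=config.fractions,
            alpha=config.alpha, injected_activity=config.injected_activity)
        for time_h, table in tables.items():
            table.to_csv(out / f"torso_{time_h:g}h.csv", index=False)
        done()

        done = stage("dosimetry")
        dose_df, act_df = torso_dosimetry(
            model, seed=config.seed, fraction=config.dosimetry_fraction,
            injected_activity=config.injected_activity)
        act_df.to_csv(out / "organ_activities.csv", index=False)
        dose_df.to_csv(out / "dose_report.csv", index=False)
        done()
    except Exception as err:  # tag the failing stage for the caller
        raise RuntimeError(f"pipeline stage {len(stages)} failed: "
                           f"{err}") from err

    manifest = {
        "config": config.to_dict(),
        "stage_seconds": stages,
        "versions": _versions(),
        "outputs": {p.name: _sha256(p) for p in sorted(out.iterdir())
                    if p.is_file() and p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _versions() -> dict:
    import numpy, scipy, pandas, skimage
    from . import __version__
    return {"lu177planar": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "pandas": pandas.__version__,
            "scikit-image": skimage.__version__}


# ---------------------------------------------------------------------------
# conjugate-view dosimetry over the torso time series
# ---------------------------------------------------------------------------

def torso_dosimetry(model: Denoiser, seed: int = 0, fraction: float = 0.3,
                    injected_activity: float = 700.0,
                    s_matrix: SMatrix = TOY_S_MATRIX
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Organ activities by conjugate view on denoised reduced-count scans.

    For each time point (retention-scaled replays of the first scan), the
    reduced-count anterior/posterior pair is denoised and each organ's
    activity estimated with the conjugate-view formula: ``T`` from the
    body thickness along the organ's line of sight, ``f`` from the organ
    thickness, and an ROI recovery coefficient (fraction of the organ's
    expected counts inside its ROI, computed from a noise-free projection
    of that organ alone) correcting for counts outside the ROI.  The
    estimated time-activity curves are integrated to cumulated activities
    and folded with the S matrix into absorbed doses, next to the same
    computation on the true curves.
    """
    tac = default_tac(injected_activity)
    phantom, labels = make_anthropomorphic(tac=tac, time_h=24.0)
    scanner = ex.desk_scanner(matrix=(176, 176))
    dy = phantom.voxel_size[1]
    views = ("anterior", "posterior")
    series = simulate_scan(phantom, scanner, (), seed=seed, views=views)
    rois = {v: {r.name: _embed(r, scanner) for r in
                organ_rois(labels, voxel_dy=dy, view=v)} for v in views}

    # per-organ geometry factors and recovery coefficients
    geo = {}
    c_cal = scanner.sensitivity / 1e6  # counts/s per Bq
    for k, organ in labels.organ_names.items():
        organ_mask = labels.labels == k
        thick = organ_mask.sum(axis=1) * dy
        body_thick = (phantom.attenuation > 0).sum(axis=1) * dy
        footprint = thick > 0
        t_factor = float(np.exp(-MU_WATER_208KEV
                                * body_thick[footprint].mean()))
        f_corr = self_attenuation_factor(MU_WATER_208KEV,
                                         float(thick[footprint].mean()))
        rec = {}
        solo = phantom.activity * organ_mask
        solo_ph = dataclasses.replace(phantom, activity=solo)
        for v in views:
            exp_img = project_expected(solo_ph, scanner, v)
            rec[v] = float(exp_img.values[rois[v][organ]].sum()
                           / exp_img.total)
        geo[organ] = {"T": t_factor, "f": f_corr, "recovery": rec}

    act_rows = []
    est_curves: dict[str, list[float]] = {o: [] for o in tac.organs}
    rng_root = np.random.SeedSequence(seed + 31).spawn(len(
        ex.TIMEPOINT_FRACTIONS))
    for (time_h, ret), ss in zip(ex.TIMEPOINT_FRACTIONS.items(), rng_root):
        streams = ss.spawn(2 * len(views))
        denoised = {}
        for vi, v in enumerate(views):
            img = series[v][1.0]
            if ret < 1.0:
                img = thin_counts(img, ret,
                                  np.random.default_rng(streams[2 * vi]))
                img = CountImage(img.counts, img.view, img.pixel_size,
                                 img.duration, fraction=1.0)
            img = thin_counts(img, fraction,
                              np.random.default_rng(streams[2 * vi + 1]))
            denoised[v] = ex.denoise_image(model, img)
        for organ in tac.organs:
            g = geo[organ]
            i_a = denoised["anterior"][rois["anterior"][organ]].sum() \
                / scanner.scan_time / g["recovery"]["anterior"]
            i_p = denoised["posterior"][rois["posterior"][organ]].sum() \
                / scanner.scan_time / g["recovery"]["posterior"]
            m = ConjugateViewMeasurement(i_a, i_p, g["T"], c_cal,
                                         f_corr=g["f"])
            a_est = conjugate_view_activity(m) / 1e6  # MBq
            a_true = tac.activity_mbq(organ, time_h)
            est_curves[organ].append(a_est)
            act_rows.append({"time_h": time_h, "organ": organ,
                             "true_mbq": a_true, "estimated_mbq": a_est,
                             "error_pct": 100.0 * abs(a_est - a_true)
                             / a_true})
    est_tac = TimeActivityCurve(
        np.asarray(list(ex.TIMEPOINT_FRACTIONS)),
        {o: np.clip(np.asarray(v) / injected_activity * 100.0, 0, 100)
         for o, v in est_curves.items()},
        injected_activity)
    doses_est = absorbed_dose(cumulated_activity_set(est_tac), s_matrix)
    doses_true = absorbed_dose(cumulated_activity_set(tac), s_matrix)
    dose_df = pd.DataFrame({
        "target_organ": list(doses_est),
        "dose_gy_estimated": list(doses_est.values()),
        "dose_gy_true": [doses_true[o] for o in doses_est],
    })
    dose_df["error_pct"] = 100.0 * (dose_df.dose_gy_estimated
                                    - dose_df.dose_gy_true).abs() \
        / dose_df.dose_gy_true
    return dose_df, pd.DataFrame(act_rows)


def _embed(roi, scanner):
    return embed_mask(roi.mask, scanner.matrix)


# ---------------------------------------------------------------------------
# publication-style tables
# ---------------------------------------------------------------------------

def make_paper_tables(run_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Re-shape a run's significance CSVs into wide per-ROI tables.

    Rows are the image variants (reference, reduced-count inputs,
    denoised outputs), columns the per-ROI mean/SD/P triples; plus the
    percent-difference summary recomputed from the tables themselves.
    """
    run_dir = Path(run_dir)
    out = {}
    for csv in sorted(run_dir.glob("derenzo_tbr*.csv")) \
            + sorted(run_dir.glob("torso_*h.csv")):
        df = pd.read_csv(csv)
        wide = df.pivot(index="image_id", columns="roi",
                        values=["mean", "sd", "p"])
        wide = wide.swaplevel(axis=1).sort_index(axis=1)
        order = (["reference"]
                 + sorted([i for i in df.image_id.unique()
                           if i.startswith("input")],
                          key=lambda s: int(s.split("_")[1]))
                 + sorted([i for i in df.image_id.unique()
                           if i.startswith("output")],
                          key=lambda s: int(s.split("_")[1])))
        wide = wide.loc[[o for o in order if o in wide.index]]
        name = csv.stem
        wide.to_csv(run_dir / f"table_{name}.csv")
        out[name] = wide
    pct = run_dir / "percent_differences.csv"
    if pct.exists():
        df = pd.read_csv(pct)
        summary = df[df.image_id.str.startswith("output")]
        summary.to_csv(run_dir / "table_percent_difference_summary.csv",
                       index=False)
        out["percent_difference_summary"] = summary
    return out
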