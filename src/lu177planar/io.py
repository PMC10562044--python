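"""Readers and writers for phantoms, count images and model checkpoints.

Phantoms travel as NIfTI pairs (activity + attenuation) with a JSON
sidecar; count images as 32-bit TIFF with a JSON sidecar; models as numpy
archives.  An optional list-mode CSV writer expands a count image into
per-event rows for interface completeness.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .denoiser import Denoiser, NetworkSpec
from .phantoms import OrganLabelMap, VoxelPhantom
from .projector import CountImage, ExpectedImage


def save_phantom(path: Path | str, phantom: VoxelPhantom,
                 labels: OrganLabelMap | None = None) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*phantom.voxel_size, 1.0])
    nib.save(nib.Nifti1Image(phantom.activity.astype(np.float32), affine),
             path / "activity.nii")
    nib.save(nib.Nifti1Image(phantom.attenuation.astype(np.float32), affine),
             path / "attenuation.nii")
    sidecar = {"name": phantom.name, "voxel_size": list(phantom.voxel_size)}
    if labels is not None:
        nib.save(nib.Nifti1Image(labels.labels.astype(np.int16), affine),
                 path / "labels.nii")
        sidecar["organ_names"] = {str(k): v
                                  for k, v in labels.organ_names.items()}
    (path / "phantom.json").write_text(json.dumps(sidecar, indent=2))


def load_phantom(path: Path | str
                 ) -> tuple[VoxelPhantom, OrganLabelMap | None]:
    path = Path(path)
    meta = json.loads((path / "phantom.json").read_text())
    act = np.asanyarray(nib.load(path / "activity.nii").dataobj)
    att = np.asanyarray(nib.load(path / "attenuation.nii").dataobj)
    phantom = VoxelPhantom(act, att, tuple(meta["voxel_size"]), meta["name"])
    labels = None
    if (path / "labels.nii").exists():
        lab = np.asanyarray(nib.load(path / "labels.nii").dataobj)
        labels = OrganLabelMap(lab.astype(np.int32),
                               {int(k): v
                                for k, v in meta["organ_names"].items()})
    return phantom, labels


def save_count_image(path: Path | str, image: CountImage | ExpectedImage
                     ) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(image, CountImage):
        data = image.counts.astype(np.uint32)
        meta = {"view": image.view, "fraction": image.fraction,
                "duration": image.duration, "pixel_size": image.pixel_size,
                "kind": "counts"}
    else:
        data = image.values.astype(np.float32)
        meta = {"view": image.view, "duration": image.duration,
                "pixel_size": image.pixel_size, "kind": "expected"}
    tifffile.imwrite(path, data)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_count_image(path: Path | str) -> CountImage | ExpectedImage:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = tifffile.imread(path)
    if meta["kind"] == "counts":
        return CountImage(data.astype(np.int64), meta["view"],
                          meta["pixel_size"], meta["duration"],
                          meta["fraction"])
    return ExpectedImage(data, meta["view"], meta["pixel_size"],
                         meta["duration"])


def write_listmode_csv(path: Path | str, image: CountImage,
                       energy_kev: float = 208.0,
                       seed: int = 0) -> int:
    """Expand a count image into a list-mode CSV (time_s, energy_keV,
    u_mm, v_mm); event times are uniform over the scan, positions at
    pixel centres.  Returns the number of events written."""
    rng = np.random.default_rng(seed)
    iu, iv = np.nonzero(image.counts)
    reps = image.counts[iu, iv]
    u = np.repeat(iu, reps) * image.pixel_size
    v = np.repeat(iv, reps) * image.pixel_size
    t = np.sort(rng.uniform(0.0, image.duration, size=u.size))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("time_s,energy_keV,u_mm,v_mm\n")
        for ti, ui, vi in zip(t, u, v):
            fh.write(f"{ti:.4f},{energy_kev:g},{ui:.2f},{vi:.2f}\n")
    return int(u.size)


def save_model(path: Path | str, model: Denoiser) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    spec = state.pop("spec")
    np.savez_compressed(
        path, __meta__=json.dumps(
            {"spec": spec, "normalization_constant":
             state.pop("normalization_constant"),
             "trained": state.pop("trained")}),
        **state)


def load_model(path: Path | str) -> Denoiser:
    with np.load(Path(path), allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        model = Denoiser(NetworkSpec(**meta["spec"]))
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    state["normalization_constant"] = meta["normalization_constant"]
    state["trained"] = meta["trained"]
    model.load_state_dict(state)
    return model
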