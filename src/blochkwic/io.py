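"""File round-tripping: configs (YAML), schedules (CSV), k-space bundles
(HDF5), images and parameter maps (NIfTI), and run manifests (JSON)."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .kwic import RadialKSpace
from .params import SequenceParams
from .phantom import PhantomDefinition, make_bsa_phantom, make_cardiac_phantom
from .sampling import SamplingPattern, SortingPlan
from .bloch import SignalPrediction

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "save_schedule",
    "load_schedule",
    "save_kspace",
    "load_kspace",
    "save_nifti",
    "load_nifti",
    "save_manifest",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    protocol: SequenceParams
    phantom: str = "bsa"  # "bsa" | "cardiac" | path to a phantom YAML
    mode: str = "bloch"
    f_nyq: float = 1.1
    noise_sigma: float = 0.0
    seed: int = 0
    outdir: str = "run"
    custom_shapes: tuple | None = None

    def __post_init__(self):
        if self.mode not in ("bloch", "serial"):
            raise ValueError("mode must be 'bloch' or 'serial'")
        if self.f_nyq <= 0:
            raise ValueError("f_nyq must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    def make_phantom(self) -> PhantomDefinition:
        if self.custom_shapes is not None:
            return PhantomDefinition(
                shapes=self.custom_shapes,
                fov=self.protocol.fov,
                matrix=self.protocol.matrix,
            )
        if self.phantom == "bsa":
            return make_bsa_phantom(fov=self.protocol.fov, matrix=self.protocol.matrix)
        if self.phantom == "cardiac":
            return make_cardiac_phantom(fov=self.protocol.fov, matrix=self.protocol.matrix)
        raise ValueError(f"unknown phantom {self.phantom!r}")


def _seq_to_dict(seq: SequenceParams) -> dict:
    d = asdict(seq)
    d["t_SL_list"] = list(d["t_SL_list"])
    d["f_SL_list"] = list(d["f_SL_list"])
    if d["weighting_order"] is not None:
        d["weighting_order"] = list(d["weighting_order"])
    return d


def save_config(config: RunConfig, path) -> None:
    doc = {
        "protocol": _seq_to_dict(config.protocol),
        "phantom": config.phantom,
        "mode": config.mode,
        "f_nyq": config.f_nyq,
        "noise_sigma": config.noise_sigma,
        "seed": config.seed,
        "outdir": config.outdir,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    proto = doc.pop("protocol")
    return RunConfig(protocol=SequenceParams(**proto), **doc)


def save_schedule(pattern: SamplingPattern, path) -> None:
    pattern.to_table().to_csv(path, index=False)


def load_schedule(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_kspace(kspace: RadialKSpace, path) -> None:
    """Write a k-space bundle to a single HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=kspace.samples)
        f.create_dataset("angles", data=kspace.angles)
        f.create_dataset("k_radii", data=kspace.k_radii)
        f.attrs["f_SL"] = kspace.f_SL
        g = f.create_group("schedule")
        tab = kspace.pattern.to_table()
        for col in tab.columns:
            g.create_dataset(col, data=tab[col].to_numpy())
        g.attrs["mode"] = kspace.pattern.plan.mode
        g.attrs["n_prep"] = kspace.pattern.n_prep
        g.attrs["NR"] = kspace.pattern.NR


def load_kspace(path) -> RadialKSpace:
    with h5py.File(path, "r") as f:
        samples = f["samples"][()]
        angles = f["angles"][()]
        k_radii = f["k_radii"][()]
        f_SL = float(f.attrs["f_SL"])
        g = f["schedule"]
        pred = SignalPrediction(
            signals=g["signal"][()],
            window_id=g["window_id"][()],
            readout_pos=g["readout_pos"][()],
            weighting_id=g["weighting_id"][()],
            f_SL=f_SL,
        )
        plan = SortingPlan(
            golden_index=g["golden_index"][()],
            angle=g["angle_deg"][()],
            mode=g.attrs["mode"],
        )
        pattern = SamplingPattern(
            plan=plan, prediction=pred, n_prep=int(g.attrs["n_prep"]), NR=int(g.attrs["NR"])
        )
    return RadialKSpace(
        samples=samples, angles=angles, k_radii=k_radii, pattern=pattern, f_SL=f_SL
    )


def save_nifti(data: np.ndarray, path, fov: float | None = None) -> None:
    """Write a 2-D map or a (W, N, N) stack as NIfTI with FOV-derived voxel size."""
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim == 3:  # stack: store weightings along the last axis
        arr = np.moveaxis(arr, 0, -1)
    affine = np.eye(4)
    if fov is not None:
        vox = fov / arr.shape[0]
        affine[0, 0] = affine[1, 1] = vox
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def load_nifti(path) -> np.ndarray:
    arr = np.asarray(nib.load(str(path)).dataobj)
    if arr.ndim == 3:
        arr = np.moveaxis(arr, -1, 0)
    return arr


def save_manifest(path, config: RunConfig, extra: dict | None = None) -> None:
    import blochkwic

    doc = {
        "package": "blochkwic",
        "version": blochkwic.__version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "mode": config.mode,
        "phantom": config.phantom,
        "f_nyq": config.f_nyq,
        "noise_sigma": config.noise_sigma,
        "protocol": _seq_to_dict(config.protocol),
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))
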