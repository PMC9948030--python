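"""File formats: 4D NIfTI volumes, TSV gas traces, YAML configs, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .relaxometry import EchoSeries
from .synthetic import GasTrace, Phantom

__all__ = [
    "load_echo_series",
    "load_volume",
    "load_labels",
    "read_gas_trace",
    "write_gas_trace",
    "save_volume",
    "write_phantom",
    "load_yaml",
    "write_json",
]

GAS_COLUMNS = ("time_s", "etco2_mmHg", "eto2_mmHg")


def load_echo_series(path: str | Path, te: float, tr: float | None = None) -> EchoSeries:
    """Load one echo's 4D NIfTI; TR from the header unless given."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4D NIfTI, got {data.ndim}D")
    if tr is None:
        zooms = img.header.get_zooms()
        if len(zooms) < 4 or zooms[3] <= 0:
            raise ValueError(f"{path}: header carries no usable TR; pass tr explicitly")
        tr = float(zooms[3])
    return EchoSeries(data, te=te, tr=tr)


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D NIfTI, returning (data, affine)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D NIfTI, got {data.ndim}D")
    return data, img.affine


def load_labels(path: str | Path) -> np.ndarray:
    data, _ = load_volume(path)
    return np.asarray(np.rint(data), dtype=np.int32)


def save_volume(
    path: str | Path,
    data: np.ndarray,
    affine: np.ndarray | None = None,
    description: str = "",
    tr: float | None = None,
) -> None:
    """Write a volume as float32 NIfTI with an optional description/TR."""
    affine = np.eye(4) if affine is None else affine
    arr = np.asarray(data, dtype=np.float32)
    img = nib.Nifti1Image(arr, affine)
    if description:
        img.header["descrip"] = description.encode()[:79]
    if tr is not None and arr.ndim == 4:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr
        img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_gas_trace(path: str | Path) -> GasTrace:
    """Read a gas trace TSV/CSV with columns time_s, etco2_mmHg[, eto2_mmHg]."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    for col in GAS_COLUMNS[:2]:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    eto2 = df[GAS_COLUMNS[2]].to_numpy() if GAS_COLUMNS[2] in df.columns else None
    return GasTrace(
        t=df["time_s"].to_numpy(), etco2=df["etco2_mmHg"].to_numpy(), eto2=eto2
    )


def write_gas_trace(path: str | Path, gas: GasTrace) -> None:
    cols = {"time_s": gas.t, "etco2_mmHg": gas.etco2}
    if gas.eto2 is not None:
        cols["eto2_mmHg"] = gas.eto2
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_phantom(phantom: Phantom, out_dir: str | Path) -> dict:
    """Serialise a phantom: one NIfTI per echo, labels, truth maps, gas TSV.

    Returns the manifest (also written as phantom.json) mapping outputs to
    file names, with the generating parameters echoed for provenance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = phantom.spec
    manifest: dict = {
        "echoes": [], "tr": spec.tr, "te": list(spec.te),
        "period": spec.period, "seed": spec.seed,
        "tsnr_target": spec.tsnr_target,
        "gas": "gas_trace.tsv", "labels": "labels.nii.gz",
        "truth": {},
    }
    for echo in phantom.echoes:
        name = f"bold_te{int(round(echo.te * 1000))}ms.nii.gz"
        save_volume(out / name, echo.data, description=f"TE={echo.te}s", tr=spec.tr)
        manifest["echoes"].append({"file": name, "te": echo.te})
    save_volume(out / "labels.nii.gz", phantom.truth.labels,
                description="0=bg 1=GM 2=WM 3=vein")
    for key in ("cbf", "cbv", "td", "cvr"):
        name = f"truth_{key}.nii.gz"
        save_volume(out / name, getattr(phantom.truth, key), description=f"true {key}")
        manifest["truth"][key] = name
    write_gas_trace(out / "gas_trace.tsv", phantom.gas)
    write_json(out / "phantom.json", manifest)
    return manifest


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return cfg


def write_json(path: str | Path, obj: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
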