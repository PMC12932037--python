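"""Serialization of spectrum series: HDF5 fixture layout and NIfTI-MRS.

Two on-disk layouts are supported:

* an HDF5 fixture: one file per series with the complex FID array
  ``fids`` (contrast x channel x average x time), the contrast axis, and
  acquisition attributes; the truth record (when present) is stored as a
  JSON string attribute and optionally as a sidecar ``.json`` file;
* NIfTI-MRS: a NIfTI-2 image of shape (1, 1, 1, time, channel, average,
  contrast) with complex data, dwell time in ``pixdim[4]``, and the MRS
  header extension (JSON, ecode 44) describing the spectrometer
  frequency, nucleus and the higher-dimension tags (DIM_COIL, DIM_DYN,
  DIM_INDIRECT_0 with the TE/TI list).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import nibabel as nib

from .spectral import AcquisitionContext
from .synthetic import SpectrumSeries, TruthRecord

__all__ = [
    "save_series_h5",
    "load_series_h5",
    "save_truth_json",
    "load_truth_json",
    "save_series_niftimrs",
    "load_series_niftimrs",
]

_ACQ_FIELDS = ("te", "ti", "tr", "tm", "dwell", "n_points", "f_transmitter", "ref_ppm")


def save_truth_json(truth: TruthRecord, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2))


def load_truth_json(path) -> TruthRecord:
    return TruthRecord.from_dict(json.loads(Path(path).read_text()))


def save_series_h5(series: SpectrumSeries, path, truth_sidecar: bool = False) -> None:
    """Write a series to the documented HDF5 fixture layout."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("fids", data=series.fids)
        f.create_dataset("contrasts", data=series.contrasts)
        f.attrs["kind"] = series.kind
        for name in _ACQ_FIELDS:
            v = getattr(series.acq, name)
            f.attrs[f"acq_{name}"] = np.nan if v is None else v
        if series.truth is not None:
            f.attrs["truth_json"] = json.dumps(series.truth.to_dict())
    if truth_sidecar and series.truth is not None:
        save_truth_json(series.truth, path.with_suffix(".truth.json"))


def load_series_h5(path) -> SpectrumSeries:
    with h5py.File(path, "r") as f:
        fids = f["fids"][()]
        contrasts = f["contrasts"][()]
        kind = f.attrs["kind"]
        kw = {}
        for name in _ACQ_FIELDS:
            v = f.attrs[f"acq_{name}"]
            if name == "n_points":
                v = int(v)
            elif name == "ti":
                v = None if np.isnan(v) else float(v)
            else:
                v = float(v)
            kw[name] = v
        truth = None
        if "truth_json" in f.attrs:
            truth = TruthRecord.from_dict(json.loads(f.attrs["truth_json"]))
    return SpectrumSeries(contrasts, str(kind), fids, AcquisitionContext(**kw), truth)


def save_series_niftimrs(series: SpectrumSeries, path) -> None:
    """Write a series as NIfTI-MRS (complex NIfTI-2 + JSON header extension)."""
    # (x, y, z, time, coil, average, indirect)
    data = np.transpose(series.fids, (3, 1, 2, 0))[None, None, None].astype(
        np.complex64
    )
    hdr_json = {
        "SpectrometerFrequency": [series.acq.f_transmitter],
        "ResonantNucleus": ["1H"],
        "dim_5": "DIM_COIL",
        "dim_6": "DIM_DYN",
        "dim_7": "DIM_INDIRECT_0",
        "dim_7_header": {
            "EchoTime" if series.kind == "TE" else "InversionTime": [
                v * 1e-3 for v in series.contrasts.tolist()
            ]
        },
        "EchoTime": series.acq.te * 1e-3,
        "RepetitionTime": series.acq.tr * 1e-3,
        "MixingTime": series.acq.tm * 1e-3,
        "ChemicalShiftReference": series.acq.ref_ppm,
        "SeriesKind": series.kind,
    }
    img = nib.Nifti2Image(data, affine=np.eye(4))
    img.header["pixdim"][4] = series.acq.dwell
    img.header.extensions.append(
        nib.nifti1.Nifti1Extension("mrs", json.dumps(hdr_json).encode())
    )
    nib.save(img, str(path))


def load_series_niftimrs(path) -> SpectrumSeries:
    img = nib.load(str(path))
    meta = None
    for ext in img.header.extensions:
        if ext.get_code() == 44:
            content = ext.get_content()
            if isinstance(content, (bytes, str)):
                meta = json.loads(content)
            else:
                meta = content
            break
    if meta is None:
        raise ValueError("no MRS header extension found")
    data = np.asanyarray(img.dataobj)
    fids = np.transpose(data[0, 0, 0], (3, 1, 2, 0)).astype(complex)
    kind = meta.get("SeriesKind", "TE")
    key = "EchoTime" if kind == "TE" else "InversionTime"
    contrasts = np.asarray(meta["dim_7_header"][key]) * 1e3
    acq = AcquisitionContext(
        te=meta["EchoTime"] * 1e3,
        ti=None,
        tr=meta["RepetitionTime"] * 1e3,
        tm=meta.get("MixingTime", 0.01) * 1e3,
        dwell=float(img.header["pixdim"][4]),
        n_points=fids.shape[-1],
        f_transmitter=meta["SpectrometerFrequency"][0],
        ref_ppm=meta.get("ChemicalShiftReference", 4.7),
    )
    return SpectrumSeries(contrasts, kind, fids, acq)
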