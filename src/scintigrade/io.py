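"""Reading and writing studies: 16-bit PNG + metadata CSV, raw matrices,
and nuclear-medicine DICOM."""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .phantom import ScintigraphyStudy

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ["id", "filename", "view", "protocol", "grade",
                    "has_metastases", "age", "seed"]

__all__ = ["write_dataset", "load_dataset", "load_image", "read_dicom",
           "METADATA_COLUMNS"]


def write_dataset(studies: list[ScintigraphyStudy], out_dir, force: bool = False,
                  raw: bool = False) -> Path:
    """Write studies as 16-bit PNGs plus a ``metadata.csv`` sidecar.

    Refuses to write into an existing non-empty directory unless ``force``.
    With ``raw=True`` the exact float matrices are also stored as ``.npy``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(studies):
        sid = s.study_id or f"study_{i:05d}"
        fname = f"{sid}.png"
        counts = np.clip(np.round(s.pixels), 0, 65535).astype(np.uint16)
        iio.imwrite(out / fname, counts)
        if raw:
            np.save(out / f"{sid}.npy", s.pixels)
        rows.append({"id": sid, "filename": fname, "view": s.view,
                     "protocol": s.protocol, "grade": s.grade,
                     "has_metastases": s.has_metastases,
                     "age": round(float(s.age), 1), "seed": s.seed})
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(out / "metadata.csv",
                                                        index=False)
    return out


def load_dataset(data_dir) -> list[ScintigraphyStudy]:
    """Load a PNG + metadata.csv dataset written by :func:`write_dataset`."""
    data = Path(data_dir)
    meta = pd.read_csv(data / "metadata.csv")
    studies = []
    for row in meta.itertuples(index=False):
        npy = data / f"{row.id}.npy"
        pixels = np.load(npy) if npy.exists() else \
            iio.imread(data / row.filename).astype(np.float64)
        studies.append(ScintigraphyStudy(
            pixels=pixels, view=row.view, protocol=row.protocol,
            grade=int(row.grade), has_metastases=bool(row.has_metastases),
            age=float(row.age), study_id=str(row.id), seed=int(row.seed)))
    return studies


def load_image(path) -> np.ndarray:
    """Load a single 2-D count image from PNG, .npy, text matrix or DICOM."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        return np.load(path).astype(np.float64)
    if suffix in (".txt", ".tsv", ".csv"):
        return np.loadtxt(path, delimiter="," if suffix == ".csv" else None)
    if suffix in (".dcm", ".ima", ""):
        return read_dicom(path).pixels
    return iio.imread(path).astype(np.float64)


def read_dicom(path, view: str | None = None) -> ScintigraphyStudy:
    """Read a planar nuclear-medicine DICOM file.

    The AP/PA view is taken from the ViewPosition or detector metadata when
    present; pass ``view`` to override. Multi-frame images use frame 0.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    if arr.ndim == 3:
        arr = arr[0]
    if view is None:
        view = str(getattr(ds, "ViewPosition", "") or "").upper()
        if view not in ("AP", "PA"):
            # some vendors store the view per detector
            try:
                view = str(ds.DetectorInformationSequence[0].ViewPosition).upper()
            except Exception:
                view = ""
        if view not in ("AP", "PA"):
            logger.warning("%s: cannot determine AP/PA view; assuming AP", path)
            view = "AP"
    protocol = "whole_body" if arr.shape[0] > 2 * arr.shape[1] else "planar"
    age = getattr(ds, "PatientAge", None)
    try:
        age = float(str(age).rstrip("YyMmDd")) if age else 0.0
    except ValueError:
        age = 0.0
    return ScintigraphyStudy(pixels=arr.astype(np.float64), view=view,
                             protocol=protocol, age=age,
                             study_id=str(getattr(ds, "SOPInstanceUID", path)))
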