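"""File round-trips: 16-bit TIFF image series with CSV manifests,
float TIFF templates with JSON sidecars, localization-record CSVs and
motion-PDF JSON dumps."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .localization import MotionPDF
from .matching import Template
from .projector import Frame, ImagingSeries, ProjectionImage

__all__ = [
    "write_series",
    "read_series",
    "write_de_image",
    "read_de_image",
    "write_phantom",
    "read_phantom",
    "write_template",
    "read_template",
    "write_records_csv",
    "write_pdf_json",
    "read_pdf_json",
]


def write_series(series: ImagingSeries, outdir, prefix: str = "series") -> Path:
    """Write one multi-page 16-bit TIFF per (view, energy) plus a manifest.

    Counts are rounded and clipped to the 16-bit range (the simulated
    detector's bit depth).  Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    keys = sorted({k for f in series.frames for k in f.images})
    rows = []
    for view, energy in keys:
        stack = np.stack(
            [
                np.clip(np.round(f.images[(view, energy)].pixels), 0, 65535)
                for f in series.frames
            ]
        ).astype(np.uint16)
        name = f"{prefix}_{view}_{energy}.tif"
        tifffile.imwrite(outdir / name, stack, photometric="minisblack")
        for f in series.frames:
            img = f.images[(view, energy)]
            rows.append(
                {
                    "frame_index": f.index,
                    "time_s": f.time,
                    "view": view,
                    "energy": energy,
                    "mAs": img.mAs,
                    "file": name,
                }
            )
    manifest = outdir / f"{prefix}_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    meta = {
        "protocol": series.protocol,
        "frame_rate": series.frame_rate,
        "tumor_reference": list(map(float, series.tumor_reference)),
        "truth_mm": series.trajectory.positions.tolist(),
        "times_s": series.trajectory.times.tolist(),
    }
    with open(outdir / f"{prefix}_meta.json", "w") as fh:
        json.dump(meta, fh)
    return manifest


def read_series(manifest_path) -> ImagingSeries:
    """Reassemble an ImagingSeries written by :func:`write_series`."""
    from .phantom import Trajectory

    manifest_path = Path(manifest_path)
    outdir = manifest_path.parent
    prefix = manifest_path.name.replace("_manifest.csv", "")
    df = pd.read_csv(manifest_path)
    with open(outdir / f"{prefix}_meta.json") as fh:
        meta = json.load(fh)
    stacks = {
        name: tifffile.imread(outdir / name).astype(float)
        for name in df["file"].unique()
    }
    times = np.asarray(meta["times_s"], dtype=float)
    positions = np.asarray(meta["truth_mm"], dtype=float)
    frames = {}
    for _, row in df.iterrows():
        i = int(row["frame_index"])
        if i not in frames:
            frames[i] = Frame(
                index=i, time=float(row["time_s"]), displacement=positions[i]
            )
        frames[i].images[(row["view"], row["energy"])] = ProjectionImage(
            pixels=stacks[row["file"]][i],
            view=row["view"],
            energy_label=row["energy"],
            mAs=float(row["mAs"]),
            frame_index=i,
            time=float(row["time_s"]),
        )
    return ImagingSeries(
        frames=[frames[i] for i in sorted(frames)],
        protocol=meta["protocol"],
        mAs={},
        tumor_reference=np.asarray(meta["tumor_reference"], dtype=float),
        trajectory=Trajectory(times=times, positions=positions),
        frame_rate=float(meta["frame_rate"]),
    )


def write_phantom(phantom, path) -> None:
    """Export a voxel phantom as a medical-image volume plus label sidecar.

    Any format SimpleITK infers from the extension works (.mha, .nii.gz,
    ...); the labels go to ``<stem>_labels<ext>``.  Array axes (LR, AP, SI)
    map to the image's (x, y, z).
    """
    import SimpleITK as sitk

    path = Path(path)

    def to_image(arr):
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr.T))
        img.SetSpacing(tuple(float(s) for s in phantom.spacing))
        img.SetOrigin(tuple(float(o) for o in phantom.origin))
        return img

    sitk.WriteImage(to_image(phantom.hu.astype(np.float32)), str(path))
    label_path = path.with_name(path.name.replace(".", "_labels.", 1))
    sitk.WriteImage(to_image(phantom.labels), str(label_path))


def read_phantom(path):
    """Read a phantom written by :func:`write_phantom`."""
    import SimpleITK as sitk

    from .phantom import VoxelPhantom

    path = Path(path)
    hu_img = sitk.ReadImage(str(path))
    label_path = path.with_name(path.name.replace(".", "_labels.", 1))
    lab_img = sitk.ReadImage(str(label_path))
    hu = sitk.GetArrayFromImage(hu_img).T.astype(float)
    labels = sitk.GetArrayFromImage(lab_img).T.astype(np.uint8)
    return VoxelPhantom(
        labels=labels,
        hu=hu,
        spacing=np.asarray(hu_img.GetSpacing()),
        origin=np.asarray(hu_img.GetOrigin()),
        slice_thickness=float(hu_img.GetSpacing()[2]),
    )


def write_de_image(de, path) -> None:
    """Store a log-domain DE image as 32-bit float TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, de.log_pixels.astype(np.float32))
    side = {
        "view": de.view,
        "frame_index": de.frame_index,
        "ws": de.ws,
        "wb": de.wb,
        "wn": de.wn,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(side, fh)


def read_de_image(path):
    from .dual_energy import DEImage

    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        side = json.load(fh)
    return DEImage(
        log_pixels=tifffile.imread(path).astype(float),
        view=side["view"],
        frame_index=side["frame_index"],
        ws=side["ws"],
        wb=side["wb"],
        wn=side["wn"],
    )


def write_template(tpl: Template, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, tpl.pixels.astype(np.float32))
    sidecar = {
        "view": tpl.view,
        "com_offset": list(tpl.com_offset),
        "source_tumor": tpl.source_tumor,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh)


def read_template(path) -> Template:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        side = json.load(fh)
    return Template(
        pixels=tifffile.imread(path).astype(float),
        view=side["view"],
        com_offset=tuple(side["com_offset"]),
        source_tumor=side.get("source_tumor", ""),
    )


def write_records_csv(records, path) -> None:
    from .evaluation import records_to_dataframe

    records_to_dataframe(records).to_csv(path, index=False)


def write_pdf_json(pdf: MotionPDF, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "mean": pdf.mean.tolist(),
                "covariance": pdf.covariance.tolist(),
                "n_samples": pdf.n_samples,
            },
            fh,
        )


def read_pdf_json(path) -> MotionPDF:
    with open(path) as fh:
        d = json.load(fh)
    return MotionPDF(
        mean=np.asarray(d["mean"]),
        covariance=np.asarray(d["covariance"]),
        n_samples=int(d["n_samples"]),
    )
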