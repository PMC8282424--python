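"""Reading and writing cohort tables, images and masks."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .records import CaseRecord

COHORT_COLUMNS = [
    "case_id", "grade", "histology", "idh", "atrx", "codel_1p19q", "mgmt",
    "image_path", "mask_path",
]


def save_image(path, image: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(Path(path), np.asarray(image, np.uint8))


def save_mask(path, mask: np.ndarray) -> None:
    """Binary mask as single-channel PNG with 0/255 values."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def load_image(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)))


def load_mask(path) -> np.ndarray:
    return (np.asarray(iio.imread(Path(path))) > 0).astype(np.uint8)


def write_cohort(records: list[CaseRecord], out_dir) -> Path:
    """Write ROI/mask PNGs and the cohort CSV; returns the CSV path."""
    out_dir = Path(out_dir)
    rows = []
    for rec in records:
        img_path = out_dir / "images" / f"{rec.case_id}.png"
        mask_path = out_dir / "masks" / f"{rec.case_id}.png"
        if rec.image is not None:
            save_image(img_path, rec.image)
        if rec.mask is not None:
            save_mask(mask_path, rec.mask)
        row = {
            "case_id": rec.case_id, "grade": rec.grade,
            "histology": rec.histology, "idh": rec.idh, "atrx": rec.atrx,
            "codel_1p19q": rec.codel_1p19q, "mgmt": rec.mgmt,
            "image_path": str(img_path.relative_to(out_dir)),
            "mask_path": str(mask_path.relative_to(out_dir)),
        }
        if rec.cellularity is not None:
            row["cellularity"] = rec.cellularity
        rows.append(row)
    df = pd.DataFrame(rows)
    csv_path = out_dir / "cohort.csv"
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(csv_path, index=False)
    return csv_path


def read_cohort(csv_path, *, load_images: bool = True) -> list[CaseRecord]:
    """Load a cohort CSV (paths resolved relative to the CSV's directory)."""
    csv_path = Path(csv_path)
    base = csv_path.parent
    df = pd.read_csv(csv_path)
    records = []
    for _, row in df.iterrows():
        image = mask = None
        if load_images and isinstance(row.get("image_path"), str):
            image = load_image(base / row["image_path"])
        if load_images and isinstance(row.get("mask_path"), str):
            mask = load_mask(base / row["mask_path"])
        cellularity = row.get("cellularity")
        records.append(CaseRecord(
            case_id=row["case_id"], grade=str(row["grade"]),
            histology=row["histology"], idh=row["idh"], atrx=row["atrx"],
            codel_1p19q=row["codel_1p19q"], mgmt=row["mgmt"],
            image=image, mask=mask,
            cellularity=None if pd.isna(cellularity) else float(cellularity),
        ))
    return records
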