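"""Reading and writing multiplex core images, masks, and score tables.

Images travel as multipage TIFF (one page per channel, nominal 0-1 floats
scaled to 16-bit) with channel name and exposure time embedded in each
page's description tag and duplicated in a JSON sidecar; ground truth as
CSV plus PNG masks.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .quantify import CHANNELS, MultiplexCoreImage
from .simulate import GroundTruth

_U16 = 65535.0


def write_core_image(image: MultiplexCoreImage, out_dir, stem: str) -> Path:
    """Write one core as <stem>.tif + <stem>.json sidecar; returns TIFF path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiff_path = out_dir / f"{stem}.tif"
    with tifffile.TiffWriter(tiff_path) as tw:
        for c in CHANNELS:
            page = np.clip(image.channels[c], 0.0, 1.0)
            tag = json.dumps({"channel": c, "exposure_ms": image.exposure_ms[c]})
            tw.write((page * _U16).round().astype(np.uint16), description=tag)
    sidecar = {
        "channels": list(CHANNELS),
        "exposure_ms": image.exposure_ms,
        "core_id": image.core_id,
        "subject_id": image.subject_id,
        "roi_class": image.roi_class,
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return tiff_path


def read_core_image(tiff_path) -> MultiplexCoreImage:
    """Read a multipage TIFF back into a core image (sidecar or page tags)."""
    tiff_path = Path(tiff_path)
    sidecar_path = tiff_path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    channels: dict[str, np.ndarray] = {}
    exposures: dict[str, float] = dict(meta.get("exposure_ms", {}))
    with tifffile.TiffFile(tiff_path) as tf:
        for i, page in enumerate(tf.pages):
            desc = page.tags.get("ImageDescription")
            if desc is not None:
                info = json.loads(desc.value)
                name = info["channel"]
                exposures.setdefault(name, float(info["exposure_ms"]))
            else:
                name = meta["channels"][i]
            channels[name] = page.asarray().astype(float) / _U16
    return MultiplexCoreImage(
        channels=channels,
        exposure_ms={c: float(exposures[c]) for c in CHANNELS},
        core_id=meta.get("core_id", tiff_path.stem),
        subject_id=meta.get("subject_id", ""),
        roi_class=meta.get("roi_class", "tumor_stroma"),
    )


def write_ground_truth(truth: GroundTruth, out_dir, stem: str) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_dir / f"{stem}_stroma_mask.png", (truth.stroma_mask * 255).astype(np.uint8))
    iio.imwrite(out_dir / f"{stem}_epithelium_mask.png", (truth.epithelium_mask * 255).astype(np.uint8))
    pd.DataFrame(
        [
            {
                "stem": stem,
                "stroma_cav1_conc": truth.stroma_cav1_conc,
                "epi_cav1_conc": truth.epi_cav1_conc,
                "cav1_gain": truth.cav1_gain,
                "stroma_px": int(truth.stroma_mask.sum()),
                "epithelium_px": int(truth.epithelium_mask.sum()),
            }
        ]
    ).to_csv(out_dir / f"{stem}_truth.csv", index=False)


SCORE_COLUMNS = ["subject_id", "core_id", "roi_class", "compartment", "score", "area_px"]


def write_scores(rows: list[dict], path) -> None:
    pd.DataFrame(rows, columns=SCORE_COLUMNS).to_csv(path, index=False)


def read_clinical_table(path, column_mapping: dict[str, str] | None = None) -> pd.DataFrame:
    """Load a clinical spreadsheet (CSV or XLS/XLSX) and rename mapped columns.

    ``column_mapping`` maps source spreadsheet column names to the canonical
    field names used by the annotation stage; unmapped extra columns are
    kept untouched.
    """
    path = Path(path)
    if path.suffix.lower() in (".xls", ".xlsx"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_mapping:
        missing = [src for src in column_mapping if src not in df.columns]
        if missing:
            raise KeyError(f"mapped columns absent from {path.name}: {missing}")
        df = df.rename(columns=column_mapping)
    return df
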