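"""Plain-text readers and writers for pipeline artifacts.

All tabular outputs are tab-separated text; geometry and run metadata are
JSON.  Images are 8- or 16-bit grayscale PNG/TIFF handled by imageio.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .extraction import N_SROIS, QISP

__all__ = [
    "read_image",
    "write_image",
    "qisps_to_frame",
    "write_qisp_table",
    "read_qisp_table",
    "write_json",
]


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image, collapsing any color axis by luminance mean."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img.mean(axis=2).astype(img.dtype)
    return img


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(path, image)


def qisps_to_frame(qisps: Sequence[QISP]) -> pd.DataFrame:
    """One row per gene: gene_id, background, then raw/corrected/smoothed 1-20."""
    rows = []
    for q in qisps:
        row: dict = {"gene_id": q.gene_id, "background": q.background_value}
        for name in ("raw", "corrected", "smoothed"):
            for i, v in enumerate(getattr(q, name), start=1):
                row[f"{name}_{i}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_qisp_table(qisps: Sequence[QISP], path: str | Path) -> None:
    qisps_to_frame(qisps).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_qisp_table(path: str | Path) -> list[QISP]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            QISP(
                gene_id=str(row["gene_id"]),
                raw=np.array([row[f"raw_{i}"] for i in range(1, N_SROIS + 1)]),
                corrected=np.array(
                    [row[f"corrected_{i}"] for i in range(1, N_SROIS + 1)]
                ),
                smoothed=np.array(
                    [row[f"smoothed_{i}"] for i in range(1, N_SROIS + 1)]
                ),
                background_value=float(row["background"]),
            )
        )
    return out


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
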