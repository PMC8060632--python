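"""Canopy-cover extraction from nadir RGB images by G−R index thresholding.

Canopy cover (CC) is the fraction of ground covered by the vertical
projection of the crop canopy.  From a nadir photograph it is estimated as
the fraction of pixels classified as vegetation.  Classification uses the
G−R colour index: the per-pixel green-channel intensity minus the
red-channel intensity.  Vegetation is green-dominant (G−R > 0) while bare
soil and senescent residue are red-dominant, so a single threshold on G−R
separates canopy from background.

The segmentation rule is strict: a pixel belongs to the canopy iff its
G−R value is *greater than* the threshold; boundary pixels are background.
The default threshold is 0 (the natural sign boundary of G−R); an automatic
mode selects the threshold by Otsu's between-class-variance criterion on
the signed 511-bin G−R histogram.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "CanopySegmentation",
    "compute_gr_index",
    "segment_canopy",
    "auto_threshold",
    "cc_from_image_file",
    "cc_table",
]

#: metadata columns expected alongside image paths in a plot-metadata CSV
META_COLUMNS = ("image_path", "site", "season", "cultivar",
                "n_rate_kg_ha", "replicate", "stage")


@dataclass(frozen=True)
class CanopySegmentation:
    """Result of thresholding a G−R index map.

    Attributes
    ----------
    mask : ndarray of bool
        True where the pixel is classified as canopy.
    threshold : int
        Signed G−R threshold that produced the mask (canopy iff G−R > t).
    n_canopy, n_total : int
        Canopy pixel count and total pixel count.
    cc : float
        Canopy cover fraction, ``n_canopy / n_total``.
    image_path : str or None
        Source file, when the segmentation came from one.
    """

    mask: np.ndarray = field(repr=False)
    threshold: int
    n_canopy: int
    n_total: int
    cc: float
    image_path: str | None = None

    def to_dict(self) -> dict:
        """Scalar summary (mask excluded), e.g. for a CC table row."""
        return {
            "image_path": self.image_path,
            "threshold": self.threshold,
            "n_canopy": self.n_canopy,
            "n_total": self.n_total,
            "cc": self.cc,
        }


def _as_rgb_array(image: "np.ndarray | Image.Image") -> np.ndarray:
    """Coerce input to an (H, W, 3) uint8 array; reject non-RGB modes."""
    if isinstance(image, Image.Image):
        if image.mode == "RGBA":
            # alpha is dropped, not composited: fixtures are opaque
            image = image.convert("RGB")
        elif image.mode != "RGB":
            raise ValueError(
                f"expected an RGB image, got mode {image.mode!r}; "
                "grayscale/palette images carry no G-R information"
            )
        arr = np.asarray(image, dtype=np.uint8)
    else:
        arr = np.asarray(image)
        if arr.ndim != 3 or arr.shape[2] < 3:
            raise ValueError(
                f"expected an (H, W, 3) RGB array, got shape {arr.shape}"
            )
        arr = arr[:, :, :3]
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must be at least 1x1 pixel")
    return arr


def compute_gr_index(image: "np.ndarray | Image.Image") -> np.ndarray:
    """Per-pixel signed G−R index of an 8-bit RGB image.

    Parameters
    ----------
    image : (H, W, 3) uint8 array or PIL RGB/RGBA image
        RGBA input has its alpha channel dropped.

    Returns
    -------
    ndarray of int16, shape (H, W)
        ``green − red`` per pixel, in [−255, 255].  The blue channel is
        ignored and no clamping is applied.
    """
    arr = _as_rgb_array(image)
    return arr[:, :, 1].astype(np.int16) - arr[:, :, 0].astype(np.int16)


def segment_canopy(gr: np.ndarray, threshold: int = 0) -> CanopySegmentation:
    """Threshold a G−R map into canopy (G−R > threshold) and background.

    The inequality is strict, so pixels exactly at the threshold count as
    background.  CC is the canopy-pixel fraction.
    """
    gr = np.asarray(gr)
    if not -255 <= threshold <= 255:
        raise ValueError(f"threshold must be in [-255, 255], got {threshold}")
    mask = gr > threshold
    n_total = int(mask.size)
    n_canopy = int(mask.sum())
    return CanopySegmentation(
        mask=mask,
        threshold=int(threshold),
        n_canopy=n_canopy,
        n_total=n_total,
        cc=n_canopy / n_total,
    )


def auto_threshold(gr: np.ndarray) -> int:
    """Otsu threshold of a signed G−R map.

    Builds the 511-bin histogram over the integer values −255…255 and
    returns the threshold t maximizing the between-class variance of the
    split {G−R ≤ t} / {G−R > t}.  Deterministic; ties are broken toward
    the lower threshold.

    Raises
    ------
    ValueError
        If the map is constant (no bimodality to exploit).
    """
    gr = np.asarray(gr)
    values = gr.ravel().astype(np.int64)
    if values.min() == values.max():
        raise ValueError(
            "G-R map is constant: no bimodality to exploit for an "
            "automatic threshold"
        )
    counts = np.bincount(values + 255, minlength=511).astype(np.float64)
    bins = np.arange(-255, 256, dtype=np.float64)

    # cumulative class weights/means for background {<= t}, t = -255..254
    w0 = np.cumsum(counts)[:-1]
    w1 = values.size - w0
    csum = np.cumsum(counts * bins)[:-1]
    total = float(np.sum(counts * bins))
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum / w0
        mu1 = (total - csum) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[(w0 == 0) | (w1 == 0)] = -np.inf  # degenerate splits excluded
    # argmax returns the first (lowest) maximizer: ties break low
    return int(bins[int(np.argmax(between))])


def cc_from_image_file(
    path: "str | os.PathLike",
    threshold: "int | str" = 0,
) -> CanopySegmentation:
    """Compute canopy cover from a JPEG/PNG file.

    Composition of :func:`compute_gr_index`, optional
    :func:`auto_threshold`, and :func:`segment_canopy`.  CC is a pure pixel
    ratio, so the result is resolution-independent for a scale-invariant
    scene.

    Parameters
    ----------
    path : path-like
        Readable JPEG or PNG file.
    threshold : int or "auto"
        Fixed signed threshold, or ``"auto"`` for Otsu selection.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            gr = compute_gr_index(im)
    except (OSError, FileNotFoundError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(
                f"threshold must be an integer or 'auto', got {threshold!r}"
            )
        t = auto_threshold(gr)
    else:
        t = int(threshold)
    seg = segment_canopy(gr, t)
    return CanopySegmentation(
        mask=seg.mask,
        threshold=seg.threshold,
        n_canopy=seg.n_canopy,
        n_total=seg.n_total,
        cc=seg.cc,
        image_path=str(path),
    )


def cc_table(
    images: "str | os.PathLike | Sequence[str | os.PathLike]",
    meta: "pd.DataFrame | None" = None,
    threshold: "int | str" = 0,
) -> pd.DataFrame:
    """Batch CC extraction over a directory or list of image files.

    Parameters
    ----------
    images : directory or sequence of file paths
        A directory is scanned (non-recursively) for .jpg/.jpeg/.png files,
        sorted by name for determinism.
    meta : DataFrame, optional
        Plot metadata with an ``image_path`` column; joined onto the CC
        rows by file name.
    threshold : int or "auto"
        Passed to :func:`cc_from_image_file` per image.

    Returns
    -------
    DataFrame
        Columns ``image_path, threshold, n_canopy, n_total, cc`` plus any
        metadata columns.
    """
    if isinstance(images, (str, os.PathLike)):
        root = Path(images)
        if not root.is_dir():
            raise NotADirectoryError(f"{root} is not a directory")
        paths: Iterable[Path] = sorted(
            p for p in root.iterdir()
            if p.suffix.lower() in {".jpg", ".jpeg", ".png"}
        )
    else:
        paths = [Path(p) for p in images]
    rows = [cc_from_image_file(p, threshold).to_dict() for p in paths]
    table = pd.DataFrame(
        rows, columns=["image_path", "threshold", "n_canopy", "n_total", "cc"]
    )
    if meta is not None:
        if "image_path" not in meta.columns:
            raise ValueError("metadata table must have an 'image_path' column")
        meta = meta.copy()
        # join on basename so the CSV may hold relative names
        table["_key"] = table["image_path"].map(lambda p: Path(p).name)
        meta["_key"] = meta["image_path"].map(lambda p: Path(str(p)).name)
        table = table.merge(
            meta.drop(columns=["image_path"]), on="_key", how="left"
        ).drop(columns=["_key"])
    return table
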