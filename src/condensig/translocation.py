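"""Adapter membrane-translocation scoring from edge-ring / core intensities.

Membrane localization of an RTK adapter (GRB2, SOS1) is the ratio of mean
fluorescence in a fixed-width ring just inside the cell boundary ("edge",
default 10 px) to the mean fluorescence of the remaining interior ("core").
Translocation is the change in membrane localization between a pre-stimulus
frame and a frame a fixed time after growth-factor addition (default 1.5 min
after EGF).  Because absolute translocation magnitudes vary with imaging
plane between acquisitions, suppression statistics are only meaningful for
cell groups imaged in the same field of view; the suppression summary takes
paired within-scene samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .puncta import LabeledImage


class TranslocationError(ValueError):
    pass


@dataclass
class RingPartition:
    """Exact partition of one cell mask into an edge ring and a core."""

    cell_id: int
    edge_mask: np.ndarray
    core_mask: np.ndarray
    ring_width_px: float

    @property
    def edge_pixels(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in zip(*np.nonzero(self.edge_mask))}

    @property
    def core_pixels(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in zip(*np.nonzero(self.core_mask))}


@dataclass
class TranslocationRecord:
    cell_id: int
    ml_pre: float
    ml_post: float
    translocation: float
    post_time_min: float = 1.5


def partition_ring(
    cell_mask: np.ndarray,
    ring_width_px: float = 10.0,
    cell_id: int = 0,
    metric: str = "euclidean",
) -> RingPartition:
    """Split a cell mask into an edge ring and the remaining core.

    The edge is the set of mask pixels whose distance to the mask complement
    is at most ``ring_width_px`` (Euclidean by default; ``metric="chebyshev"``
    uses the chessboard distance).  Equivalent to eroding the mask by a disk
    of the ring-width radius to obtain the core.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if ring_width_px <= 0:
        raise TranslocationError("ring width must be positive")
    if not cell_mask.any():
        raise TranslocationError("empty cell mask")
    if metric == "euclidean":
        dist = ndimage.distance_transform_edt(cell_mask)
    elif metric == "chebyshev":
        dist = ndimage.distance_transform_cdt(cell_mask, metric="chessboard")
    else:
        raise TranslocationError(f"unknown metric {metric!r}")
    edge = cell_mask & (dist <= ring_width_px)
    core = cell_mask & ~edge
    if not core.any():
        raise TranslocationError(
            "ring width leaves no core pixels: cell too small for requested ring"
        )
    return RingPartition(
        cell_id=cell_id, edge_mask=edge, core_mask=core, ring_width_px=ring_width_px
    )


def membrane_localization(intensity: np.ndarray, part: RingPartition) -> float:
    """Mean edge fluorescence divided by mean core fluorescence."""
    intensity = np.asarray(intensity, dtype=float)
    core_mean = float(intensity[part.core_mask].mean())
    if core_mean <= 0:
        raise TranslocationError("core mean must be positive")
    return float(intensity[part.edge_mask].mean()) / core_mean


def translocation(
    pre: np.ndarray,
    post: np.ndarray,
    part: RingPartition,
    post_time_min: float = 1.5,
) -> TranslocationRecord:
    """Change in membrane localization from pre- to post-stimulation frame."""
    ml_pre = membrane_localization(pre, part)
    ml_post = membrane_localization(post, part)
    return TranslocationRecord(
        cell_id=part.cell_id,
        ml_pre=ml_pre,
        ml_post=ml_post,
        translocation=ml_post - ml_pre,
        post_time_min=post_time_min,
    )


def translocation_table(
    pre_img: LabeledImage,
    post_img: LabeledImage,
    ring_width_px: float = 10.0,
    post_time_min: float = 1.5,
) -> pd.DataFrame:
    """Per-cell translocation for every cell of a pre/post image pair.

    Both images must share one label mask (same scene, same segmentation).
    """
    if not np.array_equal(pre_img.labels, post_img.labels):
        raise TranslocationError("pre and post images must share a label mask")
    records = []
    for cell_id in pre_img.cell_ids():
        part = partition_ring(
            pre_img.cell_mask(cell_id), ring_width_px, cell_id=cell_id
        )
        rec = translocation(
            pre_img.intensity, post_img.intensity, part, post_time_min
        )
        records.append(
            {
                "cell_id": rec.cell_id,
                "ml_pre": rec.ml_pre,
                "ml_post": rec.ml_post,
                "translocation": rec.translocation,
            }
        )
    return pd.DataFrame(records, columns=["cell_id", "ml_pre", "ml_post", "translocation"])


def translocation_suppression(
    values_oncogene: np.ndarray,
    values_wt: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict:
    """Median translocation of oncogene-expressing cells as a fraction of
    untransfected (wt) cells from the same scene, and its complement.

    ``fraction = median(oncogene) / median(wt)``; ``suppression = 1 - fraction``.
    Bootstrap quartiles (1st/3rd of ``n_boot`` resampled fractions) quantify
    uncertainty; both inputs must come from the same field of view because
    absolute magnitudes are not comparable across acquisitions.
    """
    a = np.asarray(values_oncogene, dtype=float)
    b = np.asarray(values_wt, dtype=float)
    if a.size == 0 or b.size == 0:
        raise TranslocationError("both groups must be nonempty")
    med_wt = float(np.median(b))
    if med_wt == 0:
        raise TranslocationError("wt median translocation is zero")
    fraction = float(np.median(a)) / med_wt
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, a.size, size=(n_boot, a.size))
    ib = rng.integers(0, b.size, size=(n_boot, b.size))
    boot_wt = np.median(b[ib], axis=1)
    boot_frac = np.where(
        boot_wt != 0, np.median(a[ia], axis=1) / np.where(boot_wt == 0, 1, boot_wt), np.nan
    )
    q1, q2, q3 = np.nanpercentile(boot_frac, [25, 50, 75])
    return {
        "fraction": fraction,
        "suppression": 1.0 - fraction,
        "fraction_quartiles": (float(q1), float(q2), float(q3)),
        "suppression_quartiles": (1.0 - float(q3), 1.0 - float(q2), 1.0 - float(q1)),
        "n_boot": n_boot,
        "seed": seed,
    }
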