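"""Mitotic chromatin-enrichment scoring from two-channel live-cell images.

A mitotic cell is imaged in two registered channels: an H2B marker that
labels the condensed chromatin, and the HaloTag-TF channel.  The enrichment
score is

    score = log2(mean TF intensity over chromatin / mean TF intensity over the whole cell)

so a TF that coats mitotic chromosomes scores well above 0, a uniformly
distributed TF scores 0, and an excluded TF scores below 0.  Segmentation is
automatic (Otsu thresholds on smoothed channels), with a CSV-ROI import path
for hand-drawn masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import filters, measure, morphology

logger = logging.getLogger(__name__)

__all__ = [
    "RegionMasks",
    "EnrichmentScore",
    "SegmentationError",
    "UndefinedScoreError",
    "segment_masks",
    "enrichment_score",
    "compare_constructs",
]


class SegmentationError(RuntimeError):
    """Segmentation produced an empty cell or chromatin mask."""


class UndefinedScoreError(ValueError):
    """A region mean was non-positive after background subtraction."""


@dataclass
class RegionMasks:
    chromatin: np.ndarray  # bool
    cell: np.ndarray  # bool

    def __post_init__(self) -> None:
        if self.chromatin.shape != self.cell.shape:
            raise ValueError("mask shapes differ")
        if not self.chromatin.any() or not self.cell.any():
            raise SegmentationError("empty mask")
        if np.any(self.chromatin & ~self.cell):
            raise ValueError("chromatin mask must lie inside the cell mask")


@dataclass(frozen=True)
class EnrichmentScore:
    score: float  # log2(chromatin mean / cell mean)
    chromatin_mean: float
    cell_mean: float
    cell_id: str = ""
    construct: str = ""
    replicate_id: str = ""


def segment_masks(
    h2b: np.ndarray,
    halo: np.ndarray,
    *,
    smooth_sigma: float = 2.0,
    min_area: int = 64,
) -> RegionMasks:
    """Automatic whole-cell and chromatin masks.

    The whole-cell mask is the largest connected component above the lowest
    of a three-class multi-Otsu threshold on the smoothed channel sum (three
    classes because a mitotic cell has three intensity populations:
    background, cytoplasm, chromatin); the chromatin mask is an Otsu
    threshold on the smoothed H2B channel restricted to the cell mask.  Both
    are hole-filled and cleaned of specks smaller than ``min_area`` pixels.
    """
    h2b = np.asarray(h2b, dtype=float)
    halo = np.asarray(halo, dtype=float)
    if h2b.shape != halo.shape:
        raise ValueError("channel shapes differ")
    combined = filters.gaussian(h2b + halo, sigma=smooth_sigma, preserve_range=True)
    if combined.max() == combined.min():
        raise SegmentationError("blank image: no intensity contrast to segment")
    try:
        t_low = filters.threshold_multiotsu(combined, classes=3)[0]
    except ValueError:  # too few distinct intensities for 3 classes
        t_low = filters.threshold_otsu(combined)
    cell = combined > t_low
    labels = measure.label(cell)
    if labels.max() == 0:
        raise SegmentationError("no cell found above the background threshold")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    cell = morphology.remove_small_objects(labels == largest, max_size=min_area)
    cell = morphology.remove_small_holes(cell, max_size=min_area)
    if not cell.any():
        raise SegmentationError("cell mask empty after cleaning")

    h2b_s = filters.gaussian(h2b, sigma=smooth_sigma, preserve_range=True)
    inside = h2b_s[cell]
    if inside.max() == inside.min():
        raise SegmentationError("no H2B contrast inside the cell")
    chromatin = np.zeros_like(cell)
    chromatin[cell] = inside > filters.threshold_otsu(inside)
    chromatin = morphology.remove_small_objects(chromatin, max_size=min_area)
    chromatin = morphology.remove_small_holes(chromatin, max_size=min_area)
    chromatin &= cell
    if not chromatin.any():
        raise SegmentationError("chromatin mask empty after cleaning")
    return RegionMasks(chromatin=chromatin, cell=cell)


def _image_mode(image: np.ndarray) -> float:
    """Intensity mode from a 256-bin histogram (background estimate)."""
    hist, edges = np.histogram(image, bins=256)
    i = int(np.argmax(hist))
    return float(0.5 * (edges[i] + edges[i + 1]))


def enrichment_score(
    halo: np.ndarray,
    masks: RegionMasks,
    *,
    background: float | str | None = None,
    cell_id: str = "",
    construct: str = "",
    replicate_id: str = "",
) -> EnrichmentScore:
    """log2 of the chromatin-region mean over the whole-cell mean.

    ``background`` may be None (no subtraction, the default), a number, or
    ``'mode'`` to subtract the image's histogram mode — useful when the
    camera offset is large relative to the signal.  Non-positive region means
    after subtraction raise :class:`UndefinedScoreError`.
    """
    halo = np.asarray(halo, dtype=float)
    if background == "mode":
        bg = _image_mode(halo)
    elif background is None:
        bg = 0.0
    else:
        bg = float(background)
    chrom_mean = float(halo[masks.chromatin].mean()) - bg
    cell_mean = float(halo[masks.cell].mean()) - bg
    if chrom_mean <= 0 or cell_mean <= 0:
        raise UndefinedScoreError(
            f"non-positive region mean after background subtraction "
            f"(chromatin {chrom_mean:.3g}, cell {cell_mean:.3g}, background {bg:.3g})"
        )
    return EnrichmentScore(
        score=float(np.log2(chrom_mean / cell_mean)),
        chromatin_mean=chrom_mean,
        cell_mean=cell_mean,
        cell_id=cell_id,
        construct=construct,
        replicate_id=replicate_id,
    )


def masks_from_roi_table(roi: pd.DataFrame, shape: tuple[int, int]) -> RegionMasks:
    """Build masks from a CSV ROI table with columns ``region`` ('cell' or
    'chromatin'), ``row``, ``col`` — one pixel per row, as exported from
    hand-drawn regions."""
    cell = np.zeros(shape, dtype=bool)
    chromatin = np.zeros(shape, dtype=bool)
    for region, mask in (("cell", cell), ("chromatin", chromatin)):
        sub = roi[roi["region"] == region]
        mask[sub["row"].to_numpy(int), sub["col"].to_numpy(int)] = True
    cell |= chromatin
    return RegionMasks(chromatin=chromatin, cell=cell)


def compare_constructs(
    scores: pd.DataFrame,
    *,
    equal_var: bool = True,
) -> dict:
    """Compare enrichment scores between constructs on replicate averages.

    ``scores`` needs columns ``construct``, ``replicate_id``, ``score`` (one
    row per cell).  Each biological replicate is averaged first and the
    two-tailed t-test runs on those replicate means, never on the per-cell
    technical replicates.  Returns a dict with the per-replicate mean table,
    the per-construct summary, and a pairwise p-value table (None entries
    when a construct has a single replicate).
    """
    required = {"construct", "replicate_id", "score"}
    if not required <= set(scores.columns):
        raise ValueError(f"scores table needs columns {sorted(required)}")
    rep_means = (
        scores.groupby(["construct", "replicate_id"])["score"].mean().reset_index()
    )
    summary = rep_means.groupby("construct")["score"].agg(["mean", "sem", "count"])

    constructs = sorted(summary.index)
    pvals = pd.DataFrame(index=constructs, columns=constructs, dtype=object)
    for i, a in enumerate(constructs):
        for b in constructs[i + 1 :]:
            xa = rep_means.loc[rep_means["construct"] == a, "score"]
            xb = rep_means.loc[rep_means["construct"] == b, "score"]
            if len(xa) >= 2 and len(xb) >= 2:
                _, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
                pvals.loc[a, b] = pvals.loc[b, a] = float(p)
            else:
                pvals.loc[a, b] = pvals.loc[b, a] = None
                logger.warning("construct %s vs %s: <2 replicates, t-test unavailable", a, b)
    return {"replicate_means": rep_means, "summary": summary, "p_values": pvals}
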