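"""Per-nucleus dsRNA quantification from two-channel fields.

Reimplements the standard FIJI-style measurement chain: nuclei are masked by
thresholding the DAPI channel after background subtraction and Gaussian blur;
the mask is applied to the dsRNA channel to measure per-nucleus area, min, max
and mean intensity (the mean nuclear fluorescence intensity, MNFI); a nucleus
is called dsRNA-positive when its MNFI exceeds the uninfected-control mean by
``k`` control standard deviations (default k = 4).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import filters, measure, segmentation

from .stats import rank_sum_test


@dataclass(frozen=True)
class NucleusRecord:
    nucleus_id: int
    field_id: str
    area: int
    min_intensity: float
    max_intensity: float
    mean_intensity: float  # MNFI
    positive: bool | None = None

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("nucleus area must be positive")
        if not self.min_intensity <= self.mean_intensity <= self.max_intensity:
            raise ValueError("min <= mean <= max violated")


@dataclass(frozen=True)
class PositivityThreshold:
    control_mean: float
    control_sd: float
    k: float
    n_control: int

    @property
    def threshold(self) -> float:
        return self.control_mean + self.k * self.control_sd


def segment_nuclei(
    dapi: np.ndarray,
    blur_sigma: float = 2.0,
    background_sigma: float = 50.0,
    min_area: int = 100,
) -> np.ndarray:
    """Label nuclei in a DAPI raster.

    A large-sigma Gaussian of the image estimates the smooth background, which
    is subtracted and clipped at zero; the result is blurred, thresholded by
    Otsu's method, connected components (8-connectivity) are labeled, and
    objects below ``min_area`` or touching the image border are discarded.
    Both steps are linear-plus-threshold, so the result is invariant to adding
    a constant offset to the whole image.
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got {dapi.ndim}-D")
    background = filters.gaussian(dapi, sigma=background_sigma, preserve_range=True)
    sub = np.clip(dapi - background, 0.0, None)
    blurred = filters.gaussian(sub, sigma=blur_sigma, preserve_range=True)
    if blurred.max() == blurred.min():
        return np.zeros(dapi.shape, dtype=int)
    mask = blurred > filters.threshold_otsu(blurred)
    labels = measure.label(mask, connectivity=2)
    labels = segmentation.clear_border(labels)
    out = np.zeros_like(labels)
    next_label = 1
    for prop in measure.regionprops(labels):
        if prop.area >= min_area:
            out[labels == prop.label] = next_label
            next_label += 1
    return out


def measure_nuclei(mask: np.ndarray, dsrna: np.ndarray, field_id: str = "") -> list[NucleusRecord]:
    """Apply a labeled nuclear mask to the dsRNA channel."""
    if mask.shape != dsrna.shape:
        raise ValueError("mask and dsRNA raster must have the same shape")
    records = []
    for prop in measure.regionprops(mask, intensity_image=np.asarray(dsrna, dtype=float)):
        records.append(
            NucleusRecord(
                nucleus_id=int(prop.label),
                field_id=field_id,
                area=int(prop.area),
                min_intensity=float(prop.intensity_min),
                max_intensity=float(prop.intensity_max),
                mean_intensity=float(prop.intensity_mean),
            )
        )
    return records


def classify_positive(
    records: Sequence[NucleusRecord],
    control: Sequence[NucleusRecord],
    k: float = 4.0,
) -> tuple[PositivityThreshold, list[NucleusRecord], float]:
    """Flag nuclei whose MNFI strictly exceeds control mean + k * control SD.

    The control SD is the sample standard deviation (n − 1 denominator), so at
    least two control nuclei are required.  Returns the threshold, the flagged
    records, and the percentage of positive nuclei.
    """
    if len(control) < 2:
        raise ValueError("need >= 2 control nuclei to estimate the SD")
    mnfi = np.array([r.mean_intensity for r in control], dtype=float)
    thr = PositivityThreshold(
        control_mean=float(mnfi.mean()),
        control_sd=float(mnfi.std(ddof=1)),
        k=float(k),
        n_control=len(control),
    )
    flagged = [
        NucleusRecord(
            nucleus_id=r.nucleus_id,
            field_id=r.field_id,
            area=r.area,
            min_intensity=r.min_intensity,
            max_intensity=r.max_intensity,
            mean_intensity=r.mean_intensity,
            positive=r.mean_intensity > thr.threshold,
        )
        for r in records
    ]
    pct = 100.0 * sum(r.positive for r in flagged) / len(flagged) if flagged else 0.0
    return thr, flagged, pct


def quantify_image_set(
    fields: Iterable,
    blur_sigma: float = 2.0,
    background_sigma: float = 50.0,
    min_area: int = 100,
) -> list[NucleusRecord]:
    """Segment and measure every field of an :class:`~advdsrna.sim_images.ImageSet`."""
    records: list[NucleusRecord] = []
    for f in fields:
        mask = segment_nuclei(f.dapi, blur_sigma, background_sigma, min_area)
        records.extend(measure_nuclei(mask, f.dsrna, field_id=f.field_id))
    return records


def summarize_conditions(
    records_by_condition: Mapping[str, Sequence[NucleusRecord]],
    control: Sequence[NucleusRecord],
    k: float = 4.0,
    comparisons: Sequence[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, PositivityThreshold]:
    """Condition-level summary: n cells, % positive, MNFI stats of positives.

    The mean/SD of MNFI *among positive nuclei* matches the red error bars of
    the per-cell dot plots; pairwise rank-sum tests compare full MNFI
    distributions between conditions (all pairs unless ``comparisons`` given).
    """
    if not records_by_condition:
        raise ValueError("need at least one condition")
    thr: PositivityThreshold | None = None
    rows = []
    flagged_by_cond: dict[str, list[NucleusRecord]] = {}
    for cond, recs in records_by_condition.items():
        thr, flagged, pct = classify_positive(recs, control, k=k)
        flagged_by_cond[cond] = flagged
        pos = [r.mean_intensity for r in flagged if r.positive]
        rows.append(
            {
                "condition": cond,
                "n_cells": len(flagged),
                "pct_positive": pct,
                "mean_mnfi_positive": float(np.mean(pos)) if pos else float("nan"),
                "sd_mnfi_positive": float(np.std(pos, ddof=1)) if len(pos) > 1 else float("nan"),
            }
        )
    summary = pd.DataFrame(rows)

    pairs = comparisons or list(combinations(sorted(records_by_condition), 2))
    comp_rows = []
    for ca, cb in pairs:
        va = [r.mean_intensity for r in records_by_condition[ca]]
        vb = [r.mean_intensity for r in records_by_condition[cb]]
        res = rank_sum_test(va, vb)
        comp_rows.append(
            {
                "condition_a": ca,
                "condition_b": cb,
                "u": res.u,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    comp = pd.DataFrame(
        comp_rows, columns=["condition_a", "condition_b", "u", "p_value", "method"]
    )
    assert thr is not None
    return summary, comp, thr
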