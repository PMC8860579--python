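"""Synthetic two-channel microscopy fields for the MNFI classifier.

Each field is a pair of equal-shape rasters: a DAPI channel with bright,
non-touching nuclear disks on a dark background, and a dsRNA channel that is
baseline Gaussian noise everywhere plus a fixed intensity shift inside the
nuclei flagged dsRNA-positive.  Ground truth (center, radius, positive flag per
nucleus) is retained so classifier recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FieldImage:
    field_id: str
    dapi: np.ndarray
    dsrna: np.ndarray
    ground_truth: pd.DataFrame  # nucleus_id, cy, cx, radius, positive

    def __post_init__(self) -> None:
        if self.dapi.shape != self.dsrna.shape:
            raise ValueError("channels must have the same shape")
        if (self.dapi < 0).any() or (self.dsrna < 0).any():
            raise ValueError("intensities must be nonnegative")


@dataclass
class ImageSet:
    fields: list[FieldImage]

    @property
    def ground_truth(self) -> pd.DataFrame:
        frames = []
        for f in self.fields:
            df = f.ground_truth.copy()
            df.insert(0, "field_id", f.field_id)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    @property
    def true_positive_fraction(self) -> float:
        gt = self.ground_truth
        return float(gt["positive"].mean()) if len(gt) else float("nan")


def _place_disks(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    radius_range: tuple[int, int],
    margin: int,
    max_tries: int,
) -> list[tuple[int, int, int]]:
    placed: list[tuple[int, int, int]] = []
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n} non-touching nuclei in {shape} "
                f"after {max_tries} tries"
            )
        tries += 1
        r = int(rng.integers(radius_range[0], radius_range[1] + 1))
        cy = int(rng.integers(r + margin, shape[0] - r - margin))
        cx = int(rng.integers(r + margin, shape[1] - r - margin))
        if all(
            (cy - py) ** 2 + (cx - px) ** 2 >= (r + pr + margin) ** 2
            for py, px, pr in placed
        ):
            placed.append((cy, cx, r))
    return placed


def simulate_images(
    n_fields: int,
    cells_per_field: int,
    frac_positive: float,
    mean_shift: float,
    noise_sd: float,
    seed: int,
    field_shape: tuple[int, int] = (512, 512),
    radius_range: tuple[int, int] = (12, 18),
    dapi_intensity: float = 3000.0,
    dsrna_baseline: float = 100.0,
    margin: int = 6,
    max_tries: int = 20_000,
) -> ImageSet:
    """Simulate ``n_fields`` two-channel fields with known per-nucleus truth.

    Exactly ``round(frac_positive * total_cells)`` nuclei over the whole set are
    flagged positive (assigned at random), so the realized positive fraction
    matches the requested one up to rounding.
    """
    if not 0.0 <= frac_positive <= 1.0:
        raise ValueError("frac_positive must be in [0,1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xD5])

    total = n_fields * cells_per_field
    n_pos = int(round(frac_positive * total))
    flags = np.zeros(total, dtype=bool)
    flags[rng.choice(total, size=n_pos, replace=False)] = True

    yy, xx = np.mgrid[0 : field_shape[0], 0 : field_shape[1]]
    fields: list[FieldImage] = []
    k = 0
    for fi in range(n_fields):
        disks = _place_disks(rng, field_shape, cells_per_field, radius_range, margin, max_tries)
        dapi = np.zeros(field_shape, dtype=float)
        dsrna = np.full(field_shape, dsrna_baseline, dtype=float)
        if noise_sd > 0:
            dsrna += rng.normal(0.0, noise_sd, size=field_shape)
        rows = []
        for ni, (cy, cx, r) in enumerate(disks):
            inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            dapi[inside] = dapi_intensity
            positive = bool(flags[k])
            if positive:
                dsrna = np.where(inside, dsrna + mean_shift, dsrna)
            rows.append(
                {"nucleus_id": ni, "cy": cy, "cx": cx, "radius": r, "positive": positive}
            )
            k += 1
        if noise_sd > 0:
            dapi = dapi + rng.normal(0.0, noise_sd, size=field_shape)
        fields.append(
            FieldImage(
                field_id=f"field{fi:03d}",
                dapi=np.clip(dapi, 0.0, None),
                dsrna=np.clip(np.asarray(dsrna, dtype=float), 0.0, None),
                ground_truth=pd.DataFrame(
                    rows, columns=["nucleus_id", "cy", "cx", "radius", "positive"]
                ),
            )
        )
    return ImageSet(fields=fields)
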