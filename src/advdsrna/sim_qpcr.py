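"""Synthetic Ct tables with known ground-truth abundances.

The generative model is the standard exponential-amplification idealization:
Ct = base_ct − log2(relative abundance) + Gaussian technical noise, so a 2x
more abundant template crosses the detection threshold exactly one cycle
earlier when noise is zero.  Ground-truth abundances (and hence fold changes)
are returned alongside the table so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qpcr import CT_COLUMNS


@dataclass(frozen=True)
class CtDesignRow:
    """True state of one (condition, target, fraction): relative abundance."""

    condition: str
    target: str
    abundance: float
    fraction: str = "total"  # total | input | ip

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")


def simulate_ct_table(
    design: list[CtDesignRow],
    seed: int,
    noise_sd: float = 0.15,
    base_ct: float = 30.0,
    technical_reps: int = 3,
    n_samples: int = 1,
    input_fraction: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a Ct table from ground-truth abundances.

    ``input_fraction`` (when given) dilutes rows with ``fraction == 'input'``,
    raising their Ct by log2(1/input_fraction) — emulating the 1%-input
    aliquot of an immunoprecipitation experiment.  Returns ``(ct_table,
    ground_truth)``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xC7])
    rows = []
    for d in design:
        true_ct = base_ct - float(np.log2(d.abundance))
        if input_fraction is not None and d.fraction == "input":
            true_ct += float(np.log2(1.0 / input_fraction))
        for s in range(n_samples):
            for r in range(technical_reps):
                noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
                rows.append(
                    {
                        "sample_id": f"{d.condition}_s{s}",
                        "condition": d.condition,
                        "target": d.target,
                        "fraction": d.fraction,
                        "ct": true_ct + noise,
                        "technical_rep": r,
                    }
                )
    table = pd.DataFrame(rows, columns=CT_COLUMNS)
    truth = pd.DataFrame(
        [
            {
                "condition": d.condition,
                "target": d.target,
                "fraction": d.fraction,
                "abundance": d.abundance,
            }
            for d in design
        ]
    )
    return table, truth


def fig6e_like_design(
    enrich_unspliced_mutant: float = 20.0,
    background_recovery: float = 0.01,
) -> list[CtDesignRow]:
    """An IP design with the structure of the RIP-qPCR experiment: unspliced
    viral targets strongly IP-enriched in the poorly splicing (mutant)
    condition only; housekeeping negatives recovered at background in both."""
    rows: list[CtDesignRow] = []
    for cond, mutant in (("WT", False), ("dE4", True)):
        for target in (
            "E1A_spliced",
            "E1A_unspliced",
            "TPL_spliced",
            "TPL_unspliced",
            "fiber_spliced",
            "fiber_unspliced",
            "HPRT1",
            "GAPDH",
        ):
            host = target in ("HPRT1", "GAPDH")
            unspliced = target.endswith("_unspliced")
            rows.append(CtDesignRow(cond, target, 1.0, fraction="input"))
            if host or not mutant:
                recovery = background_recovery  # no dsRNA in WT; host stays at background
            elif unspliced:
                recovery = background_recovery * enrich_unspliced_mutant
            else:  # spliced viral RNA in the mutant: above threshold, below unspliced
                recovery = background_recovery * 4.0
            rows.append(CtDesignRow(cond, target, recovery, fraction="ip"))
    return rows
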