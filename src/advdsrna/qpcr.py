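"""qPCR-derived statistics: ΔΔCt, splicing efficiency, percent-of-input.

Conventions: amplification efficiency is fixed at 2 per cycle (standard ΔΔCt);
technical replicates are averaged on the Ct scale before any Δ computation;
the 1%-input dilution is corrected on the Ct scale by subtracting
log2(1/input_fraction) from the input Ct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

CT_COLUMNS = ["sample_id", "condition", "target", "fraction", "ct", "technical_rep"]


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    ct = table["ct"]
    if not np.isfinite(ct).all() or (ct <= 0).any():
        raise ValueError("Ct values must be finite and > 0")
    key = ["sample_id", "target", "fraction", "technical_rep"]
    if table.duplicated(subset=key).any():
        raise ValueError("duplicate (sample, target, fraction, technical_rep) rows")
    return table


def ddct(
    table: pd.DataFrame,
    targets: Sequence[str],
    reference_genes: Sequence[str],
    calibrator_condition: str,
) -> pd.DataFrame:
    """Relative expression by the ΔΔCt method.

    Per condition: technical replicates are averaged per (sample, target),
    samples averaged per condition; ΔCt = Ct_target − mean over reference
    genes; ΔΔCt is taken against the calibrator condition; relative expression
    is 2^(−ΔΔCt), so the calibrator reports 1 for every target.
    """
    table = validate_ct_table(table)
    if not reference_genes:
        raise ValueError("need at least one reference gene")
    # technical reps -> sample-level Ct, then condition-level Ct
    sample_ct = (
        table.groupby(["condition", "sample_id", "target"], as_index=False)["ct"].mean()
    )
    cond_ct = sample_ct.groupby(["condition", "target"])["ct"].mean()

    conditions = sorted(table["condition"].unique())
    if calibrator_condition not in conditions:
        raise ValueError(f"calibrator condition {calibrator_condition!r} absent from table")
    ref_mean: dict[str, float] = {}
    for cond in conditions:
        refs = []
        for g in reference_genes:
            if (cond, g) not in cond_ct.index:
                raise ValueError(f"reference gene {g!r} missing for condition {cond!r}")
            refs.append(cond_ct[(cond, g)])
        ref_mean[cond] = float(np.mean(refs))

    rows = []
    for target in targets:
        d_cal = None
        per_cond = {}
        for cond in conditions:
            if (cond, target) not in cond_ct.index:
                continue
            per_cond[cond] = float(cond_ct[(cond, target)]) - ref_mean[cond]
        if calibrator_condition not in per_cond:
            raise ValueError(f"target {target!r} missing for calibrator condition")
        d_cal = per_cond[calibrator_condition]
        for cond, dct in per_cond.items():
            dd = dct - d_cal
            rows.append(
                {
                    "condition": cond,
                    "target": target,
                    "delta_ct": dct,
                    "delta_delta_ct": dd,
                    "rel_expression": float(2.0 ** (-dd)),
                }
            )
    return pd.DataFrame(rows, columns=["condition", "target", "delta_ct", "delta_delta_ct", "rel_expression"])


@dataclass(frozen=True)
class SplicingEfficiency:
    target: str
    condition: str
    spliced_rel: float
    unspliced_rel: float

    @property
    def efficiency(self) -> float:
        return self.spliced_rel / self.unspliced_rel


def splicing_efficiency(
    rel_spliced: float,
    rel_unspliced: float,
    target: str = "",
    condition: str = "",
) -> SplicingEfficiency:
    """Spliced/unspliced relative-expression ratio; the common calibrator cancels."""
    if rel_unspliced <= 0:
        raise ValueError("unspliced relative expression must be positive")
    if rel_spliced < 0:
        raise ValueError("spliced relative expression must be >= 0")
    return SplicingEfficiency(target, condition, float(rel_spliced), float(rel_unspliced))


@dataclass(frozen=True)
class PercentInputResult:
    target: str
    condition: str
    pct_input: float
    positive_threshold: float | None
    positive: bool | None


def percent_of_input(
    ct_ip: float,
    ct_input: float,
    input_fraction: float = 0.01,
    negative_controls: Sequence[float] | None = None,
    target: str = "",
    condition: str = "",
) -> PercentInputResult:
    """IP recovery as a percentage of the (dilution-adjusted) input RNA.

    The input Ct is shifted by −log2(1/input_fraction) to represent the
    undiluted input; percent of input = 100 × 2^(adjusted_input − ct_ip).  When
    negative-control percentages are given, the positivity threshold is twice
    their mean, and positivity requires strictly exceeding it.
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    adjusted_input = ct_input - float(np.log2(1.0 / input_fraction))
    pct = 100.0 * 2.0 ** (adjusted_input - ct_ip)
    threshold = positive = None
    if negative_controls is not None:
        if len(negative_controls) == 0:
            raise ValueError("negative_controls must be non-empty when given")
        threshold = 2.0 * float(np.mean(negative_controls))
        positive = pct > threshold
    return PercentInputResult(target, condition, float(pct), threshold, positive)


def percent_of_input_table(
    table: pd.DataFrame,
    targets: Sequence[str],
    negative_control_targets: Sequence[str],
    input_fraction: float = 0.01,
) -> pd.DataFrame:
    """Percent-of-input for every (condition, target) of an IP experiment.

    ``table`` must contain matched ``fraction == 'ip'`` and ``'input'`` rows.
    Negative-control percentages are computed per condition from the listed
    targets and set the 2x positivity threshold for that condition.
    """
    table = validate_ct_table(table)
    cond_ct = (
        table.groupby(["condition", "target", "fraction"])["ct"].mean()
    )

    def pct(cond: str, target: str) -> float:
        try:
            ct_ip = cond_ct[(cond, target, "ip")]
            ct_in = cond_ct[(cond, target, "input")]
        except KeyError as e:
            raise ValueError(f"missing ip/input Ct for ({cond!r}, {target!r})") from e
        return percent_of_input(ct_ip, ct_in, input_fraction).pct_input

    rows = []
    for cond in sorted(table["condition"].unique()):
        negs = [pct(cond, t) for t in negative_control_targets]
        threshold = 2.0 * float(np.mean(negs)) if negs else None
        for target in targets:
            p = pct(cond, target)
            rows.append(
                {
                    "condition": cond,
                    "target": target,
                    "pct_input": p,
                    "positive_threshold": threshold,
                    "positive": (p > threshold) if threshold is not None else None,
                }
            )
    return pd.DataFrame(
        rows, columns=["condition", "target", "pct_input", "positive_threshold", "positive"]
    )
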