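"""dsRNA-RIP-seq quantification.

Implements the quantification chain applied to strand-specific, UMI-tagged
alignments from matched input and J2-immunoprecipitated (IP) libraries:

* exact-key UMI deduplication,
* splice-junction extraction and reproducibility filtering (a junction is
  "real" only with >= 2 unique reads; for the cross-library panel, in every
  library),
* viral read fraction and IP/input dsRNA enrichment ratio,
* spliced-read percentage (viral reads carrying a reproducible junction),
* the per-junction splicing index: log2 fold change of normalized junction
  abundance between an IP library and its replicate-matched input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reads import (
    JUNCTION_COLUMNS,
    AlignedRead,
    Junction,
    JunctionTable,
    ReadLibrary,
    junction_key,
    read_junctions,
)
from .stats import rank_sum_test


def deduplicate_umis(lib: ReadLibrary) -> ReadLibrary:
    """Collapse reads sharing (UMI, reference, strand, block structure).

    One read is retained per distinct key — the lexicographically smallest
    ``read_id`` — making the operation deterministic and idempotent.  UMI
    collisions between genuinely different molecules at the same position are
    collapsed too, exactly as a position-aware deduplicator would.
    """
    best: dict[tuple, AlignedRead] = {}
    for read in lib.reads:
        if not read.umi:
            raise ValueError(f"read {read.read_id!r} has no UMI")
        key = (read.umi, read.reference, read.strand, read.blocks)
        cur = best.get(key)
        if cur is None or read.read_id < cur.read_id:
            best[key] = read
    kept = sorted(best.values(), key=lambda r: r.read_id)
    return replace(lib, reads=kept, deduplicated=True)


def extract_junctions(lib: ReadLibrary) -> JunctionTable:
    """Count unique deduplicated reads per splice junction for one library.

    Every inter-block gap of every read contributes one junction observation;
    the library's total deduplicated read count is recorded as the
    normalization denominator.
    """
    if not lib.deduplicated:
        raise ValueError(f"library {lib.library_id!r} must be deduplicated first")
    counts: dict[tuple, int] = {}
    for read in lib.reads:
        for j in read_junctions(read):
            k = junction_key(j)
            counts[k] = counts.get(k, 0) + 1
    rows = [
        {
            "library_id": lib.library_id,
            "reference": ref,
            "strand": strand,
            "donor": donor,
            "acceptor": acceptor,
            "unique_read_count": n,
        }
        for (ref, strand, donor, acceptor), n in sorted(counts.items())
    ]
    df = pd.DataFrame(rows, columns=JUNCTION_COLUMNS)
    return JunctionTable(counts=df, totals={lib.library_id: len(lib.reads)})


def filter_reproducible(
    table: JunctionTable,
    min_reads: int = 2,
    require_all_libraries: bool = False,
) -> dict[str, set[Junction]] | set[Junction]:
    """Reproducible-junction filter.

    Per-library mode (default): for each library, the set of junctions with at
    least ``min_reads`` unique reads *in that library* (used for the global
    spliced-read percentage).  Cross-library mode (``require_all_libraries``):
    the single set of junctions meeting the threshold in *every* library of the
    table (the panel for the splicing index).
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    df = table.counts
    kept = df[df["unique_read_count"] >= min_reads]
    per_lib: dict[str, set[Junction]] = {lib: set() for lib in table.totals}
    for row in kept.itertuples(index=False):
        per_lib[row.library_id].add(
            Junction(row.reference, row.strand, row.donor, row.acceptor)
        )
    if not require_all_libraries:
        return per_lib
    sets = list(per_lib.values())
    return set.intersection(*sets) if sets else set()


def viral_fraction(lib: ReadLibrary, viral_reference: str) -> float:
    """Percentage of (deduplicated) mapped reads on the viral genome."""
    if not lib.deduplicated:
        raise ValueError(f"library {lib.library_id!r} must be deduplicated first")
    if len(lib.reads) == 0:
        raise ValueError(f"library {lib.library_id!r} is empty")
    n_viral = sum(1 for r in lib.reads if r.reference == viral_reference)
    return 100.0 * n_viral / len(lib.reads)


def dsrna_enrichment(ip_pct: float, input_pct: float) -> float:
    """Fold change of the viral read percentage, IP over matched input.

    A ratio of 1 means the immunoprecipitation did not enrich viral RNA.
    """
    if input_pct <= 0:
        raise ValueError("input viral percentage must be positive")
    return ip_pct / input_pct


def spliced_read_fraction(
    lib: ReadLibrary,
    reproducible: set[Junction],
    viral_reference: str,
) -> float:
    """Percentage of viral reads carrying at least one reproducible junction."""
    if not lib.deduplicated:
        raise ValueError(f"library {lib.library_id!r} must be deduplicated first")
    viral = [r for r in lib.reads if r.reference == viral_reference]
    if not viral:
        raise ValueError(f"library {lib.library_id!r} has no viral reads")
    n_spliced = sum(
        1 for r in viral if any(j in reproducible for j in read_junctions(r))
    )
    return 100.0 * n_spliced / len(viral)


@dataclass
class SplicingIndexResult:
    """Per-junction IP-vs-input log2 fold changes and condition summaries."""

    per_replicate: pd.DataFrame  # condition, replicate, junction cols, log2fc
    per_junction: pd.DataFrame  # condition, junction cols, mean_log2fc (over reps)
    condition_summary: pd.DataFrame  # condition, n_junctions, mean, sd
    comparisons: pd.DataFrame  # condition_a, condition_b, u, p_value, method

    def condition_mean(self, condition: str) -> float:
        row = self.condition_summary.set_index("condition").loc[condition]
        return float(row["mean_log2fc"])


def splicing_index(
    table: JunctionTable,
    manifest: pd.DataFrame,
    panel: Sequence[Junction],
    pseudocount: float = 0.5,
) -> SplicingIndexResult:
    """Per-junction splicing index between IP and replicate-matched input.

    For junction *j*, condition *c*, replicate *r*::

        log2fc(j, c, r) = log2((rpm_ip(j) + pc) / (rpm_input(j) + pc))

    with rpm = unique reads per million total deduplicated reads of the
    library.  Per condition, replicates are averaged per junction first; the
    condition mean/SD is taken across the per-junction averages, and each pair
    of conditions is compared with a two-sided rank-sum test on those values.

    ``manifest`` needs columns ``library_id, condition, fraction, replicate``
    and must pair every (condition, replicate) IP library with an input one.
    """
    if not panel:
        raise ValueError("junction panel is empty")
    required = {"library_id", "condition", "fraction", "replicate"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")

    pairs: list[tuple[str, int, str, str]] = []  # condition, replicate, ip_id, input_id
    for (cond, rep), grp in manifest.groupby(["condition", "replicate"], sort=True):
        by_frac = grp.set_index("fraction")["library_id"]
        if "ip" not in by_frac.index or "input" not in by_frac.index:
            raise ValueError(f"unmatched replicate structure for ({cond}, {rep})")
        pairs.append((str(cond), int(rep), by_frac["ip"], by_frac["input"]))

    norm = table.normalized()
    rpm: dict[tuple, dict[str, float]] = {}
    for row in norm.itertuples(index=False):
        k = (row.reference, row.strand, row.donor, row.acceptor)
        rpm.setdefault(k, {})[row.library_id] = row.norm_abundance

    rows = []
    for j in panel:
        k = junction_key(j)
        per_lib = rpm.get(k, {})
        for cond, rep, ip_id, input_id in pairs:
            ip_rpm = per_lib.get(ip_id, 0.0)
            in_rpm = per_lib.get(input_id, 0.0)
            if pseudocount == 0 and (ip_rpm == 0 or in_rpm == 0):
                raise ValueError(
                    f"zero abundance for junction {k} with pseudocount 0; "
                    "use a cross-library reproducible panel or a pseudocount"
                )
            rows.append(
                {
                    "condition": cond,
                    "replicate": rep,
                    "reference": j.reference,
                    "strand": j.strand,
                    "donor": j.donor,
                    "acceptor": j.acceptor,
                    "ip_rpm": ip_rpm,
                    "input_rpm": in_rpm,
                    "log2fc": float(
                        np.log2((ip_rpm + pseudocount) / (in_rpm + pseudocount))
                    ),
                }
            )
    per_replicate = pd.DataFrame(rows)

    jcols = ["reference", "strand", "donor", "acceptor"]
    per_junction = (
        per_replicate.groupby(["condition"] + jcols, as_index=False)["log2fc"]
        .mean()
        .rename(columns={"log2fc": "mean_log2fc"})
    )
    condition_summary = (
        per_junction.groupby("condition")["mean_log2fc"]
        .agg(n_junctions="size", mean_log2fc="mean", sd_log2fc=lambda s: s.std(ddof=1))
        .reset_index()
    )

    comp_rows = []
    conds = sorted(per_junction["condition"].unique())
    for i, ca in enumerate(conds):
        for cb in conds[i + 1 :]:
            va = per_junction.loc[per_junction["condition"] == ca, "mean_log2fc"]
            vb = per_junction.loc[per_junction["condition"] == cb, "mean_log2fc"]
            res = rank_sum_test(va.to_numpy(), vb.to_numpy())
            comp_rows.append(
                {
                    "condition_a": ca,
                    "condition_b": cb,
                    "u": res.u,
                    "p_value": res.p_value,
                    "method": res.method,
                }
            )
    comparisons = pd.DataFrame(
        comp_rows, columns=["condition_a", "condition_b", "u", "p_value", "method"]
    )
    return SplicingIndexResult(per_replicate, per_junction, condition_summary, comparisons)


def library_summary(
    libs: Iterable[ReadLibrary],
    viral_reference: str,
    min_reads: int = 2,
) -> pd.DataFrame:
    """Per-library totals, viral %, and spliced % (per-library reproducible set)."""
    libs = list(libs)
    tables = [extract_junctions(lib) for lib in libs]
    combined = JunctionTable.concat(tables)
    per_lib_sets = filter_reproducible(combined, min_reads=min_reads)
    rows = []
    for lib in libs:
        vf = viral_fraction(lib, viral_reference)
        try:
            sf = spliced_read_fraction(lib, per_lib_sets[lib.library_id], viral_reference)
        except ValueError:
            sf = float("nan")
        rows.append(
            {
                "library_id": lib.library_id,
                "condition": lib.condition,
                "fraction": lib.fraction,
                "replicate": lib.replicate,
                "total_dedup_reads": len(lib.reads),
                "viral_pct": vf,
                "spliced_viral_pct": sf,
            }
        )
    return pd.DataFrame(rows)
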