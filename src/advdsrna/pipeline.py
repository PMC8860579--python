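"""End-to-end orchestration: simulate → quantify → report.

An experiment mirrors the RIP-seq study design: two conditions (an efficiently
splicing wildtype-like virus and a poorly splicing mutant-like virus), two
biological replicates each, and matched input/IP libraries — eight libraries
total.  Optional image and qPCR stages run the MNFI classifier and the
percent-of-input scoring on matched synthetic data.  Every stage writes its
artifacts to disk (SAM/GTF/BED/TSV) so the pipeline can be re-run stage by
stage from serialized files, and the whole run is a deterministic function of
the global seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io as aio
from .imaging import quantify_image_set, summarize_conditions
from .model import build_genome, predict_duplex_regions
from .qpcr import percent_of_input_table
from .reads import JunctionTable
from .ripseq import (
    deduplicate_umis,
    dsrna_enrichment,
    extract_junctions,
    filter_reproducible,
    splicing_index,
    spliced_read_fraction,
    viral_fraction,
)
from .sim_images import simulate_images
from .sim_qpcr import fig6e_like_design, simulate_ct_table
from .sim_reads import SimConfig, simulate_input_library, simulate_ip_library

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConditionSpec:
    """Ground-truth regime of one infection condition."""

    name: str
    splice_eff: float  # every intron's removal probability
    ip_duplex_capture: float  # antibody capture of duplex-engaged molecules
    frac_positive_nuclei: float = 0.0  # for the image stage


#: background (non-duplex) capture rate of the IP; the WT-like condition uses
#: the same value for duplex-engaged molecules ("no capture beyond background")
DEFAULT_BACKGROUND_CAPTURE = 0.05

WT_LIKE = ConditionSpec("WT", splice_eff=0.95, ip_duplex_capture=DEFAULT_BACKGROUND_CAPTURE)
MUTANT_LIKE = ConditionSpec("dE4", splice_eff=0.35, ip_duplex_capture=0.8, frac_positive_nuclei=0.5)

SCENARIOS: dict[str, tuple[ConditionSpec, ...]] = {
    "wt_like": (WT_LIKE,),
    "mutant_like": (MUTANT_LIKE,),
    "paired": (WT_LIKE, MUTANT_LIKE),
}


@dataclass
class ExperimentConfig:
    scenario: str = "paired"  # wt_like | mutant_like | paired | custom
    seed: int = 0
    preset: str = "ad5_like"
    replicates: int = 2
    n_molecules: int = 40_000
    n_reads: int = 100_000
    host_fraction: float = 0.25
    read_length: int = 100
    umi_dup_rate: float = 0.05
    ip_background_capture: float = DEFAULT_BACKGROUND_CAPTURE
    rnase_overhang: int = 30
    readthrough_prob: float = 0.05
    min_reads: int = 2
    pseudocount: float = 0.5
    include_images: bool = True
    include_qpcr: bool = True
    mnfi_k: float = 4.0
    image_fields: int = 3
    image_cells_per_field: int = 25
    image_mean_shift: float = 400.0
    image_noise_sd: float = 30.0
    conditions: list[dict] = field(default_factory=list)  # custom scenario only

    def condition_specs(self) -> tuple[ConditionSpec, ...]:
        if self.scenario == "custom":
            if not self.conditions:
                raise ValueError("custom scenario needs explicit condition specs")
            return tuple(ConditionSpec(**c) for c in self.conditions)
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        return SCENARIOS[self.scenario]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    def sim_config(self, spec: ConditionSpec) -> SimConfig:
        return SimConfig(
            seed=self.seed,
            n_molecules=self.n_molecules,
            n_reads=self.n_reads,
            host_fraction=self.host_fraction,
            read_length=self.read_length,
            umi_dup_rate=self.umi_dup_rate,
            rnase_overhang=self.rnase_overhang,
            ip_background_capture=self.ip_background_capture,
            ip_duplex_capture=spec.ip_duplex_capture,
            replicates=self.replicates,
        )


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    library_summary: pd.DataFrame  # per-library totals, viral %, spliced %
    enrichment: pd.DataFrame  # per condition x replicate IP/input ratio
    splicing_index_summary: pd.DataFrame | None
    splicing_index_comparisons: pd.DataFrame | None
    mnfi_summary: pd.DataFrame | None
    qpcr_percent_input: pd.DataFrame | None
    n_panel_junctions: int = 0

    def headline(self) -> dict:
        """The report's key numbers as a flat JSON-serializable dict."""
        out: dict = {"n_panel_junctions": self.n_panel_junctions}
        for row in self.enrichment.itertuples(index=False):
            out[f"enrichment_{row.condition}_r{row.replicate}"] = row.enrichment
        for row in self.library_summary.itertuples(index=False):
            out[f"viral_pct_{row.library_id}"] = row.viral_pct
            out[f"spliced_pct_{row.library_id}"] = row.spliced_viral_pct
        if self.splicing_index_summary is not None:
            for row in self.splicing_index_summary.itertuples(index=False):
                out[f"mean_splicing_index_{row.condition}"] = row.mean_log2fc
        if self.splicing_index_comparisons is not None and len(self.splicing_index_comparisons):
            out["splicing_index_ranksum_p"] = float(
                self.splicing_index_comparisons["p_value"].iloc[0]
            )
        if self.mnfi_summary is not None:
            for row in self.mnfi_summary.itertuples(index=False):
                out[f"mnfi_pct_positive_{row.condition}"] = row.pct_positive
        return out


def run_experiment(config: ExperimentConfig, outdir: str | Path | None = None) -> ExperimentReport:
    """Execute the full simulate → quantify → report chain."""
    specs = config.condition_specs()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out / "run.log")
        fh.setLevel(logging.INFO)
        logging.getLogger("advdsrna").addHandler(fh)
        aio.write_yaml(config.to_dict(), out / "config.yaml")

    libs = []
    manifest_rows = []
    viral_ref = None
    for spec in specs:
        model = build_genome(
            config.preset,
            seed=config.seed,
            splice_eff=spec.splice_eff,
            readthrough_prob=config.readthrough_prob,
        )
        viral_ref = model.genome_id
        duplexes = predict_duplex_regions(model)
        cfg = config.sim_config(spec)
        if out is not None:
            aio.write_gtf(model, out / f"genome_{spec.name}.gtf")
            aio.write_duplex_bed(duplexes, model, out / f"duplex_regions_{spec.name}.bed")
        for rep in range(config.replicates):
            logger.info("simulating %s replicate %d (seed %d)", spec.name, rep, config.seed)
            input_lib, molecules = simulate_input_library(model, cfg, rep, condition=spec.name)
            ip_lib = simulate_ip_library(model, molecules, duplexes, cfg, rep, condition=spec.name)
            for lib in (input_lib, ip_lib):
                if out is not None:
                    aio.write_sam(lib, out / f"{lib.library_id}.sam", aio.sam_references(model, cfg))
                lib = deduplicate_umis(lib)
                libs.append(lib)
                manifest_rows.append(
                    {
                        "library_id": lib.library_id,
                        "condition": lib.condition,
                        "fraction": lib.fraction,
                        "replicate": lib.replicate,
                    }
                )
    manifest = pd.DataFrame(manifest_rows)

    tables = [extract_junctions(lib) for lib in libs]
    combined = JunctionTable.concat(tables)
    per_lib_sets = filter_reproducible(combined, min_reads=config.min_reads)
    panel_set = filter_reproducible(combined, min_reads=config.min_reads, require_all_libraries=True)
    panel = sorted(
        (j for j in panel_set if j.reference == viral_ref),
        key=lambda j: (j.donor, j.acceptor, j.strand),
    )

    rows = []
    for lib in libs:
        rows.append(
            {
                "library_id": lib.library_id,
                "condition": lib.condition,
                "fraction": lib.fraction,
                "replicate": lib.replicate,
                "total_dedup_reads": len(lib.reads),
                "viral_pct": viral_fraction(lib, viral_ref),
                "spliced_viral_pct": spliced_read_fraction(
                    lib, per_lib_sets[lib.library_id], viral_ref
                ),
            }
        )
    lib_summary = pd.DataFrame(rows)

    enr_rows = []
    for (cond, rep), grp in lib_summary.groupby(["condition", "replicate"]):
        by_frac = grp.set_index("fraction")["viral_pct"]
        enr_rows.append(
            {
                "condition": cond,
                "replicate": rep,
                "input_viral_pct": float(by_frac["input"]),
                "ip_viral_pct": float(by_frac["ip"]),
                "enrichment": dsrna_enrichment(float(by_frac["ip"]), float(by_frac["input"])),
            }
        )
    enrichment = pd.DataFrame(enr_rows)

    si_summary = si_comp = None
    if panel:
        si = splicing_index(combined, manifest, panel, pseudocount=config.pseudocount)
        si_summary, si_comp = si.condition_summary, si.comparisons
        if out is not None:
            aio.write_tsv(si.per_replicate, out / "splicing_index_per_replicate.tsv")
            aio.write_tsv(si.per_junction, out / "splicing_index_per_junction.tsv")

    mnfi_summary = None
    if config.include_images:
        control_set = simulate_images(
            config.image_fields,
            config.image_cells_per_field,
            frac_positive=0.0,
            mean_shift=config.image_mean_shift,
            noise_sd=config.image_noise_sd,
            seed=config.seed * 7 + 1,
        )
        control = quantify_image_set(control_set.fields)
        by_cond = {}
        for i, spec in enumerate(specs):
            img = simulate_images(
                config.image_fields,
                config.image_cells_per_field,
                frac_positive=spec.frac_positive_nuclei,
                mean_shift=config.image_mean_shift,
                noise_sd=config.image_noise_sd,
                seed=config.seed * 7 + 2 + i,
            )
            by_cond[spec.name] = quantify_image_set(img.fields)
        mnfi_summary, mnfi_comp, _ = summarize_conditions(by_cond, control, k=config.mnfi_k)
        if out is not None:
            aio.write_tsv(mnfi_comp, out / "mnfi_comparisons.tsv")

    qpcr_table = None
    if config.include_qpcr:
        ct, _truth = simulate_ct_table(
            fig6e_like_design(), seed=config.seed * 7 + 11, input_fraction=0.01
        )
        targets = sorted(t for t in ct["target"].unique() if t not in ("HPRT1", "GAPDH"))
        qpcr_table = percent_of_input_table(
            ct, targets=targets, negative_control_targets=["HPRT1", "GAPDH"], input_fraction=0.01
        )

    report = ExperimentReport(
        config=config,
        library_summary=lib_summary,
        enrichment=enrichment,
        splicing_index_summary=si_summary,
        splicing_index_comparisons=si_comp,
        mnfi_summary=mnfi_summary,
        qpcr_percent_input=qpcr_table,
        n_panel_junctions=len(panel),
    )

    if out is not None:
        aio.write_tsv(lib_summary, out / "library_summary.tsv")
        aio.write_tsv(enrichment, out / "enrichment.tsv")
        aio.write_junction_bed(combined.counts, out / "junctions.bed")
        if si_summary is not None:
            aio.write_tsv(si_summary, out / "splicing_index_summary.tsv")
            aio.write_tsv(si_comp, out / "splicing_index_comparisons.tsv")
        if mnfi_summary is not None:
            aio.write_tsv(mnfi_summary, out / "mnfi_summary.tsv")
        if qpcr_table is not None:
            aio.write_tsv(qpcr_table, out / "qpcr_percent_input.tsv")
        (out / "report.json").write_text(json.dumps(report.headline(), indent=2, sort_keys=True))
    return report


def file_checksums(directory: str | Path, patterns: tuple[str, ...] = ("*.sam", "*.tsv", "*.bed", "*.gtf", "*.json")) -> dict[str, str]:
    """SHA-256 of every artifact in a run directory (reproducibility checks)."""
    directory = Path(directory)
    out = {}
    for pattern in patterns:
        for p in sorted(directory.glob(pattern)):
            out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out
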