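"""Serialization of models, libraries, duplex regions, and image sets.

GTF and SAM use 1-based coordinates at the boundary; everything in memory is
0-based half-open.  UMIs travel in the read name after the last ``_`` and are
mirrored in the ``RX`` tag, so either convention round-trips.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
import tifffile
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import DuplexRegion, GenomeModel, TranscriptionUnit
from .reads import AlignedRead, ReadLibrary
from .sim_images import FieldImage, ImageSet
from .sim_reads import HOST_CONTIG, SimConfig

# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def write_gtf(model: GenomeModel, path: str | Path) -> None:
    """One gene/transcript per unit plus exon features; simulation parameters
    are stored as transcript attributes so the model round-trips."""
    lines = [f'#!genome {model.genome_id} length {model.length} readthrough_length {model.readthrough_length}\n']
    for u in model.units:
        lo = min(s for s, _ in u.genomic_exons)
        hi = max(e for _, e in u.genomic_exons)
        attrs = (
            f'gene_id "{u.unit_id}"; transcript_id "{u.unit_id}.t1"; '
            f'polya_site "{u.polya_site}"; expression_weight "{u.expression_weight}"; '
            f'intron_splice_eff "{",".join(str(x) for x in u.intron_splice_eff)}"; '
            f'polya_readthrough_prob "{u.polya_readthrough_prob}";'
        )
        for feature, (s, e) in (("gene", (lo, hi)), ("transcript", (lo, hi))):
            lines.append(
                f"{model.genome_id}\tadvdsrna\t{feature}\t{s + 1}\t{e}\t.\t{u.strand}\t.\t{attrs}\n"
            )
        for i, (s, e) in enumerate(u.exons):
            lines.append(
                f"{model.genome_id}\tadvdsrna\texon\t{s + 1}\t{e}\t.\t{u.strand}\t.\t"
                f'{attrs} exon_number "{i + 1}";\n'
            )
    Path(path).write_text("".join(lines))


def _parse_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path: str | Path) -> GenomeModel:
    genome_id, length, rt_len = None, None, 500
    exons: dict[str, list[tuple[int, int, int]]] = {}
    meta: dict[str, dict[str, str]] = {}
    strands: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("#!genome"):
            parts = line.split()
            genome_id, length, rt_len = parts[1], int(parts[3]), int(parts[5])
            continue
        if line.startswith("#") or not line.strip():
            continue
        f = line.split("\t")
        attrs = _parse_attrs(f[8])
        uid = attrs["gene_id"]
        if f[2] == "transcript":
            meta[uid] = attrs
            strands[uid] = f[6]
        elif f[2] == "exon":
            exons.setdefault(uid, []).append(
                (int(attrs["exon_number"]), int(f[3]) - 1, int(f[4]))
            )
    if genome_id is None:
        raise ValueError(f"{path}: missing #!genome header line")
    units = []
    for uid, attrs in meta.items():
        ordered = [(s, e) for _, s, e in sorted(exons[uid])]
        eff = attrs["intron_splice_eff"]
        units.append(
            TranscriptionUnit(
                unit_id=uid,
                strand=strands[uid],
                exons=tuple(ordered),
                polya_site=int(attrs["polya_site"]),
                expression_weight=float(attrs["expression_weight"]),
                intron_splice_eff=tuple(float(x) for x in eff.split(",")) if eff else (),
                polya_readthrough_prob=float(attrs["polya_readthrough_prob"]),
            )
        )
    return GenomeModel(genome_id=genome_id, length=length, units=tuple(units), readthrough_length=rt_len)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_duplex_bed(regions: Sequence[DuplexRegion], model: GenomeModel, path: str | Path) -> None:
    """Duplex regions as BED6: name = class, score = interval length."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{model.genome_id}\t{r.start}\t{r.end}\t{r.klass}\t{len(r)}\t+\t"
                f"{r.top_unit}\t{r.bottom_unit}\t{r.requires_unspliced}\n"
            )


def write_junction_bed(counts: pd.DataFrame, path: str | Path) -> None:
    """Junctions as BED6: name = donor-acceptor, score = unique read count."""
    with open(path, "w") as fh:
        for row in counts.itertuples(index=False):
            fh.write(
                f"{row.reference}\t{row.donor}\t{row.acceptor}\t"
                f"{row.donor}-{row.acceptor}\t{row.unique_read_count}\t{row.strand}\n"
            )


def read_junction_bed(path: str | Path) -> list[tuple[str, str, int, int]]:
    """(reference, strand, donor, acceptor) tuples from a junction BED."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        out.append((f[0], f[5] if len(f) > 5 else "+", int(f[1]), int(f[2])))
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(model: GenomeModel, path: str | Path, seed: int = 0, host_length: int = 20_000) -> None:
    """Random seeded sequences for the viral genome and the host decoy contig."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xFA])
    records = []
    for name, length in ((model.genome_id, model.length), (HOST_CONTIG, host_length)):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
        records.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def _sam_header(references: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": length} for name, length in references.items()],
        }
    )


def write_sam(lib: ReadLibrary, path: str | Path, references: dict[str, int]) -> None:
    """Write a library as plain-text SAM; blocks become an M/N CIGAR."""
    header = _sam_header(references)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for read in lib.reads:
            a = pysam.AlignedSegment(header)
            a.query_name = f"{read.read_id}_{read.umi}"
            a.flag = 16 if read.strand == "-" else 0
            a.reference_id = list(references).index(read.reference)
            a.reference_start = read.blocks[0][0]
            a.mapping_quality = 255
            cigar = []
            for i, (s, e) in enumerate(read.blocks):
                if i:
                    cigar.append((3, s - read.blocks[i - 1][1]))  # N
                cigar.append((0, e - s))  # M
            a.cigartuples = cigar
            a.query_sequence = "N" * read.mapped_length
            a.set_tag("RX", read.umi)
            fh.write(a)


def read_sam(
    path: str | Path,
    library_id: str,
    condition: str = "",
    fraction: str = "input",
    replicate: int = 0,
) -> ReadLibrary:
    """Read a SAM file into a library; UMI from the read-name suffix after the
    last ``_``, falling back to the ``RX`` tag."""
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            name = a.query_name
            if "_" in name:
                read_id, _, umi = name.rpartition("_")
            else:
                read_id, umi = name, ""
            if not umi and a.has_tag("RX"):
                umi = str(a.get_tag("RX"))
            blocks: list[tuple[int, int]] = []
            pos = a.reference_start
            for op, ln in a.cigartuples or ():
                if op in (0, 7, 8):  # M/=/X
                    if blocks and blocks[-1][1] == pos:
                        blocks[-1] = (blocks[-1][0], pos + ln)
                    else:
                        blocks.append((pos, pos + ln))
                    pos += ln
                elif op in (2, 3):  # D/N consume reference
                    pos += ln
            reads.append(
                AlignedRead(
                    read_id=read_id,
                    umi=umi,
                    reference=a.reference_name,
                    strand="-" if a.is_reverse else "+",
                    blocks=tuple(blocks),
                    library_id=library_id,
                )
            )
    return ReadLibrary(
        library_id=library_id,
        condition=condition,
        fraction=fraction,
        replicate=replicate,
        reads=reads,
    )


def sam_references(model: GenomeModel, cfg: SimConfig) -> dict[str, int]:
    return {model.genome_id: model.length, HOST_CONTIG: cfg.host_contig_length}


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def write_image_set(image_set: ImageSet, outdir: str | Path) -> pd.DataFrame:
    """Write each field as two 16-bit TIFFs plus a ground-truth TSV; returns a
    fields manifest (field_id, dapi_path, dsrna_path)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in image_set.fields:
        dapi_path = outdir / f"{f.field_id}_dapi.tiff"
        dsrna_path = outdir / f"{f.field_id}_dsrna.tiff"
        tifffile.imwrite(dapi_path, np.clip(f.dapi, 0, 65535).astype(np.uint16))
        tifffile.imwrite(dsrna_path, np.clip(f.dsrna, 0, 65535).astype(np.uint16))
        rows.append(
            {"field_id": f.field_id, "dapi_path": str(dapi_path), "dsrna_path": str(dsrna_path)}
        )
    manifest = pd.DataFrame(rows)
    image_set.ground_truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    manifest.to_csv(outdir / "fields.tsv", sep="\t", index=False)
    return manifest


def read_field(dapi_path: str | Path, dsrna_path: str | Path, field_id: str) -> FieldImage:
    return FieldImage(
        field_id=field_id,
        dapi=tifffile.imread(str(dapi_path)).astype(float),
        dsrna=tifffile.imread(str(dsrna_path)).astype(float),
        ground_truth=pd.DataFrame(columns=["nucleus_id", "cy", "cx", "radius", "positive"]),
    )


# ---------------------------------------------------------------------------
# config / tables
# ---------------------------------------------------------------------------


def write_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
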