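"""Simulation of strand-specific, UMI-tagged input and dsRNA-IP libraries.

The generative model mirrors a directional RIP-seq experiment on an
overlapping-strand transcriptome:

* molecules are drawn per transcription unit proportional to its expression
  weight; each intron is independently removed with its splicing efficiency;
  read-through past the poly(A) site happens with the unit's probability;
* a host fraction of molecules is emitted on a synthetic decoy contig, standing
  in for the cellular transcriptome;
* the IP step models single-strand-specific RNase trimming plus anti-dsRNA
  antibody capture: a molecule is duplex-engaged when part of its footprint
  lies in a predicted duplex region whose antisense partner is present
  (unspliced where required) in the same pool; engaged molecules are captured
  efficiently and trimmed to the protected duplex interval plus a small
  overhang, everything else is captured at a low background rate untrimmed;
* reads of fixed length are sampled uniformly over all valid start positions in
  the pool (molecules weighted by mapped length − read length + 1), carry the
  strand of their transcript of origin, a random fixed-length UMI, and splice
  gaps projected to genome coordinates; PCR-style duplicates are injected at a
  configurable rate.

Everything is a deterministic function of (seed, condition, replicate).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import DuplexRegion, GenomeModel, Interval, TranscriptionUnit
from .reads import AlignedRead, ReadLibrary

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

HOST_CONTIG = "host_decoy"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated library set."""

    seed: int = 0
    n_molecules: int = 20_000
    n_reads: int = 50_000
    host_fraction: float = 0.25
    read_length: int = 100
    umi_length: int = 8
    umi_dup_rate: float = 0.05
    rnase_overhang: int = 30
    ip_background_capture: float = 0.05
    ip_duplex_capture: float = 0.8
    # probability that a molecule overlapping a duplex region actually anneals
    # per fully available partner; annealing needs a collision with an
    # antisense molecule, so it is rare even when partners exist
    duplex_formation_rate: float = 0.1
    replicates: int = 2
    host_contig_length: int = 20_000
    host_molecule_length: int = 2_000

    def __post_init__(self) -> None:
        for name in (
            "host_fraction",
            "umi_dup_rate",
            "ip_background_capture",
            "ip_duplex_capture",
            "duplex_formation_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} not in [0,1]")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")
        if self.n_molecules < 1 or self.n_reads < 0:
            raise ValueError("n_molecules must be >= 1 and n_reads >= 0")
        if self.rnase_overhang < 0:
            raise ValueError("rnase_overhang must be >= 0")
        if self.host_molecule_length > self.host_contig_length:
            raise ValueError("host molecule longer than host contig")


@dataclass(frozen=True, slots=True)
class MoleculeRecord:
    """Latent state behind the reads: one RNA molecule in the pool."""

    molecule_id: int
    unit_id: str
    reference: str
    strand: str
    retained_introns: frozenset[int]
    readthrough: bool
    span_blocks: tuple[Interval, ...]

    @property
    def mapped_length(self) -> int:
        return sum(e - s for s, e in self.span_blocks)


def _rng(cfg: SimConfig, condition: str, rep: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        [cfg.seed & 0x7FFFFFFF, zlib.crc32(condition.encode()), rep, stream]
    )


def _umis(rng: np.random.Generator, n: int, length: int) -> list[str]:
    codes = rng.integers(0, 4, size=(n, length))
    return ["".join(row) for row in _BASES[codes]]


def simulate_molecules(
    model: GenomeModel, cfg: SimConfig, rng: np.random.Generator
) -> list[MoleculeRecord]:
    """Draw the molecule pool (viral + host decoy) for one library."""
    n_host = int(rng.binomial(cfg.n_molecules, cfg.host_fraction))
    n_viral = cfg.n_molecules - n_host

    molecules: list[MoleculeRecord] = []
    weights = np.array([u.expression_weight for u in model.units], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("all expression weights are zero")
    unit_idx = rng.choice(len(model.units), size=n_viral, p=weights / weights.sum())
    counts = np.bincount(unit_idx, minlength=len(model.units))

    mol_id = 0
    for ui, unit in enumerate(model.units):
        n_u = int(counts[ui])
        if n_u == 0:
            continue
        k = unit.n_introns
        if k:
            eff = np.array(unit.intron_splice_eff)
            removed = rng.random((n_u, k)) < eff  # spliced out with prob eff
        else:
            removed = np.ones((n_u, 0), dtype=bool)
        rt = rng.random(n_u) < unit.polya_readthrough_prob
        for m in range(n_u):
            retained = frozenset(int(i) for i in np.flatnonzero(~removed[m]))
            blocks = unit.molecule_blocks(retained, bool(rt[m]), model.readthrough_length)
            molecules.append(
                MoleculeRecord(
                    molecule_id=mol_id,
                    unit_id=unit.unit_id,
                    reference=model.genome_id,
                    strand=unit.strand,
                    retained_introns=retained,
                    readthrough=bool(rt[m]),
                    span_blocks=blocks,
                )
            )
            mol_id += 1

    if n_host:
        starts = rng.integers(0, cfg.host_contig_length - cfg.host_molecule_length + 1, n_host)
        strands = rng.choice(np.array(["+", "-"]), size=n_host)
        for s, st in zip(starts, strands):
            molecules.append(
                MoleculeRecord(
                    molecule_id=mol_id,
                    unit_id=HOST_CONTIG,
                    reference=HOST_CONTIG,
                    strand=str(st),
                    retained_introns=frozenset(),
                    readthrough=False,
                    span_blocks=((int(s), int(s) + cfg.host_molecule_length),),
                )
            )
            mol_id += 1
    return molecules


def _project_read(blocks: Sequence[Interval], start: int, length: int) -> tuple[Interval, ...]:
    """Project a molecule-coordinate window onto genomic blocks."""
    out: list[Interval] = []
    remaining = length
    offset = start
    for s, e in blocks:
        blen = e - s
        if offset >= blen:
            offset -= blen
            continue
        take = min(remaining, blen - offset)
        out.append((s + offset, s + offset + take))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    if remaining:
        raise ValueError("read window exceeds molecule length")
    return tuple(out)


def sample_reads(
    molecules: Sequence[MoleculeRecord],
    cfg: SimConfig,
    rng: np.random.Generator,
    library_id: str,
) -> list[AlignedRead]:
    """Sample ``cfg.n_reads`` reads: a molecule uniformly at random, then a
    start position uniform over the molecule's valid read windows.

    Molecules shorter than the read length are skipped with a logged warning.
    """
    if not molecules or cfg.n_reads == 0:
        return []
    n_starts = np.array(
        [max(m.mapped_length - cfg.read_length + 1, 0) for m in molecules], dtype=float
    )
    n_skipped = int((n_starts == 0).sum())
    if n_skipped:
        logger.warning(
            "%s: %d molecules shorter than the read length were skipped",
            library_id,
            n_skipped,
        )
    eligible = n_starts > 0
    if not eligible.any():
        return []
    p = eligible / eligible.sum()
    mol_idx = rng.choice(len(molecules), size=cfg.n_reads, p=p)
    starts = np.floor(rng.random(cfg.n_reads) * n_starts[mol_idx]).astype(int)
    umis = _umis(rng, cfg.n_reads, cfg.umi_length)
    dup = rng.random(cfg.n_reads) < cfg.umi_dup_rate

    reads: list[AlignedRead] = []
    for i in range(cfg.n_reads):
        m = molecules[mol_idx[i]]
        blocks = _project_read(m.span_blocks, int(starts[i]), cfg.read_length)
        read = AlignedRead(
            read_id=f"{library_id}:{i:07d}",
            umi=umis[i],
            reference=m.reference,
            strand=m.strand,
            blocks=blocks,
            library_id=library_id,
        )
        reads.append(read)
        if dup[i]:
            reads.append(
                AlignedRead(
                    read_id=f"{library_id}:{i:07d}:dup",
                    umi=read.umi,
                    reference=read.reference,
                    strand=read.strand,
                    blocks=read.blocks,
                    library_id=library_id,
                )
            )
    return reads


def simulate_input_library(
    model: GenomeModel,
    cfg: SimConfig,
    rep: int,
    condition: str = "WT",
) -> tuple[ReadLibrary, list[MoleculeRecord]]:
    """Simulate one input (total RNA) library and return its latent molecules."""
    rng = _rng(cfg, condition, rep, stream=1)
    library_id = f"{condition}_input_r{rep}"
    molecules = simulate_molecules(model, cfg, rng)
    reads = sample_reads(molecules, cfg, rng, library_id)
    lib = ReadLibrary(
        library_id=library_id,
        condition=condition,
        fraction="input",
        replicate=rep,
        reads=reads,
    )
    return lib, molecules


def _merge_intervals(ivs: list[Interval]) -> list[Interval]:
    ivs = sorted(ivs)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _fragment_blocks(
    blocks: Sequence[Interval], windows: list[Interval]
) -> list[tuple[Interval, ...]]:
    """RNase-I fragments of a molecule: protected pieces, split wherever the
    RNA chain was cut.

    Pieces stay in one fragment only when the RNA is contiguous between them —
    i.e. across an original splice junction whose donor-side block end and
    acceptor-side block start are both protected.  Every other gap is a cut,
    and a sequencing read cannot span it.
    """
    fragments: list[tuple[Interval, ...]] = []
    cur: list[Interval] = []
    prev_block_idx: int | None = None
    prev_piece_end: int | None = None
    for bi, (bs, be) in enumerate(blocks):
        for ws, we in windows:
            s, e = max(bs, ws), min(be, we)
            if s >= e:
                continue
            joined = (
                bool(cur)
                and prev_block_idx == bi - 1
                and prev_piece_end == blocks[bi - 1][1]
                and s == bs
            )
            if joined:
                cur.append((s, e))
            else:
                if cur:
                    fragments.append(tuple(cur))
                cur = [(s, e)]
            prev_block_idx = bi
            prev_piece_end = e
    if cur:
        fragments.append(tuple(cur))
    return fragments


def duplex_partner_availability(
    molecules: Sequence[MoleculeRecord], duplexes: Sequence[DuplexRegion]
) -> list[dict[str, float]]:
    """Per duplex region, the fraction of each side's partner-unit molecules
    whose footprint overlaps the region (for intronic contributions this is the
    partner's unspliced fraction over the interval)."""
    by_unit: dict[str, list[MoleculeRecord]] = {}
    for m in molecules:
        by_unit.setdefault(m.unit_id, []).append(m)

    def frac_overlapping(unit_id: str, interval: Interval) -> float:
        mols = by_unit.get(unit_id, [])
        if not mols:
            return 0.0
        n = sum(
            1
            for m in mols
            if any(max(s, interval[0]) < min(e, interval[1]) for s, e in m.span_blocks)
        )
        return n / len(mols)

    avail = []
    for d in duplexes:
        avail.append(
            {
                # probability that a top-side molecule finds a bottom partner, and v.v.
                "top": frac_overlapping(d.bottom_unit, d.interval),
                "bottom": frac_overlapping(d.top_unit, d.interval),
            }
        )
    return avail


def capture_molecules(
    molecules: Sequence[MoleculeRecord],
    duplexes: Sequence[DuplexRegion],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[MoleculeRecord], int, int]:
    """IP capture step: returns (captured fragments, #molecules captured as
    duplex-engaged, #molecules captured as background).

    A molecule engages each overlapping duplex region independently with
    probability ``duplex_formation_rate × partner availability``; engaged
    molecules are captured at ``ip_duplex_capture`` and RNase-trimmed to the
    fired intervals ± ``rnase_overhang``, everything else is captured
    untrimmed at ``ip_background_capture``.
    """
    by_unit_regions: dict[str, list[tuple[int, str]]] = {}
    for i, d in enumerate(duplexes):
        by_unit_regions.setdefault(d.top_unit, []).append((i, "top"))
        by_unit_regions.setdefault(d.bottom_unit, []).append((i, "bottom"))
    avail = duplex_partner_availability(molecules, duplexes)

    captured: list[MoleculeRecord] = []
    n_engaged = n_background = 0
    for m in molecules:
        fired: list[Interval] = []
        for di, side in by_unit_regions.get(m.unit_id, ()):
            d = duplexes[di]
            overlaps = any(
                max(s, d.start) < min(e, d.end) for s, e in m.span_blocks
            )
            if overlaps and rng.random() < cfg.duplex_formation_rate * avail[di][side]:
                fired.append(d.interval)
        if fired:
            if rng.random() < cfg.ip_duplex_capture:
                n_engaged += 1
                windows = _merge_intervals(
                    [(s - cfg.rnase_overhang, e + cfg.rnase_overhang) for s, e in fired]
                )
                for blocks in _fragment_blocks(m.span_blocks, windows):
                    captured.append(
                        MoleculeRecord(
                            molecule_id=m.molecule_id,
                            unit_id=m.unit_id,
                            reference=m.reference,
                            strand=m.strand,
                            retained_introns=m.retained_introns,
                            readthrough=m.readthrough,
                            span_blocks=blocks,
                        )
                    )
        elif rng.random() < cfg.ip_background_capture:
            n_background += 1
            captured.append(m)
    return captured, n_engaged, n_background


def simulate_ip_library(
    model: GenomeModel,
    molecules: Sequence[MoleculeRecord],
    duplexes: Sequence[DuplexRegion],
    cfg: SimConfig,
    rep: int,
    condition: str = "WT",
) -> ReadLibrary:
    """Simulate the RNase-I-trimmed anti-dsRNA IP of a molecule pool.

    ``molecules`` should be the latent pool of the matched input library;
    ``duplexes`` the prediction for the same genome model.
    """
    rng = _rng(cfg, condition, rep, stream=2)
    library_id = f"{condition}_ip_r{rep}"
    captured, _, _ = capture_molecules(molecules, duplexes, cfg, rng)
    reads = sample_reads(captured, cfg, rng, library_id)
    return ReadLibrary(
        library_id=library_id,
        condition=condition,
        fraction="ip",
        replicate=rep,
        reads=reads,
    )
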