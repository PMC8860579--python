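"""Toy dual-strand viral transcriptome and antisense duplex-region prediction.

The genome model captures what matters for intermolecular dsRNA formation in a
compact DNA-virus transcriptome: transcription units on both strands, exon/intron
structure, poly(A) sites, per-intron splicing efficiencies, and optional
transcription past the poly(A) site (read-through).  A duplex-competent region is
any genomic interval where the pre-mRNA footprint of a top-strand unit overlaps
the pre-mRNA footprint of a bottom-strand unit: complementary RNA from the two
strands can anneal in *trans* there.  Regions are classified by whether the
overlap exists for normally terminated pre-mRNAs (``intron_exon``) or requires
read-through past a poly(A) site (``polya_readthrough``), and annotated with
which side must remain unspliced for the overlap to survive splicing.

Coordinates are 0-based half-open throughout; 1-based conversion happens only at
GTF/SAM serialization (see :mod:`advdsrna.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

Interval = tuple[int, int]

TOP = "+"
BOTTOM = "-"

#: default distance (nt) a read-through transcript extends past its poly(A) site
DEFAULT_READTHROUGH_LENGTH = 500


def _overlap(a: Interval, b: Interval) -> Interval | None:
    s, e = max(a[0], b[0]), min(a[1], b[1])
    return (s, e) if s < e else None


def _intervals_overlap(piece: Interval, blocks: Iterable[Interval]) -> bool:
    return any(_overlap(piece, b) is not None for b in blocks)


@dataclass(frozen=True)
class TranscriptionUnit:
    """One transcription unit: an ordered exon chain with splicing parameters.

    ``exons`` are half-open genomic intervals listed 5'→3' along the unit's own
    strand (ascending genomically for ``+``, descending for ``-``).
    ``intron_splice_eff[i]`` is the probability that intron *i* (between exon
    *i* and exon *i+1* in transcription order) is removed from a given molecule.
    """

    unit_id: str
    strand: str
    exons: tuple[Interval, ...]
    polya_site: int
    expression_weight: float = 1.0
    intron_splice_eff: tuple[float, ...] = ()
    polya_readthrough_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in (TOP, BOTTOM):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.exons) < 1:
            raise ValueError(f"{self.unit_id}: at least one exon required")
        for s, e in self.exons:
            if not s < e:
                raise ValueError(f"{self.unit_id}: empty exon ({s}, {e})")
        # transcription order: strictly progressing, non-overlapping
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            ok = e1 <= s2 if self.strand == TOP else e2 <= s1
            if not ok:
                raise ValueError(
                    f"{self.unit_id}: exons not in 5'->3' transcription order"
                )
        if len(self.intron_splice_eff) != len(self.exons) - 1:
            raise ValueError(
                f"{self.unit_id}: need {len(self.exons) - 1} splicing "
                f"efficiencies, got {len(self.intron_splice_eff)}"
            )
        for s in self.intron_splice_eff:
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"{self.unit_id}: splice efficiency {s} not in [0,1]")
        if not 0.0 <= self.polya_readthrough_prob <= 1.0:
            raise ValueError(f"{self.unit_id}: read-through prob not in [0,1]")
        if self.expression_weight < 0:
            raise ValueError(f"{self.unit_id}: negative expression weight")
        # poly(A) site at or beyond the 3'-most exon end in transcription direction
        if self.strand == TOP and self.polya_site < self.exons[-1][1]:
            raise ValueError(f"{self.unit_id}: polya_site upstream of last exon")
        if self.strand == BOTTOM and self.polya_site > self.exons[-1][0]:
            raise ValueError(f"{self.unit_id}: polya_site upstream of last exon")

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def genomic_exons(self) -> tuple[Interval, ...]:
        return tuple(sorted(self.exons))

    def intron_interval(self, i: int) -> Interval:
        """Genomic interval of intron ``i`` (transcription order)."""
        a, b = self.exons[i], self.exons[i + 1]
        return (a[1], b[0]) if self.strand == TOP else (b[1], a[0])

    def span(self, readthrough: bool, readthrough_length: int) -> Interval:
        """Pre-mRNA footprint: first exon start → poly(A) site (± read-through)."""
        ext = readthrough_length if readthrough else 0
        if self.strand == TOP:
            return (self.exons[0][0], self.polya_site + ext)
        return (max(0, self.polya_site - ext), self.exons[0][1])

    def molecule_blocks(
        self,
        retained_introns: frozenset[int] | set[int] = frozenset(),
        readthrough: bool = False,
        readthrough_length: int = DEFAULT_READTHROUGH_LENGTH,
    ) -> tuple[Interval, ...]:
        """Genomic footprint of one transcript molecule, sorted genomically.

        Retained introns merge adjacent exon blocks; the 3' block always runs to
        the poly(A) site, plus ``readthrough_length`` when the molecule read
        through.
        """
        blocks: list[list[int]] = [list(self.exons[0])]
        for i, exon in enumerate(self.exons[1:]):
            if i in retained_introns:
                if self.strand == TOP:
                    blocks[-1][1] = exon[1]
                else:
                    blocks[-1][0] = exon[0]
            else:
                blocks.append(list(exon))
        ext = readthrough_length if readthrough else 0
        if self.strand == TOP:
            blocks[-1][1] = self.polya_site + ext
        else:
            blocks[-1][0] = max(0, self.polya_site - ext)
        return tuple(sorted((s, e) for s, e in blocks))

    def mature_blocks(self) -> tuple[Interval, ...]:
        """Footprint of the fully spliced, normally terminated mRNA."""
        return self.molecule_blocks(frozenset(), readthrough=False)


@dataclass(frozen=True)
class GenomeModel:
    """A compact genome with transcription units on both strands."""

    genome_id: str
    length: int
    units: tuple[TranscriptionUnit, ...]
    readthrough_length: int = DEFAULT_READTHROUGH_LENGTH

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ValueError("unit ids must be unique")
        for u in self.units:
            lo = min(u.exons)[0]
            hi = max(e for _, e in u.exons)
            lo = min(lo, u.polya_site)
            hi = max(hi, u.polya_site)
            if lo < 0 or hi > self.length:
                raise ValueError(f"{u.unit_id}: outside [0, {self.length})")

    def unit(self, unit_id: str) -> TranscriptionUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def top_units(self) -> tuple[TranscriptionUnit, ...]:
        return tuple(u for u in self.units if u.strand == TOP)

    def bottom_units(self) -> tuple[TranscriptionUnit, ...]:
        return tuple(u for u in self.units if u.strand == BOTTOM)


@dataclass(frozen=True)
class DuplexRegion:
    """A predicted antisense pairing interval between two opposite-strand units."""

    start: int
    end: int
    top_unit: str
    bottom_unit: str
    klass: str  # intron_exon | polya_readthrough
    requires_unspliced: str  # top | bottom | both | neither

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("empty duplex interval")
        if self.klass not in ("intron_exon", "polya_readthrough"):
            raise ValueError(f"unknown duplex class {self.klass!r}")
        if self.requires_unspliced not in ("top", "bottom", "both", "neither"):
            raise ValueError(f"bad requires_unspliced {self.requires_unspliced!r}")

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


def _requires_unspliced(
    piece: Interval, top_mature: Sequence[Interval], bottom_mature: Sequence[Interval]
) -> str:
    """Which side's contribution to ``piece`` vanishes once that side is spliced."""
    need_top = not _intervals_overlap(piece, top_mature)
    need_bottom = not _intervals_overlap(piece, bottom_mature)
    if need_top and need_bottom:
        return "both"
    if need_top:
        return "top"
    if need_bottom:
        return "bottom"
    return "neither"


def _homogeneous_segments(
    piece: Interval,
    klass: str,
    top_mature: Sequence[Interval],
    bottom_mature: Sequence[Interval],
) -> list[tuple[Interval, str, str]]:
    """Split ``piece`` at mature-mRNA footprint boundaries and annotate each
    maximal sub-interval with a single (class, requires_unspliced) pair."""
    bounds = {piece[0], piece[1]}
    for blocks in (top_mature, bottom_mature):
        for s, e in blocks:
            for x in (s, e):
                if piece[0] < x < piece[1]:
                    bounds.add(x)
    pts = sorted(bounds)
    segs: list[list] = []
    for s, e in zip(pts, pts[1:]):
        req = _requires_unspliced((s, e), top_mature, bottom_mature)
        if segs and segs[-1][1] == s and segs[-1][2] == req:
            segs[-1][1] = e
        else:
            segs.append([s, e, req])
    return [((s, e), klass, req) for s, e, req in segs]


def predict_duplex_regions(model: GenomeModel, min_len: int = 1) -> list[DuplexRegion]:
    """Predict every antisense pre-mRNA overlap of length >= ``min_len``.

    For each (top unit, bottom unit) pair the overlap of normally terminated
    pre-mRNA spans yields ``intron_exon`` regions; extending a span past its
    poly(A) site (only for units with nonzero read-through probability) can add
    flanking ``polya_readthrough`` pieces that exist only by virtue of the
    extension.  Each pair overlap is split at mature-mRNA footprint boundaries,
    so every returned region is a maximal interval with a single
    (class, requires_unspliced) annotation.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    out: list[DuplexRegion] = []
    rt = model.readthrough_length
    for t in model.top_units():
        base_t = t.span(False, rt)
        ext_t = t.span(t.polya_readthrough_prob > 0, rt)
        t_mature = t.mature_blocks()
        for b in model.bottom_units():
            base_b = b.span(False, rt)
            ext_b = b.span(b.polya_readthrough_prob > 0, rt)
            ext = _overlap(ext_t, ext_b)
            if ext is None:
                continue
            base = _overlap(base_t, base_b)
            b_mature = b.mature_blocks()
            pieces: list[tuple[Interval, str]] = []
            if base is not None:
                pieces.append((base, "intron_exon"))
                if ext[0] < base[0]:
                    pieces.append(((ext[0], base[0]), "polya_readthrough"))
                if base[1] < ext[1]:
                    pieces.append(((base[1], ext[1]), "polya_readthrough"))
            else:
                pieces.append((ext, "polya_readthrough"))
            for piece, klass in pieces:
                for (s, e), kl, req in _homogeneous_segments(piece, klass, t_mature, b_mature):
                    if e - s < min_len:
                        continue
                    out.append(
                        DuplexRegion(
                            start=s,
                            end=e,
                            top_unit=t.unit_id,
                            bottom_unit=b.unit_id,
                            klass=kl,
                            requires_unspliced=req,
                        )
                    )
    out.sort(key=lambda d: (d.start, d.end, d.top_unit, d.bottom_unit, d.klass))
    return out


def duplex_bitmask_oracle(model: GenomeModel, min_len: int = 1) -> list[Interval]:
    """Brute-force per-base oracle for the union of duplex-competent intervals.

    Marks every base covered by any top-strand pre-mRNA span and any
    bottom-strand pre-mRNA span (read-through extension applied to units with
    nonzero read-through probability) and intersects the two bitmasks.
    Independent of the interval algebra in :func:`predict_duplex_regions`.
    """
    rt = model.readthrough_length
    top = np.zeros(model.length, dtype=bool)
    bottom = np.zeros(model.length, dtype=bool)
    for u in model.units:
        s, e = u.span(u.polya_readthrough_prob > 0, rt)
        s, e = max(0, s), min(model.length, e)
        (top if u.strand == TOP else bottom)[s:e] = True
    both = top & bottom
    runs: list[Interval] = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], both.view(np.int8), [0]))))
    for s, e in zip(idx[::2], idx[1::2]):
        if e - s >= min_len:
            runs.append((int(s), int(e)))
    return runs


def merged_duplex_intervals(regions: Sequence[DuplexRegion]) -> list[Interval]:
    """Union of predicted duplex intervals as maximal disjoint intervals."""
    ivs = sorted((r.start, r.end) for r in regions)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

PRESETS = ("minimal", "ad5_like")


def _minimal_units() -> tuple[TranscriptionUnit, ...]:
    # antisense pair whose exons never overlap: duplexes need an unspliced side
    top = TranscriptionUnit(
        unit_id="U_top",
        strand=TOP,
        exons=((100, 400), (800, 1200)),
        polya_site=1200,
        expression_weight=1.0,
        intron_splice_eff=(0.9,),
        polya_readthrough_prob=0.0,
    )
    bottom = TranscriptionUnit(
        unit_id="U_bottom",
        strand=BOTTOM,
        exons=((1250, 1650), (450, 750)),
        polya_site=450,
        expression_weight=1.0,
        intron_splice_eff=(0.9,),
        polya_readthrough_prob=0.0,
    )
    return (top, bottom)


def _ad5_like_units(splice_eff: float, readthrough_prob: float) -> tuple[TranscriptionUnit, ...]:
    """An Ad5-inspired layout: early/late units on the top strand, E2/E4-like
    units on the bottom strand, and a major-late family sharing a three-exon
    tripartite-leader with alternative 3' exons (L2/L3/L4/L5-like)."""

    def eff(n: int) -> tuple[float, ...]:
        return tuple([splice_eff] * n)

    tpl = ((6000, 6200), (7000, 7200), (9600, 9800))
    units = [
        TranscriptionUnit(
            "E1A", TOP, ((500, 1100), (1230, 1600)), 1600, 1.0, eff(1), readthrough_prob
        ),
        TranscriptionUnit(
            "E1B", TOP, ((1700, 2400), (3200, 4000)), 4000, 1.0, eff(1), readthrough_prob
        ),
        TranscriptionUnit(
            "MLP_L2", TOP, tpl + ((14000, 15500),), 15500, 3.0, eff(3), readthrough_prob
        ),
        TranscriptionUnit(
            "MLP_L3", TOP, tpl + ((18000, 19500),), 19500, 3.0, eff(3), readthrough_prob
        ),
        TranscriptionUnit(
            "MLP_L4", TOP, tpl + ((22000, 23500),), 23500, 3.0, eff(3), readthrough_prob
        ),
        TranscriptionUnit(
            "MLP_L5_fiber", TOP, tpl + ((30500, 32500),), 32500, 3.0, eff(3), readthrough_prob
        ),
        TranscriptionUnit(
            "E3", TOP, ((27500, 28400), (28900, 30000)), 30000, 1.0, eff(1), readthrough_prob
        ),
        TranscriptionUnit(
            "E2",
            BOTTOM,
            ((26500, 27200), (23800, 24600), (10500, 11300)),
            10500,
            2.0,
            eff(2),
            readthrough_prob,
        ),
        TranscriptionUnit(
            "E4",
            BOTTOM,
            ((34000, 35500), (32800, 33500)),
            32800,
            1.0,
            eff(1),
            readthrough_prob,
        ),
    ]
    return tuple(units)


def build_genome(
    preset: str,
    seed: int = 0,
    splice_eff: float = 0.95,
    readthrough_prob: float = 0.05,
) -> GenomeModel:
    """Build a preset genome model.

    ``minimal`` is a two-unit antisense pair (one intron each); ``ad5_like``
    mimics the overlapping-strand organization of a human adenovirus genome.
    The layout is a deterministic function of the preset; ``seed`` only matters
    for downstream stochastic stages (kept in the signature so a single seed
    can thread through an experiment config).
    """
    if preset == "minimal":
        units = _minimal_units()
        return GenomeModel(genome_id="toyAdV_minimal", length=2000, units=units)
    if preset == "ad5_like":
        units = _ad5_like_units(splice_eff, readthrough_prob)
        return GenomeModel(genome_id="toyAdV", length=36000, units=units)
    raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")


def set_splice_efficiencies(model: GenomeModel, value: float) -> GenomeModel:
    """Return a copy of ``model`` with every intron's splicing efficiency set."""
    units = tuple(
        replace(u, intron_splice_eff=tuple([value] * u.n_introns)) for u in model.units
    )
    return replace(model, units=units)


def set_readthrough_prob(model: GenomeModel, value: float) -> GenomeModel:
    units = tuple(replace(u, polya_readthrough_prob=value) for u in model.units)
    return replace(model, units=units)


def random_genome(seed: int, max_units_per_strand: int = 3, length: int = 5000) -> GenomeModel:
    """A small random genome for property testing the duplex predictor.

    Units have 1–3 exons, random splicing efficiencies, and read-through
    probability 0 or positive with equal chance; layouts are unconstrained, so
    antisense exon–exon overlaps can occur.
    """
    rng = np.random.default_rng(seed)
    units: list[TranscriptionUnit] = []
    for strand in (TOP, BOTTOM):
        for k in range(int(rng.integers(1, max_units_per_strand + 1))):
            n_exons = int(rng.integers(1, 4))
            cuts = np.sort(rng.choice(np.arange(50, length - 50), size=2 * n_exons, replace=False))
            exons = [(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n_exons)]
            exons = [e for e in exons if e[1] > e[0]]
            if not exons:
                continue
            if strand == BOTTOM:
                exons = exons[::-1]
            polya = exons[-1][1] if strand == TOP else exons[-1][0]
            if rng.random() < 0.5:  # push poly(A) a bit past the final exon
                if strand == TOP:
                    polya = min(length, polya + int(rng.integers(0, 200)))
                else:
                    polya = max(0, polya - int(rng.integers(0, 200)))
            units.append(
                TranscriptionUnit(
                    unit_id=f"{'T' if strand == TOP else 'B'}{k}_{seed}",
                    strand=strand,
                    exons=tuple(exons),
                    polya_site=polya,
                    expression_weight=float(rng.uniform(0.2, 3.0)),
                    intron_splice_eff=tuple(rng.uniform(0, 1, size=len(exons) - 1)),
                    polya_readthrough_prob=float(rng.choice([0.0, rng.uniform(0, 1)])),
                )
            )
    return GenomeModel(
        genome_id=f"random{seed}",
        length=length,
        units=tuple(units),
        readthrough_length=int(rng.integers(50, 400)),
    )
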