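"""UMI dedup, junction extraction/filtering, and RIP-seq statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from advdsrna.reads import AlignedRead, Junction, JunctionTable, ReadLibrary
from advdsrna.ripseq import (
    deduplicate_umis,
    dsrna_enrichment,
    extract_junctions,
    filter_reproducible,
    splicing_index,
    spliced_read_fraction,
    viral_fraction,
)

VIRAL = "toyAdV"


def make_lib(reads, library_id="L1", condition="WT", fraction="input", replicate=0, dedup=False):
    return ReadLibrary(library_id, condition, fraction, replicate, list(reads), deduplicated=dedup)


def read(read_id, umi="AAAA", ref=VIRAL, strand="+", blocks=((0, 50),)):
    return AlignedRead(read_id, umi, ref, strand, tuple(blocks))


@st.composite
def random_reads(draw):
    n = draw(st.integers(1, 120))
    reads = []
    for i in range(n):
        umi = draw(st.sampled_from(["AA", "AC", "AG", "AT"]))
        ref = draw(st.sampled_from([VIRAL, "host_decoy"]))
        strand = draw(st.sampled_from(["+", "-"]))
        start = draw(st.integers(0, 50)) * 10
        shape = draw(st.sampled_from([((0, 50),), ((0, 30), (60, 90)), ((10, 40), (80, 100))]))
        blocks = tuple((s + start, e + start) for s, e in shape)
        reads.append(read(f"r{i:03d}", umi, ref, strand, blocks))
    return reads


class TestDeduplicate:
    def test_same_key_collapses_to_lexicographically_smallest(self):
        lib = make_lib([read("b"), read("a")])
        out = deduplicate_umis(lib)
        assert [r.read_id for r in out.reads] == ["a"]
        assert out.deduplicated

    def test_different_position_is_a_different_molecule(self):
        lib = make_lib([read("a", blocks=((0, 50),)), read("b", blocks=((1, 51),))])
        assert len(deduplicate_umis(lib).reads) == 2

    def test_missing_umi_names_the_read(self):
        lib = make_lib([read("orphan", umi="")])
        with pytest.raises(ValueError, match="orphan"):
            deduplicate_umis(lib)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(random_reads())
    def test_count_matches_distinct_key_oracle_and_is_idempotent(self, reads):
        lib = make_lib(reads)
        out = deduplicate_umis(lib)
        oracle = {(r.umi, r.reference, r.strand, r.blocks) for r in reads}
        assert len(out.reads) == len(oracle)
        again = deduplicate_umis(out)
        assert [r.read_id for r in again.reads] == [r.read_id for r in out.reads]


class TestExtractJunctions:
    def test_requires_deduplicated_library(self):
        with pytest.raises(ValueError, match="deduplicated"):
            extract_junctions(make_lib([read("a")], dedup=False))

    def test_single_block_reads_contribute_nothing(self):
        table = extract_junctions(make_lib([read("a")], dedup=True))
        assert len(table.counts) == 0
        assert table.totals == {"L1": 1}

    def test_gap_coordinates(self):
        lib = make_lib([read("a", blocks=((100, 150), (200, 250)))], dedup=True)
        table = extract_junctions(lib)
        row = table.counts.iloc[0]
        assert (row.donor, row.acceptor) == (150, 200)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(random_reads())
    def test_counts_match_nested_loop_oracle(self, reads):
        lib = deduplicate_umis(make_lib(reads))
        table = extract_junctions(lib)
        oracle: dict[tuple, int] = {}
        for r in lib.reads:
            for (s1, e1), (s2, e2) in zip(r.blocks, r.blocks[1:]):
                k = (r.reference, r.strand, e1, s2)
                oracle[k] = oracle.get(k, 0) + 1
        got = {
            (row.reference, row.strand, row.donor, row.acceptor): row.unique_read_count
            for row in table.counts.itertuples(index=False)
        }
        assert got == oracle


class TestFilterReproducible:
    def _table(self, counts_by_lib):
        tables = []
        for lib_id, items in counts_by_lib.items():
            df = pd.DataFrame(
                [
                    {
                        "library_id": lib_id,
                        "reference": VIRAL,
                        "strand": "+",
                        "donor": d,
                        "acceptor": a,
                        "unique_read_count": n,
                    }
                    for (d, a), n in items.items()
                ]
            )
            if df.empty:
                df = pd.DataFrame(
                    columns=["library_id", "reference", "strand", "donor", "acceptor", "unique_read_count"]
                )
            tables.append(JunctionTable(df, {lib_id: 1000}))
        return JunctionTable.concat(tables)

    def test_single_read_junction_excluded_from_cross_library_panel(self):
        # one of eight libraries sees the junction only once -> excluded
        counts = {f"L{i}": {(10, 20): 5} for i in range(7)}
        counts["L7"] = {(10, 20): 1}
        table = self._table(counts)
        assert filter_reproducible(table, 2, require_all_libraries=True) == set()

    def test_junction_present_everywhere_is_kept(self):
        counts = {f"L{i}": {(10, 20): 2} for i in range(8)}
        table = self._table(counts)
        panel = filter_reproducible(table, 2, require_all_libraries=True)
        assert panel == {Junction(VIRAL, "+", 10, 20)}

    def test_per_library_mode_matches_brute_force(self, rng):
        counts = {
            f"L{i}": {
                (d * 10, d * 10 + 5): int(rng.integers(0, 5))
                for d in range(1, 6)
            }
            for i in range(4)
        }
        table = self._table(counts)
        per_lib = filter_reproducible(table, 2)
        for lib_id, items in counts.items():
            expected = {Junction(VIRAL, "+", d, a) for (d, a), n in items.items() if n >= 2}
            assert per_lib[lib_id] == expected

    def test_min_reads_below_one_rejected(self):
        table = self._table({"L0": {(10, 20): 3}})
        with pytest.raises(ValueError):
            filter_reproducible(table, 0)


class TestFractions:
    def test_viral_fraction(self):
        lib = deduplicate_umis(
            make_lib(
                [read(f"v{i}", umi=f"U{i}", blocks=((i, i + 50),)) for i in range(3)]
                + [read(f"h{i}", umi=f"H{i}", ref="host_decoy", blocks=((i, i + 50),)) for i in range(7)]
            )
        )
        assert viral_fraction(lib, VIRAL) == pytest.approx(30.0)
        with pytest.raises(ValueError, match="empty"):
            viral_fraction(make_lib([], dedup=True), VIRAL)

    def test_enrichment_ratio(self):
        assert dsrna_enrichment(50.0, 50.0) == pytest.approx(1.0)
        assert dsrna_enrichment(40.0, 20.0) == pytest.approx(2.0)
        assert dsrna_enrichment(17.0, 34.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            dsrna_enrichment(10.0, 0.0)

    def test_spliced_read_fraction_bounds(self):
        j = Junction(VIRAL, "+", 50, 100)
        spliced = [read(f"s{i}", umi=f"U{i}", blocks=((0, 50), (100, 150))) for i in range(4)]
        unspliced = [read(f"u{i}", umi=f"V{i}", blocks=((i, i + 100),)) for i in range(4)]
        lib = deduplicate_umis(make_lib(spliced + unspliced))
        assert spliced_read_fraction(lib, {j}, VIRAL) == pytest.approx(50.0)
        assert spliced_read_fraction(lib, set(), VIRAL) == pytest.approx(0.0)
        only_spliced = deduplicate_umis(make_lib(spliced))
        assert spliced_read_fraction(only_spliced, {j}, VIRAL) == pytest.approx(100.0)


class TestSplicingIndex:
    def _setup(self, rng=None, n_j=5, libs=("WT", "dE4"), reps=(0, 1), scale=1000):
        junctions = [Junction(VIRAL, "+", 100 * k, 100 * k + 50) for k in range(1, n_j + 1)]
        rows, totals, manifest = [], {}, []
        for cond in libs:
            for rep in reps:
                for frac in ("input", "ip"):
                    lib_id = f"{cond}_{frac}_r{rep}"
                    totals[lib_id] = scale * 100
                    manifest.append(
                        {"library_id": lib_id, "condition": cond, "fraction": frac, "replicate": rep}
                    )
                    for j in junctions:
                        n = int(rng.integers(2, 50)) if rng is not None else 10
                        rows.append(
                            {
                                "library_id": lib_id,
                                "reference": j.reference,
                                "strand": j.strand,
                                "donor": j.donor,
                                "acceptor": j.acceptor,
                                "unique_read_count": n,
                            }
                        )
        table = JunctionTable(pd.DataFrame(rows), totals)
        return table, pd.DataFrame(manifest), junctions

    def test_identical_tables_give_zero_index(self):
        table, manifest, junctions = self._setup()
        res = splicing_index(table, manifest, junctions)
        assert np.allclose(res.per_replicate["log2fc"], 0.0)
        assert np.allclose(res.condition_summary["mean_log2fc"], 0.0)

    def test_quarter_abundance_gives_minus_two_without_pseudocount(self):
        table, manifest, junctions = self._setup()
        counts = table.counts.copy()
        ip_rows = counts["library_id"].str.contains("_ip_")
        counts.loc[ip_rows, "unique_read_count"] = 10
        counts.loc[~ip_rows, "unique_read_count"] = 40
        table = JunctionTable(counts, table.totals)
        res = splicing_index(table, manifest, junctions, pseudocount=0.0)
        assert np.allclose(res.per_replicate["log2fc"], -2.0)

    def test_matches_formula_oracle_on_random_tables(self, rng):
        table, manifest, junctions = self._setup(rng=rng)
        pc = 0.5
        res = splicing_index(table, manifest, junctions, pseudocount=pc)
        norm = table.normalized().set_index(
            ["library_id", "reference", "strand", "donor", "acceptor"]
        )["norm_abundance"]
        for row in res.per_replicate.itertuples(index=False):
            ip_id = f"{row.condition}_ip_r{row.replicate}"
            in_id = f"{row.condition}_input_r{row.replicate}"
            key = (row.reference, row.strand, row.donor, row.acceptor)
            expected = np.log2((norm[(ip_id, *key)] + pc) / (norm[(in_id, *key)] + pc))
            assert row.log2fc == pytest.approx(expected, rel=1e-12)
        # replicate-average per junction, then condition mean
        for cond in ("WT", "dE4"):
            sub = res.per_junction[res.per_junction["condition"] == cond]
            assert res.condition_mean(cond) == pytest.approx(sub["mean_log2fc"].mean())

    def test_unmatched_replicates_rejected(self):
        table, manifest, junctions = self._setup()
        broken = manifest[~((manifest.library_id == "WT_ip_r0"))]
        with pytest.raises(ValueError, match="unmatched replicate"):
            splicing_index(table, broken, junctions)

    def test_invariant_under_read_order_permutation(self, rng):
        reads = [
            read(f"r{i}", umi=f"U{i}", strand="+", blocks=((0, 30), (60, 90)))
            for i in range(20)
        ] + [read(f"q{i}", umi=f"W{i}", blocks=((5, 95),)) for i in range(20)]
        lib_a = deduplicate_umis(make_lib(list(reads)))
        shuffled = list(reads)
        rng.shuffle(shuffled)
        lib_b = deduplicate_umis(make_lib(shuffled))
        ta, tb = extract_junctions(lib_a), extract_junctions(lib_b)
        pd.testing.assert_frame_equal(ta.counts, tb.counts)
        assert viral_fraction(lib_a, VIRAL) == viral_fraction(lib_b, VIRAL)
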