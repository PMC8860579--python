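"""Library simulator: determinism, composition, and analytic oracles."""

import numpy as np
import pytest

from advdsrna.model import build_genome, predict_duplex_regions, set_splice_efficiencies, set_readthrough_prob
from advdsrna.reads import read_junctions
from advdsrna.ripseq import deduplicate_umis
from advdsrna.sim_reads import (
    SimConfig,
    _rng,
    capture_molecules,
    sample_reads,
    simulate_input_library,
    simulate_ip_library,
    simulate_molecules,
)
from conftest import single_intron_model


def _lib_signature(lib):
    return [(r.read_id, r.umi, r.reference, r.strand, r.blocks) for r in lib.reads]


class TestInputLibrary:
    def test_deterministic_given_seed_and_rep(self, minimal_model, small_cfg):
        a, _ = simulate_input_library(minimal_model, small_cfg, rep=0)
        b, _ = simulate_input_library(minimal_model, small_cfg, rep=0)
        c, _ = simulate_input_library(minimal_model, small_cfg, rep=1)
        assert _lib_signature(a) == _lib_signature(b)
        assert _lib_signature(a) != _lib_signature(c)

    def test_host_fraction_zero_gives_all_viral_reads(self, minimal_model):
        cfg = SimConfig(seed=3, n_molecules=500, n_reads=1000, host_fraction=0.0)
        lib, _ = simulate_input_library(minimal_model, cfg, rep=0)
        assert all(r.reference == minimal_model.genome_id for r in lib.reads)

    def test_perfect_splicing_means_every_boundary_read_has_the_gap(self):
        model = single_intron_model(1.0)
        cfg = SimConfig(seed=5, n_molecules=300, n_reads=2000, host_fraction=0.0, umi_dup_rate=0.0)
        lib, molecules = simulate_input_library(model, cfg, rep=0)
        assert all(m.retained_introns == frozenset() for m in molecules if m.reference == model.genome_id)
        donor, acceptor = 1100, 1600
        for r in lib.reads:
            spans_boundary = any(s < donor for s, e in r.blocks) and any(
                e > acceptor for s, e in r.blocks
            )
            if spans_boundary:
                assert (donor, acceptor) in [
                    (e1, s2) for (_, e1), (s2, _) in zip(r.blocks, r.blocks[1:])
                ]

    def test_junction_read_fraction_matches_closed_form(self):
        """Single intron at efficiency s: a read carries the junction iff it
        came from a spliced molecule and starts in the (L-1)-wide window around
        the junction, so E[fraction] = s (L-1) / (L_spliced - L + 1)."""
        s, n_mol, n_reads, L = 0.5, 50_000, 50_000, 100
        model = single_intron_model(s)
        cfg = SimConfig(
            seed=11, n_molecules=n_mol, n_reads=n_reads, host_fraction=0.0,
            umi_dup_rate=0.0, read_length=L, umi_length=12,
        )
        lib, _ = simulate_input_library(model, cfg, rep=0)
        frac = np.mean([len(r.blocks) > 1 for r in lib.reads])
        l_spliced = 2000
        p = s * (L - 1) / (l_spliced - L + 1)
        se = np.sqrt(
            p * (1 - p) / n_reads + ((L - 1) / (l_spliced - L + 1)) ** 2 * s * (1 - s) / n_mol
        )
        assert abs(frac - p) < 3 * se

    def test_short_molecules_are_skipped_with_warning(self, caplog):
        model = single_intron_model(0.5)
        cfg = SimConfig(seed=1, n_molecules=50, n_reads=100, host_fraction=0.0, read_length=2100)
        with caplog.at_level("WARNING", logger="advdsrna.sim_reads"):
            lib, _ = simulate_input_library(model, cfg, rep=0)
        # spliced molecules (length 2000) are all shorter than the read
        assert "skipped" in caplog.text
        assert all(r.mapped_length == 2100 for r in lib.reads)

    def test_umi_duplicates_share_key_and_dedup_away(self, minimal_model):
        cfg = SimConfig(seed=9, n_molecules=500, n_reads=2000, umi_dup_rate=0.5)
        lib, _ = simulate_input_library(minimal_model, cfg, rep=0)
        assert len(lib.reads) > 2000  # duplicates injected
        assert len(deduplicate_umis(lib).reads) <= 2000


class TestIpLibrary:
    def test_background_zero_and_no_duplexes_gives_empty_library(self, minimal_model):
        cfg = SimConfig(seed=2, n_molecules=500, n_reads=500, ip_background_capture=0.0)
        _, molecules = simulate_input_library(minimal_model, cfg, rep=0)
        lib = simulate_ip_library(minimal_model, molecules, [], cfg, rep=0)
        assert len(lib.reads) == 0

    def test_wildtype_regime_ip_is_empty(self, minimal_model):
        """Perfect splicing + no read-through + zero background: nothing to pull down."""
        model = set_readthrough_prob(set_splice_efficiencies(minimal_model, 1.0), 0.0)
        duplexes = predict_duplex_regions(model)
        cfg = SimConfig(seed=2, n_molecules=1000, n_reads=500, ip_background_capture=0.0)
        _, molecules = simulate_input_library(model, cfg, rep=0)
        lib = simulate_ip_library(model, molecules, duplexes, cfg, rep=0)
        assert len(lib.reads) == 0

    def test_huge_overhang_means_no_trimming(self, minimal_model):
        duplexes = predict_duplex_regions(minimal_model)
        cfg = SimConfig(
            seed=4, n_molecules=400, n_reads=0, rnase_overhang=10_000,
            ip_background_capture=0.0, ip_duplex_capture=1.0, duplex_formation_rate=1.0,
        )
        _, molecules = simulate_input_library(minimal_model, cfg, rep=0)
        rng = _rng(cfg, "WT", 0, stream=2)
        captured, n_eng, n_bg = capture_molecules(molecules, duplexes, cfg, rng)
        assert n_eng > 0 and n_bg == 0
        originals = {m.molecule_id: m.span_blocks for m in molecules}
        for frag in captured:
            assert frag.span_blocks == originals[frag.molecule_id]

    def test_engaged_fraction_matches_probability_oracle(self, ad5_model):
        """Fraction of captured molecules that are duplex-engaged vs a direct
        per-molecule probability computation (independent nested loops)."""
        model = set_splice_efficiencies(ad5_model, 0.5)
        duplexes = predict_duplex_regions(model)
        cfg = SimConfig(seed=13, n_molecules=20_000, n_reads=0)
        _, molecules = simulate_input_library(model, cfg, rep=0)
        rng = _rng(cfg, "WT", 0, stream=2)
        _, n_eng, n_bg = capture_molecules(molecules, duplexes, cfg, rng)

        # oracle: availability and engagement probability recomputed directly
        by_unit = {}
        for m in molecules:
            by_unit.setdefault(m.unit_id, []).append(m)

        def overlaps(m, iv):
            return any(max(s, iv[0]) < min(e, iv[1]) for s, e in m.span_blocks)

        avail_oracle = []
        for d in duplexes:
            a = {}
            for side, partner in (("top", d.bottom_unit), ("bottom", d.top_unit)):
                pool = by_unit.get(partner, [])
                a[side] = sum(overlaps(x, d.interval) for x in pool) / len(pool) if pool else 0.0
            avail_oracle.append(a)

        exp_eng = exp_bg = var = 0.0
        for m in molecules:
            p_not = 1.0
            for di, d in enumerate(duplexes):
                if m.unit_id == d.top_unit:
                    side = "top"
                elif m.unit_id == d.bottom_unit:
                    side = "bottom"
                else:
                    continue
                if not overlaps(m, d.interval):
                    continue
                p_not *= 1.0 - cfg.duplex_formation_rate * avail_oracle[di][side]
            p_eng = (1.0 - p_not) * cfg.ip_duplex_capture
            p_bg = p_not * cfg.ip_background_capture
            exp_eng += p_eng
            exp_bg += p_bg
            var += p_eng * (1 - p_eng) + p_bg * (1 - p_bg)

        expected_frac = exp_eng / (exp_eng + exp_bg)
        observed_frac = n_eng / (n_eng + n_bg)
        se = np.sqrt(var) / (exp_eng + exp_bg)  # delta-method scale, conservative
        assert abs(observed_frac - expected_frac) < 3 * max(se, 0.01)

    def test_lower_splice_efficiency_never_reduces_engagement(self, ad5_model):
        """Monotonicity: retaining more introns can only create more duplexes."""
        counts = []
        for eff in (0.95, 0.6, 0.2):
            model = set_splice_efficiencies(ad5_model, eff)
            duplexes = predict_duplex_regions(model)
            cfg = SimConfig(seed=21, n_molecules=8000, n_reads=0)
            _, molecules = simulate_input_library(model, cfg, rep=0)
            rng = _rng(cfg, "WT", 0, stream=2)
            _, n_eng, _ = capture_molecules(molecules, duplexes, cfg, rng)
            counts.append(n_eng)
        assert counts[0] <= counts[1] <= counts[2]

    def test_read_order_independent_of_python_hashing(self, minimal_model, small_cfg):
        lib1 = simulate_ip_library(
            minimal_model,
            simulate_input_library(minimal_model, small_cfg, 0)[1],
            predict_duplex_regions(minimal_model),
            small_cfg,
            0,
        )
        lib2 = simulate_ip_library(
            minimal_model,
            simulate_input_library(minimal_model, small_cfg, 0)[1],
            predict_duplex_regions(minimal_model),
            small_cfg,
            0,
        )
        assert _lib_signature(lib1) == _lib_signature(lib2)


class TestSimConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"host_fraction": 1.5},
            {"umi_dup_rate": -0.1},
            {"read_length": 0},
            {"rnase_overhang": -1},
            {"duplex_formation_rate": 2.0},
        ],
    )
    def test_rejects_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)
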