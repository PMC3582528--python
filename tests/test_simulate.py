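"""Simulator: genomes, SV sets, substitutions, pairs and ideal mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deltrim.core import SVRecord
from deltrim.coverage import build_coverage
from deltrim.simulate import (
    PlacementError,
    SimConfig,
    add_substitutions,
    apply_svs,
    codes_to_str,
    draw_sv_set,
    generate_pairs,
    project_to_reference,
    simulate_reference,
    str_to_codes,
)


class TestReference:
    def test_length_and_alphabet(self):
        seq = codes_to_str(simulate_reference(10, seed=1))
        assert len(seq) == 10 and set(seq) <= set("ACGT")

    def test_deterministic(self):
        assert np.array_equal(simulate_reference(500, 3), simulate_reference(500, 3))

    def test_gc_content_near_half(self):
        codes = simulate_reference(10**6, seed=7)
        gc = np.isin(codes, [1, 2]).mean()
        assert 0.48 <= gc <= 0.52

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            simulate_reference(0, seed=1)


class TestDrawSvSet:
    def test_zero_deletions(self):
        assert draw_sv_set(SimConfig(n_deletions=0)) == []

    def test_counts_and_length_multiset(self):
        cfg = SimConfig(genome_length=10**7, n_deletions=50, seed=4)
        svs = draw_sv_set(cfg)
        dels = [s for s in svs if s.sv_type == "DEL"]
        ins = [s for s in svs if s.sv_type == "INS"]
        assert len(dels) == 50 and len(ins) == 50
        assert sorted(d.length for d in dels) == sorted(i.ins_length for i in ins)

    def test_lengths_within_sampler_bounds(self):
        svs = draw_sv_set(SimConfig(genome_length=10**7, n_deletions=50, seed=5))
        for sv in svs:
            assert 100 <= sv.length <= 10_000

    def test_sorted_and_separated(self):
        cfg = SimConfig(genome_length=10**7, n_deletions=50, seed=6)
        svs = draw_sv_set(cfg)
        for a, b in zip(svs, svs[1:]):
            assert b.start - a.end >= cfg.min_sv_gap

    def test_placement_error_when_too_dense(self):
        with pytest.raises(PlacementError):
            draw_sv_set(SimConfig(genome_length=50_000, n_deletions=50, seed=1))


def _edit_oracle(ref_str, svs, sample_str):
    """Direct string-editing check of apply_svs (insertions excised)."""
    kept = []
    cursor = 0
    for sv in svs:
        kept.append(ref_str[cursor : sv.start])
        cursor = sv.end
    kept.append(ref_str[cursor:])
    # remove novel stretches from the sample using the DEL/INS bookkeeping
    return "".join(kept), sample_str


class TestApplySvs:
    def test_single_deletion_bookkeeping(self):
        ref = simulate_reference(1000, 1)
        sample, cmap = apply_svs(ref, [SVRecord("chr1", 200, 300, "DEL")], seed=2)
        assert len(sample) == 900
        assert cmap.map_interval(150, 250) is None  # crosses the junction
        assert cmap.map_interval(210, 220) == 310  # shifted by the deletion

    def test_single_insertion_bookkeeping(self):
        ref = simulate_reference(1000, 1)
        sample, cmap = apply_svs(ref, [SVRecord("chr1", 500, 500, "INS", 50)], seed=2)
        assert len(sample) == 1050
        assert cmap.map_interval(500, 510) is None  # inside novel sequence
        assert cmap.map_interval(560, 570) == 510  # past the insertion

    def test_no_svs_is_identity(self):
        ref = simulate_reference(300, 1)
        sample, cmap = apply_svs(ref, [], seed=0)
        assert np.array_equal(sample, ref)
        assert cmap.map_interval(0, 300) == 0

    def test_rejects_overlapping_svs(self):
        ref = simulate_reference(1000, 1)
        bad = [SVRecord("chr1", 100, 300, "DEL"), SVRecord("chr1", 200, 400, "DEL")]
        with pytest.raises(ValueError):
            apply_svs(ref, bad, seed=0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(data=st.data())
    def test_length_bookkeeping_and_deleted_sequence(self, data):
        """Sample length and retained sequence match direct string editing."""
        n = data.draw(st.integers(0, 5))
        ref = simulate_reference(2000, 9)
        ref_str = codes_to_str(ref)
        # build sorted non-overlapping SVs
        cuts = sorted(data.draw(st.sets(st.integers(0, 1999), min_size=2 * n, max_size=2 * n)))
        svs = []
        for i in range(n):
            s, e = cuts[2 * i], cuts[2 * i + 1]
            if s == e:
                svs.append(SVRecord("chr1", s, e, "INS", 5))
            else:
                svs.append(SVRecord("chr1", s, e, "DEL"))
        ok = all(b.start >= a.end for a, b in zip(svs, svs[1:]))
        if not ok:
            return
        sample, cmap = apply_svs(ref, svs, seed=5)
        dels = sum(s.length for s in svs if s.sv_type == "DEL")
        ins = sum(s.ins_length for s in svs if s.sv_type == "INS")
        assert len(sample) == 2000 - dels + ins
        # non-novel sample bases spell the reference with DELs excised
        surviving = "".join(
            ref_str[cmap.ref_starts[i] : cmap.ref_starts[i] + cmap.lengths[i]]
            for i in range(len(cmap.lengths))
            if cmap.ref_starts[i] >= 0
        )
        expected, _ = _edit_oracle(ref_str, svs, None)
        assert surviving == expected


class TestSubstitutions:
    def test_rate_zero_identity(self):
        seq = simulate_reference(5000, 2)
        assert np.array_equal(add_substitutions(seq, 0.0, 1), seq)

    def test_rate_one_changes_every_base(self):
        seq = simulate_reference(5000, 2)
        mut = add_substitutions(seq, 1.0, 1)
        assert not (mut == seq).any()

    def test_default_rate_poisson_band(self):
        seq = simulate_reference(10**6, 3)
        mut = add_substitutions(seq, 1e-4, 11)
        n = int((mut != seq).sum())
        assert 70 <= n <= 130  # 100 +/- 3 sqrt(100)


class TestGeneratePairs:
    def test_pair_count_formula(self):
        cfg = SimConfig(genome_length=10**6, coverage=5.0)
        sample = simulate_reference(10**6, 4)
        pairs = generate_pairs(sample, cfg, seed=1)
        assert len(pairs) == 25_000  # c G / (2 r)

    def test_inner_distance_statistics(self):
        cfg = SimConfig(genome_length=10**6, coverage=2.0)
        sample = simulate_reference(10**6, 4)
        pairs = generate_pairs(sample, cfg, seed=2)
        gaps = (pairs["down_start"] - pairs["up_end"]).to_numpy()
        assert abs(gaps[:10_000].mean() - 200) < 1.5  # SE = 50/100
        assert (gaps >= 0).all()

    def test_reads_within_bounds(self):
        cfg = SimConfig(genome_length=20_000, coverage=5.0)
        sample = simulate_reference(20_000, 4)
        pairs = generate_pairs(sample, cfg, seed=3)
        assert (pairs["up_start"] >= 0).all()
        assert (pairs["down_end"] <= 20_000).all()

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            generate_pairs(simulate_reference(300, 1), SimConfig(), seed=1)


class TestProjectToReference:
    def _setup(self):
        ref = simulate_reference(5000, 1)
        svs = [SVRecord("chr1", 2000, 2500, "DEL")]
        sample, cmap = apply_svs(ref, svs, seed=2)
        return cmap

    def test_upstream_pair_keeps_coordinates(self):
        cmap = self._setup()
        import pandas as pd

        pairs = pd.DataFrame(
            [{"up_start": 100, "up_end": 200, "down_start": 400, "down_end": 500,
              "pair_id": "a"}]
        )
        out = project_to_reference(pairs, cmap)
        assert out.iloc[0]["up_start"] == 100 and out.iloc[0]["down_end"] == 500

    def test_deletion_spanning_pair_gap_enlarged(self):
        cmap = self._setup()
        import pandas as pd

        # sample coords: junction at 2000; inner gap 200 straddles it
        pairs = pd.DataFrame(
            [{"up_start": 1800, "up_end": 1900, "down_start": 2100, "down_end": 2200,
              "pair_id": "a"}]
        )
        out = project_to_reference(pairs, cmap)
        gap = int(out.iloc[0]["down_start"] - out.iloc[0]["up_end"])
        assert gap == 200 + 500

    def test_junction_crossing_read_dropped(self):
        cmap = self._setup()
        import pandas as pd

        pairs = pd.DataFrame(
            [{"up_start": 1950, "up_end": 2050, "down_start": 2200, "down_end": 2300,
              "pair_id": "a"}]
        )
        assert len(project_to_reference(pairs, cmap)) == 0

    def test_read_inside_insertion_dropped(self):
        ref = simulate_reference(5000, 1)
        sample, cmap = apply_svs(ref, [SVRecord("chr1", 2000, 2000, "INS", 400)], 2)
        import pandas as pd

        pairs = pd.DataFrame(
            [{"up_start": 2100, "up_end": 2200, "down_start": 2450, "down_end": 2550,
              "pair_id": "a"}]
        )
        assert len(project_to_reference(pairs, cmap)) == 0


@pytest.fixture(scope="module")
def sim():
    cfg = SimConfig(genome_length=10**6, n_deletions=5, coverage=5.0, seed=8)
    rng = np.random.default_rng(cfg.seed)
    ref = simulate_reference(cfg.genome_length, rng)
    svs = draw_sv_set(cfg, seed=rng)
    sample, cmap = apply_svs(ref, svs, rng)
    pairs = generate_pairs(sample, cfg, rng)
    aligned = project_to_reference(pairs, cmap, chrom=cfg.chrom)
    return cfg, svs, aligned


class TestPipelineScaleInvariants:
    """Coverage and deletion invariants on a 1 Mb simulation."""

    def test_mean_coverage_matches_config_far_from_svs(self, sim):
        cfg, svs, aligned = sim
        track = build_coverage(aligned, cfg.chrom, 0, cfg.genome_length)
        margin = int(cfg.distance_mean + 2 * cfg.read_length)
        mask = np.ones(cfg.genome_length, dtype=bool)
        for sv in svs:
            mask[max(0, sv.start - margin) : sv.end + margin] = False
        mask[:margin] = mask[-margin:] = False
        mean_cov = track.counts[mask].mean()
        assert abs(mean_cov - cfg.coverage) / cfg.coverage < 0.05

    def test_no_read_starts_inside_deletions(self, sim):
        cfg, svs, aligned = sim
        starts = np.concatenate(
            [aligned["up_start"].to_numpy(), aligned["down_start"].to_numpy()]
        )
        for sv in svs:
            if sv.sv_type == "DEL":
                inside = ((starts > sv.start) & (starts < sv.end)).sum()
                assert inside == 0

    def test_byte_identical_rerun(self, sim):
        cfg, svs, aligned = sim
        rng = np.random.default_rng(cfg.seed)
        ref = simulate_reference(cfg.genome_length, rng)
        svs2 = draw_sv_set(cfg, seed=rng)
        sample, cmap = apply_svs(ref, svs2, rng)
        pairs = generate_pairs(sample, cfg, rng)
        aligned2 = project_to_reference(pairs, cmap, chrom=cfg.chrom)
        assert svs2 == svs
        assert aligned2.equals(aligned)


def test_codes_str_round_trip():
    assert codes_to_str(str_to_codes("ACGTACGT")) == "ACGTACGT"
    with pytest.raises(ValueError):
        str_to_codes("ACGN")
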