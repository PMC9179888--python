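import numpy as np
import pandas as pd
import pytest

from selsig.io import MISSING, GenomeMap
from selsig.roh import (DEFAULT_CLASS_RULES, IncidenceTrack, RohClassRule,
                        call_islands, detect_roh, froh, froh_table,
                        roh_incidence)
from selsig.sim import SimConfig, make_fixture, simulate_panels

from _oracles import flag_merge_oracle, incidence_oracle, roh_windows_oracle


def _markers(pos, chrom=1):
    pos = np.asarray(pos)
    return pd.DataFrame({"snp_id": [f"s{i}" for i in range(len(pos))],
                         "chrom": chrom, "pos_bp": pos, "a1": "A", "a2": "B"})


def _genome(L):
    return GenomeMap(pd.DataFrame({"chrom": [1], "first_snp_bp": [0],
                                   "last_snp_bp": [L], "n_snps": [2]}))


class TestDetectRoh:
    def test_long_homozygous_stretch_single_segment(self):
        """100 homozygous SNPs over 4.5 Mb, gaps 0.2 Mb: one segment."""
        pos = np.arange(100) * 45_455 + 1
        g = np.full(100, 2, dtype=np.int8)
        segs = detect_roh(g, _markers(pos), DEFAULT_CLASS_RULES[1])
        assert len(segs) == 1
        assert (segs[0].start_bp, segs[0].end_bp) == (pos[0], pos[-1])
        assert segs[0].n_snps == 100

    def test_fourteen_snps_rejected(self):
        """14 homozygous SNPs over 2 Mb violate the 15-SNP minimum."""
        pos = np.linspace(1, 2_000_001, 14).astype(int)
        segs = detect_roh(np.zeros(14, dtype=np.int8), _markers(pos),
                          DEFAULT_CLASS_RULES[1])
        assert segs == []

    def test_large_gap_splits_run(self):
        """A >1 Mb gap splits an otherwise qualifying run unconditionally."""
        pos = np.concatenate([np.arange(20) * 80_000 + 1,
                              np.arange(20) * 80_000 + 3_000_000])
        g = np.full(40, 2, dtype=np.int8)
        segs = detect_roh(g, _markers(pos), DEFAULT_CLASS_RULES[1])
        assert len(segs) == 2
        assert all(s.n_snps == 20 for s in segs)

    def test_run_cannot_end_on_het_or_missing(self):
        """Endpoints must be called homozygous under a relaxed budget."""
        pos = np.arange(40) * 500_000 + 1
        g = np.full(40, 2, dtype=np.int8)
        g[0] = 1
        g[-1] = MISSING
        rule = RohClassRule(min_length_bp=4_000_000, allowed_missing=1,
                            allowed_het=1)
        segs = detect_roh(g, _markers(pos), rule)
        assert len(segs) == 1
        assert segs[0].start_bp == pos[1] and segs[0].end_bp == pos[-2]

    @pytest.mark.parametrize("class_key", sorted(DEFAULT_CLASS_RULES))
    def test_matches_exhaustive_window_oracle(self, class_key, rng):
        """Detector equals the O(n^2) exhaustive-window oracle exactly."""
        rule = DEFAULT_CLASS_RULES[class_key]
        for rep in range(20):
            n = 300
            pos = np.sort(rng.choice(np.arange(1, 40_000_000, 1000), n,
                                     replace=False))
            g = rng.choice([0, 2, 1, MISSING], n,
                           p=[0.44, 0.44, 0.10, 0.02]).astype(np.int8)
            segs = detect_roh(g, _markers(pos), rule)
            got = sorted((np.searchsorted(pos, s.start_bp),
                          np.searchsorted(pos, s.end_bp)) for s in segs)
            assert got == sorted(roh_windows_oracle(pos, g, rule))

    def test_allele_relabeling_invariance(self, rng):
        """Flipping dosage d -> 2-d at any subset of SNPs changes nothing."""
        pos = np.sort(rng.choice(np.arange(1, 30_000_000, 1000), 200,
                                 replace=False))
        g = rng.choice([0, 2, 1, MISSING], 200,
                       p=[0.45, 0.45, 0.08, 0.02]).astype(np.int8)
        flip = rng.random(200) < 0.5
        g2 = g.copy()
        called = g2 != MISSING
        g2[called & flip] = 2 - g2[called & flip]
        for rule in DEFAULT_CLASS_RULES.values():
            a = [(s.start_bp, s.end_bp) for s in detect_roh(g, _markers(pos), rule)]
            b = [(s.start_bp, s.end_bp) for s in detect_roh(g2, _markers(pos), rule)]
            assert a == b


class TestFroh:
    def test_no_segments_zero(self):
        assert froh([], _genome(100_000_000)) == 0.0

    def test_overlapping_segments_union_not_sum(self):
        """[1-3] and [2-5] Mb on L=100 Mb give 0.04, not 0.05."""
        segs = pd.DataFrame({"chrom": [1, 1],
                             "start_bp": [1_000_000, 2_000_000],
                             "end_bp": [3_000_000, 5_000_000]})
        assert froh(segs, _genome(100_000_000)) == pytest.approx(0.04)

    def test_tiling_genome_gives_one(self):
        segs = pd.DataFrame({"chrom": [1], "start_bp": [0],
                             "end_bp": [100_000_000]})
        assert froh(segs, _genome(100_000_000)) == pytest.approx(1.0)

    def test_monotone_in_class_min_length(self):
        """Per sample, F_ROH(16Mb) <= ... <= F_ROH(1Mb)."""
        panels, _ = simulate_panels(SimConfig(
            seed=11, n_chrom=4, snps_per_chrom=600, generations=20,
            populations=(SimConfig(seed=0).populations[0],)))
        panel = panels[0].subset(sample_idx=np.arange(20))
        from selsig.io import genome_map
        per_sample, _ = froh_table(panel, genome_map(panel))
        cols = [c for c in per_sample.columns if c.startswith("froh_")]
        values = per_sample[cols].to_numpy()  # ordered 16 -> 1 Mb
        assert (np.diff(values, axis=1) >= -1e-12).all()
        assert ((values >= 0) & (values <= 1)).all()


class TestIncidence:
    def test_single_segment_counts(self):
        markers = _markers(np.arange(10) * 100_000 + 1)
        seg = pd.DataFrame({"sample_id": ["s1"], "chrom": [1],
                            "start_bp": [200_001], "end_bp": [500_001]})
        track = roh_incidence(seg, markers, n_samples=5)
        assert list(track.counts) == [0, 0, 1, 1, 1, 1, 0, 0, 0, 0]

    def test_empty_segments_zero_track(self):
        markers = _markers(np.arange(5) * 1000 + 1)
        track = roh_incidence(pd.DataFrame(
            columns=["sample_id", "chrom", "start_bp", "end_bp"]),
            markers, n_samples=3)
        assert track.counts.sum() == 0

    def test_matches_membership_scan(self, rng):
        """Hand-placed overlapping segments equal the brute-force count."""
        markers = _markers(np.arange(50) * 100_000 + 1)
        rows = []
        for sid in ["a", "b", "c", "d", "e"]:
            for _ in range(rng.integers(1, 4)):
                lo, hi = np.sort(rng.choice(50, 2, replace=False))
                rows.append((sid, 1, int(markers.pos_bp[lo]),
                             int(markers.pos_bp[hi])))
        seg = pd.DataFrame(rows, columns=["sample_id", "chrom", "start_bp",
                                          "end_bp"])
        track = roh_incidence(seg, markers, n_samples=5)
        expected = incidence_oracle(rows, markers["chrom"].to_numpy(),
                                    markers["pos_bp"].to_numpy())
        assert np.array_equal(track.counts, expected)


class TestCallIslands:
    def _track(self, counts, chrom=None):
        counts = np.asarray(counts)
        n = len(counts)
        chrom = np.ones(n, dtype=int) if chrom is None else np.asarray(chrom)
        markers = pd.DataFrame({"snp_id": [f"s{i}" for i in range(n)],
                                "chrom": chrom,
                                "pos_bp": np.arange(n) * 1000 + 1})
        return IncidenceTrack(markers=markers, counts=counts,
                              n_samples=int(counts.max()) + 1)

    def test_single_peak_single_region(self):
        counts = np.zeros(100, dtype=int)
        counts[40] = 9
        regions, thr = call_islands(self._track(counts), top_fraction=0.01)
        assert thr == 9
        assert len(regions) == 1
        assert regions[0].start_bp == regions[0].end_bp == 40 * 1000 + 1
        assert regions[0].n_snps_in_region == 1

    def test_matches_quantile_merge_oracle(self, rng):
        counts = rng.integers(0, 30, 200)
        chrom = np.sort(rng.integers(1, 4, 200))
        track = self._track(counts, chrom)
        regions, thr = call_islands(track, top_fraction=0.05, merge_gap_snps=1)
        o_thr, o_groups = flag_merge_oracle(
            chrom, track.markers["pos_bp"].to_numpy(), counts,
            top_fraction=0.05, merge_gap=1)
        assert thr == o_thr
        assert [(r.chrom, r.start_bp, r.end_bp) for r in regions] == \
            [(c, s, e) for c, s, e, _ in o_groups]

    def test_constant_track_flags_all(self, caplog):
        counts = np.full(50, 7)
        with caplog.at_level("WARNING"):
            regions, thr = call_islands(self._track(counts))
        assert thr == 7
        assert sum(r.n_snps_in_region for r in regions) == 50
        assert any("degenerate" in m for m in caplog.messages)

    def test_peak_is_leftmost_max(self):
        counts = np.array([0, 5, 9, 9, 5, 0])
        regions, _ = call_islands(self._track(counts), top_fraction=0.5)
        assert regions[0].peak_snp_id == "s2"


def test_roh_toy_fixture_expected_table():
    panel, expected = make_fixture("roh_toy")
    from selsig.roh import detect_roh_panel
    seg = detect_roh_panel(panel, DEFAULT_CLASS_RULES[1])
    assert len(seg) == 1
    row = seg.iloc[0]
    exp = expected.iloc[0]
    assert (row.sample_id, row.chrom, row.start_bp, row.end_bp, row.n_snps) \
        == (exp.sample_id, exp.chrom, exp.start_bp, exp.end_bp, exp.n_snps)


def test_sample_order_permutation_invariance(rng):
    """Permuting samples permutes per-sample results and nothing else."""
    panels, _ = simulate_panels(SimConfig(
        seed=3, n_chrom=2, snps_per_chrom=400, generations=10,
        populations=(SimConfig(seed=0).populations[0],)))
    panel = panels[0].subset(sample_idx=np.arange(12))
    perm = rng.permutation(12)
    from selsig.io import genome_map
    from selsig.roh import detect_roh_panel
    gm = genome_map(panel)
    a, _ = froh_table(panel, gm)
    b, _ = froh_table(panel.subset(sample_idx=perm), gm)
    merged = a.merge(b, on="sample_id", suffixes=("_a", "_b"))
    for col in [c for c in a.columns if c.startswith("froh_")]:
        assert np.allclose(merged[f"{col}_a"], merged[f"{col}_b"])
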