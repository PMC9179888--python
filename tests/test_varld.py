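import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from selsig.io import GenotypePanel
from selsig.sim import (PopulationHistory, SimConfig, SweepSpec, make_fixture,
                        simulate_panels)
from selsig.varld import (VarLdConfig, call_varld_regions, ld_matrix,
                          varld_raw, varld_scan)

from _oracles import threshold_oracle


def _panel(dosage, pos, chrom=None, name="p"):
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_snps = dosage.shape
    chrom = np.ones(n_snps, dtype=int) if chrom is None else np.asarray(chrom)
    markers = pd.DataFrame({"snp_id": [f"s{j}" for j in range(n_snps)],
                            "chrom": chrom, "pos_bp": pos,
                            "a1": "A", "a2": "B"})
    samples = pd.DataFrame({"sample_id": [f"{name}{k}" for k in range(n_samples)],
                            "sex": 1, "population": name})
    return GenotypePanel(markers=markers, samples=samples, dosage=dosage)


class TestLdMatrix:
    def test_uncorrelated_columns_identity(self):
        d = np.array([[0, 0], [0, 2], [2, 0], [2, 2]])
        panel = _panel(d, pos=[1000, 2000])
        np.testing.assert_allclose(ld_matrix(panel, slice(0, 2)), np.eye(2),
                                   atol=1e-12)

    def test_duplicated_column_all_ones(self, rng):
        col = rng.integers(0, 3, (8, 1))
        panel = _panel(np.hstack([col, col]), pos=[1000, 2000])
        np.testing.assert_allclose(ld_matrix(panel, slice(0, 2)),
                                   np.ones((2, 2)), atol=1e-12)

    def test_three_snp_hand_computation(self, rng):
        d = rng.integers(0, 3, (10, 3))
        panel = _panel(d, pos=[1000, 2000, 3000])
        got = ld_matrix(panel, slice(0, 3))
        expected = np.corrcoef(d.T)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        np.testing.assert_allclose(ld_matrix(panel, slice(0, 3), "r2"),
                                   expected ** 2, atol=1e-12)

    def test_window_across_chromosomes_rejected(self, rng):
        panel = _panel(rng.integers(0, 3, (6, 4)), pos=[1, 2, 1, 2],
                       chrom=[1, 1, 2, 2])
        with pytest.raises(ValueError, match="chromosome"):
            ld_matrix(panel, slice(1, 3))


class TestVarldRaw:
    def test_identical_matrices_zero(self, rng):
        a = rng.random((6, 6))
        a = (a + a.T) / 2
        assert varld_raw(a, a) == 0.0

    @pytest.mark.parametrize("ra,rb", [(0.8, 0.0), (0.5, -0.5), (1.0, 0.3)])
    def test_two_snp_closed_form(self, ra, rb):
        """2x2 correlation eigenvalues are {1+|r|, 1-|r|}, so the sorted
        spectra give raw = 2 * ||rA| - |rB|| (0.8 vs 0 -> 1.6)."""
        A = np.array([[1, ra], [ra, 1]])
        B = np.array([[1, rb], [rb, 1]])
        assert varld_raw(A, B) == pytest.approx(2 * abs(abs(ra) - abs(rb)),
                                                abs=1e-9)

    def test_matches_independent_eigensolver(self, rng):
        for _ in range(20):
            a, b = rng.random((2, 10, 10))
            a, b = (a + a.T) / 2, (b + b.T) / 2
            expected = np.abs(np.sort(scipy.linalg.eigh(a, eigvals_only=True))
                              - np.sort(scipy.linalg.eigh(b, eigvals_only=True))
                              ).sum()
            assert varld_raw(a, b) == pytest.approx(expected, abs=1e-9)

    def test_symmetry_and_nonnegativity(self, rng):
        a, b = rng.random((2, 8, 8))
        a, b = (a + a.T) / 2, (b + b.T) / 2
        assert varld_raw(a, b) == pytest.approx(varld_raw(b, a))
        assert varld_raw(a, b) >= 0

    def test_common_permutation_invariance(self, rng):
        """Permuting SNP order identically in both windows changes nothing."""
        a, b = rng.random((2, 8, 8))
        a, b = (a + a.T) / 2, (b + b.T) / 2
        p = rng.permutation(8)
        assert varld_raw(a[np.ix_(p, p)], b[np.ix_(p, p)]) == \
            pytest.approx(varld_raw(a, b), abs=1e-9)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            varld_raw(np.eye(3), np.eye(4))


class TestVarldScan:
    def test_identical_panels_all_zero_degenerate(self, caplog):
        (pa, pb), expected_raw = make_fixture("varld_toy")
        with caplog.at_level("WARNING"):
            track = varld_scan(pa, pb, VarLdConfig(window_snps=10))
        assert np.allclose(track.raw_score, expected_raw)
        assert np.allclose(track.std_score, 0.0)
        assert any("degenerate" in m for m in caplog.messages)

    def test_window_count_per_chromosome(self, rng):
        """Two chromosomes (30 and 40 SNPs), window 3: 28 + 38 windows."""
        n = 70
        chrom = np.repeat([1, 2], [30, 40])
        pos = np.concatenate([np.arange(30), np.arange(40)]) * 1000 + 1
        pa = _panel(rng.integers(0, 3, (12, n)), pos, chrom, "a")
        pb = _panel(rng.integers(0, 3, (12, n)), pos, chrom, "b")
        track = varld_scan(pa, pb, VarLdConfig(window_snps=3))
        assert len(track) == (30 - 2) + (40 - 2)
        assert track.std_score.mean() == pytest.approx(0.0, abs=1e-9)
        assert track.std_score.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_anchor_is_middle_snp(self, rng):
        n = 20
        pos = np.arange(n) * 1000 + 1
        pa = _panel(rng.integers(0, 3, (10, n)), pos, name="a")
        pb = _panel(rng.integers(0, 3, (10, n)), pos, name="b")
        track = varld_scan(pa, pb, VarLdConfig(window_snps=5))
        assert track.anchor_pos_bp.iloc[0] == pos[2]
        assert track.anchor_pos_bp.iloc[-1] == pos[n - 1 - 2]

    def test_short_chromosome_skipped(self, rng, caplog):
        chrom = np.repeat([1, 2], [4, 30])
        pos = np.concatenate([np.arange(4), np.arange(30)]) * 1000 + 1
        pa = _panel(rng.integers(0, 3, (10, 34)), pos, chrom, "a")
        pb = _panel(rng.integers(0, 3, (10, 34)), pos, chrom, "b")
        with caplog.at_level("WARNING"):
            track = varld_scan(pa, pb, VarLdConfig(window_snps=10))
        assert set(track.chrom) == {2}
        assert any("skipped" in m for m in caplog.messages)

    def test_mismatched_maps_rejected(self, rng):
        pa = _panel(rng.integers(0, 3, (6, 10)), np.arange(10) * 10 + 1)
        pb = _panel(rng.integers(0, 3, (6, 10)), np.arange(10) * 10 + 2)
        with pytest.raises(ValueError, match="marker map"):
            varld_scan(pa, pb, VarLdConfig(window_snps=3))


class TestCallVarldRegions:
    def _track(self, std):
        n = len(std)
        return pd.DataFrame({"chrom": 1,
                             "anchor_snp_id": [f"s{i}" for i in range(n)],
                             "anchor_pos_bp": np.arange(n) * 1000 + 1,
                             "raw_score": np.abs(std), "std_score": std})

    def test_planted_extremes_flagged(self, rng):
        std = rng.normal(0, 1, 1000)
        planted = rng.choice(1000, 10, replace=False)
        std[planted] = 10 + rng.random(10)
        regions = call_varld_regions(self._track(std),
                                     top_fractions=(0.01,))[0.01]
        thr = threshold_oracle(std, 0.01)
        flagged_pos = {p for r in regions
                       for p in range(r.start_bp, r.end_bp + 1, 1000)}
        expected = {int(i) * 1000 + 1 for i in np.flatnonzero(std >= thr)}
        got = {int(r.start_bp) + k * 1000 for r in regions
               for k in range(r.n_snps_in_region)}
        assert got == expected
        assert set(planted * 1000 + 1) <= got

    def test_thresholds_nest(self, rng):
        std = rng.normal(0, 1, 2000)
        regions = call_varld_regions(self._track(std))
        anchors = {}
        for f, regs in regions.items():
            anchors[f] = {(r.chrom, s) for r in regs
                          for s in range(r.start_bp, r.end_bp + 1, 1000)}
        assert anchors[0.0001] <= anchors[0.001] <= anchors[0.01]

    def test_degenerate_track_no_regions(self, caplog):
        with caplog.at_level("WARNING"):
            regions = call_varld_regions(self._track(np.zeros(100)))
        assert all(not regs for regs in regions.values())


def test_differ_ld_sweep_recovered_single_seed():
    """The max standardized window lands in the injected sweep interval."""
    sweep = SweepSpec(chrom=1, start_bp=15_000_000, end_bp=35_000_000,
                      populations=("popA",), mode="differ_LD")
    cfg = SimConfig(seed=42, n_chrom=3, snps_per_chrom=750,
                    chrom_length_bp=50_000_000,
                    populations=(PopulationHistory("popA", 100, 48),
                                 PopulationHistory("popB", 100, 48)),
                    sweeps=(sweep,))
    panels, truth = simulate_panels(cfg)
    from selsig.qc import QcThresholds, apply_qc, intersect_snps
    a, _ = apply_qc(panels[0], QcThresholds())
    b, _ = apply_qc(panels[1], QcThresholds())
    a, b = intersect_snps(a, b)
    track = varld_scan(a, b, VarLdConfig())
    top = track.loc[track.std_score.idxmax()]
    assert top.chrom == 1
    assert sweep.start_bp <= top.anchor_pos_bp <= sweep.end_bp
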