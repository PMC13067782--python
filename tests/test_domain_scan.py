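"""Kernel smoothing, permutation null, region calling, recovery metrics."""

import math

import numpy as np
import pytest

from tilescan.depletion_scoring import GuideScore
from tilescan.domain_scan import (
    RegionCall,
    ResidueTrack,
    call_regions,
    consensus,
    evaluate_calls,
    interval_jaccard,
    merge_significant_residues,
    permutation_null,
    smooth_track,
)
from tilescan.errors import InputError
from tilescan.guide_design import GuideRecord
from tilescan.synthetic_screen import SimTruth


def _lib_and_scores(positions, z_values):
    lib, scores = [], []
    for i, (aa, z) in enumerate(zip(positions, z_values)):
        gid = f"g{i}"
        lib.append(GuideRecord(gid, "g", "A" * 20, "+", (aa - 1) * 3 + 4,
                               (aa - 1) * 3 + 1, aa, False))
        scores.append(GuideScore(gid, z, z, 1))
    return lib, scores


def brute_force_smooth(positions, z_values, L, h):
    """Direct double-loop Nadaraya-Watson sum, independent of the package."""
    signal = np.empty(L)
    support = np.empty(L)
    for a in range(1, L + 1):
        num = den = 0.0
        for aa, z in zip(positions, z_values):
            w = math.exp(-0.5 * ((a - aa) / h) ** 2)
            num += w * z
            den += w
        signal[a - 1] = num / den
        support[a - 1] = den
    return signal, support


class TestSmoothing:
    def test_constant_scores_give_constant_signal(self):
        lib, scores = _lib_and_scores([5, 20, 40, 60], [2.5] * 4)
        track = smooth_track(scores, lib, protein_length=70)
        sup = np.isfinite(track.signal)
        assert np.allclose(track.signal[sup], 2.5)

    def test_degenerate_bandwidth_recovers_local_mean(self):
        lib, scores = _lib_and_scores([10, 10, 30], [1.0, 3.0, 7.0])
        track = smooth_track(scores, lib, bandwidth=1e-3, protein_length=40)
        assert track.signal[9] == pytest.approx(2.0)  # mean of guides at 10
        assert track.signal[29] == pytest.approx(7.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_convolution(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(1, 201, size=200)
        z = rng.normal(size=200)
        lib, scores = _lib_and_scores(pos, z)
        track = smooth_track(scores, lib, bandwidth=5.0, min_support=0.0,
                             protein_length=200)
        expected, support = brute_force_smooth(pos, z, 200, 5.0)
        assert np.max(np.abs(track.signal - expected)) < 1e-10
        assert np.max(np.abs(track.support - support)) < 1e-10

    def test_linear_in_z_and_order_invariant(self, rng):
        pos = rng.integers(1, 101, size=50)
        z = rng.normal(size=50)
        lib, scores = _lib_and_scores(pos, z)
        t1 = smooth_track(scores, lib, protein_length=100)
        perm = rng.permutation(50)
        lib2, scores2 = _lib_and_scores(pos[perm], z[perm])
        t2 = smooth_track(scores2, lib2, protein_length=100)
        np.testing.assert_allclose(t1.signal, t2.signal, rtol=0, atol=1e-12)
        lib3, scores3 = _lib_and_scores(pos, 2 * z)
        t3 = smooth_track(scores3, lib3, protein_length=100)
        sup = np.isfinite(t1.signal)
        np.testing.assert_allclose(t3.signal[sup], 2 * t1.signal[sup],
                                   atol=1e-10)

    def test_empty_guide_list_rejected(self):
        with pytest.raises(InputError):
            smooth_track([], [], protein_length=10)


class TestPermutationNull:
    def test_p_bounded_below_by_add_one_floor(self, rng):
        pos = rng.integers(1, 101, size=80)
        z = rng.normal(size=80)
        lib, scores = _lib_and_scores(pos, z)
        track = permutation_null(scores, lib, B=100, seed=3,
                                 protein_length=100)
        p = track.p_emp[np.isfinite(track.p_emp)]
        assert (p >= 1 / 101 - 1e-12).all()
        assert (p <= 1.0 + 1e-12).all()

    def test_strong_block_reaches_floor(self, rng):
        pos = np.arange(1, 101)
        z = np.where((pos >= 40) & (pos <= 60), -10.0, rng.normal(size=100))
        lib, scores = _lib_and_scores(pos, z)
        B = 200
        track = permutation_null(scores, lib, B=B, seed=5, protein_length=100)
        block_p = track.p_emp[44:56]
        assert np.nanmin(block_p) == pytest.approx(1.0 / (B + 1))


class TestRegionCalling:
    def test_merge_rule_worked_example(self):
        sig = list(range(150, 161)) + list(range(163, 171))
        assert merge_significant_residues(sig, max_gap=2) == [
            (150, 160), (163, 170)
        ]
        assert merge_significant_residues(sig, max_gap=3) == [(150, 170)]

    def test_single_run_yields_single_call(self):
        L = 300
        p = np.full(L, 0.9)
        p[152:171] = 0.001  # residues 153..171
        track = ResidueTrack(L, signal=np.full(L, -1.0),
                             support=np.ones(L), p_emp=p)
        calls = call_regions(track, alpha=0.05, min_len=3, max_gap=2)
        assert [(c.start_aa, c.end_aa) for c in calls] == [(153, 171)]
        assert calls[0].rank == 1

    def test_no_significant_residues_yields_empty(self):
        L = 50
        track = ResidueTrack(L, signal=np.zeros(L), support=np.ones(L),
                             p_emp=np.full(L, 0.8))
        assert call_regions(track) == []

    def test_min_len_filters_short_regions(self):
        L = 100
        p = np.full(L, 0.9)
        p[10:12] = 1e-4  # 2-residue region
        p[40:50] = 1e-4  # 10-residue region
        track = ResidueTrack(L, signal=np.full(L, -1.0),
                             support=np.ones(L), p_emp=p)
        calls = call_regions(track, alpha=0.05, min_len=3)
        assert [(c.start_aa, c.end_aa) for c in calls] == [(41, 50)]

    def test_lower_alpha_never_adds_calls(self):
        L = 200
        rng = np.random.default_rng(8)
        p = rng.uniform(size=L)
        p[50:80] = rng.uniform(0, 0.01, size=30)
        track = ResidueTrack(L, signal=-p, support=np.ones(L), p_emp=p)
        res_hi = {
            a for c in call_regions(track, alpha=0.10, min_len=1, max_gap=1)
            for a in range(c.start_aa, c.end_aa + 1)
        }
        res_lo = {
            a for c in call_regions(track, alpha=0.02, min_len=1, max_gap=1)
            for a in range(c.start_aa, c.end_aa + 1)
        }
        assert res_lo <= res_hi

    def test_requires_p_values(self):
        track = ResidueTrack(10, signal=np.zeros(10), support=np.ones(10))
        with pytest.raises(InputError):
            call_regions(track)


def _call(s, e, score=-1.0, p=0.01, rank=1):
    return RegionCall(s, e, score, p, rank)


class TestConsensus:
    def test_identical_sets_are_idempotent(self):
        calls = [_call(153, 171), _call(300, 320, rank=2)]
        out = consensus([calls, calls])
        assert [(c.start_aa, c.end_aa) for c in out] == [(153, 171), (300, 320)]

    def test_overlap_intersection(self):
        out = consensus([[_call(153, 171)], [_call(150, 168)]])
        assert [(c.start_aa, c.end_aa) for c in out] == [(153, 168)]

    def test_disjoint_sets_empty(self):
        assert consensus([[_call(10, 20)], [_call(30, 40)]]) == []

    def test_needs_two_sets(self):
        with pytest.raises(InputError):
            consensus([[_call(1, 5)]])


class TestEvaluation:
    def test_jaccard_examples(self):
        assert interval_jaccard((153, 171), (153, 171)) == 1.0
        assert interval_jaccard((150, 168), (153, 171)) == pytest.approx(16 / 22)
        assert interval_jaccard((1, 10), (20, 30)) == 0.0

    def test_recovery_metrics(self):
        truth = SimTruth(protein_length=400,
                         domains=[[153, 171, 1.0], [300, 320, 0.5]])
        calls = [_call(153, 171), _call(50, 60, rank=2)]
        m = evaluate_calls(calls, truth)
        assert m["per_domain_jaccard"] == [1.0, 0.0]
        assert m["recall"] == 0.5
        assert m["precision"] == 0.5
        assert m["n_calls"] == 2

    def test_no_calls_has_nan_precision(self):
        truth = SimTruth(protein_length=100, domains=[[10, 20, 1.0]])
        m = evaluate_calls([], truth)
        assert m["n_calls"] == 0
        assert math.isnan(m["precision"])
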