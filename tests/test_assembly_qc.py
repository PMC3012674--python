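"""N50, placement, reconciliation, coverage QC and repeat finders."""

import random

import numpy as np
import pytest

from bacpanel import assembly_qc as aqc
from bacpanel import synthetic_data as sim
from oracles import (
    global_repeats_bruteforce,
    inverted_repeats_bruteforce,
    n50_bruteforce,
    revcomp,
    tandem_repeats_bruteforce,
)


def _dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestN50:
    def test_single_element(self):
        assert aqc.compute_n50([7]) == 7

    def test_worked_example(self):
        assert aqc.compute_n50([5, 4, 3, 2, 1]) == 4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aqc.compute_n50([])

    def test_matches_bruteforce_on_random_lists(self):
        rng = random.Random(0)
        for _ in range(1000):
            lengths = [rng.randint(1, 500) for _ in range(rng.randint(1, 30))]
            assert aqc.compute_n50(lengths) == n50_bruteforce(lengths)


class TestPlaceContigs:
    def setup_method(self):
        self.rng = random.Random(1)
        self.scaffold = _dna(self.rng, 3000)

    def test_exact_substring_identity_one(self):
        contig = self.scaffold[500:1200]
        placements, unplaced = aqc.place_contigs(
            {"c": contig}, {"s": self.scaffold}
        )
        assert not unplaced
        (p,) = placements
        assert (p.start, p.end, p.orientation, p.identity) == (
            500, 1200, "forward", 1.0
        )

    def test_reverse_complement_detected(self):
        contig = revcomp(self.scaffold[500:1200])
        (p,), _ = aqc.place_contigs({"c": contig}, {"s": self.scaffold})
        assert p.orientation == "reverse-complement"
        assert p.identity == 1.0

    def test_single_mismatch_identity(self):
        contig = list(self.scaffold[1000:1500])
        contig[250] = {"A": "C", "C": "A", "G": "T", "T": "G"}[contig[250]]
        (p,), _ = aqc.place_contigs(
            {"c": "".join(contig)}, {"s": self.scaffold}, max_mismatch_frac=0.01
        )
        assert p.identity == pytest.approx(0.998)

    def test_short_contig_reported_unplaced(self):
        _, unplaced = aqc.place_contigs({"c": "ACGT"}, {"s": self.scaffold})
        assert "shorter than seed" in unplaced["c"]

    def test_duplicated_target_is_ambiguous(self):
        unit = _dna(self.rng, 200)
        scaffold = _dna(self.rng, 500) + unit + _dna(self.rng, 500) + unit
        _, unplaced = aqc.place_contigs({"c": unit}, {"s": scaffold})
        assert unplaced["c"] == "ambiguous placement"


class TestReconcile:
    def test_exact_tiling(self):
        rng = random.Random(2)
        scaffold = _dna(rng, 1000)
        contigs = {f"c{i}": scaffold[i * 250:(i + 1) * 250] for i in range(4)}
        placements, _ = aqc.place_contigs(contigs, {"s": scaffold})
        rep = aqc.reconcile(placements, {"s": scaffold})
        assert rep.coverage_fraction == 1.0
        assert rep.missing_bp == 0
        assert rep.mean_identity == 1.0
        assert rep.mean_signed_distance == 0.0

    def test_two_bp_overlap(self):
        # fully covered 10 bp scaffold; contigs overlap by 2 bp
        placements = [
            aqc.Placement("a", "s", 0, 6, "forward", 1.0),
            aqc.Placement("b", "s", 4, 10, "forward", 1.0),
        ]
        rep = aqc.reconcile(placements, {"s": "ACGTACGTAC"})
        assert rep.mean_signed_distance == -2.0
        assert rep.coverage_fraction == 1.0

    def test_hole_counts_missing_bases(self):
        rng = random.Random(3)
        scaffold = _dna(rng, 1000)
        placements = [
            aqc.Placement("a", "s", 0, 495, "forward", 1.0),
            aqc.Placement("b", "s", 505, 1000, "forward", 1.0),
        ]
        rep = aqc.reconcile(placements, {"s": scaffold})
        assert rep.missing_bp == 10
        assert rep.coverage_fraction == pytest.approx(0.99)

    def test_unknown_scaffold_rejected(self):
        with pytest.raises(KeyError):
            aqc.reconcile(
                [aqc.Placement("a", "nope", 0, 5, "forward", 1.0)], {"s": "ACGTA"}
            )


class TestCoverage:
    def test_constant_depth_no_flags(self):
        track = aqc.CoverageTrack.from_depths(np.full(20_000, 50.0), 5000)
        assert aqc.coverage_flags(track) == ["normal"] * 4

    def test_thresholds_from_mean_and_sd(self):
        # windows with mean 270 and population sd 20: limits 230 / 310
        track = aqc.CoverageTrack(
            window_bp=10, window_means=np.array([250.0, 290.0]), length_bp=20
        )
        assert track.mean == 270.0 and track.sd == 20.0
        hi = track.mean + 2 * track.sd
        lo = track.mean - 2 * track.sd
        assert (lo, hi) == (230.0, 310.0)
        assert aqc.coverage_flags(track, 2) == ["normal", "normal"]

    def test_planted_high_region_flagged(self):
        depths = np.full(50_000, 100.0)
        depths[20_000:25_000] = 500.0
        track = aqc.CoverageTrack.from_depths(depths, 5000)
        flags = aqc.coverage_flags(track, 2)
        assert flags[4] == "high"
        assert flags.count("high") == 1

    def test_copy_number_arithmetic(self):
        track = aqc.CoverageTrack(
            window_bp=10, window_means=np.array([270.0, 1350.0]), length_bp=20
        )
        ratio, copies = aqc.estimate_copy_number(track, (10, 20), 270.0)
        assert ratio == pytest.approx(5.0)
        assert copies == 5
        ratio, _ = aqc.estimate_copy_number(track, (0, 10), 270.0)
        assert ratio == pytest.approx(1.0)

    def test_zero_mean_rejected(self):
        track = aqc.CoverageTrack(
            window_bp=10, window_means=np.array([1.0]), length_bp=10
        )
        with pytest.raises(ValueError):
            aqc.estimate_copy_number(track, (0, 10), 0.0)

    @pytest.mark.parametrize("k", [2, 5, 8])
    def test_simulated_collapsed_repeat_recovery(self, k):
        cfg = sim.AssemblySimConfig(repeat_copy_number=k)
        fx = sim.gen_assembly_fixture(cfg, seed=k)
        ratio, copies = aqc.estimate_copy_number(
            fx.track, fx.truth["repeat_region"], fx.truth["depth"]
        )
        assert ratio == pytest.approx(k, rel=0.10)
        assert copies == k

    def test_bedgraph_round_trip(self, tmp_path):
        track = aqc.CoverageTrack.from_depths(np.arange(12_345, dtype=float), 5000)
        p = tmp_path / "cov.bedgraph"
        track.to_bedgraph(p)
        back = aqc.CoverageTrack.from_bedgraph(p)
        assert back.window_bp == track.window_bp
        assert back.length_bp == track.length_bp
        assert np.allclose(back.window_means, track.window_means, atol=1e-4)


class TestScaffoldEnds:
    def test_random_ends_have_no_matches(self):
        rng = random.Random(4)
        scaffolds = {f"s{i}": _dna(rng, 400) for i in range(4)}
        stats = aqc.scaffold_end_repeat_stats(scaffolds)
        assert stats["fraction_with_repeat"] == 0.0

    def test_planted_block_on_two_ends(self):
        rng = random.Random(5)
        block = _dna(rng, 30)
        s1 = block + _dna(rng, 370)
        s2 = _dna(rng, 300) + block + _dna(rng, 70)  # inside the end window
        scaffolds = {"s1": s1, "s2": s2}
        stats = aqc.scaffold_end_repeat_stats(scaffolds)
        assert stats["fraction_with_repeat"] == 0.5
        assert stats["mean_repeat_length"] == 30.0
        assert stats["mean_ends_matched"] == 1.0

    def test_identical_scaffolds_all_ends_match(self):
        rng = random.Random(6)
        s = _dna(rng, 400)
        stats = aqc.scaffold_end_repeat_stats({"a": s, "b": s})
        assert stats["fraction_with_repeat"] == 1.0


class TestRepeatFinders:
    def test_tandem_worked_example(self):
        (r,) = aqc.find_tandem_repeats("ACACACAC", 1, 6, 3)
        assert (r.start, r.end, r.period, r.copies) == (0, 8, 2, 4)

    def test_inverted_worked_example(self):
        seq = "CACGT" + "AAAA" + "ACGTG"
        (r,) = aqc.find_inverted_repeats(seq, min_arm=5, loop_max=100)
        assert (r.arm_length, r.loop_length) == (5, 4)
        assert (r.left_start, r.right_end) == (0, len(seq))

    def test_planted_duplication_found_exactly(self):
        rng = random.Random(7)
        base = _dna(rng, 10_000)
        block = _dna(rng, 40)
        seq = base[:3000] + block + base[3000:7000] + block + base[7000:]
        repeats = aqc.find_global_repeats(seq, min_len=25)
        assert {(r.start, r.length) for r in repeats} == {
            (3000, 40), (3000 + 40 + 4000, 40)
        }

    @pytest.mark.parametrize("seed", range(8))
    def test_global_matches_bruteforce(self, seed):
        rng = random.Random(seed)
        n = rng.randint(50, 300)
        seq = "".join(rng.choice("AC") for _ in range(n))  # repeat-dense
        min_len = rng.choice([6, 8])
        got = {(r.start, r.end) for r in aqc.find_global_repeats(seq, min_len)}
        assert got == global_repeats_bruteforce(seq, min_len)

    @pytest.mark.parametrize("seed", range(8))
    def test_inverted_matches_bruteforce(self, seed):
        rng = random.Random(100 + seed)
        n = rng.randint(50, 200)
        seq = "".join(rng.choice("ACGT") for _ in range(n))
        got = {
            (r.left_start, r.left_end, r.right_start, r.right_end)
            for r in aqc.find_inverted_repeats(seq, min_arm=4, loop_max=20)
        }
        assert got == inverted_repeats_bruteforce(seq, 4, 20)

    @pytest.mark.parametrize("seed", range(8))
    def test_tandem_matches_bruteforce(self, seed):
        rng = random.Random(200 + seed)
        n = rng.randint(50, 300)
        seq = "".join(rng.choice("AC") for _ in range(n))
        got = {
            (r.start, r.end, r.period, r.copies)
            for r in aqc.find_tandem_repeats(seq, 1, 6, 3)
        }
        assert got == tandem_repeats_bruteforce(seq, 1, 6, 3)

    def test_catalog_rejects_bad_alphabet(self):
        with pytest.raises(ValueError):
            aqc.find_repeats("ACGU")
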