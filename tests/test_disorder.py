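import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from idrscape.disorder import (
    CH_BOUNDARIES,
    CHPoint,
    RegionSet,
    ScoreTrack,
    ch_classify,
    ch_point,
    composition,
    disorder_track_standin,
    fractional_difference_profile,
    segment_regions,
)
from idrscape.records import ProteinRecord
from idrscape.scales import AMINO_ACIDS, VIHINEN_FLEXIBILITY


def rec(seq, rid="x"):
    return ProteinRecord(rid, seq)


class TestComposition:
    @pytest.mark.parametrize(
        "seqs,expected",
        [
            (["AAAA"], {"A": 1.0}),
            (["ACDE"], {"A": 0.25, "C": 0.25, "D": 0.25, "E": 0.25}),
            (["AA", "CC"], {"A": 0.5, "C": 0.5}),
        ],
    )
    def test_examples(self, seqs, expected):
        freqs = composition([rec(s, f"r{i}") for i, s in enumerate(seqs)])
        assert freqs.sum() == pytest.approx(1.0, abs=1e-9)
        for aa in AMINO_ACIDS:
            assert freqs[aa] == pytest.approx(expected.get(aa, 0.0))

    def test_rejects_noncanonical(self):
        with pytest.raises(ValueError, match="non-canonical"):
            ProteinRecord("bad", "ACXDE")
        with pytest.raises(ValueError):
            ProteinRecord("empty", "")


class TestFractionalDifference:
    def test_formula_depletion(self):
        # query freq(A)=0.25, reference freq(A)=0.5 -> D_A = -0.5
        prof = fractional_difference_profile(rec("ACDE"), rec("AACD"), n_boot=10, seed=0)
        assert prof.table.loc["A", "d"] == pytest.approx(-0.5)

    def test_identity_gives_zero(self):
        prof = fractional_difference_profile(rec("ACDEK"), rec("ACDEK"), n_boot=10, seed=0)
        present = prof.table.loc[~prof.table["undefined"]]
        assert np.allclose(present["d"], 0.0)

    def test_missing_reference_letter_flagged(self):
        prof = fractional_difference_profile(rec("AW"), rec("AC"), n_boot=10, seed=0)
        assert bool(prof.table.loc["W", "undefined"])
        assert np.isnan(prof.table.loc["W", "d"])

    def test_ci_contains_point_estimate(self):
        q = rec("".join(np.random.default_rng(0).choice(list(AMINO_ACIDS), 500)))
        r = rec("".join(np.random.default_rng(1).choice(list(AMINO_ACIDS), 500)))
        prof = fractional_difference_profile(q, r, n_boot=2000, seed=7)
        ok = prof.table.loc[~prof.table["undefined"]]
        assert ((ok["ci_low"] <= ok["d"]) & (ok["d"] <= ok["ci_high"])).all()

    def test_ci_width_shrinks_with_length(self):
        gen = np.random.default_rng(3)
        ref = rec("".join(gen.choice(list(AMINO_ACIDS), 5000)), "ref")
        widths = {}
        for L in (50, 5000):
            q = rec("".join(gen.choice(list(AMINO_ACIDS), L)), "q")
            prof = fractional_difference_profile(q, ref, n_boot=500, seed=11)
            ok = prof.table.loc[~prof.table["undefined"]]
            widths[L] = float((ok["ci_high"] - ok["ci_low"]).mean())
        assert widths[5000] < widths[50]

    def test_disordered_vs_globular_direction(self):
        # sequences drawn from the disorder-tilted preset are depleted in
        # order-promoting and enriched in disorder-promoting residues
        from idrscape.synthetic import composition_preset, sample_sequence

        q = sample_sequence(composition_preset("disordered"), 20_000, seed=5)
        r = sample_sequence(composition_preset("globular"), 20_000, seed=6)
        prof = fractional_difference_profile(q, r, n_boot=200, seed=8)
        for aa in "CWFYVI":
            assert prof.table.loc[aa, "d"] < 0
        for aa in "QSPE":
            assert prof.table.loc[aa, "d"] > 0

    def test_vihinen_display_order(self):
        prof = fractional_difference_profile(rec("ACDE"), rec("ACDE"), n_boot=5, seed=0)
        flex = [VIHINEN_FLEXIBILITY[aa] for aa in prof.order]
        assert flex == sorted(flex)


class TestChargeHydropathy:
    def test_scale_extremum(self):
        assert ch_point(rec("IIII")).h == pytest.approx(1.0)

    @pytest.mark.parametrize("seq,q", [("DEKR", 0.0), ("KKKK", 1.0)])
    def test_net_charge(self, seq, q):
        assert ch_point(rec(seq)).q == pytest.approx(q)

    @pytest.mark.parametrize(
        "q,margin,label",
        [(0.30, 0.0585, "disordered"), (0.20, -0.0415, "ordered")],
    )
    def test_boundary_arithmetic(self, q, margin, label):
        point = CHPoint(h=0.5, q=q)
        got_label, got_margin = ch_classify(point)
        assert got_label == label
        assert got_margin == pytest.approx(margin, abs=1e-9)

    def test_tie_is_disordered(self):
        point = CHPoint(h=0.5, q=2.785 * 0.5 - 1.151)
        assert point.label == "disordered"

    def test_boundary_variant_flips_only_between_lines(self, rng):
        sm, im = CH_BOUNDARIES["methods"]
        sf, intf = CH_BOUNDARIES["figure"]
        for _ in range(500):
            h = rng.uniform(0.3, 0.7)
            q = rng.uniform(0.0, 1.0)
            lm = "disordered" if q >= sm * h + im else "ordered"
            lf = "disordered" if q >= sf * h + intf else "ordered"
            point_m = CHPoint(h, q, sm, im)
            point_f = CHPoint(h, q, sf, intf)
            assert point_m.label == lm and point_f.label == lf
            between = min(sm * h + im, sf * h + intf) <= q < max(sm * h + im, sf * h + intf)
            assert (point_m.label != point_f.label) == between


class TestStandinTrack:
    def test_extrema(self):
        most_flexible = max(VIHINEN_FLEXIBILITY, key=VIHINEN_FLEXIBILITY.get)
        most_rigid = min(VIHINEN_FLEXIBILITY, key=VIHINEN_FLEXIBILITY.get)
        assert np.allclose(disorder_track_standin(rec(most_flexible * 30), 9).scores, 1.0)
        assert np.allclose(disorder_track_standin(rec(most_rigid * 30), 9).scores, 0.0)

    def test_window_one_is_raw_propensity(self):
        from idrscape.scales import normalized

        flex = normalized(VIHINEN_FLEXIBILITY)
        track = disorder_track_standin(rec("ACDEFGHIK"), 1)
        assert np.allclose(track.scores, [flex[aa] for aa in "ACDEFGHIK"])

    def test_palindrome_symmetry(self):
        seq = "ACDEFGKGFEDCA"
        scores = disorder_track_standin(rec(seq), 5).scores
        assert np.allclose(scores, scores[::-1])
        assert np.all((scores >= 0) & (scores <= 1))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            disorder_track_standin(rec("ACDE"), 4)


class TestSegmentation:
    def test_uniform_track(self):
        track = ScoreTrack("p", np.full(100, 0.9))
        regions = segment_regions(track, 0.5, 4)
        assert regions.regions == [(1, 100, "disordered")]

    def test_ordered_dip(self):
        scores = np.full(295, 0.9)
        scores[180:205] = 0.2  # positions 181..205
        regions = segment_regions(ScoreTrack("p", scores), 0.5, 4)
        assert regions.regions == [
            (1, 180, "disordered"),
            (181, 205, "ordered"),
            (206, 295, "disordered"),
        ]

    def test_alternating_runs_get_merged(self):
        scores = np.array([0.9, 0.1] * 6)
        regions = segment_regions(ScoreTrack("p", scores), 0.5, 4)
        assert regions.length == 12
        assert len(regions.regions) < 12

    def test_partition_and_idempotence(self, rng):
        scores = rng.uniform(0, 1, size=200)
        regions = segment_regions(ScoreTrack("p", scores), 0.5, 4)
        assert regions.regions[0][0] == 1 and regions.length == 200
        again = segment_regions(regions.implied_track(), 0.5, 1)
        assert again.regions == regions.regions

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            segment_regions(ScoreTrack("p", np.full(10, 0.9)), sequence_length=12)

    def test_region_set_invariants(self):
        with pytest.raises(ValueError):
            RegionSet("p", [(1, 5, "ordered"), (7, 9, "disordered")])  # hole
        with pytest.raises(ValueError):
            RegionSet("p", [(1, 5, "ordered"), (6, 9, "ordered")])  # same label


@given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=80))
def test_composition_sums_to_one(seq):
    assert composition(rec(seq)).sum() == pytest.approx(1.0, abs=1e-9)
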