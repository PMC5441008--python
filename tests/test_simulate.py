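import math

import numpy as np
import pytest

from ptxmap import qc
from ptxmap.simulate import (
    SimScenario,
    RearrangementSpec,
    apply_rearrangements,
    default_scenario,
    simulate_meiosis,
    simulate_genotyping,
    simulate_family,
    make_synthetic_anchors,
    random_tags,
)
from ptxmap.comparative import parse_and_filter_anchors


class TestApplyRearrangements:
    def test_empty_specs_identity(self):
        bp = np.array([5.0, 50.0, 95.0])
        assert np.array_equal(apply_rearrangements(bp, [], 100), bp)

    def test_single_inversion_reflection(self):
        out = apply_rearrangements(
            np.array([12.0, 18.0]), [RearrangementSpec(1, "inversion", (10, 20))], 100
        )
        assert out.tolist() == [18.0, 12.0]  # reflection s + e - x

    def test_inversion_against_list_reversal_oracle(self):
        # 5 equally spaced markers, invert the middle 3: the middle block
        # must come out exactly reversed
        bp = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        out = apply_rearrangements(
            bp, [RearrangementSpec(1, "inversion", (15, 45))], 100
        )
        expected = bp.copy()
        expected[1:4] = bp[1:4][::-1]
        assert np.allclose(out, expected)

    def test_translocation_conserves_set_and_order(self):
        # dense grid: positions must remain a bijection onto the same range,
        # with the excised block inverted at its destination
        bp = np.arange(0.5, 100.0, 1.0)
        spec = RearrangementSpec(1, "inversion_translocation", (20, 30), 70)
        out = apply_rearrangements(bp, [spec], 100)
        assert np.all(out >= 0) and np.all(out <= 100)
        assert len(np.unique(np.round(out, 6))) == len(bp)  # bijective
        inside = (bp >= 20) & (bp < 30)
        seg = out[inside]
        assert np.all(np.diff(seg) < 0)  # inverted at destination
        # the excised 10-unit block lands where original coordinate 70 ends
        # up after the excision (70 - 10 = 60), occupying (60, 70]
        assert seg.min() > 60 and seg.max() <= 70
        # chromosome length conserved: span of outputs equals span of inputs
        assert out.max() - out.min() == pytest.approx(bp.max() - bp.min(), abs=1.0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            apply_rearrangements(
                np.array([1.0]),
                [RearrangementSpec(1, "inversion", (10, 30)),
                 RearrangementSpec(1, "inversion", (20, 40))],
                100,
            )
        with pytest.raises(ValueError):
            apply_rearrangements(
                np.array([1.0]), [RearrangementSpec(1, "inversion", (90, 120))], 100
            )
        with pytest.raises(ValueError):
            RearrangementSpec(1, "inversion", (30, 20))
        with pytest.raises(ValueError):
            RearrangementSpec(1, "inversion_translocation", (10, 20), 15)
        with pytest.raises(ValueError):
            RearrangementSpec(1, "inversion", (10, 20), 50)


def _pair_scenario(sep_cM, shape=1.0):
    return SimScenario(
        n_chromosomes=1,
        chrom_lengths_bp=(60_000_000,),
        chrom_lengths_cM=(120.0,),
        n_markers=24,
        seg_mix={"testcross_P1": 1.0},
        error_rate=0.0,
        missing_rate=0.0,
        interference_shape=shape,
        seed=5,
    )


class TestMeiosis:
    def test_zero_distance_zero_rf(self, one_chrom_scenario):
        lay = one_chrom_scenario.layout()
        g = simulate_meiosis(one_chrom_scenario, 500, "P1",
                             rng=np.random.default_rng(0))
        # nearest pair is a fraction of a cM apart: rf must be ~0
        cm = lay["cM"].to_numpy()
        i = int(np.argmin(np.diff(cm)))
        rf = (g[:, i] != g[:, i + 1]).mean()
        assert rf <= np.diff(cm)[i] / 100 + 3 * 0.5 / math.sqrt(500)

    def test_unlinked_chromosomes_rf_half(self, two_chrom_scenario):
        lay = two_chrom_scenario.layout()
        g = simulate_meiosis(two_chrom_scenario, 1000, "P1",
                             rng=np.random.default_rng(1))
        i = int(np.flatnonzero(lay["chrom"] == 1)[0])
        j = int(np.flatnonzero(lay["chrom"] == 2)[0])
        rf = (g[:, i] != g[:, j]).mean()
        assert abs(rf - 0.5) < 3 * 0.5 / math.sqrt(1000)

    def test_haldane_closed_form_without_interference(self):
        """At interference shape 1 (Poisson) the rf at d cM is the inverse
        Haldane value (1 - exp(-2d/100)) / 2."""
        sc = _pair_scenario(20.0, shape=1.0)
        lay = sc.layout()
        g = simulate_meiosis(sc, 5000, "P1", rng=np.random.default_rng(42))
        cm = lay["cM"].to_numpy()
        j = int(np.argmin(np.abs(cm - cm[0] - 20.0)))
        d = cm[j] - cm[0]
        rf = (g[:, 0] != g[:, j]).mean()
        expected = (1 - math.exp(-2 * d / 100)) / 2
        se = math.sqrt(expected * (1 - expected) / 5000)
        assert abs(rf - expected) < 3 * se

    def test_interference_suppresses_close_doubles(self):
        """With strong interference, double crossovers within ~5 cM are far
        rarer than the Poisson rate."""
        rates = {}
        for shape in (1.0, 2.5):
            sc = _pair_scenario(5.0, shape=shape)
            lay = sc.layout()
            cm = lay["cM"].to_numpy()
            g = simulate_meiosis(sc, 4000, "P1", rng=np.random.default_rng(3))
            i = int(np.argmin(np.abs(cm - 50)))
            lo = int(np.argmin(np.abs(cm - (cm[i] - 5))))
            hi = int(np.argmin(np.abs(cm - (cm[i] + 5))))
            doubles = ((g[:, lo] == g[:, hi]) & (g[:, i] != g[:, lo])).mean()
            rates[shape] = doubles
        assert rates[2.5] < 0.5 * rates[1.0]

    def test_rf_monotone_in_distance(self):
        sc = _pair_scenario(0.0, shape=2.5)
        lay = sc.layout()
        cm = lay["cM"].to_numpy()
        g = simulate_meiosis(sc, 4000, "P1", rng=np.random.default_rng(9))
        ds, rfs = [], []
        for j in range(1, len(cm)):
            d = cm[j] - cm[0]
            if d > 60:
                break
            ds.append(d)
            rfs.append((g[:, 0] != g[:, j]).mean())
        # binned means must be non-decreasing within sampling noise
        assert all(b >= a - 0.03 for a, b in zip(rfs, rfs[1:]))


class TestGenotyping:
    def test_noise_free_matrix(self, one_chrom_family):
        mat = one_chrom_family.dh["P1"]
        assert np.all(mat.call_rate() == 1.0)
        assert set(np.unique(mat.calls)) <= {0, 1}

    def test_calls_match_phase_truth(self, one_chrom_scenario, one_chrom_family):
        fam = one_chrom_family
        mat = fam.dh["P1"]
        gam = fam.phases["P1"]
        lay = one_chrom_scenario.layout()
        col = {m: i for i, m in enumerate(lay["marker"])}
        for row, mk in zip(mat.calls, mat.marker_ids):
            g = gam[:, col[str(mk)]]
            agree = (row == g).mean()
            assert agree in (0.0, 1.0)  # equal up to the arbitrary scoring phase

    def test_missing_rate_recovered(self):
        sc = SimScenario(
            n_chromosomes=1, chrom_lengths_bp=(50_000_000,), chrom_lengths_cM=(100.0,),
            n_markers=60, seg_mix={"testcross_P1": 1.0}, error_rate=0.0,
            missing_rate=0.2, missing_dispersion=None, seed=3,
        )
        fam = simulate_family(sc, 360, "F", seed=8)
        mean_cr = fam.dh["P1"].call_rate().mean()
        n_calls = fam.dh["P1"].calls.size
        se = math.sqrt(0.2 * 0.8 / n_calls)
        assert abs(mean_cr - 0.8) < 3 * se

    def test_undistorted_marker_pic_half(self, one_chrom_family):
        pics = [r.pic for r in one_chrom_family.records["P1"]]
        assert np.mean(pics) == pytest.approx(0.5, abs=0.01)
        assert max(pics) <= 0.5 + 1e-12

    def test_segregation_passes_chisq_when_clean(self, one_chrom_family):
        """Error-free 1:1 markers pass the chi-square test at alpha=0.001 in
        >= 99% of markers."""
        mat = one_chrom_family.dh["P1"]
        seg = qc.segregation_table(mat)
        assert (seg["p"] >= 0.001).mean() >= 0.99


class TestScenarioIO:
    def test_json_round_trip(self, tmp_path):
        sc = default_scenario(n_markers=300)
        path = tmp_path / "scenario.json"
        sc.to_json(path)
        back = SimScenario.from_json(path)
        assert back.rearrangements == sc.rearrangements
        assert back.chrom_lengths_bp == sc.chrom_lengths_bp
        assert back.layout().equals(sc.layout())

    def test_default_scenario_geometry(self):
        sc = default_scenario()
        kinds = [r.kind for r in sc.rearrangements]
        assert len(sc.rearrangements) == 9
        assert len({r.chromosome for r in sc.rearrangements}) == 7
        assert kinds.count("inversion_translocation") == 4
        assert kinds.count("inversion") == 5

    def test_tags_fasta_round_trip(self, tmp_path):
        from ptxmap.io import write_tags_fasta, read_tags_fasta

        tags = random_tags(["m1", "m2", "m3"], seed=1)
        assert all(len(s) == 64 for s in tags.values())
        path = tmp_path / "tags.fasta"
        write_tags_fasta(tags, path)
        assert read_tags_fasta(path) == tags


class TestSyntheticAnchors:
    def test_anchor_table_parses_and_filters(self, one_chrom_scenario):
        lay = one_chrom_scenario.layout()
        hits = make_synthetic_anchors(one_chrom_scenario, lay["marker"],
                                      fraction=1.0, seed=4, scaffold_rate=0.0)
        anchors = parse_and_filter_anchors(hits, ["Chr01"], query_lengths=64)
        acc = anchors[anchors["accepted"]]
        assert len(acc) == len(lay)
        merged = acc.merge(lay, left_on="marker", right_on="marker")
        assert np.allclose(merged["bp_start"], merged["reference_bp"], atol=1.0)
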