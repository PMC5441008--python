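import numpy as np
import pandas as pd
import pytest

from ptxmap.io import BLAST6_COLUMNS, write_blast_tab, read_blast_tab
from ptxmap import comparative as C


def _hit(q, s, length=64, e=1e-20, bit=100.0, sstart=1000, send=None, pident=98.0):
    if send is None:
        send = sstart + length - 1
    return (q, s, pident, length, 0, 0, 1, length, sstart, send, e, bit)


ANCHORED = [f"Chr{c:02d}" for c in range(1, 12)]


class TestAnchorFiltering:
    def test_coverage_and_evalue_rules(self):
        df = pd.DataFrame(
            [
                _hit("m1", "Chr01", length=62),          # 62/64 = 0.969 -> accepted
                _hit("m2", "Chr01", length=60),          # 0.9375 -> rejected
                _hit("m3", "Chr01", e=1e-9),             # e-value too large
                _hit("m4", "scaffold_12"),               # unanchored subject
            ],
            columns=BLAST6_COLUMNS,
        )
        out = C.parse_and_filter_anchors(df, ANCHORED, query_lengths=64).set_index("marker")
        assert out.at["m1", "accepted"]
        assert not out.at["m2", "accepted"]
        assert not out.at["m3", "accepted"]
        assert not out.at["m4", "accepted"]  # recorded but never accepted
        assert "m4" in out.index

    def test_equal_score_hits_collapse_deterministically(self):
        df = pd.DataFrame(
            [_hit("m1", "Chr02", sstart=3_000_000), _hit("m1", "Chr02", sstart=2_000_000)],
            columns=BLAST6_COLUMNS,
        )
        out = C.parse_and_filter_anchors(df, ANCHORED)
        assert len(out) == 1
        assert out.at[0, "bp_start"] == 2_000_000  # lowest bp wins

    def test_minus_strand_coordinates(self):
        df = pd.DataFrame(
            [_hit("m1", "Chr01", sstart=5000, send=5000 - 63)], columns=BLAST6_COLUMNS
        )
        out = C.parse_and_filter_anchors(df, ANCHORED)
        assert out.at[0, "strand"] == "-"
        assert out.at[0, "bp_start"] == 5000 - 63

    def test_malformed_lines_skipped(self, tmp_path):
        path = tmp_path / "hits.tsv"
        df = pd.DataFrame([_hit("m1", "Chr01")], columns=BLAST6_COLUMNS)
        write_blast_tab(df, path)
        with open(path, "a") as fh:
            fh.write("broken\tline\n")
        with pytest.warns(UserWarning):
            back = read_blast_tab(path)
        assert len(back) == 1


def _anchors(markers, chroms, bps, accepted=True):
    return pd.DataFrame(
        {
            "marker": markers,
            "chromosome": chroms,
            "bp_start": bps,
            "strand": "+",
            "e_value": 1e-20,
            "coverage": 1.0,
            "bitscore": 100.0,
            "accepted": accepted,
        }
    )


class TestSynteny:
    def test_majority_rule(self):
        ids = [f"m{i}" for i in range(100)]
        chroms = ["Chr02"] * 89 + ["Chr05"] * 11
        anchors = _anchors(ids, chroms, np.arange(100) * 1e5)
        chrom, status = C.assign_synteny(ids, anchors)
        assert chrom == "Chr02"
        assert (status["status"] == "nonsyntenic").sum() == 11

    def test_unanimous(self):
        ids = ["a", "b", "c"]
        chrom, status = C.assign_synteny(ids, _anchors(ids, ["Chr03"] * 3, [1, 2, 3]))
        assert chrom == "Chr03"
        assert (status["status"] == "syntenic").all()

    def test_tie_raises(self):
        ids = ["a", "b"]
        with pytest.raises(ValueError):
            C.assign_synteny(ids, _anchors(ids, ["Chr01", "Chr02"], [1, 2]))

    def test_no_anchor_raises(self):
        with pytest.raises(ValueError):
            C.assign_synteny(["a"], _anchors([], [], []))


def _group_frame(cm, bp, status=None):
    n = len(cm)
    return pd.DataFrame(
        {
            "marker": [f"m{i}" for i in range(n)],
            "position_cM": cm,
            "status": status if status is not None else ["syntenic"] * n,
            "bp_start": bp,
        }
    )


class TestCollinearity:
    def test_monotone_clean(self):
        cm = np.linspace(0, 100, 40)
        gf = _group_frame(cm, cm * 5e5)
        flags = C.flag_noncollinear(gf)
        assert (flags["collinearity"] == "syntenic_collinear").all()

    def test_displacement_threshold(self):
        cm = np.linspace(0, 100, 40)
        bp = cm * 5e5
        bp_far, bp_near = bp.copy(), bp.copy()
        bp_far[20] += 8e6
        bp_near[20] += 1e6
        far = C.flag_noncollinear(_group_frame(cm, bp_far))
        near = C.flag_noncollinear(_group_frame(cm, bp_near))
        assert far.loc[20, "collinearity"] == "syntenic_noncollinear"
        assert near.loc[20, "collinearity"] == "syntenic_collinear"

    def test_sparse_group_skipped(self):
        gf = _group_frame([0.0, 1.0], [0.0, 1e6])
        assert C.flag_noncollinear(gf) is None

    def test_simulated_inversion_flags_match_reflection(self):
        """Markers of a planted in-place inversion are flagged exactly where
        the reflection displaces them >= 2 Mb."""
        cm = np.linspace(0, 100, 80)
        bp = cm * 5e5
        s, e = 20e6, 32e6
        inside = (bp >= s) & (bp < e)
        bp_inv = bp.copy()
        bp_inv[inside] = s + e - bp[inside]
        flags = C.flag_noncollinear(_group_frame(cm, bp_inv))
        displacement = np.abs(bp_inv - bp)
        got = (flags["collinearity"] == "syntenic_noncollinear").to_numpy()
        # markers clearly beyond the threshold flagged and markers clearly
        # below it not, with at most one exception on each side right at
        # the inversion core, where the reflection crosses the diagonal and
        # the trend necessarily passes within one marker spacing
        assert (~got[displacement >= 3e6]).sum() <= 1
        assert got[displacement <= 1e6].sum() <= 1


def _inversion_frame(span_cM, chrom_cM=100.0, density=4.0, ratio=5e5, start=40.0):
    cm = np.arange(0, chrom_cM, 1.0 / density)
    bp = cm * ratio
    s, e = start * ratio, (start + span_cM) * ratio
    inside = (bp >= s) & (bp < e)
    bp = bp.copy()
    bp[inside] = s + e - bp[inside]
    return _group_frame(cm, bp)


class TestCalls:
    @pytest.mark.parametrize("span, expect_call", [(2, False), (4, False), (6, True), (10, True)])
    def test_span_rule_power(self, span, expect_call):
        flags = C.flag_noncollinear(_inversion_frame(span))
        calls = C.call_rearrangements(flags, "LG1", taxon="SIM")
        assert bool(calls) == expect_call
        if calls:
            assert calls[0].kind == "inversion"

    def test_no_flags_no_calls(self):
        cm = np.linspace(0, 100, 40)
        flags = C.flag_noncollinear(_group_frame(cm, cm * 5e5))
        assert C.call_rearrangements(flags, "LG1") == []

    def test_naming_by_map_order(self):
        gf = _inversion_frame(8, start=10.0)
        gf2 = _inversion_frame(8, start=70.0)
        both = gf.copy()
        both["bp_start"] = np.where(
            gf2["bp_start"] != gf2["position_cM"] * 5e5, gf2["bp_start"], gf["bp_start"]
        )
        flags = C.flag_noncollinear(both)
        calls = C.call_rearrangements(flags, "LG3", taxon="CCV")
        assert [c.name for c in calls] == ["CCV-in(3)1", "CCV-in(3)2"]

    def test_reversal_and_translation_invariance(self):
        gf = _inversion_frame(10)
        calls = C.call_rearrangements(C.flag_noncollinear(gf), "LG1")
        rev = gf.iloc[::-1].reset_index(drop=True)
        rev["position_cM"] = gf["position_cM"].max() - rev["position_cM"]
        calls_rev = C.call_rearrangements(C.flag_noncollinear(rev), "LG1")
        shifted = gf.copy()
        shifted["bp_start"] = shifted["bp_start"] + 7e6
        calls_sh = C.call_rearrangements(C.flag_noncollinear(shifted), "LG1")
        assert len(calls) == len(calls_rev) == len(calls_sh) == 1
        assert calls[0].kind == calls_rev[0].kind == calls_sh[0].kind

    def test_transposed_inversion_typed(self):
        cm = np.linspace(0, 100, 100)
        bp = cm * 5e5
        # segment at map 40-50 cM relocated (and reversed) to ~45 Mb
        inside = (cm >= 40) & (cm < 50)
        bp = bp.copy()
        bp[inside] = 50e6 - (bp[inside] - 20e6)
        flags = C.flag_noncollinear(_group_frame(cm, bp))
        calls = C.call_rearrangements(flags, "LG6", taxon="SIM")
        assert len(calls) == 1
        assert calls[0].kind == "inversion_translocation"
        assert "tp" in calls[0].name

    def test_flanking_markers_absent_at_group_end(self):
        gf = _inversion_frame(12, start=0.0)
        flags = C.flag_noncollinear(gf)
        calls = C.call_rearrangements(flags, "LG1")
        assert len(calls) == 1
        assert calls[0].flanking_bp[0] is None
        assert calls[0].flanking_bp[1] is not None


class TestDuplicationScreen:
    def _map_frame(self, n=30):
        return pd.DataFrame(
            {"group": "LG1", "marker": [f"m{i}" for i in range(n)],
             "position_cM": np.arange(n, dtype=float)}
        )

    def test_empty_secondary(self):
        out = C.screen_duplications(pd.DataFrame(), self._map_frame(), {"LG1": "Chr01"})
        assert out.empty

    def test_planted_block_reported(self):
        sec = pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(10, 15)],
                "chromosome": "Chr07",
                "bp_start": np.arange(5) * 1e6 + 2e6,
                "bitscore": 90.0,
            }
        )
        out = C.screen_duplications(sec, self._map_frame(), {"LG1": "Chr01"})
        assert len(out) == 1
        assert out.at[0, "n_markers"] == 5

    def test_scattered_hits_not_reported(self):
        rng = np.random.default_rng(5)
        pick = [f"m{i}" for i in sorted(rng.choice(30, 6, replace=False))
                if True][::2]  # non-consecutive markers
        sec = pd.DataFrame(
            {"marker": pick, "chromosome": "Chr07",
             "bp_start": rng.uniform(0, 5e7, len(pick)), "bitscore": 90.0}
        )
        out = C.screen_duplications(sec, self._map_frame(), {"LG1": "Chr01"})
        assert out.empty


class TestDotplot:
    def test_empty_inputs_no_crash(self, tmp_path):
        df = C.export_dotplot(
            pd.DataFrame(columns=["group", "marker", "position_cM"]),
            {}, {"Chr01": 1e7},
            tsv_path=tmp_path / "dp.tsv", png_path=tmp_path / "dp.png",
        )
        assert df.empty
        assert (tmp_path / "dp.tsv").exists()
        assert (tmp_path / "dp.png").exists()

    def test_collinear_staircase(self, tmp_path):
        cm = np.linspace(0, 50, 20)
        gf = _group_frame(cm, cm * 5e5)
        gf.insert(0, "group", "LG1")
        gf["chromosome"] = "Chr01"
        flags = C.flag_noncollinear(gf)
        df = C.export_dotplot(gf, {"LG1": flags}, {"Chr01": 4e7},
                              tsv_path=tmp_path / "dp.tsv")
        assert len(df) == 20
        assert (np.diff(df["cum_bp"]) >= 0).all()
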