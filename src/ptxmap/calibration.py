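"""Calibration harnesses: single-group screens on ground-truthed simulations.

These helpers run the detection pathway (simulate one linkage group ->
order -> anchor -> flag -> call) at small, fixed problem sizes, for
false-positive calibration and for power checks against planted events.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ptxmap import binning
from ptxmap.comparative import (
    parse_and_filter_anchors,
    assign_synteny,
    flag_noncollinear,
    call_rearrangements,
)
from ptxmap.linkage import order_regression
from ptxmap.simulate import (
    SimScenario,
    RearrangementSpec,
    simulate_family,
    make_synthetic_anchors,
)

_PLANTED = (RearrangementSpec(1, "inversion_translocation",
                              (15_000_000, 29_000_000), 44_000_000),)
_CHROMS = [f"Chr{c:02d}" for c in range(1, 13)]


def simulate_and_screen_group(seed: int, planted: bool = False,
                              n_offspring: int = 360, n_markers: int = 40,
                              error_rate: float = 0.01,
                              anchor_noise: float = 0.05):
    """One 100 cM group end to end; returns (|spearman rho|, n major calls).

    The group is simulated with genotyping error, ordered and cleaned with
    the full iterative removal loop (which catches the occasional gross
    misplacement genotyping error produces), anchored against the
    (optionally rearranged) reference with wrong-homolog anchor noise, and
    screened for major rearrangement calls.  rho is the
    orientation-normalised order correlation over syntenic anchors, the
    statistic the per-group map-vs-genome table reports.
    """
    from ptxmap.linkage import iterative_clean

    sc = SimScenario(
        n_chromosomes=1,
        chrom_lengths_bp=(50_000_000,),
        chrom_lengths_cM=(100.0,),
        n_markers=n_markers,
        seg_mix={"testcross_P1": 1.0},
        error_rate=error_rate,
        missing_rate=0.0,
        rearrangements=_PLANTED if planted else (),
        seed=seed,
    )
    fam = simulate_family(sc, n_offspring, "F", seed=seed + 50_000)
    mat = fam.dh["P1"]
    # map only class 1-2 markers, as the map-building stage does
    good = {r.id for r in fam.records["P1"] if r.quality_class in (1, 2)}
    mat = mat.subset_markers([m for m in mat.marker_ids if str(m) in good])
    order, pos, _log = iterative_clean(mat, [str(m) for m in mat.marker_ids])

    hits = make_synthetic_anchors(sc, [str(m) for m in order], fraction=1.0,
                                  noise_rate=anchor_noise, seed=seed + 90_000,
                                  scaffold_rate=0.0)
    anchors = parse_and_filter_anchors(hits, _CHROMS, query_lengths=64)
    chrom, status = assign_synteny([str(m) for m in order], anchors)
    acc = anchors[anchors["accepted"]].set_index("marker")
    df = pd.DataFrame({
        "marker": [str(m) for m in order],
        "position_cM": pos,
        "status": status["status"].to_numpy(),
    })
    df["bp_start"] = [
        float(acc.at[m, "bp_start"]) if m in acc.index else np.nan
        for m in df["marker"]
    ]
    syn = df[df["status"] == "syntenic"]
    rho = stats.spearmanr(syn["position_cM"], syn["bp_start"]).statistic
    if rho < 0:
        df["position_cM"] = df["position_cM"].max() - df["position_cM"]
        df = df.iloc[::-1].reset_index(drop=True)
    flags = flag_noncollinear(df)
    calls = call_rearrangements(flags, "LG1") if flags is not None else []
    return abs(float(rho)), len(calls)


def random_small_group(seed: int, n_offspring: int = 150):
    """A clean simulated group of 5-8 markers and its pairwise counts, for
    comparing orderings against exhaustive-permutation optima."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(5, 9))
    sc = SimScenario(
        n_chromosomes=1,
        chrom_lengths_bp=(30_000_000,),
        chrom_lengths_cM=(float(rng.integers(30, 80)),),
        n_markers=m,
        seg_mix={"testcross_P1": 1.0},
        error_rate=0.0,
        missing_rate=0.0,
        seed=int(rng.integers(1, 1_000_000)),
    )
    fam = simulate_family(sc, n_offspring, "F", seed=int(rng.integers(1, 1_000_000)))
    mat = fam.dh["P1"]
    R, N = binning.pairwise_counts(mat)
    return mat, R, N
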