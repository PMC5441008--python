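"""End-to-end pipeline: simulate -> qc -> bin -> map -> compare.

Orchestrates the two-family pseudo-testcross design: parental bin maps in
each family, a combined-family map of the shared parent (offspring pooled,
markers re-binned at the larger sample size), comprehensive maps with binned
markers reintegrated, and the map-versus-reference rearrangement analysis
with a cross-map replication report.  All stages are deterministic given the
config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ptxmap.io import DHMatrix, MISSING, ensure_dir, records_to_frame
from ptxmap import qc as _qc
from ptxmap import binning as _binning
from ptxmap import linkage as _lk
from ptxmap import comparative as _cmp
from ptxmap.simulate import (
    SimScenario,
    default_scenario,
    simulate_family,
    make_synthetic_anchors,
)


@dataclass
class PipelineConfig:
    """Every numeric threshold of the workflow, at its standard default."""

    scenario: SimScenario | None = None
    n_family_a: int = 115
    n_family_b: int = 245
    lod_min: float = 3.0
    missing_max: float = 0.10
    repulsion_rf: float = 0.03  # per-family binning bound
    repulsion_cM: float = 3.0  # combined-family binning bound (Kosambi)
    chisq_contrib_bin: float = 1.0
    chisq_contrib_comprehensive: float = 2.0
    dxo_max: int = 1
    shift_max_cM: float = 1.0
    coverage_min: float = 0.95
    evalue_max: float = 1e-10
    noncollinear_bp: float = 2e6
    min_span_cM: float = 5.0
    gap_tolerance: int = 1
    anchor_fraction: float = 0.8
    anchor_noise: float = 0.05
    mapped_classes: tuple = (1, 2)
    taxon: str = "SIM"
    seed: int = 1
    outdir: str | None = None

    def __post_init__(self):
        if self.scenario is None:
            self.scenario = default_scenario()
        for f in ("lod_min", "missing_max", "repulsion_rf", "repulsion_cM",
                  "chisq_contrib_bin", "chisq_contrib_comprehensive",
                  "shift_max_cM", "coverage_min", "noncollinear_bp",
                  "min_span_cM"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    def echo(self) -> list:
        d = {k: v for k, v in dataclasses.asdict(self).items()
             if k not in ("scenario", "outdir")}
        return [f"config: {json.dumps(d, default=str)}"]


# -- family combination ----------------------------------------------------


def combine_families(mat_a: DHMatrix, mat_b: DHMatrix, lod_min: float = 3.0,
                     min_signal: float = 0.05) -> DHMatrix:
    """Merge two crosses of a shared parent into one population.

    Offspring columns are concatenated.  Because dominant-marker scoring
    phase is arbitrary and independent between datasets, shared markers are
    first phase-aligned: on the graph of marker pairs firmly linked in both
    crosses, relative flips are propagated from the unfolded mismatch
    fractions (a pair linked in coupling in one cross but in repulsion in
    the other implies one flip).  Markers private to one cross are carried
    with missing calls in the other.
    """
    ids_a = set(map(str, mat_a.marker_ids))
    ids_b = set(map(str, mat_b.marker_ids))
    shared = sorted(ids_a & ids_b)
    if not shared:
        raise ValueError("no shared markers between the crosses")

    sub_a = mat_a.subset_markers(shared)
    sub_b = mat_b.subset_markers(shared)
    flips = _phase_flips(sub_a.calls, sub_b.calls, lod_min, min_signal)

    all_ids = sorted(ids_a | ids_b)
    n_a, n_b = mat_a.n_offspring, mat_b.n_offspring
    calls = np.full((len(all_ids), n_a + n_b), MISSING, dtype=np.int8)
    index_a = mat_a.marker_index()
    index_b = mat_b.marker_index()
    flip_of = dict(zip(shared, flips))
    for i, mk in enumerate(all_ids):
        if mk in index_a:
            calls[i, :n_a] = mat_a.calls[index_a[mk]]
        if mk in index_b:
            row = mat_b.calls[index_b[mk]]
            if flip_of.get(mk, 0):
                row = np.where(row >= 0, row ^ 1, row)
            calls[i, n_a:] = row
    offspring = np.concatenate([mat_a.offspring_ids, mat_b.offspring_ids])
    return DHMatrix(np.array(all_ids, dtype=object), offspring, calls)


def _phase_flips(calls_a, calls_b, lod_min, min_signal):
    """Per-marker flip (0/1) of dataset B relative to A, by BFS over the
    strong-linkage graph using unfolded mismatch fractions."""
    from collections import deque

    def unfolded(calls):
        present = (calls != MISSING).astype(np.float64)
        ones = np.where(calls == 1, 1.0, 0.0)
        zeros = present - ones
        N = present @ present.T
        mis = ones @ zeros.T + zeros @ ones.T
        with np.errstate(invalid="ignore"):
            f = np.where(N > 0, mis / np.maximum(N, 1), 0.5)
        R = np.minimum(mis, N - mis)
        lod = _lk.lod_from_counts(R, N)
        return f, lod

    f_a, lod_a = unfolded(calls_a)
    f_b, lod_b = unfolded(calls_b)
    m = calls_a.shape[0]
    strong = (
        (lod_a >= lod_min)
        & (lod_b >= lod_min)
        & (np.abs(f_a - 0.5) >= min_signal)
        & (np.abs(f_b - 0.5) >= min_signal)
    )
    np.fill_diagonal(strong, False)
    need_flip = (f_a - 0.5) * (f_b - 0.5) < 0  # opposite linkage phase

    flips = np.zeros(m, dtype=np.int8)
    seen = np.zeros(m, dtype=bool)
    for root in range(m):
        if seen[root]:
            continue
        seen[root] = True
        queue = deque([root])
        while queue:
            u = queue.popleft()
            for v in np.flatnonzero(strong[u]):
                if seen[v]:
                    continue
                seen[v] = True
                flips[v] = flips[u] ^ int(need_flip[u, v])
                queue.append(v)
    return flips


# -- map construction ------------------------------------------------------


@dataclass
class MapBuild:
    """Everything produced while mapping one parent dataset."""

    label: str
    n_offspring: int
    repulsion_threshold: int
    bins: list
    bin_map: _lk.LinkageMap
    comprehensive: _lk.LinkageMap
    removal_log: pd.DataFrame
    unplaced: list


def build_map(mat: DHMatrix, records: pd.DataFrame, config: PipelineConfig,
              label: str, rf_bound: float | None = None,
              cM_bound: float | None = None,
              chisq_contrib: float | None = None) -> MapBuild:
    """Bin markers, group at LOD >= 3, order and clean each group, then
    reintegrate binned markers into a comprehensive map."""
    mat, dropped_m, dropped_o = _qc.filter_missing(mat, config.missing_max)
    usable = records[records["quality_class"] != "excluded"]
    keep = [m for m in mat.marker_ids if m in set(usable["marker"])]
    mat = mat.subset_markers(keep)

    if rf_bound is None and cM_bound is None:
        rf_bound = config.repulsion_rf
    threshold = _binning.max_repulsion_for_target(
        mat.n_offspring, rf_bound=rf_bound, cM_bound=cM_bound
    )
    bins = _binning.build_bins(mat, threshold, records.set_index("marker"))

    qmap = records.set_index("marker")["quality_class"].to_dict()
    reps = [b.representative for b in bins
            if qmap.get(b.representative) in config.mapped_classes]
    rep_mat = mat.subset_markers(reps)
    R, N = _binning.pairwise_counts(rep_mat)
    lod = _lk.lod_from_counts(R, N)
    with np.errstate(invalid="ignore"):
        rf = np.where(N > 0, R / np.maximum(N, 1), 0.5)
    groups, unplaced = _lk.group_markers(rep_mat.marker_ids, lod, config.lod_min,
                                         rf_matrix=rf)

    criteria = _lk.RemovalCriteria(
        chisq_contrib_max=chisq_contrib
        if chisq_contrib is not None else config.chisq_contrib_bin,
        max_double_crossovers=config.dxo_max,
        collinearity_shift_max_cM=config.shift_max_cM,
    )
    lk_groups, logs = [], []
    for gi, gids in enumerate(groups, start=1):
        try:
            order, pos, log = _lk.iterative_clean(rep_mat, gids, criteria)
        except RuntimeError as exc:
            logs.append(pd.DataFrame(
                [("abort", ";".join(map(str, gids)), str(exc))],
                columns=["iteration", "marker", "reason"]))
            continue
        log.insert(0, "group", f"G{gi:02d}")
        logs.append(log)
        lk_groups.append(_lk.LinkageGroup(f"G{gi:02d}", order, pos))
    bin_map = _lk.LinkageMap(lk_groups, algorithm="regression")
    comprehensive = _binning.reintegrate_bins(bin_map, bins, mat)
    removal_log = (pd.concat(logs, ignore_index=True)
                   if logs else pd.DataFrame(columns=["group", "iteration", "marker", "reason"]))
    return MapBuild(
        label=label,
        n_offspring=mat.n_offspring,
        repulsion_threshold=threshold,
        bins=bins,
        bin_map=bin_map,
        comprehensive=comprehensive,
        removal_log=removal_log,
        unplaced=unplaced,
    )


# -- comparative stage -----------------------------------------------------


@dataclass
class Comparison:
    label: str
    anchors: pd.DataFrame
    map_frame: pd.DataFrame  # oriented, groups renamed to reference numbering
    flags_by_group: dict
    group_chrom: dict
    spearman_vs_genome: pd.DataFrame
    calls: list
    duplication_report: pd.DataFrame


def compare_map(build: MapBuild, scenario: SimScenario, config: PipelineConfig,
                anchor_seed: int, label: str, hits=None) -> Comparison:
    """Anchor a comprehensive map to the reference and call rearrangements.

    When ``hits`` is None, synthetic tabular hits are generated from the
    scenario's rearranged reference with the configured anchor density and
    noise.  Linkage groups are renamed and oriented to the reference
    chromosome convention before flagging.
    """
    comp = build.comprehensive
    marker_ids = [str(m) for g in comp.groups for m in g.marker_ids]
    if hits is None:
        hits = make_synthetic_anchors(
            scenario,
            marker_ids,
            fraction=config.anchor_fraction,
            noise_rate=config.anchor_noise,
            seed=anchor_seed,
        )
    anchored_chroms = [f"Chr{c:02d}" for c in range(1, scenario.n_chromosomes + 1)]
    anchors = _cmp.parse_and_filter_anchors(hits, anchored_chroms, query_lengths=64)

    acc = anchors[anchors["accepted"]].set_index("marker")
    frames, group_chrom = [], {}
    used_names = {}
    for g in comp.groups:
        ids = [str(m) for m in g.marker_ids]
        try:
            chrom, status = _cmp.assign_synteny(ids, anchors)
        except ValueError:
            continue
        df = pd.DataFrame(
            {
                "marker": ids,
                "position_cM": g.positions,
                "status": status["status"].to_numpy(),
            }
        )
        df["bp_start"] = [
            float(acc.at[m, "bp_start"]) if m in acc.index else np.nan for m in ids
        ]
        df["chromosome"] = [
            str(acc.at[m, "chromosome"]) if m in acc.index else "" for m in ids
        ]
        syn = df[df["status"] == "syntenic"]
        if len(syn) >= 3:
            rho = _sp(syn["position_cM"], syn["bp_start"])
            if rho < 0:
                top = df["position_cM"].max()
                df["position_cM"] = top - df["position_cM"]
                df = df.iloc[::-1].reset_index(drop=True)
        num = int(chrom.removeprefix("Chr"))
        name = f"LG{num}"
        if name in used_names:
            used_names[name] += 1
            name = f"{name}{chr(96 + used_names[name])}"
        else:
            used_names[name] = 1
        df.insert(0, "group", name)
        group_chrom[name] = chrom
        frames.append(df)
    frames.sort(key=lambda d: str(d["group"].iloc[0]))
    map_frame = (pd.concat(frames, ignore_index=True)
                 if frames else pd.DataFrame(columns=["group", "marker", "position_cM",
                                                      "status", "bp_start"]))

    flags_by_group, rows, calls = {}, [], []
    for name, gdf in map_frame.groupby("group", sort=True):
        flags = _cmp.flag_noncollinear(gdf, config.noncollinear_bp)
        flags_by_group[name] = flags
        syn = gdf[gdf["status"] == "syntenic"]
        rho = _sp(syn["position_cM"], syn["bp_start"]) if len(syn) >= 3 else np.nan
        rows.append((name, group_chrom[name], abs(rho) if rho == rho else np.nan,
                     len(syn)))
        calls.extend(
            _cmp.call_rearrangements(
                flags, name,
                min_span_cM=config.min_span_cM,
                threshold_bp=config.noncollinear_bp,
                gap_tolerance=config.gap_tolerance,
                taxon=config.taxon,
            )
        )
    spearman = pd.DataFrame(
        rows, columns=["group", "chromosome", "spearman_rho", "n_syntenic"]
    )
    sec = _cmp.secondary_hits(hits, anchors, anchored_chroms, query_lengths=64,
                              evalue_max=config.evalue_max,
                              coverage_min=config.coverage_min)
    dup = _cmp.screen_duplications(sec, map_frame, group_chrom)
    return Comparison(
        label=label,
        anchors=anchors,
        map_frame=map_frame,
        flags_by_group=flags_by_group,
        group_chrom=group_chrom,
        spearman_vs_genome=spearman,
        calls=calls,
        duplication_report=dup,
    )


def _sp(a, b) -> float:
    from scipy import stats

    res = stats.spearmanr(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic) if res.statistic == res.statistic else 0.0


# -- replication -----------------------------------------------------------


def call_overlap(call_a, call_b) -> float:
    """Overlap of two calls' spanning reference intervals, relative to the
    shorter of the two.

    The shorter basis (rather than reciprocal overlap) is used because the
    spanning interval a map recovers scales with that map's marker density
    in the region: a sparse map legitimately sees a shorter slice of the
    same event.
    """
    a0, a1 = sorted(call_a.spanning_bp)
    b0, b1 = sorted(call_b.spanning_bp)
    inter = max(0.0, min(a1, b1) - max(a0, b0))
    shorter = max(min(a1 - a0, b1 - b0), 1.0)
    return inter / shorter


def mark_replicated(calls, other_call_sets, group_chrom, other_chrom_maps,
                    min_overlap: float = 0.5) -> None:
    """Flag calls supported by an overlapping call in every other map.

    A call replicates in another map when that map carries a call on the
    homologous chromosome whose spanning reference interval overlaps
    reciprocally by >= ``min_overlap``.
    """
    for c in calls:
        chrom = group_chrom.get(c.linkage_group)
        support = 0
        for other_calls, other_chrom in zip(other_call_sets, other_chrom_maps):
            hit = any(
                other_chrom.get(o.linkage_group) == chrom
                and call_overlap(c, o) >= min_overlap
                for o in other_calls
            )
            support += bool(hit)
        c.replicated = bool(other_call_sets) and support == len(other_call_sets)


# -- full run --------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> qc -> bin -> map -> compare for the whole design.

    Produces bin and comprehensive maps for the shared parent (per family
    and combined) and for each family's seed parent, cross-map order
    correlations, rearrangement calls per map, and the replication report.
    Writes TSV outputs under ``config.outdir`` when set; identical config +
    seed gives identical outputs.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(4)]
    sc = config.scenario
    out = Path(config.outdir) if config.outdir else None
    if out:
        ensure_dir(out)
    log = []

    def stage(name, fn):
        try:
            result = fn()
            log.append((name, "ok"))
            return result
        except Exception as exc:
            log.append((name, f"FAILED: {exc}"))
            if out:
                pd.DataFrame(log, columns=["stage", "status"]).to_csv(
                    out / "pipeline_log.tsv", sep="\t", index=False)
            raise RuntimeError(f"stage [{name}] failed: {exc}") from exc

    fam_a = stage("simulate_family_a",
                  lambda: simulate_family(sc, config.n_family_a, "FA", seeds[0]))
    fam_b = stage("simulate_family_b",
                  lambda: simulate_family(sc, config.n_family_b, "FB", seeds[1]))

    rec = {
        ("FA", p): records_to_frame(fam_a.records[p]) for p in ("P1", "P2")
    } | {("FB", p): records_to_frame(fam_b.records[p]) for p in ("P1", "P2")}

    # parental bin maps in each family
    builds = {}
    for fam, sim in (("FA", fam_a), ("FB", fam_b)):
        for p in ("P1", "P2"):
            label = f"{fam}_{p}"
            builds[label] = stage(
                f"map_{label}",
                lambda sim=sim, p=p, fam=fam, label=label: build_map(
                    sim.dh[p], rec[(fam, p)], config, label,
                    rf_bound=config.repulsion_rf,
                ),
            )

    # combined shared-parent dataset, re-binned at the larger n
    combined = stage(
        "combine_families",
        lambda: combine_families(fam_a.dh["P1"], fam_b.dh["P1"], config.lod_min),
    )
    rec_combined = (
        pd.concat([rec[("FB", "P1")], rec[("FA", "P1")]])
        .drop_duplicates("marker", keep="first")
        .reset_index(drop=True)
    )
    builds["COMBINED_P1"] = stage(
        "map_combined_p1",
        lambda: build_map(
            combined, rec_combined, config, "COMBINED_P1",
            cM_bound=config.repulsion_cM,
            chisq_contrib=config.chisq_contrib_comprehensive,
        ),
    )

    # comparative analysis of the three comprehensive maps
    comparisons = {}
    for k, label in enumerate(("COMBINED_P1", "FA_P2", "FB_P2")):
        comparisons[label] = stage(
            f"compare_{label}",
            lambda label=label, k=k: compare_map(
                builds[label], sc, config, anchor_seed=seeds[2] + k, label=label
            ),
        )

    # replication: the combined map's calls checked against both seed-parent
    # maps; the seed-parent maps checked against each other
    main = comparisons["COMBINED_P1"]
    ct_a, ct_b = comparisons["FA_P2"], comparisons["FB_P2"]
    stage("replication", lambda: (
        mark_replicated(main.calls, [ct_a.calls, ct_b.calls],
                        main.group_chrom, [ct_a.group_chrom, ct_b.group_chrom]),
        mark_replicated(ct_a.calls, [ct_b.calls], ct_a.group_chrom,
                        [ct_b.group_chrom]),
        mark_replicated(ct_b.calls, [ct_a.calls], ct_b.group_chrom,
                        [ct_a.group_chrom]),
    ))

    spearman_parents = stage(
        "spearman_replication",
        lambda: _replication_spearman(builds, fam_a, fam_b),
    )

    bundle = {
        "config": config,
        "families": {"FA": fam_a, "FB": fam_b},
        "records": rec,
        "builds": builds,
        "comparisons": comparisons,
        "spearman_parents": spearman_parents,
        "log": log,
    }
    if out:
        stage("write_outputs", lambda: _write_outputs(bundle, out, sc, config))
    return bundle


def _match_groups(map_a: _lk.LinkageMap, map_b: _lk.LinkageMap):
    """Pair groups of two maps by shared-marker overlap."""
    pairs = []
    for ga in map_a.groups:
        ids_a = set(map(str, ga.marker_ids))
        best, best_n = None, 0
        for gb in map_b.groups:
            n = len(ids_a & set(map(str, gb.marker_ids)))
            if n > best_n:
                best, best_n = gb, n
        if best is not None and best_n >= 3:
            pairs.append((ga, best, best_n))
    return pairs


def _strip_parent_suffix(ids):
    return [str(m).removesuffix("_P1").removesuffix("_P2") for m in ids]


def _replication_spearman(builds, fam_a, fam_b) -> pd.DataFrame:
    """Order correlations: technical (shared parent across families) and
    biological (the two parents within a family, via split fully-informative
    loci matched on their base marker id)."""
    rows = []
    # technical: P1 bin maps of the two families
    a, b = builds["FA_P1"].bin_map, builds["FB_P1"].bin_map
    for ga, gb, n in _match_groups(a, b):
        pos_a = pd.Series(ga.positions, index=[str(m) for m in ga.marker_ids])
        pos_b = pd.Series(gb.positions, index=[str(m) for m in gb.marker_ids])
        rho, p, n_sh = _lk.spearman_order(pos_a, pos_b)
        rows.append(("technical_P1", ga.group_id, gb.group_id, rho, p, n_sh))
    # biological: P1 vs P2 comprehensive maps within each family
    for fam in ("FA", "FB"):
        a = builds[f"{fam}_P1"].comprehensive
        b = builds[f"{fam}_P2"].comprehensive
        for ga, gb, n in _match_groups_base(a, b):
            pos_a = pd.Series(ga.positions, index=_strip_parent_suffix(ga.marker_ids))
            pos_b = pd.Series(gb.positions, index=_strip_parent_suffix(gb.marker_ids))
            pos_a = pos_a[~pos_a.index.duplicated()]
            pos_b = pos_b[~pos_b.index.duplicated()]
            rho, p, n_sh = _lk.spearman_order(pos_a, pos_b)
            rows.append((f"biological_{fam}", ga.group_id, gb.group_id, rho, p, n_sh))
    return pd.DataFrame(
        rows, columns=["comparison", "group_a", "group_b", "rho", "p", "n_shared"]
    )


def _match_groups_base(map_a, map_b):
    pairs = []
    for ga in map_a.groups:
        ids_a = set(_strip_parent_suffix(ga.marker_ids))
        best, best_n = None, 0
        for gb in map_b.groups:
            n = len(ids_a & set(_strip_parent_suffix(gb.marker_ids)))
            if n > best_n:
                best, best_n = gb, n
        if best is not None and best_n >= 3:
            pairs.append((ga, best, best_n))
    return pairs


def _write_outputs(bundle, out: Path, scenario, config) -> None:
    header = config.echo()
    for label, build in bundle["builds"].items():
        build.bin_map.to_tsv(out / f"{label}_bin_map.tsv", header)
        build.comprehensive.to_tsv(out / f"{label}_comprehensive_map.tsv", header)
        build.comprehensive.summary().to_csv(out / f"{label}_summary.tsv",
                                             sep="\t", index=False)
        build.removal_log.to_csv(out / f"{label}_removals.tsv", sep="\t", index=False)
        _binning.bin_table(build.bins).to_csv(out / f"{label}_bins.tsv",
                                              sep="\t", index=False)
    for label, compn in bundle["comparisons"].items():
        _cmp.calls_table(compn.calls).to_csv(out / f"{label}_calls.tsv",
                                             sep="\t", index=False)
        compn.spearman_vs_genome.to_csv(out / f"{label}_spearman_genome.tsv",
                                        sep="\t", index=False)
        flag_frames = []
        for f in compn.flags_by_group.values():
            if f is not None:
                f = f.copy()
                f.attrs = {}
                flag_frames.append(f)
        flags = pd.concat(flag_frames, ignore_index=True) if flag_frames else pd.DataFrame()
        flags.to_csv(out / f"{label}_flags.tsv", sep="\t", index=False)
        chrom_lengths = {
            f"Chr{c:02d}": scenario.chrom_lengths_bp[c - 1]
            for c in range(1, scenario.n_chromosomes + 1)
        }
        _cmp.export_dotplot(
            compn.map_frame, compn.flags_by_group, chrom_lengths,
            tsv_path=out / f"{label}_dotplot.tsv",
            png_path=out / f"{label}_dotplot.png",
            calls=compn.calls,
        )
        compn.duplication_report.to_csv(out / f"{label}_duplications.tsv",
                                        sep="\t", index=False)
    bundle["spearman_parents"].to_csv(out / "spearman_parents.tsv",
                                      sep="\t", index=False)
    pd.DataFrame(bundle["log"], columns=["stage", "status"]).to_csv(
        out / "pipeline_log.tsv", sep="\t", index=False)
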