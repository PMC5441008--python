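"""Map-versus-genome synteny and collinearity analysis.

Mapped markers are anchored to reference chromosomes through filtered
tabular sequence-search hits.  Each linkage group is assigned its homologous
chromosome (the modal chromosome of its accepted anchors), a collinear
reference trend is computed as the longest monotone subsequence of anchor
positions in map order, and markers displaced >= 2 Mb from the trend are
flagged non-collinear.  Maximal runs of consecutive non-collinear markers
spanning > 5 cM become rearrangement calls, typed as in-place inversions or
transposed inversions ("tp") from the run's orientation and displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ptxmap.io import read_blast_tab, BLAST6_COLUMNS

NONCOLLINEAR_BP = 2_000_000
MIN_SPAN_CM = 5.0


# -- anchor filtering ------------------------------------------------------


def parse_and_filter_anchors(hits, anchored_chromosomes, query_lengths=64):
    """Best-hit filtering of tabular alignment hits into marker anchors.

    ``hits``: path to a 12-column tabular file or an equivalent DataFrame.
    ``query_lengths``: scalar tag length or dict per marker.  Per marker the
    highest bit-score hit is kept; equal-score hits on the same chromosome
    within 2 Mb collapse to the one with the lowest bp then lexicographic
    subject id.  A kept hit is accepted iff query coverage > 0.95, e-value
    < 1e-10, and the subject is an anchored chromosome (scaffold hits are
    recorded but never accepted).

    Returns a DataFrame: marker, chromosome, bp_start, strand, e_value,
    coverage, bitscore, accepted.
    """
    if isinstance(hits, (str, bytes)) or hasattr(hits, "__fspath__"):
        df = read_blast_tab(hits)
    else:
        df = hits.loc[:, BLAST6_COLUMNS].copy()
    anchored = set(map(str, anchored_chromosomes))
    if len(df) == 0:
        return pd.DataFrame(
            columns=["marker", "chromosome", "bp_start", "strand", "e_value",
                     "coverage", "bitscore", "accepted"]
        )
    if isinstance(query_lengths, dict):
        qlen = df["qseqid"].map(query_lengths).astype(float)
    else:
        qlen = float(query_lengths)
    df = df.assign(
        coverage=df["length"] / qlen,
        bp_start=np.minimum(df["sstart"], df["send"]),
        strand=np.where(df["send"] >= df["sstart"], "+", "-"),
    )
    rows = []
    for mk, sub in df.groupby("qseqid", sort=True):
        best_score = sub["bitscore"].max()
        top = sub[sub["bitscore"] == best_score]
        # deterministic collapse of equal-score hits: lowest bp, then subject
        top = top.sort_values(["bp_start", "sseqid"], kind="stable")
        hit = top.iloc[0]
        on_chrom = str(hit["sseqid"]) in anchored
        accepted = bool(
            on_chrom and hit["coverage"] > 0.95 and hit["evalue"] < 1e-10
        )
        rows.append(
            (str(mk), str(hit["sseqid"]), float(hit["bp_start"]), hit["strand"],
             float(hit["evalue"]), float(hit["coverage"]), float(hit["bitscore"]),
             accepted)
        )
    return pd.DataFrame(
        rows,
        columns=["marker", "chromosome", "bp_start", "strand", "e_value",
                 "coverage", "bitscore", "accepted"],
    )


def secondary_hits(hits, best_anchors: pd.DataFrame, anchored_chromosomes,
                   query_lengths=64, evalue_max=1e-10, coverage_min=0.95):
    """High-quality hits other than each marker's chosen best anchor."""
    if isinstance(hits, (str, bytes)) or hasattr(hits, "__fspath__"):
        df = read_blast_tab(hits)
    else:
        df = hits.copy()
    anchored = set(map(str, anchored_chromosomes))
    if isinstance(query_lengths, dict):
        qlen = df["qseqid"].map(query_lengths).astype(float)
    else:
        qlen = float(query_lengths)
    df = df.assign(
        coverage=df["length"] / qlen,
        bp_start=np.minimum(df["sstart"], df["send"]),
    )
    df = df[(df["evalue"] < evalue_max) & (df["coverage"] > coverage_min)]
    df = df[df["sseqid"].astype(str).isin(anchored)]
    best = best_anchors.set_index("marker")
    out = []
    for _, row in df.iterrows():
        mk = str(row["qseqid"])
        if mk in best.index:
            b = best.loc[mk]
            if (str(row["sseqid"]) == b["chromosome"]
                    and abs(row["bp_start"] - b["bp_start"]) < 1):
                continue  # the chosen best hit itself
        out.append((mk, str(row["sseqid"]), float(row["bp_start"]),
                    float(row["bitscore"])))
    return pd.DataFrame(out, columns=["marker", "chromosome", "bp_start", "bitscore"])


# -- synteny ---------------------------------------------------------------


def assign_synteny(group_markers, anchors: pd.DataFrame):
    """Homologous chromosome of a linkage group and per-marker synteny.

    The group's chromosome is the modal chromosome among its accepted
    anchors (a tie raises).  Returns (chromosome, DataFrame of marker,
    status in {syntenic, nonsyntenic, unanchored}).
    """
    ids = [str(m) for m in group_markers]
    acc = anchors[anchors["accepted"]].set_index("marker")
    hit_chrom = {m: acc.at[m, "chromosome"] for m in ids if m in acc.index}
    if not hit_chrom:
        raise ValueError("no accepted anchor in group")
    counts = pd.Series(list(hit_chrom.values())).value_counts()
    top = counts[counts == counts.iloc[0]]
    if len(top) > 1:
        raise ValueError(f"modal chromosome tie: {sorted(top.index)}")
    chrom = str(counts.index[0])
    status = [
        ("syntenic" if hit_chrom[m] == chrom else "nonsyntenic")
        if m in hit_chrom else "unanchored"
        for m in ids
    ]
    return chrom, pd.DataFrame({"marker": ids, "status": status})


# -- collinearity ----------------------------------------------------------


def _longest_monotone(bp: np.ndarray, cm: np.ndarray, slack_bp: float = 2e6,
                      jump_penalty: float = 6.0):
    """Weighted longest monotone subsequence of bp along the map, best of
    increasing and decreasing; ties prefer increasing.

    Each marker scores one point, but a link whose local slope exceeds 1.5x
    the group's overall Mb/cM ratio (plus a noise slack) costs
    ``jump_penalty`` points.  A genuine trend jump — rejoining the diagonal
    after a transposed segment's insertion point — recruits the rest of the
    chromosome and easily pays the penalty; weaving through the leading
    edge of an inverted segment (which would both unflag part of the event
    and corrupt the interpolated expectation used for typing) gains only a
    few noise points and does not.
    """
    n = len(bp)
    span_cm = max(float(cm[-1] - cm[0]), 1e-9)
    ratio = abs(float(bp.max() - bp.min())) / span_cm
    cap = 1.5 * ratio
    slack = 0.5 * slack_bp

    def lis(vals):
        score = np.ones(n, dtype=float)
        prev = np.full(n, -1, dtype=int)
        for i in range(n):
            for j in range(i):
                if vals[j] > vals[i]:
                    continue
                pen = 0.0
                if vals[i] - vals[j] > cap * (cm[i] - cm[j]) + slack:
                    pen = jump_penalty
                cand = score[j] + 1.0 - pen
                if cand > score[i]:
                    score[i] = cand
                    prev[i] = j
        k = int(np.argmax(score))
        seq = []
        while k >= 0:
            seq.append(k)
            k = prev[k]
        return seq[::-1], float(np.max(score))

    inc, s_inc = lis(bp)
    dec, s_dec = lis(-bp)
    if s_inc >= s_dec:
        return inc, True
    return dec, False


def _trend_interp(cm_t, bp_t, cm_query):
    """Piecewise-linear trend bp at query cM, extrapolating terminal slopes.

    Terminal slopes are taken over a baseline of up to 5 trend points so a
    pair of tightly spaced noisy markers at a map end cannot swing the
    extrapolation (terminal inversions are typed from it)."""
    cm_t = np.asarray(cm_t, dtype=float)
    bp_t = np.asarray(bp_t, dtype=float)
    out = np.interp(cm_query, cm_t, bp_t)
    if len(cm_t) >= 2:
        k = min(5, len(cm_t) - 1)
        lo = cm_query < cm_t[0]
        hi = cm_query > cm_t[-1]
        s0 = (bp_t[k] - bp_t[0]) / max(cm_t[k] - cm_t[0], 1e-9)
        s1 = (bp_t[-1] - bp_t[-1 - k]) / max(cm_t[-1] - cm_t[-1 - k], 1e-9)
        out = np.where(lo, bp_t[0] + s0 * (cm_query - cm_t[0]), out)
        out = np.where(hi, bp_t[-1] + s1 * (cm_query - cm_t[-1]), out)
    return out


def flag_noncollinear(group_frame: pd.DataFrame, threshold_bp: float = NONCOLLINEAR_BP):
    """Collinearity flags for one linkage group.

    ``group_frame``: markers in map order with columns marker, position_cM,
    status (from assign_synteny), bp_start (NaN when unanchored).  The
    collinear order is the longest monotone subsequence of reference
    positions along the map; displacement is each marker's |bp -
    interpolated trend bp at its cM|, and markers displaced >=
    ``threshold_bp`` are non-collinear.  Groups with fewer than 3 syntenic
    anchors are skipped (returns None).
    """
    df = group_frame.reset_index(drop=True)
    syn = df[df["status"] == "syntenic"]
    if len(syn) < 3:
        return None
    cm = syn["position_cM"].to_numpy(float)
    bp = syn["bp_start"].to_numpy(float)
    trend_idx, increasing = _longest_monotone(bp, cm, slack_bp=threshold_bp)
    cm_t, bp_t = cm[trend_idx], bp[trend_idx]
    # collapse duplicate trend cM for interpolation
    tt = pd.DataFrame({"cm": cm_t, "bp": bp_t}).groupby("cm", as_index=False).mean()
    # virtual boundary anchors: a group covering its chromosome runs from
    # ~bp 0 to the top of its anchored range, which disciplines the
    # expectation across trendless terminal events (extrapolation over a
    # long terminal inversion is otherwise unconstrained)
    lo_bp, hi_bp = (0.0, float(bp.max())) if increasing else (float(bp.max()), 0.0)
    # a stolen terminal point (the leading marker of a terminal inversion
    # continues the diagonal flatly) is inconsistent with the boundary
    # anchor under the same slope cap used for the trend itself
    ratio = abs(float(bp.max() - bp.min())) / max(float(cm[-1] - cm[0]), 1e-9)
    cap, slack = 1.5 * ratio, 0.5 * threshold_bp
    while len(tt) > 2 and (
        abs(tt["bp"].iloc[0] - lo_bp) > cap * (tt["cm"].iloc[0] - (cm.min() - 1.0)) + slack
    ):
        tt = tt.iloc[1:]
    while len(tt) > 2 and (
        abs(hi_bp - tt["bp"].iloc[-1]) > cap * ((cm.max() + 1.0) - tt["cm"].iloc[-1]) + slack
    ):
        tt = tt.iloc[:-1]
    tt = pd.concat(
        [pd.DataFrame({"cm": [cm.min() - 1.0], "bp": [lo_bp]}), tt,
         pd.DataFrame({"cm": [cm.max() + 1.0], "bp": [hi_bp]})],
        ignore_index=True,
    )
    expected = _trend_interp(tt["cm"].to_numpy(), tt["bp"].to_numpy(), cm)
    displacement = np.abs(bp - expected)
    status = np.where(displacement >= threshold_bp,
                      "syntenic_noncollinear", "syntenic_collinear")
    out = df.copy()
    out["displacement_bp"] = np.nan
    out["collinearity"] = out["status"].map(
        {"nonsyntenic": "nonsyntenic", "unanchored": "unanchored"}
    )
    out.loc[syn.index, "displacement_bp"] = displacement
    out.loc[syn.index, "collinearity"] = status
    out.attrs["trend_increasing"] = bool(increasing)
    out.attrs["trend_cm"] = tt["cm"].to_numpy()
    out.attrs["trend_bp"] = tt["bp"].to_numpy()
    return out


# -- rearrangement calls ---------------------------------------------------


@dataclass
class RearrangementCall:
    """A maximal non-collinear run: one putative chromosomal rearrangement."""

    name: str
    linkage_group: str
    members: list
    span_cM: float
    spanning_bp: tuple  # reference bp of first and last member
    flanking_bp: tuple  # bp of first collinear marker on either side (None at ends)
    kind: str  # inversion | inversion_translocation | unknown
    map_interval_cM: tuple = (0.0, 0.0)
    replicated: bool = False


def _candidate_runs(flags: pd.DataFrame, gap_tolerance: int):
    """Maximal runs of non-collinear markers along the map order.

    Unanchored markers are invisible — runs are read off the sequence of
    anchored markers only.  Nonsyntenic markers (anchored to the wrong
    chromosome) interleave without breaking a run up to ``gap_tolerance``
    consecutive; a collinear syntenic marker breaks it.
    """
    runs, current = [], []
    gap = 0
    for _, row in flags.iterrows():
        c = row["collinearity"]
        if c == "unanchored" or pd.isna(c):
            continue
        if c == "syntenic_noncollinear":
            current.append(row)
            gap = 0
        elif c == "nonsyntenic":
            gap += 1
            if current and gap > gap_tolerance:
                runs.append(current)
                current, gap = [], 0
        else:  # collinear
            if current:
                runs.append(current)
            current, gap = [], 0
    if current:
        runs.append(current)
    return [pd.DataFrame(r) for r in runs if r]


def _merge_runs(runs, flags, threshold_bp, max_stray=2):
    """Join adjacent runs split by the low-displacement core of an inversion.

    Two neighbouring runs merge only when both have >= 2 members, their
    reference-bp envelopes lie within 2x the displacement threshold, the
    combined run remains monotone (|Spearman| >= 0.8), and the collinear
    anchored markers separating them sit inside the merged reference
    envelope (an inversion's core crosses the diagonal and its markers'
    positions fall between the flagged flanks at any marker density,
    whereas unrelated diagonal markers interrupt for good); up to
    ``max_stray`` stragglers outside the envelope are tolerated.
    """
    if len(runs) < 2:
        return runs
    syn = flags[flags["collinearity"].isin(
        ["syntenic_collinear", "syntenic_noncollinear"])]
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for k in range(len(runs) - 1):
            a = runs[k]
            if len(a) < 2:
                continue
            # partner may sit past interleaved singleton runs (isolated
            # wrong-homolog or noise anchors), which stay as their own runs
            for l in range(k + 1, min(k + 4, len(runs))):
                b = runs[l]
                if len(b) < 2:
                    continue
                if any(len(runs[t]) > 1 for t in range(k + 1, l)):
                    break
                lo_a, hi_a = a["bp_start"].min(), a["bp_start"].max()
                lo_b, hi_b = b["bp_start"].min(), b["bp_start"].max()
                gap_bp = max(lo_b - hi_a, lo_a - hi_b, 0.0)
                if gap_bp > 2 * threshold_bp:
                    break
                cm_hi = b["position_cM"].min()
                cm_lo = a["position_cM"].max()
                between = syn[(syn["position_cM"] > cm_lo)
                              & (syn["position_cM"] < cm_hi)
                              & (syn["collinearity"] == "syntenic_collinear")]
                env_lo = min(lo_a, lo_b) - threshold_bp
                env_hi = max(hi_a, hi_b) + threshold_bp
                outside = ((between["bp_start"] < env_lo)
                           | (between["bp_start"] > env_hi)).sum()
                if outside > max_stray:
                    break
                comb = pd.concat([a, b])
                rho = stats.spearmanr(comb["position_cM"], comb["bp_start"]).statistic
                if np.isnan(rho) or abs(rho) < 0.8:
                    break
                runs = (runs[:k] + [comb.sort_values("position_cM")]
                        + runs[k + 1:l] + runs[l + 1:])
                changed = True
                break
            if changed:
                break
    return runs


def type_rearrangement(run: pd.DataFrame, trend_cm, trend_bp, trend_increasing):
    """Classify a called run as an in-place or transposed inversion.

    The run is inverted when its internal bp-vs-cM slope opposes the group
    trend; it is additionally transposed (inversion_translocation) when the
    run's reference interval sits clearly away from the reference window
    interpolated at its map location — i.e. somewhere else on the
    chromosome, not merely in reversed order.  The separation must exceed
    both the displacement threshold and the spans of the two intervals,
    because a partially anchored in-place inversion covers only part of the
    reflected segment and shows a gap of up to its own span.
    """
    bp = run["bp_start"].to_numpy(float)
    cm = run["position_cM"].to_numpy(float)
    if len(run) < 2:
        return "unknown", "unknown"
    rho = stats.spearmanr(cm, bp).statistic
    run_dir = "increasing" if rho >= 0 else "decreasing"
    trend_dir = "increasing" if trend_increasing else "decreasing"
    inverted = run_dir != trend_dir
    expected = _trend_interp(trend_cm, trend_bp, np.array([cm.min(), cm.max()]))
    exp_lo, exp_hi = float(np.min(expected)), float(np.max(expected))
    gap = max(bp.min() - exp_hi, exp_lo - bp.max(), 0.0)
    tol = max(NONCOLLINEAR_BP, bp.max() - bp.min(), exp_hi - exp_lo)
    transposed = gap > tol
    if transposed:
        return "inversion_translocation", "inverted" if inverted else "direct"
    if inverted:
        return "inversion", "inverted"
    return "unknown", "direct"


def call_rearrangements(flags: pd.DataFrame, group_id: str,
                        min_span_cM: float = MIN_SPAN_CM,
                        threshold_bp: float = NONCOLLINEAR_BP,
                        gap_tolerance: int = 1,
                        taxon: str = "SIM"):
    """Rearrangement calls for one linkage group from collinearity flags.

    Runs of consecutive non-collinear markers (gap-tolerant, with
    inversion-core merging) whose map span exceeds ``min_span_cM`` become
    calls, named <taxon>-in(<LG>)[tp]<k> with k counting events per group
    in map order.
    """
    if flags is None:
        return []
    runs = _candidate_runs(flags, gap_tolerance)
    runs = _merge_runs(runs, flags, threshold_bp)
    trend_cm = flags.attrs.get("trend_cm")
    trend_bp = flags.attrs.get("trend_bp")
    trend_inc = flags.attrs.get("trend_increasing", True)
    syn = flags[flags["collinearity"] == "syntenic_collinear"]
    calls = []
    for run in runs:
        run = run.sort_values("position_cM")
        span = float(run["position_cM"].max() - run["position_cM"].min())
        if span <= min_span_cM:
            continue
        if _is_offset_segment(run, syn, trend_inc, threshold_bp):
            continue
        kind, orientation = type_rearrangement(run, trend_cm, trend_bp, trend_inc)
        lo_cm, hi_cm = run["position_cM"].min(), run["position_cM"].max()
        left = syn[syn["position_cM"] < lo_cm]
        right = syn[syn["position_cM"] > hi_cm]
        flank = (
            float(left["bp_start"].iloc[-1]) if len(left) else None,
            float(right["bp_start"].iloc[0]) if len(right) else None,
        )
        spanning = (float(run["bp_start"].iloc[0]), float(run["bp_start"].iloc[-1]))
        calls.append(
            RearrangementCall(
                name="",  # assigned below, in map order
                linkage_group=str(group_id),
                members=[str(m) for m in run["marker"]],
                span_cM=span,
                spanning_bp=spanning,
                flanking_bp=flank,
                kind=kind,
                map_interval_cM=(float(lo_cm), float(hi_cm)),
            )
        )
    calls.sort(key=lambda c: c.map_interval_cM)
    lg_num = "".join(ch for ch in str(group_id) if ch.isdigit()) or str(group_id)
    for k, c in enumerate(calls, start=1):
        tp = "tp" if c.kind == "inversion_translocation" else ""
        c.name = f"{taxon}-in({int(lg_num)}){tp}{k}"
    return calls


def _is_offset_segment(run, collinear, trend_increasing, threshold_bp) -> bool:
    """True when a flagged run preserves marker order and only carries a
    coordinate offset — the signature of a length difference upstream (for
    instance past a transposed segment's insertion point), not of a
    rearrangement.  Such runs keep the trend direction internally and sit
    in bp order between their anchored neighbours.
    """
    bp = run["bp_start"].to_numpy(float)
    cm = run["position_cM"].to_numpy(float)
    if len(run) >= 3:
        rho = stats.spearmanr(cm, bp).statistic
        if np.isnan(rho) or abs(rho) < 0.8:
            return False
        if (rho > 0) != trend_increasing:
            return False
    elif len(run) == 2:
        if (bp[1] >= bp[0]) != trend_increasing:
            return False
    before = collinear[collinear["position_cM"] < cm.min()]
    after = collinear[collinear["position_cM"] > cm.max()]
    prev_bp = float(before["bp_start"].iloc[-1]) if len(before) else None
    next_bp = float(after["bp_start"].iloc[0]) if len(after) else None
    if trend_increasing:
        if prev_bp is not None and bp.min() < prev_bp - threshold_bp:
            return False
        if next_bp is not None and next_bp < bp.max() - threshold_bp:
            return False
    else:
        if prev_bp is not None and bp.max() > prev_bp + threshold_bp:
            return False
        if next_bp is not None and next_bp > bp.min() + threshold_bp:
            return False
    return True


def calls_table(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "name": c.name,
                "linkage_group": c.linkage_group,
                "type": c.kind,
                "span_cM": round(c.span_cM, 2),
                "n_markers": len(c.members),
                "flank_left_bp": c.flanking_bp[0],
                "flank_right_bp": c.flanking_bp[1],
                "spanning_first_bp": c.spanning_bp[0],
                "spanning_last_bp": c.spanning_bp[1],
                "map_start_cM": round(c.map_interval_cM[0], 2),
                "map_end_cM": round(c.map_interval_cM[1], 2),
                "replicated": c.replicated,
            }
        )
    return pd.DataFrame(rows)


# -- duplication screen ----------------------------------------------------


def screen_duplications(secondary: pd.DataFrame, map_frame: pd.DataFrame,
                        group_chrom: dict, min_series: int = 3):
    """Detect series of map-consecutive markers whose secondary hits are
    collinear on a single chromosome other than the group's homolog.

    Returns a DataFrame of reported series (empty when, as on the real data
    the design mirrors, no inter-chromosomal duplication exists).
    """
    out = []
    if len(secondary) == 0:
        return pd.DataFrame(columns=["group", "chromosome", "n_markers", "markers"])
    sec = secondary.sort_values("bitscore", ascending=False)
    for gid, gmap in map_frame.groupby("group", sort=True):
        gmap = gmap.sort_values("position_cM").reset_index(drop=True)
        own = str(group_chrom.get(gid, ""))
        markers = gmap["marker"].astype(str).tolist()
        for chrom, hits in sec.groupby("chromosome", sort=True):
            if str(chrom) == own:
                continue
            best = hits.drop_duplicates("marker").set_index("marker")["bp_start"]
            series = []
            for mk in markers:
                if mk in best.index:
                    series.append((mk, float(best[mk])))
                else:
                    if len(series) >= min_series and _is_monotone([b for _, b in series]):
                        out.append((gid, str(chrom), len(series),
                                    ",".join(m for m, _ in series)))
                    series = []
            if len(series) >= min_series and _is_monotone([b for _, b in series]):
                out.append((gid, str(chrom), len(series),
                            ",".join(m for m, _ in series)))
    return pd.DataFrame(out, columns=["group", "chromosome", "n_markers", "markers"])


def _is_monotone(vals) -> bool:
    d = np.diff(vals)
    return bool(np.all(d >= 0) or np.all(d <= 0))


# -- dot plot --------------------------------------------------------------


def export_dotplot(map_frame: pd.DataFrame, flags_by_group: dict,
                   chrom_lengths: dict, tsv_path=None, png_path=None,
                   calls=()):
    """Cumulative map-vs-genome coordinates (TSV is normative, PNG optional).

    ``flags_by_group`` maps group id -> flag frame (or None); chromosome
    and group offsets accumulate in id order so every marker gets one
    (cumulative cM, cumulative bp) pair.
    """
    group_ids = sorted(map_frame["group"].unique(), key=str)
    g_off, off = {}, 0.0
    for g in group_ids:
        g_off[g] = off
        sub = map_frame[map_frame["group"] == g]
        off += float(sub["position_cM"].max()) if len(sub) else 0.0
    chroms = sorted(chrom_lengths, key=str)
    c_off, off = {}, 0.0
    for c in chroms:
        c_off[c] = off
        off += float(chrom_lengths[c])
    rows = []
    for g in group_ids:
        flags = flags_by_group.get(g)
        if flags is None:
            continue
        for _, r in flags.iterrows():
            if pd.isna(r.get("bp_start")) or r["collinearity"] == "unanchored":
                continue
            chrom = r["chromosome"]
            if chrom not in c_off:
                continue
            rows.append(
                (r["marker"], g, r["position_cM"], g_off[g] + r["position_cM"],
                 chrom, r["bp_start"], c_off[chrom] + r["bp_start"],
                 r["collinearity"])
            )
    df = pd.DataFrame(
        rows, columns=["marker", "group", "position_cM", "cum_cM",
                       "chromosome", "bp_start", "cum_bp", "collinearity"]
    )
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 7))
        if len(df):
            colors = df["collinearity"].map(
                {"syntenic_collinear": "#3366aa", "syntenic_noncollinear": "#cc3333",
                 "nonsyntenic": "#999999"}
            )
            ax.scatter(df["cum_cM"], df["cum_bp"] / 1e6, s=4, c=colors)
        for g in group_ids[1:]:
            ax.axvline(g_off[g], color="0.85", lw=0.5)
        for c in chroms[1:]:
            ax.axhline(c_off[c] / 1e6, color="0.85", lw=0.5)
        for call in calls:
            x = g_off.get(call.linkage_group)
            if x is not None:
                ax.annotate(call.name,
                            xy=(x + call.map_interval_cM[0], 0),
                            xytext=(x + call.map_interval_cM[0], -30),
                            fontsize=6, rotation=90,
                            arrowprops=dict(arrowstyle="->", lw=0.5))
        ax.set_xlabel("linkage map (cumulative cM)")
        ax.set_ylabel("reference genome (cumulative Mb)")
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
    return df
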