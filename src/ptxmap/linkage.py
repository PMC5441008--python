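"""Two-point linkage analysis and map ordering for DH-coded testcross data.

Markers are grouped at a minimum LOD, ordered within groups by a
Stam-style incremental regression algorithm under the Kosambi mapping
function, cleaned iteratively against goodness-of-fit, double-crossover and
segregation-distortion criteria, and verified by re-ordering with an
independent minimum-recombination (maximum-likelihood style) algorithm.

All algorithms are deterministic given their inputs: ties break on marker
id, and no step draws random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

LOG10_2 = np.log10(2.0)
_RF_CAP = 0.4999


# -- mapping function ------------------------------------------------------


def kosambi(r):
    """Kosambi map distance in cM: d = 25 ln((1+2r)/(1-2r))."""
    r = np.asarray(r, dtype=float)
    if np.any(r >= 0.5) or np.any(r < 0):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d):
    """Inverse Kosambi: r = 0.5 tanh(d/50) for d in cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


# -- two-point statistics --------------------------------------------------


@dataclass(frozen=True)
class PairwiseLinkage:
    marker_1: str
    marker_2: str
    r_hat: float
    lod: float
    n: int


def lod_from_counts(R, N):
    """LOD of linkage vs independence at r_hat = R/N (phase-free counts).

    LOD = R log10(r) + (N-R) log10(1-r) + N log10(2), with the 0*log(0)
    limits taken as 0.
    """
    R = np.asarray(R, dtype=float)
    N = np.asarray(N, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(N > 0, R / np.maximum(N, 1), np.nan)
        t1 = np.where(R > 0, R * np.log10(np.where(r > 0, r, 1.0)), 0.0)
        t2 = np.where(N - R > 0, (N - R) * np.log10(np.where(r < 1, 1 - r, 1.0)), 0.0)
    lod = t1 + t2 + N * LOG10_2
    return np.where(N > 0, np.maximum(lod, 0.0), 0.0)


def rf_lod(m1: np.ndarray, m2: np.ndarray, ids=("m1", "m2")) -> PairwiseLinkage:
    """Two-point estimate for a pair of DH rows."""
    from ptxmap.binning import count_recombinants

    R, N = count_recombinants(m1, m2)
    r = R / N
    lod = float(lod_from_counts(R, N))
    return PairwiseLinkage(str(ids[0]), str(ids[1]), float(r), lod, int(N))


def group_markers(marker_ids, lod_matrix: np.ndarray, lod_min: float = 3.0,
                  triangle_support: int = 1, rf_matrix=None, rf_max: float = 0.30):
    """Partition markers into linkage groups: connected components of the
    graph whose edges have LOD >= ``lod_min``.  Singletons are unplaced.

    With tens of thousands of marker pairs, the two-point LOD's sampling
    tail produces occasional spurious edges between chromosomes, and tight
    local linkage replicates any such fluke across a marker's neighbours.
    Two safeguards (the algorithmic analogue of choosing stable nodes in a
    grouping tree) therefore prune the edge set before taking components:
    edges must lie below ``rf_max`` (chromosome connectivity only ever needs
    short edges, while a false edge below rf 0.30 is a many-sigma event at
    these sample sizes), and must have at least ``triangle_support`` common
    neighbours.  Returns (groups, unplaced): groups is a list of marker-id
    arrays sorted by decreasing size.
    """
    marker_ids = np.asarray(marker_ids, dtype=object)
    dense = np.asarray(lod_matrix >= lod_min)
    np.fill_diagonal(dense, False)
    if rf_matrix is not None and rf_max is not None:
        dense = dense & (np.asarray(rf_matrix) <= rf_max)
    if triangle_support > 0 and len(marker_ids) > 2:
        common = (dense.astype(np.int32) @ dense.astype(np.int32))
        dense = dense & (common >= triangle_support)
    adj = csr_matrix(dense)
    n_comp, labels = connected_components(adj, directed=False)
    groups, unplaced = [], []
    for c in range(n_comp):
        ids = marker_ids[labels == c]
        if len(ids) == 1:
            unplaced.append(str(ids[0]))
        else:
            groups.append(np.sort(ids))
    groups.sort(key=lambda g: (-len(g), str(g[0])))
    return groups, unplaced


# -- map containers --------------------------------------------------------


@dataclass
class LinkageGroup:
    group_id: str
    marker_ids: np.ndarray
    positions: np.ndarray  # cM, non-decreasing, starting at 0
    flags: np.ndarray | None = None

    def __post_init__(self):
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.flags is None:
            self.flags = np.array([""] * len(self.marker_ids), dtype=object)

    @property
    def length(self) -> float:
        return float(self.positions.max() - self.positions.min()) if len(self.positions) else 0.0

    def unique_positions(self) -> int:
        return len(np.unique(np.round(self.positions, 6)))


@dataclass
class LinkageMap:
    groups: list
    algorithm: str = "regression"

    def group(self, group_id) -> LinkageGroup:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(group_id)

    @property
    def n_markers(self) -> int:
        return sum(len(g.marker_ids) for g in self.groups)

    def positions_by_marker(self) -> pd.Series:
        idx, vals = [], []
        for g in self.groups:
            idx.extend(g.marker_ids.tolist())
            vals.extend(g.positions.tolist())
        return pd.Series(vals, index=idx, name="position_cM")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for mk, pos, fl in zip(g.marker_ids, g.positions, g.flags):
                rows.append((g.group_id, mk, round(float(pos), 4), fl))
        return pd.DataFrame(rows, columns=["group", "marker", "position_cM", "flags"])

    def to_tsv(self, path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    def summary(self) -> pd.DataFrame:
        """Per-map summary: length, group length range, marker and unique
        position counts, mean/max marker interval over unique positions."""
        lengths = [g.length for g in self.groups]
        intervals = []
        for g in self.groups:
            up = np.unique(np.round(g.positions, 6))
            if len(up) > 1:
                intervals.extend(np.diff(up).tolist())
        return pd.DataFrame(
            {
                "length_cM": [float(np.sum(lengths))],
                "group_length_min_cM": [float(np.min(lengths)) if lengths else 0.0],
                "group_length_max_cM": [float(np.max(lengths)) if lengths else 0.0],
                "n_groups": [len(self.groups)],
                "markers": [self.n_markers],
                "unique_positions": [sum(g.unique_positions() for g in self.groups)],
                "mean_interval_cM": [float(np.mean(intervals)) if intervals else 0.0],
                "max_interval_cM": [float(np.max(intervals)) if intervals else 0.0],
            }
        )


# -- regression ordering ---------------------------------------------------


def _distance_weight(R, N, rf_weight_max: float = 0.40):
    """Pairwise Kosambi distance estimates and LOD^2 weights.

    Pairs at r >= ``rf_weight_max`` get weight 0: they carry no reliable
    order information, and under crossover interference the folded
    (phase-free) recombination fraction of very distant pairs can dip below
    0.5 spuriously, so long-range estimates must not constrain the fit.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(N > 0, R / np.maximum(N, 1), 0.5)
    lod = lod_from_counts(R, N)
    W = lod**2
    rc = np.clip(r, 0.0, _RF_CAP)
    D = kosambi(rc)
    W = np.where(r >= rf_weight_max, 0.0, W)
    np.fill_diagonal(W, 0.0)
    return D, W


def _fit_positions(order, D, W):
    """Weighted least-squares map positions for a fixed order.

    Interval lengths are fit by non-negative least squares against all
    pairwise distance estimates; returns (positions starting at 0,
    objective = sum w (d_fit - D)^2).
    """
    m = len(order)
    if m == 1:
        return np.zeros(1), 0.0
    rank = {mk: k for k, mk in enumerate(order)}
    rows_a, rows_b, ws, ds = [], [], [], []
    for a in range(m):
        for b in range(a + 1, m):
            ia, ib = order[a], order[b]
            w = W[ia, ib]
            if w <= 0:
                continue
            rows_a.append(a)
            rows_b.append(b)
            ws.append(w)
            ds.append(D[ia, ib])
    if not ws:
        return np.arange(m, dtype=float), 0.0
    ws = np.sqrt(np.asarray(ws))
    ds = np.asarray(ds)
    ra = np.asarray(rows_a)[:, None]
    rb = np.asarray(rows_b)[:, None]
    ks = np.arange(m - 1)[None, :]
    X = ((ra <= ks) & (ks < rb)) * ws[:, None]
    g, _ = nnls(X, ws * ds)
    pos = np.concatenate([[0.0], np.cumsum(g)])
    fit = X @ g
    obj = float(np.sum((fit - ws * ds) ** 2))
    return pos, obj


def _ripple(order, D, W, window=3, max_passes=5):
    """Local exhaustive permutations of consecutive windows, first-improvement,
    scored with full weighted least-squares refits."""
    from itertools import permutations

    order = list(order)
    best_pos, best_obj = _fit_positions(order, D, W)
    for _ in range(max_passes):
        improved = False
        for s in range(0, len(order) - window + 1):
            seg = order[s : s + window]
            for perm in permutations(seg):
                if list(perm) == seg:
                    continue
                cand = order[:s] + list(perm) + order[s + window :]
                pos, obj = _fit_positions(cand, D, W)
                if obj < best_obj - 1e-12:
                    order, best_pos, best_obj = cand, pos, obj
                    improved = True
                    break
        if not improved:
            break
    return order, best_pos, best_obj


def _chain_positions(order, D):
    """Fast surrogate positions: cumulative adjacent distance estimates."""
    pos = np.zeros(len(order))
    for k in range(1, len(order)):
        pos[k] = pos[k - 1] + D[order[k - 1], order[k]]
    return pos


class _ChainEvaluator:
    """Surrogate objective for candidate orders over a fixed marker subset.

    The local distance/weight matrices are built once; each candidate order
    is scored by assigning chain positions to markers and evaluating the
    weighted lack of fit against all pairwise estimates on the fixed
    matrices, with no per-candidate submatrix indexing.
    """

    def __init__(self, universe, D, W):
        self.loc = {g: k for k, g in enumerate(universe)}
        sub = np.ix_(universe, universe)
        self.Dm = D[sub]
        self.Wm = W[sub]
        self._p = np.empty(len(universe))

    def __call__(self, order) -> float:
        loc, Dm, p = self.loc, self.Dm, self._p
        prev = order[0]
        x = 0.0
        p[loc[prev]] = 0.0
        for g in order[1:]:
            x += Dm[loc[prev], loc[g]]
            p[loc[g]] = x
            prev = g
        diff = np.abs(p[:, None] - p[None, :]) - Dm
        return 0.5 * float(np.sum(self.Wm * diff * diff))


def _two_opt_chain(order, D, W, max_rounds=10, evaluator=None):
    """Segment-reversal (2-opt) refinement on the chain-position surrogate;
    escapes 'folded chromosome' local optima that window ripples cannot."""
    order = list(order)
    ev = evaluator if evaluator is not None else _ChainEvaluator(order, D, W)
    best_obj = ev(order)
    for _ in range(max_rounds):
        improved = False
        m = len(order)
        for i in range(m - 1):
            for j in range(i + 1, m):
                cand = order[:i] + order[i : j + 1][::-1] + order[j + 1 :]
                obj = ev(cand)
                if obj < best_obj - 1e-12:
                    order, best_obj = cand, obj
                    improved = True
        if not improved:
            break
    return order


def _ripple_chain(order, D, W, window=3, max_passes=5, evaluator=None):
    """Ripple pass for large groups, scored on the chain-position surrogate."""
    from itertools import permutations

    order = list(order)
    ev = evaluator if evaluator is not None else _ChainEvaluator(order, D, W)
    best_obj = ev(order)
    for _ in range(max_passes):
        improved = False
        for s in range(0, len(order) - window + 1):
            seg = order[s : s + window]
            for perm in permutations(seg):
                if list(perm) == seg:
                    continue
                cand = order[:s] + list(perm) + order[s + window :]
                obj = ev(cand)
                if obj < best_obj - 1e-12:
                    order, best_obj = cand, obj
                    improved = True
                    break
        if not improved:
            break
    return order


def _canonical(order, positions, marker_ids):
    """Deterministic orientation: smaller terminal marker id first."""
    if str(marker_ids[order[-1]]) < str(marker_ids[order[0]]):
        order = order[::-1]
        positions = positions.max() - positions[::-1]
    return order, positions


def order_regression(marker_ids, R, N):
    """Stam-style incremental regression ordering with Kosambi distances.

    Seeds with the highest-LOD pair, inserts markers by decreasing total
    LOD at the slot minimising the LOD^2-weighted least-squares lack of fit,
    ripples a window of 3 after each insertion (cheap slot scoring) and
    again with full refits at the end.  Returns (ordered ids, positions,
    objective); markers with no finite linkage to any placed marker are
    returned in the third slot of the log as unplaced.
    """
    marker_ids = np.asarray(marker_ids, dtype=object)
    m = len(marker_ids)
    if m == 1:
        return marker_ids, np.zeros(1), 0.0, []
    D, W = _distance_weight(R, N)
    lod = np.sqrt(W)
    sum_lod = lod.sum(axis=1)

    # highest-LOD seed pair, ties by marker ids
    iu = np.triu_indices(m, k=1)
    best = None
    for i, j in zip(*iu):
        key = (-lod[i, j], str(marker_ids[i]), str(marker_ids[j]))
        if best is None or key < best[0]:
            best = (key, i, j)
    i0, j0 = best[1], best[2]
    if lod[i0, j0] <= 0:
        # no informative linkage at all: arbitrary deterministic order
        order = sorted(range(m), key=lambda i: str(marker_ids[i]))
        return marker_ids[order], np.arange(m, dtype=float), 0.0, []

    small = m <= 12
    placed = [i0, j0]
    queue = [k for k in range(m) if k not in (i0, j0)]
    queue.sort(key=lambda k: (-sum_lod[k], str(marker_ids[k])))
    positions, _ = _fit_positions(placed, D, W)
    unplaced = []
    # markers linked only to not-yet-placed markers are deferred, not dropped
    while queue:
        progressed = False
        deferred = []
        for t in queue:
            if not np.any(W[t, placed] > 0):
                deferred.append(t)
                continue
            slot = _best_slot(t, placed, positions, D, W)
            placed = placed[:slot] + [t] + placed[slot:]
            progressed = True
            if small:
                placed, positions, _ = _ripple(placed, D, W, max_passes=2)
            else:
                placed = _ripple_chain(placed, D, W, max_passes=1)
                positions = _chain_positions(placed, D)
        queue = deferred
        if not progressed:
            unplaced = queue
            break
    if small:
        order, positions, obj = _ripple(placed, D, W)
    else:
        order = _two_opt_chain(placed, D, W)
        order = _ripple_chain(order, D, W, max_passes=3)
        positions, obj = _fit_positions(order, D, W)
        # independent restart from the minimum-recombination path: guards
        # against insertion-order local optima on long groups
        sub_ids = [str(marker_ids[k]) for k in order]
        alt_ids, _, _ = order_ml(sub_ids, R[np.ix_(order, order)], N[np.ix_(order, order)])
        back = {mk: k for mk, k in zip(sub_ids, order)}
        alt = [back[str(mk)] for mk in alt_ids]
        alt = _two_opt_chain(alt, D, W)
        alt = _ripple_chain(alt, D, W, max_passes=3)
        alt_pos, alt_obj = _fit_positions(alt, D, W)
        if alt_obj < obj - 1e-12:
            order, positions, obj = alt, alt_pos, alt_obj
    order, positions = _canonical(order, positions, marker_ids)
    return marker_ids[order], positions, obj, [str(marker_ids[u]) for u in unplaced]


def _best_slot(t, placed, positions, D, W):
    """Insertion slot for marker t with placed positions held fixed."""
    w = W[t, placed]
    d = D[t, placed]
    mask = w > 0
    best_slot, best_score = 0, np.inf
    bounds = np.concatenate([[-np.inf], positions, [np.inf]])
    for s in range(len(placed) + 1):
        lo, hi = bounds[s], bounds[s + 1]
        sign = np.where(np.arange(len(placed)) < s, 1.0, -1.0)
        target = positions + sign * d
        ww = w[mask]
        x = np.sum(ww * target[mask]) / np.sum(ww)
        x = min(max(x, lo), hi)
        score = float(np.sum(ww * (np.abs(x - positions[mask]) - d[mask]) ** 2))
        if score < best_score - 1e-12:
            best_score, best_slot = score, s
    return best_slot


# -- maximum-likelihood style ordering ------------------------------------


def _adjacent_cost(order, cost):
    tot = 0.0
    for a, b in zip(order, order[1:]):
        c = cost[a, b]
        tot += c if np.isfinite(c) else 1e9
    return tot


def order_ml(marker_ids, R, N):
    """Minimum-recombination ordering: greedy nearest-neighbour paths from
    every start, then 2-opt refinement on the sum of adjacent recombinant
    counts.  Deterministic; returns (ordered ids, positions, total count)."""
    marker_ids = np.asarray(marker_ids, dtype=object)
    m = len(marker_ids)
    if m == 1:
        return marker_ids, np.zeros(1), 0.0
    with np.errstate(invalid="ignore"):
        cost = np.where(N > 0, R, np.inf).astype(float)
    np.fill_diagonal(cost, np.inf)

    best_order, best_cost = None, np.inf
    for start in range(m):
        seen = [start]
        used = np.zeros(m, dtype=bool)
        used[start] = True
        while len(seen) < m:
            c = cost[seen[-1]].copy()
            c[used] = np.inf
            nxt = int(np.argmin(c))  # argmin is deterministic (first minimum)
            seen.append(nxt)
            used[nxt] = True
        tc = _adjacent_cost(seen, cost)
        if tc < best_cost - 1e-12:
            best_order, best_cost = seen, tc

    # 2-opt on the path: reversing order[i..j] swaps only two boundary edges
    def edge(a, b):
        if a is None or b is None:
            return 0.0
        c = cost[order[a], order[b]]
        return c if np.isfinite(c) else 1e9

    order = best_order
    improved = True
    rounds = 0
    while improved and rounds < 60:
        improved = False
        rounds += 1
        for i in range(len(order) - 1):
            for j in range(i + 1, len(order)):
                left = i - 1 if i > 0 else None
                right = j + 1 if j + 1 < len(order) else None
                delta = (
                    edge(left, j) + edge(i, right) - edge(left, i) - edge(j, right)
                )
                if delta < -1e-12:
                    order = order[:i] + order[i : j + 1][::-1] + order[j + 1 :]
                    best_cost += delta
                    improved = True

    positions = [0.0]
    for a, b in zip(order, order[1:]):
        n = N[a, b]
        r = min(R[a, b] / n if n > 0 else _RF_CAP, _RF_CAP)
        positions.append(positions[-1] + kosambi(r))
    positions = np.asarray(positions)
    order, positions = _canonical(order, positions, marker_ids)
    return marker_ids[order], positions, float(best_cost)


# -- diagnostics -----------------------------------------------------------


def phase_align(calls_ordered: np.ndarray) -> np.ndarray:
    """Resolve arbitrary per-row scoring phase along a map order.

    Each row is flipped, greedily from the top, whenever it mismatches the
    previous aligned row in more than half of the jointly scored offspring;
    on tightly linked rows this recovers a consistent haplotype coding.
    """
    out = calls_ordered.copy()
    for i in range(1, out.shape[0]):
        a, b = out[i - 1], out[i]
        ok = (a >= 0) & (b >= 0)
        if not ok.any():
            continue
        if (a[ok] != b[ok]).mean() > 0.5:
            out[i] = np.where(b >= 0, b ^ 1, b)
    return out


def detect_double_crossovers(calls_ordered: np.ndarray) -> np.ndarray:
    """Per-marker double-crossover participation counts.

    ``calls_ordered``: markers x offspring in map order.  For each
    offspring, a call differing from both of its nearest non-missing
    flanking calls (which agree) counts one double crossover against that
    marker.
    """
    m, n = calls_ordered.shape
    counts = np.zeros(m, dtype=int)
    for j in range(n):
        col = calls_ordered[:, j]
        idx = np.flatnonzero(col >= 0)
        if len(idx) < 3:
            continue
        vals = col[idx]
        mid = vals[1:-1]
        flip = (mid != vals[:-2]) & (mid != vals[2:])
        counts[idx[1:-1][flip]] += 1
    return counts


def gof_contributions(order_idx, positions, D, W, R, N):
    """Per-marker goodness-of-fit contribution: the LOD^2-weighted mean of
    squared distance residuals standardized by the delta-method sampling
    variance of each pairwise Kosambi estimate.  Values near or below ~0.5
    indicate a marker whose pairwise distances are internally consistent
    with the fitted map; error-carrying markers rise above 1."""
    m = len(order_idx)
    pos = np.asarray(positions)
    c = np.zeros(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(N > 0, R / np.maximum(N, 1), 0.5)
    for a in range(m):
        num = den = 0.0
        for b in range(m):
            if a == b:
                continue
            ia, ib = order_idx[a], order_idx[b]
            w = W[ia, ib]
            if w <= 0:
                continue
            n = N[ia, ib]
            rr = min(max(r[ia, ib], 0.25 / max(n, 1)), _RF_CAP)
            var_d = (100.0 / (1 - 4 * rr * rr)) ** 2 * rr * (1 - rr) / n
            resid = abs(pos[a] - pos[b]) - D[ia, ib]
            num += w * resid * resid / var_d
            den += w
        c[a] = num / den if den > 0 else 0.0
    return c


@dataclass
class RemovalCriteria:
    """Thresholds of the iterative marker-removal loop."""

    chisq_contrib_max: float = 1.0  # 2.0 in comprehensive rounds
    max_double_crossovers: int = 1
    distortion_alpha: float = 0.001
    distortion_delta: float = 0.10  # allowed departure from the local median
    distortion_window_cM: float = 5.0
    collinearity_shift_max_cM: float = 1.0
    max_batch_fraction: float = 0.05
    max_iterations: int = 30

    def __post_init__(self):
        for f in ("chisq_contrib_max", "max_double_crossovers",
                  "collinearity_shift_max_cM", "max_batch_fraction"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be strictly positive")


def _distortion_outliers(mat, order_ids, positions, criteria):
    from ptxmap.qc import segregation_table

    sub = mat.subset_markers(order_ids)
    seg = segregation_table(sub)
    dist = seg["distortion"].to_numpy()
    pvals = seg["p"].to_numpy()
    out = np.zeros(len(order_ids), dtype=bool)
    for i in range(len(order_ids)):
        if pvals[i] >= criteria.distortion_alpha:
            continue
        near = np.abs(positions - positions[i]) <= criteria.distortion_window_cM
        near[i] = False
        if not near.any():
            out[i] = True
            continue
        med = float(np.median(dist[near]))
        out[i] = abs(dist[i] - med) > criteria.distortion_delta
    return out


def iterative_clean(mat, marker_ids, criteria: RemovalCriteria | None = None,
                    intercross_ids=()):
    """Iteratively order, evaluate, and prune one linkage group.

    Repeats order -> (goodness-of-fit, double crossovers, distortion
    outliers) -> remove worst violators (at most ``max_batch_fraction`` of
    the group per round, preferring to retain intercross markers) until all
    criteria are met; then enforces collinearity between the regression and
    minimum-recombination orders, removing the least supported shifting
    marker while any shared marker moves more than the 1 cM threshold.

    Returns (ordered ids, positions, removal log DataFrame).  Raises
    RuntimeError if the group shrinks below 2 markers.
    """
    from ptxmap.binning import pairwise_counts

    if criteria is None:
        criteria = RemovalCriteria()
    ids = list(marker_ids)
    intercross_ids = set(intercross_ids)
    log = []

    def compute(ids_now):
        sub = mat.subset_markers(ids_now)
        R, N = pairwise_counts(sub)
        order, pos, obj, unplaced = order_regression(sub.marker_ids, R, N)
        return sub, R, N, order, pos, unplaced

    for it in range(criteria.max_iterations):
        if len(ids) < 2:
            raise RuntimeError("group shrank below 2 markers")
        sub, R, N, order, pos, unplaced = compute(ids)
        for u in unplaced:
            log.append((it, u, "unlinked"))
            ids.remove(u)
        if unplaced:
            continue
        idx_of = {mk: k for k, mk in enumerate(sub.marker_ids)}
        order_idx = [idx_of[mk] for mk in order]
        D, W = _distance_weight(R, N)
        gof = gof_contributions(order_idx, pos, D, W, R, N)
        dxo = detect_double_crossovers(phase_align(sub.calls[order_idx]))
        dis = _distortion_outliers(sub, order, pos, criteria)

        sev = np.maximum(gof / criteria.chisq_contrib_max,
                         dxo / (criteria.max_double_crossovers + 1e-9))
        sev = np.maximum(sev, np.where(dis, 1.0 + 1e-6, 0.0))
        violating = sev > 1.0
        if not violating.any():
            break
        batch = max(1, int(np.floor(len(ids) * criteria.max_batch_fraction)))
        cand = np.flatnonzero(violating)
        # retain intercross markers where possible: remove testcross first
        cand = sorted(
            cand,
            key=lambda k: (str(order[k]) in intercross_ids, -sev[k], str(order[k])),
        )
        for k in cand[:batch]:
            mk = str(order[k])
            reason = []
            if gof[k] > criteria.chisq_contrib_max:
                reason.append(f"gof={gof[k]:.2f}")
            if dxo[k] > criteria.max_double_crossovers:
                reason.append(f"dxo={dxo[k]}")
            if dis[k]:
                reason.append("distortion")
            log.append((it, mk, "+".join(reason)))
            ids.remove(mk)
    # two-algorithm order verification
    for it in range(criteria.max_iterations):
        if len(ids) < 2:
            raise RuntimeError("group shrank below 2 markers")
        sub, R, N, order, pos, unplaced = compute(ids)
        idx_of = {mk: k for k, mk in enumerate(sub.marker_ids)}
        ml_order, ml_pos, _ = order_ml(sub.marker_ids, R, N)
        shifts = _order_shifts(order, pos, ml_order, ml_pos)
        if shifts.max() <= criteria.collinearity_shift_max_cM:
            break
        order_idx = [idx_of[mk] for mk in order]
        D, W = _distance_weight(R, N)
        gof = gof_contributions(order_idx, pos, D, W, R, N)
        moving = np.flatnonzero(shifts > criteria.collinearity_shift_max_cM)
        worst = max(moving, key=lambda k: (gof[k], str(order[k])))
        log.append((f"algcheck{it}", str(order[worst]),
                    f"shift={shifts[worst]:.2f}cM"))
        ids.remove(str(order[worst]))
    sub, R, N, order, pos, _ = compute(ids)
    log_df = pd.DataFrame(log, columns=["iteration", "marker", "reason"])
    return order, pos, log_df


def _order_shifts(order_a, pos_a, order_b, pos_b):
    """Per-marker |cM shift| of map B's marker order measured on map A's scale.

    Each marker's position implied by its rank in order B (read off map A's
    sorted positions) is compared with its actual map-A position, after
    orientation alignment.  Identical orders give zero shift regardless of
    the two estimators' length scales, so only genuine order discrepancies
    register.
    """
    ids_a = [str(m) for m in order_a]
    ids_b = [str(m) for m in order_b]
    pos_a = np.asarray(pos_a, dtype=float)
    rank_b = {mk: k for k, mk in enumerate(ids_b)}
    ranks = np.array([rank_b[mk] for mk in ids_a])
    if stats.spearmanr(np.arange(len(ids_a)), ranks).statistic < 0:
        ranks = len(ids_b) - 1 - ranks
    implied = np.sort(pos_a)[ranks]
    return np.abs(pos_a - implied)


def spearman_order(pos_a: pd.Series, pos_b: pd.Series):
    """Orientation-normalised Spearman correlation of shared marker orders.

    Returns (rho, p, n_shared); rho/p are NaN when fewer than 3 markers are
    shared.  The sign convention makes the best-aligned orientation
    positive, so a cleanly reversed group still scores +1.
    """
    shared = pos_a.index.intersection(pos_b.index)
    n = len(shared)
    if n < 3:
        return float("nan"), float("nan"), n
    res = stats.spearmanr(pos_a.loc[shared].to_numpy(), pos_b.loc[shared].to_numpy())
    rho = float(res.statistic)
    p = float(res.pvalue)
    return abs(rho), p, n
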