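"""Repulsion-threshold marker binning.

Thousands of tightly linked markers are collapsed into bins before ordering:
a bin is a set of markers in which every pair shows at most a fixed number of
recombination events (the repulsion threshold), and a single representative
("bin marker") is mapped in its place.  After map construction the binned
markers are reintegrated around their representative.

Because dominant marker phase is arbitrary before mapping, all recombinant
counting here is phase-free: the count for a pair is min(mismatches,
matches), whichever orientation implies fewer recombinations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _linkage, fcluster

from ptxmap.io import DHMatrix, MISSING
from ptxmap.linkage import kosambi


def count_recombinants(m1: np.ndarray, m2: np.ndarray) -> tuple:
    """Phase-free recombinant count for two DH rows: (R, N).

    N counts offspring scored in both rows; R = min(mismatches, N -
    mismatches), the recombinant count under the better of the two possible
    phase orientations.  Raises if no offspring is informative.
    """
    ok = (m1 != MISSING) & (m2 != MISSING)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no informative offspring for this pair")
    mis = int((m1[ok] != m2[ok]).sum())
    return min(mis, n - mis), n


def pairwise_counts(mat: DHMatrix) -> tuple:
    """All-pairs phase-free (R, N) matrices via dense matrix products."""
    present = (mat.calls != MISSING).astype(np.float64)
    ones = np.where(mat.calls == 1, 1.0, 0.0)
    zeros = present - ones
    N = present @ present.T
    mis = ones @ zeros.T + zeros @ ones.T
    R = np.minimum(mis, N - mis)
    return R, N


def max_repulsion_for_target(
    n: int, rf_bound: float | None = None, cM_bound: float | None = None
) -> int:
    """Largest recombinant count whose implied rf (or Kosambi cM) stays
    strictly below the target bound at ``n`` informative offspring."""
    if n <= 0:
        raise ValueError("n must be positive")
    if (rf_bound is None) == (cM_bound is None):
        raise ValueError("give exactly one of rf_bound / cM_bound")
    if rf_bound is not None:
        if rf_bound <= 0:
            raise ValueError("target must be positive")
        k = int(np.ceil(rf_bound * n)) - 1
        if (k + 1) / n < rf_bound:  # strict inequality edge
            k += 1
        return max(k, 0)
    if cM_bound <= 0:
        raise ValueError("target must be positive")
    k = 0
    while (k + 1) / n < 0.5 and kosambi((k + 1) / n) < cM_bound:
        k += 1
    return k


@dataclass
class Bin:
    """A set of co-segregating, tightly linked markers and its representative."""

    bin_id: str
    representative: str
    members: list  # of (marker id, R vs representative, N vs representative)
    span_estimate_cM: float = 0.0

    @property
    def size(self) -> int:
        return len(self.members)


def build_bins(mat: DHMatrix, threshold: int, records: pd.DataFrame | None = None) -> list:
    """Partition markers into complete-linkage bins at the repulsion threshold.

    Every intra-bin pair has a phase-free recombinant count <= ``threshold``
    (guaranteed by cutting a complete-linkage dendrogram at that height).
    The representative is the member with the best quality class, then the
    highest call rate, then the lexicographically smallest id; ``records``
    (indexed by marker, columns quality_class / call_rate) supplies the
    metrics and may be omitted, in which case call rate is taken from the
    matrix and all classes rank equal.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    m = mat.n_markers
    if m == 0:
        return []
    if m == 1:
        labels = np.array([1])
        R = np.zeros((1, 1))
        N = np.ones((1, 1))
    else:
        R, N = pairwise_counts(mat)
        iu = np.triu_indices(m, k=1)
        condensed = R[iu]
        Z = _linkage(condensed, method="complete")
        labels = fcluster(Z, t=threshold, criterion="distance")

    call_rate = mat.call_rate()
    if records is not None:
        qmap = records["quality_class"].to_dict()
        cmap = records["call_rate"].to_dict()
    else:
        qmap, cmap = {}, {}

    def rank(i):
        mk = mat.marker_ids[i]
        qc = qmap.get(mk, 1)
        qc = 9 if qc == "excluded" else int(qc)
        return (qc, -float(cmap.get(mk, call_rate[i])), str(mk))

    bins = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        rep_i = min(idx, key=rank)
        members = []
        for i in idx:
            members.append(
                (str(mat.marker_ids[i]), int(R[rep_i, i]), int(N[rep_i, i]))
            )
        if len(idx) > 1:
            sub = idx[:, None], idx[None, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                rf = R[sub] / np.maximum(N[sub], 1)
            span = kosambi(min(float(np.nanmax(rf)), 0.4999))
        else:
            span = 0.0
        rep = str(mat.marker_ids[rep_i])
        bins.append(Bin(bin_id=f"bin_{rep}", representative=rep, members=members,
                        span_estimate_cM=float(span)))
    bins.sort(key=lambda b: b.representative)
    return bins


def bin_table(bins) -> pd.DataFrame:
    rows = []
    for b in bins:
        for mk, r, n in b.members:
            rf = r / n if n else np.nan
            off = kosambi(min(rf, 0.4999)) if n else np.nan
            rows.append((b.bin_id, b.representative, mk, r, n, off))
    return pd.DataFrame(
        rows, columns=["bin_id", "representative", "member", "R", "N", "offset_cM"]
    )


def reintegrate_bins(bin_map, bins, mat: DHMatrix):
    """Place binned markers around their fixed representatives.

    Each member sits at representative_cM +/- Kosambi(R/N versus the
    representative); the side is chosen toward the neighbouring
    representative with the smaller recombinant fraction.  Members with zero
    recombinants co-locate with the representative.  Returns a comprehensive
    LinkageMap with representatives at unchanged positions and markers
    sorted by cM within each group.
    """
    from ptxmap.linkage import LinkageGroup, LinkageMap

    by_rep = {b.representative: b for b in bins}
    idx = mat.marker_index()
    groups = []
    for g in bin_map.groups:
        reps = list(g.marker_ids)
        pos = np.asarray(g.positions, dtype=float)
        out_ids, out_pos, out_flags = [], [], []
        for k, rep in enumerate(reps):
            rep_cm = float(pos[k])
            out_ids.append(rep)
            out_pos.append(rep_cm)
            out_flags.append("bin_marker")
            b = by_rep.get(rep)
            if b is None:
                continue
            left = reps[k - 1] if k > 0 else None
            right = reps[k + 1] if k + 1 < len(reps) else None
            for mk, r, n in b.members:
                if mk == rep:
                    continue
                if n == 0:
                    warnings.warn(f"{mk}: undefined rf vs representative, co-locating")
                    offset = 0.0
                else:
                    offset = kosambi(min(r / n, 0.4999))
                side = 1.0
                if offset > 0:
                    rf_l = _rf_to(mat, idx, mk, left)
                    rf_r = _rf_to(mat, idx, mk, right)
                    if rf_l < rf_r:
                        side = -1.0
                out_ids.append(mk)
                out_pos.append(rep_cm + side * offset)
                out_flags.append(f"binned:{rep}")
        order = np.argsort(np.asarray(out_pos), kind="stable")
        out_pos = np.asarray(out_pos)[order]
        out_pos = out_pos - out_pos.min()
        groups.append(
            LinkageGroup(
                group_id=g.group_id,
                marker_ids=np.asarray(out_ids, dtype=object)[order],
                positions=out_pos,
                flags=np.asarray(out_flags, dtype=object)[order],
            )
        )
    return LinkageMap(groups=groups, algorithm=bin_map.algorithm + "+reintegrated")


def _rf_to(mat, idx, mk, other):
    if other is None:
        return np.inf
    try:
        r, n = count_recombinants(mat.calls[idx[mk]], mat.calls[idx[other]])
    except (ValueError, KeyError):
        return np.inf
    return r / n if n else np.inf
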