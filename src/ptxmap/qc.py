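"""Marker quality classification, DH recoding, and segregation statistics.

Dominant and SNP markers arrive with three supplier metrics — reproducibility,
call rate, and PIC (polymorphism information content, here the gene-diversity
form 1 - sum(p_i^2), which equals 0.5 at perfect 1:1 segregation).  Markers
are sorted into three quality classes used at different mapping stages, and
testcross markers are recoded into a double-haploid (A/B) configuration so
that binning and two-point analysis operate on phase classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ptxmap.io import DHMatrix, MarkerRecord, A, B, MISSING

# class thresholds: (min reproducibility, strict?, min call rate, min PIC dominant, min PIC snp)
_CLASS_RULES = (
    (1, 1.0, True, 0.95, 0.35, 0.20),
    (2, 0.9, False, 0.90, 0.25, 0.15),
    (3, 0.9, False, 0.80, 0.15, 0.10),
)


def compute_pic(class_frequencies) -> float:
    """Gene-diversity PIC: 1 - sum(p_i^2) over phenotype class frequencies."""
    p = np.asarray(class_frequencies, dtype=float)
    if (p < 0).any():
        raise ValueError("negative class frequency")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"class frequencies sum to {p.sum()}, not 1")
    return float(1.0 - np.sum(p**2))


def classify_marker(record: MarkerRecord, is_snp: bool = False):
    """Quality class 1/2/3 or "excluded"; classes checked in order, first match wins."""
    for cls, min_repro, exact, min_call, min_pic_dom, min_pic_snp in _CLASS_RULES:
        if exact:
            ok_repro = record.reproducibility >= min_repro
        else:
            ok_repro = record.reproducibility > min_repro
        min_pic = min_pic_snp if is_snp else min_pic_dom
        if ok_repro and record.call_rate > min_call and record.pic > min_pic:
            return cls
    return "excluded"


def segregation_chisq(counts) -> tuple:
    """Chi-square goodness of fit against 1:1 for (n_A, n_B); returns (chi2, p)."""
    n_a, n_b = counts
    tot = n_a + n_b
    if tot <= 0:
        raise ValueError("marker has no scored offspring")
    chi2 = (n_a - n_b) ** 2 / tot
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def recode_to_dh(raw: pd.DataFrame, parents: pd.DataFrame) -> DHMatrix:
    """Recode raw testcross genotypes into double-haploid A/B rows.

    ``raw``: markers x offspring genotype strings ("Aa", "aa", ...; "--" =
    missing).  ``parents``: per-marker columns P1, P2 with the parental
    genotypes.  For a marker heterozygous in exactly one parent, offspring
    that carry the informative parent's segregating allele are coded A, the
    rest B.  Offspring genotypes impossible under the parents are flagged
    missing.  Fully informative 1:1:1:1 markers (both parents heterozygous
    for four distinguishable alleles, e.g. AB x CD) are split into two
    loci, one tracking each parent's alleles.
    """
    marker_ids, rows = [], []
    for mk, geno in raw.iterrows():
        p1, p2 = parents.at[mk, "P1"], parents.at[mk, "P2"]
        al1, al2 = set(p1), set(p2)
        het1, het2 = len(al1) == 2, len(al2) == 2
        if het1 and het2 and not (al1 & al2):
            # AB x CD: one split locus per parent
            for tag, alleles in ((f"{mk}_P1", sorted(al1)), (f"{mk}_P2", sorted(al2))):
                a_allele, b_allele = alleles
                row = np.full(len(geno), MISSING, dtype=np.int8)
                for j, g in enumerate(geno):
                    got = set(g) - {"-"}
                    hit = got & {a_allele, b_allele}
                    if len(hit) == 1:
                        row[j] = A if hit.pop() == a_allele else B
                marker_ids.append(tag)
                rows.append(row)
            continue
        if het1 == het2:
            raise ValueError(f"marker {mk} is not testcross (parents {p1} x {p2})")
        hetp = p1 if het1 else p2
        homp = p2 if het1 else p1
        seg_allele = (set(hetp) - set(homp)) or set(hetp)
        seg_allele = sorted(seg_allele)[0]
        hom_allele = sorted(set(homp))[0]
        possible = {
            "".join(sorted(x + y)) for x in hetp for y in homp
        }
        row = np.full(len(geno), MISSING, dtype=np.int8)
        for j, g in enumerate(geno):
            if "-" in g:
                continue
            key = "".join(sorted(g))
            if key not in possible:
                continue  # impossible under parents -> missing
            row[j] = A if seg_allele in g and key != hom_allele * 2 else B
        marker_ids.append(str(mk))
        rows.append(row)
    return DHMatrix(
        np.array(marker_ids, dtype=object),
        raw.columns.to_numpy(object),
        np.vstack(rows) if rows else np.empty((0, raw.shape[1]), dtype=np.int8),
    )


def filter_missing(mat: DHMatrix, max_missing: float = 0.10):
    """Drop markers then individuals with > ``max_missing`` missing data.

    Sweep order: markers first, then individuals, then markers re-checked.
    Returns (filtered matrix, dropped marker ids, dropped offspring ids).
    """
    dropped_m, dropped_o = [], []
    miss_m = 1.0 - mat.call_rate()
    keep = miss_m <= max_missing
    dropped_m.extend(mat.marker_ids[~keep].tolist())
    mat = DHMatrix(mat.marker_ids[keep], mat.offspring_ids, mat.calls[keep])
    if mat.n_markers:
        miss_o = (mat.calls == MISSING).mean(axis=0)
        keep_o = miss_o <= max_missing
        dropped_o.extend(mat.offspring_ids[~keep_o].tolist())
        mat = mat.subset_offspring(keep_o)
        miss_m = 1.0 - mat.call_rate()
        keep = miss_m <= max_missing
        dropped_m.extend(mat.marker_ids[~keep].tolist())
        mat = DHMatrix(mat.marker_ids[keep], mat.offspring_ids, mat.calls[keep])
    return mat, dropped_m, dropped_o


def segregation_table(mat: DHMatrix) -> pd.DataFrame:
    """Per-marker A/B counts, signed distortion, and the 1:1 chi-square test."""
    nA = (mat.calls == A).sum(axis=1)
    nB = (mat.calls == B).sum(axis=1)
    tot = np.maximum(nA + nB, 1)
    chi2 = (nA - nB) ** 2 / tot
    p = stats.chi2.sf(chi2, df=1)
    return pd.DataFrame(
        {
            "marker": mat.marker_ids,
            "n_A": nA,
            "n_B": nB,
            "distortion": (nA - nB) / tot,
            "chi2": chi2,
            "p": p,
        }
    ).set_index("marker")


def class_report(records) -> pd.DataFrame:
    """Counts of markers per quality class x segregation type."""
    df = pd.DataFrame(
        [(r.seg_type, r.quality_class, r.is_snp) for r in records],
        columns=["seg_type", "quality_class", "is_snp"],
    )
    return (
        df.groupby(["seg_type", "quality_class", "is_snp"])
        .size()
        .rename("n_markers")
        .reset_index()
    )
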