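"""Forward simulation of a two-family outbred F1 pedigree with rearrangements.

The simulated design mirrors a pseudo-testcross mapping study: two F1 hybrid
families (default n = 115 and n = 245) share one pollen parent, and markers
heterozygous in a single parent segregate 1:1 in its offspring.  Meiosis is
modelled as a stationary gamma-renewal crossover process on the cM scale,
with crossover interference (shape > 1) as real plant meiosis shows; shape 1
recovers the memoryless no-interference (Poisson/Haldane) process.
The reference genome differs from the mapped genome by a configurable set of
chromosomal rearrangements (in-place inversions and transposed inversions),
and full ground truth is retained for scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ptxmap.io import DHMatrix, MarkerRecord, A, B, MISSING, BLAST6_COLUMNS
from ptxmap import qc as _qc

MB = 1_000_000

SEG_MIX_DEFAULT = {
    "testcross_P1": 0.45,
    "testcross_P2": 0.38,
    "fully_informative_1111": 0.05,
    "intercross_121": 0.07,
    "dominant_31": 0.05,
}


@dataclass(frozen=True)
class RearrangementSpec:
    """One rearrangement distinguishing the reference from the mapped genome.

    Coordinates are half-open, 1-based bp on the mapped genome.  An
    ``inversion`` reflects the interval in place; an
    ``inversion_translocation`` excises the interval, inverts it, and
    reinserts it at ``insertion_point_bp`` elsewhere on the same chromosome
    ("transposed" in map-vs-genome dot plots).
    """

    chromosome: int  # 1-based
    kind: str  # "inversion" | "inversion_translocation"
    source_interval_bp: tuple  # (start, end), half-open
    insertion_point_bp: int | None = None

    def __post_init__(self):
        s, e = self.source_interval_bp
        if e <= s:
            raise ValueError(f"empty interval {self.source_interval_bp}")
        if self.kind not in ("inversion", "inversion_translocation"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "inversion" and self.insertion_point_bp is not None:
            raise ValueError("in-place inversion must not carry an insertion point")
        if self.kind == "inversion_translocation":
            if self.insertion_point_bp is None:
                raise ValueError("inversion_translocation requires insertion_point_bp")
            if s <= self.insertion_point_bp < e:
                raise ValueError("insertion point inside the source interval")

    @property
    def length(self) -> int:
        s, e = self.source_interval_bp
        return e - s


def _validate_specs(specs, chrom_length: int) -> None:
    ivs = sorted(s.source_interval_bp for s in specs)
    for s, e in ivs:
        if s < 0 or e > chrom_length:
            raise ValueError(f"interval ({s},{e}) outside chromosome (len {chrom_length})")
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping rearrangement intervals ({s1},{e1}) / ({s2},{e2})")
    for sp in specs:
        if sp.insertion_point_bp is None:
            continue
        p = sp.insertion_point_bp
        if p < 0 or p > chrom_length:
            raise ValueError("insertion point outside chromosome")
        for other in specs:
            s, e = other.source_interval_bp
            if s <= p < e and not (other is sp):
                raise ValueError("insertion point falls inside another rearranged interval")


def apply_rearrangements(bp: np.ndarray, specs, chrom_length: int) -> np.ndarray:
    """Map mapped-genome bp positions (one chromosome) to reference bp.

    In-place inversions reflect positions about the interval (s + e - x);
    transposed segments are excised, inverted, and reinserted at their
    insertion point, with intervening coordinates shifted so chromosome
    length is conserved.
    """
    bp = np.asarray(bp, dtype=float)
    specs = list(specs)
    _validate_specs(specs, chrom_length)
    out = bp.copy()

    # in-place inversions: pure reflection
    for sp in specs:
        if sp.kind != "inversion":
            continue
        s, e = sp.source_interval_bp
        inside = (bp >= s) & (bp < e)
        out[inside] = s + e - bp[inside]

    trans = [sp for sp in specs if sp.kind == "inversion_translocation"]
    if not trans:
        return out

    sources = np.array([sp.source_interval_bp for sp in trans], dtype=float)
    src_len = sources[:, 1] - sources[:, 0]
    ins = np.array([sp.insertion_point_bp for sp in trans], dtype=float)
    # deterministic insertion order at identical points: by source start
    order = np.lexsort((sources[:, 0], ins))

    def shifted(y):
        """Final coordinate of a kept-frame point y (outside all sources).

        Points exactly at an insertion point land after the inserted segment.
        """
        removed = src_len[sources[:, 1] <= y].sum()
        inserted = src_len[ins <= y].sum()
        return y - removed + inserted

    def segment_start(k):
        """Final coordinate where translocated segment k begins."""
        base = ins[k]
        removed = src_len[sources[:, 1] <= base].sum()
        inserted = 0.0
        for j in order:
            if j == k:
                break
            if ins[j] <= base:
                inserted += src_len[j]
        return base - removed + inserted

    final = np.empty_like(out)
    for i, x in enumerate(out):
        for k, sp in enumerate(trans):
            s, e = sp.source_interval_bp
            if s <= x < e:
                final[i] = segment_start(k) + (e - x)  # inverted within the segment
                break
        else:
            final[i] = shifted(x)
    return final


@dataclass
class SimScenario:
    """Configuration of the simulated study: genome, markers, noise, events."""

    n_chromosomes: int = 11
    chrom_lengths_bp: tuple = ()
    chrom_lengths_cM: tuple = ()
    n_markers: int = 6000
    seg_mix: dict = field(default_factory=lambda: dict(SEG_MIX_DEFAULT))
    snp_fraction: float = 0.25
    rearrangements: tuple = ()
    error_rate: float = 0.01
    missing_rate: float = 0.10
    missing_dispersion: float | None = 2.0  # Beta concentration; None = constant rate
    interference_shape: float = 2.5  # gamma-renewal crossover shape; 1.0 = Poisson
    distortion: dict = field(default_factory=dict)  # marker id -> directional miscall prob
    seed: int = 20170522

    _layout_cache: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not self.chrom_lengths_bp:
            raise ValueError("chrom_lengths_bp required")
        if len(self.chrom_lengths_bp) != self.n_chromosomes:
            raise ValueError("chrom_lengths_bp length mismatch")
        if len(self.chrom_lengths_cM) != self.n_chromosomes:
            raise ValueError("chrom_lengths_cM length mismatch")
        by_chrom = {}
        for sp in self.rearrangements:
            by_chrom.setdefault(sp.chromosome, []).append(sp)
        for c, specs in by_chrom.items():
            _validate_specs(specs, self.chrom_lengths_bp[c - 1])

    # -- marker layout ----------------------------------------------------
    def layout(self) -> pd.DataFrame:
        """Per-marker (chromosome, bp, cM, seg_type, is_snp, reference_bp).

        Deterministic given the scenario seed.  cM increases linearly with
        bp within a chromosome (uniform recombination), so cM order equals
        mapped bp order before rearrangement.
        """
        if self._layout_cache is not None:
            return self._layout_cache
        rng = np.random.default_rng(self.seed)
        total_cM = float(sum(self.chrom_lengths_cM))
        rows = []
        seg_names = list(self.seg_mix)
        seg_p = np.array([self.seg_mix[k] for k in seg_names], dtype=float)
        seg_p = seg_p / seg_p.sum()
        for c in range(1, self.n_chromosomes + 1):
            Lbp = self.chrom_lengths_bp[c - 1]
            LcM = self.chrom_lengths_cM[c - 1]
            n_c = max(4, int(round(self.n_markers * LcM / total_cM)))
            bp = np.sort(rng.uniform(1, Lbp, size=n_c))
            cM = bp / Lbp * LcM
            seg = rng.choice(seg_names, size=n_c, p=seg_p)
            snp = rng.random(n_c) < self.snp_fraction
            for i in range(n_c):
                rows.append(
                    (f"M{c:02d}_{i:04d}", c, float(bp[i]), float(cM[i]), seg[i], bool(snp[i]))
                )
        df = pd.DataFrame(rows, columns=["marker", "chrom", "bp", "cM", "seg_type", "is_snp"])
        ref = np.empty(len(df))
        for c in range(1, self.n_chromosomes + 1):
            mask = df["chrom"] == c
            specs = [sp for sp in self.rearrangements if sp.chromosome == c]
            ref[mask.to_numpy()] = apply_rearrangements(
                df.loc[mask, "bp"].to_numpy(), specs, self.chrom_lengths_bp[c - 1]
            )
        df["reference_bp"] = ref
        object.__setattr__(self, "_layout_cache", df)
        return df

    # -- JSON round trip --------------------------------------------------
    def to_json(self, path) -> None:
        d = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_lengths_bp": list(self.chrom_lengths_bp),
            "chrom_lengths_cM": list(self.chrom_lengths_cM),
            "n_markers": self.n_markers,
            "seg_mix": self.seg_mix,
            "snp_fraction": self.snp_fraction,
            "rearrangements": [
                {
                    "chromosome": sp.chromosome,
                    "kind": sp.kind,
                    "source_interval_bp": list(sp.source_interval_bp),
                    "insertion_point_bp": sp.insertion_point_bp,
                }
                for sp in self.rearrangements
            ],
            "error_rate": self.error_rate,
            "missing_rate": self.missing_rate,
            "missing_dispersion": self.missing_dispersion,
            "distortion": self.distortion,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimScenario":
        with open(path) as fh:
            d = json.load(fh)
        d["rearrangements"] = tuple(
            RearrangementSpec(
                chromosome=r["chromosome"],
                kind=r["kind"],
                source_interval_bp=tuple(r["source_interval_bp"]),
                insertion_point_bp=r["insertion_point_bp"],
            )
            for r in d["rearrangements"]
        )
        d["chrom_lengths_bp"] = tuple(d["chrom_lengths_bp"])
        d["chrom_lengths_cM"] = tuple(d["chrom_lengths_cM"])
        return cls(**d)


# chromosome sizes loosely follow the 11 eucalypt chromosomes (bp) and a
# ~1,100 cM genetic map; ratios give ~2 cM/Mb.
_CHROM_BP = tuple(int(x * MB) for x in (40, 64, 80, 42, 75, 54, 52, 74, 39, 39, 45))
_CHROM_CM = (100.0, 110.0, 120.0, 95.0, 115.0, 105.0, 100.0, 110.0, 90.0, 95.0, 100.0)


def default_rearrangements() -> tuple:
    """Nine events on seven chromosomes: five in-place inversions and four
    transposed inversions, with 5-13 Mb spans (each >5 cM at ~2 cM/Mb)."""
    return (
        RearrangementSpec(2, "inversion_translocation", (41 * MB, 46 * MB), 58 * MB),
        RearrangementSpec(4, "inversion", (30 * MB, 39 * MB)),
        RearrangementSpec(6, "inversion_translocation", (14 * MB, 19 * MB), 2 * MB),
        RearrangementSpec(6, "inversion_translocation", (24 * MB, 29 * MB), 8 * MB),
        RearrangementSpec(6, "inversion_translocation", (33 * MB, 40 * MB), 48 * MB),
        RearrangementSpec(8, "inversion", (33 * MB, 42 * MB)),
        RearrangementSpec(9, "inversion", (21 * MB, 34 * MB)),
        RearrangementSpec(10, "inversion", (500_000, 13 * MB)),
        RearrangementSpec(11, "inversion", (31 * MB, 44 * MB)),
    )


def default_scenario(**overrides) -> SimScenario:
    kw = dict(
        n_chromosomes=11,
        chrom_lengths_bp=_CHROM_BP,
        chrom_lengths_cM=_CHROM_CM,
        n_markers=6000,
        rearrangements=default_rearrangements(),
        error_rate=0.01,
        missing_rate=0.10,
        seed=20170522,
    )
    kw.update(overrides)
    return SimScenario(**kw)


# -- meiosis ---------------------------------------------------------------

PARENTS = ("P1", "P2")  # P1 = shared pollen parent, P2 = seed parent of a family


def simulate_meiosis(scenario: SimScenario, n_offspring: int, parent: str, rng=None) -> np.ndarray:
    """Gamete haplotypes for ``n_offspring`` meioses of one parent.

    Returns an (n_offspring, n_markers) int8 array of phase labels (0/1):
    which of the parent's two chromosome copies each gamete carries at each
    marker.  Crossovers follow a stationary gamma-renewal process on the cM
    scale with one event per 100 cM on average: ``interference_shape`` = 1
    gives the memoryless Poisson process (recombination fractions at the
    inverse-Haldane value of the cM separation), while larger shapes model
    crossover interference, suppressing double crossovers over short
    intervals as real plant meiosis does.  At small separations the
    expected recombination fraction is d/100 for every shape.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    if rng is None:
        rng = np.random.default_rng(scenario.seed + hash(parent) % 10_000)
    layout = scenario.layout()
    m = len(layout)
    nu = float(scenario.interference_shape)
    if nu <= 0:
        raise ValueError("interference_shape must be positive")
    burn = 400.0  # cM of burn-in so the renewal process is ~stationary at 0
    phases = np.empty((n_offspring, m), dtype=np.int8)
    for c in range(1, scenario.n_chromosomes + 1):
        mask = (layout["chrom"] == c).to_numpy()
        cM = layout.loc[layout["chrom"] == c, "cM"].to_numpy()
        L = scenario.chrom_lengths_cM[c - 1]
        start = rng.integers(0, 2, size=n_offspring, dtype=np.int8)
        block = np.empty((n_offspring, mask.sum()), dtype=np.int8)
        n_draw = max(8, int((L + burn) / 100.0 * 3) + 6)
        for i in range(n_offspring):
            gaps = rng.gamma(nu, 100.0 / nu, size=n_draw)
            xo = np.cumsum(gaps) - burn
            while xo[-1] < L:  # rare: extend until past chromosome end
                more = rng.gamma(nu, 100.0 / nu, size=n_draw)
                xo = np.concatenate([xo, xo[-1] + np.cumsum(more)])
            xo = xo[(xo >= 0.0) & (xo < L)]
            crosses = np.searchsorted(xo, cM)
            block[i] = (start[i] + crosses) % 2
        phases[:, mask] = block
    return phases


# -- genotyping ------------------------------------------------------------


@dataclass
class FamilySim:
    """Simulated observations and truth for one F1 family."""

    family_id: str
    n_offspring: int
    dh: dict  # parent label ("P1"/"P2") -> DHMatrix of testcross + split loci
    records: dict  # parent label -> list[MarkerRecord]
    intercross: pd.DataFrame  # 1:2:1 / 3:1 genotype codes (markers x offspring)
    truth: pd.DataFrame  # layout + reference_bp
    phases: dict  # parent label -> (n_offspring, n_markers) gamete phases
    marker_orientation: dict  # parent label -> {locus id: 0/1 flip applied}


def _per_marker_missing(scenario: SimScenario, n_markers: int, rng) -> np.ndarray:
    p = scenario.missing_rate
    if p <= 0:
        return np.zeros(n_markers)
    k = scenario.missing_dispersion
    if k is None:
        return np.full(n_markers, p)
    a, b = p * k, (1 - p) * k
    return rng.beta(a, b, size=n_markers)


def _emit_dh_rows(gam: np.ndarray, hap_assign: np.ndarray, flips: np.ndarray,
                  err: np.ndarray, miss: np.ndarray, dist: np.ndarray, rng) -> np.ndarray:
    """DH calls for testcross loci of one parent.

    gam: (n_off, m) gamete phases for these markers; hap_assign: which
    haplotype carries the scored allele; flips: per-marker arbitrary scoring
    phase; err/miss/dist: per-marker miscall, missing and directional-bias
    rates.
    """
    calls = (gam.T ^ hap_assign[:, None]) ^ flips[:, None]  # (m, n_off)
    calls = calls.astype(np.int8)
    m, n = calls.shape
    if dist.any():
        bias = (rng.random((m, n)) < dist[:, None]) & (calls == B)
        calls[bias] = A
    if err.any():
        flip = rng.random((m, n)) < err[:, None]
        calls[flip] ^= 1
    if miss.any():
        gone = rng.random((m, n)) < miss[:, None]
        calls[gone] = MISSING
    return calls


def _reproducibility_and_error(scenario: SimScenario, n_markers: int, rng):
    """Per-marker reproducibility scores and the miscall rates tied to them.

    Reproducibility is the supplier's repeatability metric — a property of
    the marker assay, not of the family — so it is drawn from the scenario
    seed and shared by all crosses.  Markers scoring 1.0 carry the fewest
    miscalls; per-marker error multipliers grow with (1 - reproducibility)
    and are normalised to mean 1, so the population per-call miscall rate
    equals ``scenario.error_rate`` exactly.
    """
    if n_markers == 0:
        return np.zeros(0), np.zeros(0)
    rng = np.random.default_rng(scenario.seed + 13)
    hi = rng.random(n_markers) < 0.6
    repro = np.where(hi, 1.0, 0.85 + 0.15 * rng.random(n_markers))
    if scenario.error_rate <= 0:
        return repro, np.zeros(n_markers)
    # miscalls concentrate in low-reproducibility markers: a marker scoring
    # 1.0 across replicate assays is nearly error-free, while the bulk of
    # the population error budget sits in the low tier
    mult = np.where(repro >= 1.0, 0.05,
                    np.where(repro > 0.93, 0.15, 1.5 + 15.0 * (0.93 - repro)))
    mult = mult / mult.mean()
    return repro, scenario.error_rate * mult


def simulate_genotyping(gametes: dict, scenario: SimScenario, rng=None):
    """Observe gametes as DArT-style marker calls.

    ``gametes`` maps parent label -> (n_offspring, n_markers) phase array
    (both parents of one family).  Returns (dh, records, intercross,
    orientation): per-parent DH matrices over testcross loci (with
    fully-informative 1:1:1:1 markers split into one locus per parent),
    per-parent marker records with emitted quality metrics, a genotype-code
    table for 1:2:1 and 3:1 intercross markers, and the per-locus arbitrary
    scoring-phase flips that were applied.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed + 991)
    layout = scenario.layout()
    m_all = len(layout)
    n_off = next(iter(gametes.values())).shape[0]
    offspring_ids = np.array([f"O{j:04d}" for j in range(n_off)], dtype=object)

    # parent haplotype assignment of the scored allele: a parent-level
    # property, deterministic given the scenario seed
    hap_rng = np.random.default_rng(scenario.seed + 7)
    hap = {p: hap_rng.integers(0, 2, size=m_all, dtype=np.int8) for p in PARENTS}

    miss = _per_marker_missing(scenario, m_all, rng)
    dist = np.zeros(m_all)
    if scenario.distortion:
        idx = {mk: i for i, mk in enumerate(layout["marker"])}
        for mk, d in scenario.distortion.items():
            dist[idx[mk]] = d

    seg = layout["seg_type"].to_numpy()
    dh, records, orientation = {}, {}, {}
    for p in PARENTS:
        own = np.flatnonzero(seg == f"testcross_{p}")
        shared = np.flatnonzero(seg == "fully_informative_1111")
        rows_idx = np.concatenate([own, shared])
        order = np.argsort(layout["marker"].to_numpy()[rows_idx])
        rows_idx = rows_idx[order]
        ids = np.array(
            [
                mk if seg[i] != "fully_informative_1111" else f"{mk}_{p}"
                for i, mk in zip(rows_idx, layout["marker"].to_numpy()[rows_idx])
            ],
            dtype=object,
        )
        flips = rng.integers(0, 2, size=len(rows_idx), dtype=np.int8)
        repro, err = _reproducibility_and_error(scenario, len(rows_idx), rng)
        calls = _emit_dh_rows(
            gametes[p][:, rows_idx],
            hap[p][rows_idx],
            flips,
            err,
            miss[rows_idx],
            dist[rows_idx],
            rng,
        )
        mat = DHMatrix(ids, offspring_ids, calls)
        dh[p] = mat
        orientation[p] = dict(zip(ids, flips.tolist()))
        records[p] = _make_records(mat, layout.iloc[rows_idx], repro)

    intercross = _emit_intercross(gametes, scenario, layout, hap, miss, rng, offspring_ids)
    return dh, records, intercross, orientation


def _make_records(mat: DHMatrix, sub_layout: pd.DataFrame, repro: np.ndarray) -> list:
    call_rate = mat.call_rate()
    recs = []
    for i, mk in enumerate(mat.marker_ids):
        row = mat.calls[i]
        nA = int((row == A).sum())
        nB = int((row == B).sum())
        tot = nA + nB
        if tot:
            pic = _qc.compute_pic((nA / tot, nB / tot))
        else:
            pic = 0.0
        is_snp = bool(sub_layout.iloc[i]["is_snp"])
        rec = MarkerRecord(
            id=str(mk),
            seg_type=str(sub_layout.iloc[i]["seg_type"]),
            reproducibility=float(repro[i]),
            call_rate=float(call_rate[i]),
            pic=float(pic),
            is_snp=is_snp,
        )
        rec.quality_class = _qc.classify_marker(rec, is_snp=is_snp)
        recs.append(rec)
    return recs


def _emit_intercross(gametes, scenario, layout, hap, miss, rng, offspring_ids) -> pd.DataFrame:
    """Genotype codes for biparentally segregating markers.

    1:2:1 markers: count of scored alleles (0/1/2).  3:1 dominant markers:
    band presence (0/1).  Missing coded -1.
    """
    seg = layout["seg_type"].to_numpy()
    idx = np.flatnonzero((seg == "intercross_121") | (seg == "dominant_31"))
    if idx.size == 0:
        return pd.DataFrame(index=pd.Index([], name="marker"), columns=offspring_ids)
    a1 = (gametes["P1"][:, idx].T ^ hap["P1"][idx][:, None]) ^ 1  # 1 = scored allele
    a2 = (gametes["P2"][:, idx].T ^ hap["P2"][idx][:, None]) ^ 1
    dose = (a1 + a2).astype(np.int8)
    out = np.where(seg[idx][:, None] == "dominant_31", (dose > 0).astype(np.int8), dose)
    if scenario.error_rate > 0:
        err = rng.random(out.shape) < scenario.error_rate
        jitter = rng.integers(0, 2, size=out.shape).astype(np.int8)
        hi = np.where(seg[idx][:, None] == "dominant_31", 1, 2)
        out = np.where(err, np.clip(out + np.where(jitter > 0, 1, -1), 0, hi), out)
    gone = rng.random(out.shape) < miss[idx][:, None]
    out = np.where(gone, -1, out).astype(np.int8)
    return pd.DataFrame(out, index=pd.Index(layout["marker"].to_numpy()[idx], name="marker"),
                        columns=offspring_ids)


def simulate_family(scenario: SimScenario, n_offspring: int, family_id: str, seed: int) -> FamilySim:
    """Simulate one F1 family end to end (meiosis in both parents + genotyping)."""
    rng = np.random.default_rng(seed)
    gametes = {
        p: simulate_meiosis(scenario, n_offspring, p, rng=rng) for p in PARENTS
    }
    dh, records, intercross, orientation = simulate_genotyping(gametes, scenario, rng=rng)
    # offspring ids made family-unique so combined matrices keep columns apart
    for p in PARENTS:
        dh[p].offspring_ids = np.array(
            [f"{family_id}_{o}" for o in dh[p].offspring_ids], dtype=object
        )
    intercross.columns = [f"{family_id}_{o}" for o in intercross.columns]
    return FamilySim(
        family_id=family_id,
        n_offspring=n_offspring,
        dh=dh,
        records=records,
        intercross=intercross,
        truth=scenario.layout(),
        phases=gametes,
        marker_orientation=orientation,
    )


# -- synthetic anchors -----------------------------------------------------


def make_synthetic_anchors(
    scenario: SimScenario,
    marker_ids,
    fraction: float = 0.5,
    noise_rate: float = 0.0,
    seed: int = 0,
    tag_len: int = 64,
    scaffold_rate: float = 0.02,
    duplicated_blocks=(),
) -> pd.DataFrame:
    """Tabular alignment hits of marker tags against the rearranged reference.

    A ``fraction`` of markers receive a high-quality best hit at their true
    reference position; ``noise_rate`` of those anchors are corrupted to a
    uniform position on a *different* chromosome (wrong-homolog hits — the
    signature of a search matching a paralogue; equal-scoring duplicates on
    the same chromosome are collapsed by the 2 Mb rule upstream); a small
    share lands on unanchored scaffolds.  ``duplicated_blocks`` is a list of
    (marker_ids, chromosome, start_bp, step_bp) tuples planting collinear
    secondary hits for the duplication screen.
    """
    rng = np.random.default_rng(seed)
    layout = scenario.layout().set_index("marker")
    base_ids = [str(m).removesuffix("_P1").removesuffix("_P2") for m in marker_ids]
    rows = []
    for mid, base in zip(marker_ids, base_ids):
        if base not in layout.index:
            continue
        if rng.random() > fraction:
            continue
        chrom = int(layout.at[base, "chrom"])
        bp = float(layout.at[base, "reference_bp"])
        if rng.random() < scaffold_rate:
            sseq = f"scaffold_{rng.integers(100, 999)}"
            bp = float(rng.integers(1, 50_000))
        elif noise_rate > 0 and rng.random() < noise_rate:
            n_alt = max(scenario.n_chromosomes, 2)
            wrong = 1 + (chrom - 1 + 1 + int(rng.integers(0, n_alt - 1))) % n_alt
            clen = (scenario.chrom_lengths_bp[wrong - 1]
                    if wrong <= scenario.n_chromosomes
                    else scenario.chrom_lengths_bp[0])
            bp = float(rng.uniform(1, clen))
            sseq = f"Chr{wrong:02d}"
        else:
            sseq = f"Chr{chrom:02d}"
        length = int(rng.integers(62, tag_len + 1))
        pident = float(rng.uniform(96.0, 100.0))
        bit = 100.0 + round(float(rng.uniform(0, 20)), 1)
        rows.append(
            (mid, sseq, pident, length, 0, 0, 1, length,
             int(bp), int(bp) + length - 1, 1e-25, bit)
        )
    for block_ids, chrom, start, step in duplicated_blocks:
        for j, mid in enumerate(block_ids):
            rows.append(
                (mid, f"Chr{int(chrom):02d}", 97.0, tag_len, 0, 0, 1, tag_len,
                 int(start + j * step), int(start + j * step) + tag_len - 1,
                 1e-20, 90.0)
            )
    return pd.DataFrame(rows, columns=BLAST6_COLUMNS)


def true_event_intervals(scenario: SimScenario) -> list:
    """Ground-truth reference-coordinate interval of every planted event.

    Returns a list of (chromosome, ref_lo, ref_hi, kind): the span each
    rearranged segment occupies on the rearranged reference, against which
    detected calls can be scored.  Used only for evaluation.
    """
    out = []
    for c in range(1, scenario.n_chromosomes + 1):
        specs = [sp for sp in scenario.rearrangements if sp.chromosome == c]
        if not specs:
            continue
        L = scenario.chrom_lengths_bp[c - 1]
        for sp in specs:
            s, e = sp.source_interval_bp
            grid = np.linspace(s, e - 1, 25)
            ref = apply_rearrangements(grid, specs, L)
            out.append((c, float(ref.min()), float(ref.max()), sp.kind))
    return out


def match_calls_to_truth(calls, group_chrom, scenario, min_coverage=0.5):
    """Score detected calls against the planted events.

    A call matches an event when it sits on the homologous group and its
    spanning reference interval overlaps the event's by >= ``min_coverage``
    of the shorter of the two (a sparse map legitimately spans only part of
    an event).  Returns (matched_events, matched_calls) as index sets.
    """
    truth = true_event_intervals(scenario)
    matched_events, matched_calls = set(), set()
    for k, call in enumerate(calls):
        chrom = group_chrom.get(call.linkage_group, "")
        lo, hi = sorted(call.spanning_bp)
        for ti, (c, t_lo, t_hi, kind) in enumerate(truth):
            if chrom != f"Chr{c:02d}":
                continue
            inter = max(0.0, min(hi, t_hi) - max(lo, t_lo))
            shorter = max(min(hi - lo, t_hi - t_lo), 1.0)
            if inter / shorter >= min_coverage:
                matched_events.add(ti)
                matched_calls.add(k)
    return matched_events, matched_calls


def random_tags(marker_ids, tag_len: int = 64, seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    alph = np.array(list("ACGT"))
    return {
        str(m): "".join(rng.choice(alph, size=tag_len)) for m in marker_ids
    }
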