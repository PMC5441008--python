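"""Containers and plain-text I/O.

Genotype matrices travel as TSV (rows = markers, columns = offspring, values
A/B/H/U/-), marker tag sequences as FASTA, and reference anchors as 12-column
tabular alignment hits (the common ``outfmt 6`` dialect:
qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue
bitscore).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# call codes in DH (double-haploid) coding
A, B, MISSING = 0, 1, -1

_CODE_TO_CHAR = {0: "A", 1: "B", -1: "-"}
_CHAR_TO_CODE = {"A": 0, "B": 1, "-": -1, "U": -1}


@dataclass
class DHMatrix:
    """Markers x offspring genotype calls in double-haploid coding.

    ``calls`` is int8 with 0 = A, 1 = B, -1 = missing.  Rows are testcross
    loci recoded so each call names the inherited haplotype of the
    informative parent; row phase (which haplotype is called "A") is
    arbitrary, so all downstream counting is phase-free.
    """

    marker_ids: np.ndarray  # dtype=object / str, shape (m,)
    offspring_ids: np.ndarray  # shape (n,)
    calls: np.ndarray  # int8, shape (m, n)

    def __post_init__(self) -> None:
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.offspring_ids = np.asarray(self.offspring_ids, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.marker_ids), len(self.offspring_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.marker_ids)} markers x {len(self.offspring_ids)} offspring"
            )

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_offspring(self) -> int:
        return len(self.offspring_ids)

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return (self.calls != MISSING).mean(axis=1)

    def marker_index(self) -> dict:
        return {m: i for i, m in enumerate(self.marker_ids)}

    def subset_markers(self, ids) -> "DHMatrix":
        idx = self.marker_index()
        rows = np.array([idx[m] for m in ids], dtype=int)
        return DHMatrix(self.marker_ids[rows], self.offspring_ids, self.calls[rows])

    def subset_offspring(self, keep: np.ndarray) -> "DHMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            cols = np.flatnonzero(keep)
        else:
            cols = keep
        return DHMatrix(self.marker_ids, self.offspring_ids[cols], self.calls[:, cols])

    def to_frame(self) -> pd.DataFrame:
        chars = np.vectorize(_CODE_TO_CHAR.get)(self.calls)
        return pd.DataFrame(chars, index=self.marker_ids, columns=self.offspring_ids)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "marker"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DHMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        calls = df.applymap(lambda c: _CHAR_TO_CODE.get(c, MISSING)).to_numpy(
            dtype=np.int8
        )
        return cls(df.index.to_numpy(object), df.columns.to_numpy(object), calls)


@dataclass
class MarkerRecord:
    """Per-marker metadata: segregation type, quality metrics, class."""

    id: str
    seg_type: str  # testcross_P1 | testcross_P2 | intercross_121 | dominant_31 | fully_informative_1111
    reproducibility: float = 1.0
    call_rate: float = 1.0
    pic: float = 0.5
    is_snp: bool = False
    quality_class: int | str = 1  # 1 | 2 | 3 | "excluded"
    tag_seq: str = ""


SEG_TYPES = (
    "testcross_P1",
    "testcross_P2",
    "intercross_121",
    "dominant_31",
    "fully_informative_1111",
)

BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "marker": r.id,
                "seg_type": r.seg_type,
                "reproducibility": r.reproducibility,
                "call_rate": r.call_rate,
                "pic": r.pic,
                "is_snp": r.is_snp,
                "quality_class": r.quality_class,
            }
            for r in records
        ]
    )


def read_blast_tab(path) -> pd.DataFrame:
    """Read 12-column tabular alignment hits, skipping malformed lines."""
    rows = []
    bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                bad += 1
                continue
            try:
                rows.append(
                    (
                        parts[0],
                        parts[1],
                        float(parts[2]),
                        int(parts[3]),
                        int(parts[4]),
                        int(parts[5]),
                        int(parts[6]),
                        int(parts[7]),
                        int(parts[8]),
                        int(parts[9]),
                        float(parts[10]),
                        float(parts[11]),
                    )
                )
            except ValueError:
                bad += 1
    if bad:
        import warnings

        warnings.warn(f"skipped {bad} malformed alignment line(s) in {path}")
    return pd.DataFrame(rows, columns=BLAST6_COLUMNS)


def write_blast_tab(df: pd.DataFrame, path) -> None:
    df.loc[:, BLAST6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def write_tags_fasta(tags: dict, path) -> None:
    """Write marker tag sequences (64 bp) as FASTA via Biopython."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(s), id=str(m), description="") for m, s in tags.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_tags_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
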