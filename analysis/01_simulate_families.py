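"""Simulate the two-family pseudo-testcross design and write its raw data.

Generates the default nine-rearrangement scenario (11 chromosomes, ~6,000
markers, 1% mean genotyping error, 10% mean missing data), simulates the
two F1 families (n = 115 and n = 245) sharing one pollen parent, and writes
the genotype matrices, marker metadata, tag FASTA and scenario JSON under
results/01_simulation/.
"""

import sys
from pathlib import Path

import numpy as np

from ptxmap.io import ensure_dir, records_to_frame, write_tags_fasta
from ptxmap.qc import class_report
from ptxmap.simulate import default_scenario, simulate_family, random_tags

OUT = ensure_dir(Path("results") / "01_simulation")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    sc = default_scenario()
    sc.to_json(OUT / "scenario.json")
    lay = sc.layout()
    lay.to_csv(OUT / "truth_layout.tsv", sep="\t", index=False)
    print(f"scenario: {sc.n_chromosomes} chromosomes, {len(lay)} markers, "
          f"{len(sc.rearrangements)} rearrangements on "
          f"{len({r.chromosome for r in sc.rearrangements})} chromosomes")

    ss = np.random.SeedSequence(SEED)
    seeds = [int(s) % (2**31) for s in ss.generate_state(2)]
    for fam_id, n, seed in (("FA", 115, seeds[0]), ("FB", 245, seeds[1])):
        fam = simulate_family(sc, n, fam_id, seed)
        for p in ("P1", "P2"):
            fam.dh[p].to_tsv(OUT / f"{fam_id}_{p}_dh.tsv")
            records_to_frame(fam.records[p]).to_csv(
                OUT / f"{fam_id}_{p}_markers.tsv", sep="\t", index=False)
            rep = class_report(fam.records[p])
            rep.to_csv(OUT / f"{fam_id}_{p}_class_report.tsv", sep="\t", index=False)
            print(f"{fam_id} {p}: {fam.dh[p].n_markers} testcross loci x "
                  f"{n} offspring; classes: "
                  + ", ".join(f"{r.quality_class}:{r.n_markers}"
                              for r in rep.groupby('quality_class')['n_markers']
                              .sum().reset_index().itertuples()))
        fam.intercross.to_csv(OUT / f"{fam_id}_intercross.tsv", sep="\t")
    tags = random_tags(lay["marker"], seed=SEED)
    write_tags_fasta(tags, OUT / "marker_tags.fasta")
    print(f"wrote raw data under {OUT}")


if __name__ == "__main__":
    main()
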