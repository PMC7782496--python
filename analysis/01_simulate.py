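#!/usr/bin/env python
"""Generate the default synthetic study dataset and summarize what was planted.

Eight piRNA-producing loci (three long intronless, two with a long first
exon, three short) on a 2 x 2 Mb toy genome, with promoter CG classes,
abundances, regulatory flags, conservation classes, and three decoy read
pile-ups that each violate one cluster-calling filter.

Writes results/truth_clusters.tsv and results/truth_decoys.tsv.
"""

import pathlib

from pachyscan.synthetic import SimulationConfig, simulate_all

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1):
    ds = simulate_all(SimulationConfig(seed=seed))
    RESULTS.mkdir(exist_ok=True)
    ds.truth.clusters.to_csv(RESULTS / "truth_clusters.tsv", sep="\t")
    ds.truth.decoys.to_csv(RESULTS / "truth_decoys.tsv", sep="\t")
    t = ds.truth.clusters
    print(f"genome: {len(ds.genome)} chromosomes x {ds.config.chrom_length / 1e6:.0f} Mb")
    print(f"planted clusters: {len(t)} "
          f"({dict(t['structural_type'].value_counts())})")
    print(f"reads materialized: {len(ds.reads)} "
          f"(normalized to {ds.unique_total:.0f} unique mappers)")
    print(f"decoys: {list(ds.truth.decoys.index)}")
    print(t[["chrom", "start", "end", "strand", "structural_type",
             "cg_class", "rpm"]].to_string())
    return ds


if __name__ == "__main__":
    main()
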