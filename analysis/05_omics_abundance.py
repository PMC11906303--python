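#!/usr/bin/env python
"""MAG read fractions from the packaged metagenome table, and a
closed-loop metaproteome quantification demonstration.

Part 1 recomputes each MAG's share of the quality-filtered reads and the
summed binning coverage for both regimes from the raw mapped-read
counts.  Part 2 samples multinomial spectral counts from a known
proteome composition, applies the MW-normalization, detection filters
and MAG aggregation, and compares recovered to true MAG shares.  Writes
results/mag_read_fractions.tsv and results/proteome_recovery.tsv.
"""

import numpy as np
import pandas as pd

from nosbal import datasets, io
from nosbal.omics import (
    UNBINNED,
    MagAssignment,
    filter_and_average,
    mag_normalized_abundance,
    mag_proteome_fraction,
    mag_read_fraction,
    normalize_spectral_counts,
)
from nosbal.synthetic import ProteomeGroundTruth, generate_spectral_counts

SEED = 20260921


def read_fractions() -> None:
    table = datasets.mag_read_counts()
    rows = []
    for regime, grp in table.groupby("regime"):
        binned_grp = grp[grp["bin_id"] != UNBINNED]
        contigs = pd.DataFrame(
            {
                "mag_id": binned_grp["bin_id"].to_numpy(),
                "length_bp": (binned_grp["bin_size_mbp"] * 1e6).astype(int).to_numpy(),
                "mapped_reads": binned_grp["mapped_reads"].to_numpy(),
            },
            index=pd.Index(binned_grp["bin_id"], name="contig_id"),
        )
        asg = MagAssignment(contigs=contigs)
        pct, binned = mag_read_fraction(
            asg, datasets.TOTAL_QUALITY_FILTERED_READS[regime]
        )
        norm = mag_normalized_abundance(asg)
        for mag in pct.index:
            rows.append(
                {"regime": regime, "mag_id": mag, "mapped_reads_pct": pct[mag],
                 "normalized_abundance": norm[mag]}
            )
        print(f"{regime}: binned MAGs cover {binned:.1f}% of quality-filtered reads; "
              f"dominant MAG {pct.idxmax()} at {pct.max():.1f}%")
    io.write_table(pd.DataFrame(rows), "results/mag_read_fractions.tsv",
                   comments=["recomputed from raw mapped-read counts and bin sizes"])


def proteome_recovery() -> None:
    rng = np.random.default_rng(SEED)
    n = 40
    raw = rng.uniform(0.2, 3.0, size=n)
    fractions = tuple(raw / raw.sum())
    mags = ["AZO"] * 15 + ["THA"] * 10 + [UNBINNED] * 15
    truth = ProteomeGroundTruth(
        mass_fractions=fractions,
        molecular_weights=tuple(rng.uniform(15e3, 90e3, size=n)),
        depth=20_000,
        n_contaminants=5,
        seed=SEED,
    )
    t = generate_spectral_counts(truth)
    abund = filter_and_average(normalize_spectral_counts(t), t)
    pmap = {f"prot_{i:04d}": m for i, m in enumerate(mags)}
    pmap.update({f"cont_{i:04d}": UNBINNED for i in range(5)})
    recovered = mag_proteome_fraction(abund, pmap)
    # true MAG shares carry the 2% contaminant mass the generator diverts
    true_pct = {m: 98.0 * sum(f for f, g in zip(fractions, mags) if g == m)
                for m in ("AZO", "THA", UNBINNED)}
    rows = [
        {"mag_id": m, "true_pct": true_pct[m], "recovered_pct": recovered.get(m, 0.0)}
        for m in true_pct
    ]
    df = pd.DataFrame(rows)
    io.write_table(df, "results/proteome_recovery.tsv",
                   comments=[f"multinomial sampling depth 20000 x 4 injections, seed={SEED}"])
    print("\nmetaproteome MAG shares (true vs recovered, %):")
    print(df.to_string(index=False))


def main() -> None:
    read_fractions()
    proteome_recovery()


if __name__ == "__main__":
    main()
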