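"""Relative-abundance arithmetic for metaproteomes and metagenomes.

Metaproteome side: label-free quantification by molecular-weight
normalized spectral counts.  Within each LC-MS injection a protein's
share is (SC/MW) / sum_k (SC_k/MW_k); proteins are retained when they
have >= 2 unique peptides and are detected in >= 2 of the injections,
and their relative abundance is the mean share over the injections in
which they were detected.  Shares aggregate to metagenome-assembled
genomes (MAGs) through a protein->MAG map, with an explicit row for
unbinned proteins.

Metagenome side: a MAG's read fraction is its mapped reads over the
total quality-filtered reads, and its length-normalized relative
abundance divides the read density (reads per bp of the MAG's contigs)
by the summed density over all bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils import molecular_weight

__all__ = [
    "SpectralCountTable",
    "MagAssignment",
    "AssignmentError",
    "UNBINNED",
    "normalize_spectral_counts",
    "filter_and_average",
    "mag_proteome_fraction",
    "mag_read_fraction",
    "mag_normalized_abundance",
    "protein_weights_from_fasta",
]

#: reserved MAG label for proteins/contigs outside every bin
UNBINNED = "unbinned"


class AssignmentError(KeyError):
    """A protein or contig has no entry in the MAG assignment."""


@dataclass(frozen=True)
class SpectralCountTable:
    """Per-protein spectral counts over J injections.

    ``counts`` is indexed by protein id with one integer column per
    injection; ``molecular_weight`` in Da and ``unique_peptides`` share
    that index.
    """

    counts: pd.DataFrame
    molecular_weight: pd.Series
    unique_peptides: pd.Series

    def __post_init__(self) -> None:
        if self.counts.shape[1] < 1:
            raise ValueError("at least one injection column is required")
        if not self.counts.index.equals(self.molecular_weight.index) or not (
            self.counts.index.equals(self.unique_peptides.index)
        ):
            raise ValueError("counts, MW and unique-peptide indexes must match")
        arr = self.counts.to_numpy()
        if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
            raise ValueError("spectral counts must be non-negative integers")
        if np.any(self.molecular_weight.to_numpy() <= 0):
            raise ValueError("molecular weights must be > 0")

    @property
    def n_injections(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class MagAssignment:
    """Contig->MAG table (lengths, mapped reads) and protein->MAG map."""

    contigs: pd.DataFrame  # columns: mag_id, length_bp, mapped_reads
    protein_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"mag_id", "length_bp", "mapped_reads"}
        if not required.issubset(self.contigs.columns):
            raise ValueError(f"contig table needs columns {sorted(required)}")
        if self.contigs.index.has_duplicates:
            raise ValueError("each contig may map to at most one MAG")
        if np.any(self.contigs["length_bp"].to_numpy() <= 0):
            raise ValueError("contig lengths must be > 0")
        if np.any(self.contigs["mapped_reads"].to_numpy() < 0):
            raise ValueError("mapped read counts must be >= 0")

    def per_mag(self) -> pd.DataFrame:
        """Summed length and mapped reads per MAG."""
        return self.contigs.groupby("mag_id")[["length_bp", "mapped_reads"]].sum()


def normalize_spectral_counts(
    table: SpectralCountTable, denominator: str = "normalized"
) -> pd.DataFrame:
    """Per-injection protein shares from MW-normalized spectral counts.

    share_ij = (SC_ij / MW_i) / sum_k (SC_kj / MW_k).  With
    ``denominator="raw"`` the per-injection denominator is the raw
    spectral-count total instead (a published variant of the same
    normalization); shares then no longer sum to one.  Injections with
    zero total are skipped with a warning and returned as NaN.
    """
    if denominator not in ("normalized", "raw"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    nsc = table.counts.div(table.molecular_weight, axis=0)
    if denominator == "normalized":
        totals = nsc.sum(axis=0)
    else:
        totals = table.counts.sum(axis=0).astype(float)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"skipping empty injections: {list(totals.index[empty])}"
        )
        totals = totals.where(~empty)
    return nsc.div(totals, axis=1)


def filter_and_average(
    shares: pd.DataFrame,
    table: SpectralCountTable,
    min_unique_peptides: int = 2,
    min_injections: int = 2,
    average_over: str = "detected",
) -> pd.DataFrame:
    """Detection filtering and per-protein averaging of injection shares.

    A protein is retained when it has >= ``min_unique_peptides`` unique
    peptides and a nonzero count in >= ``min_injections`` injections.
    Its relative abundance is the mean share over the injections where
    it was detected (``average_over="detected"``), or over all
    injections counting zeros (``average_over="all"``).
    """
    if min_unique_peptides < 1 or min_injections < 1:
        raise ValueError("thresholds must be >= 1")
    if average_over not in ("detected", "all"):
        raise ValueError(f"unknown averaging convention {average_over!r}")
    detected = table.counts > 0
    detected_in = detected.sum(axis=1)
    retained = (table.unique_peptides >= min_unique_peptides) & (
        detected_in >= min_injections
    )
    if average_over == "detected":
        mean_share = shares.where(detected).mean(axis=1).fillna(0.0)
    else:
        mean_share = shares.fillna(0.0).mean(axis=1)
    return pd.DataFrame(
        {
            "detected_in": detected_in,
            "mean_relative_abundance": mean_share,
            "retained": retained,
        },
        index=table.counts.index,
    )


def mag_proteome_fraction(
    abundances: pd.DataFrame,
    assignment: "MagAssignment | Mapping[str, str]",
    retained_only: bool = True,
) -> pd.Series:
    """Percent of the metaproteome attributed to each MAG.

    Sums the mean relative abundances of (by default retained) proteins
    per MAG and rescales by 100.  ``assignment`` is a MagAssignment or a
    bare protein->MAG mapping.  Proteins absent from the map raise
    AssignmentError; the reserved ``unbinned`` label is reported as its
    own row.
    """
    protein_map = (
        assignment.protein_map if isinstance(assignment, MagAssignment) else assignment
    )
    sel = abundances[abundances["retained"]] if retained_only else abundances
    unknown = [p for p in sel.index if p not in protein_map]
    if unknown:
        raise AssignmentError(
            f"proteins without MAG assignment: {unknown[:5]}"
            + ("..." if len(unknown) > 5 else "")
        )
    mags = pd.Series(
        [protein_map[p] for p in sel.index], index=sel.index, name="mag_id"
    )
    return (
        sel["mean_relative_abundance"].groupby(mags).sum().mul(100.0).rename("pct")
    )


def mag_read_fraction(
    assignment: MagAssignment, total_quality_filtered_reads: int
) -> tuple[pd.Series, float]:
    """Percent of quality-filtered reads mapping to each MAG.

    Returns the per-MAG percentages and the summed fraction over all
    bins other than ``unbinned`` (the binning coverage of the
    metagenome).
    """
    per_mag = assignment.per_mag()
    mapped = per_mag["mapped_reads"]
    if total_quality_filtered_reads < mapped.sum():
        raise ValueError(
            "total quality-filtered reads is below the summed mapped reads"
        )
    pct = (100.0 * mapped / total_quality_filtered_reads).rename("pct")
    binned = float(pct.drop(index=UNBINNED, errors="ignore").sum())
    return pct, binned


def mag_normalized_abundance(assignment: MagAssignment) -> pd.Series:
    """Length-normalized relative abundance per MAG.

    density_M = mapped reads / summed contig length; abundances are the
    densities rescaled to sum to one over all bins present in the table
    (including an unbinned pseudo-bin when provided).
    """
    per_mag = assignment.per_mag()
    density = per_mag["mapped_reads"] / per_mag["length_bp"]
    total = density.sum()
    if total == 0:
        raise ValueError("no mapped reads in any MAG")
    return (density / total).rename("relative_abundance")


def protein_weights_from_fasta(path) -> pd.Series:
    """Average (water-corrected) molecular weights, Da, from a protein FASTA."""
    weights = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).replace("*", "").upper()
        weights[record.id] = molecular_weight(seq, seq_type="protein", monoisotopic=False)
    if not weights:
        raise ValueError(f"no sequences found in {path}")
    return pd.Series(weights, name="molecular_weight")
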