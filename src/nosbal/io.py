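"""Readers and writers for the tab-separated interchange formats.

All tables are UTF-8 TSV with an optional ``#``-prefixed comment header
carrying units and provenance; numeric output keeps 12 significant
digits so a write/read round trip is lossless at that precision.
Species systems are declared in a small YAML config (name, formula
string, phase, measured flag, role).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .batch import BatchSeries
from .omics import MagAssignment, SpectralCountTable
from .reconciliation import RateVector
from .stoichiometry import ConfigurationError, Species, parse_formula

__all__ = [
    "read_table",
    "write_table",
    "load_species_config",
    "read_rate_table",
    "read_batch_table",
    "read_spectral_counts",
    "read_contig_map",
    "read_protein_map",
    "read_mag_assignment",
]

FLOAT_FORMAT = "%.12g"


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV, skipping ``#`` comment lines."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(
    df: pd.DataFrame, path: str | Path, comments: Iterable[str] = ()
) -> None:
    """Write a TSV with a commented header block at 12 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def load_species_config(path: str | Path) -> list[Species]:
    """Species definitions from YAML.

    Expected structure::

        species:
          - name: acetate
            formula: C2H3O2-
            measured: true
            role: electron_donor
            phase: aq
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "species" not in cfg:
        raise ConfigurationError(f"{path}: missing top-level 'species' list")
    out = []
    for entry in cfg["species"]:
        try:
            out.append(
                Species(
                    name=str(entry["name"]),
                    composition=parse_formula(str(entry["formula"])),
                    measured=bool(entry.get("measured", True)),
                    role=str(entry.get("role", "product")),
                    phase=str(entry.get("phase", "aq")),
                )
            )
        except KeyError as exc:
            raise ConfigurationError(
                f"{path}: species entry missing key {exc.args[0]!r}"
            ) from exc
    names = [s.name for s in out]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"{path}: duplicate species names")
    return out


def read_rate_table(path: str | Path) -> RateVector:
    """Measured rates from a TSV with columns species, rate_mmol_d, sd_mmol_d."""
    df = read_table(path)
    required = {"species", "rate_mmol_d", "sd_mmol_d"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"{path}: needs columns {sorted(required)}")
    return RateVector(
        rates=dict(zip(df["species"], df["rate_mmol_d"].astype(float))),
        sd=dict(zip(df["species"], df["sd_mmol_d"].astype(float))),
    )


def read_batch_table(path: str | Path) -> list[BatchSeries]:
    """Long-format batch series: time_h, conc_mM, replicate, biomass_gvss[, biomass_sd]."""
    df = read_table(path)
    required = {"time_h", "conc_mM", "replicate", "biomass_gvss"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"{path}: needs columns {sorted(required)}")
    series = []
    for rep, grp in df.groupby("replicate", sort=False):
        grp = grp.sort_values("time_h")
        biomass = float(grp["biomass_gvss"].iloc[0])
        biomass_sd = float(grp["biomass_sd"].iloc[0]) if "biomass_sd" in grp else 0.0
        series.append(
            BatchSeries(
                times_h=tuple(grp["time_h"].astype(float)),
                conc_mM=tuple(grp["conc_mM"].astype(float)),
                replicate=str(rep),
                biomass_gvss=biomass,
                biomass_sd=biomass_sd,
            )
        )
    return series


def read_spectral_counts(
    path: str | Path, molecular_weights: Mapping[str, float] | pd.Series | None = None
) -> SpectralCountTable:
    """Spectral counts from TSV: protein_id, unique_peptides, [mw_da,] inj_1..inj_J.

    Molecular weights come from an ``mw_da`` column or, when absent,
    from ``molecular_weights`` (e.g. computed from a protein FASTA).
    """
    df = read_table(path).set_index("protein_id")
    inj_cols = [c for c in df.columns if c.startswith("inj_")]
    if not inj_cols:
        raise ConfigurationError(f"{path}: no injection columns (inj_1, inj_2, ...)")
    if "unique_peptides" not in df.columns:
        raise ConfigurationError(f"{path}: missing unique_peptides column")
    if "mw_da" in df.columns:
        mw = df["mw_da"].astype(float)
    elif molecular_weights is not None:
        mw = pd.Series(molecular_weights, dtype=float).reindex(df.index)
        if mw.isna().any():
            missing = list(mw.index[mw.isna()][:5])
            raise ConfigurationError(f"{path}: no molecular weight for {missing}")
    else:
        raise ConfigurationError(
            f"{path}: provide an mw_da column or molecular weights from FASTA"
        )
    return SpectralCountTable(
        counts=df[inj_cols].astype(int),
        molecular_weight=mw.rename("molecular_weight"),
        unique_peptides=df["unique_peptides"].astype(int),
    )


def read_contig_map(path: str | Path) -> pd.DataFrame:
    """Contig map TSV: contig_id, mag_id, length_bp, mapped_reads."""
    df = read_table(path)
    required = {"contig_id", "mag_id", "length_bp", "mapped_reads"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"{path}: needs columns {sorted(required)}")
    return df.set_index("contig_id")


def read_protein_map(path: str | Path) -> dict[str, str]:
    """Protein->MAG map TSV: protein_id, mag_id."""
    df = read_table(path)
    if not {"protein_id", "mag_id"}.issubset(df.columns):
        raise ConfigurationError(f"{path}: needs columns protein_id, mag_id")
    return dict(zip(df["protein_id"].astype(str), df["mag_id"].astype(str)))


def read_mag_assignment(
    contig_path: str | Path, protein_path: str | Path | None = None
) -> MagAssignment:
    """Assemble a MagAssignment from contig (and optional protein) tables."""
    contigs = read_contig_map(contig_path)
    protein_map = read_protein_map(protein_path) if protein_path else {}
    return MagAssignment(contigs=contigs, protein_map=protein_map)
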