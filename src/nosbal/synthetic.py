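"""Ground-truth generators emulating the study's measurement structure.

Each generator draws from a known ground truth so the downstream
computations (reconciliation, yield and maintenance estimation, batch
regression, proteome/metagenome abundance) can be tested closed-loop:

* steady-state chemostat rate vectors follow a Herbert-Pirt yield law
  and exact elemental balances before Gaussian measurement noise with a
  stated coefficient of variation is added;
* batch bottles deplete linearly from 1.1 mmol/L with additive Gaussian
  noise, truncated at zero;
* spectral counts are multinomial draws per injection with category
  probabilities proportional to mass fraction x molecular weight, so the
  MW-normalized shares are unbiased for the mass fractions;
* per-contig read counts are Poisson with mean proportional to
  abundance x contig length.

All draws are bit-reproducible given a seed.  The two presets mirror
the enrichments' operating points: acetate/N2O influent loads of
31.6/382 mmol/d under N2O excess and 46.1/84 mmol/d under N2O
limitation, dilution rates 0.006-0.089 1/h, and maintenance
coefficients 0.019 and 0.008 C-mol Ac/(C-mol X h).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .batch import BatchSeries
from .physiology import Measurement, YieldSet
from .omics import UNBINNED, MagAssignment, SpectralCountTable
from .reconciliation import RateVector
from .stoichiometry import degree_of_reduction, parse_formula

__all__ = [
    "ChemostatGroundTruth",
    "ProteomeGroundTruth",
    "CHEMOSTAT_PRESETS",
    "generate_chemostat_dataset",
    "generate_batch_series",
    "generate_spectral_counts",
    "generate_mag_reads",
]


@dataclass(frozen=True)
class ChemostatGroundTruth:
    """Herbert-Pirt + fixed-stoichiometry truth for one regime."""

    y_max: float = 0.29  # C-mol X / C-mol Ac
    m_s: float = 0.019  # C-mol Ac / (C-mol X h)
    d_levels: tuple[float, ...] = (0.006, 0.028, 0.089)  # 1/h
    acetate_load: float = 31.6  # mmol/d consumed at steady state
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.y_max < 8 / 8.4:
            raise ValueError("y_max must lie in (0, 8/8.4)")
        if self.m_s < 0 or self.noise_cv < 0:
            raise ValueError("m_s and noise CV must be >= 0")
        if any(d <= 0 for d in self.d_levels):
            raise ValueError("dilution rates must be > 0")
        if self.acetate_load <= 0:
            raise ValueError("acetate load must be > 0")


#: operating points of the two enrichment regimes
CHEMOSTAT_PRESETS: dict[str, ChemostatGroundTruth] = {
    "N2Oexc": ChemostatGroundTruth(m_s=0.019, acetate_load=31.6, seed=0),
    "N2Olim": ChemostatGroundTruth(
        m_s=0.008, acetate_load=46.1, d_levels=(0.006, 0.027, 0.086), seed=0
    ),
}


def pirt_yield(d: float, y_max: float, m_s: float) -> float:
    """Observed growth yield Y(D) = D / (D/Y_max + m_s)."""
    return d / (d / y_max + m_s)


def true_rate_vector(acetate_load: float, y_x_ac: float) -> dict[str, float]:
    """Exactly balanced rates (mmol/d, production-positive) at a given yield.

    Acetate is fully consumed; biomass follows the yield; ammonium
    uptake is the biomass N content; N2O closes the electron balance
    (8 e-/mol acetate, 4.2 e-/C-mol biomass, 2 e-/mol N2O).
    """
    biomass = parse_formula("CH1.8O0.5N0.2")
    gamma_ac = degree_of_reduction(parse_formula("C2H3O2-"))  # 8
    gamma_x = degree_of_reduction(biomass)  # 4.2
    r_ac = -acetate_load
    r_x = y_x_ac * 2.0 * acetate_load  # C-mmol/d
    r_n2o = -(gamma_ac * acetate_load - gamma_x * r_x) / 2.0
    r_nh4 = -biomass.n_N * r_x
    return {"acetate": r_ac, "N2O": r_n2o, "NH4": r_nh4, "biomass": r_x}


def generate_chemostat_dataset(
    truth: ChemostatGroundTruth,
) -> tuple[dict[float, RateVector], YieldSet]:
    """Noisy measured rate vectors per dilution rate, plus the true yields.

    The reported SD of each rate is CV x |true rate| (the nominal
    measurement precision).  The returned YieldSet holds the noiseless
    truth at the lowest dilution rate with zero SDs.
    """
    rng = np.random.default_rng(truth.seed)
    datasets: dict[float, RateVector] = {}
    for d in truth.d_levels:
        y = pirt_yield(d, truth.y_max, truth.m_s)
        r_true = true_rate_vector(truth.acetate_load, y)
        rates, sds = {}, {}
        for name, r in r_true.items():
            sd = truth.noise_cv * abs(r)
            rates[name] = r + rng.normal(0.0, sd) if sd > 0 else r
            # noiseless rates still need a positive SD to be reconcilable;
            # keep it far above float rounding so h stays numerically zero
            sds[name] = sd if sd > 0 else 1e-6 * max(1.0, abs(r))
        datasets[d] = RateVector(rates=rates, sd=sds)
    y0 = pirt_yield(truth.d_levels[0], truth.y_max, truth.m_s)
    r0 = true_rate_vector(truth.acetate_load, y0)
    true_yields = YieldSet(
        y_x_ac=Measurement(y0, 0.0),
        y_x_n2o=Measurement(abs(r0["biomass"] / r0["N2O"]), 0.0),
        y_n2o_ac=Measurement(abs(r0["N2O"] / r0["acetate"]), 0.0),
        y_nh4_x=Measurement(abs(r0["NH4"] / r0["biomass"]), 0.0),
    )
    return datasets, true_yields


def generate_batch_series(
    q_true: float,
    biomass_gvss: float,
    n_points: int = 8,
    dt_h: float = 0.5,
    noise_sd: float = 0.02,
    seed: int = 0,
    c0_mM: float = 1.1,
    replicate: str = "bottle-1",
    biomass_sd: float = 0.0,
) -> BatchSeries:
    """Linear substrate depletion with additive noise, truncated at zero.

    ``q_true`` is the biomass-specific consumption rate (mmol per g VSS
    per h); the volumetric slope is q_true x biomass.
    """
    if n_points < 4:
        raise ValueError("a batch series needs at least 4 points")
    if q_true < 0 or biomass_gvss <= 0 or dt_h <= 0 or noise_sd < 0 or c0_mM <= 0:
        raise ValueError("batch generator parameters must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * dt_h
    c = c0_mM - q_true * biomass_gvss * t
    if noise_sd > 0:
        c = c + rng.normal(0.0, noise_sd, size=n_points)
    c = np.clip(c, 0.0, None)
    return BatchSeries(
        times_h=tuple(t),
        conc_mM=tuple(c),
        replicate=replicate,
        biomass_gvss=biomass_gvss,
        biomass_sd=biomass_sd,
    )


@dataclass(frozen=True)
class ProteomeGroundTruth:
    """Known proteome composition for multinomial spectral-count sampling."""

    mass_fractions: tuple[float, ...]
    molecular_weights: tuple[float, ...]  # Da
    depth: int = 20000  # spectra per injection
    n_injections: int = 4
    n_contaminants: int = 0  # single-unique-peptide decoy-like entries
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.mass_fractions)
        if np.any(f < 0) or not np.isclose(f.sum(), 1.0):
            raise ValueError("mass fractions must be >= 0 and sum to 1")
        if len(self.molecular_weights) != f.size:
            raise ValueError("one molecular weight per protein is required")
        if any(w <= 0 for w in self.molecular_weights):
            raise ValueError("molecular weights must be > 0")
        if self.depth < 1 or self.n_injections < 1 or self.n_contaminants < 0:
            raise ValueError("depth and injection counts must be positive")


def generate_spectral_counts(truth: ProteomeGroundTruth) -> SpectralCountTable:
    """Multinomial spectral counts whose normalized shares recover the truth.

    Spectral counts are proportional to protein mass, i.e. the sampling
    probability of protein i is fraction_i x MW_i (renormalized), so the
    MW-normalized share is unbiased for fraction_i.  Contaminant entries
    carry a single unique peptide and 2% of each injection's residual
    probability mass split evenly; real proteins draw >= 2 unique
    peptides.
    """
    rng = np.random.default_rng(truth.seed)
    f = np.asarray(truth.mass_fractions, dtype=float)
    mw = np.asarray(truth.molecular_weights, dtype=float)
    ids = [f"prot_{i:04d}" for i in range(f.size)]
    upep = 2 + rng.poisson(3.0, size=f.size)
    if truth.n_contaminants:
        cont_mw = rng.uniform(10e3, 60e3, size=truth.n_contaminants)
        cont_frac = np.full(truth.n_contaminants, 0.02 / truth.n_contaminants)
        f = np.concatenate([f * 0.98, cont_frac])
        mw = np.concatenate([mw, cont_mw])
        ids += [f"cont_{i:04d}" for i in range(truth.n_contaminants)]
        upep = np.concatenate([upep, np.ones(truth.n_contaminants, dtype=int)])
    p = f * mw
    p = p / p.sum()
    counts = rng.multinomial(truth.depth, p, size=truth.n_injections).T
    cols = [f"inj_{j + 1}" for j in range(truth.n_injections)]
    index = pd.Index(ids, name="protein_id")
    return SpectralCountTable(
        counts=pd.DataFrame(counts, index=index, columns=cols),
        molecular_weight=pd.Series(mw, index=index, name="molecular_weight"),
        unique_peptides=pd.Series(upep, index=index, name="unique_peptides"),
    )


def generate_mag_reads(
    abundances: Mapping[str, float],
    contig_lengths: Mapping[str, Sequence[int]],
    total_reads: int,
    seed: int = 0,
    unbinned_length: int = 5_000_000,
) -> tuple[MagAssignment, int]:
    """Per-contig Poisson read counts proportional to abundance x length.

    ``abundances`` are length-normalized (cell-fraction) abundances per
    MAG summing to <= 1; the remainder is assigned to an unbinned
    pseudo-bin of ``unbinned_length`` bp.  Returns the assignment and the
    realized total read count (binned + unbinned), which is the quantity
    to pass to ``mag_read_fraction`` as the quality-filtered total.
    """
    a = {m: float(v) for m, v in abundances.items()}
    if any(v < 0 for v in a.values()):
        raise ValueError("abundances must be >= 0")
    s = sum(a.values())
    if s > 1 + 1e-9:
        raise ValueError("abundances must sum to <= 1")
    if total_reads < 0:
        raise ValueError("total reads must be >= 0")
    lengths = {m: list(contig_lengths[m]) for m in a}
    if 1 - s > 1e-9:
        a[UNBINNED] = 1 - s
        lengths[UNBINNED] = [unbinned_length]
    rng = np.random.default_rng(seed)
    # expected reads per contig: total * a_M * l_c / sum_M' a_M' L_M'
    weight_total = sum(a[m] * sum(lengths[m]) for m in a)
    rows = []
    for m in a:
        for i, l in enumerate(lengths[m]):
            if l <= 0:
                raise ValueError("contig lengths must be > 0")
            mean = 0.0 if weight_total == 0 else total_reads * a[m] * l / weight_total
            reads = int(rng.poisson(mean)) if total_reads > 0 else 0
            rows.append((f"{m}_c{i:03d}", m, int(l), reads))
    contigs = pd.DataFrame(
        rows, columns=["contig_id", "mag_id", "length_bp", "mapped_reads"]
    ).set_index("contig_id")
    realized_total = int(contigs["mapped_reads"].sum())
    return MagAssignment(contigs=contigs), realized_total
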