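# Methods

This note documents the models, conventions and numerical choices behind
`nosbal`, and what the closed-loop tests do and do not establish.

## Black-box stoichiometry

The culture is treated as a single black-box conversion over eight species:
acetate (C₂H₃O₂⁻, electron donor), N₂O (acceptor), NH₄⁺ (nitrogen source),
biomass (CH₁.₈O₀.₅N₀.₂ per C-mol, the conventional average composition),
CO₂, N₂, H₂O and H⁺. Conservation of C, H, O, N and charge gives a 5×8
matrix E; any vector of net conversion rates or stoichiometric coefficients
must satisfy E·v = 0.

The degree of reduction γ = 4n_C + n_H − 2n_O + v_N·n_N − z counts available
electrons per formula unit. The nitrogen reference valence v_N is a
parameter: −3 (ammonia reference) for organics, biomass and ammonium, 0
(dinitrogen reference) when counting electrons accepted on the N₂O/N₂ couple
(γ(N₂O) = −2, two electrons per mole). With these references acetate carries
8 e⁻/mol and biomass 4.2 e⁻/C-mol, and the exact catabolic balance yields
4 mol N₂O per mol acetate. Signs are products-positive throughout;
consumption is negative. Balance closure on exact solves is required to
1e−9 — the coefficients are rationals with small denominators, so anything
larger indicates a real inconsistency, which is reported with the
worst-violated balance named.

`predict_yields_from_electron_balance` closes the donor electron budget
around a measured biomass yield: γ_Ac = n_C·γ_X·Y_X/Ac + 2·Y_N2O/Ac, i.e.
Y_N2O/Ac = 4 − 4.2·Y_X/Ac for the default compositions. This assumes
nitrogen uptake exactly stoichiometric with biomass (Y_NH4/X = n_N = 0.2).
The measured ammonium yields of the enrichments (0.41–0.44) are roughly
twice that value; the package does not resolve this discrepancy but exposes
the biomass composition as a parameter so alternative N contents can be
explored.

## Rate reconciliation

Only four of the eight rates are measured. Eliminating the unmeasured block
E_u by projecting onto its left null space leaves K·E_m, the constraints
testable from data. For this system the five balances collapse to exactly
one redundancy, proportional to

  8·r_Ac − 2·r_N2O + 3·r_NH4 + 4.8·r_X = 0   (production-positive signs).

This is the electron balance expressed before substituting the N-source
coupling; when ammonium uptake is exactly 0.2·r_X it reduces to the familiar
8·|r_Ac| = 4.2·r_X + 2·|r_N2O|. The reconciled rates are the
minimum-variance adjustment r̂ = r − ΣEᵀ(EΣEᵀ)⁻¹Er with diagonal Σ from the
per-rate SDs (measurement errors are taken independent; the data provide no
covariances). The residual statistic h = εᵀ(EΣEᵀ)⁻¹ε is χ²(dof) under
consistent measurements, with dof the rank of the reduced matrix (relative
singular-value threshold 1e−10), so duplicated balances can never inflate
the test — they are rejected as a singular constraint covariance (condition
number > 1e12). Zero redundancy is a valid, flagged outcome, not an error.
Unmeasured rates are back-solved from the full balance set afterwards and
reported only where the null space of E_u leaves them uniquely determined
(CO₂ from carbon, N₂ from nitrogen, H₂O and H⁺ from the rest).

A switch can exempt named species from the nitrogen balance, which is the
pragmatic way to reconcile data in which ammonium consumption exceeds the
fixed biomass N content.

## Yields, maintenance, gas arithmetic

Yields are ratios of reconciled volumetric rates, magnitudes only, with
first-order error propagation σ_Y = Y·√((σ_num/r_num)² + (σ_den/r_den)²).
Acetate is converted to C-mol by its carbon number (2), taken from the
declared composition rather than hard-coded.

Maintenance follows Herbert–Pirt, q_s = D/Y_max + m_s. The default
estimator is ordinary least squares of 1/Y on 1/D (slope m_s, intercept
1/Y_max). This linearization reproduces both regimes' published maintenance
coefficients from the three printed (D, Y) points (0.0195 → 0.019 ± 0.001
under N₂O excess, 0.0076 → 0.008 ± 0.001 under limitation), whereas a
weighted fit or the q_s-on-D form would weight the low-D point differently;
the q_s-on-D form (intercept m_s) is available via `form="specific_rate"`,
and inverse-variance weighting via `weighted=True`. A raw Y-on-D line has no
Herbert–Pirt interpretation and is not offered. Standard errors use the
usual OLS formulas; with two points the fit is exact and SEs are reported
as zero.

Dissolved N₂O uses Henry's law c = H·p with H = 2.4·10⁻⁴ mmol/(L·Pa), the
constant appropriate at the 20 °C operating temperature; no temperature
correction is applied. In a membrane bioreactor the biomass dilution rate is
D = 1/(24·SRT) with SRT in days.

## Batch rates

The volumetric rate is the sign-flipped OLS slope through at least four
concentration points — fewer points are rejected, mirroring the assay
protocol. No automatic change-point detection is attempted: the caller
marks the linear window, which is a documented limitation for curves that
saturate. Replicates aggregate as the mean of per-bottle slopes with the
across-bottle SD; the specific rate divides by biomass with the usual
relative-error propagation. Biomass converts between g VSS and C-mol via
the molar mass of the declared composition (24.6 g/C-mol by default).

## Omics quantification

Within an injection, a protein's share is (SC/MW)/Σ(SC/MW): spectral counts
scale with protein mass, so dividing by molecular weight gives a molar-like
quantity and the MW-normalized denominator makes shares sum to one. The
variant with a raw spectral-count denominator appears in parts of the
literature and is available via `denominator="raw"`; the normalized
denominator is the default because it is the self-consistent definition.
Detection filtering retains proteins with ≥2 unique peptides detected in ≥2
injections (defaults, both configurable). Averaging is over the injections
in which a protein was detected — undetected injections are treated as
missing at random; averaging zeros over all injections is available via
`average_over="all"`. MAG aggregation by default uses retained proteins
only. Molecular weights from FASTA use average (not monoisotopic) residue
masses, water-corrected.

MAG read fractions are mapped reads over total quality-filtered reads; the
length-normalized abundance divides each MAG's read density (reads per bp)
by the summed density, which estimates cell fractions when genome copy
numbers are comparable.

## Synthetic generators

The generators encode the study conditions: influent acetate loads of
31.6 mmol/d (N₂O excess, 382 mmol/d N₂O) and 46.1 mmol/d (N₂O limitation,
84 mmol/d N₂O), dilution levels spanning 0.006–0.089 h⁻¹, Y_max = 0.29,
m_s = 0.019 or 0.008, and 5% measurement CV — the noise scale implied by
the published rate SDs. Chemostat rate vectors satisfy every balance
exactly before Gaussian noise is added, so the reconciliation h statistic
is exactly χ²(1)-distributed under the generator. Batch series deplete
linearly from 1.1 mmol/L with additive Gaussian noise (sd 0.02 mmol/L by
default), truncated at zero. Spectral counts are multinomial with category
probability ∝ mass fraction × MW; per-contig read counts are Poisson with
mean ∝ abundance × length, and the realized total is reported as the
quality-filtered total so all downstream preconditions hold by
construction. All generators are bit-reproducible given a seed.

What the generators do *not* emulate: temporal autocorrelation of reactor
measurements, systematic (bias-type) measurement error, peptide-level
identification noise and shared-peptide ambiguity, GC- or
mappability-dependent coverage, and multi-copy marker variation. Passing
closed-loop tests therefore demonstrates correctness of the arithmetic
under the stated error models, not robustness to those real-data effects.

## Problem sizes in the test suite

The statistical acceptance checks use 1000 single-level simulations for the
χ²(1) distribution of h, 500 seeds for maintenance-coefficient recovery
(three dilution levels each), 200 seeds for batch-slope recovery, and
multinomial/Poisson draws at depths of 2·10⁴–10⁶; these sizes give
Monte-Carlo errors comfortably below the asserted tolerances while keeping
the full suite under half a minute.
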