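"""MW-normalized spectral-count quantification and MAG abundance arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nosbal import datasets
from nosbal.omics import (
    UNBINNED,
    AssignmentError,
    MagAssignment,
    SpectralCountTable,
    filter_and_average,
    mag_normalized_abundance,
    mag_proteome_fraction,
    mag_read_fraction,
    normalize_spectral_counts,
    protein_weights_from_fasta,
)


def make_table(counts, mw, upep):
    ids = pd.Index([f"p{i}" for i in range(len(mw))], name="protein_id")
    counts = pd.DataFrame(
        np.atleast_2d(counts),
        index=ids,
        columns=[f"inj_{j+1}" for j in range(np.atleast_2d(counts).shape[1])],
    )
    return SpectralCountTable(
        counts=counts,
        molecular_weight=pd.Series(mw, index=ids),
        unique_peptides=pd.Series(upep, index=ids),
    )


class TestNormalizeSpectralCounts:
    def test_mw_weighting(self):
        # equal counts, MW 50 and 100 kDa -> shares 2/3 and 1/3
        t = make_table([[10], [10]], [50e3, 100e3], [3, 3])
        shares = normalize_spectral_counts(t)
        np.testing.assert_allclose(shares["inj_1"], [2 / 3, 1 / 3])

    def test_single_protein_share_one(self):
        t = make_table([[7]], [30e3], [4])
        assert normalize_spectral_counts(t).iloc[0, 0] == 1.0

    def test_three_protein_hand_example(self):
        t = make_table([[10], [10], [5]], [20e3, 40e3, 10e3], [3, 3, 3])
        np.testing.assert_allclose(
            normalize_spectral_counts(t)["inj_1"], [0.4, 0.2, 0.4]
        )

    def test_shares_sum_to_one_per_injection(self):
        rng = np.random.default_rng(3)
        t = make_table(
            rng.integers(0, 50, size=(20, 4)),
            rng.uniform(10e3, 90e3, size=20),
            rng.integers(1, 9, size=20),
        )
        shares = normalize_spectral_counts(t)
        np.testing.assert_allclose(shares.sum(axis=0), 1.0, atol=1e-9)

    def test_empty_injection_skipped_with_warning(self):
        t = make_table([[10, 0], [5, 0]], [20e3, 20e3], [3, 3])
        with pytest.warns(UserWarning, match="inj_2"):
            shares = normalize_spectral_counts(t)
        assert shares["inj_2"].isna().all()
        np.testing.assert_allclose(shares["inj_1"], [2 / 3, 1 / 3])

    def test_raw_denominator_variant(self):
        t = make_table([[10], [10]], [50e3, 100e3], [3, 3])
        shares = normalize_spectral_counts(t, denominator="raw")
        np.testing.assert_allclose(shares["inj_1"], [10 / 50e3 / 20, 10 / 100e3 / 20])


class TestFilterAndAverage:
    def test_single_injection_detection_not_retained(self):
        t = make_table([[9, 0, 0, 0]], [30e3], [5])
        out = filter_and_average(normalize_spectral_counts(t), t)
        assert not out["retained"].iloc[0]

    def test_single_unique_peptide_not_retained(self):
        t = make_table([[9, 9, 9, 9]], [30e3], [1])
        out = filter_and_average(normalize_spectral_counts(t), t)
        assert not out["retained"].iloc[0]

    def test_mean_over_detected_injections(self):
        shares = pd.DataFrame(
            [[0.1, 0.2, 0.0, 0.0]],
            index=pd.Index(["p0"], name="protein_id"),
            columns=["inj_1", "inj_2", "inj_3", "inj_4"],
        )
        t = make_table([[1, 1, 0, 0]], [30e3], [3])
        out = filter_and_average(shares, t)
        assert out["mean_relative_abundance"].iloc[0] == pytest.approx(0.15)
        out_all = filter_and_average(shares, t, average_over="all")
        assert out_all["mean_relative_abundance"].iloc[0] == pytest.approx(0.075)

    def test_filter_monotone_in_unique_peptides(self):
        rng = np.random.default_rng(5)
        t = make_table(
            rng.integers(0, 20, size=(30, 4)),
            rng.uniform(10e3, 90e3, size=30),
            rng.integers(1, 6, size=30),
        )
        shares = normalize_spectral_counts(t)
        retained = [
            set(
                filter_and_average(shares, t, min_unique_peptides=k).query("retained").index
            )
            for k in (1, 2, 3, 4)
        ]
        for small, big in zip(retained[1:], retained):
            assert small <= big


class TestMagProteomeFraction:
    def test_all_in_one_mag(self):
        t = make_table([[5, 5], [5, 5]], [30e3, 30e3], [3, 3])
        abund = filter_and_average(normalize_spectral_counts(t), t)
        frac = mag_proteome_fraction(abund, {"p0": "A", "p1": "A"})
        assert frac["A"] == pytest.approx(100.0)

    def test_split_and_unbinned(self):
        t = make_table([[6, 6], [4, 4]], [30e3, 30e3], [3, 3])
        abund = filter_and_average(normalize_spectral_counts(t), t)
        frac = mag_proteome_fraction(abund, {"p0": "A", "p1": UNBINNED})
        assert frac["A"] == pytest.approx(60.0)
        assert frac[UNBINNED] == pytest.approx(40.0)

    def test_unknown_protein_raises(self):
        t = make_table([[5, 5]], [30e3], [3])
        abund = filter_and_average(normalize_spectral_counts(t), t)
        with pytest.raises(AssignmentError):
            mag_proteome_fraction(abund, {})


def make_assignment(rows):
    df = pd.DataFrame(
        rows, columns=["contig_id", "mag_id", "length_bp", "mapped_reads"]
    ).set_index("contig_id")
    return MagAssignment(contigs=df)


class TestMagReadFraction:
    def test_published_dominant_mag(self):
        asg = make_assignment([("c1", "AZO_exc", 2_700_000, 62_591_220)])
        pct, _ = mag_read_fraction(asg, 75.2e6)
        assert pct["AZO_exc"] == pytest.approx(83.2, abs=0.05)

    def test_published_binned_totals(self):
        table = datasets.mag_read_counts()
        for regime, printed in [("N2Oexc", 94.5), ("N2Olim", 74.1)]:
            grp = table[(table["regime"] == regime) & (table["bin_id"] != UNBINNED)]
            asg = make_assignment(
                [(b, b, int(s * 1e6), r)
                 for b, s, r in zip(grp["bin_id"], grp["bin_size_mbp"], grp["mapped_reads"])]
            )
            _, binned = mag_read_fraction(
                asg, datasets.TOTAL_QUALITY_FILTERED_READS[regime]
            )
            assert abs(binned - printed) <= 0.1

    def test_zero_mapped_reads(self):
        asg = make_assignment([("c1", "A", 1000, 0)])
        pct, binned = mag_read_fraction(asg, 100)
        assert pct["A"] == 0.0 and binned == 0.0

    def test_total_below_mapped_rejected(self):
        asg = make_assignment([("c1", "A", 1000, 200)])
        with pytest.raises(ValueError):
            mag_read_fraction(asg, 100)

    def test_invariant_to_contig_regrouping(self):
        one = make_assignment([("c1", "A", 3000, 300)])
        split = make_assignment([("c1", "A", 1000, 120), ("c2", "A", 2000, 180)])
        p1, _ = mag_read_fraction(one, 1000)
        p2, _ = mag_read_fraction(split, 1000)
        assert p1["A"] == pytest.approx(p2["A"])


class TestMagNormalizedAbundance:
    def test_length_normalization(self):
        asg = make_assignment([("c1", "A", 1000, 500), ("c2", "B", 2000, 500)])
        ab = mag_normalized_abundance(asg)
        assert ab["A"] == pytest.approx(2 / 3)
        assert ab["B"] == pytest.approx(1 / 3)

    def test_single_mag_is_one(self):
        asg = make_assignment([("c1", "A", 1000, 10)])
        assert mag_normalized_abundance(asg)["A"] == 1.0


class TestProteinWeightsFromFasta:
    def test_average_mass_from_sequence(self, tmp_path):
        fasta = tmp_path / "proteins.fasta"
        fasta.write_text(">prot_a test\nMKT\n>prot_b\nGGGG\n")
        mw = protein_weights_from_fasta(fasta)
        # M+K+T average residue masses + water
        assert mw["prot_a"] == pytest.approx(131.19 + 128.17 + 101.10 + 18.02, abs=0.2)
        assert mw["prot_b"] == pytest.approx(4 * 57.05 + 18.02, abs=0.2)
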