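"""Data-reduction operations: ratios, folds, growth rates, rates, SNPs."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acetoflux import (
    SNPRecord,
    TimeCourse,
    endpoint_ratio,
    fold_change,
    growth_rate,
    load_adaptation_snp_table,
    read_snp_table,
    read_timecourse_csv,
    snp_report,
    specific_rate,
    write_snp_table,
    write_timecourse_csv,
)

positive = st.floats(
    min_value=1e-3, max_value=1e3, allow_nan=False, allow_infinity=False
)


class TestEndpointRatio:
    @pytest.mark.parametrize(
        "consumed,produced,orientation,expected",
        [
            # 22.9 mM fructose -> 58.6 mM acetate
            (22.9, 58.6, "produced_per_consumed", 2.6),
            # Na+-depleted resting cells: 35.3 mM CO -> 31.9 mM formate
            (35.3, 31.9, "consumed_per_produced", 1.1),
            # 300 mM bicarbonate: 28.9 mM CO -> 25.6 mM formate
            (28.9, 25.6, "consumed_per_produced", 1.1),
            (7.0, 7.0, "produced_per_consumed", 1.0),
        ],
    )
    def test_printed_worked_examples(self, consumed, produced, orientation, expected):
        assert endpoint_ratio(consumed, produced, orientation=orientation) == expected

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            endpoint_ratio(0.0, 5.0)
        with pytest.raises(ValueError):
            endpoint_ratio(5.0, -1.0)

    @settings(derandomize=True, deadline=None)
    @given(a=positive, b=positive, k=positive)
    def test_scale_invariance(self, a, b, k):
        assert endpoint_ratio(k * a, k * b) == endpoint_ratio(a, b)


class TestFoldChange:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (27.3, 4.1, 6.7),  # Fd reduction from formate, mutant vs control
            (55.3, 2.2, 25),  # formate production from Fd2-, integer >= 10
            (3.14, 3.14, 1.0),
        ],
    )
    def test_printed_activity_folds(self, a, b, expected):
        assert fold_change(a, b) == expected

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)

    @settings(derandomize=True, deadline=None)
    @given(a=positive, b=positive, k=positive)
    def test_scale_invariance(self, a, b, k):
        assert fold_change(k * a, k * b) == fold_change(a, b)


class TestGrowthRate:
    def test_noiseless_exponential_recovered_exactly(self):
        t = np.arange(0.0, 48.0, 2.0)
        od = 0.05 * np.exp(0.05 * t)
        fit = growth_rate(TimeCourse(t, od, unit="OD600"))
        assert fit.mu == pytest.approx(0.05, abs=1e-9)
        assert fit.n_points == len(t)  # whole series: every window ties at R2=1
        assert not fit.degenerate

    @settings(derandomize=True, deadline=None)
    @given(k=st.floats(min_value=0.01, max_value=100.0))
    def test_invariant_to_od_scaling(self, k):
        t = np.arange(0.0, 48.0, 2.0)
        od = 0.05 * np.exp(0.03 * t)
        base = growth_rate(TimeCourse(t, od, unit="OD600"))
        scaled = growth_rate(TimeCourse(t, k * od, unit="OD600"))
        assert scaled.mu == pytest.approx(base.mu, rel=1e-9)
        assert scaled.window == base.window

    def test_constant_series_is_degenerate(self):
        t = np.arange(0.0, 20.0, 2.0)
        fit = growth_rate(TimeCourse(t, np.full_like(t, 0.3), unit="OD600"))
        assert fit.degenerate and fit.mu == 0.0 and fit.r_squared is None
        assert math.isinf(fit.doubling_time)

    def test_too_few_positive_points_rejected(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="positive OD"):
            growth_rate(TimeCourse(t, np.array([0.0, 0.0, 0.1, 0.2]), unit="OD600"))


class TestSpecificRate:
    def test_unit_arithmetic(self):
        """60 mM consumed in 60 min at 1 mg/mL is 1000 nmol/min/mg."""
        tc = TimeCourse(
            np.array([0.0, 1.0]), np.array([60.0, 0.0]), protein_conc=1.0
        )
        assert specific_rate(tc) == pytest.approx(1000.0)

    def test_zero_change_is_zero(self):
        tc = TimeCourse(
            np.array([0.0, 2.0]), np.array([5.0, 5.0]), protein_conc=1.0
        )
        assert specific_rate(tc) == 0.0

    def test_requires_protein_concentration(self):
        tc = TimeCourse(np.array([0.0, 1.0]), np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="protein_conc"):
            specific_rate(tc)

    def test_window_selects_samples(self):
        t = np.array([0.0, 0.5, 1.0, 2.0])
        v = np.array([100.0, 70.0, 40.0, 40.0])  # linear then exhausted
        tc = TimeCourse(t, v, protein_conc=2.0)
        # 60 mM over the first hour at 2 mg/mL
        assert specific_rate(tc, (0.0, 1.0)) == pytest.approx(500.0)


class TestSNPReport:
    def test_unique_fixed_variant_after_adaptation(self):
        """Only the HycB2 substitution sweeps to fixation on CO."""
        records = load_adaptation_snp_table()
        fixed = snp_report(records, "10th transfer", min_frequency=100.0)
        assert len(fixed) == 1
        assert fixed[0].gene == "hycB2"
        assert "R165P" in fixed[0].amino_acid_change

    def test_high_frequency_set(self):
        records = load_adaptation_snp_table()
        hits = snp_report(records, "10th transfer", min_frequency=75.0)
        assert [(r.gene, r.frequency_at("10th transfer")) for r in hits] == [
            ("hycB2", 100.0),
            ("modC2", 81.2),
            ("fdhC", 78.9),
        ]

    def test_min_zero_returns_all_sorted(self):
        records = load_adaptation_snp_table()
        out = snp_report(records, "10th transfer", min_frequency=0.0)
        assert len(out) == len(records) == 15
        freqs = [r.frequency_at("10th transfer") for r in out]
        assert freqs == sorted(freqs, reverse=True)
        # ties broken by ascending position -> ordering is total
        assert out == snp_report(records, "10th transfer", 0.0)

    def test_empty_input(self):
        assert snp_report([], "10th transfer", 50.0) == []

    def test_absent_timepoint_counts_as_zero(self):
        rec = SNPRecord(position=5, mutation="A->T", frequencies={"tp1": 40.0})
        assert rec.frequency_at("tp2") == 0.0
        assert snp_report([rec], "tp2", 10.0) == []

    def test_blank_cells_flagged_as_undetected(self):
        records = load_adaptation_snp_table()
        fdhc = next(r for r in records if r.gene == "fdhC")
        assert "before adaptation" in fdhc.undetected
        assert fdhc.frequency_at("before adaptation") == 0.0

    def test_malformed_frequency_names_row(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text(
            "position\tmutation\tfreq_before\tfreq_adapted\tfreq_10th"
            "\taa_change\tgene\tannotation\n"
            "100\tA->T\tlots\t1\t2\tX1Y\tg\tnote\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_snp_table(bad)

    def test_frequency_bounds_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            SNPRecord(position=1, mutation="A->T", frequencies={"t": 101.0})


class TestIO:
    def test_timecourse_csv_round_trip(self, tmp_path):
        a = TimeCourse(
            np.array([0.0, 1.0, 2.0]),
            np.array([100.0, 60.0, 20.0]),
            label="formate",
            protein_conc=1.0,
        )
        b = TimeCourse(
            np.array([0.0, 1.0, 2.0]),
            np.array([0.0, 10.0, 20.0]),
            label="acetate",
            protein_conc=1.0,
        )
        path = tmp_path / "conv.csv"
        write_timecourse_csv([a, b], path)
        back = {c.label: c for c in read_timecourse_csv(path)}
        assert set(back) == {"formate", "acetate"}
        np.testing.assert_allclose(back["formate"].values, a.values)
        assert back["acetate"].protein_conc == 1.0

    def test_metadata_comments_parsed(self):
        text = (
            "# protein_mg_per_ml: 2.5\n# unit: mM\n"
            "time_h,value\n0,10\n1,5\n2,0\n"
        )
        (course,) = read_timecourse_csv(io.StringIO(text))
        assert course.protein_conc == 2.5
        assert course.unit == "mM"

    def test_snp_table_round_trip(self, tmp_path):
        records = load_adaptation_snp_table()
        path = tmp_path / "snps.tsv"
        write_snp_table(records, path)
        back = read_snp_table(path)
        assert [r.position for r in back] == [r.position for r in records]
        assert back[1].frequencies == records[1].frequencies
        assert back[0].undetected == records[0].undetected

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            TimeCourse(np.array([0.0, 2.0, 1.0]), np.array([1.0, 2.0, 3.0]))
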