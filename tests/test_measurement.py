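import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from labeldyn.datasets import (
    glucose_lactate_measurements,
    glucose_only_measurements,
    printed_fit_glucose_only,
)
from labeldyn.measurement import (
    MeasurementTable,
    add_natural_abundance,
    chi_square,
    correct_natural_abundance,
    load_measurements,
    write_measurements,
)


def _table(rows):
    return MeasurementTable(
        pd.DataFrame(
            rows,
            columns=["experiment", "metabolite", "fragment", "quantity",
                     "mean", "sd", "units"],
        )
    )


class TestChiSquare:
    def test_perfect_agreement_is_zero(self):
        tab = _table([("e", "glc", "C1-C6", "m0", 0.5, 0.01, "fraction")])
        rep = chi_square({("glc", "C1-C6", "m0"): 0.5}, tab)
        assert rep.total == 0.0
        assert rep.n == 1

    def test_one_sigma_deviation_is_one(self):
        tab = _table([("e", "glc", "C1-C6", "m0", 0.5, 0.1, "fraction")])
        rep = chi_square({("glc", "C1-C6", "m0"): 0.4}, tab)
        assert rep.total == pytest.approx(1.0)

    def test_unmatched_row_raises_with_key(self):
        tab = _table([("e", "glc", "C1-C6", "m0", 0.5, 0.1, "fraction")])
        with pytest.raises(KeyError, match="glc"):
            chi_square({}, tab)

    def test_row_order_invariance(self):
        rows = [
            ("e", "glc", "C1-C6", "m0", 0.5, 0.1, "fraction"),
            ("e", "lac", "C1-C3", "m2", 0.2, 0.05, "fraction"),
            ("e", "glc", "C1-C6", "m1", 0.1, 0.02, "fraction"),
        ]
        sim = {
            ("glc", "C1-C6", "m0"): 0.45,
            ("glc", "C1-C6", "m1"): 0.12,
            ("lac", "C1-C3", "m2"): 0.25,
        }
        rep1 = chi_square(sim, _table(rows))
        rep2 = chi_square(sim, _table(rows[::-1]))
        assert rep1.total == pytest.approx(rep2.total)
        assert rep1.groups == pytest.approx(rep2.groups)

    def test_sd_scaling_property(self):
        rows = [("e", "glc", "C1-C6", "m0", 0.5, 0.1, "fraction")]
        scaled = [("e", "glc", "C1-C6", "m0", 0.5, 0.2, "fraction")]
        sim = {("glc", "C1-C6", "m0"): 0.43}
        assert chi_square(sim, _table(rows)).total == pytest.approx(
            4.0 * chi_square(sim, _table(scaled)).total
        )

    def test_sd_zero_rejected(self):
        with pytest.raises(ValueError):
            _table([("e", "glc", "C1-C6", "m0", 0.5, 0.0, "fraction")])


@pytest.fixture(scope="module")
def reports():
    tab = glucose_only_measurements()
    df = printed_fit_glucose_only()
    out = {}
    for col in ("channeling", "mixed"):
        sim = {
            (r.metabolite, r.fragment, r.quantity): getattr(r, col)
            for r in df.itertuples()
        }
        out[col] = chi_square(sim, tab)
    return out


class TestPrintedTableRecomputation:
    """Per-group χ² recomputed from the printed measured and simulated values."""

    @pytest.mark.parametrize(
        "model, metabolite, fragment, printed",
        [
            ("channeling", "glucose", "C1-C6", 0.442),
            ("channeling", "glutamate", "C2-C5", 0.0564),
            ("channeling", "lactate", "C1-C3", 1.43),
            ("channeling", "glycogen", "C1-C6", 1.2),
            ("mixed", "glucose", "C1-C6", 0.406),
            ("mixed", "lactate", "C1-C3", 7.32),
            ("mixed", "glycogen", "C1-C6", 30.5),
        ],
    )
    def test_group_chi2_matches_printed(self, reports, model, metabolite,
                                        fragment, printed):
        got = reports[model].group(metabolite, fragment)
        tol = max(0.1, 0.25 * printed)
        assert got == pytest.approx(printed, abs=tol)

    def test_whole_molecule_sum_matches_printed(self, reports):
        frag_groups = {("glycogen", "C1-C4"), ("glycogen", "C3-C6")}
        for model, printed in (("channeling", 3.13), ("mixed", 38.28)):
            sigma1 = sum(
                v for k, v in reports[model].groups.items()
                if k not in frag_groups
            )
            assert sigma1 == pytest.approx(printed, abs=max(0.5, 0.12 * printed))


class TestNaturalAbundance:
    def test_zero_abundance_is_identity(self):
        raw = np.array([0.6, 0.3, 0.1, 0.0])
        out = correct_natural_abundance(raw, 3, p13c=0.0)
        assert np.allclose(out, raw)

    def test_unlabeled_glucose_spectrum_corrects_to_m0(self):
        pure = np.zeros(7)
        pure[0] = 1.0
        raw = add_natural_abundance(pure, 6)
        assert raw[1] > 0  # natural abundance shifts some mass up
        out = correct_natural_abundance(raw, 6)
        assert out[0] == pytest.approx(1.0, abs=1e-12)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=7, max_size=7)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_forward_then_correct_round_trip(self, values):
        total = sum(values)
        if total < 1e-6:
            return
        true = np.array(values) / total
        raw = add_natural_abundance(true, 6)
        out = correct_natural_abundance(raw, 6)
        assert np.allclose(out, true, atol=1e-9)

    def test_bad_abundance_rejected(self):
        with pytest.raises(ValueError):
            correct_natural_abundance(np.array([1.0, 0.0]), 1, p13c=0.6)


class TestIO:
    def test_packaged_fixture_row_counts(self):
        tab = glucose_only_measurements()
        assert len(tab) == 28
        whole = tab.data[~tab.data.fragment.isin(["C1-C4", "C3-C6"])]
        assert len(whole) == 22  # the whole-molecule + concentration points
        both = glucose_lactate_measurements()
        assert set(both.experiments()) == {
            "glucose_lactate_labelglc", "glucose_lactate_labellac"
        }

    def test_round_trip(self, tmp_path):
        tab = glucose_only_measurements()
        path = tmp_path / "out.csv"
        write_measurements(tab, path)
        again = load_measurements(path)
        pd.testing.assert_frame_equal(
            again.data, tab.data.reset_index(drop=True), check_dtype=False
        )

    def test_malformed_row_reported_with_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "experiment,metabolite,fragment,quantity,mean,sd,units\n"
            "e,glc,C1-C6,m0,not_a_number,0.1,fraction\n"
        )
        with pytest.raises(ValueError, match="bad.csv:2"):
            load_measurements(path)

    def test_missing_experiment_slice_raises(self):
        with pytest.raises(KeyError):
            glucose_only_measurements().for_experiment("nope")
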