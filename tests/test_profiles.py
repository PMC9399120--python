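"""Plate-control subtraction, consensus aggregation, cytotoxicity filter."""

import numpy as np
import pandas as pd
import pytest

from mitofusion import profiles, synthetic
from mitofusion.errors import ConfigurationError, NormalizationError


def wells_frame(rows):
    return pd.DataFrame(rows, columns=["plate", "well", "compound_id",
                                       "dose", "f"])


def dose_retention_oracle(doses):
    """Brute-force within-one-sample-SD interval check."""
    doses = np.asarray(doses, dtype=float)
    mean, sd = doses.mean(), doses.std(ddof=1)
    return [d for d in doses if mean - sd <= d <= mean + sd]


class TestSubtractPlateControl:
    def test_subtracts_plate_dmso_mean(self):
        wells = wells_frame([
            ("P1", "A01", "DMSO", 0.0, 10.0),
            ("P1", "A02", "X", 1.0, 12.0),
        ])
        out = profiles.subtract_plate_control(wells)
        assert out.loc[1, "f"] == pytest.approx(2.0)

    def test_dmso_wells_center_to_zero_mean(self):
        wells = wells_frame([
            ("P1", "A01", "DMSO", 0.0, 8.0),
            ("P1", "A02", "DMSO", 0.0, 12.0),
            ("P1", "A03", "X", 1.0, 15.0),
        ])
        out = profiles.subtract_plate_control(wells)
        dmso = out.loc[out["compound_id"] == "DMSO", "f"]
        assert dmso.mean() == pytest.approx(0.0)

    def test_per_plate_correction_differs(self):
        # same raw perturbation value on plates with different DMSO means
        wells = wells_frame([
            ("P1", "A01", "DMSO", 0.0, 10.0),
            ("P1", "A02", "X", 1.0, 12.0),
            ("P2", "A01", "DMSO", 0.0, 4.0),
            ("P2", "A02", "Y", 1.0, 12.0),
        ])
        out = profiles.subtract_plate_control(wells)
        assert out.loc[1, "f"] == pytest.approx(2.0)
        assert out.loc[3, "f"] == pytest.approx(8.0)

    def test_between_compound_differences_unchanged_within_plate(self):
        wells = wells_frame([
            ("P1", "A01", "DMSO", 0.0, 7.0),
            ("P1", "A02", "X", 1.0, 12.5),
            ("P1", "A03", "Y", 1.0, 9.0),
        ])
        out = profiles.subtract_plate_control(wells)
        assert (out.loc[1, "f"] - out.loc[2, "f"]) == pytest.approx(3.5)

    def test_plate_without_dmso_is_an_error_naming_the_plate(self):
        wells = wells_frame([
            ("P1", "A01", "DMSO", 0.0, 10.0),
            ("P2", "A01", "X", 1.0, 12.0),
        ])
        with pytest.raises(NormalizationError, match="P2"):
            profiles.subtract_plate_control(wells)


class TestConsensus:
    def test_replicate_median(self):
        wells = wells_frame([
            ("P1", "A01", "DMSO", 0.0, 0.0),
            ("P1", "A02", "X", 1.0, 1.0),
            ("P1", "A03", "X", 1.0, 2.0),
            ("P1", "A04", "X", 1.0, 9.0),
        ])
        cons = profiles.consensus(wells)
        assert cons.loc["X", "f"] == pytest.approx(2.0)
        assert cons.loc["X", "concentration"] == pytest.approx(1.0)

    def test_single_dose_degenerate(self):
        wells = wells_frame([
            ("P1", "A01", "DMSO", 0.0, 0.0),
            ("P1", "A02", "X", 5.0, 3.0),
        ])
        cons = profiles.consensus(wells)
        assert cons.loc["X", "f"] == pytest.approx(3.0)
        assert cons.loc["X", "concentration"] == pytest.approx(5.0)

    @pytest.mark.parametrize("doses", [[1.0, 2.0, 3.0, 100.0],
                                       [1.0, 1.0, 1.0, 100.0],
                                       [0.3, 1.0, 3.0, 10.0]])
    def test_dose_retention_matches_brute_force_oracle(self, doses):
        rows = [("P1", "A00", "DMSO", 0.0, 0.0)]
        rows += [("P1", f"A{i:02d}", "X", d, float(d))
                 for i, d in enumerate(dict.fromkeys(doses), start=1)]
        cons = profiles.consensus(wells_frame(rows))
        retained = dose_retention_oracle(sorted(set(doses)))
        assert cons.loc["X", "f"] == pytest.approx(np.median(retained))
        assert cons.loc["X", "concentration"] == pytest.approx(
            np.median(retained))

    def test_permutation_invariant_over_well_order(self, small_dataset):
        wells = small_dataset.well_table
        shuffled = wells.sample(frac=1.0, random_state=0)
        a = profiles.consensus(wells)
        b = profiles.consensus(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_global_dose_stats_mode_runs(self):
        wells = wells_frame([
            ("P1", "A01", "DMSO", 0.0, 0.0),
            ("P1", "A02", "X", 1.0, 1.0),
            ("P1", "A03", "X", 10.0, 5.0),
            ("P1", "A04", "Y", 1.0, 2.0),
        ])
        cons = profiles.consensus(wells, dose_stats="global")
        assert set(cons.index) == {"X", "Y"}
        with pytest.raises(ConfigurationError):
            profiles.consensus(wells, dose_stats="bogus")


class TestCellCountFilter:
    def _profiles(self, values):
        return pd.DataFrame(
            {profiles.CELL_COUNT_FEATURE: values, "other": 0.0},
            index=[f"C{i}" for i in range(len(values))])

    def test_threshold_spares_symmetric_cohort(self):
        # mean 0, sample SD ~15.81 -> threshold ~ -23.7: nothing excluded
        pset = profiles.filter_low_cellcount(
            self._profiles([-20.0, -10.0, 0.0, 10.0, 20.0]))
        assert len(pset.excluded) == 0
        assert pset.excluded.attrs["threshold"] == pytest.approx(
            -23.717, abs=1e-3)

    def test_threshold_catches_outlier(self):
        # mean -8, sample SD ~17.9 -> threshold ~ -34.8: -40 is excluded
        pset = profiles.filter_low_cellcount(
            self._profiles([-40.0, 0.0, 0.0, 0.0, 0.0]))
        assert list(pset.excluded["compound_id"]) == ["C0"]
        assert (pset.excluded["reason"] == "cytotoxic").all()
        assert len(pset.retained) == 4

    def test_fixed_threshold_mode(self):
        pset = profiles.filter_low_cellcount(
            self._profiles([-20.0, -10.0, 0.0]), fixed_threshold=-15.0)
        assert list(pset.excluded["compound_id"]) == ["C0"]

    def test_missing_feature_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="Cells_Number"):
            profiles.filter_low_cellcount(
                pd.DataFrame({"other": [1.0, 2.0]}))

    def test_recall_of_planted_cytotoxic_compounds(self):
        """Cohort-statistics threshold recovers >= 90% of compounds whose
        cell count was depressed by 3 SD, pooled over 10 seeds."""
        hits, total = 0, 0
        for seed in range(10):
            cfg = synthetic.SyntheticConfig(
                n_compounds=200, n_cp_features=40, n_ge_features=5,
                n_planted_cp=0, n_planted_ge=0, cytotoxic_fraction=0.1,
                cytotoxic_depression_sd=3.0, n_inconclusive=0,
                fp_bits=32, n_scaffolds=4, seed=seed)
            ds = synthetic.generate(cfg)
            cons = profiles.consensus(
                profiles.subtract_plate_control(ds.well_table))
            pset = profiles.filter_low_cellcount(cons)
            truth = {c for c, f in ds.truth["cytotoxic"].items() if f}
            flagged = set(pset.excluded["compound_id"])
            hits += len(truth & flagged)
            total += len(truth)
        assert hits / total >= 0.9


class TestBlocklist:
    def test_empty_blocklist_is_identity(self, small_tables):
        cp = small_tables[0]["cp"]
        pd.testing.assert_frame_equal(profiles.drop_blocklisted(cp, []), cp)

    def test_removes_named_features(self, small_tables):
        cp = small_tables[0]["cp"]
        names = list(cp.columns[:2])
        out = profiles.drop_blocklisted(cp, names)
        assert out.shape[1] == cp.shape[1] - 2

    def test_absent_names_warn_without_change(self, small_tables, caplog):
        cp = small_tables[0]["cp"]
        with caplog.at_level("WARNING"):
            out = profiles.drop_blocklisted(cp, ["not_a_feature"])
        pd.testing.assert_frame_equal(out, cp)
        assert "absent" in caplog.text
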