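"""Truth classification, power metrics and the experiment grid."""

import numpy as np
import pandas as pd
import pytest

from polyqtl import (
    ExperimentConfig,
    QTLInterval,
    classify,
    detection_power,
    false_positive_rate,
    peak_accuracy,
    precisions,
    run_experiment,
)
from polyqtl.genmap import QTLSpec
from polyqtl.mixedmodel import ScanResult, VarianceComponents
from polyqtl.phenotype import PhenotypeParams
from polyqtl.power import summarize


def _scan(positions, neglog10p, chroms):
    table = pd.DataFrame(
        {
            "locus": [f"m{i}" for i in range(len(positions))],
            "chromosome": chroms,
            "position_cM": positions,
            "F": 1.0,
            "df1": 1,
            "neglog10p": neglog10p,
            "flag": "ok",
        }
    )
    return ScanResult(table, "snp", VarianceComponents(0.0, 1.0))


def _iv(chrom, positions, neglog10p=None):
    positions = list(map(float, positions))
    neglog10p = neglog10p or [5.0] * len(positions)
    return QTLInterval(chrom, [f"x{p}" for p in positions], positions, neglog10p)


TRUTH = [("2", 61.2)]


class TestClassify:
    def test_containing_interval_is_true_positive(self):
        scan = _scan([60.0, 63.1], [5.0, 5.0], ["2", "2"])
        cls = classify([_iv("2", [60.0, 63.1])], scan, TRUTH, threshold=3.0)
        assert cls.is_true_positive == [True]
        assert cls.covered_truths == [True]

    def test_distant_interval_markers_are_false_positives(self):
        scan = _scan([40.0, 45.0], [5.0, 5.0], ["2", "2"])
        cls = classify([_iv("2", [40.0, 45.0])], scan, TRUTH, threshold=3.0)
        assert cls.is_true_positive == [False]
        assert cls.n_tp_interval_markers == 0
        assert cls.n_interval_markers == 2

    def test_window_membership_arithmetic(self):
        # marker at 65.9 is 4.7 cM from the truth: inside the +/-5 window,
        # hence excluded from the true negatives N
        scan = _scan([65.9, 70.0, 10.0], [1.0, 1.0, 1.0], ["2", "2", "2"])
        cls = classify([], scan, TRUTH, threshold=3.0)
        assert cls.n_true_negative_markers == 2

    def test_isolated_significant_markers_count_toward_rate_only(self):
        scan = _scan([10.0, 70.0], [5.0, 5.0], ["2", "2"])
        cls = classify([], scan, TRUTH, threshold=3.0)
        assert cls.n_fp_markers_outside_windows == 2
        assert cls.n_interval_markers == 0


class TestMetrics:
    def test_detection_counts_each_truth_once(self):
        truth3 = [("1", 10.0), ("2", 20.0), ("3", 30.0)]
        scan = _scan([9.0, 11.0], [5.0, 5.0], ["1", "1"])
        ivs = [_iv("1", [9.0, 10.5]), _iv("1", [9.5, 11.0])]  # both cover truth 1
        cls = classify(ivs, scan, truth3, threshold=3.0)
        assert detection_power(cls) == pytest.approx(1 / 3)

    def test_full_and_zero_detection(self):
        truth3 = [("1", 10.0), ("2", 20.0), ("3", 30.0)]
        scan = _scan([10.0], [1.0], ["1"])
        ivs = [_iv(c, [p - 1, p + 1]) for c, p in truth3]
        assert detection_power(classify(ivs, scan, truth3, threshold=3.0)) == 1.0
        assert detection_power(classify([], scan, truth3, threshold=3.0)) == 0.0

    def test_false_positive_rate_arithmetic(self):
        # 6 markers outside windows, 2 significant -> 1/3
        scan = _scan([1, 5, 9, 13, 17, 21], [5.0, 5.0, 1, 1, 1, 1], ["1"] * 6)
        cls = classify([], scan, [("1", 40.0)], threshold=3.0)
        assert false_positive_rate(cls) == pytest.approx(1 / 3)

    def test_rate_undefined_when_no_true_negatives(self):
        scan = _scan([61.0, 62.0], [5.0, 1.0], ["2", "2"])
        cls = classify([], scan, TRUTH, threshold=3.0)
        assert false_positive_rate(cls) is None

    def test_precisions_formulae(self):
        scan = _scan([60.0, 61.5, 40.0, 41.0], [5.0] * 4, ["2"] * 4)
        ivs = [_iv("2", [60.0, 61.5]), _iv("2", [40.0, 41.0])]
        cls = classify(ivs, scan, TRUTH, threshold=3.0)
        qtl_p, marker_p = precisions(cls)
        assert qtl_p == pytest.approx(0.5)
        assert marker_p == pytest.approx(0.5)

    def test_precisions_undefined_without_intervals(self):
        scan = _scan([60.0], [1.0], ["2"])
        cls = classify([], scan, TRUTH, threshold=3.0)
        assert precisions(cls) == (None, None)

    def test_peak_accuracy_mean_distance(self):
        truth = [("1", 61.2), ("2", 20.0)]
        scan = _scan([60.7], [5.0], ["1"])
        ivs = [
            _iv("1", [60.0, 60.7, 62.0], [4.0, 6.0, 4.0]),  # peak 60.7, truth 61.2
            _iv("2", [19.5, 20.5, 21.0], [4.0, 6.0, 4.0]),  # peak 20.5, truth 20.0
        ]
        cls = classify(ivs, scan, truth, threshold=3.0)
        assert peak_accuracy(cls) == pytest.approx(0.5 * (0.5 + 0.5))

    def test_peak_accuracy_absent_without_true_positives(self):
        scan = _scan([10.0], [1.0], ["2"])
        cls = classify([_iv("2", [10.0, 11.0])], scan, TRUTH, threshold=3.0)
        assert peak_accuracy(cls) is None


@pytest.fixture(scope="module")
def tiny_experiment():
    config = ExperimentConfig(
        diversity_levels=(1,),
        replicates=1,
        models=("snp",),
        l_grid=(0.0, 1.0, 3.0),
        n_perm=20,
        n_ags=3,
        n_founders=4,
        generations=2,
        ag_size=12,
        offspring_per_cross=5,
        n_chromosomes=1,
        n_markers=120,
        qtls=QTLSpec(major_qtls=(("1", 67.88),), n_polygenic=5),
        phenotype=PhenotypeParams(),
        seed=123,
    )
    return config, run_experiment(config)


class TestRunExperiment:
    def test_one_row_per_l(self, tiny_experiment):
        config, df = tiny_experiment
        assert (df["error"] == "").all()
        assert len(df) == len(config.l_grid)

    def test_rerun_is_bit_identical(self, tiny_experiment):
        config, df = tiny_experiment
        df2 = run_experiment(config)
        pd.testing.assert_frame_equal(df, df2)

    def test_summary_excludes_missing_values(self):
        df = pd.DataFrame(
            {
                "diversity": [1, 1],
                "replicate": [0, 1],
                "model": ["snp", "snp"],
                "l": [3.0, 3.0],
                "detection_power": [1.0, 0.0],
                "false_positive_rate": [0.1, None],
                "qtl_precision": [None, None],
                "marker_precision": [1.0, 0.5],
                "peak_accuracy_cM": [0.2, None],
                "error": ["", ""],
            }
        )
        s = summarize(df)
        row = s.iloc[0]
        assert row["false_positive_rate"] == pytest.approx(0.1)
        assert np.isnan(row["qtl_precision"])
        assert row["detection_power"] == pytest.approx(0.5)

    def test_scaled_config(self):
        c = ExperimentConfig().scaled(0.25)
        assert c.n_chromosomes == 2
        assert c.replicates == 3
        assert c.n_perm >= 20
        with pytest.raises(ValueError):
            ExperimentConfig().scaled(0.0)

    def test_report_fields_respect_bounds(self, tiny_experiment):
        _, df = tiny_experiment
        for col in ("detection_power", "false_positive_rate", "qtl_precision", "marker_precision"):
            vals = df[col].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()
        acc = df["peak_accuracy_cM"].dropna()
        assert (acc >= 0).all()
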