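"""KM estimation, log-rank oracle, scans, escape classification, Cox drugs."""

import numpy as np
import pandas as pd
import pytest

from tumordnds.cohort_io import ClinicalRecord
from tumordnds.regression import PairedObservation
from tumordnds.survival import (
    IN_GROUP_BETTER,
    IN_GROUP_WORSE,
    SurvivalDataError,
    classify_neutral_escape,
    cox_drug_effects,
    km_estimate,
    logrank,
    paired_scan,
    range_scan,
)


def surv(times_events):
    return np.array(times_events, dtype=float)


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        # events at 1 and 3, censoring at 2: S(1)=2/3, S(3)=0
        curve = km_estimate(surv([(1, 1), (2, 0), (3, 1)]))
        assert curve.probability_at(1) == pytest.approx(2 / 3)
        assert curve.probability_at(2.5) == pytest.approx(2 / 3)
        assert curve.probability_at(3) == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        curve = km_estimate(surv([(1, 0), (2, 0), (3, 0)]))
        assert curve.probability_at(3) == pytest.approx(1.0)
        assert len(curve.censor_times) == 3

    def test_single_event_drops_to_zero(self):
        curve = km_estimate(surv([(5, 1)]))
        assert curve.probability_at(4.9) == pytest.approx(1.0)
        assert curve.probability_at(5) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        for _ in range(100):
            times = rng.exponential(10, size=int(rng.integers(3, 20)))
            curve = km_estimate(surv([(t, 1) for t in times]))
            for t in rng.uniform(0, 20, 5):
                empirical = np.mean(times > t)
                assert curve.probability_at(t) == pytest.approx(empirical)

    def test_empty_input_rejected(self):
        with pytest.raises(SurvivalDataError):
            km_estimate([])


class TestLogrank:
    def test_identical_groups(self):
        group = surv([(1, 1), (2, 1), (3, 0)])
        chi2, p = logrank(group, group)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # A events at 1,2; B events at 3,4; no censoring:
        # O-E = 7/6, V = 0.25 + 2/9 -> chi2 = (7/6)^2 / (17/36) = 2.882
        chi2, _ = logrank(surv([(1, 1), (2, 1)]), surv([(3, 1), (4, 1)]))
        assert chi2 == pytest.approx((7 / 6) ** 2 / (17 / 36), rel=1e-6)

    def test_label_swap_invariance(self, rng):
        a = surv([(t, 1) for t in rng.exponential(5, 20)])
        b = surv([(t, 1) for t in rng.exponential(8, 25)])
        assert logrank(a, b)[0] == pytest.approx(logrank(b, a)[0])

    def test_zero_event_group_warns_but_computes(self):
        with pytest.warns(UserWarning):
            chi2, p = logrank(surv([(1, 0), (2, 0)]), surv([(1, 1), (2, 1)]))
        assert 0 <= p <= 1


class TestRangeScan:
    @staticmethod
    def cohort(rng, n=200, beta=2.0):
        dnds = np.exp(rng.uniform(np.log(0.3), np.log(3), n))
        dis = np.abs(1 - dnds)
        rate = 0.05 * np.exp(beta * (0.5 - dis))
        time = rng.exponential(1 / rate)
        return pd.DataFrame(dict(dnds=dnds, time=time, event=1))

    def test_membership_counts_partition_cohort(self, rng):
        data = self.cohort(rng)
        result = range_scan(data, [0.8, 1.0, 1.2], [0.1, 0.3])
        assert (result.cells["n_in"] + result.cells["n_out"] == len(data)).all()

    def test_neutral_cell_detects_worse_prognosis(self, rng):
        data = self.cohort(rng, n=200, beta=2.0)
        result = range_scan(data, [1.0], [0.2])
        cell = result.cells.iloc[0]
        assert not cell["masked"]
        assert cell["p"] < 0.05
        assert cell["direction"] == IN_GROUP_WORSE

    def test_oversized_sigma_masks_cell(self, rng):
        data = self.cohort(rng, n=30)
        result = range_scan(data, [1.0], [10.0])  # everyone inside
        assert bool(result.cells.iloc[0]["masked"])

    def test_missing_column_rejected(self):
        with pytest.raises(SurvivalDataError):
            range_scan(pd.DataFrame(dict(dnds=[1.0])), [1.0], [0.1])


class TestEscapeClassification:
    @pytest.mark.parametrize(
        "dnds_1, dnds_2, dis_thr, delta_thr, expected",
        [
            (1.0, 1.0, 0.3, 0.3, "neutral"),
            (0.9, 0.5, 0.3, 0.3, "escape"),  # dis = 0.5 >= 0.3
            (1.0, 1.05, 0.3, 0.02, "neutral"),  # big delta but inside 1 +/- 0.1
            (0.5, 1.3, 0.4, 0.3, "escape"),  # delta 0.8, ends outside the band
            (1.5, 0.7, 0.4, 0.3, "escape"),  # negative swing counts via |delta|
        ],
    )
    def test_rule(self, dnds_1, dnds_2, dis_thr, delta_thr, expected):
        pair = PairedObservation("p", dnds_1, dnds_2)
        assert classify_neutral_escape(pair, dis_thr, delta_thr) == expected

    def test_signed_delta_option(self):
        pair = PairedObservation("p", 1.5, 0.7)  # delta = -0.8
        assert classify_neutral_escape(pair, 0.4, 0.3, signed_delta=True) == "neutral"

    @pytest.mark.parametrize("dis_thr, delta_thr", [(0.38, 0.24), (0.32, 0.3)])
    def test_reported_grid_points_classify_cleanly(self, dis_thr, delta_thr):
        near = PairedObservation("p", 1.2, 1.02)
        far = PairedObservation("q", 1.0, 1.6)
        assert classify_neutral_escape(near, dis_thr, delta_thr) == "neutral"
        assert classify_neutral_escape(far, dis_thr, delta_thr) == "escape"


class TestPairedScan:
    @staticmethod
    def build(rng, n=150, neutral_hazard_ratio=2.0):
        pairs, clinical = [], {}
        for i in range(n):
            pid = f"p{i}"
            dnds_1 = float(np.exp(rng.uniform(np.log(0.4), np.log(2.5))))
            near = rng.random() < 0.5
            dnds_2 = float(rng.normal(1.0, 0.05)) if near else float(
                rng.choice([-1, 1]) * rng.uniform(0.4, 0.8) + 1
            )
            pair = PairedObservation(pid, dnds_1, dnds_2)
            rate = 0.1 * (neutral_hazard_ratio if near else 1.0)
            clinical[pid] = ClinicalRecord(pid, float(rng.exponential(1 / rate)), True)
            pairs.append(pair)
        return pairs, clinical

    def test_neutral_class_worse_detected(self, rng):
        pairs, clinical = self.build(rng)
        result = paired_scan(pairs, clinical, [0.2, 0.3], [0.2, 0.3])
        unmasked = result.unmasked
        assert (unmasked["p"] < 0.05).any()
        significant = unmasked[unmasked["p"] < 0.05]
        assert (significant["direction"] == IN_GROUP_WORSE).all()

    def test_all_escape_cell_masked(self, rng):
        pairs, clinical = self.build(rng, n=20)
        result = paired_scan(pairs, clinical, [0.0], [0.0])  # everyone escapes
        assert bool(result.cells.iloc[0]["masked"])

    def test_unlinked_pairs_rejected(self):
        with pytest.raises(SurvivalDataError):
            paired_scan([PairedObservation("p", 1.0, 1.0)], {}, [0.1], [0.1])


class TestCoxDrugs:
    @staticmethod
    def frame(rng, n=400, effect=0.5):
        exposed = rng.random(n) < 0.5
        other = rng.random(n) < 0.5
        scale = np.where(exposed, 0.5 * effect, 0.5)
        return pd.DataFrame(
            dict(dis=rng.exponential(scale),
                 drug_X=exposed.astype(int),
                 drug_Y=other.astype(int))
        )

    def test_halved_scale_doubles_hazard(self, rng):
        result = cox_drug_effects(self.frame(rng))
        row = result.loc["drug_X"]
        assert row["ci_low"] < 2.0 < row["ci_high"]
        assert result.loc["drug_Y", "ci_low"] < 1.0 < result.loc["drug_Y", "ci_high"]

    def test_never_administered_drug_dropped(self, rng):
        frame = self.frame(rng, n=200)
        frame["drug_Z"] = 0
        with pytest.warns(UserWarning, match="drug_Z"):
            result = cox_drug_effects(frame)
        assert "drug_Z" not in result.index

    def test_requires_two_contrasting_drugs(self, rng):
        frame = self.frame(rng, n=50)[["dis", "drug_X"]]
        with pytest.raises(SurvivalDataError):
            cox_drug_effects(frame)

    def test_negative_dis_rejected(self):
        with pytest.raises(SurvivalDataError):
            cox_drug_effects(pd.DataFrame(dict(dis=[-0.1, 0.2], drug_A=[0, 1], drug_B=[1, 0])))
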