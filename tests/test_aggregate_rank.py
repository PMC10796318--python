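import numpy as np
import pandas as pd
import pytest

from slimscan.aggregate_rank import (
    cross_partner_matrix,
    pool_protocols,
    rank_scan,
    replicate_from_score_table,
    select_best,
    stratified_success,
    success_rate,
)
from slimscan.formats_io import Region
from slimscan.msa_coalign import build_coalignment
from slimscan.predict_backend import MockBackend, PredictedModel, confidence_score
from slimscan.quality_eval import CapriClass
from slimscan.synthetic_fixtures import make_msa_pair


def model(ptm=0.7, iptm=0.8, run=0, idx=0, protocol="p"):
    return PredictedModel(
        structure=None,
        plddt=np.full(10, 80.0),
        ptm=ptm,
        iptm=iptm,
        confidence=confidence_score(ptm, iptm),
        protocol=protocol,
        run_index=run,
        model_index=idx,
        seed=0,
    )


class TestSelectBest:
    def test_unique_maximum(self):
        pool = [model(iptm=0.1 + 0.03 * i, idx=i) for i in range(25)]
        assert select_best(pool, "confidence") is pool[-1]

    def test_ties_break_to_lower_run_then_model(self):
        a = model(run=3, idx=0)
        b = model(run=1, idx=2)
        c = model(run=1, idx=4)
        assert select_best([a, b, c], "confidence") is b

    def test_key_choice_can_reverse_winners(self):
        # same confidence ordering trick: high ptm lifts confidence, not iptm
        by_iptm = model(ptm=0.2, iptm=0.9)
        by_conf = model(ptm=1.0, iptm=0.85)
        pool = [by_iptm, by_conf]
        assert select_best(pool, "iptm") is by_iptm
        assert select_best(pool, "confidence") is by_conf

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            select_best([], "confidence")


class TestPooling:
    def test_four_pools_of_25_give_100(self):
        pools = {p: [model(protocol=p) for _ in range(25)] for p in "abcd"}
        assert len(pool_protocols(pools)) == 100

    def test_combined_best_is_max_of_per_protocol_bests(self):
        rng = np.random.default_rng(0)
        pools = {
            p: [model(iptm=float(rng.uniform(0, 1)), idx=i) for i in range(25)]
            for p in "abcd"
        }
        combined = pool_protocols(pools)
        best = select_best(combined, "confidence").confidence
        assert best == max(
            select_best(v, "confidence").confidence for v in pools.values()
        )

    def test_empty_protocol_shrinks_pool_with_warning(self, caplog):
        pools = {"a": [model() for _ in range(25)], "b": []}
        pools["c"] = [model() for _ in range(25)]
        pools["d"] = [model() for _ in range(25)]
        assert len(pool_protocols(pools)) == 75


class TestRankScan:
    def test_highest_overlapping_fragment_wins(self):
        results = [
            (Region(1, 100), 0.3),
            (Region(71, 170), 0.8),
            (Region(141, 240), 0.5),
        ]
        v = rank_scan(results, motif=Region(120, 140))
        assert v.success is True
        assert v.top_fragment == Region(71, 170)

    def test_failure_when_non_overlapping_scores_highest(self):
        results = [(Region(1, 100), 0.9), (Region(71, 170), 0.4)]
        v = rank_scan(results, motif=Region(150, 160))
        assert v.success is False
        assert v.best_overlapping == (Region(71, 170), 0.4)

    def test_only_best_of_several_overlapping_reported(self):
        results = [(Region(1, 100), 0.6), (Region(71, 170), 0.4)]
        v = rank_scan(results, motif=Region(90, 110))  # overlaps both
        assert v.best_overlapping == (Region(1, 100), 0.6)

    def test_no_motif_gives_ranking_only(self):
        v = rank_scan([(Region(1, 100), 0.2)])
        assert v.success is None


class TestSuccessRate:
    def test_benchmark_arithmetic(self):
        classes = [CapriClass.Acceptable] * 18 + [CapriClass.Incorrect] * 24
        s = success_rate(classes)
        assert s.n_cases == 42
        assert s.success_rate == 42.9  # 18/42 to one decimal

    def test_all_high(self):
        s = success_rate([CapriClass.High] * 7)
        assert s.success_rate == 100.0
        assert s.class_counts[CapriClass.High] == 7

    def test_none_acceptable(self):
        assert success_rate([CapriClass.Incorrect] * 5).success_rate == 0.0

    def test_counts_partition_cases(self):
        classes = [CapriClass.High, CapriClass.Medium, CapriClass.Incorrect]
        s = success_rate(classes)
        assert sum(s.class_counts.values()) == s.n_cases == 3


class TestStratifiedSuccess:
    def test_all_successful_means_100_with_zero_sd(self):
        cases = {"a": [True] * 3, "b": [True] * 7}
        mean, sd = stratified_success(cases, n_iter=1000, seed=1)
        assert mean == 100.0 and sd == 0.0

    def test_two_categories_of_known_rates_average_to_half(self):
        cases = {"good": [True] * 10, "bad": [False] * 10}
        mean, sd = stratified_success(cases, n_iter=1000, seed=2)
        assert mean == 50.0 and sd == 0.0  # draws are deterministic per category

    def test_singleton_categories_have_no_sampling_variance(self):
        cases = {"a": [True], "b": [False], "c": [True], "d": [True]}
        mean, sd = stratified_success(cases, n_iter=200, seed=3)
        assert sd == 0.0
        assert mean == pytest.approx(75.0)

    def test_mixed_category_converges_with_mc_error(self):
        cases = {"a": [True, False], "b": [True] * 2}
        mean, sd = stratified_success(cases, n_iter=1000, seed=4)
        # expectation: (0.5 + 1.0)/2 = 75%; MC se of the mean ~ 0.6%
        assert mean == pytest.approx(75.0, abs=3 * 0.6)

    def test_reproducible_given_seed(self):
        cases = {"a": [True, False, False], "b": [True, True, False]}
        assert stratified_success(cases, seed=7) == stratified_success(cases, seed=7)

    def test_empty_category_rejected(self):
        with pytest.raises(ValueError):
            stratified_success({"a": []})


class TestCrossPartner:
    def _setup(self, ceilings):
        rec, lig = make_msa_pair(4, 3, 2, seed=0, ligand_length=30)
        coaln = build_coalignment([rec], lig, mode="no_ligand_msa")
        receptors = {
            rid: {lid: coaln for lid in ceilings[rid]} for rid in ceilings
        }

        def factory(rid, lid):
            return MockBackend(
                planted=(Region(1, 30), ceilings[rid][lid])
            )

        return receptors, factory

    def test_cognate_planted_highest_is_top_ranked(self):
        ceilings = {
            "r1": {"l1": 0.9, "l2": 0.4, "l3": 0.3},
            "r2": {"l1": 0.3, "l2": 0.85, "l3": 0.2},
        }
        receptors, factory = self._setup(ceilings)
        report = cross_partner_matrix(
            receptors, ["l1", "l2", "l3"], factory,
            cognate={"r1": "l1", "r2": "l2"},
        )
        assert report.cognate_top == {"r1": True, "r2": True}
        assert report.n_discriminated == 2

    def test_receptor_without_cognate_rejected(self):
        receptors, factory = self._setup({"r1": {"l1": 0.5}})
        with pytest.raises(ValueError, match="cognate"):
            cross_partner_matrix(receptors, ["l1"], factory, cognate={})

    def test_promiscuous_ligand_flagged_by_column_outlier(self):
        ceilings = {
            f"r{i}": {"l1": 0.31 + 0.002 * i, "l2": 0.30, "l3": 0.9}
            for i in range(3)
        }
        receptors, factory = self._setup(ceilings)
        report = cross_partner_matrix(
            receptors, ["l1", "l2", "l3"], factory,
            cognate={f"r{i}": "l1" for i in range(3)},
        )
        assert report.promiscuous_ligands == ["l3"]


class TestReplicateFromScoreTable:
    def _table(self):
        rows = []
        rng = np.random.default_rng(0)
        for case in range(6):
            for protocol in ("mixed", "unpaired"):
                for i in range(5):
                    good = (case + (protocol == "unpaired")) % 2 == 0
                    conf = rng.uniform(0.7, 0.9) if good else rng.uniform(0.2, 0.5)
                    rows.append(
                        {
                            "case_id": f"c{case}",
                            "protocol": protocol,
                            "run_index": 0,
                            "model_index": i,
                            "confidence": conf,
                            "capri_class": "Medium" if good else "Incorrect",
                        }
                    )
        return pd.DataFrame(rows)

    def test_selection_and_classification_recompute_rates(self):
        out = replicate_from_score_table(self._table())
        assert out["per_protocol"]["mixed"].success_rate == 50.0
        assert out["per_protocol"]["unpaired"].success_rate == 50.0
        assert out["combined"].success_rate == 100.0  # protocols complement

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="lacks columns"):
            replicate_from_score_table(pd.DataFrame({"case_id": []}))
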