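import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adrmine import association as assoc
from adrmine.datamodel import ContingencyTable, DrugAdrPair, DrugTargetPair
from adrmine.datamodel import PipelineConfig


def exact_upper_tail(a, b, c, d):
    """Independent oracle: exact rational hypergeometric upper tail."""
    n_adr, n_tgt, N = a + c, a + b, a + b + c + d
    denom = comb(N, n_tgt)
    total = Fraction(0)
    for k in range(a, min(n_adr, n_tgt) + 1):
        total += Fraction(comb(n_adr, k) * comb(N - n_adr, n_tgt - k), denom)
    return float(total)


class TestBuildTable:
    def test_enumerated_example(self):
        universe = {"D1", "D2", "D3", "D4"}
        t = assoc.build_table(
            "T1", "A1", universe,
            {"A1": {"D1", "D2"}}, {"T1": {"D1", "D3"}},
        )
        assert t.as_tuple() == (1, 1, 1, 1)

    def test_adr_hit_by_no_drug(self):
        t = assoc.build_table("T1", "A9", {"D1"}, {}, {"T1": {"D1"}})
        assert t.n_adr == 0 and t.n_adr_and_target == 0

    def test_all_drugs_both(self):
        u = {"D1", "D2"}
        t = assoc.build_table("T1", "A1", u, {"A1": u}, {"T1": u})
        assert t.n_neither == 0 and t.n_adr_and_target == 2


class TestFisher:
    def test_zero_overlap_gives_one(self):
        assert assoc.fisher_p(ContingencyTable(0, 3, 3, 3)) == 1.0

    def test_printed_example_against_factorial_oracle(self):
        # table (3,1,1,3), N=8: upper tail at k=3 plus k=4
        t = ContingencyTable(3, 1, 1, 3)
        assert assoc.fisher_p(t) == pytest.approx(
            exact_upper_tail(3, 1, 1, 3), abs=1e-14
        )

    @given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10),
           st.integers(0, 10))
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle_small_tables(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        t = ContingencyTable(a, b, c, d)
        assert assoc.fisher_p(t) == pytest.approx(
            exact_upper_tail(a, b, c, d), abs=1e-12
        )

    def test_monotone_in_joint_evidence(self):
        # a drug that both binds and presents the ADR can only strengthen
        # the enrichment (margins updated accordingly)
        rng = np.random.default_rng(8)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 8, size=4))
            p0 = assoc.fisher_p(ContingencyTable(a, b, c, d))
            p1 = assoc.fisher_p(ContingencyTable(a + 1, b, c, d))
            assert p1 <= p0 + 1e-12

    def test_two_sided_option(self):
        t = ContingencyTable(3, 1, 1, 3)
        p2 = assoc.fisher_p(t, "two-sided")
        from scipy.stats import fisher_exact

        _, expected = fisher_exact([[3, 1], [1, 3]], alternative="two-sided")
        assert p2 == pytest.approx(expected, abs=1e-10)


class TestQvalues:
    def test_single_pvalue_is_its_own_q(self):
        assert assoc.qvalues([0.03]) == pytest.approx([0.03])

    def test_bh_closed_form(self):
        q = assoc.qvalues([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assoc.qvalues([0.5, 1.2])

    def test_monotone_in_p_and_bh_bound(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50)  # m < 100 -> pi0 = 1 (BH)
        q = assoc.qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        ranks = np.empty(50, dtype=int)
        ranks[order] = np.arange(1, 51)
        assert (q <= p * 50 / ranks + 1e-12).all()

    def test_order_preserved(self):
        p = [0.2, 0.01, 0.6]
        q = assoc.qvalues(p)
        assert q[1] == min(q)


def _toy_inputs():
    """4 drugs, 2 proteins, 3 ADRs; hand-enumerable."""
    evidence = [
        DrugAdrPair("D1", "A1", "sider_like"),
        DrugAdrPair("D2", "A1", "sider_like"),
        DrugAdrPair("D1", "A2", "sider_like"),
        DrugAdrPair("D3", "A3", "sider_like"),
    ]
    targets = [
        DrugTargetPair("D1", "T1", "dtc_like", affinity_nM=5.0),
        DrugTargetPair("D2", "T1", "dtc_like", affinity_nM=5.0),
        DrugTargetPair("D3", "T2", "dtc_like", affinity_nM=5.0),
        DrugTargetPair("D4", "T2", "dtc_like", affinity_nM=5.0),
    ]
    return evidence, targets


class TestAssociate:
    def test_empty_inputs(self, config):
        assert assoc.associate([], [], config) == []

    def test_toy_fixture_hand_enumeration(self, config):
        evidence, targets = _toy_inputs()
        results = assoc.associate(evidence, targets, config,
                                  evidence_set="curated")
        got = {(r.uniprot_id, r.pt_code): r for r in results}
        # universe = {D1,D2,D3}; D4 has no ADR evidence
        # (T1, A1): a=2, b=0, c=0, d=1 -> p = C(2,2)C(1,0)/C(3,2) = 1/3
        assert got[("T1", "A1")].table.as_tuple() == (2, 0, 0, 1)
        assert got[("T1", "A1")].p_value == pytest.approx(1 / 3)
        # (T2, A3): a=1, b=0, c=0, d=2 -> p = 1/3
        assert got[("T2", "A3")].table.as_tuple() == (1, 0, 0, 2)
        assert got[("T2", "A3")].p_value == pytest.approx(1 / 3)
        # zero-overlap pairs not tested by default
        assert ("T2", "A1") not in got
        assert got[("T1", "A1")].drug_ids == frozenset({"D1", "D2"})

    def test_zero_overlap_testable_by_config(self):
        cfg = PipelineConfig(test_zero_overlap=True)
        evidence, targets = _toy_inputs()
        results = assoc.associate(evidence, targets, cfg)
        assert ("T2", "A1") in {(r.uniprot_id, r.pt_code) for r in results}

    def test_input_order_irrelevant(self, config):
        evidence, targets = _toy_inputs()
        r1 = assoc.associate(evidence, targets, config)
        r2 = assoc.associate(evidence[::-1], targets[::-1], config)
        key = lambda r: (r.uniprot_id, r.pt_code)
        assert [(key(a), a.p_value, a.q_value) for a in sorted(r1, key=key)] \
            == [(key(a), a.p_value, a.q_value) for a in sorted(r2, key=key)]

    def test_evidence_set_isolation(self, config):
        # self-reporting results are a pure function of their own inputs:
        # whatever happens on the curated side cannot change them
        evidence, targets = _toy_inputs()
        before = assoc.associate(evidence, targets, config,
                                 evidence_set="self-reporting")
        _ = assoc.associate(evidence[:1], targets[:2], config,
                            evidence_set="curated")
        after = assoc.associate(evidence, targets, config,
                                evidence_set="self-reporting")
        assert [(r.p_value, r.q_value) for r in before] == \
            [(r.p_value, r.q_value) for r in after]


class TestNullFdr:
    def test_no_planted_links_yields_near_zero_discoveries(self):
        """Null generator (family structure, no causal links): the realized
        false-positive proportion at q <= 0.05 stays below 0.10."""
        from adrmine.synthetic import GeneratorParams, generate_fixture

        cfg = PipelineConfig()
        n_sig = n_tested = 0
        for seed in range(20):
            params = GeneratorParams(
                n_drugs=60, n_targets=12, n_families=3, n_adrs=60, n_socs=15,
                n_reports=50, planted_link_count=0, n_adr_only_drugs=4,
                n_target_only_drugs=3, n_conflict_drugs=2, idio_pool_size=30,
                idio_pool_excluded_socs=8, idio_adr_mean=15,
                duplicate_rate=0.0, seed=100 + seed,
            )
            fx = generate_fixture(params)
            e = fx.ground_truth.expected
            evidence = [DrugAdrPair(d, pt, "sider_like")
                        for d, pt in e["curated_pairs_after_sparse"]]
            targets = [DrugTargetPair(d, u, "dtc_like", affinity_nM=5.0)
                       for d, u in e["target_pairs_after_main_prune"]]
            results = assoc.associate(evidence, targets, cfg,
                                      evidence_set="curated")
            n_tested += len(results)
            n_sig += sum(r.significant for r in results)
        assert n_tested > 200
        assert n_sig / n_tested <= 0.10
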