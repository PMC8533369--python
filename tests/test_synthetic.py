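import filecmp
from pathlib import Path

import numpy as np
import pytest

from adrmine import ingest
from adrmine.adr_filter import is_excluded_term
from adrmine.datamodel import (
    DEFAULT_EXCLUDED_GO_TERMS,
    DEFAULT_EXCLUDED_SOCS,
    INCHIKEY_PATTERN,
    PipelineConfig,
)
from adrmine.synthetic import (
    GeneratorParams,
    emit_fixture,
    generate_fixture,
    generate_vocabulary,
)
from conftest import SMALL_PARAMS


@pytest.fixture(scope="module")
def small_fx():
    return generate_fixture(GeneratorParams(**SMALL_PARAMS))


class TestVocabulary:
    def test_every_pt_has_one_soc_and_count_matches(self):
        params = GeneratorParams(**SMALL_PARAMS)
        terms = generate_vocabulary(params)
        assert len(terms) == params.n_adrs
        assert len({t.pt_code for t in terms}) == params.n_adrs
        socs = {t.soc for t in terms}
        assert len(socs) == params.n_socs

    def test_excluded_soc_names_present_verbatim(self):
        terms = generate_vocabulary(GeneratorParams(**SMALL_PARAMS))
        socs = {t.soc for t in terms}
        for name in DEFAULT_EXCLUDED_SOCS:
            assert name in socs

    def test_psychiatric_soc_has_both_kinds_of_hlgts(self):
        terms = generate_vocabulary(GeneratorParams(**SMALL_PARAMS))
        cfg = PipelineConfig()
        psych = [t for t in terms if t.soc == "Psychiatric disorders"]
        assert any(is_excluded_term(t, cfg) for t in psych)
        assert any(not is_excluded_term(t, cfg) for t in psych)


class TestProteome:
    def test_identity_bands_enforced(self, small_fx):
        pr = small_fx.proteome
        params = small_fx.params
        m = params.members_per_family
        for fam in range(params.n_families):
            fam_ids = [u for u, f in pr.family_of.items() if f == fam]
            founder = f"T{fam:02d}A"
            near_dup = f"T{fam:02d}B"
            assert 0.92 <= pr.ident(founder, near_dup) <= 0.97
            for sib in fam_ids:
                if sib in (founder, near_dup):
                    continue
                assert 0.70 < pr.ident(founder, sib) < 0.90
        for a in pr.uniprot_ids:
            for b in pr.uniprot_ids:
                if a < b and pr.family_of[a] != pr.family_of[b]:
                    assert pr.ident(a, b) < params.between_family_identity

    def test_go_annotated_families(self, small_fx):
        pr = small_fx.proteome
        params = small_fx.params
        annotated = {
            u for u in pr.uniprot_ids
            if set(pr.go_terms[u]) & set(DEFAULT_EXCLUDED_GO_TERMS)
        }
        expected_fams = set(range(
            params.n_families - params.go_annotated_families,
            params.n_families,
        ))
        assert {pr.family_of[u] for u in annotated} == expected_fams


class TestChemistry:
    def test_inchikeys_well_formed_and_structures_parse(self, small_fx):
        from rdkit import Chem

        for rec in small_fx.chemistry.target_records:
            assert INCHIKEY_PATTERN.match(rec["inchikey"])
            assert Chem.MolFromSmiles(rec["smiles"]) is not None

    def test_conflict_drugs_have_dissimilar_structures(self, small_fx):
        from adrmine.drug_unify import tanimoto

        chem = small_fx.chemistry
        by_id = {r["drug_id"]: r for r in chem.adr_records}
        tgt_by_name = {r["standard_name"]: r for r in chem.target_records}
        for aid in chem.conflict_adr_ids:
            a = by_id[aid]
            t = tgt_by_name[a["standard_name"]]
            assert tanimoto(a["smiles"], t["smiles"]) < 0.7

    def test_family_biased_binding(self, small_fx):
        chem, pr = small_fx.chemistry, small_fx.proteome
        within = across = 0
        for tid, bound in chem.bindings.items():
            fams = [pr.family_of[u] for u in bound]
            primary_fam = max(set(fams), key=fams.count)
            within += sum(f == primary_fam for f in fams) - 1
            across += sum(f != primary_fam for f in fams)
        n_pairs = sum(len(b) for b in chem.bindings.values())
        # sibling binding is concentrated in the primary family relative to
        # the per-target chance rate across the other families
        assert within / n_pairs > 0.1


class TestTruthAndReports:
    def test_causal_pairs_subset_of_truth(self, small_fx):
        for d, pt in small_fx.causal_pairs:
            assert pt in small_fx.truth_adrs[d]

    def test_both_report_sources_share_the_truth(self, small_fx):
        # each source's reports mention causal PTs for the causal drugs
        for tag, rs in small_fx.report_sets.items():
            mentioned = set()
            for row in rs.reports:
                for name in row["_resolvable_ids"]:
                    for pt in row["pts"]:
                        mentioned.add((name, pt))
            causal_seen = sum(
                1 for pair in small_fx.causal_pairs if pair in mentioned
            )
            assert causal_seen >= 0.9 * len(small_fx.causal_pairs)

    def test_per_drug_marginals_near_report_rate(self, small_fx):
        params = small_fx.params
        rs = small_fx.report_sets["faers_like"]
        counts: dict[str, int] = {}
        hits: dict[tuple, int] = {}
        for row in rs.reports:
            if row["_is_dup"]:
                continue
            for d in row["_resolvable_ids"]:
                counts[d] = counts.get(d, 0) + 1
                for pt in small_fx.truth_adrs[d]:
                    if pt in row["pts"]:
                        hits[(d, pt)] = hits.get((d, pt), 0) + 1
        drug = max(counts, key=counts.get)
        n = counts[drug]
        for pt in sorted(small_fx.truth_adrs[drug])[:5]:
            k = hits.get((drug, pt), 0)
            p = params.report_adr_rate
            se = np.sqrt(p * (1 - p) / n)
            assert abs(k / n - p) < 5 * se

    def test_duplicate_injection_counts(self, small_fx):
        for rs in small_fx.report_sets.values():
            n_dups = sum(1 for r in rs.reports if r["_is_dup"])
            assert n_dups == int(round(
                small_fx.params.duplicate_rate
                * (rs.emitted - n_dups)
            ))


class TestEmission:
    def test_byte_identical_reemission_under_same_seed(self, tmp_path):
        params = GeneratorParams(**{**SMALL_PARAMS, "n_reports": 300})
        emit_fixture(params, tmp_path / "a")
        emit_fixture(params, tmp_path / "b")
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert files
        for name in files:
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_all_emitted_files_parse_through_ingest(self, small_fixture_dir):
        d = Path(small_fixture_dir)
        assert len(ingest.read_vocabulary(d / "vocabulary.tsv")) == 60
        assert ingest.read_synonym_table(d / "synonyms.tsv")
        assert ingest.read_drug_table(d / "drugs_adr_side.tsv")
        assert ingest.read_fasta(d / "targets.fasta")
        assert ingest.read_drug_target_pairs(
            d / "drug_targets_dtc_like.tsv", "dtc_like")
        assert ingest.read_spontaneous_reports(
            d / "reports_faers_like.tsv")[0]
        pairs, _ = ingest.read_drug_adr_pairs(
            d / "pairs_sider_like.tsv", "sider_like")
        assert pairs


class TestEffectSizeDial:
    def test_power_monotone_in_causal_rate(self):
        """Recovered planted links never decrease as the causal ADR rate
        grows (checked on the curated branch at three rates)."""
        from adrmine.association import associate
        from adrmine.datamodel import DrugAdrPair, DrugTargetPair

        cfg = PipelineConfig()
        recovered = []
        for rate in (0.05, 0.35, 0.75):
            params = GeneratorParams(
                n_drugs=120, n_targets=24, n_families=6, n_adrs=80, n_socs=15,
                n_reports=50, planted_link_count=6, n_adr_only_drugs=4,
                n_target_only_drugs=3, n_conflict_drugs=2, idio_pool_size=30,
                idio_pool_excluded_socs=8, idio_adr_mean=15,
                causal_adr_rate=rate, seed=11,
            )
            fx = generate_fixture(params)
            e = fx.ground_truth.expected
            evidence = [DrugAdrPair(d, pt, "sider_like")
                        for d, pt in e["curated_pairs_after_sparse"]]
            targets = [DrugTargetPair(d, u, "dtc_like", affinity_nM=5.0)
                       for d, u in e["target_pairs_after_main_prune"]]
            results = associate(evidence, targets, cfg, evidence_set="curated")
            sig = {(r.uniprot_id, r.pt_code) for r in results if r.significant}
            planted = {tuple(p) for p in fx.ground_truth.planted_links}
            recovered.append(len(sig & planted))
        assert recovered[0] <= recovered[1] <= recovered[2]
        assert recovered[2] >= 1
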