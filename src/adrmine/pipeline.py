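"""End-to-end workflow: curation -> ADR filter -> unification -> sparse-drug
filter -> target filters -> association -> export.

The stage order is fixed; each stage consumes only earlier stages'
outputs.  A machine-readable run manifest (config hash, seed, per-stage
in/out counts) is written next to the result tables.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import adr_filter, association, drug_unify, ingest, pharmacovigilance
from . import target_filter
from .datamodel import (
    AssociationResult,
    DrugAdrPair,
    DrugTargetPair,
    PipelineConfig,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "run_stages", "query",
           "REQUIRED_FILES"]

REQUIRED_FILES = [
    "vocabulary.tsv",
    "synonyms.tsv",
    "drugs_adr_side.tsv",
    "drugs_target_side.tsv",
    "targets.fasta",
    "go_annotations.tsv",
    "drug_targets_dtc_like.tsv",
    "drug_targets_stitch_like.tsv",
    "pairs_sider_like.tsv",
    "pairs_offsides_like.tsv",
    "reports_faers_like.tsv",
    "reports_medeffect_like.tsv",
]


@dataclass
class PipelineResult:
    """Results plus every intermediate needed for auditing a run."""

    results: dict[str, list[AssociationResult]] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    intermediates: dict = field(default_factory=dict)
    unify: drug_unify.UnifyResult | None = None

    def record(self, name: str, n_in: int, n_out: int) -> None:
        self.stages.append(
            {"stage": name, "n_in": n_in, "n_out": n_out,
             "n_removed": n_in - n_out}
        )


def _map_adr_pairs(pairs, unify):
    mapped = []
    for p in pairs:
        ent = unify.by_side_id.get(p.drug_id)
        if ent is not None:
            mapped.append(DrugAdrPair(ent.drug_id, p.pt_code, p.source,
                                      p.evidence_stat))
    # duplicate (drug, pt, source) rows can arise from synonym collapse
    return sorted(set(mapped), key=lambda p: (p.drug_id, p.pt_code, p.source))


def _map_target_pairs(pairs, unify):
    mapped = []
    for p in pairs:
        ent = unify.by_side_id.get(p.drug_id)
        if ent is not None:
            mapped.append(DrugTargetPair(ent.drug_id, p.uniprot_id, p.source,
                                         p.affinity_nM, p.confidence))
    return mapped


def run_stages(
    config: PipelineConfig,
    input_dir: str | Path,
    evidence_sets: tuple[str, ...] = ("self-reporting", "curated"),
) -> PipelineResult:
    """Execute the workflow on an input directory; pure computation."""
    ind = Path(input_dir)
    missing = [f for f in REQUIRED_FILES if not (ind / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing input file(s) in {ind}: {', '.join(missing)}"
        )
    res = PipelineResult()
    vocab = ingest.read_vocabulary(ind / "vocabulary.tsv")
    synonyms = ingest.read_synonym_table(ind / "synonyms.tsv")
    adr_drugs = ingest.read_drug_table(ind / "drugs_adr_side.tsv")
    tgt_drugs = ingest.read_drug_table(ind / "drugs_target_side.tsv")
    go = ingest.read_go_annotations(ind / "go_annotations.tsv")
    targets = {
        t.uniprot_id: t for t in ingest.read_fasta(ind / "targets.fasta", go)
    }

    # ---- target side -----------------------------------------------------
    t_pairs = ingest.read_drug_target_pairs(
        ind / "drug_targets_dtc_like.tsv", "dtc_like"
    ) + ingest.read_drug_target_pairs(
        ind / "drug_targets_stitch_like.tsv", "stitch_like"
    )
    n0 = len(t_pairs)
    t_pairs = target_filter.filter_affinity(t_pairs, config)
    res.record("target_affinity_filter", n0, len(t_pairs))
    res.intermediates["target_pairs_after_affinity"] = {
        (p.drug_id, p.uniprot_id) for p in t_pairs
    }
    n0 = len(t_pairs)
    t_pairs = target_filter.drop_metabolism_proteins(t_pairs, targets, config)
    res.record("target_go_filter", n0, len(t_pairs))
    res.intermediates["target_pairs_after_go"] = {
        (p.drug_id, p.uniprot_id) for p in t_pairs
    }

    # ---- drug unification ------------------------------------------------
    unify = drug_unify.unify_drugs(adr_drugs, tgt_drugs, config)
    res.unify = unify
    res.record(
        "drug_unification",
        len(adr_drugs) + len(tgt_drugs),
        len(unify.entities),
    )
    n0 = len(t_pairs)
    t_pairs = _map_target_pairs(t_pairs, unify)
    res.record("target_pairs_to_unified", n0, len(t_pairs))
    res.intermediates["target_pairs_after_unify"] = {
        (p.drug_id, p.uniprot_id) for p in t_pairs
    }

    # ---- target clustering chain ----------------------------------------
    present = sorted({p.uniprot_id for p in t_pairs})
    clusters90 = target_filter.greedy_cluster(
        [targets[u] for u in present], config.redundancy_identity
    )
    res.intermediates["clusters_90"] = clusters90
    n0 = len(t_pairs)
    t_pairs = target_filter.dedupe_redundant(
        t_pairs, clusters90, config.merge_redundant_evidence
    )
    res.record("target_redundancy_90", n0, len(t_pairs))
    res.intermediates["target_pairs_after_dedupe90"] = {
        (p.drug_id, p.uniprot_id) for p in t_pairs
    }
    centroids = sorted({p.uniprot_id for p in t_pairs})
    clusters70 = target_filter.greedy_cluster(
        [targets[u] for u in centroids], config.family_identity
    )
    res.intermediates["families_70"] = clusters70
    n0 = len(t_pairs)
    t_pairs = target_filter.exclude_large_families(t_pairs, clusters70, config)
    res.record("target_family_cap", n0, len(t_pairs))
    res.intermediates["target_pairs_after_family_cap"] = {
        (p.drug_id, p.uniprot_id) for p in t_pairs
    }
    override = None
    override_path = ind / "main_targets.tsv"
    if override_path.exists():
        override = {
            r["family_centroid_uniprot"]: r["main_target_uniprot"]
            for r in csv.DictReader(override_path.open(), delimiter="\t")
        }
    n0 = len(t_pairs)
    t_pairs = target_filter.main_target_prune(t_pairs, clusters70, config,
                                              main_target_override=override)
    res.record("target_main_prune", n0, len(t_pairs))
    res.intermediates["target_pairs_after_main_prune"] = {
        (p.drug_id, p.uniprot_id) for p in t_pairs
    }
    gene_names = {u: targets[u].gene_name for u in targets}

    # ---- evidence branches -----------------------------------------------
    for ev in evidence_sets:
        if ev == "self-reporting":
            pairs = self_reporting_pairs(config, ind, synonyms, res)
        else:
            pairs = curated_pairs(config, ind, vocab, res)
        n0 = len(pairs)
        pairs, removed = adr_filter.filter_adrs(pairs, vocab, config)
        res.record(f"{ev}_soc_filter", n0, len(pairs))
        res.intermediates[f"{ev}_soc_removed"] = removed
        n0 = len(pairs)
        pairs = _map_adr_pairs(pairs, unify)
        res.record(f"{ev}_pairs_to_unified", n0, len(pairs))
        res.intermediates[f"{ev}_pairs_after_unify"] = {
            (p.drug_id, p.pt_code) for p in pairs
        }
        n0 = len(pairs)
        pairs, dropped = drug_unify.drop_sparse_drugs(pairs, config)
        res.record(f"{ev}_sparse_drug_filter", n0, len(pairs))
        res.intermediates[f"{ev}_sparse_dropped"] = dropped
        res.intermediates[f"{ev}_pairs_after_sparse"] = {
            (p.drug_id, p.pt_code) for p in pairs
        }
        results = association.associate(
            pairs, t_pairs, config, vocabulary=vocab, evidence_set=ev,
            gene_names=gene_names,
        )
        res.record(f"{ev}_association", len(pairs), len(results))
        res.results[ev] = results
    return res


def self_reporting_pairs(config, ind, synonyms, res) -> list[DrugAdrPair]:
    pairs_by_source = []
    curated_reports = []
    for tag, fname in (("faers_like", "reports_faers_like.tsv"),
                       ("medeffect_like", "reports_medeffect_like.tsv")):
        reports, skipped = ingest.read_spontaneous_reports(ind / fname)
        n0 = len(reports)
        reports, stats = pharmacovigilance.normalize_drug_names(
            reports, synonyms
        )
        res.record(f"{tag}_normalize", n0, len(reports))
        res.intermediates[f"{tag}_norm_stats"] = stats
        n0 = len(reports)
        reports = pharmacovigilance.deduplicate_reports(reports)
        res.record(f"{tag}_dedup", n0, len(reports))
        curated_reports.append(reports)
    pairs = pharmacovigilance.screen_signals(
        curated_reports[0], curated_reports[1], config
    )
    res.record(
        "lrt_screen",
        sum(len(r) for r in curated_reports),
        len(pairs),
    )
    return pairs


def curated_pairs(config, ind, vocab, res) -> list[DrugAdrPair]:
    pairs = []
    for tag, fname in (("sider_like", "pairs_sider_like.tsv"),
                       ("offsides_like", "pairs_offsides_like.tsv")):
        p, skipped = ingest.read_drug_adr_pairs(ind / fname, tag, vocab)
        res.intermediates[f"{tag}_skipped"] = skipped
        pairs.extend(p)
    return pairs


def run_pipeline(
    config: PipelineConfig,
    input_dir: str | Path,
    out_dir: str | Path,
    evidence_set: str = "both",
) -> PipelineResult:
    """Run the workflow and write result tables plus the run manifest."""
    sets = (
        ("self-reporting", "curated")
        if evidence_set == "both"
        else (evidence_set,)
    )
    res = run_stages(config, input_dir, evidence_sets=sets)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = {"self-reporting": "selfreporting", "curated": "curated"}
    for ev in sets:
        ingest.write_associations(
            res.results[ev], out / f"associations_{suffix[ev]}.tsv"
        )
        removed = res.intermediates.get(f"{ev}_soc_removed", {})
        with (out / f"soc_removals_{suffix[ev]}.tsv").open("w") as fh:
            fh.write("soc\tremoved_count\n")
            for soc in sorted(removed):
                fh.write(f"{soc}\t{removed[soc]}\n")
    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.rng_seed,
        "evidence_sets": list(sets),
        "stage_order": [s["stage"] for s in res.stages],
        "stages": res.stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for s in res.stages:
        log.info("stage %-28s in=%-7d out=%-7d removed=%d",
                 s["stage"], s["n_in"], s["n_out"], s["n_removed"])
    return res


def query(results_path: str | Path, by: str, term: str) -> pd.DataFrame:
    """Case-insensitive exact-match query of an association table."""
    df = pd.read_csv(results_path, sep="\t", dtype=str)
    t = term.casefold()
    if by == "uniprot":
        mask = df["uniprot_id"].str.casefold() == t
    elif by == "gene":
        mask = df["gene_name"].str.casefold() == t
    elif by == "adr":
        mask = (df["pt_name"].str.casefold() == t) | (
            df["pt_code"].str.casefold() == t
        )
    elif by == "drug":
        mask = df["supporting_drugs"].fillna("").str.casefold().apply(
            lambda s: t in s.split(";")
        )
    else:
        raise ValueError(f"unknown query key {by!r}")
    return df[mask]
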