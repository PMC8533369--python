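"""Protein-side filters: potency thresholds, metabolism-protein exclusion,
redundancy and family clustering, and the main-target drug-sharing rule.

Sequence identity follows the CD-HIT convention: identical residues in a
global pairwise alignment divided by the length of the *shorter*
sequence.  Clustering is greedy and incremental over sequences sorted by
decreasing length (ties broken by uniprot id): each sequence joins the
first existing cluster whose centroid (founder) it matches at or above
the threshold, else founds a new cluster.  Redundant proteins are
collapsed at 90% identity; families are formed at 70% on the remaining
centroids.  Word-filter acceleration heuristics of production clustering
tools are unnecessary at this scale; exact pairwise alignment is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align

from .datamodel import DrugTargetPair, PipelineConfig, TargetProtein

log = logging.getLogger(__name__)

__all__ = [
    "ProteinCluster",
    "filter_affinity",
    "drop_metabolism_proteins",
    "pairwise_identity",
    "greedy_cluster",
    "dedupe_redundant",
    "exclude_large_families",
    "main_target_prune",
    "drugs_per_target",
]


@dataclass(frozen=True)
class ProteinCluster:
    """A greedy identity cluster; the centroid is its founder."""

    members: frozenset[str]
    centroid: str
    identity_level: float

    def __post_init__(self) -> None:
        if self.centroid not in self.members:
            raise ValueError("centroid must be a cluster member")


def filter_affinity(
    pairs: list[DrugTargetPair], config: PipelineConfig
) -> list[DrugTargetPair]:
    """Keep potent / high-confidence pairs.

    Affinity-typed pairs survive iff affinity_nM <= ic50_max_nM ("100 nM or
    better": exactly 100 nM is kept); confidence-typed pairs survive iff
    confidence >= stitch_min_score.
    """
    kept = []
    for p in pairs:
        if p.affinity_nM is not None:
            if p.affinity_nM <= config.ic50_max_nM:
                kept.append(p)
        elif p.confidence >= config.stitch_min_score:
            kept.append(p)
    return kept


def drop_metabolism_proteins(
    pairs: list[DrugTargetPair],
    targets: dict[str, TargetProtein],
    config: PipelineConfig,
) -> list[DrugTargetPair]:
    """Remove pairs whose target is annotated with a drug-metabolism GO term."""
    excluded = set(config.excluded_go_terms)
    kept = []
    for p in pairs:
        tgt = targets.get(p.uniprot_id)
        go = tgt.go_terms if tgt is not None else frozenset()
        if not (go & excluded):
            kept.append(p)
    return kept


_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1.0,
    mismatch_score=-1.0,
    open_gap_score=-2.0,
    extend_gap_score=-0.5,
)


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical aligned residues over the shorter length."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    identities = aln.counts().identities
    return identities / min(len(seq_a), len(seq_b))


def greedy_cluster(
    targets: list[TargetProtein], identity_threshold: float
) -> list[ProteinCluster]:
    """CD-HIT-style greedy incremental clustering; deterministic."""
    ordered = sorted(targets, key=lambda t: (-len(t.sequence), t.uniprot_id))
    centroids: list[TargetProtein] = []
    members: dict[str, list[str]] = {}
    for t in ordered:
        placed = False
        for c in centroids:
            if pairwise_identity(t.sequence, c.sequence) >= identity_threshold:
                members[c.uniprot_id].append(t.uniprot_id)
                placed = True
                break
        if not placed:
            centroids.append(t)
            members[t.uniprot_id] = [t.uniprot_id]
    return [
        ProteinCluster(
            members=frozenset(members[c.uniprot_id]),
            centroid=c.uniprot_id,
            identity_level=identity_threshold,
        )
        for c in centroids
    ]


def dedupe_redundant(
    pairs: list[DrugTargetPair],
    clusters_90: list[ProteinCluster],
    merge_evidence: bool = True,
) -> list[DrugTargetPair]:
    """Collapse highly redundant proteins onto their 90% centroid.

    With ``merge_evidence`` (default) removed members' drugs are
    re-attributed to the centroid (union), so no drug evidence is lost;
    otherwise non-centroid evidence is discarded.  Idempotent.
    """
    to_centroid = {m: c.centroid for c in clusters_90 for m in c.members}
    best: dict[tuple[str, str], DrugTargetPair] = {}
    for p in pairs:
        centroid = to_centroid.get(p.uniprot_id, p.uniprot_id)
        if not merge_evidence and centroid != p.uniprot_id:
            continue
        key = (p.drug_id, centroid)
        moved = (
            p
            if centroid == p.uniprot_id
            else DrugTargetPair(
                drug_id=p.drug_id,
                uniprot_id=centroid,
                source=p.source,
                affinity_nM=p.affinity_nM,
                confidence=p.confidence,
            )
        )
        prev = best.get(key)
        if prev is None or _stronger(moved, prev):
            best[key] = moved
    return sorted(best.values(), key=lambda p: (p.drug_id, p.uniprot_id))


def _stronger(a: DrugTargetPair, b: DrugTargetPair) -> bool:
    """Prefer the more potent / more confident of two merged pairs."""
    if a.affinity_nM is not None and b.affinity_nM is not None:
        return a.affinity_nM < b.affinity_nM
    if a.confidence is not None and b.confidence is not None:
        return a.confidence > b.confidence
    return a.affinity_nM is not None  # prefer measured potency


def drugs_per_target(pairs: list[DrugTargetPair]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for p in pairs:
        out.setdefault(p.uniprot_id, set()).add(p.drug_id)
    return out


def exclude_large_families(
    pairs: list[DrugTargetPair],
    clusters_70: list[ProteinCluster],
    config: PipelineConfig,
) -> list[DrugTargetPair]:
    """Collapse promiscuous (drug, family) bindings onto the family centroid.

    When a drug binds strictly more than ``max_family_size`` members of a
    70% family, all its pairs into that family are replaced by a single
    pair to the centroid (binding exactly the threshold count is left
    unchanged: "more than" reading).
    """
    family_of = {m: c for c in clusters_70 for m in c.members}
    per_drug_family: dict[tuple[str, str], list[DrugTargetPair]] = {}
    for p in pairs:
        fam = family_of.get(p.uniprot_id)
        key = (p.drug_id, fam.centroid if fam else p.uniprot_id)
        per_drug_family.setdefault(key, []).append(p)
    out: list[DrugTargetPair] = []
    for (drug, centroid), plist in sorted(per_drug_family.items()):
        if len({p.uniprot_id for p in plist}) > config.max_family_size:
            existing = [p for p in plist if p.uniprot_id == centroid]
            if existing:
                out.append(existing[0])
            else:
                strongest = plist[0]
                for p in plist[1:]:
                    if _stronger(p, strongest):
                        strongest = p
                out.append(
                    DrugTargetPair(
                        drug_id=drug,
                        uniprot_id=centroid,
                        source=strongest.source,
                        affinity_nM=strongest.affinity_nM,
                        confidence=strongest.confidence,
                    )
                )
            log.info("collapsed %d pairs of drug %s onto family centroid %s",
                     len(plist), drug, centroid)
        else:
            out.extend(plist)
    return sorted(out, key=lambda p: (p.drug_id, p.uniprot_id))


def main_target_prune(
    pairs: list[DrugTargetPair],
    clusters_70: list[ProteinCluster],
    config: PipelineConfig,
    main_target_override: dict[str, str] | None = None,
) -> list[DrugTargetPair]:
    """Keep family members only if they share enough drugs with the main
    target.

    The main target of each family is the member bound by the most unified
    drugs (ties: lexicographically smallest uniprot id), overridable per
    family centroid via ``main_target_override``.  Another member is kept
    iff it shares at least ``main_target_share`` of the drugs binding the
    main target.  The main target itself is always kept.
    """
    binding = drugs_per_target(pairs)
    keep_targets: set[str] = set()
    clustered: set[str] = set()
    for fam in clusters_70:
        present = sorted(m for m in fam.members if m in binding)
        clustered.update(fam.members)
        if not present:
            continue
        override = (main_target_override or {}).get(fam.centroid)
        if override in present:
            main = override
        else:
            main = max(present, key=lambda m: (len(binding[m]), m))
            # ties: most drugs first, then lexicographically smallest id
            best_n = len(binding[main])
            main = min(m for m in present if len(binding[m]) == best_n)
        keep_targets.add(main)
        main_drugs = binding[main]
        for m in present:
            if m == main:
                continue
            share = len(binding[m] & main_drugs) / len(main_drugs)
            if share >= config.main_target_share:
                keep_targets.add(m)
    kept = [
        p for p in pairs
        if p.uniprot_id in keep_targets or p.uniprot_id not in clustered
    ]
    return kept
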