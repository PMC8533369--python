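"""Drug unification across the ADR and target evidence sides.

Drugs named in adverse-event sources must be matched with drugs named in
binding databases before any (protein, ADR) contingency table can be
built.  Matching precedence:

1. identical full 27-character InChIKey -> merge (stereo-safe);
2. identical case-folded standard name, and -- when both sides carry a
   structure -- 2D Tanimoto similarity at or above the threshold -> merge;
3. identical name but Tanimoto below threshold -> NOT merged, conflict
   logged.

A name carried by two distinct InChIKeys on the same side is ambiguous;
name-matching is disabled for it.  Unmatched drugs remain single-sided and
cannot contribute to associations.  Fingerprints are 2048-bit circular
(Morgan) of radius 2, the de-facto 2D standard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit import DataStructs, RDLogger

from .datamodel import DrugAdrPair, DrugEntity, PipelineConfig

RDLogger.DisableLog("rdApp.*")  # rdkit parse chatter

log = logging.getLogger(__name__)

__all__ = ["tanimoto", "morgan_bits", "unify_drugs", "UnifyResult",
           "drop_sparse_drugs"]

_FPGEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def morgan_bits(smiles: str) -> frozenset[int]:
    """On-bit set of the 2048-bit radius-2 circular fingerprint.

    Raises ValueError for unparseable SMILES.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    fp = _FPGEN.GetFingerprint(mol)
    return frozenset(fp.GetOnBits())


def tanimoto(smiles_a: str, smiles_b: str) -> float:
    """Jaccard coefficient of the two molecules' fingerprint bit sets."""
    mol_a = Chem.MolFromSmiles(smiles_a)
    mol_b = Chem.MolFromSmiles(smiles_b)
    if mol_a is None or mol_b is None:
        bad = smiles_a if mol_a is None else smiles_b
        raise ValueError(f"unparseable SMILES: {bad!r}")
    fa = _FPGEN.GetFingerprint(mol_a)
    fb = _FPGEN.GetFingerprint(mol_b)
    return DataStructs.TanimotoSimilarity(fa, fb)


@dataclass
class UnifyResult:
    """Outcome of cross-side drug unification."""

    entities: list[DrugEntity] = field(default_factory=list)
    by_side_id: dict[str, DrugEntity] = field(default_factory=dict)
    name_only_merges: list[str] = field(default_factory=list)  # unified ids
    conflicts: list[dict] = field(default_factory=list)
    ambiguous_names: list[str] = field(default_factory=list)
    unmatched_adr: list[str] = field(default_factory=list)
    unmatched_target: list[str] = field(default_factory=list)


def _ambiguous_names(records: list[dict]) -> set[str]:
    seen: dict[str, set[str]] = {}
    for r in records:
        if r.get("inchikey"):
            seen.setdefault(r["standard_name"].casefold(), set()).add(r["inchikey"])
    return {name for name, keys in seen.items() if len(keys) > 1}


def unify_drugs(
    adr_side_drugs: list[dict],
    target_side_drugs: list[dict],
    config: PipelineConfig,
) -> UnifyResult:
    """Match ADR-side and target-side drug records into unified entities.

    Each record is a dict with keys drug_id, standard_name, inchikey,
    smiles (the structure table schema).  Deterministic: records are
    sorted before greedy matching, so input order is irrelevant.
    """
    adr_recs = sorted(adr_side_drugs, key=lambda r: r["drug_id"])
    tgt_recs = sorted(target_side_drugs, key=lambda r: r["drug_id"])
    result = UnifyResult()
    disabled = _ambiguous_names(adr_recs) | _ambiguous_names(tgt_recs)
    result.ambiguous_names = sorted(disabled)
    for name in disabled:
        log.warning("name-matching disabled for ambiguous name %r", name)

    tgt_by_key: dict[str, list[dict]] = {}
    tgt_by_name: dict[str, list[dict]] = {}
    for r in tgt_recs:
        if r.get("inchikey"):
            tgt_by_key.setdefault(r["inchikey"], []).append(r)
        tgt_by_name.setdefault(r["standard_name"].casefold(), []).append(r)

    matched_tgt: set[str] = set()
    merges: list[tuple[dict, dict, str]] = []  # (adr_rec, tgt_rec, how)

    for ar in adr_recs:
        # precedence 1: full InChIKey equality
        key = ar.get("inchikey")
        hit: Optional[dict] = None
        how = ""
        if key and key in tgt_by_key:
            for cand in tgt_by_key[key]:
                if cand["drug_id"] not in matched_tgt:
                    hit, how = cand, "inchikey"
                    break
        # precedence 2/3: case-folded standard name (+ Tanimoto gate)
        if hit is None:
            name = ar["standard_name"].casefold()
            if name not in disabled:
                for cand in tgt_by_name.get(name, []):
                    if cand["drug_id"] in matched_tgt:
                        continue
                    if ar.get("smiles") and cand.get("smiles"):
                        try:
                            sim = tanimoto(ar["smiles"], cand["smiles"])
                        except ValueError:
                            result.conflicts.append(
                                {"name": name, "adr_id": ar["drug_id"],
                                 "target_id": cand["drug_id"],
                                 "reason": "unparseable_smiles"}
                            )
                            continue
                        if sim >= config.tanimoto_min:
                            hit, how = cand, "name+tanimoto"
                            break
                        result.conflicts.append(
                            {"name": name, "adr_id": ar["drug_id"],
                             "target_id": cand["drug_id"],
                             "tanimoto": sim, "reason": "below_threshold"}
                        )
                    else:
                        hit, how = cand, "name_only"
                        break
        if hit is not None:
            matched_tgt.add(hit["drug_id"])
            merges.append((ar, hit, how))
        else:
            result.unmatched_adr.append(ar["drug_id"])

    result.unmatched_target = sorted(
        r["drug_id"] for r in tgt_recs if r["drug_id"] not in matched_tgt
    )

    for i, (ar, tr, how) in enumerate(merges):
        uid = f"U{i:05d}"
        entity = DrugEntity(
            drug_id=uid,
            standard_name=tr["standard_name"].casefold(),
            inchikey=tr.get("inchikey") or ar.get("inchikey"),
            smiles=tr.get("smiles") or ar.get("smiles"),
            synonyms=frozenset(
                {ar["standard_name"], tr["standard_name"],
                 tr["standard_name"].casefold()}
            ),
        )
        result.entities.append(entity)
        result.by_side_id[ar["drug_id"]] = entity
        result.by_side_id[tr["drug_id"]] = entity
        if how == "name_only":
            result.name_only_merges.append(uid)
    return result


def drop_sparse_drugs(
    pairs: list[DrugAdrPair],
    config: PipelineConfig,
) -> tuple[list[DrugAdrPair], set[str]]:
    """Discard drugs presenting fewer than the minimum number of ADRs.

    Counts distinct post-filter preferred terms per drug; a drug with
    exactly ``min_adrs_per_drug`` terms is kept ("less than" reading).
    Returns surviving pairs and the dropped drug ids.
    """
    per_drug: dict[str, set[str]] = {}
    for p in pairs:
        per_drug.setdefault(p.drug_id, set()).add(p.pt_code)
    dropped = {
        d for d, pts in per_drug.items() if len(pts) < config.min_adrs_per_drug
    }
    kept = [p for p in pairs if p.drug_id not in dropped]
    if dropped:
        log.info("sparse-drug filter removed %d drugs", len(dropped))
    return kept, dropped
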