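"""Readers and writers for the normalized TSV interchange formats.

A single normalized schema per evidence class (drug-ADR pairs, spontaneous
reports, drug-target pairs, vocabulary, drug structures) stands in for the
heterogeneous vendor dumps of spontaneous-reporting, curated side-effect
and drug-target databases.  All files are tab-delimited UTF-8 with a
header row and '.' decimals.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

from .datamodel import (
    AdrTerm,
    AssociationResult,
    DrugAdrPair,
    DrugTargetPair,
    FormatError,
    SpontaneousReport,
    TargetProtein,
)

log = logging.getLogger(__name__)

__all__ = [
    "Vocabulary",
    "read_vocabulary",
    "read_drug_adr_pairs",
    "read_spontaneous_reports",
    "read_drug_target_pairs",
    "read_drug_table",
    "read_synonym_table",
    "read_fasta",
    "read_go_annotations",
    "read_associations",
    "write_associations",
    "ASSOCIATION_COLUMNS",
]


class Vocabulary:
    """Lookup of MedDRA-like preferred terms by code and case-folded name."""

    def __init__(self, terms: Iterable[AdrTerm]):
        self.by_code: dict[str, AdrTerm] = {}
        self.by_name: dict[str, AdrTerm] = {}
        for t in terms:
            prev = self.by_code.get(t.pt_code)
            if prev is not None and prev.soc != t.soc:
                raise FormatError(
                    f"duplicate pt_code {t.pt_code} with conflicting SOC "
                    f"({prev.soc!r} vs {t.soc!r})"
                )
            if t.pt_name.casefold() in self.by_name and \
                    self.by_name[t.pt_name.casefold()].pt_code != t.pt_code:
                raise FormatError(f"duplicate pt_name {t.pt_name!r}")
            self.by_code[t.pt_code] = t
            self.by_name[t.pt_name.casefold()] = t

    def __len__(self) -> int:
        return len(self.by_code)

    def __contains__(self, pt_code: str) -> bool:
        return pt_code in self.by_code

    def term(self, pt_code: str) -> AdrTerm:
        return self.by_code[pt_code]

    def lookup_name(self, name: str) -> Optional[AdrTerm]:
        return self.by_name.get(name.casefold())


def _rows(path: str | Path, required: list[str]) -> Iterable[dict]:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(
                f"{path}: missing required column(s) {', '.join(missing)}"
            )
        yield from reader


def read_vocabulary(path: str | Path) -> Vocabulary:
    """Read a PT->HLT->HLGT->SOC vocabulary table."""
    terms = [
        AdrTerm(
            pt_code=r["pt_code"],
            pt_name=r["pt_name"],
            hlt=r["hlt"],
            hlgt=r["hlgt"],
            soc=r["soc"],
        )
        for r in _rows(path, ["pt_code", "pt_name", "hlt", "hlgt", "soc"])
    ]
    return Vocabulary(terms)


def read_drug_adr_pairs(
    path: str | Path,
    source_tag: str,
    vocabulary: Optional[Vocabulary] = None,
) -> tuple[list[DrugAdrPair], int]:
    """Read (drug_id, pt_code[, evidence_stat]) pairs.

    Duplicate (drug_id, pt_code) rows collapse to one.  Rows whose pt_code
    is absent from ``vocabulary`` (when given) are skipped with a warning;
    the skip count is returned alongside the pairs.
    """
    pairs: dict[tuple[str, str], DrugAdrPair] = {}
    skipped = 0
    for r in _rows(path, ["drug_id", "pt_code"]):
        code = r["pt_code"]
        if vocabulary is not None and code not in vocabulary:
            skipped += 1
            continue
        stat = r.get("evidence_stat")
        key = (r["drug_id"], code)
        pairs[key] = DrugAdrPair(
            drug_id=r["drug_id"],
            pt_code=code,
            source=source_tag,
            evidence_stat=float(stat) if stat not in (None, "") else None,
        )
    if skipped:
        log.warning("%s: skipped %d rows with unknown pt_code", path, skipped)
    return list(pairs.values()), skipped


def read_spontaneous_reports(path: str | Path) -> tuple[list[SpontaneousReport], int]:
    """Read raw spontaneous reports; drug strings are NOT normalized here.

    Rows with zero drugs or zero PTs are skipped with a warning; the skip
    count is returned.
    """
    reports: list[SpontaneousReport] = []
    skipped = 0
    cols = ["report_id", "drugs", "pts", "age", "sex", "weight",
            "event_date", "country"]
    for r in _rows(path, cols):
        drugs = [d for d in (r["drugs"] or "").split(";") if d]
        pts = [p for p in (r["pts"] or "").split(";") if p]
        if not drugs or not pts:
            skipped += 1
            continue
        reports.append(
            SpontaneousReport(
                report_id=r["report_id"],
                raw_drug_names=drugs,
                pt_codes=pts,
                age=float(r["age"]) if r["age"] else None,
                sex=r["sex"] or "unknown",
                weight=float(r["weight"]) if r["weight"] else None,
                event_date=r["event_date"] or None,
                country=r["country"] or None,
            )
        )
    if skipped:
        log.warning("%s: skipped %d empty-drug/PT reports", path, skipped)
    return reports, skipped


def read_drug_target_pairs(path: str | Path, source_tag: str) -> list[DrugTargetPair]:
    """Read drug-target pairs typed per source (affinity vs confidence)."""
    pairs: list[DrugTargetPair] = []
    is_affinity = "dtc" in source_tag.lower()
    col = "affinity_nM" if is_affinity else "confidence"
    for r in _rows(path, ["drug_id", "uniprot_id", col]):
        raw = r.get(col)
        if raw in (None, ""):
            raise FormatError(f"{path}: row lacking {col}: {r}")
        try:
            value = float(raw)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric {col}: {raw!r}") from exc
        pairs.append(
            DrugTargetPair(
                drug_id=r["drug_id"],
                uniprot_id=r["uniprot_id"],
                source=source_tag,
                affinity_nM=value if is_affinity else None,
                confidence=None if is_affinity else value,
            )
        )
    return pairs


def read_drug_table(path: str | Path) -> list[dict]:
    """Read a drug structure table: drug_id, standard_name, inchikey, smiles."""
    out = []
    for r in _rows(path, ["drug_id", "standard_name", "inchikey", "smiles"]):
        out.append(
            {
                "drug_id": r["drug_id"],
                "standard_name": r["standard_name"],
                "inchikey": r["inchikey"] or None,
                "smiles": r["smiles"] or None,
            }
        )
    return out


def read_synonym_table(path: str | Path) -> dict[str, str]:
    """Read raw_name -> drug_id synonym mappings."""
    return {
        r["raw_name"]: r["drug_id"] for r in _rows(path, ["raw_name", "drug_id"])
    }


def read_go_annotations(path: str | Path) -> dict[str, frozenset[str]]:
    """Read uniprot_id -> set of GO ids."""
    acc: dict[str, set[str]] = {}
    for r in _rows(path, ["uniprot_id", "go_id"]):
        acc.setdefault(r["uniprot_id"], set()).add(r["go_id"])
    return {k: frozenset(v) for k, v in acc.items()}


def read_fasta(
    path: str | Path,
    go_annotations: Optional[dict[str, frozenset[str]]] = None,
) -> list[TargetProtein]:
    """Read protein sequences; FASTA ids are ``uniprot_id|gene_name``."""
    targets = []
    for rec in SeqIO.parse(str(path), "fasta"):
        uniprot_id, _, gene = rec.id.partition("|")
        go = (go_annotations or {}).get(uniprot_id, frozenset())
        targets.append(
            TargetProtein(
                uniprot_id=uniprot_id,
                gene_name=gene or uniprot_id,
                sequence=str(rec.seq),
                go_terms=frozenset(go),
            )
        )
    return targets


ASSOCIATION_COLUMNS = [
    "uniprot_id", "gene_name", "pt_code", "pt_name", "soc",
    "p_value", "q_value", "a", "b", "c", "d",
    "evidence_set", "sources", "supporting_drugs", "significant",
]


def write_associations(results: list[AssociationResult], path: str | Path) -> None:
    """Write association results sorted ascending by q-value.

    Columns a..d are the contingency cells: a = drugs with both the ADR
    and the target, b = target only, c = ADR only, d = neither.
    """
    ordered = sorted(results, key=lambda r: (r.q_value, r.p_value, r.uniprot_id,
                                             r.pt_code))
    delim = "," if str(path).endswith(".csv") else "\t"
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delim)
        w.writerow(ASSOCIATION_COLUMNS)
        for r in ordered:
            a, b, c, d = r.table.as_tuple()
            w.writerow(
                [
                    r.uniprot_id, r.gene_name, r.pt_code, r.pt_name, r.soc,
                    f"{r.p_value:.6g}", f"{r.q_value:.6g}", a, b, c, d,
                    r.evidence_set, r.sources,
                    ";".join(sorted(r.drug_ids)),
                    "1" if r.significant else "0",
                ]
            )


def read_associations(path: str | Path) -> list[AssociationResult]:
    """Read back an association table written by :func:`write_associations`."""
    from .datamodel import ContingencyTable

    delim = "," if str(path).endswith(".csv") else "\t"
    out: list[AssociationResult] = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        missing = [c for c in ASSOCIATION_COLUMNS
                   if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        for r in reader:
            out.append(
                AssociationResult(
                    uniprot_id=r["uniprot_id"],
                    gene_name=r["gene_name"],
                    pt_code=r["pt_code"],
                    pt_name=r["pt_name"],
                    soc=r["soc"],
                    p_value=float(r["p_value"]),
                    q_value=float(r["q_value"]),
                    table=ContingencyTable(
                        int(r["a"]), int(r["b"]), int(r["c"]), int(r["d"])
                    ),
                    evidence_set=r["evidence_set"],
                    drug_ids=frozenset(
                        d for d in r["supporting_drugs"].split(";") if d
                    ),
                    sources=r["sources"],
                    significant=r["significant"] == "1",
                )
            )
    return out
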