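"""Synthetic six-source evidence ecosystem with known ground truth.

The generator emulates the inputs the mining pipeline consumes: a
MedDRA-shaped vocabulary, a proteome organised into sequence families, a
drug chemistry table with name variants and misspellings, two
spontaneous-reporting sources (with planted exact duplicates) and two
curated drug-ADR pair sources.  Adverse reactions are caused by
*targets*, not drugs: a planted causal (target, ADR) link gives every
drug binding that target a chance (``causal_adr_rate``) of truly
presenting the ADR, so family confounding arises naturally through
shared binding.  Each drug additionally carries idiosyncratic (non
target-mediated) adverse reactions drawn from a common pool, which give
drugs realistic ADR counts without creating protein-level signal.

Generation is fully deterministic under a fixed seed (byte-identical
files), and every deterministic pipeline stage's expected survivor set is
bookkept into a :class:`GroundTruth` object at generation time by
independent set arithmetic over the generator's own records.  Sequence
identity bands are enforced by rejection sampling against the same
pairwise identity function the clustering stage uses, so the 70% and 90%
thresholds are exercised on both sides.
"""

from __future__ import annotations

import hashlib
import json
import string
from dataclasses import dataclass, field, fields as dc_fields, asdict
from pathlib import Path

import numpy as np
from rdkit import Chem

from .datamodel import (
    AdrTerm,
    ConfigError,
    DEFAULT_EXCLUDED_GO_TERMS,
    DEFAULT_EXCLUDED_PSYCH_TERMS,
    DEFAULT_EXCLUDED_SOCS,
    SpontaneousReport,
)
from .drug_unify import tanimoto
from .target_filter import pairwise_identity

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "FixtureData",
    "generate_vocabulary",
    "generate_proteome",
    "generate_chemistry",
    "generate_reports_and_pairs",
    "generate_fixture",
    "emit_fixture",
    "generate_null_reports",
    "load_generator_params",
    "load_ground_truth",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

KEPT_SOC_NAMES = [
    "Gastrointestinal disorders",
    "Nervous system disorders",
    "Cardiac disorders",
    "Skin and subcutaneous tissue disorders",
    "Vascular disorders",
    "Respiratory, thoracic and mediastinal disorders",
]

PSYCH_SOC = "Psychiatric disorders"
PSYCH_KEPT_HLGTS = ["anxiety disorders and symptoms",
                    "sleep disorders and disturbances"]


@dataclass
class GeneratorParams:
    """Study conditions of the synthetic ecosystem.

    The headline sizes and effect rates define the default fixture; the
    remaining fields shape the binding structure, reporting behaviour and
    evidence noise (rationale for each default is given in the methods
    documentation).
    """

    n_drugs: int = 300
    n_targets: int = 60
    n_families: int = 12
    n_adrs: int = 120
    n_socs: int = 15
    n_reports: int = 20000
    planted_link_count: int = 15
    adr_background_rate: float = 0.02
    causal_adr_rate: float = 0.35
    within_family_identity: float = 0.78
    between_family_identity: float = 0.60
    duplicate_rate: float = 0.05
    misspelling_rate: float = 0.05
    seed: int = 42
    # reporting and evidence structure
    report_adr_rate: float = 0.50
    idio_adr_mean: float = 20.0
    idio_pool_size: int = 40
    idio_pool_excluded_socs: int = 12
    two_drug_report_rate: float = 0.15
    second_source_report_fraction: float = 0.5
    curated_coverage_a: float = 0.95
    curated_coverage_b: float = 0.90
    curated_noise_rate: float = 0.002
    # binding structure
    founder_primary_bias: float = 0.60
    sibling_bind_rate: float = 0.35
    cross_family_founder_bind_rate: float = 0.10
    cross_family_member_bind_rate: float = 0.01
    affinity_pass_rate: float = 0.85
    dual_source_binding_rate: float = 0.05
    # entity bookkeeping
    n_adr_only_drugs: int = 12
    n_target_only_drugs: int = 8
    n_conflict_drugs: int = 3
    go_annotated_families: int = 1

    def __post_init__(self) -> None:
        for name in ("adr_background_rate", "causal_adr_rate", "duplicate_rate",
                     "misspelling_rate", "report_adr_rate", "curated_coverage_a",
                     "curated_coverage_b", "curated_noise_rate",
                     "founder_primary_bias", "sibling_bind_rate",
                     "cross_family_founder_bind_rate",
                     "cross_family_member_bind_rate", "affinity_pass_rate",
                     "dual_source_binding_rate", "two_drug_report_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.causal_adr_rate <= self.adr_background_rate:
            raise ConfigError(
                "causal_adr_rate must exceed adr_background_rate "
                "(undetectable effect)"
            )
        if not (0.70 < self.within_family_identity < 1.0):
            raise ConfigError("within_family_identity must lie in (0.7, 1)")
        if not (0.0 < self.between_family_identity < 0.70):
            raise ConfigError("between_family_identity must lie below 0.7")
        if self.n_targets % self.n_families:
            raise ConfigError("n_targets must be a multiple of n_families")
        if self.n_targets // self.n_families < 3:
            raise ConfigError("families need at least 3 members")

    @property
    def members_per_family(self) -> int:
        return self.n_targets // self.n_families


_PARAM_FIELDS = {f.name for f in dc_fields(GeneratorParams)}


def load_generator_params(path: str | Path) -> GeneratorParams:
    """Load generator parameters from a flat YAML file (strict keys)."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _PARAM_FIELDS
    if unknown:
        raise ConfigError(f"unknown generator key(s): {', '.join(sorted(unknown))}")
    return GeneratorParams(**raw)


@dataclass
class GroundTruth:
    """Generation-time bookkeeping: what every deterministic pipeline
    stage is expected to produce on the emitted fixture."""

    params: dict
    planted_links: list  # [uniprot_id, pt_code]
    family_map: dict  # uniprot_id -> family index
    causal_drug_adr_pairs: list  # drug-level [adr_drug_id, pt_code]
    kept_pt_codes: list
    excluded_pt_codes: list
    report_stats: dict  # per source: emitted / after_norm / after_dedup ...
    expected: dict  # per-stage survivor sets (lists of pairs / ids)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def load_ground_truth(path: str | Path) -> GroundTruth:
    raw = json.loads(Path(path).read_text())
    return GroundTruth(**raw)


# --------------------------------------------------------------------------
# Vocabulary


def generate_vocabulary(params: GeneratorParams) -> list[AdrTerm]:
    """Build the MedDRA-shaped vocabulary.

    All excluded SOC names appear verbatim, plus a psychiatric SOC with
    both excluded and kept high-level group terms, plus organ-specific
    kept SOCs.  Each PT maps to one primary SOC.
    """
    kept_socs = list(KEPT_SOC_NAMES)
    want_kept = params.n_socs - len(DEFAULT_EXCLUDED_SOCS) - 1
    while len(kept_socs) < want_kept:
        kept_socs.append(f"Other body system disorders {len(kept_socs)}")
    kept_socs = kept_socs[:want_kept]

    terms: list[AdrTerm] = []
    idx = 0

    def add(pt_name: str, hlt: str, hlgt: str, soc: str) -> None:
        nonlocal idx
        terms.append(AdrTerm(f"P{idx:04d}", pt_name, hlt, hlgt, soc))
        idx += 1

    for soc in DEFAULT_EXCLUDED_SOCS:
        for j in range(3):
            add(f"{soc.split()[0].lower()} event {j}", f"hlt {soc} {j}",
                f"hlgt {soc}", soc)
    for j, hlgt in enumerate(DEFAULT_EXCLUDED_PSYCH_TERMS[:4]):
        add(f"psychiatric event {j}", f"hlt psych {j}", hlgt, PSYCH_SOC)
    for j, hlgt in enumerate(PSYCH_KEPT_HLGTS * 2):
        add(f"psychiatric event kept {j}", f"hlt psych kept {j}", hlgt, PSYCH_SOC)
    j = 0
    while idx < params.n_adrs:
        soc = kept_socs[j % len(kept_socs)]
        add(f"{soc.split()[0].lower()} reaction {j}", f"hlt {soc} {j}",
            f"hlgt {soc}", soc)
        j += 1
    return terms[: params.n_adrs]


# --------------------------------------------------------------------------
# Proteome


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


@dataclass
class Proteome:
    uniprot_ids: list[str]
    gene_names: dict[str, str]
    sequences: dict[str, str]
    family_of: dict[str, int]
    founders: list[str]  # per family
    go_terms: dict[str, list[str]]
    identity: dict[tuple[str, str], float]  # full symmetric matrix

    def ident(self, a: str, b: str) -> float:
        return 1.0 if a == b else self.identity[tuple(sorted((a, b)))]


def generate_proteome(params: GeneratorParams,
                      rng: np.random.Generator) -> Proteome:
    """Sequence families with enforced identity bands.

    Family founders are random sequences; one member per family is a
    near-duplicate (92-97% identity, collapsed at the 90% stage), the
    remaining members are siblings inside the band around
    ``within_family_identity`` (clustered at 70% but kept at 90%).  All
    bands are verified with the pipeline's own pairwise identity function
    and resampled until satisfied; cross-family identity is verified to
    stay below ``between_family_identity``.
    """
    m = params.members_per_family
    sib_lo = max(0.705, params.within_family_identity - 0.06)
    sib_hi = min(0.88, params.within_family_identity + 0.08)
    ids: list[str] = []
    seqs: dict[str, str] = {}
    fam_of: dict[str, int] = {}
    founders: list[str] = []
    for fam in range(params.n_families):
        length = 320 - 12 * fam  # distinct per family -> stable greedy order
        founder_id = f"T{fam:02d}A"
        founder_seq = _random_sequence(rng, length)
        fam_ids = [founder_id]
        fam_seqs = {founder_id: founder_seq}
        for member in range(1, m):
            mid = f"T{fam:02d}{string.ascii_uppercase[member]}"
            near_dup = member == 1
            lo, hi = (0.92, 0.97) if near_dup else (sib_lo, sib_hi)
            rate = 0.05 if near_dup else 1.0 - params.within_family_identity
            for _ in range(200):
                cand = _mutate(rng, founder_seq, rate)
                ident = pairwise_identity(cand, founder_seq)
                if not (lo <= ident <= hi):
                    continue
                # non-founder members must stay apart from each other so the
                # 90% stage only merges the designed near-duplicate
                if all(
                    pairwise_identity(cand, fam_seqs[o]) < 0.88
                    for o in fam_ids[1:]
                ):
                    break
            else:  # pragma: no cover - rejection loop exhausted
                raise RuntimeError("could not satisfy identity band")
            fam_ids.append(mid)
            fam_seqs[mid] = cand
        ids.extend(fam_ids)
        seqs.update(fam_seqs)
        for i in fam_ids:
            fam_of[i] = fam
        founders.append(founder_id)

    identity: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ident = pairwise_identity(seqs[a], seqs[b])
            identity[tuple(sorted((a, b)))] = ident
            if fam_of[a] != fam_of[b] and ident >= params.between_family_identity:
                raise RuntimeError(
                    f"cross-family identity {ident:.2f} between {a} and {b}"
                )

    go: dict[str, list[str]] = {}
    go_pool = ["GO:0005515", "GO:0007165", "GO:0016020", "GO:0005886"]
    annotated = set(range(params.n_families - params.go_annotated_families,
                          params.n_families))
    for u in ids:
        go[u] = [go_pool[rng.integers(len(go_pool))]]
        if fam_of[u] in annotated:
            go[u] = sorted(set(go[u]) | set(DEFAULT_EXCLUDED_GO_TERMS))
    gene_names = {u: f"GN{u[1:]}" for u in ids}
    return Proteome(ids, gene_names, seqs, fam_of, founders, go, identity)


# --------------------------------------------------------------------------
# Chemistry


_SCAFFOLDS = ["c1ccccc1", "C1CCCCC1", "c1ccncc1", "C1CCNCC1",
              "c1ccsc1", "C1CCOC1", "c1ccc2ccccc2c1", "C1CCC(CC1)O"]
_ALT_SCAFFOLDS = ["N1CCNCC1", "OC1CCOC1", "SC1CCCC1"]
_TAILS = ["O", "N", "Cl", "F", "S", "OC(=O)", "NC(=O)", "OC"]


def _smiles_pool(n: int) -> list[str]:
    """Deterministic pool of distinct, valid SMILES."""
    pool: list[str] = []
    seen: set[str] = set()
    chain = 1
    while len(pool) < n:
        for tail in _TAILS:
            for scaf in _SCAFFOLDS:
                smi = f"{tail}{'C' * chain}{scaf}"
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    continue
                canonical = Chem.MolToSmiles(mol)
                if canonical in seen:
                    continue
                seen.add(canonical)
                pool.append(smi)
                if len(pool) == n:
                    return pool
        chain += 1
    return pool


def _inchikey_like(smiles: str) -> str:
    """Deterministic 14-10-1 uppercase key hashed from the SMILES."""
    digest = hashlib.sha256(smiles.encode()).digest()
    letters = [string.ascii_uppercase[b % 26] for b in digest[:25]]
    return "".join(letters[:14]) + "-" + "".join(letters[14:24]) + "-N"


@dataclass
class Chemistry:
    names: dict[str, str]  # entity index (as str) handled via lists below
    adr_ids: list[str]
    target_ids: list[str]
    adr_records: list[dict]
    target_records: list[dict]
    synonym_table: dict[str, str]
    variants: dict[str, list[str]]  # adr_id -> resolvable raw variants
    conflict_adr_ids: list[str]
    two_sided_adr_ids: list[str]  # expected to unify
    bindings: dict[str, set[str]]  # target-side drug id -> bound uniprots
    binding_records: list[dict]  # emitted drug-target rows + pass flags
    adr_id_of_target_id: dict[str, str]


def generate_chemistry(params: GeneratorParams, proteome: Proteome,
                       rng: np.random.Generator) -> Chemistry:
    """Drug entities, structures, name variants and target bindings.

    Family founders act as pharmacological hub targets: drugs pick their
    primary target with a founder bias and additionally bind family
    siblings and (more rarely) other families' founders, reproducing the
    promiscuity pattern that motivates family-aware filtering.  Affinities
    are sampled so a known fraction passes the potency/confidence
    thresholds, with a few pairs placed exactly on the boundaries.
    """
    n_two = params.n_drugs - params.n_adr_only_drugs - params.n_target_only_drugs
    smiles = _smiles_pool(params.n_drugs)
    alt_smiles = []
    chain = 4
    for scaf in _ALT_SCAFFOLDS:
        alt_smiles.append(f"N{'C' * chain}{scaf}")
    conflict_pos = list(range(n_two - params.n_conflict_drugs, n_two))

    adr_ids, target_ids = [], []
    adr_records, target_records = [], []
    synonyms: dict[str, str] = {}
    variants: dict[str, list[str]] = {}
    adr_of_tgt: dict[str, str] = {}
    conflict_adr_ids: list[str] = []
    two_sided_adr_ids: list[str] = []

    for i in range(params.n_drugs):
        name = f"drug{i:03d}"
        on_adr_side = i < n_two + params.n_adr_only_drugs
        on_target_side = i < n_two or i >= n_two + params.n_adr_only_drugs
        smi = smiles[i]
        conflict = i in conflict_pos
        if conflict:
            alt = alt_smiles[conflict_pos.index(i) % len(alt_smiles)]
            sim = tanimoto(smi, alt)
            if sim >= 0.7:  # pragma: no cover - fixed structures are dissimilar
                raise RuntimeError(f"conflict structures too similar: {sim}")
        if on_adr_side:
            aid = f"A{i:03d}"
            adr_ids.append(aid)
            has_key = (not conflict) and rng.random() < 0.6
            has_smi = conflict or rng.random() < 0.85
            adr_records.append({
                "drug_id": aid,
                "standard_name": name,
                "inchikey": _inchikey_like(smi) if has_key else None,
                "smiles": smi if has_smi else None,
            })
            var = [name, name.upper(), f"{name} FC", f"{name.upper()} TAB"]
            variants[aid] = var
            for v in var:
                synonyms[v] = aid
        if on_target_side:
            tid = f"C{i:03d}"
            target_ids.append(tid)
            t_smi = alt if conflict else smi
            target_records.append({
                "drug_id": tid,
                "standard_name": name,
                "inchikey": _inchikey_like(t_smi),
                "smiles": t_smi,
            })
            if on_adr_side:
                adr_of_tgt[tid] = f"A{i:03d}"
                if conflict:
                    conflict_adr_ids.append(f"A{i:03d}")
                else:
                    two_sided_adr_ids.append(f"A{i:03d}")

    # bindings for target-side drugs
    m = params.members_per_family
    members_by_family = [
        [u for u in proteome.uniprot_ids if proteome.family_of[u] == f]
        for f in range(params.n_families)
    ]
    bindings: dict[str, set[str]] = {}
    records: list[dict] = []
    used_boundary = {"dtc": False, "stitch": False}
    for tid in target_ids:
        fam = int(rng.integers(params.n_families))
        fam_members = members_by_family[fam]
        if rng.random() < params.founder_primary_bias:
            primary = fam_members[0]
        else:
            primary = fam_members[1 + int(rng.integers(m - 1))]
        bound = {primary}
        for u in fam_members:
            if u != primary and rng.random() < params.sibling_bind_rate:
                bound.add(u)
        for f2 in range(params.n_families):
            if f2 == fam:
                continue
            for j, u in enumerate(members_by_family[f2]):
                rate = (params.cross_family_founder_bind_rate if j == 0
                        else params.cross_family_member_bind_rate)
                if rng.random() < rate:
                    bound.add(u)
        bindings[tid] = bound
        for u in sorted(bound):
            passes = bool(rng.random() < params.affinity_pass_rate)
            dual = rng.random() < params.dual_source_binding_rate
            srcs = ["dtc_like", "stitch_like"] if dual else (
                ["dtc_like"] if rng.random() < 0.5 else ["stitch_like"])
            for src in srcs:
                if src == "dtc_like":
                    if passes and not used_boundary["dtc"]:
                        value = 100.0  # boundary: "100 nM or better" is kept
                        used_boundary["dtc"] = True
                    elif passes:
                        value = round(10 ** rng.uniform(0.0, 2.0), 2)
                    else:
                        value = round(10 ** rng.uniform(2.2, 4.0), 2)
                else:
                    if passes and not used_boundary["stitch"]:
                        value = 0.8  # boundary: cut-off score itself passes
                        used_boundary["stitch"] = True
                    elif passes:
                        value = round(rng.uniform(0.8, 1.0), 3)
                    else:
                        value = round(rng.uniform(0.3, 0.79), 3)
                records.append({"drug_id": tid, "uniprot_id": u, "source": src,
                                "value": value, "passes": passes})
    return Chemistry(
        names={}, adr_ids=adr_ids, target_ids=target_ids,
        adr_records=adr_records, target_records=target_records,
        synonym_table=synonyms, variants=variants,
        conflict_adr_ids=conflict_adr_ids,
        two_sided_adr_ids=two_sided_adr_ids,
        bindings=bindings, binding_records=records,
        adr_id_of_target_id=adr_of_tgt,
    )


# --------------------------------------------------------------------------
# Reports and curated pairs


_COUNTRIES = ["US", "CA", "GB", "DE", "FR", "JP"]


@dataclass
class ReportSet:
    reports: list[dict]  # emission rows
    emitted: int
    misspelled_mentions: int
    duplicate_copies_resolvable: int
    expected_after_norm: int
    expected_after_dedup: int


@dataclass
class FixtureData:
    params: GeneratorParams
    vocabulary: list[AdrTerm]
    proteome: Proteome
    chemistry: Chemistry
    truth_adrs: dict[str, set[str]]  # adr drug id -> true PT set
    causal_pairs: set[tuple[str, str]]
    planted_links: list[tuple[str, str]]
    idio_pool: list[str]
    report_sets: dict[str, ReportSet]
    curated: dict[str, set[tuple[str, str]]]
    ground_truth: GroundTruth


def _draw_truth(params: GeneratorParams, chem: Chemistry,
                planted: list[tuple[str, str]], idio_pool: list[str],
                rng: np.random.Generator
                ) -> tuple[dict[str, set[str]], set[tuple[str, str]]]:
    tgt_of_adr = {v: k for k, v in chem.adr_id_of_target_id.items()}
    truth: dict[str, set[str]] = {}
    causal: set[tuple[str, str]] = set()
    by_target: dict[str, list[str]] = {}
    for u, pt in planted:
        by_target.setdefault(u, []).append(pt)
    for aid in chem.adr_ids:
        k = int(np.clip(rng.poisson(params.idio_adr_mean), 8, len(idio_pool)))
        pts = set(rng.choice(idio_pool, size=k, replace=False))
        tid = tgt_of_adr.get(aid)
        if tid is not None:
            for u in chem.bindings.get(tid, ()):
                for pt in by_target.get(u, ()):
                    if rng.random() < params.causal_adr_rate:
                        pts.add(pt)
                        causal.add((aid, pt))
        truth[aid] = pts
    return truth, causal


def _generate_reports(params: GeneratorParams, chem: Chemistry,
                      truth: dict[str, set[str]], all_pts: list[str],
                      n_reports: int, prefix: str,
                      rng: np.random.Generator) -> ReportSet:
    adr_ids = chem.adr_ids
    misspelled = 0
    rows: list[dict] = []
    keys_seen: set[tuple] = set()
    for i in range(n_reports):
        drugs = [adr_ids[int(rng.integers(len(adr_ids)))]]
        if rng.random() < params.two_drug_report_rate:
            other = adr_ids[int(rng.integers(len(adr_ids)))]
            if other != drugs[0]:
                drugs.append(other)
        truth_union = sorted(set().union(*(truth[d] for d in drugs)))
        pts = [p for p in truth_union if rng.random() < params.report_adr_rate]
        others = [p for p in all_pts if p not in set(truth_union)]
        pts += [p for p in others if rng.random() < params.adr_background_rate]
        if not pts:
            pts = [truth_union[int(rng.integers(len(truth_union)))]]
        pts = sorted(set(pts))
        raw_names, resolvable_ids = [], []
        for d in drugs:
            if rng.random() < params.misspelling_rate:
                raw_names.append("xx" + chem.variants[d][0])
                misspelled += 1
            else:
                var = chem.variants[d]
                raw_names.append(var[int(rng.integers(len(var)))])
                resolvable_ids.append(d)
        age = int(np.clip(round(rng.normal(55, 15)), 18, 90))
        if rng.random() < 0.07:
            age = None
        sex = ["M", "F", "unknown"][int(rng.choice(3, p=[0.45, 0.45, 0.10]))]
        weight = round(float(rng.normal(75, 12)), 1)
        if rng.random() < 0.07:
            weight = None
        day = int(rng.integers(730))
        date = (np.datetime64("2019-01-01") + np.timedelta64(day, "D"))
        country = _COUNTRIES[int(rng.integers(len(_COUNTRIES)))]
        if rng.random() < 0.05:
            country = None
        row = {
            "report_id": f"{prefix}{i:06d}",
            "drugs": raw_names,
            "pts": pts,
            "age": age,
            "sex": sex,
            "weight": weight,
            "event_date": str(date),
            "country": country,
            "_resolvable_ids": sorted(set(resolvable_ids)),
            "_is_dup": False,
        }
        # keep demographic keys of resolvable originals unique so the
        # dedup bookkeeping is exact (accidental collisions are perturbed)
        if row["_resolvable_ids"]:
            key = (tuple(row["_resolvable_ids"]), tuple(pts), age, sex,
                   weight, row["event_date"], country)
            while key in keys_seen:
                weight = (weight or 70.0) + 0.1
                weight = round(weight, 1)
                row["weight"] = weight
                key = (tuple(row["_resolvable_ids"]), tuple(pts), age, sex,
                       weight, row["event_date"], country)
            keys_seen.add(key)
        rows.append(row)

    n_dup = int(round(params.duplicate_rate * n_reports))
    dup_sources = rng.choice(n_reports, size=n_dup, replace=False)
    dup_resolvable = 0
    for j, src in enumerate(sorted(int(s) for s in dup_sources)):
        copy = dict(rows[src])
        copy["report_id"] = f"{prefix}{n_reports + j:06d}"
        copy["_is_dup"] = True
        if copy["_resolvable_ids"]:
            dup_resolvable += 1
        rows.append(copy)

    after_norm = sum(1 for r in rows if r["_resolvable_ids"])
    after_dedup = after_norm - dup_resolvable
    return ReportSet(
        reports=rows,
        emitted=len(rows),
        misspelled_mentions=misspelled,
        duplicate_copies_resolvable=dup_resolvable,
        expected_after_norm=after_norm,
        expected_after_dedup=after_dedup,
    )


def generate_reports_and_pairs(
    params: GeneratorParams, chem: Chemistry,
    truth: dict[str, set[str]], all_pts: list[str],
    rng: np.random.Generator,
) -> tuple[dict[str, ReportSet], dict[str, set[tuple[str, str]]]]:
    """Two spontaneous-report sources and two curated pair sources, all
    drawn from the same drug-level ADR truth so that cross-source
    intersection retains the planted signals."""
    reports = {
        "faers_like": _generate_reports(
            params, chem, truth, all_pts, params.n_reports, "RA", rng),
        "medeffect_like": _generate_reports(
            params, chem, truth, all_pts,
            int(params.n_reports * params.second_source_report_fraction),
            "RB", rng),
    }
    curated: dict[str, set[tuple[str, str]]] = {}
    for tag, cov in (("sider_like", params.curated_coverage_a),
                     ("offsides_like", params.curated_coverage_b)):
        pairs = {
            (d, pt)
            for d in chem.adr_ids
            for pt in sorted(truth[d])
            if rng.random() < cov
        }
        n_noise = int(round(params.curated_noise_rate
                            * len(chem.adr_ids) * params.n_adrs))
        added = 0
        while added < n_noise:
            d = chem.adr_ids[int(rng.integers(len(chem.adr_ids)))]
            pt = all_pts[int(rng.integers(len(all_pts)))]
            if pt not in truth[d] and (d, pt) not in pairs:
                pairs.add((d, pt))
                added += 1
        curated[tag] = pairs
    return reports, curated


# --------------------------------------------------------------------------
# Expected survivor bookkeeping


def _replicate_greedy(candidates: list[str], proteome: Proteome,
                      threshold: float) -> dict[str, list[str]]:
    """Independent replication of greedy length-ordered clustering using
    the generator's identity matrix."""
    ordered = sorted(candidates,
                     key=lambda u: (-len(proteome.sequences[u]), u))
    clusters: dict[str, list[str]] = {}
    for u in ordered:
        for c in clusters:
            if proteome.ident(u, c) >= threshold:
                clusters[c].append(u)
                break
        else:
            clusters[u] = [u]
    return clusters


def _expected_stages(params: GeneratorParams, vocab: list[AdrTerm],
                     proteome: Proteome, chem: Chemistry,
                     curated: dict[str, set[tuple[str, str]]],
                     kept_pts: set[str]) -> dict:
    # --- curated ADR branch -------------------------------------------------
    union_pairs = set().union(*curated.values())
    after_soc = {(d, pt) for d, pt in union_pairs if pt in kept_pts}
    merged = set(chem.two_sided_adr_ids)
    after_unify = {(d, pt) for d, pt in after_soc if d in merged}
    per_drug: dict[str, set[str]] = {}
    for d, pt in after_unify:
        per_drug.setdefault(d, set()).add(pt)
    sparse_dropped = {d for d, pts in per_drug.items() if len(pts) < 10}
    after_sparse = {(d, pt) for d, pt in after_unify if d not in sparse_dropped}

    # --- target branch ------------------------------------------------------
    pair_pass: dict[tuple[str, str], bool] = {}
    for rec in chem.binding_records:
        key = (rec["drug_id"], rec["uniprot_id"])
        pair_pass[key] = pair_pass.get(key, False) or rec["passes"]
    emitted = set(pair_pass)
    after_affinity = {k for k, ok in pair_pass.items() if ok}
    go_excluded = {
        u for u in proteome.uniprot_ids
        if set(proteome.go_terms[u]) & set(DEFAULT_EXCLUDED_GO_TERMS)
    }
    after_go = {(d, u) for d, u in after_affinity if u not in go_excluded}
    mapped = {
        (chem.adr_id_of_target_id[d], u)
        for d, u in after_go
        if chem.adr_id_of_target_id.get(d) in merged
    }
    surviving_targets = sorted({u for _, u in mapped})
    clusters90 = _replicate_greedy(surviving_targets, proteome, 0.90)
    centroid90 = {m: c for c, ms in clusters90.items() for m in ms}
    after_dedupe90 = {(d, centroid90[u]) for d, u in mapped}
    centroids = sorted(clusters90)
    families70 = _replicate_greedy(centroids, proteome, 0.70)
    fam_centroid = {m: c for c, ms in families70.items() for m in ms}
    # family-size cap: collapse (drug, family) bindings above the cap
    per_drug_fam: dict[tuple[str, str], set[str]] = {}
    for d, u in after_dedupe90:
        per_drug_fam.setdefault((d, fam_centroid[u]), set()).add(u)
    after_cap = set()
    for (d, c), members in per_drug_fam.items():
        if len(members) > 10:
            after_cap.add((d, c))
        else:
            after_cap.update((d, u) for u in members)
    # main-target prune
    binding: dict[str, set[str]] = {}
    for d, u in after_cap:
        binding.setdefault(u, set()).add(d)
    keep: set[str] = set()
    for c, members in families70.items():
        present = sorted(u for u in members if u in binding)
        if not present:
            continue
        best_n = max(len(binding[u]) for u in present)
        main = min(u for u in present if len(binding[u]) == best_n)
        keep.add(main)
        for u in present:
            if u != main and (
                len(binding[u] & binding[main]) / len(binding[main])
                >= 0.50
            ):
                keep.add(u)
    after_prune = {(d, u) for d, u in after_cap if u in keep}
    universe = sorted(
        {d for d, _ in after_sparse} & {d for d, _ in after_prune}
    )

    def pl(pairs):  # deterministic listing
        return sorted([list(p) for p in pairs])

    return {
        "curated_pairs_union": pl(union_pairs),
        "curated_pairs_after_soc": pl(after_soc),
        "curated_pairs_after_unify": pl(after_unify),
        "curated_sparse_dropped_drugs": sorted(sparse_dropped),
        "curated_pairs_after_sparse": pl(after_sparse),
        "unified_adr_ids": sorted(merged),
        "unmatched_adr_ids": sorted(
            set(chem.adr_ids) - merged
        ),
        "target_pairs_emitted": pl(emitted),
        "target_pairs_after_affinity": pl(after_affinity),
        "target_pairs_after_go": pl(after_go),
        "target_pairs_after_unify": pl(mapped),
        "clusters_90": {c: sorted(ms) for c, ms in clusters90.items()},
        "target_pairs_after_dedupe90": pl(after_dedupe90),
        "families_70": {c: sorted(ms) for c, ms in families70.items()},
        "target_pairs_after_family_cap": pl(after_cap),
        "target_pairs_after_main_prune": pl(after_prune),
        "surviving_targets_final": sorted(keep),
        "curated_universe": universe,
    }


# --------------------------------------------------------------------------
# Top level


def generate_fixture(params: GeneratorParams) -> FixtureData:
    """Generate the whole ecosystem in memory with its ground truth."""
    rng = np.random.default_rng(params.seed)
    vocab = generate_vocabulary(params)
    from .datamodel import PipelineConfig
    from .adr_filter import is_excluded_term

    cfg = PipelineConfig()
    kept_pts = [t.pt_code for t in vocab if not is_excluded_term(t, cfg)]
    excl_pts = [t.pt_code for t in vocab if is_excluded_term(t, cfg)]
    proteome = generate_proteome(params, rng)
    chem = generate_chemistry(params, proteome, rng)

    # idiosyncratic ADR pool: common reactions, partly from excluded SOCs
    n_excl = min(params.idio_pool_excluded_socs, len(excl_pts))
    n_kept_pool = params.idio_pool_size - n_excl
    pool = sorted(excl_pts[:n_excl] + kept_pts[:n_kept_pool])
    plantable = [p for p in kept_pts if p not in set(pool)]
    causal_families = params.n_families - params.go_annotated_families
    founders = proteome.founders[:causal_families]
    pt_pick = rng.choice(len(plantable), size=params.planted_link_count,
                         replace=False)
    planted = [
        (founders[i % len(founders)], plantable[int(j)])
        for i, j in enumerate(pt_pick)
    ]

    truth, causal = _draw_truth(params, chem, planted, pool, rng)
    all_pts = [t.pt_code for t in vocab]
    report_sets, curated = generate_reports_and_pairs(
        params, chem, truth, all_pts, rng)

    expected = _expected_stages(params, vocab, proteome, chem, curated,
                                set(kept_pts))
    report_stats = {
        tag: {
            "emitted": rs.emitted,
            "misspelled_mentions": rs.misspelled_mentions,
            "duplicate_copies_resolvable": rs.duplicate_copies_resolvable,
            "expected_after_norm": rs.expected_after_norm,
            "expected_after_dedup": rs.expected_after_dedup,
        }
        for tag, rs in report_sets.items()
    }
    gt = GroundTruth(
        params={f.name: getattr(params, f.name)
                for f in dc_fields(GeneratorParams)},
        planted_links=sorted([list(p) for p in planted]),
        family_map=dict(sorted(proteome.family_of.items())),
        causal_drug_adr_pairs=sorted([list(p) for p in causal]),
        kept_pt_codes=sorted(kept_pts),
        excluded_pt_codes=sorted(excl_pts),
        report_stats=report_stats,
        expected=expected,
    )
    return FixtureData(
        params=params, vocabulary=vocab, proteome=proteome, chemistry=chem,
        truth_adrs=truth, causal_pairs=causal, planted_links=planted,
        idio_pool=pool, report_sets=report_sets, curated=curated,
        ground_truth=gt,
    )


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")


def emit_fixture(params: GeneratorParams, outdir: str | Path) -> GroundTruth:
    """Write every interchange file plus ground_truth.json into outdir."""
    fx = generate_fixture(params)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    _write_tsv(out / "vocabulary.tsv",
               ["pt_code", "pt_name", "hlt", "hlgt", "soc"],
               [[t.pt_code, t.pt_name, t.hlt, t.hlgt, t.soc]
                for t in fx.vocabulary])
    _write_tsv(out / "drugs_adr_side.tsv",
               ["drug_id", "standard_name", "inchikey", "smiles"],
               [[r["drug_id"], r["standard_name"], r["inchikey"], r["smiles"]]
                for r in fx.chemistry.adr_records])
    _write_tsv(out / "drugs_target_side.tsv",
               ["drug_id", "standard_name", "inchikey", "smiles"],
               [[r["drug_id"], r["standard_name"], r["inchikey"], r["smiles"]]
                for r in fx.chemistry.target_records])
    _write_tsv(out / "synonyms.tsv", ["raw_name", "drug_id"],
               sorted([[k, v] for k, v in fx.chemistry.synonym_table.items()]))
    with (out / "targets.fasta").open("w") as fh:
        for u in fx.proteome.uniprot_ids:
            fh.write(f">{u}|{fx.proteome.gene_names[u]}\n")
            fh.write(fx.proteome.sequences[u] + "\n")
    _write_tsv(out / "go_annotations.tsv", ["uniprot_id", "go_id"],
               [[u, g] for u in fx.proteome.uniprot_ids
                for g in fx.proteome.go_terms[u]])
    for src in ("dtc_like", "stitch_like"):
        col = "affinity_nM" if src == "dtc_like" else "confidence"
        rows = [[r["drug_id"], r["uniprot_id"], r["value"]]
                for r in fx.chemistry.binding_records if r["source"] == src]
        _write_tsv(out / f"drug_targets_{src}.tsv",
                   ["drug_id", "uniprot_id", col], rows)
    for tag in ("sider_like", "offsides_like"):
        rows = sorted([[d, pt] for d, pt in fx.curated[tag]])
        _write_tsv(out / f"pairs_{tag}.tsv", ["drug_id", "pt_code"], rows)
    name_of = {"faers_like": "reports_faers_like.tsv",
               "medeffect_like": "reports_medeffect_like.tsv"}
    for tag, rs in fx.report_sets.items():
        rows = [[r["report_id"], ";".join(r["drugs"]), ";".join(r["pts"]),
                 r["age"], r["sex"], r["weight"], r["event_date"],
                 r["country"]] for r in rs.reports]
        _write_tsv(out / name_of[tag],
                   ["report_id", "drugs", "pts", "age", "sex", "weight",
                    "event_date", "country"], rows)
    fx.ground_truth.to_json(out / "ground_truth.json")
    return fx.ground_truth


def generate_null_reports(n_drugs: int, n_adrs: int, n_reports: int,
                          seed: int) -> list[SpontaneousReport]:
    """Reports in which the ADR is assigned independently of the drug.

    One PT per report, drawn from a fixed global popularity distribution;
    used to check the calibration of the disproportionality screen.
    """
    rng = np.random.default_rng(seed)
    weights = 1.0 / np.arange(1, n_adrs + 1)  # long-tailed term popularity
    probs = weights / weights.sum()
    reports = []
    for i in range(n_reports):
        d = int(rng.integers(n_drugs))
        a = int(rng.choice(n_adrs, p=probs))
        rep = SpontaneousReport(
            report_id=f"N{i:06d}",
            raw_drug_names=[f"drug{d:03d}"],
            pt_codes=[f"P{a:04d}"],
        )
        rep.drug_ids = [f"D{d:03d}"]
        reports.append(rep)
    return reports
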