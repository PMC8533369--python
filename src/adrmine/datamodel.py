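"""Shared domain types, identifier conventions and pipeline configuration.

All identifiers in the pipeline are opaque strings (never positional
indices) so that tables merged from different sources cannot silently
collide.  The configuration is strict-keyed: a misspelled threshold in a
config file raises instead of silently falling back to a default.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "DrugEntity",
    "AdrTerm",
    "SpontaneousReport",
    "TargetProtein",
    "DrugAdrPair",
    "DrugTargetPair",
    "ContingencyTable",
    "AssociationResult",
    "PipelineConfig",
    "ConfigError",
    "FormatError",
    "load_config",
    "save_config",
    "INCHIKEY_PATTERN",
    "DEFAULT_EXCLUDED_SOCS",
    "DEFAULT_EXCLUDED_PSYCH_TERMS",
    "DEFAULT_EXCLUDED_GO_TERMS",
]


class ConfigError(ValueError):
    """Raised for malformed or unknown configuration content."""


class FormatError(ValueError):
    """Raised for malformed interchange files."""


#: 14-10-1 dash-separated uppercase block pattern of an InChIKey.
INCHIKEY_PATTERN = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

#: System organ classes whose terms are unspecific to underlying human
#: biology (external causes, investigations, product issues ...) and are
#: excluded from association mining.
DEFAULT_EXCLUDED_SOCS = [
    "General disorders and administration site conditions",
    "Injury, poisoning and procedural complications",
    "Investigations",
    "Neoplasms benign, malignant and unspecified (incl. cysts and polyps)",
    "Product issues",
    "Social circumstances",
    "Surgical and medical procedures",
    "Infections and infestations",
]

#: Within SOC "Psychiatric disorders", high-level (group) terms excluded as
#: too general or broad; the remaining psychiatric terms are kept.
DEFAULT_EXCLUDED_PSYCH_TERMS = [
    "depressed mood disorders and disturbances",
    "eating disorders and disturbances",
    "impulse control disorders NEC",
    "manic and bipolar mood disorders and disturbances",
    "personality disorders and disturbances in behaviour",
    "psychiatric disorders NEC",
    "suicidal and self-injurious behaviours NEC",
    "paraphilias and paraphilic disorders",
    "sexual and gender identity disorders NEC",
]

#: GO annotations marking drug-metabolism proteins (catabolic / metabolic
#: process); binding to these reflects pharmacokinetics, not pharmacology.
DEFAULT_EXCLUDED_GO_TERMS = ["GO:0042737", "GO:0017144"]


@dataclass(frozen=True)
class DrugEntity:
    """A unified chemical identity linking the ADR side to the target side."""

    drug_id: str
    standard_name: str
    inchikey: Optional[str] = None
    smiles: Optional[str] = None
    synonyms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.standard_name:
            raise ValueError("standard_name must be non-empty")
        if self.inchikey is not None and not INCHIKEY_PATTERN.match(self.inchikey):
            raise ValueError(f"malformed InChIKey: {self.inchikey!r}")
        if self.standard_name not in self.synonyms:
            object.__setattr__(
                self, "synonyms", self.synonyms | {self.standard_name}
            )


@dataclass(frozen=True)
class AdrTerm:
    """A MedDRA-style preferred term with its SOC lineage.

    Each preferred term maps to exactly one primary system organ class.
    """

    pt_code: str
    pt_name: str
    hlt: str
    hlgt: str
    soc: str


@dataclass
class SpontaneousReport:
    """One pharmacovigilance report before curation."""

    report_id: str
    raw_drug_names: list[str]
    pt_codes: list[str]
    age: Optional[float] = None
    sex: str = "unknown"
    weight: Optional[float] = None
    event_date: Optional[str] = None
    country: Optional[str] = None
    drug_ids: Optional[list[str]] = None  # populated by name normalization

    def __post_init__(self) -> None:
        if not self.raw_drug_names or not self.pt_codes:
            raise ValueError("report needs at least one drug name and one PT")


@dataclass(frozen=True)
class TargetProtein:
    """A protein target with sequence and GO annotation."""

    uniprot_id: str
    gene_name: str
    sequence: str
    go_terms: frozenset[str] = field(default_factory=frozenset)

    _RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

    def __post_init__(self) -> None:
        bad = set(self.sequence) - self._RESIDUES
        if bad:
            raise ValueError(f"non-standard residues in {self.uniprot_id}: {bad}")


@dataclass(frozen=True)
class DrugAdrPair:
    """One (drug, preferred term) evidence pair with source provenance."""

    drug_id: str
    pt_code: str
    source: str
    evidence_stat: Optional[float] = None  # LLR for self-reporting evidence


@dataclass(frozen=True)
class DrugTargetPair:
    """One (drug, protein) binding pair; affinity for DTC-like sources,
    confidence for STITCH-like sources (exactly one present)."""

    drug_id: str
    uniprot_id: str
    source: str
    affinity_nM: Optional[float] = None
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.affinity_nM is None) == (self.confidence is None):
            raise ValueError(
                "exactly one of affinity_nM / confidence must be present"
            )
        if self.affinity_nM is not None and self.affinity_nM <= 0:
            raise ValueError("affinity_nM must be positive")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")


@dataclass(frozen=True)
class ContingencyTable:
    """Drug counts for one (protein, ADR) pair over the drug universe.

    ``n_adr_and_target`` is the number of drugs that both present the ADR
    and bind the protein; the margins (drugs with the ADR, drugs binding
    the target) and the universe size are derived.
    """

    n_adr_and_target: int
    n_target_only: int
    n_adr_only: int
    n_neither: int

    def __post_init__(self) -> None:
        for cell in (
            self.n_adr_and_target,
            self.n_target_only,
            self.n_adr_only,
            self.n_neither,
        ):
            if cell < 0:
                raise ValueError("contingency cells must be non-negative")

    @property
    def n_adr(self) -> int:
        """Margin (i): drugs presenting the ADR."""
        return self.n_adr_and_target + self.n_adr_only

    @property
    def n_target(self) -> int:
        """Margin (ii): drugs binding the target."""
        return self.n_adr_and_target + self.n_target_only

    @property
    def n_total(self) -> int:
        """Universe size N (all four cells)."""
        return (
            self.n_adr_and_target
            + self.n_target_only
            + self.n_adr_only
            + self.n_neither
        )

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (
            self.n_adr_and_target,
            self.n_target_only,
            self.n_adr_only,
            self.n_neither,
        )


@dataclass
class AssociationResult:
    """One protein-ADR association with its statistical support."""

    uniprot_id: str
    gene_name: str
    pt_code: str
    pt_name: str
    soc: str
    p_value: float
    q_value: float
    table: ContingencyTable
    evidence_set: str  # "self-reporting" | "curated"
    drug_ids: frozenset[str] = field(default_factory=frozenset)
    sources: str = ""
    significant: bool = False


# --------------------------------------------------------------------------
# Configuration


@dataclass
class PipelineConfig:
    """Every numeric threshold of the mining pipeline, with its default.

    Potency "100 nM or better" means ``affinity_nM <= ic50_max_nM`` (lower
    is stronger); the interaction-confidence cut-off means
    ``confidence >= stitch_min_score`` on the [0, 1] scale.
    """

    ic50_max_nM: float = 100.0
    stitch_min_score: float = 0.8
    tanimoto_min: float = 0.7
    min_adrs_per_drug: int = 10
    redundancy_identity: float = 0.90
    family_identity: float = 0.70
    max_family_size: int = 10
    main_target_share: float = 0.50
    q_threshold: float = 0.05
    lrt_alpha: float = 0.05
    lrt_mc_reps: int = 1000
    rng_seed: int = 0
    excluded_socs: list[str] = field(
        default_factory=lambda: list(DEFAULT_EXCLUDED_SOCS)
    )
    excluded_psych_terms: list[str] = field(
        default_factory=lambda: list(DEFAULT_EXCLUDED_PSYCH_TERMS)
    )
    excluded_go_terms: list[str] = field(
        default_factory=lambda: list(DEFAULT_EXCLUDED_GO_TERMS)
    )
    # behavioural switches (documented alternatives)
    fisher_alternative: str = "greater"  # or "two-sided"
    test_zero_overlap: bool = False  # also test pairs with cell (iii) = 0
    merge_redundant_evidence: bool = True  # union drugs into 90% centroid

    def __post_init__(self) -> None:
        if self.ic50_max_nM <= 0:
            raise ConfigError("ic50_max_nM must be positive")
        for name in ("stitch_min_score", "tanimoto_min", "redundancy_identity",
                     "family_identity", "main_target_share", "q_threshold",
                     "lrt_alpha"):
            v = getattr(self, name)
            if not (0.0 <= float(v) <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.min_adrs_per_drug < 0 or self.max_family_size < 1:
            raise ConfigError("count thresholds out of range")
        if self.lrt_mc_reps < 100:
            raise ConfigError("lrt_mc_reps must be >= 100")
        if self.fisher_alternative not in ("greater", "two-sided"):
            raise ConfigError(
                f"fisher_alternative must be 'greater' or 'two-sided', "
                f"got {self.fisher_alternative!r}"
            )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    def content_hash(self) -> str:
        """Stable hash of the configuration for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_CONFIG_FIELDS = {f.name: f for f in dc_fields(PipelineConfig)}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a flat YAML ``key: value`` config file.

    Unspecified keys take the pipeline defaults; unknown keys are an error
    naming the offending key (strict-key contract).
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must be a flat key: value map")
    unknown = set(raw) - set(_CONFIG_FIELDS)
    if unknown:
        raise ConfigError(
            f"unknown configuration key(s): {', '.join(sorted(unknown))}"
        )
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Serialize a config so that :func:`load_config` round-trips it."""
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=False, default_flow_style=False)
    )
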