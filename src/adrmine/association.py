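"""Protein-ADR association statistics.

For every (protein, ADR) pair the four drug counts over the unified drug
universe are assembled: (a) drugs with both the ADR and the target,
(b) binding the target only, (c) presenting the ADR only, (d) neither.
The one-sided (enrichment) Fisher exact p-value is the hypergeometric
upper tail P(X >= a) given the margins, computed in log-space for
stability.  P-values are corrected to Storey q-values within each
evidence set (self-reporting and curated evidence are never combined);
when too few tests are available for a stable pi0 estimate the correction
falls back to pi0 = 1, i.e. Benjamini-Hochberg.  An association is
significant when q <= q_threshold.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np

from .datamodel import (
    AssociationResult,
    ContingencyTable,
    DrugAdrPair,
    DrugTargetPair,
    PipelineConfig,
)
from .ingest import Vocabulary

log = logging.getLogger(__name__)

__all__ = [
    "build_table",
    "fisher_p",
    "hypergeom_logpmf",
    "qvalues",
    "storey_pi0",
    "associate",
]


def build_table(
    protein: str,
    adr: str,
    drug_universe: set[str],
    drug_adr_map: dict[str, set[str]],
    drug_target_map: dict[str, set[str]],
) -> ContingencyTable:
    """Assemble the 2x2 drug counts for one (protein, ADR) pair.

    ``drug_adr_map`` maps pt_code -> drugs presenting it and
    ``drug_target_map`` maps uniprot_id -> drugs binding it; both are
    intersected with the universe.  A protein or ADR absent from the maps
    yields an empty margin, not an error.
    """
    adr_drugs = drug_adr_map.get(adr, set()) & drug_universe
    tgt_drugs = drug_target_map.get(protein, set()) & drug_universe
    both = adr_drugs & tgt_drugs
    return ContingencyTable(
        n_adr_and_target=len(both),
        n_target_only=len(tgt_drugs) - len(both),
        n_adr_only=len(adr_drugs) - len(both),
        n_neither=len(drug_universe) - len(adr_drugs | tgt_drugs),
    )


def hypergeom_logpmf(k: int, n_total: int, n_adr: int, n_target: int) -> float:
    """log P(X = k) for X ~ Hypergeom(N, K=n_adr, n=n_target)."""
    return (
        _lchoose(n_adr, k)
        + _lchoose(n_total - n_adr, n_target - k)
        - _lchoose(n_total, n_target)
    )


def _lchoose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_p(table: ContingencyTable, alternative: str = "greater") -> float:
    """Fisher exact p-value for a contingency table.

    The default one-sided (enrichment) alternative returns the upper
    hypergeometric tail P(X >= a) given the margins; "two-sided" sums the
    probabilities of all tables no more probable than the observed one.
    Computed by log-space summation of exact pmf terms.
    """
    a = table.n_adr_and_target
    n_tot, n_adr, n_tgt = table.n_total, table.n_adr, table.n_target
    if n_tot == 0:
        return 1.0
    k_min = max(0, n_adr + n_tgt - n_tot)
    k_max = min(n_adr, n_tgt)
    logpmf = np.array(
        [hypergeom_logpmf(k, n_tot, n_adr, n_tgt) for k in range(k_min, k_max + 1)]
    )
    if alternative == "greater":
        sel = logpmf[a - k_min:]
    elif alternative == "two-sided":
        cutoff = logpmf[a - k_min] + 1e-12  # tolerance for ties
        sel = logpmf[logpmf <= cutoff]
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    m = sel.max()
    p = float(np.exp(m) * np.exp(sel - m).sum())
    return min(p, 1.0)


def storey_pi0(pvalues: Sequence[float]) -> float:
    """Smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the
    grid lambda = 0.05, 0.10, ..., 0.95 and a cubic polynomial smoother is
    read off at the largest lambda, clipped into (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_l = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_l, 3)
    pi0 = float(np.polyval(coeffs, lambdas[-1]))
    return min(max(pi0, 1.0 / len(p)), 1.0)


def qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Storey q-values (BH when the test count is too small for pi0).

    With fewer than 100 p-values the pi0 estimate is unstable, so pi0 = 1
    is used, which reduces to Benjamini-Hochberg.  Output preserves input
    order; q sorted by p is non-decreasing.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = 1.0 if m < 100 else storey_pi0(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def associate(
    evidence_pairs: Iterable[DrugAdrPair],
    target_pairs: Iterable[DrugTargetPair],
    config: PipelineConfig,
    vocabulary: Vocabulary | None = None,
    evidence_set: str = "self-reporting",
    gene_names: dict[str, str] | None = None,
) -> list[AssociationResult]:
    """Test every (protein, ADR) pair over the shared drug universe.

    The universe is the set of drugs present on both evidence sides after
    all upstream filters; by default only pairs with at least one drug in
    cell (a) are tested (a one-sided test cannot reach significance from
    zero overlap, and skipping them keeps the multiple-testing burden
    honest).  Both significant and non-significant results are returned,
    flagged at q <= q_threshold.
    """
    drug_adr: dict[str, set[str]] = {}
    adr_sources: dict[str, set[str]] = {}
    adr_drugs_all: set[str] = set()
    for p in evidence_pairs:
        drug_adr.setdefault(p.pt_code, set()).add(p.drug_id)
        adr_sources.setdefault(p.pt_code, set()).add(p.source)
        adr_drugs_all.add(p.drug_id)
    drug_tgt: dict[str, set[str]] = {}
    tgt_sources: dict[str, set[str]] = {}
    tgt_drugs_all: set[str] = set()
    for p in target_pairs:
        drug_tgt.setdefault(p.uniprot_id, set()).add(p.drug_id)
        tgt_sources.setdefault(p.uniprot_id, set()).add(p.source)
        tgt_drugs_all.add(p.drug_id)
    universe = adr_drugs_all & tgt_drugs_all
    if not universe:
        return []

    results: list[AssociationResult] = []
    pvals: list[float] = []
    for protein in sorted(drug_tgt):
        tgt_drugs = drug_tgt[protein] & universe
        if not tgt_drugs:
            continue
        for adr in sorted(drug_adr):
            adr_drugs = drug_adr[adr] & universe
            overlap = tgt_drugs & adr_drugs
            if not overlap and not config.test_zero_overlap:
                continue
            if not adr_drugs:
                continue
            table = build_table(protein, adr, universe, drug_adr, drug_tgt)
            p = fisher_p(table, config.fisher_alternative)
            term = vocabulary.term(adr) if vocabulary is not None else None
            results.append(
                AssociationResult(
                    uniprot_id=protein,
                    gene_name=(gene_names or {}).get(protein, protein),
                    pt_code=adr,
                    pt_name=term.pt_name if term else adr,
                    soc=term.soc if term else "",
                    p_value=p,
                    q_value=math.nan,
                    table=table,
                    evidence_set=evidence_set,
                    drug_ids=frozenset(overlap),
                    sources=";".join(
                        sorted(adr_sources[adr] | tgt_sources[protein])
                    ),
                )
            )
            pvals.append(p)
    if not results:
        return []
    qs = qvalues(pvals)
    for r, q in zip(results, qs):
        r.q_value = float(q)
        r.significant = q <= config.q_threshold
    log.info("%s evidence: %d tested pairs, %d significant at q<=%.3g",
             evidence_set, len(results), sum(r.significant for r in results),
             config.q_threshold)
    return results
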