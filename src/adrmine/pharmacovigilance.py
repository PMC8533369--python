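"""Curation and disproportionality screening of spontaneous reports.

Raw reports are curated in three steps: drug-name normalization against a
synonym table, demographic-key deduplication, and a per-drug multinomial
likelihood-ratio screen.  For a fixed drug with ``n_drug`` reports the
statistic for ADR j is the one-sided binomial log-likelihood ratio

    llr = n log(n / E) + (n_drug - n) log((n_drug - n) / (n_drug - E)),
    E   = n_drug * n_adr / N,

zero whenever the observed count does not exceed expectation (signal
detection seeks over-reporting only).  Significance is judged against the
Monte-Carlo null of the per-drug *maximum* llr over ADRs, under multinomial
allocation of the drug's reports across ADRs with probabilities
proportional to the ADR margins; a (drug, ADR) pair is a signal when its
llr exceeds the drug's (1 - alpha) null quantile.  Only signals present in
both self-reporting sources are kept.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datamodel import ConfigError, DrugAdrPair, PipelineConfig, SpontaneousReport

log = logging.getLogger(__name__)

__all__ = [
    "SignalScreenResult",
    "normalize_raw_name",
    "normalize_drug_names",
    "deduplicate_reports",
    "count_matrix",
    "llr_statistic",
    "mc_null_quantile",
    "screen_source",
    "screen_signals",
]


@dataclass(frozen=True)
class SignalScreenResult:
    """Screen outcome for one (drug, ADR) pair in one source."""

    drug_id: str
    pt_code: str
    n_ij: int
    e_ij: float
    llr: float
    null_quantile: float
    significant: bool


_PUNCT = re.compile(r"[^\w\s]")
_WS = re.compile(r"\s+")


def normalize_raw_name(name: str) -> str:
    """Case-fold, trim and punctuation-strip a raw drug string."""
    return _WS.sub(" ", _PUNCT.sub(" ", name.casefold())).strip()


def normalize_drug_names(
    reports: list[SpontaneousReport],
    synonym_table: dict[str, str],
) -> tuple[list[SpontaneousReport], dict[str, int]]:
    """Resolve raw drug strings to drug_ids via the synonym table.

    Unresolvable names are dropped from the report; reports left with zero
    drugs are discarded.  Returns the surviving reports (with ``drug_ids``
    populated) and a stats dict with ``resolved``, ``dropped_names`` and
    ``dropped_reports`` counts.
    """
    if not synonym_table:
        raise ConfigError("empty synonym table")
    lookup = {normalize_raw_name(k): v for k, v in synonym_table.items()}
    out: list[SpontaneousReport] = []
    resolved = dropped_names = dropped_reports = 0
    for rep in reports:
        ids: list[str] = []
        for raw in rep.raw_drug_names:
            did = lookup.get(normalize_raw_name(raw))
            if did is None:
                dropped_names += 1
            else:
                resolved += 1
                if did not in ids:
                    ids.append(did)
        if not ids:
            dropped_reports += 1
            continue
        rep.drug_ids = ids
        out.append(rep)
    stats = {
        "resolved": resolved,
        "dropped_names": dropped_names,
        "dropped_reports": dropped_reports,
    }
    if dropped_names:
        log.info("name normalization dropped %d raw names, %d reports",
                 dropped_names, dropped_reports)
    return out, stats


def _dedup_key(rep: SpontaneousReport):
    drugs = tuple(sorted(rep.drug_ids if rep.drug_ids is not None
                         else rep.raw_drug_names))
    return (
        drugs,
        tuple(sorted(set(rep.pt_codes))),
        rep.age,
        rep.sex,
        rep.weight,
        rep.event_date,
        rep.country,
    )


def deduplicate_reports(reports: list[SpontaneousReport]) -> list[SpontaneousReport]:
    """Collapse reports sharing the identical demographic key.

    The key is (sorted drug ids, sorted PT codes, age, sex, weight,
    event_date, country); the lexicographically smallest report_id
    survives.  Absent demographics only collapse with equally absent ones,
    never with conflicting present values.  Idempotent.
    """
    best: dict[tuple, SpontaneousReport] = {}
    for rep in reports:
        key = _dedup_key(rep)
        kept = best.get(key)
        if kept is None or rep.report_id < kept.report_id:
            best[key] = rep
    survivors = list(best.values())
    survivors.sort(key=lambda r: r.report_id)
    return survivors


def count_matrix(
    reports: list[SpontaneousReport],
) -> tuple[dict[tuple[str, str], int], dict[str, int], dict[str, int], int]:
    """Count reports per (drug, ADR) with per-drug and per-ADR margins.

    ``n_ij`` counts deduplicated reports mentioning both drug i and PT j;
    margins count reports mentioning the drug (resp. the PT); N is the
    number of reports.
    """
    n_ij: dict[tuple[str, str], int] = {}
    n_drug: dict[str, int] = {}
    n_adr: dict[str, int] = {}
    for rep in reports:
        drugs = rep.drug_ids if rep.drug_ids is not None else rep.raw_drug_names
        pts = sorted(set(rep.pt_codes))
        for d in set(drugs):
            n_drug[d] = n_drug.get(d, 0) + 1
            for p in pts:
                n_ij[(d, p)] = n_ij.get((d, p), 0) + 1
        for p in pts:
            n_adr[p] = n_adr.get(p, 0) + 1
    return n_ij, n_drug, n_adr, len(reports)


def llr_statistic(n_ij: int, n_drug: int, n_adr: int, n_total: int) -> float:
    """One-sided log-likelihood-ratio statistic for one (drug, ADR) count.

    Zero when the observed count does not exceed its expectation; terms
    with a zero count contribute zero.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_ij <= min(n_drug, n_adr)) or n_drug > n_total:
        raise ValueError(
            f"inconsistent margins: n_ij={n_ij}, n_drug={n_drug}, "
            f"n_adr={n_adr}, N={n_total}"
        )
    e = n_drug * n_adr / n_total
    if n_ij <= e or n_ij == 0:
        return 0.0
    llr = n_ij * math.log(n_ij / e)
    rest = n_drug - n_ij
    if rest > 0:
        llr += rest * math.log(rest / (n_drug - e))
    return llr


def _llr_vector(counts: np.ndarray, n_drug: int, n_adr: np.ndarray,
                n_total: int) -> np.ndarray:
    """Vectorized llr over ADR columns for one drug (counts may be 2-D)."""
    e = n_drug * n_adr / n_total
    counts = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(counts > 0, counts * np.log(counts / e), 0.0)
        rest = n_drug - counts
        t2 = np.where(rest > 0, rest * np.log(rest / (n_drug - e)), 0.0)
    llr = t1 + t2
    return np.where(counts > e, llr, 0.0)


def mc_null_quantile(
    n_drug: dict[str, int],
    n_adr: dict[str, int],
    n_total: int,
    alpha: float,
    reps: int,
    seed: int,
) -> dict[str, float]:
    """Per-drug Monte-Carlo critical value of the max-over-ADRs llr.

    For each drug, ``reps`` multinomial allocations of its reports across
    ADRs (probabilities proportional to the ADR margins) are drawn; the
    empirical (1 - alpha) quantile of the per-replicate maximum llr is the
    drug's critical value.  Deterministic for a fixed seed.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    adr_codes = sorted(n_adr)
    margins = np.array([n_adr[a] for a in adr_codes], dtype=float)
    probs = margins / margins.sum()
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for drug in sorted(n_drug):
        nd = n_drug[drug]
        if nd == 0:
            log.warning("drug %s has zero reports; excluded from screen", drug)
            continue
        draws = rng.multinomial(nd, probs, size=reps)
        maxllr = _llr_vector(draws, nd, margins, n_total).max(axis=1)
        out[drug] = float(np.quantile(maxllr, 1.0 - alpha))
    return out


def screen_source(
    reports: list[SpontaneousReport],
    config: PipelineConfig,
    seed: Optional[int] = None,
) -> dict[tuple[str, str], SignalScreenResult]:
    """Run the LRT screen on one (already curated) report set."""
    n_ij, n_drug, n_adr, n_total = count_matrix(reports)
    if n_total == 0:
        return {}
    crit = mc_null_quantile(
        n_drug, n_adr, n_total, config.lrt_alpha, config.lrt_mc_reps,
        config.rng_seed if seed is None else seed,
    )
    results: dict[tuple[str, str], SignalScreenResult] = {}
    for (d, a), n in n_ij.items():
        if d not in crit:
            continue
        e = n_drug[d] * n_adr[a] / n_total
        llr = llr_statistic(n, n_drug[d], n_adr[a], n_total)
        results[(d, a)] = SignalScreenResult(
            drug_id=d, pt_code=a, n_ij=n, e_ij=e, llr=llr,
            null_quantile=crit[d], significant=llr > crit[d],
        )
    return results


def screen_signals(
    reports_a: list[SpontaneousReport],
    reports_b: list[SpontaneousReport],
    config: PipelineConfig,
    source_tag: str = "faers_like+medeffect_like",
) -> list[DrugAdrPair]:
    """Intersect per-source significant (drug, ADR) signals.

    A pair is kept only if significant in both self-reporting sources; its
    evidence statistic is the smaller of the two llr values.
    """
    res_a = screen_source(reports_a, config, seed=config.rng_seed)
    res_b = screen_source(reports_b, config, seed=config.rng_seed + 1)
    sig_a = {k for k, r in res_a.items() if r.significant}
    sig_b = {k for k, r in res_b.items() if r.significant}
    kept = sorted(sig_a & sig_b)
    return [
        DrugAdrPair(
            drug_id=d,
            pt_code=a,
            source=source_tag,
            evidence_stat=min(res_a[(d, a)].llr, res_b[(d, a)].llr),
        )
        for d, a in kept
    ]
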