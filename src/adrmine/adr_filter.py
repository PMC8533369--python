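"""SOC-based filtering of unspecific adverse-event terms.

Preferred terms whose *primary* system organ class is on the exclusion
list describe external causes, investigations, product issues and other
concepts unspecific to human biology; they are removed before
association mining.  Within "Psychiatric disorders", only the listed
high-level (group) terms are excluded, matched case-insensitively at
either the HLT or HLGT level; other psychiatric terms are kept.
"""

from __future__ import annotations

import logging

from .datamodel import DrugAdrPair, PipelineConfig
from .ingest import Vocabulary

log = logging.getLogger(__name__)

__all__ = ["filter_adrs", "is_excluded_term"]

PSYCHIATRIC_SOC = "Psychiatric disorders"


def is_excluded_term(term, config: PipelineConfig) -> bool:
    """Whether a vocabulary term falls under the exclusion rules."""
    if term.soc in config.excluded_socs:
        return True
    if term.soc == PSYCHIATRIC_SOC:
        excl = {t.casefold() for t in config.excluded_psych_terms}
        return term.hlt.casefold() in excl or term.hlgt.casefold() in excl
    return False


def filter_adrs(
    pairs: list[DrugAdrPair],
    vocabulary: Vocabulary,
    config: PipelineConfig,
) -> tuple[list[DrugAdrPair], dict[str, int]]:
    """Remove pairs whose PT falls in an excluded SOC (or excluded
    psychiatric sub-term).

    Returns the kept pairs and per-SOC removal counts.  Kept and removed
    partition the input; the operation is idempotent and order-free.
    """
    kept: list[DrugAdrPair] = []
    removed_by_soc: dict[str, int] = {}
    for p in pairs:
        if p.pt_code not in vocabulary:
            raise KeyError(f"unresolvable pt_code {p.pt_code!r}")
        term = vocabulary.term(p.pt_code)
        if is_excluded_term(term, config):
            removed_by_soc[term.soc] = removed_by_soc.get(term.soc, 0) + 1
        else:
            kept.append(p)
    if removed_by_soc:
        log.info("SOC filter removed %d pairs across %d SOCs",
                 sum(removed_by_soc.values()), len(removed_by_soc))
    return kept, removed_by_soc
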