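"""Query-set curation: length and domain-evidence filters.

Queries shorter than 100 aa are presumed fragments and queries longer than
600 aa erroneous fusions; both bounds are exclusive (100 and 600 themselves
are retained).  Domain filtering keeps proteins with a significant hit to the
family signature domain (7tm_6 for insect odorant receptors) at E ≤ 0.01;
duplicate hits resolve to the minimum E-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import FormatError, HitRecord

MIN_QUERY_LEN = 100
MAX_QUERY_LEN = 600
DOMAIN_NAME = "7tm_6"
DOMAIN_EVALUE = 0.01


@dataclass
class QueryProtein:
    id: str
    seq: str
    domain_hits: list[HitRecord] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.seq)


def filter_by_length(proteins, min_len: int = MIN_QUERY_LEN,
                     max_len: int = MAX_QUERY_LEN):
    """Keep proteins with min_len <= length <= max_len.

    Returns ``(retained, rejection_log)`` where the log lists
    ``(id, length, reason)`` for every removed record.
    """
    retained, log = [], []
    for p in proteins:
        n = len(p.seq)
        if n < min_len:
            log.append((p.id, n, f"shorter than {min_len} aa"))
        elif n > max_len:
            log.append((p.id, n, f"longer than {max_len} aa"))
        else:
            retained.append(p)
    return retained, log


def best_domain_evalue(hits, domain: str = DOMAIN_NAME) -> dict[str, float]:
    """Minimum E-value per protein id for the given domain."""
    best: dict[str, float] = {}
    for h in hits:
        if h.domain_name != domain:
            continue
        if h.evalue < 0:
            raise FormatError(f"negative evalue for {h.query_id}")
        if h.query_id not in best or h.evalue < best[h.query_id]:
            best[h.query_id] = h.evalue
    return best


def filter_by_domain(proteins, hit_table, domain: str = DOMAIN_NAME,
                     evalue_cutoff: float = DOMAIN_EVALUE):
    """Keep proteins with a domain hit at E <= cutoff; absent ids are rejected."""
    best = best_domain_evalue(hit_table, domain)
    retained, log = [], []
    for p in proteins:
        ev = best.get(p.id)
        if ev is not None and ev <= evalue_cutoff:
            retained.append(p)
        elif ev is None:
            log.append((p.id, len(p.seq), f"no {domain} hit"))
        else:
            log.append((p.id, len(p.seq), f"{domain} evalue {ev:g} > {evalue_cutoff:g}"))
    return retained, log


def curate_queries(proteins, hit_table, min_len: int = MIN_QUERY_LEN,
                   max_len: int = MAX_QUERY_LEN, domain: str = DOMAIN_NAME,
                   evalue_cutoff: float = DOMAIN_EVALUE):
    """Length filter then domain filter (the composition is order-independent)."""
    kept, log1 = filter_by_length(proteins, min_len, max_len)
    kept, log2 = filter_by_domain(kept, hit_table, domain, evalue_cutoff)
    return kept, log1 + log2
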