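"""Gene-model validation: 2-of-3 membrane-topology consensus and domain checks.

An odorant-receptor-like protein is expected to show the family signature
domain and at least six transmembrane helices.  Topology predictors disagree
at single-residue level, so per-residue consensus over three predictors
(label M where at least two agree) is used before counting helices; a helix
is a maximal consensus-M run of at least ``min_run`` residues.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .query_curation import DOMAIN_EVALUE, DOMAIN_NAME, best_domain_evalue

MIN_TMH_RUN = 10
SIX_PLUS = 6


@dataclass
class TopologySet:
    protein_id: str
    predictions: list[str]
    consensus: str = ""
    tmh_count: int = 0

    def __post_init__(self):
        if len(self.predictions) != 3:
            raise ValueError("exactly three predictions required")
        self.consensus = consensus_topology(self.predictions)
        self.tmh_count = count_tmh(self.consensus)


def consensus_topology(predictions: list[str]) -> str:
    """Per-residue 2-of-3 vote: M where >= 2 predictors say M, else '-'.

    The inside/outside states are collapsed: only membrane occupancy matters
    for helix counting.
    """
    lengths = {len(p) for p in predictions}
    if len(lengths) != 1:
        raise ValueError("predictions have unequal lengths")
    out = []
    for column in zip(*predictions):
        out.append("M" if sum(c == "M" for c in column) >= 2 else "-")
    return "".join(out)


def count_tmh(consensus: str, min_run: int = MIN_TMH_RUN) -> int:
    """Number of maximal M-runs of length >= min_run."""
    return sum(1 for m in re.finditer("M+", consensus)
               if len(m.group()) >= min_run)


@dataclass
class ValidationReport:
    rows: list[dict] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.rows)

    def fraction(self, key: str) -> float:
        if not self.rows:
            return float("nan")
        return sum(bool(r[key]) for r in self.rows) / len(self.rows)

    def summary(self) -> dict:
        return {
            "n_proteins": self.n,
            "domain_pass_fraction": self.fraction("domain_pass"),
            "six_plus_tmh_fraction": self.fraction("six_plus"),
            "both_pass_fraction": self.fraction("both_pass"),
        }


def validate_models(proteins: dict[str, str], topology_map: dict[str, list[str]],
                    domain_hits, evalue: float = DOMAIN_EVALUE,
                    domain: str = DOMAIN_NAME,
                    min_run: int = MIN_TMH_RUN) -> ValidationReport:
    """Per-protein validation table.

    ``topology_map`` maps protein id to its three predictor strings; proteins
    missing from either table are flagged (``domain_pass``/``six_plus`` False
    with a note), never fatal.
    """
    best = best_domain_evalue(domain_hits, domain)
    report = ValidationReport()
    for pid in sorted(proteins):
        row = {"protein_id": pid, "length": len(proteins[pid]),
               "domain_pass": False, "tmh_count": 0, "six_plus": False,
               "note": ""}
        ev = best.get(pid)
        if ev is None:
            row["note"] += "no-domain-hit;"
        elif ev <= evalue:
            row["domain_pass"] = True
        preds = topology_map.get(pid)
        if preds is None or len(preds) != 3:
            row["note"] += "missing-topology;"
        else:
            ts = TopologySet(pid, list(preds))
            row["tmh_count"] = count_tmh(ts.consensus, min_run)
            row["six_plus"] = row["tmh_count"] >= SIX_PLUS
        row["both_pass"] = row["domain_pass"] and row["six_plus"]
        report.rows.append(row)
    return report
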