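"""Candidate annotation: GO summaries, weighted subcellular localization,
and phosphosite-database cross-reference.

Subcellular calls follow the SUBA-style consensus rule: for each protein,
every evidence row votes for a compartment, experimental rows counting
five times an in-silico prediction; the compartment with the highest score
wins, ties resolved by the follow-up priority order and flagged.

Database cross-reference asks whether a candidate's full 20-mer occurs
verbatim in a database protein (exact substring matching — equivalent to a
100%-identity, full-coverage BLASTP hit) and whether that database lists a
phosphosite at the aligned position.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .library_design import PeptideEntry
from .quantify import LOCALIZATION_PRIORITY

COMPARTMENTS = (
    "plasma membrane",
    "cytosol",
    "nucleus",
    "endoplasmic reticulum",
    "mitochondrion",
    "plastid",
    "extracellular",
    "other",
)

EXPERIMENTAL_WEIGHT = 5
PREDICTED_WEIGHT = 1


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class LocalizationEvidence:
    protein_accession: str
    compartment: str
    evidence_type: str  # "experimental" | "predicted"

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise AnnotationError(
                f"compartment {self.compartment!r} not in controlled vocabulary"
            )
        if self.evidence_type not in ("experimental", "predicted"):
            raise AnnotationError(
                f"evidence_type must be experimental|predicted, got "
                f"{self.evidence_type!r}"
            )


@dataclass(frozen=True)
class DbPhosphosite:
    """One phosphosite record from an experimental phosphoproteome
    database (e.g. P3DB- or PhosPhAt-style flat files)."""

    database: str
    accession: str
    protein_sequence: str
    site_position: int  # 1-based in protein_sequence


def summarize_go_abundance(
    protein_to_terms: Mapping[str, Sequence[tuple[str, str]]],
    candidates: Iterable[str],
    min_percent: float = 1.0,
) -> pd.DataFrame:
    """Per-namespace GO-class abundance among candidate proteins.

    ``protein_to_terms`` maps accession -> [(namespace, term), ...]. The
    percentage of a class is its share of all annotation assignments in
    that namespace among the candidates (so percentages sum to 100 per
    namespace); only classes strictly above ``min_percent`` are kept.
    Unannotated candidates contribute one "unannotated" assignment per
    namespace so they stay visible in the denominator.
    """
    candidates = sorted(set(candidates))
    if not candidates:
        raise AnnotationError("empty candidate set")
    namespaces = sorted(
        {ns for terms in protein_to_terms.values() for ns, _ in terms}
    ) or ["biological process"]
    counts: dict[str, dict[str, int]] = {ns: defaultdict(int) for ns in namespaces}
    for acc in candidates:
        terms = protein_to_terms.get(acc, [])
        seen_ns = set()
        for ns, term in terms:
            counts.setdefault(ns, defaultdict(int))
            counts[ns][term] += 1
            seen_ns.add(ns)
        for ns in counts:
            if ns not in seen_ns:
                counts[ns]["unannotated"] += 1
    rows = []
    for ns in sorted(counts):
        total = sum(counts[ns].values())
        for term, c in sorted(counts[ns].items()):
            pct = 100.0 * c / total
            if pct > min_percent:
                rows.append(
                    {"namespace": ns, "term": term, "count": c, "percent": pct}
                )
    return pd.DataFrame(rows, columns=["namespace", "term", "count", "percent"])


def score_subcellular_localization(
    evidence: Sequence[LocalizationEvidence],
    protein_accession: str,
) -> tuple[str, dict[str, int], bool]:
    """Weighted-vote compartment call for one protein.

    Returns (winning compartment, score table, tie_flag). With no evidence
    the call is "unknown". Experimental rows weigh
    ``EXPERIMENTAL_WEIGHT``-fold over predictions; score ties are broken
    by the follow-up priority order, then the controlled-vocabulary order.
    """
    rows = [e for e in evidence if e.protein_accession == protein_accession]
    if not rows:
        return "unknown", {}, False
    scores: dict[str, int] = defaultdict(int)
    for e in rows:
        w = EXPERIMENTAL_WEIGHT if e.evidence_type == "experimental" else PREDICTED_WEIGHT
        scores[e.compartment] += w
    best = max(scores.values())
    tied = [c for c, s in scores.items() if s == best]

    def priority(compartment: str) -> tuple[int, int]:
        try:
            p = LOCALIZATION_PRIORITY.index(compartment)
        except ValueError:
            p = len(LOCALIZATION_PRIORITY)
        return p, COMPARTMENTS.index(compartment)

    winner = min(tied, key=priority)
    return winner, dict(scores), len(tied) > 1


def crossref_phospho_databases(
    candidate: PeptideEntry,
    site: int,
    databases: Mapping[str, Sequence[DbPhosphosite]],
) -> dict[str, str]:
    """Status of one candidate window against each phosphosite database.

    ``site`` is the 1-based phosphosite index within the 20-mer window.
    Per database: "confirmed" if the window occurs verbatim in a database
    protein with a listed phosphosite at the aligned position;
    "sequence-only" if the window occurs but never with the site;
    otherwise "novel". All occurrences of the window are checked.
    """
    window = candidate.window
    status: dict[str, str] = {}
    for db_name, records in databases.items():
        by_protein: dict[str, tuple[str, set[int]]] = {}
        for rec in records:
            seq, sites = by_protein.setdefault(rec.accession, (rec.protein_sequence, set()))
            sites.add(rec.site_position)
        verdict = "novel"
        for seq, sites in by_protein.values():
            start = seq.find(window)
            while start != -1:
                verdict = "sequence-only" if verdict == "novel" else verdict
                if (start + site) in sites:  # start is 0-based; site 1-based
                    verdict = "confirmed"
                    break
                start = seq.find(window, start + 1)
            if verdict == "confirmed":
                break
        status[db_name] = verdict
    return status


def summarize_db_status(
    per_candidate_status: Mapping[int, Mapping[str, str]],
) -> dict[str, int]:
    """Bookkeeping over all candidates: how many are known (confirmed) in
    either database, in both, or novel. Satisfies
    known_in_either + novel == total and known_in_both <= known_in_either.
    """
    either = both = 0
    for status in per_candidate_status.values():
        confirmed = [db for db, v in status.items() if v == "confirmed"]
        if confirmed:
            either += 1
        if len(confirmed) >= 2:
            both += 1
    total = len(per_candidate_status)
    return {
        "total": total,
        "known_in_either": either,
        "known_in_both": both,
        "novel": total - either,
    }


def db_status_label(status: Mapping[str, str]) -> str:
    """Collapse per-database verdicts to the report vocabulary
    none | one | both (counting confirmed databases)."""
    n = sum(1 for v in status.values() if v == "confirmed")
    return "none" if n == 0 else ("one" if n == 1 else "both")
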