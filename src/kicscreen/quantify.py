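"""Spectral-count stoichiometry and candidate prioritization.

Stoichiometry for a surviving phosphosite is the spectral-count ratio

    stoichiometry = 100 * phospho PSM count / total PSM count

computed within the test condition only (wildtype +ATP), where the total
counts every PSM of the peptide sequence, modified or not. 100% therefore
means the unmodified peptide was never observed there.

Candidates are ranked lexicographically on the evidence hierarchy used for
follow-up prioritization: stoichiometry, phospho spectral counts,
subcellular localization (plasma membrane > cytosol > endoplasmic
reticulum > nucleus > everything else — compartments plausibly shared with
a plasma-membrane receptor kinase rank first), consensus-motif membership,
and finally library id for a total, reproducible order.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .psm_filtering import PSMRecord

logger = logging.getLogger(__name__)

LOCALIZATION_PRIORITY = (
    "plasma membrane",
    "cytosol",
    "endoplasmic reticulum",
    "nucleus",
)


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class StoichiometryResult:
    library_id: int
    site: int  # in-peptide 1-based index
    phospho_psm_count: int
    total_psm_count: int
    stoichiometry: float  # percentage in [0, 100]
    n_sites_on_peptide: int = 1


@dataclass(frozen=True)
class CandidateReport:
    rank: int
    library_id: int
    site: int
    protein_accession: str
    stoichiometry: float
    phospho_psm_count: int
    localization: str
    in_consensus_motif: bool
    known_in_databases: str  # "none" | "one" | "both"
    source: str


def compute_stoichiometry(
    records: Sequence[PSMRecord],
    survivors: Iterable[tuple[int, int]],
) -> list[StoichiometryResult]:
    """Per surviving (library_id, site): phospho support over total PSMs.

    ``records`` must be the PSMs of one condition. The denominator is all
    PSMs of the peptide (any modification state); the numerator counts the
    phospho-PSMs listing that site, so a doubly phosphorylated spectrum
    supports both of its sites.
    """
    survivors = set(survivors)
    total_by_peptide: dict[int, int] = defaultdict(int)
    phospho_by_site: dict[tuple[int, int], int] = defaultdict(int)
    for r in records:
        total_by_peptide[r.library_id] += 1
        if r.is_phospho:
            for site in r.site_positions:
                phospho_by_site[(r.library_id, site)] += 1
    sites_per_peptide: dict[int, int] = defaultdict(int)
    for lib_id, _site in survivors:
        sites_per_peptide[lib_id] += 1
    out: list[StoichiometryResult] = []
    for lib_id, site in sorted(survivors):
        total = total_by_peptide.get(lib_id, 0)
        if total == 0:
            raise QuantError(
                f"peptide {lib_id} has surviving site {site} but no PSMs in "
                "the condition; survivors must come from these records"
            )
        phospho = phospho_by_site.get((lib_id, site), 0)
        out.append(
            StoichiometryResult(
                library_id=lib_id,
                site=site,
                phospho_psm_count=phospho,
                total_psm_count=total,
                stoichiometry=100.0 * phospho / total,
                n_sites_on_peptide=sites_per_peptide[lib_id],
            )
        )
    return out


def localization_rank(compartment: str | None) -> int:
    """Position of a compartment in the follow-up priority order; unknown
    or unlisted compartments rank last."""
    if compartment is None:
        return len(LOCALIZATION_PRIORITY)
    try:
        return LOCALIZATION_PRIORITY.index(compartment.lower())
    except ValueError:
        return len(LOCALIZATION_PRIORITY)


def rank_candidates(
    stoich: Sequence[StoichiometryResult],
    localization: Mapping[int, str] | None = None,
    motif_members: Iterable[int] = (),
    db_status: Mapping[int, str] | None = None,
    accessions: Mapping[int, str] | None = None,
    sources: Mapping[int, str] | None = None,
) -> list[CandidateReport]:
    """Produce the ranked candidate table from per-site stoichiometry plus
    annotation evidence, all keyed by library_id.

    Missing annotation ranks the candidate lowest for that key and logs a
    warning; database-known status is reported but deliberately not part
    of the sort key (novel and known candidates are equally actionable).
    """
    localization = localization or {}
    db_status = db_status or {}
    accessions = accessions or {}
    sources = sources or {}
    motif_set = set(motif_members)
    if localization:
        for s in stoich:
            if s.library_id not in localization:
                logger.warning(
                    "no localization for peptide %d; ranking it last on that key",
                    s.library_id,
                )

    def key(s: StoichiometryResult):
        return (
            -s.stoichiometry,
            -s.phospho_psm_count,
            localization_rank(localization.get(s.library_id)),
            s.library_id not in motif_set,
            s.library_id,
            s.site,
        )

    ordered = sorted(stoich, key=key)
    return [
        CandidateReport(
            rank=i + 1,
            library_id=s.library_id,
            site=s.site,
            protein_accession=accessions.get(s.library_id, ""),
            stoichiometry=s.stoichiometry,
            phospho_psm_count=s.phospho_psm_count,
            localization=localization.get(s.library_id, "unknown"),
            in_consensus_motif=s.library_id in motif_set,
            known_in_databases=db_status.get(s.library_id, "none"),
            source=sources.get(s.library_id, ""),
        )
        for i, s in enumerate(ordered)
    ]
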