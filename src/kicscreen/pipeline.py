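"""End-to-end orchestration of the screen analysis.

Stage order (each stage consumes only earlier outputs):

1. obtain a screen — either simulate one from a
   :class:`~kicscreen.synthetic.SyntheticScreenConfig` or load library and
   PSM tables from disk;
2. flag ubiquitous-outlier peptides (phospho-detected in every sample) and
   drop them everywhere, *before* thresholds are derived — a peptide that
   lights up in the negatives too would otherwise inflate the background
   Xcorr bound;
3. derive filtration criteria from the negative-control samples;
4. apply the criteria to the wildtype +ATP sample -> surviving
   (peptide, site) phosphopeptides;
5. spectral-count stoichiometry per survivor;
6. redundancy-reduce survivor windows and detect the consensus motif;
7. optional annotation (GO, localization, database cross-reference);
8. rank candidates and attribute them to library sources.

A run manifest records the config, input digests, per-stage counts and
seeds; identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .annotation import (
    DbPhosphosite,
    LocalizationEvidence,
    crossref_phospho_databases,
    db_status_label,
    score_subcellular_localization,
    summarize_db_status,
)
from .library_design import PeptideEntry
from .motif import MotifError, cluster_redundant_peptides, find_positional_motif
from .predictors import AMINO_ACIDS
from .psm_filtering import (
    FilterCriteria,
    PSMRecord,
    apply_filters,
    derive_filter_thresholds,
    flag_ubiquitous_outliers,
    phospho_detected_per_sample,
)
from .quantify import CandidateReport, StoichiometryResult, compute_stoichiometry, rank_candidates
from .synthetic import SyntheticScreen, SyntheticScreenConfig, generate_screen

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config: dict
    input_digests: dict[str, str]
    counts: dict[str, int]
    version: str
    random_seeds: dict[str, int]

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()

    def validate(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("manifest counts must be non-negative")
        if self.counts.get("survivors", 0) > self.counts.get("library_size", 0):
            raise ValueError("survivors cannot exceed the library size")


@dataclass
class PipelineResult:
    manifest: RunManifest
    criteria: FilterCriteria
    outlier_ids: set[int]
    survivors: set[tuple[int, int]]
    stoichiometry: list[StoichiometryResult]
    report: list[CandidateReport]
    source_attribution: pd.DataFrame
    motif_consensus: str = ""
    motif_member_ids: list[int] = field(default_factory=list)
    db_summary: dict[str, int] = field(default_factory=dict)


def attribute_sources(
    candidates: Sequence[int],
    library: Sequence[PeptideEntry],
) -> pd.DataFrame:
    """Per-source candidate counts and hit rates.

    The hit rate of a source is 100 * candidates from that source /
    library members from that source (the per-source identification
    percentage of the screen).
    """
    lib_by_id = {e.library_id: e for e in library}
    unknown = [c for c in candidates if c not in lib_by_id]
    if unknown:
        raise PipelineError("attribute_sources", f"candidates not in library: {unknown}")
    sources = sorted({e.source for e in library})
    rows = []
    cand = set(candidates)
    for source in sources:
        members = [e for e in library if e.source == source]
        n_hits = sum(1 for e in members if e.library_id in cand)
        rows.append(
            {
                "source": source,
                "library_members": len(members),
                "candidates": n_hits,
                "hit_rate_percent": 100.0 * n_hits / len(members) if members else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _library_background(library: Sequence[PeptideEntry]) -> dict[str, float]:
    counts = {a: 0 for a in AMINO_ACIDS}
    total = 0
    for e in library:
        for c in e.window:
            if c in counts:
                counts[c] += 1
                total += 1
    return {a: counts[a] / total for a in AMINO_ACIDS}


def run_pipeline(
    screen: SyntheticScreen | None = None,
    config: SyntheticScreenConfig | None = None,
    library: Sequence[PeptideEntry] | None = None,
    psm_tables: Mapping[str, Sequence[PSMRecord]] | None = None,
    go_mapping: Mapping[str, list[tuple[str, str]]] | None = None,
    localization: Sequence[LocalizationEvidence] | None = None,
    phospho_dbs: Mapping[str, Sequence[DbPhosphosite]] | None = None,
    criteria: FilterCriteria | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis; simulate a screen when only a config is given.

    ``criteria`` overrides the negative-control derivation with fixed
    thresholds. When ``out_dir`` is set, all stage outputs and the
    manifest are written there as TSV/JSON.
    """
    t0 = time.time()
    if screen is None and config is not None:
        screen = generate_screen(config)
    if screen is not None:
        library = screen.library
        psm_tables = screen.psm_tables
        cfg_snapshot = asdict(screen.config)
        seed = screen.config.random_seed
    else:
        if library is None or psm_tables is None:
            raise PipelineError("inputs", "need a screen/config or library + PSM tables")
        cfg_snapshot = {}
        seed = -1

    counts: dict[str, int] = {"library_size": len(library)}
    logger.info("library: %d peptides", len(library))

    # --- outlier flagging -------------------------------------------------
    try:
        # build per-sample detection from the tables directly so samples
        # with zero PSMs still count as "peptide not detected there"
        detected = {
            sid: {r.library_id for r in records if r.is_phospho}
            for sid, records in psm_tables.items()
        }
        outliers = flag_ubiquitous_outliers(detected)
    except Exception as exc:  # pragma: no cover - surfaced with stage context
        raise PipelineError("flag_outliers", str(exc)) from exc
    counts["ubiquitous_outliers"] = len(outliers)

    def keep(r: PSMRecord) -> bool:
        return r.library_id not in outliers

    # --- thresholds from negatives ---------------------------------------
    negatives = [
        r
        for records in psm_tables.values()
        for r in records
        if r.is_negative_control and keep(r)
    ]
    test_records = [
        r
        for records in psm_tables.values()
        for r in records
        if not r.is_negative_control and keep(r)
    ]
    try:
        if criteria is None:
            if negatives:
                criteria = derive_filter_thresholds(negatives)
            elif len(psm_tables) >= 2:
                # negative samples exist but recorded no PSMs at all:
                # vacuous background, minimal thresholds
                criteria = FilterCriteria(1, 0.0)
            else:
                raise PipelineError("derive_thresholds", "no negative-control samples")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("derive_thresholds", str(exc)) from exc
    logger.info(
        "criteria: PSM count >= %d, Xcorr > %.3f, site prob >= %.2f",
        criteria.min_psm_count, criteria.min_xcorr, criteria.min_site_probability,
    )

    # --- filtering and quantification ------------------------------------
    survivors = apply_filters(test_records, criteria)
    counts["survivors"] = len(survivors)
    counts["negative_passthrough"] = len(apply_filters(negatives, criteria))
    stoich = compute_stoichiometry(test_records, survivors)

    # --- motif on surviving windows ---------------------------------------
    lib_by_id = {e.library_id: e for e in library}
    survivor_ids = sorted({lib_id for lib_id, _ in survivors})
    windows = [lib_by_id[i].window for i in survivor_ids]
    motif_consensus = ""
    motif_member_ids: list[int] = []
    if windows:
        reps, assignment = cluster_redundant_peptides(windows)
        try:
            motif = find_positional_motif(reps, _library_background(library))
            motif_consensus = motif.consensus
            rep_members = set(motif.member_ids)
            motif_member_ids = [
                survivor_ids[i]
                for i in range(len(windows))
                if assignment[i] in rep_members
            ]
        except MotifError as exc:
            logger.info("motif stage skipped: %s", exc)
    counts["motif_members"] = len(motif_member_ids)

    # --- annotation --------------------------------------------------------
    loc_calls: dict[int, str] = {}
    if localization:
        for lib_id in survivor_ids:
            winner, _scores, _tie = score_subcellular_localization(
                localization, lib_by_id[lib_id].protein_accession
            )
            loc_calls[lib_id] = winner
    db_labels: dict[int, str] = {}
    db_summary: dict[str, int] = {}
    if phospho_dbs:
        per_candidate = {}
        for lib_id in survivor_ids:
            entry = lib_by_id[lib_id]
            status = crossref_phospho_databases(entry, entry.site_offset, phospho_dbs)
            per_candidate[lib_id] = status
            db_labels[lib_id] = db_status_label(status)
        db_summary = summarize_db_status(per_candidate)

    # --- ranking and source attribution -----------------------------------
    report = rank_candidates(
        stoich,
        localization=loc_calls,
        motif_members=motif_member_ids,
        db_status=db_labels,
        accessions={i: lib_by_id[i].protein_accession for i in survivor_ids},
        sources={i: lib_by_id[i].source for i in survivor_ids},
    )
    counts["candidates"] = len(report)
    attribution = attribute_sources(survivor_ids, library)

    manifest = RunManifest(
        config=cfg_snapshot,
        input_digests={},
        counts=counts,
        version=__version__,
        random_seeds={"screen": seed},
    )
    manifest.validate()

    result = PipelineResult(
        manifest=manifest,
        criteria=criteria,
        outlier_ids=outliers,
        survivors=survivors,
        stoichiometry=stoich,
        report=report,
        source_attribution=attribution,
        motif_consensus=motif_consensus,
        motif_member_ids=motif_member_ids,
        db_summary=db_summary,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return result


def report_frame(report: Sequence[CandidateReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": c.rank,
                "library_id": c.library_id,
                "site": c.site,
                "accession": c.protein_accession,
                "stoichiometry": round(c.stoichiometry, 2),
                "phospho_psm_count": c.phospho_psm_count,
                "localization": c.localization,
                "in_consensus_motif": c.in_consensus_motif,
                "known_in_databases": c.known_in_databases,
                "source": c.source,
            }
            for c in report
        ]
    )


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report_frame(result.report).to_csv(out / "candidates.tsv", sep="\t", index=False)
    result.source_attribution.to_csv(out / "source_attribution.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "library_id": s.library_id,
                "site": s.site,
                "phospho_psm_count": s.phospho_psm_count,
                "total_psm_count": s.total_psm_count,
                "stoichiometry": round(s.stoichiometry, 2),
                "n_sites_on_peptide": s.n_sites_on_peptide,
            }
            for s in result.stoichiometry
        ]
    ).to_csv(out / "stoichiometry.tsv", sep="\t", index=False)
    manifest_dict = asdict(result.manifest)
    manifest_dict["manifest_digest"] = result.manifest.digest()
    manifest_dict["criteria"] = asdict(result.criteria)
    manifest_dict["motif_consensus"] = result.motif_consensus
    manifest_dict["db_summary"] = result.db_summary
    (out / "manifest.json").write_text(json.dumps(manifest_dict, indent=2, default=str))
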