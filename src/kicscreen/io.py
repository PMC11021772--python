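"""Readers and writers for the pipeline's plain-text formats.

Everything on disk is FASTA or tab-separated text with a header row, so
every intermediate is diffable and greppable:

* proteome: FASTA (accession = record id);
* seed peptides: ``accession  peptide  site_index  residue  origin``;
* library: ``library_id  accession  window  site_offset  source`` plus a
  FASTA mirror;
* scan hits: ``accession  position  window  score  evalue  predictor``;
* GO mapping: ``accession  namespace  term``;
* localization evidence: ``accession  compartment  evidence_type``;
* phosphosite databases: ``database  accession  sequence  site_position``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import DbPhosphosite, LocalizationEvidence
from .library_design import PeptideEntry, SeedPhosphopeptide
from .predictors import ScanHit


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=acc, description="") for acc, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_seeds(path: str | Path) -> list[SeedPhosphopeptide]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        SeedPhosphopeptide(
            protein_accession=r.accession,
            peptide_sequence=r.peptide,
            site_index=int(r.site_index),
            residue=r.residue,
            origin_screen=getattr(r, "origin", "") or "",
        )
        for r in df.itertuples(index=False)
    ]


def write_seeds(seeds: Iterable[SeedPhosphopeptide], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "accession": s.protein_accession,
                "peptide": s.peptide_sequence,
                "site_index": s.site_index,
                "residue": s.residue,
                "origin": s.origin_screen,
            }
            for s in seeds
        ]
    ).to_csv(path, sep="\t", index=False)


def read_library(path: str | Path) -> list[PeptideEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        PeptideEntry(
            library_id=int(r.library_id),
            protein_accession=r.accession,
            window=r.window,
            site_offset=int(r.site_offset),
            source=r.source,
        )
        for r in df.itertuples(index=False)
    ]


def write_library(library: Iterable[PeptideEntry], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "library_id": e.library_id,
                "accession": e.protein_accession,
                "window": e.window,
                "site_offset": e.site_offset,
                "source": e.source,
            }
            for e in library
        ]
    ).to_csv(path, sep="\t", index=False)


def write_library_fasta(library: Iterable[PeptideEntry], path: str | Path) -> None:
    write_fasta(
        ((f"pep{e.library_id}|{e.protein_accession}|{e.source}", e.window) for e in library),
        path,
    )


def write_scan_hits(hits: Iterable[ScanHit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "accession": h.protein_accession,
                "position": h.site_position,
                "window": h.window,
                "score": f"{h.score:.4f}",
                "evalue": "" if h.evalue is None else f"{h.evalue:.3e}",
                "predictor": h.predictor,
            }
            for h in hits
        ],
        columns=["accession", "position", "window", "score", "evalue", "predictor"],
    ).to_csv(path, sep="\t", index=False)


def read_go_mapping(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping: dict[str, list[tuple[str, str]]] = {}
    for r in df.itertuples(index=False):
        mapping.setdefault(r.accession, []).append((r.namespace, r.term))
    return mapping


def read_localization(path: str | Path) -> list[LocalizationEvidence]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        LocalizationEvidence(r.accession, r.compartment, r.evidence_type)
        for r in df.itertuples(index=False)
    ]


def read_phospho_db(path: str | Path) -> dict[str, list[DbPhosphosite]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[DbPhosphosite]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.database, []).append(
            DbPhosphosite(r.database, r.accession, r.sequence, int(r.site_position))
        )
    return out


def write_ground_truth(truth, path: str | Path) -> None:
    rows = []
    for lib_id in sorted(truth.true_substrate_ids):
        rows.append(
            {
                "library_id": lib_id,
                "role": "substrate",
                "site": truth.planted_sites.get(lib_id, ""),
                "stoichiometry": truth.planted_stoichiometries.get(lib_id, ""),
                "in_motif": lib_id in truth.motif_ids,
            }
        )
    for lib_id in sorted(truth.outlier_ids):
        rows.append(
            {
                "library_id": lib_id,
                "role": "ubiquitous_outlier",
                "site": "",
                "stoichiometry": "",
                "in_motif": False,
            }
        )
    pd.DataFrame(
        rows, columns=["library_id", "role", "site", "stoichiometry", "in_motif"]
    ).to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path):
    from .synthetic import GroundTruth

    df = pd.read_csv(path, sep="\t")
    truth = GroundTruth(set(), {}, {})
    for r in df.itertuples(index=False):
        if r.role == "substrate":
            lib_id = int(r.library_id)
            truth.true_substrate_ids.add(lib_id)
            truth.planted_sites[lib_id] = int(r.site)
            truth.planted_stoichiometries[lib_id] = float(r.stoichiometry)
            if bool(r.in_motif):
                truth.motif_ids.add(lib_id)
        else:
            truth.outlier_ids.add(int(r.library_id))
    return truth
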