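"""Design of a centered synthetic phosphopeptide library.

A KiC (kinase-client) assay library is a pool of fixed-length synthetic
peptides, each carrying one candidate phosphosite. Library members are
20-mer windows cut from parent proteins with the phosphorylatable S/T/Y
residue at a fixed offset, assembled from three sources: prior
experimentally observed phosphopeptides (positive controls), profile-HMM
proteome-scan hits, and KNN similarity-scorer hits.

All windows use 1-based site coordinates; the phosphosite sits at window
position ``SITE_OFFSET`` (10 of 20), i.e. 9 upstream and 10 downstream
flanking residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

WINDOW_LENGTH = 20
SITE_OFFSET = 10  # 1-based position of the phosphosite within a window
PHOSPHO_RESIDUES = frozenset("STY")

SOURCE_PRIORITY = ("hmm", "ml", "experimental_control")


class LibraryDesignError(ValueError):
    """Raised for invalid peptides, sites, or assembly inputs."""


@dataclass(frozen=True)
class SeedPhosphopeptide:
    """One experimentally observed phosphopeptide used to seed the library.

    ``site_index`` is the 1-based position of the phospho-residue within
    ``peptide_sequence``; ``origin_screen`` records which kinase screen the
    peptide came from (e.g. ``P2K1`` / ``P2K2``).
    """

    protein_accession: str
    peptide_sequence: str
    site_index: int
    residue: str
    origin_screen: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.site_index <= len(self.peptide_sequence):
            raise LibraryDesignError(
                f"site_index {self.site_index} out of bounds for peptide of "
                f"length {len(self.peptide_sequence)}"
            )
        actual = self.peptide_sequence[self.site_index - 1]
        if actual != self.residue:
            raise LibraryDesignError(
                f"residue field {self.residue!r} does not match sequence "
                f"position {self.site_index} ({actual!r})"
            )
        if self.residue not in PHOSPHO_RESIDUES:
            raise LibraryDesignError(
                f"phosphosite residue must be S, T or Y, got {self.residue!r}"
            )


@dataclass(frozen=True)
class PeptideEntry:
    """One library member: a 20-mer window with the phosphosite centered."""

    library_id: int
    protein_accession: str
    window: str
    site_offset: int = SITE_OFFSET
    source: str = "experimental_control"

    def __post_init__(self) -> None:
        if len(self.window) != WINDOW_LENGTH:
            raise LibraryDesignError(
                f"window must be {WINDOW_LENGTH} residues, got "
                f"{len(self.window)}: {self.window!r}"
            )
        if self.window[self.site_offset - 1] not in PHOSPHO_RESIDUES:
            raise LibraryDesignError(
                f"window position {self.site_offset} must be S/T/Y: "
                f"{self.window!r}"
            )


@dataclass(frozen=True)
class PoolSpec:
    """Equal-volume pooling of peptide stocks into one assay pool."""

    n_peptides: int
    stock_concentration: float  # molar units; output is in the same units
    aliquot_volume: float = 10.0

    def __post_init__(self) -> None:
        if self.n_peptides <= 0:
            raise LibraryDesignError("n_peptides must be positive")
        if self.stock_concentration <= 0 or self.aliquot_volume <= 0:
            raise LibraryDesignError("concentration and volume must be positive")


def extract_window(
    protein_sequence: str,
    site_position: int,
    site_offset: int = SITE_OFFSET,
    window_length: int = WINDOW_LENGTH,
) -> str:
    """Cut the fixed-length window around a phosphosite in a protein.

    ``site_position`` is 1-based in the protein. The site lands at
    ``site_offset`` (1-based) of the returned window, requiring
    ``site_offset - 1`` upstream and ``window_length - site_offset``
    downstream residues. Sites too close to either terminus are rejected
    rather than padded.
    """
    if not 1 <= site_position <= len(protein_sequence):
        raise LibraryDesignError(
            f"site_position {site_position} out of bounds for protein of "
            f"length {len(protein_sequence)}"
        )
    residue = protein_sequence[site_position - 1]
    if residue not in PHOSPHO_RESIDUES:
        raise LibraryDesignError(
            f"site residue must be S, T or Y, got {residue!r} at position "
            f"{site_position}"
        )
    upstream = site_offset - 1
    downstream = window_length - site_offset
    if site_position - 1 < upstream or len(protein_sequence) - site_position < downstream:
        raise LibraryDesignError(
            f"site at position {site_position} lacks the {upstream} upstream / "
            f"{downstream} downstream residues required for a "
            f"{window_length}-mer window"
        )
    start = site_position - site_offset  # 0-based
    return protein_sequence[start : start + window_length]


def filter_site_distance(peptide: SeedPhosphopeptide, min_flank: int = 5) -> bool:
    """Keep only peptides whose phosphosite is at least ``min_flank``
    residues from either end (the pre-filter applied to seed peptides)."""
    upstream = peptide.site_index - 1
    downstream = len(peptide.peptide_sequence) - peptide.site_index
    return upstream >= min_flank and downstream >= min_flank


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = 0.0
_aligner.open_gap_score = -1.0
_aligner.extend_gap_score = -1.0


def pairwise_similarity(a: str, b: str) -> float:
    """Identical-match fraction of an optimal global alignment.

    Score model: match +1, mismatch 0, gap -1 per gapped column; the
    fraction is the number of identically aligned residue pairs divided by
    the length of the longer sequence, so it is symmetric and lies in
    [0, 1] with 1.0 only for identical sequences.
    """
    if not a or not b:
        raise LibraryDesignError("cannot compare empty sequences")
    if a == b:
        return 1.0
    alignment = _aligner.align(a, b)[0]
    aligned_a, aligned_b = alignment[0], alignment[1]
    matches = sum(x == y for x, y in zip(aligned_a, aligned_b) if x != "-")
    return matches / max(len(a), len(b))


def deduplicate(
    peptides: Sequence[str],
    threshold: float = 0.6,
) -> list[str]:
    """Greedy similarity-based redundancy removal.

    Peptides are visited in the given (deterministic) order; one is dropped
    iff its similarity to an already-retained peptide is strictly greater
    than ``threshold``. The retained set therefore has pairwise similarity
    <= threshold. Callers wanting the experimental-first ordering sort
    before calling (see :func:`dedup_order`).
    """
    if not 0 < threshold <= 1:
        raise LibraryDesignError("threshold must be in (0, 1]")
    retained: list[str] = []
    for pep in peptides:
        if all(pairwise_similarity(pep, kept) <= threshold for kept in retained):
            retained.append(pep)
    return retained


def dedup_order(
    peptides: Iterable[str],
    experimental: Iterable[str] = (),
) -> list[str]:
    """Deterministic visiting order for :func:`deduplicate`: peptides with
    experimental evidence first, then lexicographic within each block."""
    exp = set(experimental)
    return sorted(set(peptides), key=lambda p: (p not in exp, p))


def assemble_library(
    hmm_hits: Sequence[PeptideEntry | tuple[str, str]],
    ml_hits: Sequence[PeptideEntry | tuple[str, str]],
    controls: Sequence[PeptideEntry | tuple[str, str]],
) -> list[PeptideEntry]:
    """Concatenate the three library sources into the final numbered library.

    Inputs may be ``PeptideEntry`` objects or ``(accession, window)`` pairs.
    Windows appearing in more than one source are kept once, attributed by
    the priority hmm > ml > experimental_control; ids are assigned 1..n in
    that order. Malformed windows are reported together.
    """
    groups = (("hmm", hmm_hits), ("ml", ml_hits), ("experimental_control", controls))
    seen: dict[str, PeptideEntry] = {}
    errors: list[str] = []
    next_id = 1
    out: list[PeptideEntry] = []
    for source, members in groups:
        for member in members:
            if isinstance(member, PeptideEntry):
                accession, window = member.protein_accession, member.window
            else:
                accession, window = member
            if window in seen:
                continue
            try:
                entry = PeptideEntry(
                    library_id=next_id,
                    protein_accession=accession,
                    window=window,
                    source=source,
                )
            except LibraryDesignError as exc:
                errors.append(f"{source}:{accession}: {exc}")
                continue
            seen[window] = entry
            out.append(entry)
            next_id += 1
    if errors:
        raise LibraryDesignError(
            "invalid windows in library assembly:\n  " + "\n  ".join(errors)
        )
    return out


def sample_controls(
    seed_peptides: Sequence,
    n: int = 57,
    random_seed: int = 0,
) -> list:
    """Uniform sample of positive-control peptides, without replacement."""
    if n > len(seed_peptides):
        raise LibraryDesignError(
            f"cannot sample {n} controls from {len(seed_peptides)} peptides"
        )
    rng = np.random.default_rng(random_seed)
    idx = rng.choice(len(seed_peptides), size=n, replace=False)
    return [seed_peptides[i] for i in sorted(idx)]


def pool_per_peptide_concentration(pool: PoolSpec) -> float:
    """Per-peptide concentration after equal-volume pooling of identical
    stocks: stock / n (e.g. 5 mM pooled 225-way -> 22.2 uM)."""
    return pool.stock_concentration / pool.n_peptides


def merge_seed_pools(*pools: Sequence[SeedPhosphopeptide]) -> list[SeedPhosphopeptide]:
    """Merge per-screen seed lists (e.g. the P2K1 and P2K2 pools) into one
    working pool, preserving order and origin labels."""
    merged: list[SeedPhosphopeptide] = []
    for pool in pools:
        merged.extend(pool)
    return merged
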