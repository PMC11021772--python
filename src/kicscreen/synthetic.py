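"""Synthetic KiC-screen generator.

Emulates the full study design at desk scale with known ground truth: a
toy proteome, seed phosphopeptide pools from two prior kinase screens, a
centered 20-mer library, and simulated PSM tables for the 2x2 screen
(wildtype / dead enzyme x +/- ATP).

The generative model mirrors what the filtration criteria were built to
separate:

* true substrates appear in the wildtype +ATP sample as multi-PSM,
  high-Xcorr, well-localized phosphopeptides, with unmodified PSMs added
  so the empirical phospho fraction targets the planted stoichiometry;
* every sample (negatives included) picks up spurious single phospho-PSMs
  at low Xcorr and shaky site localization — exactly the background a
  "count >= 2, Xcorr above the worst negative" rule removes;
* optionally one peptide is phosphorylated in every sample, the
  uninformative ubiquitous-outlier pattern.

All randomness flows from ``random_seed``; a fixed seed reproduces the
screen byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .library_design import (
    PeptideEntry,
    SeedPhosphopeptide,
    SITE_OFFSET,
    WINDOW_LENGTH,
    extract_window,
)
from .predictors import AMINO_ACIDS, iter_candidate_sites
from .psm_filtering import PSMRecord

# Rough globular-protein residue composition; S/T/Y kept realistic so a
# random proteome offers plenty of candidate phosphosites.
BACKGROUND_COMPOSITION: dict[str, float] = {
    "A": 0.0777, "C": 0.0157, "D": 0.0530, "E": 0.0656, "F": 0.0405,
    "G": 0.0691, "H": 0.0227, "I": 0.0591, "K": 0.0595, "L": 0.0960,
    "M": 0.0238, "N": 0.0427, "P": 0.0469, "Q": 0.0393, "R": 0.0526,
    "S": 0.0822, "T": 0.0584, "V": 0.0667, "W": 0.0113, "Y": 0.0292,
}
_COMP = np.array([BACKGROUND_COMPOSITION[a] for a in AMINO_ACIDS])
_COMP = _COMP / _COMP.sum()

SAMPLES = (
    ("wt_plus", "wildtype", "plus"),
    ("wt_minus", "wildtype", "minus"),
    ("dead_plus", "dead", "plus"),
    ("dead_minus", "dead", "minus"),
)


class SyntheticDataError(ValueError):
    pass


@dataclass
class SyntheticScreenConfig:
    """Knobs of the simulated screen; defaults emulate the study scale
    (225-peptide library, 46 true substrates, 405 seed peptides)."""

    random_seed: int = 0
    n_proteins: int = 80
    protein_length_range: tuple[int, int] = (120, 400)
    n_library_peptides: int = 225
    n_true_substrates: int = 46
    n_seeds_per_screen: tuple[int, int] = (177, 228)  # P2K1, P2K2 pools
    planted_motif: dict[int, str] | None = None  # offset -> residue
    planted_motif_sites: int = 12
    motif_in_seed_fraction: float = 0.0  # share of seed peptides carrying it
    signal_psm_rate: float = 4.0
    signal_xcorr: tuple[float, float] = (3.0, 0.4)
    noise_rate: float = 0.02
    noise_xcorr: tuple[float, float] = (1.7, 0.25)
    planted_stoichiometry: float = 0.8
    include_ubiquitous_outlier: bool = True

    def __post_init__(self) -> None:
        if self.n_true_substrates > self.n_library_peptides:
            raise SyntheticDataError("n_true_substrates exceeds the library size")
        if not 0 <= self.noise_rate <= 1:
            raise SyntheticDataError("noise_rate must be a probability")
        if not 0 <= self.motif_in_seed_fraction <= 1:
            raise SyntheticDataError("motif_in_seed_fraction must be in [0, 1]")
        if not 0 < self.planted_stoichiometry <= 1:
            raise SyntheticDataError("planted_stoichiometry must be in (0, 1]")
        lo, hi = self.protein_length_range
        if lo > hi or lo < WINDOW_LENGTH:
            raise SyntheticDataError("invalid protein_length_range")
        if self.planted_motif:
            flank_lo, flank_hi = -(SITE_OFFSET - 1), WINDOW_LENGTH - SITE_OFFSET
            for off in self.planted_motif:
                if off == 0 or not flank_lo <= off <= flank_hi:
                    raise SyntheticDataError(
                        f"motif offset {off} outside the window flanks "
                        f"[{flank_lo}, {flank_hi}] (0 is the phosphosite)"
                    )


@dataclass
class GroundTruth:
    true_substrate_ids: set[int]
    planted_sites: dict[int, int]  # library_id -> in-peptide site index
    planted_stoichiometries: dict[int, float]
    outlier_ids: set[int] = field(default_factory=set)
    motif_ids: set[int] = field(default_factory=set)


@dataclass
class SyntheticScreen:
    """Everything one simulated screen produces."""

    config: SyntheticScreenConfig
    proteome: list[tuple[str, str]]
    seeds: list[SeedPhosphopeptide]
    library: list[PeptideEntry]
    truth: GroundTruth
    psm_tables: dict[str, list[PSMRecord]]


def _random_protein(rng: np.random.Generator, length: int) -> str:
    letters = np.array(list(AMINO_ACIDS))
    return "".join(letters[rng.choice(len(letters), size=length, p=_COMP)])


def generate_proteome_and_seeds(
    config: SyntheticScreenConfig,
) -> tuple[list[tuple[str, str]], list[SeedPhosphopeptide], GroundTruth, list[PeptideEntry]]:
    """Generate the proteome, the seed pools, the library, and ground truth.

    Library sites are eligible S/T/Y positions with full 20-mer flanks;
    ``n_true_substrates`` of them are designated true substrates, the
    first ``planted_motif_sites`` of which get the planted motif residues
    written into the protein sequence (so motif instances are verifiable
    by plain string scan). Seed peptides are variable-length (12-25 aa)
    cut-outs around further sites, split into two origin pools.
    """
    rng = np.random.default_rng(config.random_seed)
    lo, hi = config.protein_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_proteins)
    proteins: dict[str, list[str]] = {
        f"SYN{i + 1:04d}": list(_random_protein(rng, int(lengths[i])))
        for i in range(config.n_proteins)
    }
    accessions = list(proteins)

    # all eligible (accession, 1-based site) pairs, deterministic order
    eligible: list[tuple[str, int]] = []
    for acc in accessions:
        seq = "".join(proteins[acc])
        for pos, _window in iter_candidate_sites(seq):
            eligible.append((acc, pos))
    n_seeds = sum(config.n_seeds_per_screen)
    needed = config.n_library_peptides + n_seeds
    if len(eligible) < needed:
        raise SyntheticDataError(
            f"proteome offers {len(eligible)} candidate sites but "
            f"{needed} are needed; increase n_proteins or lengths"
        )
    order = rng.permutation(len(eligible))
    picked_sites = [eligible[i] for i in order]

    # Motif-bearing sites are chosen first, skipping any combination whose
    # planted residues would overwrite another chosen phosphosite; the
    # centers of all remaining sites must stay clear of the edits so every
    # library window and seed peptide keeps an S/T/Y phosphosite.
    truth = GroundTruth(set(), {}, {})
    n_motif = min(config.planted_motif_sites, config.n_true_substrates)
    n_seed_motif = (
        int(round(config.motif_in_seed_fraction * n_seeds))
        if config.planted_motif
        else 0
    )
    motif_sites: list[tuple[str, int]] = []
    edits: set[tuple[str, int]] = set()  # (accession, 0-based index) to overwrite
    if config.planted_motif and n_motif + n_seed_motif > 0:
        centers_used: set[tuple[str, int]] = set()
        for acc, pos in picked_sites:
            site_edits = {(acc, pos - 1 + off) for off in config.planted_motif}
            center = (acc, pos - 1)
            if center in edits or site_edits & centers_used or site_edits & edits:
                continue
            motif_sites.append((acc, pos))
            edits |= site_edits
            centers_used.add(center)
            if len(motif_sites) == n_motif + n_seed_motif:
                break
        if len(motif_sites) < n_motif + n_seed_motif:
            raise SyntheticDataError(
                "could not place the planted motif without collisions; "
                "motif wider than available flanks or proteome too small"
            )
        for acc, pos in motif_sites:
            for off, residue in config.planted_motif.items():
                proteins[acc][pos - 1 + off] = residue

    lib_motif_sites = motif_sites[:n_motif]
    seed_motif_sites = motif_sites[n_motif:]
    motif_set = set(motif_sites)
    rest = [
        sp
        for sp in picked_sites
        if sp not in motif_set and (sp[0], sp[1] - 1) not in edits
    ]
    n_fill = config.n_library_peptides - len(lib_motif_sites)
    n_seed_fill = n_seeds - len(seed_motif_sites)
    if len(rest) < n_fill + n_seed_fill:
        raise SyntheticDataError("not enough collision-free sites; enlarge the proteome")
    library_sites = lib_motif_sites + rest[:n_fill]
    seed_sites = seed_motif_sites + rest[n_fill : n_fill + n_seed_fill]

    proteome = [(acc, "".join(proteins[acc])) for acc in accessions]
    by_acc = dict(proteome)

    # assemble the library with study-like source proportions
    n = config.n_library_peptides
    n_hmm = round(n * 81 / 225)
    n_ml = round(n * 87 / 225)
    library: list[PeptideEntry] = []
    for idx, (acc, pos) in enumerate(library_sites):
        source = (
            "hmm" if idx < n_hmm else "ml" if idx < n_hmm + n_ml else "experimental_control"
        )
        window = extract_window(by_acc[acc], pos)
        library.append(
            PeptideEntry(
                library_id=idx + 1,
                protein_accession=acc,
                window=window,
                source=source,
            )
        )

    true_ids = set(range(1, config.n_true_substrates + 1))
    truth.true_substrate_ids = true_ids
    truth.planted_sites = {i: SITE_OFFSET for i in true_ids}
    truth.planted_stoichiometries = {
        i: config.planted_stoichiometry for i in true_ids
    }
    if config.planted_motif:
        truth.motif_ids = set(range(1, n_motif + 1))

    # seed pools with variable peptide lengths and >= 5-residue flanks
    seeds: list[SeedPhosphopeptide] = []
    origins = ["P2K1"] * config.n_seeds_per_screen[0] + ["P2K2"] * config.n_seeds_per_screen[1]
    for (acc, pos), origin in zip(seed_sites, origins):
        seq = by_acc[acc]
        up = int(rng.integers(5, 13))
        down = int(rng.integers(5, 13))
        up = min(up, pos - 1)
        down = min(down, len(seq) - pos)
        if up < 5 or down < 5:
            # eligible sites have >= 9/10 flanks, so this cannot happen;
            # guarded for safety with shorter windows
            up, down = 5, 5
        pep = seq[pos - 1 - up : pos + down]
        seeds.append(
            SeedPhosphopeptide(
                protein_accession=acc,
                peptide_sequence=pep,
                site_index=up + 1,
                residue=seq[pos - 1],
                origin_screen=origin,
            )
        )

    if config.include_ubiquitous_outlier:
        non_true = [e.library_id for e in library if e.library_id not in true_ids]
        if non_true:
            truth.outlier_ids = {non_true[0]}
    return proteome, seeds, truth, library


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    draws = rng.normal(mean, sd, size=size)
    return np.clip(draws, 0.0, None)


def simulate_psm_tables(
    config: SyntheticScreenConfig,
    library: Sequence[PeptideEntry],
    truth: GroundTruth,
) -> dict[str, list[PSMRecord]]:
    """Simulate the four per-sample PSM tables of the 2x2 screen."""
    rng = np.random.default_rng(config.random_seed + 1)
    tables: dict[str, list[PSMRecord]] = {}
    lib_by_id = {e.library_id: e for e in library}
    s = config.planted_stoichiometry
    for sample_id, enzyme, atp in SAMPLES:
        records: list[PSMRecord] = []
        is_test = enzyme == "wildtype" and atp == "plus"
        if is_test:
            for lib_id in sorted(truth.true_substrate_ids):
                entry = lib_by_id[lib_id]
                n_phos = 1 + int(rng.poisson(config.signal_psm_rate))
                xc = _trunc_normal(rng, *config.signal_xcorr, n_phos)
                probs = rng.uniform(0.9, 1.0, size=n_phos)
                site = truth.planted_sites[lib_id]
                for j in range(n_phos):
                    records.append(
                        PSMRecord(
                            sample_id, enzyme, atp, lib_id, entry.window,
                            True, (site,), float(xc[j]), float(probs[j]),
                        )
                    )
                n_unmod = int(round(n_phos * (1 - s) / s))
                xcu = _trunc_normal(rng, *config.signal_xcorr, n_unmod)
                for j in range(n_unmod):
                    records.append(
                        PSMRecord(
                            sample_id, enzyme, atp, lib_id, entry.window,
                            False, (), float(xcu[j]), None,
                        )
                    )
        # spurious identifications hit every sample alike
        spurious = rng.random(len(library)) < config.noise_rate
        xcn = _trunc_normal(rng, *config.noise_xcorr, int(spurious.sum()))
        probs = rng.uniform(0.3, 0.95, size=int(spurious.sum()))
        j = 0
        for entry, hit in zip(library, spurious):
            if not hit:
                continue
            records.append(
                PSMRecord(
                    sample_id, enzyme, atp, entry.library_id, entry.window,
                    True, (entry.site_offset,), float(xcn[j]), float(probs[j]),
                )
            )
            j += 1
        for out_id in sorted(truth.outlier_ids):
            entry = lib_by_id[out_id]
            xo = _trunc_normal(rng, 2.5, 0.3, 2)
            po = rng.uniform(0.8, 1.0, size=2)
            for j in range(2):
                records.append(
                    PSMRecord(
                        sample_id, enzyme, atp, out_id, entry.window,
                        True, (entry.site_offset,), float(xo[j]), float(po[j]),
                    )
                )
        tables[sample_id] = records
    return tables


def generate_screen(config: SyntheticScreenConfig) -> SyntheticScreen:
    """One-call generation of a complete synthetic screen."""
    proteome, seeds, truth, library = generate_proteome_and_seeds(config)
    tables = simulate_psm_tables(config, library, truth)
    return SyntheticScreen(config, proteome, seeds, library, truth, tables)


def write_screen(screen: SyntheticScreen, out_dir: str | Path) -> dict[str, Path]:
    """Write the screen to plain-text files (FASTA, TSVs); returns paths."""
    from . import io as kio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["proteome"] = out / "proteome.fasta"
    kio.write_fasta(screen.proteome, paths["proteome"])
    paths["seeds"] = out / "seeds.tsv"
    kio.write_seeds(screen.seeds, paths["seeds"])
    paths["library"] = out / "library.tsv"
    kio.write_library(screen.library, paths["library"])
    kio.write_library_fasta(screen.library, out / "library.fasta")
    from .psm_filtering import write_psm_table

    for sample_id, records in screen.psm_tables.items():
        p = out / f"psm_{sample_id}.tsv"
        write_psm_table(records, p)
        paths[f"psm_{sample_id}"] = p
    paths["truth"] = out / "ground_truth.tsv"
    kio.write_ground_truth(screen.truth, paths["truth"])
    return paths
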