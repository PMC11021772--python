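#!/usr/bin/env python
"""Quantify and prioritize the called substrates: spectral-count
stoichiometry, 90%-identity redundancy clustering plus consensus-motif
detection, source attribution, and the final ranked candidate report.

Reads results/screen/ and results/filtering/; writes results/candidates/.
"""

from pathlib import Path

import pandas as pd

from kicscreen import io as kio
from kicscreen.motif import cluster_redundant_peptides, find_positional_motif
from kicscreen.pipeline import _library_background, attribute_sources
from kicscreen.psm_filtering import read_psm_table
from kicscreen.quantify import compute_stoichiometry, rank_candidates

SCREEN = Path("results/screen")
FILTERING = Path("results/filtering")
OUT = Path("results/candidates")


def main() -> None:
    library = kio.read_library(SCREEN / "library.tsv")
    truth = kio.read_ground_truth(SCREEN / "ground_truth.tsv")
    test = read_psm_table(SCREEN / "psm_wt_plus.tsv")
    surv_df = pd.read_csv(FILTERING / "survivors.tsv", sep="\t")
    survivors = {(int(r.library_id), int(r.site)) for r in surv_df.itertuples()}

    stoich = compute_stoichiometry(test, survivors)
    full = [s for s in stoich if s.stoichiometry == 100.0]
    print(f"stoichiometry for {len(stoich)} surviving sites; "
          f"{len(full)} at 100% (no unmodified spectra observed)")

    lib_by_id = {e.library_id: e for e in library}
    survivor_ids = sorted({lib for lib, _ in survivors})
    windows = [lib_by_id[i].window for i in survivor_ids]
    reps, assignment = cluster_redundant_peptides(windows)
    motif = find_positional_motif(reps, _library_background(library))
    members = [survivor_ids[i] for i in range(len(windows))
               if assignment[i] in set(motif.member_ids)]
    print(f"redundancy clustering: {len(windows)} windows -> {len(reps)} "
          f"representatives; consensus motif {motif.consensus!r} with "
          f"{len(members)} member peptides "
          f"(planted motif carriers among survivors: "
          f"{len(set(members) & truth.motif_ids)}/{len(truth.motif_ids & set(survivor_ids))})")

    report = rank_candidates(
        stoich,
        motif_members=members,
        accessions={i: lib_by_id[i].protein_accession for i in survivor_ids},
        sources={i: lib_by_id[i].source for i in survivor_ids},
    )
    attribution = attribute_sources(survivor_ids, library)
    print("source attribution:")
    for r in attribution.itertuples():
        print(f"  {r.source}: {r.candidates}/{r.library_members} "
              f"({r.hit_rate_percent:.1f}%)")

    OUT.mkdir(parents=True, exist_ok=True)
    from kicscreen.pipeline import report_frame

    report_frame(report).to_csv(OUT / "ranked_candidates.tsv", sep="\t", index=False)
    attribution.to_csv(OUT / "source_attribution.tsv", sep="\t", index=False)
    motif.pvalues.to_csv(OUT / "motif_enrichment.tsv", sep="\t", index=False)
    top = report[0]
    print(f"top candidate: peptide {top.library_id} ({top.protein_accession}), "
          f"{top.stoichiometry:.0f}% stoichiometry, "
          f"{top.phospho_psm_count} phospho-PSMs, "
          f"motif member: {top.in_consensus_motif}")
    print(f"wrote ranked candidates, attribution and motif table under {OUT}/")


if __name__ == "__main__":
    main()
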