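#!/usr/bin/env python
"""Simulate the reference 2x2 kinase screen used by the rest of the
analysis: a 225-peptide centered library over a toy proteome, 46 planted
true substrates at 80% stoichiometry, spurious low-Xcorr identifications
in every sample, and one ubiquitous-outlier peptide.

Writes results/screen/: proteome FASTA, seed + library TSVs, four
per-sample PSM tables and the ground truth.
"""

from pathlib import Path

from kicscreen.synthetic import SyntheticScreenConfig, generate_screen, write_screen

OUT = Path("results/screen")
SEED = 1


def main() -> None:
    config = SyntheticScreenConfig(
        random_seed=SEED,
        planted_motif={-3: "D", -2: "W", 2: "P"},
        planted_motif_sites=12,
        # prior screens of a kinase with this motif would have caught it:
        # a third of the seed phosphopeptides carry it too, which is what
        # gives the trained predictors something to generalize from
        motif_in_seed_fraction=0.33,
    )
    screen = generate_screen(config)
    paths = write_screen(screen, OUT)

    n_phospho = {
        sid: sum(r.is_phospho for r in recs)
        for sid, recs in screen.psm_tables.items()
    }
    print(f"proteome: {len(screen.proteome)} proteins")
    print(f"seed pool: {len(screen.seeds)} peptides "
          f"({sum(s.origin_screen == 'P2K1' for s in screen.seeds)} P2K1 + "
          f"{sum(s.origin_screen == 'P2K2' for s in screen.seeds)} P2K2)")
    print(f"library: {len(screen.library)} peptides, "
          f"{len(screen.truth.true_substrate_ids)} planted substrates, "
          f"{len(screen.truth.motif_ids)} carrying the planted motif")
    print("phospho-PSMs per sample:", n_phospho)
    print(f"outlier peptide(s): {sorted(screen.truth.outlier_ids)}")
    print(f"wrote {len(paths)} files under {OUT}/")


if __name__ == "__main__":
    main()
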