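#!/usr/bin/env python
"""Annotate the called substrates with synthetic evidence tables built
alongside the toy proteome: GO-class abundance, weighted subcellular
localization, and cross-reference against two synthetic phosphosite
databases (one of which deliberately contains half of the surviving
windows, so both 'known' and 'novel' categories are exercised).

All annotation inputs here are synthetic stand-ins generated from the
screen itself — they demonstrate the bookkeeping, not real biology.

Reads results/screen/ and results/filtering/; writes results/annotation/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from kicscreen import io as kio
from kicscreen.annotation import (
    DbPhosphosite,
    LocalizationEvidence,
    COMPARTMENTS,
    crossref_phospho_databases,
    score_subcellular_localization,
    summarize_db_status,
    summarize_go_abundance,
)

SCREEN = Path("results/screen")
FILTERING = Path("results/filtering")
OUT = Path("results/annotation")
SEED = 1

GO_TERMS = {
    "molecular function": ["kinase activity", "catalytic activity",
                           "transferase activity", "protein binding", "other"],
    "biological process": ["metabolic process", "response to stress",
                           "structure development", "other cellular process"],
}


def main() -> None:
    rng = np.random.default_rng(SEED)
    library = kio.read_library(SCREEN / "library.tsv")
    proteome = dict(kio.read_fasta(SCREEN / "proteome.fasta"))
    surv_df = pd.read_csv(FILTERING / "survivors.tsv", sep="\t")
    survivor_ids = sorted(set(surv_df.library_id))
    lib_by_id = {e.library_id: e for e in library}
    accessions = sorted({lib_by_id[i].protein_accession for i in survivor_ids})

    # synthetic GO assignments: 1-3 terms per namespace per protein
    go = {}
    for acc in accessions:
        terms = []
        for ns, vocab in GO_TERMS.items():
            picks = rng.choice(len(vocab), size=rng.integers(1, 4), replace=False)
            terms += [(ns, vocab[i]) for i in picks]
        go[acc] = terms
    go_df = summarize_go_abundance(go, accessions)
    print("GO classes above 1% abundance:")
    for ns, sub in go_df.groupby("namespace"):
        top = sub.sort_values("percent", ascending=False).iloc[0]
        print(f"  {ns}: {len(sub)} classes, top {top.term!r} ({top.percent:.1f}%)")

    # synthetic localization evidence: a favored compartment per protein,
    # one experimental row plus a few possibly-conflicting predictions
    evidence = []
    for acc in accessions:
        favored = COMPARTMENTS[rng.integers(0, len(COMPARTMENTS))]
        evidence.append(LocalizationEvidence(acc, favored, "experimental"))
        for _ in range(int(rng.integers(0, 4))):
            other = COMPARTMENTS[rng.integers(0, len(COMPARTMENTS))]
            evidence.append(LocalizationEvidence(acc, other, "predicted"))
    calls = {}
    for acc in accessions:
        winner, _scores, tie = score_subcellular_localization(evidence, acc)
        calls[acc] = winner
    membrane = sum(1 for c in calls.values() if c == "plasma membrane")
    print(f"localization: {membrane}/{len(calls)} candidate proteins called "
          "plasma membrane")

    # synthetic databases: DB-A holds every second surviving window with
    # the correct site; DB-B holds every fourth, site shifted for some
    dbs: dict[str, list[DbPhosphosite]] = {"synthA": [], "synthB": []}
    for rank, lib_id in enumerate(survivor_ids):
        entry = lib_by_id[lib_id]
        seq = proteome[entry.protein_accession]
        start = seq.find(entry.window)
        site_pos = start + entry.site_offset
        if rank % 2 == 0:
            dbs["synthA"].append(
                DbPhosphosite("synthA", entry.protein_accession, seq, site_pos))
        if rank % 4 == 0:
            dbs["synthB"].append(
                DbPhosphosite("synthB", entry.protein_accession, seq, site_pos))
    per_candidate = {}
    for lib_id in survivor_ids:
        entry = lib_by_id[lib_id]
        per_candidate[lib_id] = crossref_phospho_databases(
            entry, entry.site_offset, dbs)
    summary = summarize_db_status(per_candidate)
    print(f"database cross-reference: {summary['known_in_either']} known in "
          f"either, {summary['known_in_both']} in both, "
          f"{summary['novel']} novel (of {summary['total']})")
    assert summary["known_in_either"] + summary["novel"] == summary["total"]

    OUT.mkdir(parents=True, exist_ok=True)
    go_df.to_csv(OUT / "go_abundance.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"accession": a, "compartment": c} for a, c in sorted(calls.items())]
    ).to_csv(OUT / "localization_calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"library_id": k, **v} for k, v in sorted(per_candidate.items())]
    ).to_csv(OUT / "db_crossref.tsv", sep="\t", index=False)
    print(f"wrote annotation tables under {OUT}/")


if __name__ == "__main__":
    main()
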