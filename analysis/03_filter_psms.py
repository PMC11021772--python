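#!/usr/bin/env python
"""Negative-control filtration of the simulated screen: flag ubiquitous
outliers, derive the validity criteria from the three negative-control
samples, and call passing phosphopeptides in the wildtype +ATP condition.

Reads results/screen/; writes results/filtering/.
"""

from pathlib import Path

import pandas as pd

from kicscreen import io as kio
from kicscreen.psm_filtering import (
    apply_filters,
    derive_filter_thresholds,
    flag_ubiquitous_outliers,
    read_psm_table,
)

IN = Path("results/screen")
OUT = Path("results/filtering")
SAMPLES = ("wt_plus", "wt_minus", "dead_plus", "dead_minus")


def main() -> None:
    tables = {sid: read_psm_table(IN / f"psm_{sid}.tsv") for sid in SAMPLES}
    truth = kio.read_ground_truth(IN / "ground_truth.tsv")

    detected = {sid: {r.library_id for r in recs if r.is_phospho}
                for sid, recs in tables.items()}
    outliers = flag_ubiquitous_outliers(detected)
    print(f"ubiquitous outliers (phospho in all {len(tables)} samples): "
          f"{sorted(outliers)} (planted: {sorted(truth.outlier_ids)})")

    negatives = [r for recs in tables.values() for r in recs
                 if r.is_negative_control and r.library_id not in outliers]
    criteria = derive_filter_thresholds(negatives)
    print(f"criteria from negatives: PSM count >= {criteria.min_psm_count}, "
          f"Xcorr > {criteria.min_xcorr:.3f}, "
          f"site probability >= {criteria.min_site_probability}")

    rows = []
    for sid, recs in tables.items():
        kept = [r for r in recs if r.library_id not in outliers]
        passing = apply_filters(kept, criteria)
        rows.append({"sample": sid, "phospho_psms": sum(r.is_phospho for r in kept),
                     "passing_phosphopeptides": len(passing)})
        print(f"  {sid}: {len(passing)} passing phosphopeptides")
    survivors = apply_filters(
        [r for r in tables["wt_plus"] if r.library_id not in outliers], criteria
    )
    called = {lib for lib, _ in survivors}
    tp = len(called & truth.true_substrate_ids)
    print(f"wildtype +ATP: {len(called)} called, {tp} of "
          f"{len(truth.true_substrate_ids)} planted substrates recovered "
          f"(precision {tp / len(called):.3f}, "
          f"recall {tp / len(truth.true_substrate_ids):.3f})")

    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "per_sample_pass_counts.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(survivors), columns=["library_id", "site"]).to_csv(
        OUT / "survivors.tsv", sep="\t", index=False
    )
    pd.DataFrame([{
        "min_psm_count": criteria.min_psm_count,
        "min_xcorr": round(criteria.min_xcorr, 4),
        "min_site_probability": criteria.min_site_probability,
        "outliers": ";".join(map(str, sorted(outliers))),
    }]).to_csv(OUT / "criteria.tsv", sep="\t", index=False)
    print(f"wrote per-sample counts, survivors and criteria under {OUT}/")


if __name__ == "__main__":
    main()
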