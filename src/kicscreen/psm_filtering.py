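"""PSM-table ingestion and negative-control-derived filtering.

A 2x2 kinase screen (wildtype / catalytically dead enzyme x +/- ATP) gives
one PSM table per sample. Only the wildtype +ATP reaction can produce
genuine kinase signal; the other three samples are negative controls whose
phosphopeptide identifications are by construction false positives. The
filtration thresholds for valid phosphopeptide calls are derived from
those false positives so that, applied back to the negatives, nothing
survives:

1. per-site phospho-PSM count >= min_psm_count,
2. at least one supporting PSM with Xcorr strictly above min_xcorr,
3. phosphosite localization probability >= min_site_probability.

A peptide whose phosphorylated form shows up in every sample (negatives
included) carries no condition information and is flagged as a ubiquitous
outlier and excluded from all analyses.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

DEFAULT_SITE_PROBABILITY = 0.75

PSM_COLUMNS = [
    "sample_id",
    "enzyme_state",
    "atp_state",
    "library_id",
    "sequence",
    "is_phospho",
    "site_positions",
    "xcorr",
    "site_probability",
]


class PSMError(ValueError):
    pass


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match with its screen-condition metadata."""

    sample_id: str
    enzyme_state: str  # "wildtype" | "dead"
    atp_state: str  # "plus" | "minus"
    library_id: int
    sequence: str
    is_phospho: bool
    site_positions: tuple[int, ...] = ()
    xcorr: float = 0.0
    site_probability: float | None = None

    def __post_init__(self) -> None:
        if self.is_phospho != bool(self.site_positions):
            raise PSMError(
                "is_phospho must match whether site_positions is non-empty"
            )
        if self.xcorr < 0:
            raise PSMError("xcorr must be >= 0")
        if self.site_probability is not None and not 0 <= self.site_probability <= 1:
            raise PSMError("site_probability must be in [0, 1]")
        if self.enzyme_state not in ("wildtype", "dead"):
            raise PSMError(f"unknown enzyme_state {self.enzyme_state!r}")
        if self.atp_state not in ("plus", "minus"):
            raise PSMError(f"unknown atp_state {self.atp_state!r}")

    @property
    def is_negative_control(self) -> bool:
        """True for any sample that cannot produce genuine kinase signal."""
        return self.enzyme_state == "dead" or self.atp_state == "minus"


@dataclass(frozen=True)
class FilterCriteria:
    min_psm_count: int = 2
    min_xcorr: float = 2.04  # strict lower bound
    min_site_probability: float = DEFAULT_SITE_PROBABILITY

    def __post_init__(self) -> None:
        if self.min_psm_count < 0 or self.min_xcorr < 0 or self.min_site_probability < 0:
            raise PSMError("criteria must be non-negative")


def _parse_sites(cell) -> tuple[int, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    text = str(cell).strip()
    if not text or text in (".", "-"):
        return ()
    return tuple(int(tok) for tok in text.replace(",", ";").split(";") if tok.strip())


def read_psm_table(path: str | Path) -> list[PSMRecord]:
    """Read a tab-separated PSM table into validated records.

    Malformed rows are collected and reported together with their
    1-based data line numbers; a missing column is a schema error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise PSMError(f"{path}: missing column(s) {missing}")
    records: list[PSMRecord] = []
    errors: list[str] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        try:
            prob = row.site_probability.strip()
            records.append(
                PSMRecord(
                    sample_id=row.sample_id,
                    enzyme_state=row.enzyme_state,
                    atp_state=row.atp_state,
                    library_id=int(row.library_id),
                    sequence=row.sequence,
                    is_phospho=str(row.is_phospho).strip().lower()
                    in ("1", "true", "yes"),
                    site_positions=_parse_sites(row.site_positions),
                    xcorr=float(row.xcorr),
                    site_probability=float(prob) if prob not in ("", ".") else None,
                )
            )
        except (PSMError, ValueError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise PSMError(f"{path}: {len(errors)} malformed row(s):\n  " + "\n  ".join(errors))
    return records


def write_psm_table(records: Iterable[PSMRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "enzyme_state": r.enzyme_state,
                "atp_state": r.atp_state,
                "library_id": r.library_id,
                "sequence": r.sequence,
                "is_phospho": str(r.is_phospho).lower(),
                "site_positions": ";".join(map(str, r.site_positions)),
                "xcorr": f"{r.xcorr:.4f}",
                "site_probability": ""
                if r.site_probability is None
                else f"{r.site_probability:.4f}",
            }
        )
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, sep="\t", index=False)


def derive_filter_thresholds(
    negative_controls: Sequence[PSMRecord],
    min_site_probability: float = DEFAULT_SITE_PROBABILITY,
) -> FilterCriteria:
    """Derive filtration thresholds from negative-control false positives.

    ``min_xcorr`` is the best Xcorr any negative phospho-PSM achieved (used
    as a strict bound, so that exact score is excluded); ``min_psm_count``
    is one more than the worst per-peptide phospho-PSM count seen in any
    single negative sample. Re-applying the result to the negatives passes
    zero phosphopeptides by construction.
    """
    if not negative_controls:
        raise PSMError("no negative-control records supplied")
    if any(not r.is_negative_control for r in negative_controls):
        raise PSMError(
            "derive_filter_thresholds accepts only negative-control records "
            "(dead enzyme or -ATP)"
        )
    phospho = [r for r in negative_controls if r.is_phospho]
    if not phospho:
        return FilterCriteria(1, 0.0, min_site_probability)
    max_xcorr = max(r.xcorr for r in phospho)
    per_sample_counts = Counter(
        (r.sample_id, r.library_id) for r in phospho
    )
    max_count = max(per_sample_counts.values())
    return FilterCriteria(max_count + 1, max_xcorr, min_site_probability)


def apply_filters(
    records: Sequence[PSMRecord],
    criteria: FilterCriteria,
) -> set[tuple[int, int]]:
    """Return the (library_id, site) phosphopeptides passing the criteria.

    Records should be restricted to one test condition. A PSM carrying
    several phosphosites contributes one observation to each listed site.
    """
    support: dict[tuple[int, int], list[PSMRecord]] = defaultdict(list)
    for r in records:
        if not r.is_phospho:
            continue
        for site in r.site_positions:
            support[(r.library_id, site)].append(r)
    passing: set[tuple[int, int]] = set()
    for key, psms in support.items():
        if len(psms) < criteria.min_psm_count:
            continue
        if not any(p.xcorr > criteria.min_xcorr for p in psms):
            continue
        best_prob = max(
            (p.site_probability for p in psms if p.site_probability is not None),
            default=0.0,
        )
        if best_prob < criteria.min_site_probability:
            continue
        passing.add(key)
    return passing


def phospho_detected_per_sample(
    records: Sequence[PSMRecord],
) -> dict[str, set[int]]:
    """Map each sample_id to the set of library_ids with any phospho-PSM."""
    detected: dict[str, set[int]] = defaultdict(set)
    for r in records:
        detected.setdefault(r.sample_id, set())
        if r.is_phospho:
            detected[r.sample_id].add(r.library_id)
    return dict(detected)


def flag_ubiquitous_outliers(
    all_samples: Mapping[str, set[int]],
) -> set[int]:
    """Peptides whose phosphorylated form appears in *every* sample.

    Such peptides (the study's "Peptide 154" pattern) are uninformative
    about the kinase and are excluded from all downstream analyses.
    Requires at least two samples so "every sample" is meaningful.
    """
    if len(all_samples) < 2:
        raise PSMError("outlier flagging needs >= 2 samples")
    sets = list(all_samples.values())
    ubiquitous = set(sets[0])
    for s in sets[1:]:
        ubiquitous &= s
    return ubiquitous
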