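"""Consensus-motif detection on center-aligned phosphopeptide windows.

Candidate windows are first redundancy-reduced by greedy identity
clustering (CD-HIT-style, 90% identity on the 20-mer), then scanned for
position-specific residue enrichment. Because every window is already
aligned on its phosphosite, motif discovery reduces to a one-sided
binomial test per (offset, residue) cell against background residue
frequencies: is residue ``a`` observed at offset ``d`` more often than a
background draw would allow? Cells with p < alpha define the motif; the
reported motif is confined to a short contiguous window of offsets (<= 5
by default) around the strongest enrichment, mirroring the short-motif
regime of classical motif discovery.

The phosphosite offset itself (0) is fixed at S/T/Y by construction and is
never tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .library_design import SITE_OFFSET, WINDOW_LENGTH
from .predictors import AMINO_ACIDS


class MotifError(ValueError):
    pass


@dataclass
class MotifResult:
    """Positional-enrichment motif around the phosphosite.

    ``positions`` are offsets relative to the phosphosite (-9..+10 for a
    20-mer with the site at position 10) that are significantly enriched
    and fall inside the selected contiguous motif window;
    ``enriched_residues`` maps each such offset to (residue, p, p_adjusted)
    for its most enriched residue. ``member_ids`` lists the input windows
    matching every consensus position (empty when no cell is significant).
    """

    positions: list[int]
    enriched_residues: dict[int, tuple[str, float, float]]
    consensus: str
    member_ids: list[int]
    pvalues: pd.DataFrame = field(repr=False, default=None)


def window_identity(a: str, b: str) -> float:
    """Fraction of identical positions between two equal-length windows."""
    if len(a) != len(b):
        raise MotifError("identity requires equal-length windows")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def cluster_redundant_peptides(
    windows: Sequence[str],
    identity_threshold: float = 0.90,
) -> tuple[list[str], dict[int, int]]:
    """Greedy identity clustering with representative selection.

    Windows are visited in input order; each joins the first existing
    representative it matches at >= ``identity_threshold`` identity
    (matches / window length), otherwise it founds a new cluster. Returns
    the representatives and a map from input index to representative index
    (a partition of the inputs).
    """
    representatives: list[str] = []
    assignment: dict[int, int] = {}
    for i, w in enumerate(windows):
        for r, rep in enumerate(representatives):
            if window_identity(w, rep) >= identity_threshold:
                assignment[i] = r
                break
        else:
            representatives.append(w)
            assignment[i] = len(representatives) - 1
    return representatives, assignment


def _offsets(window_length: int, site_offset: int) -> list[int]:
    return [p - site_offset for p in range(1, window_length + 1)]


def positional_pvalues(
    representatives: Sequence[str],
    background: Mapping[str, float] | Sequence[float],
    site_offset: int = SITE_OFFSET,
) -> pd.DataFrame:
    """One-sided binomial enrichment p-value for every (offset, residue).

    For n representatives with residue ``a`` observed k times at an
    offset, p = P(X >= k) with X ~ Binomial(n, background[a]). The
    phosphosite offset 0 is skipped. Returns a tidy frame with columns
    offset, residue, count, background, pvalue, pvalue_bonferroni.
    """
    n = len(representatives)
    if isinstance(background, Mapping):
        bg = np.array([background.get(a, 0.0) for a in AMINO_ACIDS], dtype=float)
    else:
        bg = np.asarray(background, dtype=float)
    if not math.isclose(float(bg.sum()), 1.0, abs_tol=1e-6):
        raise MotifError(f"background frequencies sum to {bg.sum():.8f}, not 1")
    length = len(representatives[0])
    if any(len(w) != length for w in representatives):
        raise MotifError("representatives must be equal-length")
    rows = []
    offsets = _offsets(length, site_offset)
    n_cells = sum(1 for d in offsets if d != 0) * len(AMINO_ACIDS)
    for pos, offset in enumerate(offsets):
        if offset == 0:
            continue
        column = [w[pos] for w in representatives]
        for ai, a in enumerate(AMINO_ACIDS):
            k = column.count(a)
            p = float(stats.binom.sf(k - 1, n, bg[ai])) if bg[ai] > 0 else (
                1.0 if k == 0 else 0.0
            )
            rows.append(
                {
                    "offset": offset,
                    "residue": a,
                    "count": k,
                    "background": bg[ai],
                    "pvalue": min(p, 1.0),
                    "pvalue_bonferroni": min(p * n_cells, 1.0),
                }
            )
    return pd.DataFrame(rows)


def find_positional_motif(
    representatives: Sequence[str],
    background: Mapping[str, float] | Sequence[float],
    alpha: float = 0.05,
    max_window: int = 5,
    site_offset: int = SITE_OFFSET,
    min_representatives: int = 5,
    min_support: float = 0.2,
) -> MotifResult:
    """Detect the consensus motif among center-aligned representatives.

    Cells significant at raw p < ``alpha`` AND matched by at least
    ``min_support`` of the representatives are candidates (the support
    floor mirrors the minimum-occurrence rule of greedy motif finders:
    for rare residues a handful of chance occurrences can reach raw
    significance without describing any shared motif). The motif is the
    contiguous run of at most ``max_window`` offsets maximizing the total
    -log10 p of its candidate cells (leftmost run on ties). The consensus
    shows the most enriched residue per significant offset, '.' elsewhere,
    and '*' at the phosphosite; members are the inputs matching all
    consensus residues.
    """
    if len(representatives) < min_representatives:
        raise MotifError(
            f"need >= {min_representatives} representatives, got "
            f"{len(representatives)}"
        )
    table = positional_pvalues(representatives, background, site_offset)
    support = max(1, math.ceil(min_support * len(representatives)))
    sig = table[(table["pvalue"] < alpha) & (table["count"] >= support)]
    length = len(representatives[0])
    offsets = _offsets(length, site_offset)

    if sig.empty:
        consensus = "".join("*" if d == 0 else "." for d in offsets)
        return MotifResult([], {}, consensus, [], table)

    # best residue (lowest p) per significant offset
    best = (
        sig.sort_values(["pvalue", "residue"]).groupby("offset").first().reset_index()
    )
    weight = {
        int(r.offset): -math.log10(max(r.pvalue, 1e-300)) for r in best.itertuples()
    }
    candidates = sorted(weight)
    best_span: tuple[float, int] | None = None
    for start in offsets:
        span = [d for d in candidates if start <= d < start + max_window]
        total = sum(weight[d] for d in span)
        if total > 0 and (best_span is None or total > best_span[0]):
            best_span = (total, start)
    start = best_span[1]
    chosen = [d for d in candidates if start <= d < start + max_window]

    enriched: dict[int, tuple[str, float, float]] = {}
    for row in best.itertuples():
        d = int(row.offset)
        if d in chosen:
            enriched[d] = (row.residue, float(row.pvalue), float(row.pvalue_bonferroni))

    consensus_chars = []
    for d in offsets:
        if d == 0:
            consensus_chars.append("*")
        elif d in enriched:
            consensus_chars.append(enriched[d][0])
        else:
            consensus_chars.append(".")
    consensus = "".join(consensus_chars)

    members = []
    for i, w in enumerate(representatives):
        ok = all(
            w[offsets.index(d)] == residue for d, (residue, _, _) in enriched.items()
        )
        if ok:
            members.append(i)
    return MotifResult(chosen, enriched, consensus, members, table)


def position_frequency_matrix(representatives: Sequence[str]) -> pd.DataFrame:
    """Plain-count PFM (rows: offsets, columns: residues) for export."""
    length = len(representatives[0])
    offsets = _offsets(length, SITE_OFFSET) if length == WINDOW_LENGTH else list(
        range(1, length + 1)
    )
    data = {a: [0] * length for a in AMINO_ACIDS}
    for w in representatives:
        for pos, c in enumerate(w):
            if c in data:
                data[c][pos] += 1
    pfm = pd.DataFrame(data)
    pfm.insert(0, "offset", offsets)
    return pfm
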