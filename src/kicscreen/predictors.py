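"""In-silico phosphosite candidate generators.

Two predictors are trained on the centered seed 20-mers and used to scan a
proteome for new candidate substrate windows:

* a linear profile hidden Markov model (match/insert/delete architecture,
  scored by the forward algorithm in bits against a background model), with
  significance reported as an E-value from a Gumbel null calibrated on
  shuffled decoy windows;
* a k-nearest-neighbour similarity scorer over BLOSUM62 window similarity,
  in the spirit of the KNN sequence-similarity feature at the core of
  published phosphosite predictors such as Musite. This is an explicit
  stand-in for a trained deep-learning predictor, which is not
  reproducible without its original training corpus; the conventional 0.8
  score cutoff is applied to the KNN positive fraction.

Every S/T/Y in the scanned proteome with full flanks yields exactly one
candidate window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from Bio.Align import substitution_matrices

from .library_design import (
    PHOSPHO_RESIDUES,
    SITE_OFFSET,
    WINDOW_LENGTH,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class PredictorError(ValueError):
    pass


def _encode(seq: str, alphabet: str) -> np.ndarray:
    idx = np.frompyfunc(alphabet.find, 1, 1)(np.array(list(seq))).astype(int)
    if (idx < 0).any():
        bad = sorted({c for c in seq if c not in alphabet})
        raise PredictorError(f"unknown residue symbol(s) {bad} for alphabet {alphabet!r}")
    return idx


# ---------------------------------------------------------------------------
# Profile HMM
# ---------------------------------------------------------------------------

@dataclass
class ProfileHMM:
    """Linear profile HMM over a fixed-length gapless training alignment.

    Node ``j`` (1-based, ``j = 0`` is the non-emitting begin state) carries a
    match state ``M_j`` with its own emission row, an insert state ``I_j``
    emitting from ``insert_emissions``, and a silent delete state ``D_j``.
    ``transitions[kind][j]`` holds P(kind) out of node ``j``; match states
    split over {mm, mi, md}, inserts over {im, ii}, deletes over {dm, dd}.
    The end state is reached from node ``length`` via the mm/im/dm entries.
    """

    length: int
    match_emissions: np.ndarray  # (length, |alphabet|), rows sum to 1
    insert_emissions: np.ndarray  # (|alphabet|,)
    transitions: dict[str, np.ndarray]  # keys mm, mi, md, im, ii, dm, dd
    background: np.ndarray  # (|alphabet|,)
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        a = len(self.alphabet)
        if self.match_emissions.shape != (self.length, a):
            raise PredictorError("match_emissions shape mismatch")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise PredictorError("match emission rows must sum to 1")
        if not math.isclose(float(self.insert_emissions.sum()), 1.0, abs_tol=1e-9):
            raise PredictorError("insert emissions must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise PredictorError("background must sum to 1")
        t = self.transitions
        if not np.allclose(t["mm"] + t["mi"] + t["md"], 1.0, atol=1e-9):
            raise PredictorError("match-state transitions must sum to 1")
        if not np.allclose(t["im"] + t["ii"], 1.0, atol=1e-9):
            raise PredictorError("insert-state transitions must sum to 1")
        if not np.allclose(t["dm"][1:] + t["dd"][1:], 1.0, atol=1e-9):
            raise PredictorError("delete-state transitions must sum to 1")


def train_profile_hmm(
    windows: Sequence[str],
    pseudocount: float = 1.0,
    alphabet: str = AMINO_ACIDS,
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from equal-length, already-aligned windows.

    Match emissions use Laplace smoothing,
    ``(count_j(a) + pseudocount) / (n + |alphabet| * pseudocount)``.
    A gapless alignment contributes only match->match transition counts, so
    with the same pseudocount the model is strongly match-dominated; insert
    and delete states remain reachable only through the pseudocount mass.
    """
    if not windows:
        raise PredictorError("training set is empty")
    length = len(windows[0])
    if any(len(w) != length for w in windows):
        raise PredictorError("training windows must all have the same length")
    if pseudocount < 0:
        raise PredictorError("pseudocount must be >= 0")
    a = len(alphabet)
    n = len(windows)
    counts = np.zeros((length, a))
    for w in windows:
        counts[np.arange(length), _encode(w, alphabet)] += 1
    match_emissions = (counts + pseudocount) / (n + a * pseudocount)
    if pseudocount == 0:
        # renormalize in case a column is a single observed residue
        match_emissions = counts / counts.sum(axis=1, keepdims=True)

    if background is None:
        background = np.full(a, 1.0 / a)
    background = np.asarray(background, dtype=float)
    insert_emissions = background.copy()

    npos = length + 1  # node index 0..length
    c = pseudocount
    if c > 0:
        mm = np.full(npos, (n + c) / (n + 3 * c))
        mi = np.full(npos, c / (n + 3 * c))
        md = np.full(npos, c / (n + 3 * c))
        im = np.full(npos, 0.5)
        ii = np.full(npos, 0.5)
        dm = np.full(npos, 0.5)
        dd = np.full(npos, 0.5)
    else:
        mm = np.ones(npos)
        mi = np.zeros(npos)
        md = np.zeros(npos)
        im = np.ones(npos)
        ii = np.zeros(npos)
        dm = np.ones(npos)
        dd = np.zeros(npos)
    # no deletes may extend past the last node
    dd[length] = 0.0
    dm[length] = 1.0
    transitions = {"mm": mm, "mi": mi, "md": md, "im": im, "ii": ii, "dm": dm, "dd": dd}
    return ProfileHMM(
        length=length,
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        transitions=transitions,
        background=background,
        alphabet=alphabet,
    )


def forward_probability(model: ProfileHMM, window: str) -> float:
    """Total probability of ``window`` under the model, summed over all
    state paths (forward algorithm, linear space)."""
    x = _encode(window, model.alphabet)
    n = len(x)
    L = model.length
    t = model.transitions
    e_m = model.match_emissions
    e_i = model.insert_emissions

    # fM[j, i]: paths ending in M_j after emitting i symbols (M_0 = begin)
    fM = np.zeros((L + 1, n + 1))
    fI = np.zeros((L + 1, n + 1))
    fD = np.zeros((L + 1, n + 1))
    fM[0, 0] = 1.0
    # silent delete chain at i = 0
    for j in range(1, L + 1):
        fD[j, 0] = fM[j - 1, 0] * t["md"][j - 1] + fD[j - 1, 0] * t["dd"][j - 1]
    for i in range(1, n + 1):
        sym = x[i - 1]
        for j in range(0, L + 1):
            if j >= 1:
                fM[j, i] = e_m[j - 1, sym] * (
                    fM[j - 1, i - 1] * t["mm"][j - 1]
                    + fI[j - 1, i - 1] * t["im"][j - 1]
                    + fD[j - 1, i - 1] * t["dm"][j - 1]
                )
            fI[j, i] = e_i[sym] * (
                fM[j, i - 1] * t["mi"][j] + fI[j, i - 1] * t["ii"][j]
            )
            if j >= 1:
                fD[j, i] = fM[j - 1, i] * t["md"][j - 1] + fD[j - 1, i] * t["dd"][j - 1]
    return float(
        fM[L, n] * t["mm"][L] + fI[L, n] * t["im"][L] + fD[L, n] * t["dm"][L]
    )


def forward_log_odds(model: ProfileHMM, window: str) -> float:
    """Forward score in bits: log2 P(window | model) / P(window | background)."""
    p_model = forward_probability(model, window)
    x = _encode(window, model.alphabet)
    p_null = float(np.prod(model.background[x]))
    if p_model <= 0.0:
        return -math.inf
    return math.log2(p_model / p_null)


# ---------------------------------------------------------------------------
# E-value calibration
# ---------------------------------------------------------------------------

@dataclass
class EvalueCalibration:
    """Gumbel null for forward log-odds scores.

    ``evalue(s)`` is the expected number of decoy windows in a search space
    of ``search_space_size`` windows scoring >= s: size * (1 - CDF(s)).
    """

    gumbel_location: float
    gumbel_scale: float
    decoy_count: int
    search_space_size: int

    def __post_init__(self) -> None:
        if self.gumbel_scale <= 0:
            raise PredictorError("Gumbel scale must be positive")

    def evalue(self, score: float) -> float:
        return self.search_space_size * float(
            stats.gumbel_r.sf(score, loc=self.gumbel_location, scale=self.gumbel_scale)
        )


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel (type-I extreme value) fit; returns
    (location, scale)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2 or np.ptp(scores) == 0:
        raise PredictorError("degenerate score sample: cannot fit a Gumbel")
    loc, scale = stats.gumbel_r.fit(scores)
    return float(loc), float(scale)


def calibrate_evalues(
    model: ProfileHMM,
    n_decoys: int = 10_000,
    random_seed: int = 0,
    search_space_size: int = 1,
    windows: Sequence[str] | None = None,
) -> EvalueCalibration:
    """Calibrate the E-value null by scoring decoy windows.

    Decoys are residue-shuffles of ``windows`` (sampled with replacement)
    when a window set is supplied, otherwise i.i.d. draws from the model
    background — either way they preserve composition but destroy
    positional signal. A Gumbel distribution is fit to the decoy forward
    log-odds scores by maximum likelihood.
    """
    if n_decoys < 100:
        raise PredictorError("need at least 100 decoys to calibrate")
    rng = np.random.default_rng(random_seed)
    a = len(model.alphabet)
    scores = np.empty(n_decoys)
    if windows:
        pool = [np.array(list(w)) for w in windows]
        picks = rng.integers(0, len(pool), size=n_decoys)
        for i, p in enumerate(picks):
            decoy = "".join(rng.permutation(pool[p]))
            scores[i] = forward_log_odds(model, decoy)
    else:
        draws = rng.choice(a, size=(n_decoys, model.length), p=model.background)
        alpha_arr = np.array(list(model.alphabet))
        for i in range(n_decoys):
            scores[i] = forward_log_odds(model, "".join(alpha_arr[draws[i]]))
    loc, scale = fit_gumbel(scores)
    return EvalueCalibration(
        gumbel_location=loc,
        gumbel_scale=scale,
        decoy_count=n_decoys,
        search_space_size=search_space_size,
    )


# ---------------------------------------------------------------------------
# KNN similarity scorer
# ---------------------------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_SUB62 = np.asarray(_BLOSUM62)[
    np.ix_(
        [_BLOSUM62.alphabet.index(c) for c in AMINO_ACIDS],
        [_BLOSUM62.alphabet.index(c) for c in AMINO_ACIDS],
    )
]


def default_k(n_references: int) -> int:
    return max(1, min(15, int(math.isqrt(n_references)) * 3))


@dataclass
class KNNScorer:
    """Positive-fraction-of-k-nearest-windows phosphosite score.

    Window similarity is the sum of position-wise BLOSUM62 scores between
    the query and a reference 20-mer. The score is the fraction of the k
    most similar reference windows that are known phosphosite windows, so
    it lies in [0, 1]. Ties in similarity are broken deterministically by
    window string, positives before negatives.
    """

    positive_windows: Sequence[str]
    negative_windows: Sequence[str]
    k: int | None = None
    _refs: list[tuple[str, bool]] = field(init=False, repr=False)
    _ref_idx: np.ndarray = field(init=False, repr=False)
    _ref_pos: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        refs = [(w, True) for w in self.positive_windows] + [
            (w, False) for w in self.negative_windows
        ]
        if not refs:
            raise PredictorError("KNN scorer needs at least one reference window")
        # deterministic internal order regardless of input order
        refs.sort(key=lambda r: (r[0], not r[1]))
        self._refs = refs
        if self.k is None:
            self.k = default_k(len(refs))
        if self.k > len(refs):
            raise PredictorError(
                f"k={self.k} exceeds the {len(refs)} reference windows"
            )
        self._ref_idx = np.array(
            [_encode(w, AMINO_ACIDS) for w, _ in refs], dtype=int
        )
        self._ref_pos = np.array([pos for _, pos in refs], dtype=bool)

    def similarities(self, window: str) -> np.ndarray:
        q = _encode(window, AMINO_ACIDS)
        return _SUB62[q[None, :], self._ref_idx].sum(axis=1)

    def score(self, window: str) -> float:
        sims = self.similarities(window)
        # stable deterministic order: similarity desc, then internal rank
        nearest = np.argsort(-sims, kind="stable")[: self.k]
        return float(self._ref_pos[nearest].mean())


def knn_score(scorer: KNNScorer, window: str) -> float:
    """Functional wrapper over :meth:`KNNScorer.score`."""
    return scorer.score(window)


# ---------------------------------------------------------------------------
# Proteome scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanHit:
    protein_accession: str
    site_position: int  # 1-based in the protein
    window: str
    score: float
    evalue: float | None
    predictor: str  # "hmm" | "ml"


def iter_candidate_sites(
    sequence: str,
    site_offset: int = SITE_OFFSET,
    window_length: int = WINDOW_LENGTH,
) -> Iterable[tuple[int, str]]:
    """Yield (1-based site position, window) for every S/T/Y with full
    flanks in a protein sequence."""
    upstream = site_offset - 1
    downstream = window_length - site_offset
    for pos0, residue in enumerate(sequence):
        if residue not in PHOSPHO_RESIDUES:
            continue
        if pos0 < upstream or len(sequence) - pos0 - 1 < downstream:
            continue
        yield pos0 + 1, sequence[pos0 - upstream : pos0 + downstream + 1]


def scan_proteome(
    proteome: Iterable[tuple[str, str]],
    model: ProfileHMM | KNNScorer,
    threshold: float | None = None,
    calibration: EvalueCalibration | None = None,
    site_offset: int = SITE_OFFSET,
) -> list[ScanHit]:
    """Score every full-flank S/T/Y window in the proteome and keep hits.

    With a :class:`ProfileHMM`, ``threshold`` is an E-value ceiling
    (default 0.001) and ``calibration`` is required; with a
    :class:`KNNScorer`, ``threshold`` is a score floor (default 0.8).
    Output is sorted by significance, then accession and position.
    """
    is_hmm = isinstance(model, ProfileHMM)
    if is_hmm and calibration is None:
        raise PredictorError("HMM scanning requires an E-value calibration")
    if threshold is None:
        threshold = 0.001 if is_hmm else 0.8
    hits: list[ScanHit] = []
    for accession, sequence in proteome:
        for position, window in iter_candidate_sites(sequence, site_offset):
            if is_hmm:
                s = forward_log_odds(model, window)
                e = calibration.evalue(s)
                if e < threshold:
                    hits.append(ScanHit(accession, position, window, s, e, "hmm"))
            else:
                s = model.score(window)
                if s > threshold:
                    hits.append(ScanHit(accession, position, window, s, None, "ml"))
    if is_hmm:
        hits.sort(key=lambda h: (h.evalue, h.protein_accession, h.site_position))
    else:
        hits.sort(key=lambda h: (-h.score, h.protein_accession, h.site_position))
    return hits
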