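"""Profile-HMM training and scoring, E-value calibration, KNN scoring and
proteome scanning, each checked against an independent oracle."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kicscreen.library_design import SITE_OFFSET
from kicscreen.predictors import (
    AMINO_ACIDS,
    EvalueCalibration,
    KNNScorer,
    PredictorError,
    ProfileHMM,
    calibrate_evalues,
    default_k,
    fit_gumbel,
    forward_log_odds,
    forward_probability,
    iter_candidate_sites,
    knn_score,
    scan_proteome,
    train_profile_hmm,
)
from kicscreen.predictors import _SUB62, _encode


def enumerate_paths_probability(model: ProfileHMM, window: str) -> float:
    """Independent oracle: sum P(path, window) over every state path by
    explicit recursion (exponential; only for tiny models)."""
    t = model.transitions
    L = model.length
    x = [model.alphabet.index(c) for c in window]
    total = 0.0

    def step(kind, node, i, p):
        nonlocal total
        if p == 0.0:
            return
        if kind == "M":
            outs = [("M", node + 1, t["mm"][node]), ("I", node, t["mi"][node]),
                    ("D", node + 1, t["md"][node])]
        elif kind == "I":
            outs = [("M", node + 1, t["im"][node]), ("I", node, t["ii"][node])]
        else:
            outs = [("M", node + 1, t["dm"][node]), ("D", node + 1, t["dd"][node])]
        for nk, nn, tp in outs:
            if tp == 0.0:
                continue
            if nk == "M" and nn == L + 1:  # end state
                if i == len(x):
                    total += p * tp
                continue
            if nn > L:
                continue
            if nk == "M":
                if i < len(x):
                    step("M", nn, i + 1, p * tp * model.match_emissions[nn - 1, x[i]])
            elif nk == "I":
                if i < len(x):
                    step("I", nn, i + 1, p * tp * model.insert_emissions[x[i]])
            else:
                step("D", nn, i, p * tp)

    step("M", 0, 0, 1.0)
    return total


def random_toy_model(rng, L):
    me = rng.dirichlet([1, 1], size=L)
    m3 = rng.dirichlet([1, 1, 1], size=L + 1)
    i2 = rng.dirichlet([1, 1], size=L + 1)
    d2 = rng.dirichlet([1, 1], size=L + 1)
    tr = {"mm": m3[:, 0], "mi": m3[:, 1], "md": m3[:, 2],
          "im": i2[:, 0], "ii": i2[:, 1], "dm": d2[:, 0], "dd": d2[:, 1]}
    tr["dd"][L] = 0.0
    tr["dm"][L] = 1.0
    return ProfileHMM(L, me, rng.dirichlet([1, 1]), tr, rng.dirichlet([1, 1]), "AB")


class TestTraining:
    def test_single_window_zero_pseudocount_is_deterministic(self):
        m = train_profile_hmm(["ACD"], pseudocount=0.0)
        for j, res in enumerate("ACD"):
            assert m.match_emissions[j, AMINO_ACIDS.index(res)] == 1.0

    def test_laplace_count_formula(self):
        # two windows, pseudocount 1, both A at a position -> (2+1)/(2+20)
        m = train_profile_hmm(["AC", "AD"], pseudocount=1.0)
        assert m.match_emissions[0, AMINO_ACIDS.index("A")] == pytest.approx(3 / 22)
        assert m.match_emissions[1, AMINO_ACIDS.index("C")] == pytest.approx(2 / 22)

    def test_uniform_training_set_gives_near_uniform_emissions(self, rng):
        windows = ["".join(rng.choice(list(AMINO_ACIDS), 20)) for _ in range(1000)]
        m = train_profile_hmm(windows)
        assert np.all(np.abs(m.match_emissions - 0.05) < 0.05)

    def test_transitions_match_dominated_for_gapless_alignment(self, rng):
        windows = ["".join(rng.choice(list(AMINO_ACIDS), 20)) for _ in range(315)]
        m = train_profile_hmm(windows)
        assert np.all(m.transitions["mm"] > 0.99)

    def test_empty_and_ragged_inputs_rejected(self):
        with pytest.raises(PredictorError):
            train_profile_hmm([])
        with pytest.raises(PredictorError):
            train_profile_hmm(["AA", "AAA"])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_normalization_invariants_hold_for_random_training_sets(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        length = int(rng.integers(1, 25))
        windows = ["".join(rng.choice(list(AMINO_ACIDS), length)) for _ in range(n)]
        pc = float(rng.uniform(0, 3))
        m = train_profile_hmm(windows, pseudocount=pc)
        assert np.allclose(m.match_emissions.sum(axis=1), 1.0, atol=1e-9)
        t = m.transitions
        assert np.allclose(t["mm"] + t["mi"] + t["md"], 1.0, atol=1e-9)
        assert np.allclose(t["im"] + t["ii"], 1.0, atol=1e-9)
        assert np.allclose(t["dm"][1:] + t["dd"][1:], 1.0, atol=1e-9)


class TestForward:
    def test_forward_equals_path_enumeration_on_toy_models(self, rng):
        for _ in range(15):
            L = int(rng.integers(1, 4))
            model = random_toy_model(rng, L)
            for n in range(1, 5):
                for w in itertools.product("AB", repeat=n):
                    w = "".join(w)
                    assert forward_probability(model, w) == pytest.approx(
                        enumerate_paths_probability(model, w), abs=1e-9
                    )

    def test_background_model_scores_zero_bits(self):
        L = 20
        bg = np.full(20, 0.05)
        tr = {"mm": np.ones(L + 1), "mi": np.zeros(L + 1), "md": np.zeros(L + 1),
              "im": np.ones(L + 1), "ii": np.zeros(L + 1),
              "dm": np.ones(L + 1), "dd": np.zeros(L + 1)}
        m = ProfileHMM(L, np.tile(bg, (L, 1)), bg.copy(), tr, bg.copy())
        assert forward_log_odds(m, AMINO_ACIDS) == pytest.approx(0.0, abs=1e-12)

    def test_training_window_is_maximum_likelihood_on_own_model(self, rng):
        w = "".join(rng.choice(list(AMINO_ACIDS), 20))
        m = train_profile_hmm([w], pseudocount=0.0)
        own = forward_log_odds(m, w)
        for _ in range(20):
            other = "".join(rng.choice(list(AMINO_ACIDS), 20))
            assert forward_log_odds(m, other) <= own

    def test_unknown_residue_rejected(self):
        m = train_profile_hmm(["ACD"])
        with pytest.raises(PredictorError, match="unknown residue"):
            forward_log_odds(m, "AXZ")


class TestEvalueCalibration:
    def test_evalue_monotone_non_increasing_in_score(self):
        cal = EvalueCalibration(0.0, 1.0, 1000, 10_000)
        scores = np.linspace(-5, 15, 200)
        evals = [cal.evalue(s) for s in scores]
        assert all(a >= b for a, b in zip(evals, evals[1:]))

    def test_gumbel_parameter_recovery(self, rng):
        draws = rng.gumbel(0.0, 1.0, size=10_000)
        loc, scale = fit_gumbel(draws)
        assert abs(loc) < 0.1
        assert abs(scale - 1.0) < 0.1

    def test_evalue_at_decoy_median_is_half_search_space(self, default_screen, rng):
        windows = [e.window for e in default_screen.library[:100]]
        m = train_profile_hmm(windows)
        cal = calibrate_evalues(
            m, n_decoys=2000, random_seed=5, search_space_size=10_000,
            windows=windows,
        )
        decoy_rng = np.random.default_rng(5)
        pool = [np.array(list(w)) for w in windows]
        picks = decoy_rng.integers(0, len(pool), size=2000)
        scores = [
            forward_log_odds(m, "".join(decoy_rng.permutation(pool[p])))
            for p in picks
        ]
        med = float(np.median(scores))
        assert cal.evalue(med) == pytest.approx(5000, rel=0.10)

    def test_degenerate_decoy_scores_rejected(self):
        with pytest.raises(PredictorError, match="degenerate"):
            fit_gumbel(np.ones(500))

    def test_too_few_decoys_rejected(self, default_screen):
        m = train_profile_hmm([default_screen.library[0].window])
        with pytest.raises(PredictorError):
            calibrate_evalues(m, n_decoys=50, random_seed=0)


class TestKNN:
    def test_query_identical_to_positive(self):
        s = KNNScorer(["A" * 20], ["W" * 20], k=1)
        assert s.score("A" * 20) == 1.0

    def test_query_identical_to_negative(self):
        s = KNNScorer(["A" * 20], ["W" * 20], k=1)
        assert s.score("W" * 20) == 0.0

    def test_matches_exhaustive_nearest_neighbour_oracle(self, rng):
        refs = ["".join(rng.choice(list(AMINO_ACIDS), 20)) for _ in range(10)]
        positives, negatives = refs[:5], refs[5:]
        scorer = KNNScorer(positives, negatives, k=5)
        for _ in range(20):
            q = "".join(rng.choice(list(AMINO_ACIDS), 20))
            qi = _encode(q, AMINO_ACIDS)
            sims = []
            for r in refs:
                ri = _encode(r, AMINO_ACIDS)
                sims.append((sum(_SUB62[a, b] for a, b in zip(qi, ri)), r))
            ordered = sorted(
                sims, key=lambda t: (-t[0], t[1], t[1] not in positives)
            )[:5]
            expected = sum(r in positives for _, r in ordered) / 5
            assert scorer.score(q) == pytest.approx(expected)

    def test_invariant_to_reference_order(self, rng):
        refs = ["".join(rng.choice(list(AMINO_ACIDS), 20)) for _ in range(12)]
        a = KNNScorer(refs[:6], refs[6:], k=5)
        b = KNNScorer(refs[:6][::-1], refs[6:][::-1], k=5)
        for _ in range(10):
            q = "".join(rng.choice(list(AMINO_ACIDS), 20))
            assert a.score(q) == b.score(q)

    def test_k_exceeding_reference_count_rejected(self):
        with pytest.raises(PredictorError):
            KNNScorer(["A" * 20], [], k=5)

    def test_default_k_rule(self):
        assert default_k(4) == 6
        assert default_k(100) == 15
        assert default_k(1) == 3


class TestScan:
    def test_no_sty_means_no_hits(self, default_screen):
        windows = [e.window for e in default_screen.library[:50]]
        m = train_profile_hmm(windows)
        cal = calibrate_evalues(m, n_decoys=200, random_seed=0,
                                search_space_size=100, windows=windows)
        hits = scan_proteome([("p1", "ACDEFGHIKLMNPQRVWACDEFGHIKLMNPQRVW")], m,
                             calibration=cal)
        assert hits == []

    def test_flank_rule_excludes_terminal_sites(self):
        seq = "AAAASAAAAAAAAAAAAAAAAAAAS"  # S at 5 (short upstream), S at 25
        sites = list(iter_candidate_sites(seq))
        positions = [p for p, _ in sites]
        assert 5 not in positions
        assert len(seq) - 25 < 10  # downstream flank short too
        assert 25 not in positions

    def test_planted_signal_recovery(self, rng):
        # proteome of background noise plus 10 planted copies of a strong
        # motif window; the trained model must find exactly the planted sites
        train = ["AAAAAAADWSPAAAAAAAAA" for _ in range(30)]  # S at offset 10
        m = train_profile_hmm(train, pseudocount=0.1)
        proteome = []
        planted = []
        letters = [c for c in AMINO_ACIDS if c not in "STY"]
        for i in range(10):
            backbone = list("".join(rng.choice(letters, 60)))
            backbone[20:40] = list(train[0])
            proteome.append((f"p{i}", "".join(backbone)))
            planted.append((f"p{i}", 30))  # site lands at protein position 30
        n_windows = sum(
            1 for _, seq in proteome for _ in iter_candidate_sites(seq)
        )
        cal = calibrate_evalues(m, n_decoys=1000, random_seed=3,
                                search_space_size=n_windows, windows=train)
        hits = scan_proteome(proteome, m, threshold=0.001, calibration=cal)
        assert {(h.protein_accession, h.site_position) for h in hits} == set(planted)

    def test_training_windows_beat_their_shuffles(self, default_screen, rng):
        windows = [e.window for e in default_screen.library[:60]]
        m = train_profile_hmm(windows)
        cal = calibrate_evalues(m, n_decoys=500, random_seed=1,
                                search_space_size=1000, windows=windows)
        real = np.median([cal.evalue(forward_log_odds(m, w)) for w in windows])
        shuf = np.median([
            cal.evalue(forward_log_odds(m, "".join(rng.permutation(list(w)))))
            for w in windows
        ])
        assert real < shuf

    def test_empty_proteome(self, default_screen):
        windows = [e.window for e in default_screen.library[:20]]
        m = train_profile_hmm(windows)
        cal = calibrate_evalues(m, n_decoys=200, random_seed=0,
                                search_space_size=10, windows=windows)
        assert scan_proteome([], m, calibration=cal) == []
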