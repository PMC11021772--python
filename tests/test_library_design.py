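"""Library construction: window extraction, flank filtering, similarity
dedup, assembly bookkeeping and pooling arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kicscreen.library_design import (
    LibraryDesignError,
    PeptideEntry,
    PoolSpec,
    SeedPhosphopeptide,
    SITE_OFFSET,
    WINDOW_LENGTH,
    assemble_library,
    dedup_order,
    deduplicate,
    extract_window,
    filter_site_distance,
    merge_seed_pools,
    pairwise_similarity,
    pool_per_peptide_concentration,
    sample_controls,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_window(rng, center="S"):
    chars = rng.choice(list(AA), size=WINDOW_LENGTH)
    chars[SITE_OFFSET - 1] = center
    return "".join(chars)


class TestExtractWindow:
    def test_whole_protein_is_its_own_window(self):
        protein = "AAAAAAAAASAAAAAAAAAA"  # 20-mer, S at position 10
        assert extract_window(protein, 10) == protein

    def test_interior_site_index_arithmetic(self):
        # 40-aa protein, site at 20 -> residues 11..30 with site at offset 10
        protein = "".join(AA[i % 20] for i in range(40))
        protein = protein[:19] + "S" + protein[20:]
        window = extract_window(protein, 20)
        assert window == protein[10:30]
        assert window[SITE_OFFSET - 1] == "S"

    def test_insufficient_upstream_flank_rejected(self):
        protein = "AAAASAAAAAAAAAAAAAAAAAAAAAAAAA"  # site at 5: only 4 upstream
        with pytest.raises(LibraryDesignError, match="upstream"):
            extract_window(protein, 5)

    def test_non_sty_site_rejected(self):
        with pytest.raises(LibraryDesignError, match="S, T or Y"):
            extract_window("A" * 40, 20)

    def test_out_of_range_site_rejected(self):
        with pytest.raises(LibraryDesignError, match="out of bounds"):
            extract_window("A" * 10, 11)

    def test_window_round_trips_into_source_protein(self, rng):
        protein = "".join(rng.choice(list(AA), size=200))
        for pos0, res in enumerate(protein):
            pos = pos0 + 1
            if res in "STY" and 10 <= pos <= len(protein) - 10:
                window = extract_window(protein, pos)
                start = pos - SITE_OFFSET
                assert protein[start : start + WINDOW_LENGTH] == window


class TestFlankFilter:
    @pytest.mark.parametrize(
        "length,site,expected",
        [
            (12, 6, True),  # 5 before, 6 after
            (10, 3, False),  # 2 before
            (11, 6, True),  # exactly 5 on each side
            (11, 5, False),  # 4 before
            (11, 7, False),  # 4 after
        ],
    )
    def test_min_flank_rule(self, length, site, expected):
        pep = "A" * (site - 1) + "S" + "A" * (length - site)
        seed = SeedPhosphopeptide("P1", pep, site, "S", "P2K1")
        assert filter_site_distance(seed) is expected

    def test_site_residue_invariant_enforced(self):
        with pytest.raises(LibraryDesignError):
            SeedPhosphopeptide("P1", "AAASAA", 2, "S", "P2K1")
        with pytest.raises(LibraryDesignError):
            SeedPhosphopeptide("P1", "AAASAA", 7, "S", "P2K1")


class TestPairwiseSimilarity:
    def test_identity_is_one(self):
        assert pairwise_similarity("PEPTIDE", "PEPTIDE") == 1.0

    def test_mismatch_fraction_without_indels(self):
        # 8 substitutions to rare letters that cannot re-align elsewhere
        a = "AAAAAAAAAAAAAAAAAAAA"
        b = "WCWCWCWCAAAAAAAAAAAA"
        assert sum(x != y for x, y in zip(a, b)) == 8
        assert pairwise_similarity(a, b) == pytest.approx(0.60)

    def test_disjoint_alphabets_are_zero(self):
        assert pairwise_similarity("AAAAA", "GGGGG") == 0.0

    def test_symmetric(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list(AA), size=int(rng.integers(5, 25))))
            b = "".join(rng.choice(list(AA), size=int(rng.integers(5, 25))))
            assert pairwise_similarity(a, b) == pytest.approx(
                pairwise_similarity(b, a)
            )

    def test_empty_input_rejected(self):
        with pytest.raises(LibraryDesignError):
            pairwise_similarity("", "AAA")


class TestDeduplicate:
    def test_identical_peptides_collapse(self):
        assert deduplicate(["PEPTIDE", "PEPTIDE"]) == ["PEPTIDE"]

    def test_exact_threshold_retains_both(self):
        a = "AAAAAAAAAAAAAAAAAAAA"
        c = "AAAAAAAAAAAACDEFGHIK"  # 12/20 matches = 0.60 exactly
        assert pairwise_similarity(a, c) == pytest.approx(0.60)
        assert deduplicate([a, c], threshold=0.6) == [a, c]

    def test_greedy_trace(self):
        # A~B 0.8 (B dropped), A~C and B~C low -> {A, C}
        a = "AAAAAAAAAAAAAAAAAAAA"
        b = "AAAAAAAAAAAAAAAAWCWC"  # 16/20 = 0.8 vs a
        c = "WCWCWCWCWCWCWCWCWCWC"
        assert pairwise_similarity(a, b) == pytest.approx(0.8)
        assert deduplicate([a, b, c]) == [a, c]

    def test_output_pairwise_similarity_bounded_brute_force(self, rng):
        peptides = [
            "".join(rng.choice(list("AG"), size=10)) for _ in range(30)
        ]
        kept = deduplicate(peptides, threshold=0.6)
        # brute-force all-pairs oracle
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert pairwise_similarity(a, b) <= 0.6
        # every dropped peptide is similar to something retained
        for p in peptides:
            if p not in kept:
                assert any(pairwise_similarity(p, q) > 0.6 for q in kept)

    def test_dedup_order_experimental_first(self):
        order = dedup_order(["CCC", "BBB", "AAA"], experimental=["CCC"])
        assert order == ["CCC", "AAA", "BBB"]


class TestAssembleLibrary:
    def test_study_sized_assembly(self, rng):
        windows = {random_window(rng) for _ in range(400)}
        windows = sorted(windows)[:225]
        hmm = [("H", w) for w in windows[:81]]
        ml = [("M", w) for w in windows[81:168]]
        ctl = [("C", w) for w in windows[168:225]]
        library = assemble_library(hmm, ml, ctl)
        assert len(library) == 225
        assert [e.library_id for e in library] == list(range(1, 226))
        by_source = {s: sum(e.source == s for e in library) for s in
                     ("hmm", "ml", "experimental_control")}
        assert by_source == {"hmm": 81, "ml": 87, "experimental_control": 57}

    def test_empty_inputs_empty_library(self):
        assert assemble_library([], [], []) == []

    def test_cross_source_duplicate_kept_once_with_priority(self, rng):
        w = random_window(rng)
        other = random_window(rng)
        library = assemble_library([("H", w)], [("M", w), ("M", other)], [])
        assert len(library) == 2
        assert library[0].source == "hmm" and library[0].window == w

    def test_malformed_window_reported(self):
        with pytest.raises(LibraryDesignError, match="invalid windows"):
            assemble_library([("H", "TOOSHORT")], [], [])

    def test_every_entry_satisfies_window_invariants(self, default_screen):
        for e in default_screen.library:
            assert len(e.window) == WINDOW_LENGTH
            assert e.window[e.site_offset - 1] in "STY"


class TestSampleControls:
    def test_full_population(self):
        pop = list("ABCDEFGHIJ")
        assert sorted(sample_controls(pop, n=10, random_seed=1)) == pop

    def test_deterministic_for_fixed_seed(self):
        pop = list(range(100))
        assert sample_controls(pop, 57, random_seed=7) == sample_controls(
            pop, 57, random_seed=7
        )

    def test_oversampling_rejected(self):
        with pytest.raises(LibraryDesignError):
            sample_controls([1, 2, 3], n=4, random_seed=0)

    def test_inclusion_frequency_uniform(self):
        pop = list(range(10))
        counts = np.zeros(10)
        for seed in range(1000):
            for x in sample_controls(pop, 5, random_seed=seed):
                counts[x] += 1
        freqs = counts / 1000
        assert np.all(np.abs(freqs - 0.5) < 0.05)


class TestPooling:
    def test_study_pool_concentration(self):
        # 5 mM stock pooled 225-way -> 22.2 uM per peptide
        conc_mM = pool_per_peptide_concentration(PoolSpec(225, 5.0))
        assert conc_mM * 1000 == pytest.approx(22.2, abs=0.05)

    def test_single_peptide_is_stock(self):
        assert pool_per_peptide_concentration(PoolSpec(1, 3.3)) == 3.3

    def test_dilution_arithmetic(self):
        assert pool_per_peptide_concentration(PoolSpec(100, 5.0)) == pytest.approx(0.05)

    @given(st.floats(0.1, 100), st.integers(1, 1000))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, stock, n):
        one = pool_per_peptide_concentration(PoolSpec(n, stock))
        two = pool_per_peptide_concentration(PoolSpec(n, 2 * stock))
        assert two == pytest.approx(2 * one)

    def test_zero_peptides_rejected(self):
        with pytest.raises(LibraryDesignError):
            PoolSpec(0, 5.0)


def test_merge_seed_pools_preserves_order_and_origin():
    p1 = [SeedPhosphopeptide("A", "AAAAASAAAAA", 6, "S", "P2K1")]
    p2 = [SeedPhosphopeptide("B", "AAAAATAAAAA", 6, "T", "P2K2")]
    merged = merge_seed_pools(p1, p2)
    assert [s.origin_screen for s in merged] == ["P2K1", "P2K2"]
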