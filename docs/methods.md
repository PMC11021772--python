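# Methods

`kicscreen` implements a kinase–client (KiC) screening workflow: design a
centered synthetic phosphopeptide library, predict additional candidate
substrate windows in silico, and call, quantify and prioritize substrates
from peptide-spectrum-match (PSM) tables of a 2×2 screen (wildtype /
catalytically dead kinase × ±ATP). This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Library design

Library members are 20-mer windows cut from parent proteins with the
phosphorylatable S/T/Y fixed at window position 10 (1-based), i.e. 9
upstream and 10 downstream residues. A 20-mer has no exact center; we fix
position 10 and expose it as a parameter. Sites without full flanks are
rejected, never padded: padding characters would corrupt every downstream
model trained on the windows.

Seed phosphopeptides are pre-filtered to sites at least 5 residues from
either peptide end. Redundancy is removed greedily at a similarity
threshold of 0.6 (strictly greater is dropped). Similarity is the
identical-match fraction of an optimal global alignment (match +1,
mismatch 0, gap −1 per column) normalized by the longer sequence — chosen
because it is reproducible without a substitution matrix and coincides
with simple mismatch counting when no indels help. The greedy pass visits
peptides in a deterministic order, experimentally observed windows first
and lexicographic within blocks, so experimental representatives are
retained in preference to predicted ones.

The final library concatenates profile-HMM hits, KNN hits and randomly
sampled positive controls, in that priority order for windows occurring
in more than one source. Equal-volume pooling of equal-concentration
stocks gives each peptide stock/n — e.g. 5 mM stocks pooled 225-way give
22.2 µM per peptide.

## In-silico predictors

**Profile HMM.** A linear match/insert/delete profile over the centered
windows, trained with Laplace smoothing
((count + c)/(n + 20c), default pseudocount c = 1) on a gapless
alignment, so transitions are match-dominated with insert/delete
reachable only through pseudocount mass. Windows are scored by the
forward algorithm in linear space (probabilities of 20-mers stay far from
underflow) as log₂ odds against a background composition, by default
uniform and configurable to the scanned proteome's composition.
Correctness is pinned by exhaustive path enumeration on toy models.

**E-values.** The upstream homology tool calibrates E-values internally;
here significance is calibrated explicitly: decoy windows (residue
shuffles of the training windows, or i.i.d. background draws when no
windows are supplied) are scored, a Gumbel (type-I extreme value)
distribution is fit by maximum likelihood, and
E(s) = search-space size × (1 − CDF(s)). Shuffling preserves composition
while destroying positional signal, which is the null the scan must
reject. Constant decoy scores abort calibration.

**KNN similarity scorer.** The deep-learning phosphosite predictor used
alongside the HMM in the original workflow cannot be retrained without
its corpus; in its place stands the KNN sequence-similarity score that is
the core published feature of such predictors. Query-to-reference
similarity is the sum of position-wise BLOSUM62 scores over the 20-mer;
the score is the fraction of the k nearest references that are known
sites, with negatives drawn as non-seed S/T/Y windows from the same
proteome. k defaults to min(15, 3·⌊√n⌋). Ties are broken by window
string with positives first, making the score independent of reference
order. The conventional 0.8 cutoff is applied to this fraction. This is
a stand-in, deliberately simple and fully reproducible.

A practical note from the synthetic runs: a profile averaged over a
diffuse seed pool that shares only a short (3-residue) motif does not
reach E < 0.001 against a calibrated Gumbel null — the exponential tail
demands tens of bits of separation, which only family-level conservation
provides. The calibration therefore correctly returns zero homology
calls on such a pool, while the KNN scorer, which rewards local
similarity, still generalizes. This division of labor is expected, not a
defect.

## PSM filtering

Samples with a dead kinase or without ATP cannot contain genuine signal;
their phosphopeptide identifications are false positives by construction
and define the filtration thresholds: the Xcorr bound is the best Xcorr
any negative phospho-PSM achieved (applied strictly, so that exact value
is excluded), and the PSM-count floor is one more than the worst
per-peptide count in any single negative sample. Re-applied to the
negatives, the criteria pass zero phosphopeptides by construction. Site
localization has no printed cutoff in the upstream tooling, so a
conventional 0.75 probability floor is the configurable default. A PSM
carrying several phosphosites contributes one observation to each site,
because multiply-phosphorylated peptides are reported per site
downstream.

Peptides whose phosphorylated form appears in *every* sample, negatives
included, carry no condition information and are flagged as ubiquitous
outliers. The pipeline flags them **before** deriving thresholds and
excludes them from the negative set: an outlier with respectable Xcorr in
the negatives would otherwise inflate the background bound and destroy
recall. When negative samples exist but recorded no PSMs at all, the
pipeline falls back to vacuous thresholds (count ≥ 1, Xcorr > 0).

## Quantification and prioritization

Stoichiometry per surviving (peptide, site) is
100 × phospho-PSM count / total PSM count of that peptide within the
test condition only (wildtype +ATP); the negatives define background,
not abundance, so they never enter the denominator. 100% therefore means
the unmodified peptide was never observed there.

Candidates are ranked lexicographically: stoichiometry, phospho-PSM
count, subcellular localization (plasma membrane > cytosol >
endoplasmic reticulum > nucleus > other — compartments plausibly shared
with a plasma-membrane receptor kinase first), consensus-motif
membership, then library id for a total order. The evidence is used
hierarchically rather than as a weighted sum because no principled
weights exist; database-known status is reported but kept out of the
sort key, since known and novel candidates are equally actionable.
Continuous stoichiometry values are reported; binning (100 / ≥50 / <50)
is available but off by default.

## Annotation

GO abundance is the share of annotation assignments per namespace among
candidates (so classes sum to 100% per namespace even for multi-term
proteins); classes at or below the 1% floor are dropped (strict).
Unannotated candidates are kept visible as an "unannotated" class.

Subcellular calls use weighted voting per protein: experimental evidence
counts five-fold over in-silico predictions; ties resolve by the
prioritization order above and are flagged.

Database cross-reference replaces a BLASTP search at 100% identity and
full coverage with exact substring matching — mathematically equivalent
at that operating point and dependency-free. A candidate is "confirmed"
in a database iff its full 20-mer occurs verbatim in a database protein
with a phosphosite recorded at the aligned position; "sequence-only" if
the window occurs without the site (reported separately rather than
merged into "known", since the two readings differ); otherwise "novel".
known_in_either + novel = total and known_in_both ≤ known_in_either are
asserted on every run.

## Motif analysis

Candidate windows are redundancy-reduced by greedy identity clustering
(matches/20 ≥ 0.90 joins the first matching representative), mirroring
CD-HIT's representative selection at desk scale. Because all windows are
already phosphosite-centered, motif discovery reduces to positional
enrichment: a one-sided exact binomial test per (offset, residue) cell
against background residue frequencies (default: the library's own
composition; configurable to the proteome's). The phosphosite offset
itself is fixed by construction and is never tested. Cells at raw
p < 0.05 are significant, as in the original tool's configuration;
Bonferroni-adjusted values are reported alongside. Consensus cells must
additionally be matched by ≥ 20% of representatives — the
minimum-occurrence rule of greedy motif finders — because for rare
residues two or three chance occurrences reach raw significance without
describing any shared motif, and a consensus containing such cells would
match no peptide. The reported motif is confined to the contiguous run
of ≤ 5 offsets maximizing summed −log₁₀ p (leftmost on ties), matching
the short-motif width limit; members are the windows matching every
consensus residue.

The exact binomial test is discrete: its attained size depends on the
number of representatives and is at most the nominal α. The null
simulation in the test suite uses 268 uniform representatives, for which
the attained size is 0.04998 — near-nominal, so the empirical false-
positive rate is comparable to α rather than to an unknown conservative
level.

## Synthetic screen generator

The generator emulates the study design at desk scale with known ground
truth. Defaults mirror the study's bookkeeping: a 225-peptide library
over an 80-protein toy proteome (i.i.d. residues at globular-protein
composition, lengths 120–400), 46 true substrates, seed pools of 177 and
228 peptides from two prior screens, and one ubiquitous-outlier peptide.

PSM simulation per sample: true substrates in wildtype +ATP receive
1 + Poisson(4) phospho-PSMs with Xcorr ~ Normal(3.0, 0.4) truncated at
0 and localization probability ~ U(0.9, 1), plus unmodified PSMs chosen
so the empirical phospho fraction targets the planted stoichiometry
(default 0.8). Every sample, negatives included, picks up spurious
single phospho-PSMs per peptide with probability 0.02 at
Xcorr ~ Normal(1.7, 0.25) and probability ~ U(0.3, 0.95) — exactly the
background the count ≥ 2 / Xcorr rules were designed to remove, so the
generator makes the criteria both necessary (noise present) and
sufficient (signal separable). Xcorr is modeled as a truncated normal
rather than a decoy-score model because only its ordering against the
thresholds matters downstream. The outlier peptide appears with two
mid-Xcorr phospho-PSMs in all four samples.

A planted motif (offset → residue map) can be written into the protein
sequences around chosen sites — 12 library sites by default when a motif
is given, mirroring the motif-member bookkeeping of the study — with
collision-safe placement so no edit overwrites another chosen
phosphosite. `motif_in_seed_fraction` optionally plants the same motif
at a share of seed-peptide sites, emulating prior screens of a kinase
whose specificity the seeds already reflect.

What the generator does **not** emulate: spectrum-level detail (m/z,
charge, retention time), search-engine score correlations, peptide
ionizability differences, and real phosphosite sequence context
(disorder, compositional bias). Passing tests therefore demonstrate the
correctness and calibration of the decision rules, not performance on
real LC-MS/MS data.

## Problem sizes and reproducibility

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; fixed seeds reproduce byte-identical output
files, and the pipeline manifest records config, counts and seeds with a
SHA-256 digest. The test and acceptance workloads use the default screen
scale (225 peptides, 80 proteins): 100 seeded screens for the
negative-control property, 20 for planted-substrate recovery, 60 null
draws for the motif type-I check — sizes chosen so the full suite runs
in well under a minute of simulation time while keeping Monte-Carlo
error small against the asserted margins.

## Known limitations

* The KNN scorer is a stand-in for a trained deep phosphosite predictor;
  its 0.8 cutoff inherits the convention, not a calibration.
* E-value calibration assumes Gumbel-distributed null scores; for very
  short or compositionally extreme models the fit degrades.
* The greedy dedup and clustering depend on visiting order; both orders
  are fixed and documented, but a different order can retain a different
  (equally valid) representative set.
* GO summaries are abundance percentages, not enrichment tests against a
  genome background.
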