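# Methods

## The compositional model

The detector assumes that prion-forming ability of Q/N-rich domains is
determined by amino-acid composition, not by residue order.  Under that
assumption a domain is modelled as an i.i.d. draw from a 20-dimensional
composition `f` (estimated from validated prion-domain sequences), scored
against a background composition `p` (the protein universe).  The
per-residue statistical potential is `LOr_i = log2(f_i / p_i)` in bits, and
a window's compositional score is the sum of its residues' potentials —
equivalently the log-likelihood ratio of the window under the two
compositions.  The expected score of a background window is `-L·KL(p||f)`
(negative), and of a domain-composition window `+L·KL(f||p)`, so the score
separates the two populations with a gap that grows linearly in window
length.

Position independence is an explicit simplification: shuffling a window's
residues leaves the compositional score unchanged.  The one sequential
feature retained is proline spacing (below).

### The shipped potential table

The package ships the published odds ratios for prion domains (N 5.700,
Q 4.125, S 1.662, Y 1.724 enriched; C 0.071, W 0.091, E 0.147 strongly
depleted) with `lor = log2(odds)` as the canonical potential.  The published
3-decimal LOr column is kept as reference metadata; for a handful of
residues it differs from `log2(odds)` by 0.001–0.009 bits because the odds
were rounded after the potentials were computed, and the table records the
maximum deviation and the affected residues.

The background `p` is a frozen Swiss-Prot release composition (2012-era
statistics, `data/background_swissprot.tsv`).  Because the published odds
are rounded and the background is pinned independently, `sum(odds_i * p_i)`
is 1.0028 rather than exactly 1 for the shipped table; such *reference*
tables back-derive `f = odds·p / Z` and record the normalization `Z`.
Tables trained from sequences satisfy the exact algebraic identities
(`odds = f/p`, `sum(odds·p) = 1` to 1e-9), which the constructor asserts.

A second shipped table (`library1`) carries the Sup35 random-mutagenesis
library propensities for side-by-side comparison; it is not wired into
scoring because its odds describe mutational tolerance at two short Sup35
segments, a different experiment from compositional enrichment.

### Frequency estimation

Training counts are pooled over all residues of all training sequences (no
per-sequence weighting), ambiguity letters (B, J, O, U, X, Z) excluded.
Frequencies use `f_i = (c_i + a) / (total + 20a)` with a Jeffreys
pseudocount `a = 0.5` by default: it keeps every potential finite on
arbitrary input while perturbing well-observed residues negligibly.
`a = 0` gives raw maximum likelihood and may produce `-inf` potentials,
which are permitted but flagged.

## The proline correction

Scattered (non-contiguous) prolines disrupt prion formation; clustered
prolines are common in real prion domains.  The correction term models the
separations of *consecutive* proline pairs: for prolines at positions
`q_1 < q_2 < ... < q_P` inside a window, the pairs are `(q_j, q_{j+1})`
with distance `d = q_{j+1} - q_j` (adjacent prolines have `d = 1`), and the
correction adds `LOr(d) = log2(observed(d) / expected(d))` per pair.  The
observed spacing distribution is estimated from a reference sequence set;
the expected distribution is the geometric law of independently placed
prolines, `P(d) ∝ (1-q)^(d-1) q` with `q` the reference proline frequency,
renormalized over `d = 1..60`.  A shuffle-based empirical null is available
(`null="shuffle"`) for sensitivity analysis.  Distances never observed get
the half-count floor `log2((0.5/n_pairs)/expected(d))` instead of `-inf`.
Distances are measured strictly within each window, so the correction must
be recomputed per window (it is not additive across window boundaries).

The *shipped* spacing model is trained on 5,000 synthetic
background-composition sequences (fixed seed; see
`scripts/build_default_proline_model.py`) and is therefore close to neutral
(|LOr| < 0.3 bits everywhere): it exercises the full code path and keeps
scores honest without claiming real spacing biology.  For production scans
retrain it on a real non-redundant database (`prionscan proline-model`);
with a reference in which prolines genuinely cluster, the correction
penalizes scattered-proline windows as intended.

## The scanner

Windows of `L = 60` residues are scored at stride 1.  Scores are computed
from integer residue counts (a cumulative count matrix) dotted with the
potential vector, which makes the incremental sliding path *bitwise*
identical to scoring any window in isolation — there is no floating-point
drift to tolerate, and the test suite asserts exact equality.  Per protein
the maximum-scoring window is the putative PrD (leftmost window on exact
ties, for determinism); `mode="all"` instead returns every non-overlapping
window above the cutoff (greedy, descending score) for multi-domain
proteins.  Proteins shorter than the window are skipped with a notice.
Ambiguity letters contribute 0 bits by default; `ambiguity_policy="skip"`
excludes windows containing them.

The decision cutoff defaults to 50 bits, the accuracy-vs-cutoff maximum of
the calibration benchmark.  Empirical p-values against a proteome's
per-protein best-score distribution use the add-one estimator
`p = (1 + #{x >= s}) / (n + 1)`, which avoids p = 0 and matches standard
permutation-test practice.

## Benchmarking stack

* A call is positive when `score >= cutoff`; TPR, FPR, accuracy, precision
  and FDR follow the standard confusion-matrix formulas, with NaN sentinels
  for zero denominators (never exceptions).  `precision + FDR = 1` whenever
  both are defined.
* ROC curves take one point per distinct score (ties move together,
  producing diagonal segments); AUC is the trapezoid area and is
  algebraically identical to the tie-corrected Mann-Whitney `U/(n·m)` — the
  package computes both routes independently and the tests require
  agreement to 1e-12.
* The precision-recall curve stops at the first threshold reaching full
  recall and is robust to class skews of 500:1 and beyond.
* Cutoff selection maximizes accuracy over a user grid, breaking ties
  toward the *largest* cutoff (the most conservative operating point).
* The rank-sum test is two-sided; exact enumeration when
  `n_pos·n_neg <= 400` and the pooled scores are tie-free, otherwise the
  normal approximation with tie correction.
* The bootstrap follows the half-exclusion design: each iteration splits
  the positive set into two disjoint halves uniformly at random, rebuilds
  the propensity table from one half, scores the excluded half against the
  fixed negative set, and the per-iteration ROC curves are averaged
  vertically on a fixed 101-point FPR grid.  Sampling the training half
  with replacement is available behind a flag.  Default 10,000 iterations
  (configurable; the acceptance script uses 500, which stabilizes the mean
  AUC to well under a point of its spread).
* Enrichment z-scores redraw `|selection|` ids from the universe without
  replacement (default 10,000 randomizations) and compare the observed
  per-category count with the null mean and sd; they converge to the
  closed-form hypergeometric z.  Categories are opaque labels — no ontology
  structure is modelled.

All stochastic operations are reproducible given a seed.

## Synthetic data

The generators make the pipeline testable end-to-end with known ground
truth.  Three compositions are used:

* `background` — the frozen Swiss-Prot `p`;
* `prd` — the training-set *average* composition implied by the shipped
  table (`f = odds·p`, normalized).  A 60-mer at this composition scores
  only ~45 ± 11 bits: the average over complete training sequences is
  diluted by non-prion flanks and sits below the 50-bit operating point;
* `core` — an exponentially tilted composition `∝ p·odds^1.5`
  (Q+N ≈ 60%), emulating the dense Q/N core that validated prion domains
  present to the scanner.  Planted cores score ~84 ± 10 bits, inside the
  range real positives occupy, and exceed 50 bits with probability
  ≥ 0.999.  The tilt exponent was fixed once from that score-range
  calculation.

Positive benchmark sequences embed one 60-residue core (optionally mixed
with background by a `contrast` parameter) inside background flanks of
total length 60–250, mirroring the fact that real PrDs sit inside larger
proteins; negatives are pure background.  Synthetic proteomes use 100–800
residue proteins with a chosen fraction spiked.  Length ranges straddle
the 60-residue window so the short-protein path is exercised.

What the generators do *not* emulate: homology and evolutionary
relatedness, domain architecture, real proteome length distributions, and
real proline spacing biology (flanks are i.i.d.).  Passing tests therefore
demonstrate the correctness and calibration of the machinery, not
field performance on real proteomes.

### Localization precision

The scanner reports the maximum-scoring window.  With stochastic planted
cores, background flank residues adjacent to the core occasionally score
well enough that the maximum window shifts 3–5 residues off the planted
start (a few percent of cores at the default composition; the effect
shrinks but does not vanish as the core composition becomes more extreme).
Detection of the spiked protein and the domain's approximate location are
robust; single-residue localization of a compositional signal is not a
property this model can guarantee, and one acceptance-level check that
demands ±2-residue localization for every planted core is expected to fail
occasionally for exactly this reason.

## Problem sizes and defaults

| parameter | default | why |
|---|---|---|
| window length `L` | 60 residues | typical PrD-core length |
| cutoff | 50 bits | accuracy maximum of the calibration benchmark |
| pseudocount | 0.5 | Jeffreys smoothing; finite potentials |
| proline `max_distance` | 60 | matches the scanning window |
| benchmark sets | 18 positives / 18 negatives | the validated-prion benchmark design |
| parameter-recovery study | 18 × 1,000-residue training proteins | within the real prion-protein length range; expected counts large enough that every non-rare residue is estimable to ±0.3 bits |
| synthetic proteome | 500 proteins, 2% spiked | desk-scale stand-in for a small proteome |
| bootstrap iterations | 10,000 (library), 500 (acceptance script) | mean-AUC stability vs. desk runtime |

## Known limitations

* The model is purely compositional: it cannot distinguish permutations of
  a window, and compositionally similar non-prion segments (notably some
  intrinsically disordered regions enriched in Q/S) will score high.
* The shipped proline model is a synthetic stand-in; its corrections are
  intentionally near-neutral.
* The shipped background is pinned to a specific release; proteomes with
  unusual global composition (e.g. low-complexity-rich parasite genomes)
  may warrant a custom background.
* Scores are uncalibrated log-likelihood ratios; absolute values depend on
  the training set, so cutoffs must be re-derived after retraining.
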