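# Methods

This note documents the models, defaults and numerical choices behind
`linkbench`, and what the synthetic benchmark can and cannot say about real
record linkage.

## The synthetic scenario

Real paired EHR identifier data cannot be shared, so the benchmark runs on a
generator that emulates their statistical structure. A latent population of
`n_persons` carries first/last names drawn from Zipf-ranked pools (first-name
pool 1,200, last-name pool 5,000, exponent 1.4 — sized so last names are
markedly more diverse than first names, as in real identifier data, which is
what makes u_last < u_first and gives last-name agreement more weight),
gender, race, a 5-digit ZIP, a date of birth, and a unique latent MRN. Ages
follow a two-part law: an infant mode (8% aged < 1, feeding the newborn
channel) and a uniform draw over 1–90 years; DOB is uniform within the age
stratum and YOB/age are derived from it at a fixed reference date
(2015-12-31), so the three fields are mutually consistent by construction.
Ages are capped at 90.

Persons are split across sources: `overlap_fraction` (default 0.3) of them
appear in both, and the remainder are allocated so the outpatient population
is `opd_to_ipd_ratio` (default 2.5) times the inpatient one — outpatient
practices cover far more people than a hospital admits, and this asymmetry
drives both the blocked-pair composition and the missing-MRN pattern.

Each inpatient person contributes `1 + Poisson(admission_rate − 1)` rows
(default mean 1.5; the admission-count law is a modeling choice — the
marginal distribution of admissions per patient is rarely published — and
Poisson is the simplest single-parameter law). Every IPD row passes
independently through error channels:

- **Typos** (rate 0.02 per name field): one random substitution, insertion,
  deletion, or adjacent transposition, uniform over positions and the A–Z
  alphabet. Each channel produces a string at restricted Damerau–Levenshtein
  distance exactly 1; inputs admitting no such edit (empty strings,
  all-equal characters under transposition) are rejected as degenerate.
- **Newborn placeholder naming** (5% of infants): the inpatient system
  records first name "Male"/"Female" by gender with the mother's surname,
  while the outpatient record carries the real name — a documented
  real-world failure mode for name-based linkage.
- **Compound surnames** (1% of rows): a hyphenated second surname appears in
  one system only.
- **Missing gender** (0.2% of rows).
- **MRN corruption** (0.75% of rows, the middle of the 0.5–1% error range
  reported for enterprise MRN assignment), split 77% different MRN / 22%
  missing / 1% misassigned to another person, the shares a manual review of
  gold-standard discordances attributes to each mechanism. The misassignment
  channel creates pairs that agree on MRN but are different people, so the
  gold standard is *alloyed* in both directions.

OPD rows are one per person and clean, except that persons never admitted
lack an inpatient MRN with probability 0.25 — concentrating missing MRNs on
the non-overlapping population, which is why rank-1 gold discordance stays
in the low percent range rather than tracking the missing-MRN share.

Everything derives from one seed through salted `numpy` generator streams;
identical configuration gives byte-identical CSV output.

**What the generator does not emulate:** real name distributions (names are
pronounceable random strings), case and formatting variation, name changes
at marriage, nickname/suffix conventions, OPD-side typos, clinical content,
and — most importantly — the scale of real linkage problems. At desk scale
(default 20,000 persons) random DOB collisions are far rarer relative to
true matches than in a population of hundreds of thousands, so blocked pairs
here are match-dominated, whereas real DOB-blocked candidate sets are
dominated by coincidental collisions. Structural results (distinct-weight
counts, rank agreement, dialect differences) transfer; absolute metric
values do not.

## Preprocessing

Harmonization recodes gender ("1"/"2" and spelled-out forms to M/F; unknown
codes become missing and are counted), collapses race to {Asian, black,
white, other, missing}, nulls implausible ZIPs (anything but 5 digits),
extracts YOB from DOB, and caps age at 90. Names are deliberately left
untouched — no case folding or suffix stripping — because comparator
behaviour on raw names is part of what is being benchmarked.

Inpatient deduplication collapses rows identical on the seven-field key
(MRN, last name, first name, gender, YOB, race, ZIP), keeping the lowest
record id. A row whose only deficiency is a missing ZIP is dropped when a
sibling identical on the other six fields carries a valid ZIP. Missing
values elsewhere in the key compare as ordinary values (two missings agree)
— the simplest consistent reading. The operation is idempotent and
order-stable.

## Comparison

Blocking is a hash join on the non-missing block values; pairs with a
missing block value on either side are excluded (they cannot agree on the
block) and counted in the log. Exact comparison is byte-identical equality,
capitalization included. Jaro similarity uses the standard window
⌊max(|s₁|,|s₂|)/2⌋ − 1 and the strcmp95 convention of halving the
out-of-order count with truncation; empty strings score 0 by convention.
The Winkler prefix bonus (scale 0.1, prefix capped at 4) is applied
unconditionally — the most common dialect; a boost threshold is exposed for
parity experiments. Gender, a one-character field, is always compared
exactly, similarity being meaningless there.

## Weighting dialects and the 17-run matrix

Log base 2 throughout (so gender agreement at m = 0.95, u = 0.5 is worth
0.926 bits). The matrix reproduces, via dialect flags, the behaviours real
linkage packages exhibit:

| dialect axis | options |
| --- | --- |
| string mode | exact / Jaro–Winkler |
| method | FS / EM / EpiLink / deterministic |
| missing policy | scored as disagreement (R-style, 8 distinct exact weights) / zero contribution (MTB/CUPLE-style, extra distinct weights per missing pattern, ranking "both names disagree, gender missing" above full disagreement) |
| inexact conversion | binarize at a similarity threshold (default 0.95) / interpolate w = s·w_agree + (1−s)·w_disagree |
| output truncation | Link-Plus-style positive-only weights (non-positive weights unrecoverable downstream) |

Nine exact profiles and eight inexact ones give 17 runs. EpiLink appears
only with exact matching and zero-contribution missing handling (its
normalised sum drops missing fields by construction). EpiLink parameters
are tied to the FS vocabulary: e_i = 1 − m_i, f_i = u_i. The
threshold-binary reconstruction of the R-style inexact FS run is exactly
that — a reconstruction; package internals differ and the exact mechanism
behind some published distinct-weight counts is not recoverable.

EM initialises at m = 0.9, u at the field defaults, p = 0.01, stops when the
largest parameter change falls below 1e-6 (at most 500 iterations), clamps
estimates to [1e-6, 1 − 1e-6] with a degeneracy flag, and swaps classes if
label-switching leaves u ≥ m everywhere. Iteration is over collapsed
agreement patterns, so cost is independent of pair count. The log-likelihood
is non-decreasing by construction of EM.

**Known limitation — boundary drift.** With a highly discriminating field
(m near 1, u near 0) and few matches, the unpenalized mixture MLE can push
that field's m to the 1 − ε boundary: the likelihood of the drifted solution
genuinely exceeds the truth's, so this is a property of the estimator, not
of the implementation. Estimates are clamped and flagged; parameter-recovery
accuracy on simulated vectors is therefore draw-dependent near the
tolerance. A penalized/MAP M-step would suppress this at the cost of leaving
the classical estimator; the package keeps the classical form.

Deterministic weighting counts missing as non-agreement. At least two
distinct agreement patterns are required for EM; a single observed pattern
is flagged degenerate and the initial parameters are returned.

## Postprocessing and evaluation

Scaling is the affine map (W − min)/(max − min); a constant column maps to
all zeros and is flagged rather than erroring, keeping degenerate synthetic
scenarios runnable. Ranks are dense (tied weights share a rank; ranks
advance one per distinct weight), so "pairs at rank 1" equals "pairs at the
maximum weight". The ensemble average always divides by the number of runs;
pairs absent from truncated runs contribute that run's scaled minimum, 0.
Vote counting tallies runs ranking a pair in the top k (default 2).

Gold labels are MRN agreement with missing-counts-as-non-match — how an MRN
check behaves operationally. ROC curves place one operating point per
distinct weight with trapezoidal AUC (equivalent to the Mann–Whitney
statistic under the ½ tie convention); pairs a truncated run never weighted
sit below every threshold. Weight relationships use Pearson correlation and
an eigendecomposition of the correlation matrix of scaled weights
(zero-variance columns dropped and flagged). Sensitivity/specificity/PPV/NPV
are reported as NaN when undefined (zero denominators).

## Problem sizes

Defaults are sized for a single desktop core: the default scenario uses
20,000 latent persons (≈11,000 deduplicated IPD rows, ≈16,000 OPD rows,
≈10,000–15,000 DOB-blocked pairs), and a full 17-run experiment including
EM fits, both ensembles and evaluation completes in a few seconds. Repeated
-seed studies (e.g. 20-seed comparisons of ensemble vs individual-run AUC)
use the same default scenario end to end. Paper-scale populations remain a
configuration choice, not a code change.

## Design choices where the design was open

- Admissions per patient: Poisson, one parameter, no published marginal to
  match.
- Survivor among exact duplicates: lowest record id — deterministic.
- Missing-MRN placement: concentrated on never-admitted persons (see above).
- Ensemble handling of truncated runs: impute scaled 0; published analyses
  do not state their handling, and 0 is the only value a positive-only run
  can be said to have assigned.
- The seven-field deduplication key follows the enumerated field list even
  where a summary count says six; the enumeration is authoritative.
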