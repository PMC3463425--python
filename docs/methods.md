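# Methods

## The biological setting

CcpA mediates carbon catabolite repression in Firmicutes by binding
14-nt pseudo-palindromic operators (cre boxes) in or near promoters.
Because binding competition scales with regulator abundance, a
dose–response design — expression profiling at low, medium and high
regulator induction — ranks operators operationally: operators whose
operons respond at the lowest dose bind first ("high affinity" in the
hierarchical, not biophysical, sense), operators responding only at higher
doses bind later ("low affinity"). This package reconstructs that analysis
as a reusable pipeline: motif scan → positional filter → three-dose
classification → sequence/position statistics, plus a synthetic benchmark
that makes the whole chain testable against planted truth.

## Motif model

Independent-column PFM/PWM. Counts are tallied from a gap-free alignment
of width w (default 14, but all code is width-generic); probabilities use a
pseudocount k (default **0.5**, Laplace-style — the training sets here are
31–69 sequences, small enough that unsmoothed zeros produce −∞ log-odds);
log-odds are base 2 against a background composition (default **uniform**,
optionally genome-derived mononucleotide frequencies). Scores are kept at
full precision internally and written at 2 decimals.

Degenerate consensus calling uses raw (unsmoothed) column frequencies: top
base if its frequency ≥ θ_single (default **0.70**), else the IUPAC
two-base code of the top two if their sum ≥ θ_pair (default **0.75**), else
N; ties break alphabetically. The thresholds are a documented heuristic
chosen to reproduce accepted single- vs two-base calls at the
group-discriminating cre positions (6 and 14); they are not a published
rule, and full consensus strings at every position should not be
over-interpreted near the thresholds.

Unscorable windows (any base outside ACGT) return a None sentinel rather
than a numeric score, so N-containing genome windows can never tie with a
real score.

## Scan cutoff calibration

A sum of independent per-column discrete scores has an exactly computable
distribution: the package convolves the per-column (score, probability)
pairs on a 10⁻³ grid. The scan cutoff is set at the q-quantile of the
score distribution of sites drawn from each training-group model
(default false-negative rate **q = 0.01** per group, taking the minimum
over groups), i.e. the cutoff is chosen to lose at most ~1% of true sites
per class rather than to hit any particular false-positive rate. This is a
deliberately sensitivity-first choice: on random background it is
permissive (roughly one hit per 80 bp of the synthetic genome), and the
positional window plus the expression classification downstream are the
specificity filters. The calibration is cross-checked in the tests against
a Monte-Carlo quantile of sampled sites. Scan hits respect monotonicity in
the cutoff, strand-mirror symmetry, and per-contig locality, all
property-tested.

## Coordinates, windows, distances

0-based half-open internally; 1-based inclusive in every written file.
The positional filter keeps predicted sites whose conserved central G
(motif position 8; genomically `start+7` on the upper strand, `start+w−8`
on the lower) lies within **−500..+100 nt**, closed on both ends, of the
first base of the start codon of an operon first gene, signed in the
gene's reading direction. The central-G anchor is reused for TSS
distances (0 = central G at the TSS); distance signs always follow the
regulated gene's reading direction, never the cre's own strand.
Literature-supplied sites bypass the window (documented cases sit
kilobases into an operon); a curated site duplicating a predicted one at
the same central-G coordinate replaces it.

## Affinity classification

A condition is significant iff its upstream significance flag is set AND
|fc| ≥ threshold (default **1.8**, signed-ratio convention with |fc| ≥ 1).
The flag is not redundant: upstream testing can fail a gene whose
magnitude passes (the curated table contains such a case), so magnitude
alone is accepted only as a documented fallback when flags are absent.
The decision tree, gated on regulation at the high dose in either
direction: significant repression at low → `high_affinity`; significant
activation at all three doses → `activating`; significant repression at
medium or high → `low_affinity`; else `unclassified`. Mixed significant
directions and partial activation refuse classification with a warning
rather than silently. Raising the threshold can only move calls toward
`unclassified` (tested). Per-dose operon counts deduplicate multi-cre
operons.

## Palindromicity

For even width w, pair (i, w+1−i) is palindromic iff the bases are
Watson–Crick complements; the score counts palindromic pairs (max w/2).
Pairs containing an ambiguous base count as non-palindromic (scanned sites
with N remain profileable). Group statistics round half-up; percentages
pass through a one-decimal intermediate before the integer rounding
(39.47 → 39.5 → 40), the display convention of common spreadsheet software
and the one under which the package reproduces curated reference tables
cell-for-cell. The score is invariant under reverse complement and the
per-position percentage row is symmetric about the center, both
property-tested.

## Helical phase

Phase = distance mod period with floored modulo (−27 mod 10.5 = 4.5),
default period **10.5 nt** (canonical B-DNA turn; reported operator
spacings in this system are "10–11 nt"), default bin width **1.5 nt**.
The module is descriptive — binned counts and median |fc| at the high dose
per affinity group — and fits no periodogram; the phase clustering of
real operator lists is approximate (adjacent reported positions can differ
by 13 nt), so no hard test asserts single-period alignment. A scatter
writer can cap |distance| for display; the full table is always written.

## Synthetic data generator

Emulates the study design, not the microarray platform: it emits fold
changes directly (no probe intensities or normalization).

* **Genome**: i.i.d. background at GC 0.435 (*B. subtilis*-like), default
  200 kb, one contig, 70 operon slots. Empirical GC converges within 2
  points by 100 kb (tested).
* **Operons**: per slot one gene with random strand, TSS at the slot
  center, leader length uniform 20–80 nt.
* **Sites**: default 20 strong + 20 weak + 3 activating (= 43 regulated)
  + 20 decoys. Strong/activating sequences are drawn column-wise from the
  high-affinity group's probability matrix, weak from the low-affinity
  one; decoys are uniform random 14-mers rejection-sampled below the scan
  cutoff. The TSS distance is a mixture (70% Normal(0, 15) near-TSS
  cluster, else uniform −100..+120), reflecting the observed clustering of
  strong sites near the TSS, and placements always land inside the
  −500..+100 start-codon window. Slots keep planted sites from
  overlapping.
* **Expression**: noise-free per-class |fc| effects are drawn uniformly on
  the fold-change scale per dose — strong 2.0–7.4 / 2.5–21.9 / 2.5–35.8
  (repression), weak 1.0–1.5 / 2.0–6.6 / 2.0–12.2, activating 2.0–6.2 at
  all doses — then perturbed by Gaussian noise (default sd **0.25**) on
  the log2 scale and converted back to signed ratios. The ranges span the
  spread of the curated regulon data but are inset from the 1.8 decision
  threshold by roughly the noise scale: observed tables are themselves
  significance-truncated noisy measurements, and a noise-free truth effect
  placed exactly on the classifier's threshold would make the planted
  label a coin flip rather than a recoverable truth. Significance flags
  are |fc| ≥ 1.8 on the emitted value, with an optional false-flag rate
  (default 0).
* **Determinism**: one seed drives everything; equal specs give
  byte-identical FASTA/TSV/GFF3 output (tested). A YAML schema mirrors the
  spec dataclass.

What passing the benchmark does and does not show: site recovery ≥95% at
exact coordinates demonstrates scanner and calibration correctness for
sites that genuinely match the motif model, and label recovery (100%
noise-free, ≥90% at sd 0.25) demonstrates the classifier under the noise
model it assumes. Real data violate the generator's assumptions in known
ways — background is not i.i.d. (coding bias, repeats), operator strength
is a continuum rather than two classes, expression noise is not
homoscedastic log-Gaussian, and significance flags come from a real test
with its own error structure — so benchmark numbers bound idealized, not
field, performance.

## Problem sizes and numerical notes

Default analyses run on the bundled 72-row regulon table and 200 kb
synthetic genomes (a few seconds end-to-end); the exhaustive best-window
oracle is exercised at widths ≤ 7 where 4^w enumeration is exact.
Score-grid resolution for quantile calibration is 10⁻³ bits; probability
columns are validated to sum to 1 within 10⁻⁹; −∞ log-odds are permitted
only at pseudocount 0 and excluded from calibration. BED output scales
scores into the format's 0–1000 integer range (linear against a supplied
maximum, else rounded and clamped); the TSV writers keep full precision.

## Known limitations

* The positional window anchor (central G) is a declared convention; other
  choices (site 5′ edge, any-overlap) shift marginal sites in or out.
* The calibrated cutoff is not comparable to scores from other PWM tools
  (different background, pseudocount, or log base rescale the axis).
* Activating sites are modelled from the high-affinity matrix for lack of
  a dedicated training set; the class is tiny everywhere.
* No statistical test is attached to group palindromicity differences or
  phase clustering; both modules are descriptive.
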