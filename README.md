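# crebox

Genome-wide analysis of **cre boxes** — the 14-nt pseudo-palindromic
operators bound by CcpA, the master regulator of carbon catabolite
repression in *Bacillus subtilis* and other Firmicutes. The package is
aimed at bacterial regulatory genomicists who want to map a regulator's
operator hierarchy from a dose–response expression experiment: which
operators respond when the regulator is scarce (high affinity), which only
when it is plentiful (low affinity), and what sequence and positional
features separate the two.

## What it computes

**Motif model and scan.** From an alignment of known cre 14-mers the
package builds a position frequency matrix with counts
$c_{b,i}$, pseudocount-smoothed probabilities
$p_{b,i} = (c_{b,i} + k)/(N + 4k)$, and base-2 log-odds
$W_{b,i} = \log_2(p_{b,i}/q_b)$ against a background composition $q$.
A window $s$ scores $S(s) = \sum_i W_{s_i,i}$; both genome strands are
scanned and windows with $S \ge$ cutoff are reported. The cutoff is
calibrated as an exact quantile of the score distribution under the motif
model itself (a chosen false-negative rate), computed by convolution over
columns.

**Positional filtering.** Hits are attached to operon first genes when the
site's conserved central G falls within −500..+100 nt of the start codon in
the gene's reading direction; literature-curated sites bypass the window.
Distances to the transcription start site (TSS) use the same central-G
anchor.

**Affinity classification.** Given signed expression fold changes at three
regulator-induction doses with significance flags, a site is called
`high_affinity` (significant repression already at the low dose),
`low_affinity` (repression only at medium/high), `activating` (significant
activation at all three doses), or `unclassified`; a condition counts only
if flagged *and* |fc| ≥ 1.8. Per-dose counts of distinct repressed operons
summarize the regulon's titration behaviour.

**Sequence and position statistics.** Palindrome scores (number of
complementary symmetric pairs per 14-mer, 0–7), per-position palindrome
percentages and group means; degenerate IUPAC consensus calls; and
TSS-distance / helical-phase (period ~10.5 nt) summaries.

**Synthetic benchmarks.** A seeded generator plants cre sites of graded
affinity in a synthetic genome with a matching three-dose expression table
and truth tables, for end-to-end recovery testing.

## Worked example

The package bundles a curated table of *B. subtilis* CcpA-regulon cre
boxes with fold changes at three CcpA induction doses:

```python
from crebox import (MotifAlignment, build_pfm, consensus_call, group_profile,
                    classify_cre, count_regulated_operons, datasets)

table = datasets.load_reference_table()
strong = table[table.group == "high"]["cre_sequence"].tolist()
weak = table[table.group == "low"]["cre_sequence"].tolist()

print(consensus_call(build_pfm(MotifAlignment(strong))))  # TGAAAGCGYTWWCA
print(consensus_call(build_pfm(MotifAlignment(weak))))    # TGWAARCGYTTWCW

hp, lp = group_profile(strong), group_profile(weak)
print(hp.mean_score, lp.mean_score)   # 4.6 4.3
print(hp.percent)                     # (68, 71, 52, 61, 84, 32, 97, 97, 32, 84, 61, 52, 71, 68)

records = datasets.reference_expression_records()
calls = [classify_cre(r).call for r in records]
print(calls.count("high_affinity"), calls.count("low_affinity"),
      calls.count("activating"))      # 31 38 3
print(count_regulated_operons(records, datasets.reference_operon_map()))
# (30, 58, 67)
```

The strong group's consensus is fixed to G at position 6 and A at 14 where
the weak group degenerates to R and W, and strong sites are more palindromic
on average (4.6 vs 4.3 of 7 possible pairs) — the central C7:G8 pair is
complementary in 97% of strong sites vs 90% of weak ones. Classification
says 31 cre boxes (30 operons) respond already at low regulator dose, 38
(37 operons) only at medium/high, and the numbers of repressed operons per
dose (30, 58, 67) show the regulon being titrated in.

An end-to-end synthetic run:

```python
from crebox import scan_genome, classify_cre
from crebox.synthetic_data import (SyntheticSpec, generate_genome, generate_expression,
                                   default_matrices, calibrated_cutoff,
                                   site_recovery, label_recovery)

spec = SyntheticSpec(seed=1)          # 200 kb, 43 planted sites + 20 decoys
ds = generate_genome(spec)
mats = default_matrices()
cutoff = calibrated_cutoff(mats["combined"], [mats["strong"], mats["weak"]])
hits = scan_genome(mats["combined"], ds.genome, cutoff)
records, truth = generate_expression(ds)
calls = {r.gene_id: classify_cre(r).call for r in records}
print(site_recovery(hits, ds.truth_sites))   # 1.000
print(label_recovery(calls, truth))          # 0.977
```

All 43 planted sites are recovered at exact coordinates and 97.7% of the
planted affinity labels survive the default expression noise (sd 0.25 on
log2 fold changes); at zero noise label recovery is 100%.

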