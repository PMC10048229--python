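# Methods

## Scope and data model

`cubkit` analyzes codon usage in cohorts of protein-coding nucleotide
sequences labelled by gene, taxon and family. Every index operates on a
`CodonCounts` table (64-codon occurrence counts); sequences are reduced to
counts once, after QC and terminal-stop stripping, and group-level analyses
work on element-wise sums of those tables. The genetic code defaults to NCBI
translation table 11 (plastid/bacterial), whose degeneracy structure is that
of the standard code: 9 two-fold families, Ile as the single three-fold
family, 5 four-fold families, 3 six-fold families (Leu, Ser, Arg), and the
single-codon amino acids Met and Trp.

## QC filtering

A CDS is retained iff it (1) begins with an accepted start codon, (2) ends
with a stop codon, (3) has no internal stop, (4) has length divisible by 3,
(5) is strictly longer than `min_len_nt` (default 300 nt, counting start and
stop), and (6) has at most 5 % of its codons containing an ambiguous base.
Failures are reported with reason codes, never raised. Choices worth noting:

- **Accepted starts** default to a strict `{ATG}`; table-11 alternative
  initiators (GTG, TTG) can be admitted via configuration. Plastid
  annotation practice varies and the strict default is the conservative one.
- **Ambiguity handling.** Codons containing N are excluded from all counts
  and denominators, which keeps every index well defined; a gene is rejected
  outright only when more than 5 % of its codons are ambiguous.
- **"Longer than 300 bp"** is read as strictly greater than.
- GenBank CDS features are spliced across compound locations and
  reverse-complemented on the minus strand (1-based inclusive coordinates,
  per the format); features without a `gene` qualifier are skipped with a
  warning rather than crashing a whole-genome import.

Cohort assembly (e.g. keeping only genes that pass QC in every taxon) is
left to configuration: QC is reported per record.

## Indices

**RSCU.** `rscu_c = x_c · k_a / X_a` over sense codons of amino acids with
degeneracy ≥ 2. Amino acids with zero count yield *undefined* (NaN) entries,
never zeros — a zero would be indistinguishable from "observed but unused".

**ENC (Wright).** Per synonymous family, the small-sample codon
homozygosity is `F̂ = (n Σ p̂_j² − 1)/(n − 1)`; families with `n < 2` or
`F̂ ≤ 0` are excluded. Class means `F̄_k` are averaged over the usable
families of each degeneracy class and

    ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆.

A missing `F̄₃` (Ile absent or unusable) is replaced by `(F̄₂ + F̄₄)/2`; the
raw value is capped at the theoretical maximum of 61; a missing two-, four-
or six-fold class mean makes the result undefined, with the reason recorded.
These conventions are the published ones for the estimator (and what CodonW
implements). Note the estimator is only asymptotically scale-invariant:
multiplying all counts by 10 changes ENC by `O(1/n_family)`, roughly 2 ENC
units at 500 codons and below 0.05 only once families hold thousands of
codons. The test suite checks the decay, not an absolute bound at small n.

**PR2.** Third-base counts are summed over fourfold-degenerate codon boxes
and reported as AU bias `A3/(A3+U3)` and GC bias `G3/(G3+C3)`. The default
box set is the inclusive one — all eight boxes with a fully degenerate third
position (Ala, Gly, Pro, Thr, Val plus the CTN/TCN/CGN boxes of Leu, Ser,
Arg); both this and the restrictive five-box reading (strictly four-fold
amino acids only) appear in the literature, so the choice is a flag
(`pr2_boxes = eight | five`). A coordinate whose denominator is zero is
undefined (NaN), never 0.5.

**ENC–GC3s.** The mutation-only expectation is
`ENC*(s) = 2 + s + 29/(s² + (1−s)²)`. Each record gets
`deviation = ENC*(gc3s) − enc`, and a per-group fraction of points with
`|deviation| ≤ band` is reported. The near-curve band defaults to 2 ENC
units — "on or near the curve" has no canonical threshold, so it is
configurable and always reported alongside the raw deviations.

**Neutrality plot.** Ordinary least squares of GC12 on GC3 (scipy
`linregress`), per family across genes plus a pooled fit over all records.
The fit requires ≥ 3 points and non-constant GC3; a perfectly flat GC12
response returns slope 0, r 0, p 1 (the correlation of a constant is taken
as zero rather than undefined). Raw two-sided p-values are reported as the
primary column, with a clearly-labelled Benjamini–Hochberg column alongside.

**Summaries and clustering.** Group cells report mean and *sample* SD
(n−1 denominator); single-observation cells get SD 0 and a flag. Family ×
codon RSCU matrices are clustered agglomeratively on rows and columns
(Euclidean distance, average linkage by default — the common heatmap
convention; nothing in the analysis depends on the linkage). Rows and
columns are canonicalized by sorted label before linkage so the tree and
leaf order are invariant to input ordering (scipy breaks distance ties by
observation index). Undefined RSCU entries are imputed as 0 for clustering
only, with a logged note. Trees are exported as Newick.

## Synthetic data generator

The generator emulates an AT-rich plastid gene cohort with family structure,
under three regimes that differ in which force drives third-position
composition:

- **mutation** — every codon is drawn with probability proportional to the
  product of its three base weights at the gene's mutational GC pressure
  `θ` (`P(G) = P(C) = θ/2`), renormalized over sense codons. This is exactly
  rejection sampling of stop codons, and is also why realized GC3 deviates
  from θ by a small, documented amount (≈ +0.007 at θ = 0.35: the excluded
  stops are AT-rich). All positions track θ, so GC12 follows GC3 across
  genes and the neutrality slope is near 1 (attenuated a few percent by
  third-position sampling noise).
- **selection** — the amino-acid content of each gene is fixed by a usage
  profile (uniform over the 20 amino acids by default) with deterministic
  largest-remainder allocation: this is the strong protein-level-constraint
  limit, and it is what makes GC12 essentially constant across genes so the
  regression slope is genuinely near zero instead of merely zero-mean with
  large sampling noise. Within each synonymous family, a codon's odds are
  its full-codon mutational weight at θ times `exp(s)` for the family's
  preferred codon (the first A-ending codon, else T-ending, under the
  default AT preference). Third positions therefore still feel θ — damped
  by selection — while first/second positions vary only through the
  six-fold families' sub-box choices (TTR/CTN, TCN/AGY, CGN/AGR). That
  leakage produces small *positive* slopes, the empirically typical pattern
  for plastid cohorts, rather than slopes scattered symmetrically about 0.
- **mixed** — each gene's codons are split evenly between the two
  mechanisms, landing the slope strictly between the pure regimes.

Per-gene heterogeneity: `θ_gene ~ U(θ ± spread)` (defaults 0.35 ± 0.15, so
θ spans 0.2–0.5) and `s_gene ~ s_sel · U(0.7, 1.3)` (default `s_sel` = 1).
Defaults for the study layout are 11 families × 50 genes × 400 codons.
Under these conditions the selection regime realizes GC3 roughly in the
0.1–0.35 window and mean ENC around 41, and the mutation regime mean ENC
around 55 — an AT-rich cohort in which the two regimes are cleanly
separable by the neutrality slope (selection ≈ 0.04–0.09, mutation ≈
0.85–1.05 per family at this sample size). Sequences are emitted as
`ATG` + shuffled body + a stop codon drawn by mutational weight, so every
generated gene passes QC by construction for ≥ 100 codons.

What the generator does **not** emulate: phylogenetic correlation among
taxa within a family (each family is represented by one synthetic taxon),
amino-acid composition differences between genes, strand asymmetry,
context-dependent mutation, indels, and annotation error. Passing tests on
synthetic data therefore demonstrate that the statistics recover the forces
the generator encodes — not that real plastome cohorts satisfy the
generator's independence assumptions.

## Numerical and interface choices

- Fractions (GC metrics) are kept in [0, 1] throughout; any percentage
  rendering belongs to downstream reports.
- Undefined values (ENC without usable classes, RSCU of absent amino acids,
  PR2 with empty denominators, GC3s with no synonymous codons) propagate as
  explicit missing values with reasons — never silent zeros.
- All randomness flows through explicit `numpy.random.Generator` objects
  seeded from function arguments; there is no global state, and identical
  parameters + seed give byte-identical FASTA/metadata/truth outputs.
- Pipeline runs write to versioned `run-NNN` directories and hash every
  artifact into a manifest; tables re-run bit-identically (figures may
  differ at the byte level through format metadata).
- Test and acceptance simulations use 11 × 50 × 400-codon datasets (the
  default study layout) and 30–50-gene grids for monotonicity checks —
  sizes at which the sampling error of each check is far below its
  assertion margin.

## Known limitations

- ENC small-sample behavior (above): comparisons across genes of very
  different lengths inherit an O(1/n) bias from the homozygosity
  correction.
- The neutrality regression treats genes as independent points; in real
  cohorts shared ancestry inflates the apparent precision of the slope.
- GC3s follows the convention of excluding only degeneracy-1 amino acids;
  tools that also drop the three-fold Ile family will differ slightly.
- GenBank ingestion trusts the annotation; no re-annotation or
  frame-repair is attempted (out of scope by design).
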