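# Methods

## The measurement model

A single synonymous codon substitution library of a toxin gene inside a
toxin–antitoxin (TA) operon is read out by deep sequencing in three
strains: a toxin-resistant strain (neutral growth, measures library
composition), a toxin-sensitive strain (growth decreases with free toxin),
and a RelE reporter strain in which a RelE toxin gene sits behind the TA
promoter, so growth increases with the amount of repressing
toxin–antitoxin complex.

For variant *i* with read counts *x*, *y*, *z* in the resistant, sensitive
and RelE conditions, the fraction representation within a condition is

    F(x_i) = x_i / (Σ x_i + x_WT)

with the sum over the variants retained by the depth filter, so fractions
are a proper composition of the analysed set. The deepseq ratio and
enrichment score are

    ratio_i = F(y_i) / F(x_i)        ES_i^CcdB = ratio_i / ratio_WT

and identically for the RelE condition. ES = 1 is wild-type-like by
construction; the reference variant scores exactly 1. Per-replicate scores
are combined by arithmetic mean on the linear scale (a geometric-mean
option exists; for near-neutral scores the two differ negligibly, and the
linear mean keeps depleted variants at finite values).

Variants with fewer than 20 resistant-strain reads in *either* replicate
are removed before fractions are computed; the boundary is inclusive
(exactly 20 in both replicates is retained). The reference variant is
exempt from the filter because every score is a ratio to it; its dropout
raises an error rather than producing silent infinities. Zero reads in a
selective strain yield ES = 0 with a `depleted` flag rather than a
pseudocount; an optional +0.5 pseudocount mode exists only for the
log-based degree-of-variation statistics.

The degree of variation folds a score onto the ≥1 axis
(x = ES if ES > 1 else 1/ES) and reports log2(x / x_min) against the
least-deviating variant at the same codon position, so each position's
minimiser sits at exactly 0.

## Phenotype classes

Activity is classed from ES^CcdB (hyperactive < 0.7, inactive > 1.8) and
regulation from ES^RelE (repressing > 1, derepressing < 1); all
inequalities are strict, so a score exactly at a cutoff stays uncalled.
The four joint classes H+D, H+R, I+D, I+R require both a non-intermediate
activity and a non-neutral regulation call; anything else is neutral. The
0.7/1.8 constants are the normative defaults; `kmeans_thresholds` (k = 3
on log2 scores, 100 restarts, fixed seed) returns data-driven candidate
boundaries as midpoints between adjacent cluster extremes mapped back to
the linear scale, for use as an advisory sanity check only.

A double-library analysis, in which a parent hyperactive mutation is the
background "wild type", is the same code path with `reference_label`
naming the anchoring mutant: its counts become the reference counts and it
leaves the variant set. RelE scores from such re-anchored runs are
computed but compress against the anchor's own regulation phenotype and
should be interpreted with caution.

## Codon-level covariates

* **ΔGC** — G+C count of the mutant codon minus the WT codon; bounded by
  ±3 and typically within ±2 for synonymous pairs.
* **RCU** — ratio of genome-wide usage frequencies (occurrences per 1000
  codons), mutant over WT. The packaged table is an E. coli K-12
  genome-wide table; "rare" and "optimal" follow its ranking.
* **CAI** — geometric mean over a gene of relative-adaptiveness weights
  w = f / max f among synonyms. Weights are derived from the packaged
  usage table by default; an explicit weight table (e.g. from a
  highly-expressed reference gene set) can be supplied instead.
* **RtrnaA** — ratio of the percent of the cellular tRNA pool decoding
  each codon; codons read by several tRNAs sum their decoders. The
  packaged default derives these fractions from E. coli K-12 tRNA gene
  copy numbers, a standard proxy for measured abundance in fast-growing
  cells; a measured-abundance table can be passed directly.
* **tAI** — per-codon weight Σ (1 − s) · tGCN over recognising tRNAs
  under wobble rules (G:U s = 0.41, I:C s = 0.28, I:A s = 0.9999,
  U:G s = 0.68), normalised by the maximum; zero-weight codons take the
  geometric mean of the nonzero weights. Decoding is restricted to tRNAs
  of the codon's own amino acid, with an explicit override for the
  lysidine-modified isoleucine tRNA that reads ATA as cognate. The
  s-values are the standard published defaults and are overridable; tAI
  values are therefore comparable within a run, not across parameter
  sets.
* **Hydropathy** — raw Kyte–Doolittle per residue, with an optional
  centred moving-average window (odd, truncated at the edges). Published
  "hydropathy index" plots sometimes use undisclosed windows; no attempt
  is made to force agreement with any particular smoothed variant.

## RNA energetics

The transcript model is the putative SD stretch starting 18 nt upstream of
the start codon plus the full CDS (324 nt for a 306-nt toxin CDS). DNA is
transcribed (T→U) at the engine boundary; coordinates are 1-based
inclusive throughout.

* **Anti-SD pausing profile** — every 10-nt window (step 1) is scored for
  its minimum bimolecular duplex energy with the 16S rRNA anti-SD
  consensus 5'CACCUCCU3'. ΔaSD is the mean mutant-minus-WT difference
  over the *affected* windows (those overlapping the mutated codon, at
  most window+2 of them). Averaging over all ~300 windows would dilute a
  local 3-nt effect towards 0 and make genes of different length
  incomparable; the all-windows variant is available and related by the
  identity ΔaSD_affected = ΔaSD_all × (total/affected), which the test
  suite asserts. Positive ΔaSD = weaker anti-SD pairing = less predicted
  pausing than WT.
* **Transcript stability** — mean single-strand MFE over 30-nt windows
  (step 1); ΔMFE = mutant − WT, positive = destabilised mutant mRNA.
* **RBS occlusion** — fraction of SD-span bases unpaired in the MFE
  structure of a supplied initiation-region stretch (1 = fully
  accessible).

The folding engine is a pluggable contract (deterministic; single-strand
MFE ≤ 0; duplex energy ≤ 0 or "no stable duplex", recorded as 0). The
default backend is the ViennaRNA nearest-neighbor implementation with
current default Turner parameters at 37 °C, duplexes computed with
intramolecular pairing disallowed (the appropriate model for an 8–10-nt
bimolecular interaction) and dangling ends at the engine default. The
engine reports its parameter provenance for reproducibility. The folding
recursions themselves are deliberately not reimplemented.

## Conservation

Homolog hits are filtered on identity ≤ 95% and query coverage in
[90, 100], boundaries inclusive; filtering is idempotent. In-frame
trimming is the caller's responsibility; the module validates frame only.
At each codon position the homolog codons synonymous with the WT amino
acid are tallied; gapped or non-synonymous codons are excluded from the
ranking and reported in a separate column. The WT codon is "most"
conserved only as a strict maximum and "least" only as a strict minimum;
ties fall to "intermediate", a deliberately conservative tie-break.
Residue conservation is the percent of non-gap homolog residues matching
WT per column; all-gap columns are reported missing.

## The synthetic-data generator

The generator emulates the study design — every synonymous substitution of
a ~100-codon gene, observed as one multinomial draw of configurable depth
per condition and replicate (default 10^6), two replicates, uniform
library composition with a WT anchor (a Dirichlet option models cloning
bottlenecks). Substreams are derived from the master seed by fixed
(strain, replicate) offsets, so adding a condition never perturbs existing
draws and a fixed seed gives byte-identical outputs.

Ground truth is carried as per-variant true enrichment ratios ρ_sen and
ρ_relE (WT ≡ 1). In direct-ρ mode the ratios are specified or drawn
lognormal (median 1, log-sd 0.5) — the cleanest setting for estimator
tests. In mechanistic mode each variant carries a translational-efficiency
factor ε and folded fraction φ, mapped through a minimal toxin–antitoxin
balance: total active toxin t = ε·φ, complex = min(t, α) for antitoxin
capacity α, free toxin = t − complex, and promoter derepression
= (α − complex) + γ·free, with survival mapping through exponential
selection (k_f = k_r = 4 by default). The γ term (default 1) models
conditional cooperativity — excess free toxin converts the repressing
complex into a non-repressing form — which is what lets an over-translated
toxin simultaneously kill faster and derepress its operon (the H+D
signature) or a mildly under-translated one look inactive yet repressing
(I+R). With γ = 0 the model reduces to a pure capacity model in which
derepression is monotone in toxin and only the I+D and H+R corners are
reachable. `CLASS_SIGNATURES` records one (α, ε, φ) setting per class
whose implied true scores sit well outside a ±40% guard band around the
classification cutoffs.

What the generator does *not* model: PCR amplification bias, sequencing
error, barcode misassignment, replicate-level biological variation beyond
multinomial resampling, and mutation-specific mRNA degradation. Passing
recovery tests therefore demonstrates correctness of the scoring algebra
and classification under idealised counting noise, not robustness to
library-preparation artifacts in real data.

## Numerical choices and degenerate inputs

* Fractions must sum to 1 within 1e-12; a zero-total condition is a hard
  error.
* A retained variant with zero resistant-strain fraction indicates a
  filter violation and raises an internal-consistency error rather than
  producing an infinity.
* ES = 0 propagates as NaN (with a warning) into degree-of-variation
  statistics instead of a synthetic floor.
* Correlations use pairwise-complete observations, require ≥3 pairs and
  nonzero variance per cell, and mask significance at p ≤ 0.05 with no
  multiple-testing correction by default (a Benjamini–Hochberg option is
  provided, off by default).
* Mutant ordering for moving averages is ascending codon position, ties
  by codon lexicographic order.
* Stop-codon rows (the terminator position) are accepted by the reader
  but flagged, and excluded from residue-level covariates.
* Estimator-recovery checks at scale use depth 10^6 and 200 variants; the
  region partition and report summaries run on full ~300-variant
  libraries of a 101-codon gene.

## Known limitations

* CAI weights default to usage-derived relative adaptiveness rather than
  a curated highly-expressed reference set; supply explicit weights for
  strict comparability with external CAI calculators.
* tRNA-pool fractions default to a gene-copy-number proxy; measured
  abundances differ by growth condition.
* Duplex energetics depend on the thermodynamic parameter set and dangle
  model; values are comparable only within one engine configuration,
  which the engine records.
* The mechanistic truth model is a deliberately minimal caricature of TA
  autoregulation, adequate for generating class-labelled test data, not
  for quantitative fitting of real operon dynamics.
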