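# Methods

## Scope and data flow

`panenrich` covers the computational side of amplification-centric antibody
library design: repertoire ingest → per-sequence enrichment scoring →
per-length sequence-to-enrichment models → candidate simulation and
screening → T-cell-epitope exclusion → oligo pool design.  Wet-lab steps
(panning itself, gel separation, cloning, SPR) are out of scope; the
package only parses and aggregates their tabulated outcomes.

## CDR extraction

Synthetic fixed-scaffold libraries have invariant framework regions, so a
CDR is defined operationally as the residues between two exact framework
anchor matches (`FrameworkScheme`).  Matching is exact by design — the
frameworks are invariant in the library, and tolerant matching would blur
the designed/non-designed distinction the analysis depends on.  Nucleotide
reads are translated in the single frame in which the left anchor appears;
reads with ambiguous bases (N), missing or duplicated anchors, stop codons
in the CDR, or out-of-range CDR lengths are rejected and tallied by reason.
Reads are assumed pre-merged (paired-end merging is standard upstream
tooling).  Kabat numbering (CDR-H3 from H95, lettered insertions after
H100) is applied as a reporting convention only.

## Germline enrichment

Non-H3 CDRs of a simulated-hypermutation library are traced to their
germline ancestor by global edit distance with unit costs (edlib, NW mode).
Substitutions dominate such designs, but germline CDRs of one region can
differ in length, hence a full edit distance rather than Hamming.  Ties are
broken lexicographically and flagged ambiguous.  Per-germline frequencies
are read-count-weighted and normalized within each repertoire; fold change
uses +inf/0 conventions at zero frequencies, and the two-fold / half-fold
thresholds define the enriched/depleted flags.

## Enrichment score

    ES = log2[(n_post/N_post)/(n_pre/N_pre)] * (n_post+n_pre)/(med_post+med_pre)

Choices the formula leaves open, resolved here:

- **Pseudocount.** A raw count of 0 becomes 0.5 in both the log and weight
  terms, and the record is flagged.  Dropping unobserved-on-one-side
  sequences would censor exactly the most depleted (or most enriched)
  clones.
- **Median set.** The medians are computed over the pseudocounted counts of
  the same designed, whitelisted sequence set that is being scored.
- **Fold-enrichment scale.** The histogram axis is log10 of the frequency
  ratio (so "20-fold" sits at 1.3), distinct from the log2 inside ES; both
  are stored per record.
- **Significance of positional shifts.** A pooled two-proportion z-test per
  (position, residue), uncorrected by default (Benjamini–Hochberg behind a
  flag), with stars at p < 0.05 and p < 0.01.

## Per-length enrichment model

One model per CDR-H3 length 9–16 aa: ridge regression (unpenalized
intercept) of ES on one-hot `(position, residue)` indicators, lambda = 1e-6
by default, fitted in closed form (scikit-learn, SVD solver).  The
objective — L2-penalized least squares on categorical residue features —
fully determines the solution, so a deterministic solver is used rather
than any stochastic optimizer.  The 70/30 split is a seeded uniform random
split without stratification.  Residues unseen in training carry no weight;
positions with a single observed residue are dropped as constant columns.
Text n-gram features are deliberately not used: positional categoricals are
the declared feature set.  Screening keeps candidates with predicted
ES strictly greater than zero.

The decile diagnostic ranks evaluation sequences into ten near-equal groups
by actual ES and reports the mean/SD percentile rank (100·(rank−0.5)/n,
average-tied) of the predicted ES per group: a perfect predictor gives
5, 15, …, 95; an uninformative one gives ≈50 throughout.

## Candidate CDR-H3 simulation

Candidates are sampled position-wise from a per-position frequency table
over 18 residues (Cys and Met excluded by design), with rejection of
duplicates and of sequences containing liability motifs.  The shipped motif
defaults are the literature-standard set (NG/NS deamidation, DG/DS
isomerization, DP cleavage, N-X-S/T sequon with X ≠ P) and are editable
configuration.  The bundled position-independent frequency table
(`synthetic_usage_model`) is a clearly-labelled synthetic stand-in shaped
like natural CDR-H3 composition (Gly/Tyr/Ser/Asp-rich); real analyses
should supply measured tables.  The retry budget is 100× the requested
count; exhaustion raises an error carrying the achieved count.

## Deimmunization

Each CDR is flanked by its adjoining 8-aa framework context (flanks are
per-region configuration, since framework context differs by region) and
all L+8 overlapping 9-mers are scored for the 20-allele HLA-DRB panel.  A
percentile rank ≤ 0.5 (inclusive — "within the top 0.5%") for any
(window, allele) discards the CDR.  The MHC-II predictor is pluggable: TSV
import of precomputed ranks, an external-command adapter (9-mers on stdin,
allele as last argument, TSV on stdout), or a deterministic hash-based toy
scorer that exercises the plumbing in tests and carries no binding
information.  Binding prediction itself is out of scope.

## Oligo design

Reverse translation is deterministic: the most-used human codon per
residue, demoted to the next-ranked human codon when the top choice is in
the configurable E. coli rare-codon set (default ATA, AGG, AGA, CGA, CTA,
CCC, GGA); residues with no non-rare codon are flagged.  Both tables are
configuration.  Oligos are exactly 136 nt: adaptors and the CDR are fixed,
and the framework flanks are trimmed from their distal ends (the
CDR-adjacent bases are the assembly-PCR priming context and are always
kept), with an odd leftover base assigned to the 5′ side.  Adaptor and
flank sequences are user configuration; the defaults in tests/examples are
synthetic examples.

## Synthetic panning generator

`simulate_panning` emulates the statistical structure the ES and model
stages assume: clone fitness w = Σ effect(position, residue) + N(0,
noise_sd); pre frequencies ~ symmetric Dirichlet; post frequencies ∝
pre · exp(rounds·w); multinomial read sampling per repertoire.  It is a
test harness for the estimators, not a model of phage biology (no display
valency, wash kinetics, or helper-phage effects).

Defaults (the reference study condition used in tests and the acceptance
script): 5,000 unique length-9 clones (uniform over the 18 permitted
residues), per-(position,residue) effects i.i.d. N(0, 0.1) in log-fitness
units, clone noise SD 0.1, Dirichlet concentration 5 (mild pre-library
skew), rounds = 1, 10⁶ reads per repertoire.  The effect scale and single
composite round are chosen so that total selection strength
(rounds·SD(w) ≈ 0.3) stays in the regime where ES is approximately
proportional to fitness — the regime the linear screening model assumes and
in which linear effect recovery is meaningful.  Under strong selection
(several rounds, 20-fold-plus enrichment tails), the count-dependent weight
term makes ES markedly convex in fitness: rank-based statements survive,
but absolute linear effect recovery does not, which is a property of the
statistic, not of the implementation.  A strong-selection configuration is
exercised separately in the fold-histogram tests via explicit config.

Effect-recovery comparisons convert ridge weights (ES units) to fitness
units by dividing by the OLS slope of ES on true fitness from the
generator's truth table, then compare after per-position centering (only
within-position contrasts are identifiable under one-hot coding).

What passing tests show — and do not show — about real data: the estimators
recover planted linear structure under multinomial sequencing noise and
library skew; real repertoires add synthesis errors, PCR bias,
clone-by-clone epistasis and context effects that the generator does not
model, so held-out correlations on real data are expected to be lower.

## Numerical choices

- Pseudocount 0.5; median over pseudocounted designed counts.
- Ridge: SVD solver; split by `numpy` `default_rng(seed).permutation`;
  train size = round(0.7·n).
- Percentile ranks: average-tied, 100·(rank−0.5)/n.
- Deciles: stable argsort, `array_split` into 10 near-equal groups.
- Aggregate rounding: half-up (decimal), percentages at printed precision.
- Histogram bins aligned to multiples of the 0.1 bin width; numpy's closed
  right edge on the final bin.
- Germline fold change: inf/0 conventions at zero frequency; both-zero
  germlines omitted.

## Problem sizes

Test-suite and acceptance-script simulations use 200–5,000 clones and
2×10⁴–10⁶ reads per repertoire — sizes chosen so every planted-truth check
is stable yet the whole suite runs in well under a minute; they match the
scale at which the statistical claims (Spearman > 0.9, effect recovery
within 0.05) hold by design of the reference condition.

## Known limitations

- Exact anchor matching discards reads with framework sequencing errors;
  on real MiSeq data this lowers yield but not correctness of counts.
- The germline similarity metric (unit-cost edit distance) and its tie rule
  are package decisions; other reasonable metrics could assign borderline
  CDRs differently.
- The per-length linear model ignores inter-position interactions by
  construction.
- The population-coverage figures of allele panels are not computed here;
  the panel ships as configuration.
- The bundled amino-acid usage table and oligo adaptor/flank defaults are
  synthetic stand-ins; production runs must supply real configuration.
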