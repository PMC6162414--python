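# Methods

## The question the pipeline answers

miRNAs (guiding Argonaute) and RNA-binding proteins both recognize short
sequence elements on a transcript. When their binding sites coincide or lie
very close, the two regulators can compete sterically for the same stretch
of RNA. Given a transcript, a set of mature miRNAs and a set of RBP motifs,
the pipeline asks, for every (RBP, miRNA) pair: *do their predicted binding
sites co-occur more often than expected for a sequence of this composition?*

## Scanning stage

**miRNA sites.** The seed is bases 2–8 of the mature miRNA. A site is an
occurrence of the seed's reverse complement on the transcript strand,
classified into the canonical types — 8mer (full 7-nt match + A), 7mer-m8
(full 7-nt match), 7mer-A1 (6-nt core + A), 6mer (6-nt core). Only
Watson–Crick pairing counts; G:U wobbles are not seed matches. Each 6-nt
core occurrence is one locus, reported once with the highest-priority
supported type (8mer > 7mer-m8 > 7mer-A1 > 6mer). This is a deliberate,
verifiable simplification of full miRNA target predictors: context
features, 3'-supplementary pairing and conservation are out of scope.

**Energetic filter (ddG).** Each site can carry a stability score: the
seed:target duplex free energy from the Watson–Crick nearest-neighbor
stacking parameters of Xia et al. (1998), shipped as
`data/nn_stacking.json` (kcal/mol at 37 °C, one value per 5'→3'
dinucleotide step; the trailing A of 8mer/7mer-A1 sites is recognized
unpaired and contributes nothing). In the accessibility-based formulation
ddG = dG_duplex − dG_open; the default energy model sets dG_open = 0, so
the cutoff (default −6 kcal/mol, more negative = more stable) applies to
the duplex term alone. This is the single largest simplification in the
scanner; it is isolated behind `mirna_scan.ddg_score` /
`mirna_scan.duplex_dg` so an accessibility model can replace it. Under the
default model ddG depends only on (seed, site type), which the permutation
engine exploits by precomputing it. Search modes: `seed_only` (no filter),
`energy`/`intersection` (seed match **and** ddG ≤ cutoff), `union` (all
seed matches, ddG annotated).

**RBP sites.** Motifs are position frequency matrices (MEME minimal or a
TSV dialect; one motif = one RBP name). Windows are scored with the
log-odds matrix log2(p̂(i,b)/bg(b)) in bits, p̂ pseudocount-regularized
(default pseudocount 0.01). The window score's exact null distribution
under the 0-order background is computed by convolving per-position score
distributions on a discretized grid (default bin 0.01 bits), giving an
exact p-value P(score ≥ s); windows with p ≤ cutoff (default 0.01, ties
kept) are sites. The scanner scores with the *same* discretized matrix the
distribution is built from, so scan scores and p-values are mutually
consistent and exactly reproducible against exhaustive 4^k enumeration.
All overlapping windows are reported; merging would silently change the
downstream co-occurrence counts. Because the distribution is discrete, the
attained false-positive rate at the threshold is ≤ the cutoff, typically a
factor 2–4 below it for sharp motifs — relevant when predicting expected
site counts.

## Evaluation stage

Two sites co-occur at distance d when, with gap
g = max(starts) − min(ends), g < d or g < 0: at d = 0 they must share at
least one base; d > 0 additionally admits gaps up to d − 1 (allowed range
0–100). The observed count O for a pair is the number of co-occurring
(miRNA site, RBP site) *pair events* — one miRNA site near two RBP sites
counts twice — computed by a sorted sweep that is contract-equal to the
all-pairs check.

The null model shuffles the transcript's nucleotides uniformly (identical
mononucleotide composition; an Altschul–Erickson dinucleotide-preserving
shuffle is available behind `preserve_dinucleotides`, default off).
Replicate i uses seed `base_seed + i`, so any replicate is independently
reproducible. The full scanning stage is re-run on each of N shuffles
(default N = 5000; RBP score distributions depend only on motif and
background and are cached). With K = #{i : Ci ≥ O} (ties count toward K),

    p = K / N,

reported exactly, including p = 0 (the tables carry `p_floor = 1/N`; a
(K+1)/(N+1) correction is available behind `pvalue_correction`, default
off). Pairs with O = 0 are not tested — their p-value would be
uninformative and would dilute the FDR. Benjamini–Hochberg q-values are
assigned per transcript by default; `global_fdr` pools all transcripts'
p-values into one correction for collection-level runs.

### Calibration, and what "tested pairs" means

On sparse null sequences (a 1 kb i.i.d. transcript carries ~0.24 expected
seed sites per miRNA), a pair enters the tested set precisely when its
miRNA site occurred by chance, while the shuffle null is unconditional.
The fraction of *tested* pairs reaching p ≤ α is therefore structurally
above α — a selection effect, not a defect of the permutation machinery.
The calibrated quantity is the rejection rate over all examined pairs
(untested pairs are never rejected), bounded near
(⌊αN⌋ + 1)/(N + 1) by exchangeability of the real sequence among its
shuffles; `experiments.type_one_error_rate` reports both numbers. By the
same mechanism, at stringent settings the significant set on real-scale
collections contains single-event pairs (O = 1, p = 0): interpret
small-O discoveries with the `p_floor` column in hand.

The calibration experiment itself runs at distance 100 and RBP cutoff 0.05
(chosen so null co-occurrence counts are non-degenerate; at the stringent
profile a 1 kb null transcript yields almost no events and nothing to
calibrate), with 200 transcripts × N = 200.

## Synthetic data

`synthetic_data` generates every test input: i.i.d. transcripts with a
chosen base composition, Dirichlet random motifs (low concentration =
sharp), uniform random miRNAs, and planted fixtures. Plants overwrite
background bases at fixed coordinates (recorded in a truth table): the
exact 8mer site string of a miRNA plus a motif's consensus at a
configurable gap; overlapping plants must agree letter-for-letter
(negative gaps are engineered by constructing the motif consensus to start
with the site's terminal A). The power preset plants 10 exact-overlap
events of one pair in 2 kb plus decoy regulators; the landscape preset
plants one shared pair across a subset of transcripts and one distinct
private pair per ~500 nt so that significant-pair counts grow with length
(the shared pair's host transcripts are spread across the length range).
The generator emulates only 0-order composition — no splice structure,
repeats, compositional domains or realistic lncRNA word statistics — so
passing tests demonstrate correctness and calibration of the statistic,
not biological accuracy of the simplified scanners on real transcripts.

## Numerical and design choices

* Coordinates are 0-based half-open internally; output tables are 1-based
  inclusive and say so in a header comment.
* PWM discretization at 0.01 bits keeps p-value discretization error
  < 1e-3 for k ≤ 12; impossible bases (pseudocount 0) are tracked as
  excluded mass, never as finite scores.
* Ambiguity codes in input sequences are rejected, not randomized —
  randomization would make the permutation null irreproducible.
* Degree ties in network hub lists break lexicographically; the
  largest-component fraction is over nodes. RBP and miRNA node namespaces
  are kept disjoint internally so a shared name cannot merge two nodes.
* Determinism contract: identical inputs + `base_seed` give byte-identical
  pair/site tables and GraphML.
* Problem sizes used by the standing experiments: calibration 200 × 1 kb
  at N = 200; power 20 replicates × 2 kb at N = 1000; landscape 16
  transcripts (0.8–3.8 kb) at N = 500 and RBP cutoff 0.05 (chosen so every
  pair's null co-occurrence rate exceeds the permutation resolution 1/N;
  sharper cutoffs let one-event pairs reach p = 0 spuriously).
  Published-style runs use N = 5000.

## Known limitations

* The ddG term omits target-site accessibility entirely (dG_open = 0).
* The PWM scanner replaces weighted-rank/conservation scoring of dedicated
  RBP site predictors; only (interval, p-value) semantics are preserved.
* One motif per RBP name; supply paralogous motifs under distinct names.
* The permutation null conditions on mononucleotide composition only;
  dinucleotide-preserving shuffling is optional and slower.
* p-values are granular at 1/N; at N = 5000 the smallest nonzero p is
  2e-4, and q-values inherit that granularity.
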