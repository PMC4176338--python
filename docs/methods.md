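# Methods

## The composition null model

The census asks whether particular XPPP motifs (a residue X followed by a
run of ≥ 3 prolines) are over- or under-represented in a proteome.  Under
the null hypothesis that residues occur independently with their global
frequencies, the expected number of XPPP motifs is

    E[XPPP] = p^n · x_X · g

with `p` the proline fraction, `x_X` the fraction of residue X, `g` the
proteome size in amino acids, and `n` the number of prolines in the motif
(`n_pro`, default 3).  `n_pro` is exposed as a parameter: `n_pro = 2` gives
the corresponding XPP null.  Only the 20 standard amino acids enter `p`,
`x` and `g`; ambiguity codes (B, J, O, U, X, Z) are kept in sequences so
positions stay aligned, but are excluded from the counts, and any non-P
character — including ambiguity codes — breaks a proline run.

The formula deliberately ignores edge effects: it multiplies by the whole
proteome size `g` rather than summing `L_i − n` over proteins, and it does
not condition on the following residue being non-proline (maximality).
Both corrections are of relative order `1/L` and `p` respectively and are
captured empirically by the shuffle null (below); keeping the single-formula
null makes the analytic expectation transparent.

### Counting conventions

Two census modes are implemented:

* `per_run` (default): each *maximal* run of ≥ `min_run` prolines
  contributes exactly one occurrence to the residue at its −1 position.
  Runs that begin at the N-terminus have no −1 residue and are tallied
  separately under a terminus marker, never under any X.
* `windowed`: every 4-mer window `[not-P]PPP` contributes to its leading
  residue, and every `PPPP` window contributes to X = P.  This is the right
  convention when PPPP itself is treated as an XPPP motif with X = P.

`per_run` is the default because the biological unit is the stall site:
a protein with a single TPPPP stretch stalls once, at one site.

### The shuffle null

`shuffle_null` permutes the residues *within each protein* independently
(preserving per-protein length and composition), recounts motifs, and
reports the replicate mean plus a two-sided empirical p-value with the
add-one rule `(r + 1)/(n_shuffles + 1)`, where `r` counts replicates at
least as far from the null mean as the observed count.  Within-protein
permutation was chosen over whole-proteome permutation because it preserves
the length distribution and per-protein composition, which is the exchange
that the analytic null idealizes.  On proteomes of ≥ 10^5 residues the
shuffle mean agrees with `p³·x·g` within three standard errors of the
replicate mean (this is a tested property).

## The −1 context classifier

The default class sets encode only what both reporter systems (NlpD- and
CadC-based LacZ fusions) agree on:

* weak (stalling suppressed): C, T, G, L, S
* strong (stalling promoted): E, H, K, Q, R, W, Y, P
* intermediate: the remaining seven residues (A, D, F, I, M, N, V)

A, in particular, behaves as a weak staller in one reporter context and a
strong one in the other, so ambiguous residues default to intermediate, and
both sets are configurable (`--weak/--strong` on the CLI).  A run with no
−1 residue (N-terminal) is labelled `no_context`.  A protein's overall
class is the strongest among its runs (strong > intermediate > weak >
no_context).

The weak-context filter defaults to the `all_weak` policy: a protein is
removed iff every run that has a −1 residue is weak-context *and* at least
one such run exists.  Removing a protein that also carries a strong-context
motif would defeat the purpose of the filter (isolating EF-P-dependent
proteins), and a protein whose only run is N-terminal offers no context
evidence either way, so it is kept.  The `any_weak` policy is available by
flag; `all_weak` removals are always a subset of `any_weak` removals.

## SILAC re-analysis

Ratios are stored log2-transformed and inverted so that negative values
mean down-regulation in the deletion strain; a `flip` flag accommodates
tables in native H/L orientation.  The removal-shift statistic is the
change in *median* of the PPP-protein ratio distribution after removing the
weak-context proteins.  The median (with midpoint interpolation, also used
for the quartiles) was chosen over the mean because ratio distributions are
heavy-tailed and the scientific claim is about the distribution's location.
Histograms use 0.25-log2-unit bins on [−6, 6] with open-ended tails.

Significance comes from a permutation null that removes the same number of
proteins uniformly at random from the PPP set and counts replicates whose
median shift is at least as negative as the observed one (one-sided,
add-one rule).  This permutation formalization is this package's own — the
comparison it quantifies was originally made by visual inspection of
distributions — and the output labels it as such.  The strain contrast
flags a strain when the filtered PPP median lies more than a threshold
(default 0.5 log2 units, roughly the separation visible between background
scatter and a convincing down-shift; configurable) below the all-protein
median.  The four strain contrasts (Δefp, ΔyjeA, ΔyjeK, ΔyfcM) are planned
comparisons and are reported without multiplicity correction.

## Reporter statistics

Toeprint stalling efficiency treats band intensities as already
background-subtracted inputs (densitometry is out of scope) and computes
`100·(I_site1 + I_site2)/(I_site1 + I_site2 + I_trap)`, where the two stall
bands correspond to ribosomes with peptidyl-Pro-Pro-tRNA (XPP/P) and
peptidyl-PPP-tRNA (XPPP/Z) in the P site, and the trap band to ribosomes
arrested at a downstream glutamine codon by glutamine starvation.  The
statistic is invariant to rescaling all three bands.

Relative β-galactosidase activity is `100·(fusion Δefp/wt)/(control
Δefp/wt)`: the activity ratio of the motif fusion between Δefp and
wild-type strains, normalized by a motif-free control construct assigned
100%.  With this orientation stronger stalling gives *lower* values, so
the weak→strong context gradient maps onto a single descending axis; the
reciprocal orientation is available via `invert`.  Replicate tables are
summarized per construct as n, mean and sample standard deviation (missing
for n = 1).

## Synthetic data

The generators define the study conditions for every test:

* **Proteomes** draw residues i.i.d. from a configurable composition
  (default `ECOLI_LIKE_COMPOSITION`, frequencies shaped like a bacterial
  proteome with p ≈ 0.044) with lengths normal(mean, sd) rounded and
  floored.  Planted motifs are inserted at uniform positions such that the
  run is maximal — the −1 residue is the requested X, the +1 flank is
  forced non-proline — and plants never overlap, so per-run census recovery
  of plants is exact by construction; accidental background runs add on top
  and are found by scanning.
* **SILAC tables** draw each PPP protein's ratio from
  normal(class_mean[class][strain], σ) and background proteins from
  normal(0, σ).  The recovery suite uses 50 weak (mean 0) and 50 strong
  (mean −1.5) proteins with σ = 0.3 — a separation of the size that makes
  the removal shift unambiguous while keeping within-class overlap
  realistic — giving an expected median shift of ≈ −0.75 after removing the
  weak half.
* **Reporter tables** multiply true band intensities / activities by
  independent unit-mean log-normal noise with a given coefficient of
  variation; CV = 0 reproduces the true statistic exactly.

What the generators do *not* emulate: real proteomes are not i.i.d. in
composition (codon bias, domain structure, low-complexity regions), SILAC
ratios have missing proteins and heavy non-Gaussian tails, and real band
intensities share lane-level noise.  Passing recovery tests therefore
demonstrates correctness of the computations under known truth, not that
real data will show effects of these sizes.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run at desk scale: 210 proteins
× mean length 500 (≈ 10^5 residues) for the null-model cross-validation
with 500 shuffle replicates; 1,000 random sequences for the oracle
equivalence check; 100 PPP + 1,000 background proteins with 999
permutations for the removal shift.  All randomness flows through
`numpy.random.default_rng` seeds; seeded runs are byte-identical across
invocations.  Degenerate inputs fail loudly: empty proteomes, all-zero
band intensities, removals that empty the PPP set, and permutation counts
below zero all raise `ValueError`, and malformed FASTA/TSV inputs raise
format errors naming the offending record.

## Known limitations

* The analytic null ignores protein boundaries; for very short proteins or
  very long motifs use the shuffle null.
* Quantitative stalling strength (bar heights, rate constants) is out of
  scope: the context model is a three-class label, not a regression, and
  positions −2…−5 — which show a monotone but weaker influence — are
  recorded in each run's upstream window but not scored.
* MaxQuant output parsing, densitometry and Miller-unit computation from
  raw OD curves are upstream of this package: it consumes id → ratio and
  band-intensity tables.
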