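# Methods

## Statistical model

The analysis treats each polarized SNP as one mutation drawn from a
process whose rate may depend on the ancestral word around the site. For a
context `C = {mut|pos, W}` and subcontext `S = {mut|pos', W'}`, the ratio
`P_W / P_W'` of word frequencies estimates the probability that an
occurrence of `W'` extends to `W`; under context-independent rates it
equals the expected count ratio `N_C / N_S`, so

    contrast(C, S) = (N_C / N_S) / (P_W / P_W')

is 1 in expectation under the null. *Mutation bias* is the contrast
against the 1-letter subcontext; *minimal contrast* is the contrast
closest to 1 over all contiguous subcontexts, i.e. the excess no single
subword accounts for. Dinucleotide contexts have exactly one subcontext,
so their two summaries coincide.

Significance uses the conditional binomial: given the `N_S` subcontext
mutations, each falls in `C` with probability `q = P_W / P_W'` under the
null, so `N_C ~ Bin(N_S, q)`. The reported p-value is the one-sided tail
in the observed direction. The default threshold is 1e-15 with the family
size (13 728 context/subcontext pairs for lengths 2–4) reported alongside
("paper" mode); a conventional `alpha/m` mode is available. Sampling noise
in the two frequency estimates can push `q` marginally above 1; it is
clamped to 1 up to a tolerance of 1.25 and treated as a data inconsistency
beyond that.

Assumptions worth stating: mutations are independent across sites; shared
ancestral polymorphism is negligible (two-outgroup parsimony would need
three extra mutations to be misled); word frequencies are stationary
across the regions contributing SNPs; and the data are strand-unaware, so
every context is reported together with its reverse complement rather than
collapsed onto a canonical strand.

## Inclusion criteria and polarization

A SNP is used only if: exactly two alleles; one allele equals the
orthologous base in *both* outgroups; both 21 bp outgroup windows present;
no gap or N in any window; at most 1 human–chimp and 6 human–orangutan
mismatches over the 20 flank positions (the site itself is not counted —
for orangutan as well, a symmetric choice the criteria leave open); and
perfect human–chimp identity over the ±3 bp around the site. Region
exclusion removes SNPs inside genes, within 1000 bp of a gene, or inside a
CpG island (BED3 inputs, 0-based half-open; all internal coordinates
0-based). All failed criteria are reported, and rejected records are
tallied under their first failed code so the run log conserves counts.
The accepted record's window is *ancestralized* (ancestral base at the
center): contexts describe the sequence a mutation arose in, not the one
it produced.

## Counting and frequencies

Every record contributes one count to each context whose word can be
placed over its window with the site at the context position (10
placements for lengths 1–4). Word frequencies come from the two 5 bp
intervals at −10…−6 and +6…+10 relative to the site — far enough that
they are independent of the ≤4 bp context under test in an i.i.d. genome
— with placements kept strictly inside each interval, pooled over all
records and both intervals before normalizing per length; or, as a
control, from a sliding whole-genome count (vectorized k-mer codes;
windows containing non-ACGT are skipped). Flank intervals support word
lengths up to 5 only; longer words are a configuration error.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes and
nothing more: an i.i.d. ancestral sequence; independent per-site,
per-target mutation probabilities `baseline × m`, where `m` is the
largest planted multiplier whose context word matches the ancestral
sequence at that site (largest-wins keeps truth interpretable where
planted words overlap); at most one SNP per site; outgroup windows equal
to the ancestral sequence plus i.i.d. substitution noise, never at the
site itself, so polarization is exact by construction and divergence only
erodes flank criteria. Under `strand_symmetric` (default) a planted
context is mirrored to its reverse complement; conflicting multipliers
for a mirrored pair are a configuration error.

Defaults, chosen once as desk-scale study conditions: human-like base
composition A=T=0.295, C=G=0.205 (GC ≈ 41%); baseline per-site per-target
probability 1e-3 (high for a per-generation rate, deliberately so — it
yields ~3 SNPs/kb so that megabase genomes give usable counts);
chimp-like divergence 0.01 and orangutan-like 0.03 per flank site;
`seed` makes output byte-identical across runs.

What it does **not** emulate: CpG depletion or any higher-order
composition (the ancestral genome is i.i.d., so e.g. CG dinucleotides are
at composition-expected frequency, several-fold above real mammalian
genomes), demography, selection, recombination, alignment error beyond
i.i.d. flank noise, indels, or shared polymorphism. Passing recovery
tests therefore demonstrate estimator correctness under the assumed
model, not robustness to real-data violations of it.

### Estimator attenuation

The mutation-bias denominator counts *all* mutations of the substitution
type, including those inside the context. For a planted multiplier `m`
on a context whose word occupies a fraction `f` of the 1-letter
subcontext's sites (for i.i.d. sequence, the product of the flanking-base
probabilities), the estimated bias converges to

    bias_observed = m / (1 + (m − 1) · f)

not to `m`. The package exposes `expected_observed_bias` and
`context_site_fraction` for this. Two consequences matter. For 4 bp
contexts `f ≈ 0.018` under the default composition and the attenuation is
~4%. For the CpG dinucleotide `f = p_G ≈ 0.2`, the maximum attainable
bias is `1/f ≈ 4.9`, and a planted 5.1 yields an observed bias near 2.8;
measured biases on real, CpG-depleted genomes (`f ≈ 0.05`) are likewise
attenuated estimates of the underlying mechanistic rate ratio. This is a
property of the bias definition itself, not of the implementation.

## Distribution report

Cluster labels on the bias/minimal-contrast plane are structural —
`cg-core` for the two CpG transition contexts, `cg-containing` for
contexts having one as a subcontext, `top-outlier` by configurable
thresholds on both coordinates (defaults 2.5 and 1.5), else `main` — so
they are reproducible and invariant under complementation, rather than
the output of a clustering algorithm.

The bulk of minimal contrasts is summarized by a normal fitted with plain
sample moments on a central range (default 0.7–1.2; ≥30 values required).
Plain restricted moments estimate the *truncated* distribution's moments
— for draws from Normal(0.99, 0.12) restricted to that range they are
≈(0.982, 0.106) — a deliberate simplification over truncated-normal
inversion, kept because the fit is descriptive. Consequently the tail
comparison (default range 1.2–5.1, 10 equal bins, values beyond the range
folded into the last bin) is *conditional*: observed tail counts are
compared against the fitted normal's conditional bin probabilities scaled
to the observed tail total, by chi-square with pooling of bins expecting
<1 count and a 0.5 floor on expected values. An empty tail gives p = 1;
mass far beyond the bulk registers as a significant shape excess. An
absolute-mass comparison would reject every null simply because
restricted moments misestimate absolute tail mass.

## Numerical and design choices

* Positions are 0-based internally; identifiers render 1-based
  (`C>T|1,CG`), and that string form is the dictionary key across all
  modules and files.
* Minimal-contrast ties (two values equidistant from 1) resolve to the
  value below 1 — arbitrary but deterministic.
* Contexts with a zero count or an undefined frequency anywhere in their
  subcontext lattice are excluded from the ranked table and listed in a
  diagnostics file; no sentinel values. Minimal contrast is known to be
  unstable near such boundaries.
* Each ranked context's reported p-value is that of its minimal-contrast
  pair — the most conservative pair in its lattice.
* Per-run problem sizes: unit tests use 0.1–5 Mb simulations; the
  recovery and calibration checks use 40 Mb and the acceptance script
  80 Mb (≈240 000 SNPs), where the Monte-Carlo SE of a recovered 4 bp
  context bias is ≈3%.

## Known limitations

* Flank-based word frequencies carry sampling noise that the binomial
  model does not propagate; with them, null p-values are slightly
  overdispersed (the whole-genome control source is preferred for
  calibration checks).
* `bias_standard_error` is a delta-method count-only approximation; it
  omits frequency-estimation noise (~2% relative at the 40 Mb scale).
* The real-data input path expects precomputed orthologous windows (as
  from UCSC alignments); the package performs no alignment or liftover.
* Discontiguous context words (e.g. AT·G) are out of scope.
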