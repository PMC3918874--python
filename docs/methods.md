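# Methods

## The kinetic model

The package formalizes a qualitative mechanism — copy-number selectivity
of RNAi through hybridization kinetics — as the smallest reaction network
that distinguishes single from multi-copy and clustered from dispersed
loci. Species per locus family: local sense/antisense ssRNA (S_L, A_L),
bulk ssRNA (S_C, A_C), dsRNA (D) and siRNA (R). Per compartment holding
m_c copies:

    dS_L/dt = m_c·α_s − (e + δ_s)·S_L − φ·k·S_L·A_L / V_local
    dA_L/dt = m_c·α_a − (e + δ_a)·A_L − φ·k·S_L·A_L / V_local
    dS_C/dt = Σ e·S_L − δ_s·S_C − k·S_C·A_C / V_bulk      (sum over compartments)
    dA_C/dt = Σ e·A_L − δ_a·A_C − k·S_C·A_C / V_bulk
    dD/dt   = Σ φ·k·S_L·A_L/V_local + k·S_C·A_C/V_bulk − γ·D
    R       = γ·D·y / δ_r   at steady state

Tandem arrays, plasmid clusters and extrachromosomal elements share one
local compartment (n_compartments = 1); dispersed copies get one
compartment each (n = m), so a dispersed family has φ(1) = 0 in every
compartment and can only anneal in the bulk. The co-presence gate

    φ(m) = 1 − (1−q_s)^m − (1−q_a)^m + (1−q_s−q_a)^m

is the probability that at least one copy is engaged on each strand, under
independent per-copy engagement with probabilities q_s, q_a; it encodes
the fact that one copy cannot transcribe both strands simultaneously.
φ(1) = 0 identically and φ is non-decreasing in m.

Assumptions: well-mixed compartments (no explicit diffusion), first-order
export and decay, catalytic dicing, no Argonaute-mediated target slicing
feeding back on the ssRNA pools, and compartment-agnostic dicing — whether
dsRNA is processed in the nucleus or the cytoplasm is deliberately not
modelled, since the evidence does not resolve it; D is a single pool.

### Parameters (defaults; time in minutes, volumes in cell volumes)

| parameter | default | meaning / rationale |
|---|---|---|
| α_s, α_a | 0.1 /copy/min | initiation rates; moderate ncRNA-level expression |
| δ_s, δ_a | 0.2 /min | ssRNA decay, ~3.5 min half-life (unstable ncRNA scale) |
| e | 1 /min | export, fast relative to decay |
| k | 1e-3 vol/min | bimolecular annealing constant |
| V_local | 1e-4 | transcription-site neighborhood: a ~0.1 µm-radius zone is ~4×10⁻³ µm³ against a ~40 µm³ cell. This ratio sets the local concentration advantage (V_bulk/V_local ≈ 10⁴); a much larger local volume would let the 1/m multi-mapper dilution cancel the local advantage for weakly expressed families, leaving the model outside the regime in which copy number is selected at all abundance levels |
| V_bulk | 1 | the cell |
| γ | 0.1 /min | dsRNA processing |
| y | ⌊duplex length / 23⌋ | siRNA duplexes per dsRNA; siRNA length defaults to 23 nt (configurable 21–24) |
| δ_r | 0.05 /min | siRNA decay (stable, ~14 min half-life) |
| q_s, q_a | α·τ (τ = 2 min, capped at 0.49) | engagement probability = initiation rate × polymerase occupancy time |

The pervasive-transcription preset sets the per-copy initiation rate so a
single-copy locus holds 1/14 of an ssRNA molecule per strand at steady
state — the abundance scale of a tightly repressed locus (about one
molecule per 14 cells).

### Solver

The steady state is solved exactly rather than iteratively: within each
compartment class the two balance equations share the single annealing
flux u, giving one scalar quadratic c·u² − (c(a_s+a_a)+B)·u + c·a_s·a_a = 0
whose admissible root is computed in the numerically stable form
u = 2c·a_s·a_a / (P + √(P² − 4c²a_s a_a)); the local pair is solved first,
the bulk pair (fed by the summed export) second, and D, R follow by
back-substitution. This replaces a damped Newton iteration — the system is
small enough that the closed form is both faster and free of convergence
failure; a test verifies that the solution zeroes every balance equation
to 1e-10.

### Stochastic counterpart

The Gillespie simulation runs the same network with integer counts.
Transcript production is a constant-rate Poisson process (m_c·α per
compartment). Each copy carries an explicit engagement state
(idle / sense / antisense) switching as a 3-state Markov chain with
off-rate 1/τ and on-rates chosen so the stationary law is (q_s, q_a);
local annealing in a compartment is only possible while at least one copy
is sense-engaged and one antisense-engaged. The mean-field limit of this
closure is exactly the ODE system with factor φ, and a test checks
ODE/SSA agreement of mean siRNA within 3 SE in a high-count,
weak-annealing regime. With `phi_override` set, the engagement gate is
replaced by a constant — the mechanism-off variant used for null
calibration. Trajectories are deterministic given the seed.

## The synthetic data generator

`genome.build_genome` plants locus families (single, tandem, dispersed, or
tandem clusters on an extrachromosomal element) into an i.i.d. uniform
random background (GC 50%). Divergence between copies is substitution-only
(each copy independently mutated at divergence/2 from a family consensus,
so the pairwise difference rate is the nominal divergence) — indels are
excluded so copy alignment and copy-number ground truth stay exact.
`reads.sample_reads` draws reads multinomially over (copy, strand) cells
proportional to steady-state abundances, splitting a family's abundance
evenly across copies, with uniform start positions and error-free
sequences by default (an optional uniform substitution rate exists; the
0/1-mismatch distinction made little difference in the original analyses).
The pervasive background is modelled as 500 bp windows tiling unplanted
sequence, each holding the 1/14-molecule ssRNA level per strand.

What this does *not* emulate: realistic chromosome composition
(centromeres, telomeres, GC structure), indel divergence, transcript
isoforms and boundaries, library-preparation biases, adapter or quality
artifacts, and paired ends. Passing tests therefore demonstrate the
correctness of the pipeline's logic and the direction and detectability of
the copy-number effect under controlled conditions — not performance on
real libraries, where mappability, expression structure, and annotation
error add noise the generator deliberately omits.

## The analysis pipeline

Reads are placed by exhaustive exact (optionally 1-mismatch) substring
search on both strands; a read with several equally good sites is assigned
uniformly at random from a dedicated seeded RNG stream, which divides a
family's reads evenly amongst copies (the standard multi-mapper policy).
Reads are attributed to the 100 bp (or 50 bp) bin containing their 5′ end
— the usual small-RNA convention, chosen because the attribution rule for
boundary-spanning reads is otherwise underdetermined; it makes count
conservation exact. Copy number per bin is the arithmetic mean of the
multiplicities of the 20 bp segments starting in the bin, with
reverse-complement occurrences counted by default (reads map to either
strand, so an inverted repeat is multi-copy for mapping purposes); both
choices are flags, since mean-vs-median and strandedness of the original
segment remapping are not pinned down.

Bin-table preparation adds a pseudocount of 1 to both counts, excludes
bins above 100,000 raw total reads (the printed figure "10,0000" read as
100,000 — 10,000 would cut into moderately expressed bins that plainly
remain in the analysis; the cap is configurable) and flags user-supplied
exclusion regions, e.g. sequence that is single copy in an assembly but
high copy in the cell. Three normalization schemes are provided: total×CN
(totals corrected for multi-mapper dilution, siRNA left per producing
copy), none, and both×CN. The siRNA:total ratio uses pseudocounted raw
counts (raw division by zero otherwise) and is provably identical under
the `none` and `both×CN` schemes — any copy-number factor cancels — so the
top-ratio enrichment analysis is normalization-free; ratio ties are broken
by genomic position for determinism.

The rank-sum test is implemented directly (it is itself a deliverable):
exact enumeration of the permutation distribution of the rank sum for
groups of ≤ 8, and a tie- and continuity-corrected normal approximation
otherwise; both paths are validated against independent enumeration,
scipy's exact Mann–Whitney, and large permutation estimates. Student's
t-test (ORF-level siRNA comparison) comes from scipy.

The antisense census counts, per minimum-overlap threshold (50–500 bp),
ORFs with at least one opposite-strand feature overlapping them by at
least the threshold, once per class column, with ORF–ORF (convergent or
divergent gene pairs) tallied separately from ORF–ncRNA. CUTs and XUTs
count as unstable; SUTs as stable. The SUT→XUT re-classification rule
(drop a SUT whose same-strand reciprocal overlap with an XUT is ≥ 0.5) is
this package's parameterized choice; the historical collation did not
record its rule, so exact reproduction of published counts may require
adjusting `reclass_overlap_fraction`.

## Null calibration

The mechanism-off null forces the co-presence gate to a shared constant
and matches per-copy siRNA rates, so a copy behaves identically whether it
sits in a single- or a ten-copy family. Two subtleties make the naive
construction non-null even without a mechanism. First, if all bins of a
locus share one expression-rate draw, observations within a locus are
correlated and any independent-sample test over-rejects regardless of
groups; the null generator therefore draws per-bin rates i.i.d. from the
shared law. Second, background bins follow a different abundance law and
belong only to the single-copy group, so conditioning on *observed*
abundance (the category axis) mixes true abundances differently in the
two groups through Poisson noise alone; the calibration excludes the
background — the same composition effect that motivates discarding the
lowest abundance category as noise in the genuine analysis. Under this
construction the per-category rejection rate at α = 0.05 over 200
simulated tables sits inside the binomial 99% CI (measured 0.04–0.06).

## Problem sizes

The default end-to-end scenario plants 50 single-copy and 50 ten-copy
clustered families of 1 kb units (per-family total initiation rates drawn
log-uniformly from 0.2–2 /min on each strand, so both groups span several
abundance categories under every normalization scheme) in a ~1.2 Mb
genome, sequencing 200,000 total-RNA reads (50 bp) and 20,000 siRNA reads
(23 nt). Copy-number-track exactness is checked against a brute-force
k-mer count on a 100 kb genome with 1–8-copy families; the null
calibration uses 200 simulated tables; stochastic kinetic contrasts use 20
paired seeds of ~1500-minute trajectories. These sizes give the analyses
comfortable power (the weakest populated category is detected at
p < 10⁻³⁰) while a full test-suite run stays in the minutes range.

## Known limitations

- The kinetic closure is phenomenological: engagement gating approximates
  nascent-RNA retention near the site; no explicit nuclear/cytoplasmic
  dicing split; no trans-acting knockdown feedback.
- The mapper is exact/1-mismatch substring search — adequate for
  error-free synthetic reads, not a general aligner (no indels, splicing,
  or quality weighting).
- k-mer copy-number counting is exact and in-memory; genome sizes beyond
  tens of Mb would need a sketch- or index-based approach.
- Census reproduction of historical published counts depends on the
  undocumented SUT/XUT re-classification rule (see above).
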