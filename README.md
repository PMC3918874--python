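# endosirna

Simulation and genome-wide analysis of **copy-number-driven endogenous RNA
interference**.

Many protein-coding genes have an antisense non-coding RNA that overlaps
them in genomic coordinates; sense and antisense transcripts are perfectly
complementary and can anneal into double-stranded RNA, the substrate Dicer
processes into siRNA. Yet a minimal RNAi system does not attack all
sense–antisense pairs equally: loci present in many near-identical genomic
copies yield far more siRNA than equivalently expressed single-copy loci.
This package provides (a) a mechanistic hybridization-kinetics model of why
that is, and (b) the genome-wide, copy-number-aware analysis pipeline that
detects the effect in binned sequencing data — exercised end to end on
synthetic genomes with known ground truth, so every stage is testable
without downloads.

## The model

dsRNA forms by second-order annealing: per compartment of volume *V*
holding *n_s* sense and *n_a* antisense molecules, the flux is

    v = k · n_s · n_a / V

(on concentrations, both strands contribute a 1/V factor — the rate falls
with the square of the reaction volume). Each locus family transcribes
into a tiny *local* compartment around its transcription sites (volume
`V_local`, ~10⁻⁴ of the cell) and exports into the *bulk* cytoplasm
(`V_bulk`). A single copy can transcribe only one strand at a time, so
local annealing is gated by the co-presence probability that among *m*
copies of a compartment at least one is sense-engaged **and** one is
antisense-engaged,

    φ(m) = 1 − (1−q_s)^m − (1−q_a)^m + (1−q_s−q_a)^m,   φ(1) = 0.

Single-copy loci can therefore anneal only in the bulk, which is ~10⁴-fold
larger; clustered multi-copy loci anneal locally at high concentration.
dsRNA is diced at rate γ into `y` siRNA duplexes per molecule. Steady
states are solved in closed form; an exact Gillespie simulation of the same
network (with explicit per-copy engagement states) is the stochastic
counterpart.

On the analysis side, the pipeline reproduces the copy-number-aware
treatment of binned read counts: per-100-bp-bin siRNA and total-RNA counts
(multi-mapped reads assigned uniformly at random among their best sites), a
copy-number track from the multiplicity of overlapping 20 bp genomic
segments, pseudocounts, copy-number normalization schemes, Wilcoxon
rank-sum comparisons of single- vs multi-copy bins per abundance category,
and the siRNA:total-RNA ratio analysis — which needs no copy-number
normalization at all, because any such factor cancels in the ratio. An
antisense-overlap census of ORFs against the CUT/SUT/XUT ncRNA classes is
included.

## Worked example

Matched total output, one locus as a single copy vs ten clustered copies
(sense = antisense = 0.3 initiations/min in total):

```python
import dataclasses
from endosirna import KineticParams, steady_state

single = KineticParams(alpha_s=0.3, alpha_a=0.3, m=1)
multi = KineticParams(alpha_s=0.03, alpha_a=0.03, m=10, n_compartments=1)
for name, p in [("single", single), ("ten-copy cluster", multi)]:
    st = steady_state(p)
    print(f"{name:18s} ssRNA={st.ssRNA_total:8.3f}  dsRNA={st.D:8.4f}  siRNA={st.R:9.2f}")
```

```
single             ssRNA=   2.985  dsRNA=  0.0154  siRNA=     2.65
ten-copy cluster   ssRNA=   2.267  dsRNA=  0.7329  siRNA=   126.06
```

Both loci hold ~3 ssRNA molecules at steady state, but the clustered family
converts its transcripts into dsRNA ~50× faster (0.73 vs 0.015 molecules)
and accumulates ~48× more siRNA — copy-number selectivity from hybridization
kinetics alone.

The same contrast detected from sequencing data, end to end (10 single-copy
and 10 ten-copy families, 40k total + 4k siRNA reads):

```python
from endosirna import copy_number_scenario, run_scenario
from endosirna import stats as an

cfg = copy_number_scenario(seed=1, n_single=10, n_multi=10,
                           n_total_reads=40_000, n_sirna_reads=4_000)
res = run_scenario(cfg)
for c in an.category_compare(res.table):
    if c.applicable:
        print(f"{c.label:6s} n_single={c.n_single:5d} n_multi={c.n_multi:5d} p={c.p:.3g}")
e = res.enrichment
print(f"top 1% mean CN {e.mean_cn_top:.2f} vs bulk {e.mean_cn_bulk:.2f} (p={e.p:.3g})")
```

```
0-2    n_single=  139 n_multi=    2 p=1
2-4    n_single= 1938 n_multi=    8 p=3.55e-160
4-6    n_single=   22 n_multi=  331 p=0.000944
6-8    n_single=   65 n_multi=  664 p=4.02e-24
top 1% mean CN 9.97 vs bulk 3.74 (p=1.07e-14)
```

Rows are log₂ total-RNA abundance categories; within each adequately
populated category the multi-copy bins carry significantly more siRNA, and
the 1% of bins with the highest siRNA:total ratio is almost purely
multi-copy (mean copy number ~10 vs ~3.7 in the rest of the genome).

## Command line

A single `endosirna` entry point exposes the stages:
`simulate-genome`, `simulate-kinetics`, `simulate-reads`, `map`, `bin`,
`cn-track`, `analyze`, `overlap-census` and `reproduce` (the full chain
with a manifest of output hashes). Scenario configs are YAML or TOML; see
`examples/minimal.yaml`. Exit codes: 0 ok, 2 validation error, 3 numerical
error.

```sh
endosirna reproduce --config examples/minimal.yaml --seed 3 --out run/
```

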