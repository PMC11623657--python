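# Model and methods

`pcmat` implements a mechanistic account of how serum antibody affinity can
mature even though selection *into* the plasma-cell (PC) compartment is
affinity-permissive: germinal-center (GC) B cells of widely varying affinity
leave the GC as PC precursors at the same per-cell rate, but each emigrant
then executes a number of "inertial" divisions proportional to the T-cell
help it captured at export. High-affinity emigrants therefore found larger
PC families, and the PC pool — and the serum it secretes — becomes enriched
for high-affinity antibodies without any affinity bias in who leaves.

## The help chain

Three scalar maps form the causal chain, shared by GC selection and export:

  capture(a) = cmax · a / (a + K)           antigen captured at affinity a
  myc(c)     = m0 + k · c                   Myc proxy induced by capture c
  budget     = round(β · IL21 · myc)        licensed divisions (or Poisson)

`K` (default 4, on a scale where a typical naive clone has affinity 1 and
the high-affinity V-gene analog 3) is chosen above the founder affinity
range so capture remains discriminating over the simulated affinity span;
`m0 = 0.3` gives unselected cells a small baseline; `k = 1` and `β = 2`
put GC dark-zone bursts at 1–3 divisions. The IL-21 factor (default 3.5)
applies only to budgets assigned at GC export, reflecting cytokine-driven
amplification of post-GC PC expansion in extrafollicular foci; dark-zone
re-entry uses scale 1. Budgets are deterministic (`round`) by default —
the Poisson mode is available — and capped at 9 to bound family sizes.

## The discrete-time GC

One step is 12 h. Each step: (1) prePCs that have spent a full step mature
to PCs; (2) light-zone (LZ) cells compete for selection with probability
`min(1, f·w_i/Σw)` where `w_i = capture_i^T` (selection fraction
`f = 0.2`, temperature `T = 0.3` — soft, proportional selection rather
than strict ranking); selected cells receive a budget and move to the dark
zone (DZ); (3) DZ cells spend their whole budget as a burst of divisions
within the step (DZ inter-division times are short relative to 12 h), each
division mutating each chain with probability `mutation_rate = 0.2`, and
return to the LZ; (4) every LZ cell, independent of affinity, exports to
the prePC pool with probability 0.05 per step, fixing its help signal
(capture → Myc → IL-21-scaled budget) at that moment; (5) PCs with
remaining budget divide once per step without further mutation; (6) death:
GC cells at 0.04 per step, PCs at 0.12 per step plus lymph-node egress at
0.16 per step (both affinity-independent); a carrying capacity of 300 GC
cells is enforced by uniform random culling; (7) live PCs secrete into a
cumulative serum pool. Naive founder clones continue to enter the GC
(10 per step on average), the diversification that keeps late GCs from
sweeping to fixation. Egress models PC departure to circulation and bone
marrow; FTY720 in an intervention schedule sets it to zero, which is why
the 32-day treatment designs dose it.

## Receptors and hypermutation

Receptors are paired heavy/light amino-acid strings pre-aligned to
synthetic germline V segments (110 and 100 residues; the germline registry
is a randomly generated stand-in, not IMGT sequences). One germline,
the IGHV1-72 analog, carries the anchor residues W33/K59/Y99 so the
canonical affinity-enhancing substitutions W33L (×8), K59R (×2) and Y99G
(×2) can arise; those positions are mutational hotspots (30× weight) and,
when hit, yield the designated residue with probability 0.9, modeling the
strong recurrence of these single-nucleotide substitutions in the anti-NP
response. All other substitutions are lethal (30%), deleterious (40%,
×0.7 on affinity) or neutral (30%). Germline strings are never modified,
so mutation calling is an aligned diff.

## Interventions

All treatments act on schedule (step resolution): anti-CD40L stops
selection, DZ cycling, export and founder influx immediately and kills
GC/prePC cells within `delay_steps` (default 4 = 2 days); existing PCs
keep spending their budgets. TACI-Ig sets the PC death hazard to 1.
Doxycycline starts mCherry halving at each division (before it, the label
is constant); tamoxifen in the S1pr2 or Blimp1 driver instantaneously
ZSG-labels GC/prePC cells or PCs respectively, and labels are inherited
and never lost. DEC205-targeted antigen loads `dose · cmax` onto
DEC205-wt cells (10% of founders), overriding BCR capture at the next help
assignment only; the Myc and budget fixed at that assignment are recorded
for the dose-response readout.

## Analysis pipeline

The simulator emits an AIRR-style paired-chain TSV. The pipeline keeps
cells with exactly 1 heavy + 1 light chain, calls amino-acid mutations
against the germline ('.'/'-'/'X' positions skipped), flags cells whose
heavy V is the target gene and whose mutations include any of
{W33L, K59R, Y99G} (an `all` rule is available), and groups clones by
heavy V + J + junction length with ≥85% junction identity under single
linkage. Genotype nodes collapse identical (heavy, light) pairs within a
clone; prePCs count as GC cells for node composition. Diversity uses the
bias-corrected Chao1 estimator `S_obs + f1(f1−1)/(2(f2+1))` on clone
abundances. Division tracking gates each animal's PCs at the outer
quartiles of mCherry (rank-based, ties broken by cell id) and compares a
flag between gates with a paired two-sided t-test across animals; the
division–affinity coupling is the least-squares slope of division count on
log-affinity with a seeded 1000-resample bootstrap CI.

The avidity readout models plates bearing 7 or 28 hapten copies: a species
at concentration c with dissociation constant kd contributes
`n·c/(c + kd/n)` at valency n. The NP7/NP28 ratio is computed after
rescaling the mixture to unit total concentration — the in-silico analog
of measuring at a standardized dilution — which makes it scale-invariant
with analytic single-species limits 0.25 (kd→0) and 0.0625 (kd→∞).
Simulated antibodies have `kd = kd0/affinity` with `kd0 = 50`, placing the
simulated affinity range on the informative part of that curve. This
functional form is a deliberately simple monotone surrogate; no empirical
avidity value should be read quantitatively from it.

## Calibration and what the defaults represent

The defaults emulate an NP-OVA-like primary response in one draining
lymph node, scaled to desk size: GC capacity 300 (real GCs are 10–100×
larger), a PC pool of several hundred, 28 steps (14 days) by default.
Founder V genes are drawn uniformly from four heavy analogs (target-gene
baseline affinity 3, others 1, lognormal clone jitter σ=0.25). The
parameters above were fixed once, during generator design, so that the
day-14 state lands in the experimentally reported regime — roughly 40–60%
of GC cells and 60–70% of PCs carrying designated substitutions, with the
PC excess arising purely from differential post-export division — and so
that serum avidity is still rising between days 12 and 32. They are not
adjusted per analysis.

Scaling artifacts worth knowing about: with a 300-cell GC and amino-acid
genotypes, identical-sequence sharing between the GC and PC compartments
is heavily undersampled, so "mixed" genotype nodes hold a minority of PC
cells here (PCs are still far more concentrated in mixed nodes than GC
cells are, and mixed nodes are the largest — both asserted in tests); in
the full-size system most PCs sit in mixed nodes. Likewise the PC-only
node fraction is higher here than in a full-size dataset.

## Calibration harness

Type-I-error calibration (1000 replicate null experiments) and
coupling-slope recovery (n = 5000 cells × 10 replicates per slope) run on
a vectorized cohort sampler built from the same capture→Myc→budget
primitives rather than the full agent loop; the quantities under test are
properties of the analysis, not of GC dynamics, and the cohort form makes
thousands of replicates cheap. The sampler's default intercept (≈4
divisions) keeps Poisson-mean truncation at zero negligible, so the
generative slope is exactly the least-squares target.

## Determinism and numerics

One master seed drives fixed-label child streams (founders, selection,
budgets, mutation, export, death, measurement), so adding draws to one
subsystem does not perturb the others and identical (config, seed) yields
byte-identical output tables. Degenerate inputs are handled explicitly:
all-equal fluorescence is gated by deterministic tie-break and flagged;
constant affinity leaves the coupling slope undefined and flagged; a
paired t-test on identical samples reports statistic 0, p = 1; Chao1 is
defined at f2 = 0 via the bias-corrected form.

## Limitations

No spatial structure, no T-cell dynamics beyond the scalar help signal,
no transcriptome, no bone-marrow compartment, amino-acid (not nucleotide)
hypermutation without targeting-motif structure, a GC orders of magnitude
smaller than real ones, and an invented (if analytically well-behaved)
avidity readout. Passing tests show the model's mechanisms produce the
expected directional signatures under these synthetic conditions; they do
not validate parameter values against real repertoires.
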