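# Methods

This note documents the models, numerical choices and limitations behind
`evoscreen`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Chemostat model

A constant-volume vessel (V, litres) is fed at dilution rate D (h⁻¹) with
medium carrying fructose at S_f (g l⁻¹). Per genotype class *i* with Monod
growth μ_i(S) = μ_max,i·S/(Ks + S):

    dX_i/dt = (μ_i(S) − D)·X_i
    dS/dt   = D·(S_f − S) − Σ_i μ_i(S)·X_i / Y

Biomass X is carried in cells ml⁻¹ and the yield Y in cells ml⁻¹ per g l⁻¹
consumed, so the steady-state closed forms hold directly in those units:
S\* = Ks·D/(μ_max − D), X\* = Y·(S_f − S\*). The defaults (μ_max = 0.35 h⁻¹,
Ks = 0.05 g l⁻¹, Y = 1.25 × 10⁷ cells ml⁻¹ per g l⁻¹, S_f = 4 g l⁻¹) put
X\* at ≈4.9 × 10⁷ cells ml⁻¹ — the cell-density target the evolution
experiment was designed around.

Integration is fixed-step classical RK4 (default dt = 0.01 h) for
deterministic, bit-reproducible trajectories; the system is not stiff at
these parameters, and a stability guard rejects dt·(μ_max + D_max) > 0.5.
Cell divisions accumulate as ∫ Σμ_i X_i · V·10³ dt (vessel totals), and
generations as ∫ μ̄ dt / ln 2 with μ̄ the population-mean growth rate —
which equals D at steady state, making the design-arithmetic function
`generations(schedule)` = ∫D dt / ln 2 the piecewise-exact limit. Batch
phases (D = 0) are simulated but contribute no generations.

Two genotype classes are tracked: the resident and one adaptive class with
μ_max scaled by (1 + advantage) — the experiment's accounting follows a
single winning lineage, and modelling clonal interference among multiple
adaptive lineages is out of scope. With stochastic seeding enabled, mutant
arrival is a thinned Poisson process on resident division increments
(default rate 10⁻¹¹ per division); each event seeds one founding cell.

The ramp of the experiment's dilution programme is published as a rate list
(0.08, 0.12, 0.14, 0.15, 0.18 h⁻¹) with a 220 h total; individual step
durations are not published, so `study_schedule()` divides the ramp into
equal-duration steps. Generation counts are insensitive to this choice at
the ~1 % level because the ramp contributes only ~12 % of ∫D dt. The feed
description "2.13 g l⁻¹ h⁻¹ at 50 ml h⁻¹" is consistent with D·S_f = 2.0
g l⁻¹ h⁻¹ only for V ≈ 470 ml; both volumes are accepted through the
schedule config and no default is asserted beyond the nominal 500 ml.

## Plate fermentation model

The forward model behind the synthetic screen integrates biomass X (g l⁻¹),
glucose G and fructose F with per-sugar Monod uptake, a fructose-preference
scalar p_f ∈ (0, 1], and exponential damping by cumulative consumption
E = (G₀−G) + (F₀−F), a proxy for accumulated ethanol:

    v_g = μ_glu·G/(K_g+G)·e^(−k_e·E),  v_f = p_f·μ_fru·F/(K_f+F)·e^(−k_e·E)
    dX/dt = (v_g + v_f)·X,  dG/dt = −v_g·X/Y,  dF/dt = −v_f·X/Y

Nothing moves before the lag. Defaults (μ = 0.12 h⁻¹, Ks = 2 g l⁻¹,
Y = 0.05, k_e = 0.03 l g⁻¹, lag 4 h, X₀ = 0.05 g l⁻¹) were chosen once so
that, from the screen's 50 + 50 g l⁻¹ sugar load sampled daily over 7 days,
a p_f = 0.65 parent goes dry at ~120 h with GLU/FRU ≈ 0.7 — the regime the
screen operated in. GLU/FRU is strictly increasing in p_f (verified by
direct integration), reaching exactly 1 at p_f = 1 by symmetry. Large k_e
produces stuck fermentations whose residual is mostly fructose, the
phenotype of ethanol-sensitive glucophilic isolates. The smooth exponential
damping (rather than a hard cutoff) keeps the RK4 solution four-th order
convergent; halving the step changes outputs by < 10⁻⁶ relative.

Plate noise is additive Gaussian truncated at zero (residual sugar cannot
be negative), default SD 0.5 g l⁻¹ — the plate-to-plate variability of the
0.2 ml screen is not quantified in the source experiment, so this is a
module choice, exposed as `noise_sd`. Each well draws from an independent
substream keyed by (seed, plate, well), so changing the layout does not
shift unrelated draws.

## Screen statistics

AUC is composite trapezoidal area of *residual* (not consumed) sugar versus
time, exact for piecewise-linear curves sampled at their breakpoints.
Replicates are averaged pointwise on the union time grid restricted to the
overlapping range *before* any AUC is taken — robust to a single aberrant
well, and identical to AUC-then-average for complete data by linearity of
the trapezoid. Missing interior values are linearly interpolated. Dryness
(< 2.5 g l⁻¹ total sugar) is evaluated at the final observed time only.

Candidate selection: an optional top-N shortlist by GLU/FRU (the historical
screen shortlisted 50; whether by top-N or a ratio cutoff is not published,
so `shortlist_n` has no default), then OFP ≤ `ofp_max` (default 1.0) and,
when required, GLU/FRU strictly above the in-plate parent's. Ties order by
lower OFP then isolate id. Control wells (parent, mixed population) are
consumed as references, not emitted as records; sterile wells are dropped.

## Variant QC

Filter expressions are evaluated with strict inequalities exactly as
written, no epsilon slack. A missing required field fails a freebayes or
LoFreq record with reason `missing:<field>` (conservative), while absent
GATK annotations do not trigger their clause — the convention for
annotations that are undefined on homozygous-reference-biased sites. The
engines are checked against an independent brute-force re-evaluation of the
boolean expressions on 10⁴ boundary-heavy random records. The freebayes
strand clauses use (SRF+SAF) and (SRR+SAR) — forward-total and
reverse-total fractions — verbatim; whether alt-only strand balance was
intended upstream is unknowable, so the printed form is implemented.

Multi-allelic records are split per alt allele before filtering, with depth
fields shared. Coordinates are 1-based VCF positions for sites internally,
0-based half-open (BED) for windows and segments on output. VCF I/O goes
through pysam; generated VCFs round-trip losslessly because the generator
quantises float evidence fields to values that survive htslib's float32
storage and 6-significant-digit text formatting.

Consequence annotation supports intron-less single-CDS genes only (the toy
genome has none); variants overlapping a CDS boundary raise an explicit
unsupported-case error rather than guessing. Substitution classes are
pyrimidine-anchored (G>A counted as C>T), making the spectrum invariant
under strand mirroring; the EMS footprint is the G/C→A/T transition
fraction.

LOH calling automates what was originally a visual inspection: maximal runs
of ≥ `min_sites` consecutive sites with AF ≤ `hom_low` or ≥ `hom_high`,
broken by any intermediate site or chromosome boundary. Defaults
(0.1 / 0.9 / 6 sites) are motivated by the six-SNP homozygous run the
original analysis flagged; all three are configurable. Copy-number windows
divide per-window depth by the genome-wide mean depth, so a CNV-free track
has mean exactly 1 by construction; deviant runs outside [0.6, 1.4] are
flagged. On a toy genome a large implanted CNV inflates the normalising
mean itself (a real yeast genome dilutes this), so recovered ratios for a
ratio-2 segment spanning ~4 % of windows land near 1.92 rather than 2.00.

## Uptake assay

Calibration is ordinary least squares of CPM on nmol with intercept
retained (background counts exist); amounts are ((CPM − intercept)/slope)/
DCW floored at zero, since retained label cannot be negative. Fold
comparisons use final-time amounts against a named reference and are
invariant to the calibration slope. Dry cell weight is treated as known;
its measurement variability is not modelled. Michaelis–Menten transport
kinetics are out of scope — the assay reports amounts, not Km/Vmax.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* the analyses assume:
two-sugar depletion curves with strain-specific fructose preference and
truncated plate noise; EMS-biased (G/C→A/T) heterozygous variant sets whose
evidence fields satisfy the freebayes filter at a requested rate, with
heterozygous sites at allele frequency exactly 0.5 and homozygous at 1.0;
Poisson depth tracks; linear calibration data. They do not emulate read-
level artefacts (mapping error, PCR duplicates, indel realignment noise),
linkage between variants, real yeast gene density or introns, or systematic
plate-position effects. Passing tests therefore demonstrate that the
pipeline's operations are correct on data obeying their stated assumptions,
not that the upstream callers or aligners would behave identically on real
sequencing data.

## Problem sizes

The shipped tests and the acceptance script use a 2 × 30 kb (variants) or
2 × 100 kb (CNV) toy genome, 1000-variant sets for fraction recovery,
54 isolates in quadruplicate across 3 plates for rank recovery, 20 random
chemostat draws at dt = 0.02 h, and 10⁴ random records for the filter
oracle — sizes at which every stochastic check is stable across seeds while
the whole suite stays fast.
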