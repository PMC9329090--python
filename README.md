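# evoscreen

A tested, reusable implementation of the analytical chain behind a
directed-evolution programme for improving fructose utilization in a
glucophilic wine yeast. Wine fermentations often stall with residual
fructose because *Saccharomyces cerevisiae* consumes glucose preferentially;
one route to more fructophilic strains is EMS mutagenesis followed by
continuous-culture evolution under fructose limitation, high-throughput
plate screening of evolved isolates, and genomic QC of the winners.
`evoscreen` packages every computational step of that chain and ships
seeded synthetic-data generators for all of its inputs, so the whole
pipeline is exercisable end-to-end without the (undeposited) raw data.

## What it computes

**Chemostat design arithmetic and simulation** (`evoscreen.chemostat`).
A chemostat at dilution rate *D* (h⁻¹) and volume *V* has feed flow *DV*;
at steady state the specific growth rate equals *D*, so generations
accumulate as ∫*D* dt / ln 2 and the Monod closed forms hold:

    S* = Ks·D / (μmax − D),   X* = Y·(S_f − S*)

`simulate` integrates per-genotype Monod growth (fixed-step RK4), accounts
cell divisions, and can seed adaptive mutants as a thinned Poisson process
at a configurable rate per cell division (default 10⁻¹¹).

**AUC-based fructophilicity screening** (`evoscreen.kinetics`).
Residual glucose/fructose time courses are reduced to trapezoidal areas
under the curve (AUC, g·h l⁻¹). The **GLU/FRU ratio** (glucose AUC over
fructose AUC; 1 = equally fast on both sugars) measures fructophilicity;
the **OFP ratio** (isolate total-sugar AUC over the in-plate parent's;
≤ 1 = at least as fast as the parent) measures overall fermentation
performance. `select_candidates` applies the two-criterion rule — OFP ≤ 1
and GLU/FRU above the in-plate parent — with an optional top-N shortlist.
A fermentation is *dry* when final total sugar is below 2.5 g l⁻¹.

**Variant QC** (`evoscreen.variants`). Caller-specific hard filters
evaluated with strict inequalities exactly as written (freebayes
`MQM>30 & MQMR>30 & QUAL>20 & DP>40 & (SAF+SAR)>4 & …`; LoFreq DP4-based
clauses; the GATK exclusion rule `QD<2.0 || FS>60.0 || MQ<40.0 || …`),
the EMS mutational footprint (fraction of SNVs that are G/C→A/T
transitions), zygosity accounting, coding-consequence annotation with
protein notation (E726K, Q20\*, frameshifts), allele-frequency tracks with
automated loss-of-heterozygosity run calling, and 1000-bp windowed copy
ratios normalised by genome-wide mean depth.

**¹⁴C-fructose uptake** (`evoscreen.uptake`). OLS calibration of CPM on
spiked nmol standards, conversion of scintillation counts to nmol per mg
dry cell weight, and fold-differences between strains at the final time.

**Synthetic data** (`evoscreen.synth`). Seeded generators for toy genomes
with gene models, EMS-biased heterozygous variant sets with caller evidence
fields, microfermentation plates driven by a two-substrate Monod model with
ethanol damping, Poisson depth tracks with implantable CNV segments, and
linear calibration data. Fixed seed ⇒ byte-identical outputs.

## Worked example

```python
import numpy as np
import evoscreen as ev

# the printed continuous-culture programme: 0.08 h⁻¹ ramped to 0.2 h⁻¹
# over 220 h, then held for the rest of the 1278 h experiment
sched = ev.study_schedule()
print(round(ev.generations(sched), 1))        # 347.8  (~350 generations)
print(ev.flow_rate(0.2, 0.5) * 1000)          # 100.0  (ml/h at D = 0.2)

# one screening plate: 18 isolates + parent + mixed population, quadruplicate
ids = [f"I{i:02d}" for i in range(1, 19)]
rng = np.random.default_rng(1)
params = {i: ev.StrainParams(fructo_pref=float(rng.uniform(0.5, 0.95)))
          for i in ids}
params["parent"] = ev.StrainParams(fructo_pref=0.65)
params["MP"] = ev.StrainParams(fructo_pref=0.70)
curves = ev.gen_plate(ev.quadruplicate_layout(ids, "P1"), params, seed=1)
records = ev.summarize_plates(curves)
chosen = ev.select_candidates(records)
print(len(records), len(chosen))              # 18 12
print(round(records[0].parent_glu_fru_ratio, 3))  # 0.696
```

The parent's GLU/FRU ratio of ≈0.70 reflects its glucophily (fructose AUC
larger than glucose AUC); the twelve selected isolates are those that both
ferment at least as fast as the parent (OFP ≤ 1) and are more fructophilic
than it.

A full synthetic end-to-end run (genome → variants → plates → screen →
uptake) is one command:

```
evoscreen demo --seed 1 --out demo_out
```

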