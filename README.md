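# penescreen

Screening for modifiers of incomplete penetrance of a cardiomyopathy
founder variant in family-structured population cohorts.

## The problem

The phospholamban founder deletion PLN:c.40_42delAGA (p.Arg14del) confers
a high risk of dilated/arrhythmogenic cardiomyopathy, yet many carriers
never develop symptoms. Finding out *why* — which phenotypes and which
genetic factors travel with the absence of symptoms — requires comparing
the rare asymptomatic carriers not just with symptomatic carriers but with
the asymptomatic general population, inside a biobank whose family design
makes every naive test anticonservative. `penescreen` is the analysis
pipeline for that design: it is aimed at statistical geneticists and
cardio-genetics groups who want to run the same screen on their own cohort
or probe its operating characteristics on simulated ones.

Every stage runs on synthetic cohorts with known ground truth, generated
by the package itself, so the full pipeline is reproducible without
restricted data.

## What it computes

* **Four-group classification** — asymptomatic/symptomatic ×
  carrier/non-carrier from questionnaire symptoms, ECG signs and (for
  carriers) cause of death; crude odds ratios with Wald intervals.
* **Kinship mixed-model trait screen** — per trait,
  `Y ~ age + age² + sex + PC1…PC4 + outcome + (1|ID)` with the random
  effect covariance `2Φ σ²_g` from pedigree kinship, fitted by block-wise
  eigendecomposition and 1-D profile REML; empirical q-values from a
  pooled permutation null in which only the trait vector is shuffled;
  directional confirmation contrasts; rank-normal and 1:4 age/sex-matched
  sensitivity re-runs.
* **Founder-haplotype window expansion** — grows a window around the index
  variant on the phased deletion-bearing chromosomes, freezing a side when
  adding a variant would split more than a threshold number of carriers
  off the modal haplotype; chi-square tests of the main haplotype groups
  against symptom status.
* **Genome-wide logistic scan** on an unrelated subset
  (`logit(outcome) ~ age + sex + PC1 + dosage`, group-specific MAF and
  INFO filters), with an LD-confound screen that flags which sub-threshold
  signals merely tag the founder haplotype (regressing −log10 p on r² with
  the deletion) versus independent suggestive hits.
* **Rare-variant burden tests** per region and frequency tier, with a
  label-permutation p-value that stays calibrated under ~40 cases vs
  ~20,000 controls, plus ten-segment subregion scans of significant
  regions.
* **Polygenic scores** — weighted allele-dosage scoring with allele
  matching and chromosome exclusion, percentile/extreme-tail group
  associations, and the `trait ~ age + sex + group + PGS + PGS:group`
  interaction model with per-group partial correlations.
* **Design power calculators** (Wald, log-OR) for the carrier design and
  the per-allele GWAS test, validated against simulation.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on one
study-scale synthetic cohort (~3,100 participants, 88 carriers of whom 54
stay asymptomatic; protective effects HR +6.41 beats/min, QRS −5.7 ms and
lnSDNN −0.216 injected into asymptomatic carriers; a 3× stronger
PGS→QRS response in symptomatic carriers) and write their tables under
`results/`:

```bash
cd analysis
python 01_simulate_cohort.py   # writes scratch/data/*.tsv|.vcf|.fam
python 02_classify_and_qc.py
python 03_protective_screen.py
...
python 08_power_and_calibration.py
```

Driver 02 prints the four-group table and its crude odds ratio — the
probability of being symptomatic is ~10-fold for carriers:

```
four groups: {'asymptomatic_noncarrier': 2844, 'symptomatic_noncarrier': 168,
              'asymptomatic_carrier': 54, 'symptomatic_carrier': 34}
crude OR (symptomatic | carrier) = 10.66 (95% CI 6.75-16.82, p = 2.95e-24)
```

Driver 03 runs the screen (B = 1000 permutations). The two strongest
injected effects come out at the q-value floor; lnSDNN, the weakest
injected effect (design |z| ≈ 2.3), narrowly misses in this single
replicate — borderline by construction:

```
        beta      se       p       q
HR    7.4284  1.5430  0.0000  0.0010
QRS  -6.0272  1.5194  0.0001  0.0010
lnSDNN -0.1275 0.0559  0.0225  0.0890
hits (q <= 0.05): ['HR', 'QRS']
step-2 verdicts:  HR confirmed, QRS not_confirmed
```

The HR verdict shows the confirmation logic passing (same direction in
carriers, null in the cross contrast); QRS shows it withholding — in this
replicate the 34 symptomatic carriers happened to drift low on QRS, so the
strict rule refuses to call the effect protective. Across 50 replicates
the screen recovers and confirms each injected trait in well over 80% of
runs (see the acceptance results below).

Driver 04 recovers the founder haplotype: the common-variant profile
(MAF ≥ 0.01, split threshold 3) returns a 1.37 Mb window with 83 of 88
carriers in one identical modal haplotype, the five implanted recombinants
splitting off. Driver 05 scans ~560 variants: genomic control λ = 0.98,
the only signals (p down to 8×10⁻¹⁵) are founder-region variants, and all
20 sub-threshold variants are flagged `founder_LD` by the confound screen
— none survives as an independent hit, matching the generating truth.
Driver 06 shows the same confound at the burden level: the founder region
is "significant" at the low-frequency tier (permutation p = 0.001) purely
because the shared haplotype carries its alleles, and the subregion scan
localizes it. Driver 07 detects the injected interaction:

```
PGS_QRS x group:  symptomatic_carrier beta 5.92, p = 0.004 (rank-normal 0.0045)
partial correlations: symptomatic_carrier 0.71 vs asymptomatic_noncarrier 0.39
```

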