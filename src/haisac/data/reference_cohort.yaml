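# Default calibration for the synthetic three-group cohort generator.
#
# Group means (SDs) are the published validation-cohort summaries for the
# HAI-SAC instrument across the three diagnostic strata: cognitively
# unimpaired (CU), mild cognitive impairment due to AD (MCI) and dementia of
# the Alzheimer's type (DAT).  The FD row of the published table duplicates
# the IADL row and cannot describe a {0,12} binary item; it is shipped
# verbatim for scale-level moment reproduction, while the item-level
# generator derives FD's Bernoulli probability from the informant subscore
# minus CD (see factor_model below).
groups:
  CU:
    n: 133
    male_proportion: 0.44361  # 59/133
    variables:
      age:          {mean: 72.15, sd: 7.38}
      education_years: {mean: 7.38, sd: 4.76}
      cdr_sb:       {mean: 0.35, sd: 0.32}
      npi_sb:       {mean: 2.64, sd: 3.45}
      iadl:         {mean: 7.79, sd: 0.55}
      casi:         {mean: 83.86, sd: 8.64}
      mmse:         {mean: 25.81, sd: 3.30}
      moca:         {mean: 21.07, sd: 5.10}
      haisac_total: {mean: 48.47, sd: 6.58}
      haisac3:      {mean: 33.95, sd: 4.53}
      cnocd:        {mean: 14.85, sd: 1.69}
      ml:           {mean: 9.04, sd: 3.07}
      rfo:          {mean: 10.06, sd: 1.57}
      haisaci:      {mean: 14.53, sd: 4.19}
      cd:           {mean: 2.71, sd: 3.80}
      fd:           {mean: 7.79, sd: 0.55}
  MCI:
    n: 231
    male_proportion: 0.38528  # 89/231
    variables:
      age:          {mean: 74.90, sd: 7.29}
      education_years: {mean: 5.78, sd: 4.43}
      cdr_sb:       {mean: 1.96, sd: 2.16}
      npi_sb:       {mean: 4.42, sd: 6.06}
      iadl:         {mean: 6.58, sd: 2.03}
      casi:         {mean: 73.12, sd: 15.93}
      mmse:         {mean: 22.24, sd: 5.20}
      moca:         {mean: 15.99, sd: 6.33}
      haisac_total: {mean: 38.94, sd: 10.53}
      haisac3:      {mean: 29.77, sd: 6.94}
      cnocd:        {mean: 13.88, sd: 2.32}
      ml:           {mean: 6.83, sd: 4.17}
      rfo:          {mean: 9.06, sd: 2.07}
      haisaci:      {mean: 9.18, sd: 6.36}
      cd:           {mean: 0.76, sd: 2.35}
      fd:           {mean: 6.58, sd: 2.03}
  DAT:
    n: 397
    male_proportion: 0.29975  # 119/397
    variables:
      age:          {mean: 81.17, sd: 7.81}
      education_years: {mean: 4.27, sd: 4.53}
      cdr_sb:       {mean: 7.17, sd: 4.58}
      npi_sb:       {mean: 6.16, sd: 9.18}
      iadl:         {mean: 2.20, sd: 2.53}
      casi:         {mean: 44.83, sd: 22.70}
      mmse:         {mean: 13.98, sd: 6.55}
      moca:         {mean: 7.21, sd: 5.40}
      haisac_total: {mean: 21.51, sd: 11.29}
      haisac3:      {mean: 19.42, sd: 9.27}
      cnocd:        {mean: 10.54, sd: 4.37}
      ml:           {mean: 2.51, sd: 3.55}
      rfo:          {mean: 6.37, sd: 3.29}
      haisaci:      {mean: 2.09, sd: 4.71}
      cd:           {mean: 0.12, sd: 0.98}
      fd:           {mean: 2.20, sd: 2.53}

# Two-factor latent structure for the item-level generator: a semantic-memory/
# contextual-binding factor (smcb) carried by the objective subtests and an
# informant factor (inf) carried by the two informant items; FD cross-loads.
# The inter-factor correlation is not published; 0.30 is a typical moderate
# oblique correlation for cognitive vs informant-report factors.
factor_model:
  items: [cnocd, rfo, ml, cd, fd]
  factors: [smcb, inf]
  loadings:
    cnocd: [0.95, 0.0]
    rfo:   [0.96, 0.0]
    ml:    [0.55, 0.0]
    cd:    [0.0, 0.97]
    fd:    [0.48, 0.45]
  factor_correlation: 0.30
  # Bernoulli probabilities for the binary informant items: CD from the
  # printed mean over its 8-point value; FD from (informant subscore mean
  # minus CD mean) over its 12-point value.
  cd_no_decline_prob: {CU: 0.33875, MCI: 0.095, DAT: 0.015}
  fd_no_interference_prob: {CU: 0.98500, MCI: 0.70167, DAT: 0.16417}

# Clipping bounds used by the bounded generation mode; variables not listed
# are clipped at zero only.
bounds:
  age: [60, 100]
  education_years: [0, 23]
  cdr_sb: [0, 18]
  npi_sb: [0, 144]
  iadl: [0, 8]
  casi: [0, 100]
  mmse: [0, 30]
  moca: [0, 30]
  haisac_total: [0, 60]
  haisac3: [0, 40]
  cnocd: [0, 16]
  ml: [0, 12]
  rfo: [0, 12]
  haisaci: [0, 20]
  cd: [0, 8]
  fd: [0, 12]
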