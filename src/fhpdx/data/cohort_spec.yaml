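# Default synthetic-cohort specification: per-level FNTA and radiographic
# parameter distributions (degrees; CSA in mm) for the four FHP levels.
# Per-level counts are a documented placeholder (the source cohort's
# per-level allocation is unpublished); they sum to 145.
seed: 0
truncate_fnta_to_level_range: true
levels:
  - level: 0
    n: 38
    fnta: {mean: 8.61, sd: 5.04}
    params:
      CSA: {mean: 19.61, sd: 10.62}
      CCA: {mean: 71.64, sd: 12.18}
      T1S: {mean: 12.88, sd: 10.12}
      CL: {mean: 14.18, sd: 17.67}
      CranT: {mean: 6.03, sd: 7.51}
      CervT: {mean: 7.64, sd: 7.88}
      C7S: {mean: 14.03, sd: 9.93}
      TK: {mean: 18.45, sd: 10.16}
  - level: 1
    n: 55
    fnta: {mean: 17.25, sd: 3.82}
    params:
      CSA: {mean: 19.20, sd: 10.38}
      CCA: {mean: 76.25, sd: 11.19}
      T1S: {mean: 10.67, sd: 8.09}
      CL: {mean: 10.11, sd: 13.46}
      CranT: {mean: 5.76, sd: 5.82}
      CervT: {mean: 6.08, sd: 7.75}
      C7S: {mean: 12.72, sd: 7.97}
      TK: {mean: 16.59, sd: 10.21}
  - level: 2
    n: 36
    fnta: {mean: 31.24, sd: 4.36}
    params:
      CSA: {mean: 19.62, sd: 7.76}
      CCA: {mean: 76.55, sd: 8.50}
      T1S: {mean: 13.76, sd: 10.51}
      CL: {mean: 8.07, sd: 13.44}
      CranT: {mean: 5.97, sd: 4.72}
      CervT: {mean: 7.76, sd: 9.22}
      C7S: {mean: 16.03, sd: 10.58}
      TK: {mean: 20.72, sd: 10.74}
  - level: 3
    n: 16
    fnta: {mean: 54.71, sd: 12.34}
    params:
      CSA: {mean: 22.14, sd: 9.75}
      CCA: {mean: 64.86, sd: 13.55}
      T1S: {mean: 13.00, sd: 11.37}
      CL: {mean: 16.71, sd: 26.32}
      CranT: {mean: 12.29, sd: 7.48}
      CervT: {mean: 3.43, sd: 7.57}
      C7S: {mean: 14.71, sd: 12.65}
      TK: {mean: 17.43, sd: 15.02}
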