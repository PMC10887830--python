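# fhpdx

Screening and preliminary diagnosis of **forward head posture (FHP)** in
adolescents from the **forward neck tilt angle (FNTA)** — the angle between
the vertical and the line joining the tragus of the ear to the acromion of
the shoulder, measured externally with a depth sensor — backed by an
ensemble of linear boundary-line models fitted against eight radiographic
sagittal-alignment parameters (CSA, CCA, T1S, CL, CranT, CervT, C7S, TK).

The package is aimed at musculoskeletal researchers and clinical-screening
tool builders who want to reproduce, stress-test or refit this diagnostic
procedure without access to the original cohort: it ships the published
boundary constants and evaluation sheet, and a seeded synthetic-cohort
generator with the published per-level distributions.

## The model

Screening bins FNTA into four levels by half-open intervals:
Normal `[0°, 12°)`, Level 1 `[12°, 25°)`, Level 2 `[25°, 40°)`, and
Level 3 `[40°, ∞)` — the level at which radiographic imaging is requested.

For each radiographic parameter *X* a diagnostic model holds three
classification lines in the (*X*, FNTA) plane, one per adjacent level pair,

```
0 = K + L1·X + L2·Y        ⇔        Y = −(K + L1·X) / L2,      L2 < 0,
```

each fitted as the two-class Fisher linear discriminant boundary (equal
priors, pooled covariance) between the adjacent levels. At diagnosis time
only the FNTA is available, so each line is reduced to its FNTA range
`[min Y(X), max Y(X)]` over its parameter-axis span: an FNTA below the range
is unambiguously on the lower-level side, above it on the higher-level side,
and strictly inside it *ambiguous*, in which case both levels the line
separates become candidates. Each of the eight models votes for every level
in its candidate set; the diagnosis **D** is the level with the most votes
(ties resolve to the higher level and are flagged). Agreement between D and
the pure threshold classification **PC** is summarised as a percent ratio
and a 4×4 confusion chart with per-row TPR/FNR and per-column PPV/FDR.

## Worked example

Diagnose the packaged 43-participant evaluation sheet with the packaged
constants bank, then evaluate agreement:

```sh
$ fhp diagnose --out sheet.csv
diagnosed 43 participants -> sheet.csv
$ fhp evaluate --in sheet.csv --out eval.csv
agreement 95.35% over 43 participants -> eval.csv
```

`eval.csv` records the disagreeing participants — FNTA 11° (screened
Normal, diagnosed Level 1) and FNTA 25° (screened Level 2, diagnosed
Level 1) — and the confusion chart; both Level 3 participants (FNTA 52°
and 62°) are diagnosed Level 3, i.e. every radiology referral is caught.

The same from Python, for one borderline measurement:

```pycon
>>> import fhpdx
>>> bank = fhpdx.load_model_bank()
>>> res = fhpdx.vote_diagnosis(bank, 25.0)
>>> {p: c.notation() for p, c in res.per_model_candidates.items()}
{'CSA': '1', 'CCA': '1.2', 'T1S': '1.2', 'CL': '1.2', 'CranT': '1.2',
 'CervT': '1.2', 'C7S': '1.2', 'TK': '1.2'}
>>> res.vote_counts, res.pc_level, res.final_level
((0, 8, 7, 0), 2, 1)
```

An FNTA of exactly 25° screens as Level 2, but it lies inside seven of the
eight boundary ranges separating Levels 1 and 2 (only the CSA model calls
it a clear Level 1), so Level 1 wins the vote 8–7 — the kind of borderline
case the ensemble is designed to surface.

The full pipeline on synthetic data:

```sh
fhp simulate --seed 7 --out cohort.csv        # 145 participants, 4 levels
fhp fit      --in cohort.csv --out bank.json  # refit all 24 boundary lines
fhp diagnose --in cohort.csv --bank bank.json --out sheet.csv
fhp evaluate --in sheet.csv --out eval.csv
fhp report   --in sheet.csv --out confusion.png
```

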