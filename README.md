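# persym

Analysis pipeline for randomized trials whose primary endpoint is a
**participant-selected ("respective") symptom outcome**: each participant
nominates at baseline the symptom they most want improved, and that symptom's
instrument score — standardized within the subgroup of participants who chose
the same symptom — becomes a common, dimensionless primary outcome (mean 0 at
baseline, per-subgroup s.d. 1, lower = better).

The package covers the full methodology for a two-arm wait-list design:

| module | what it does |
|---|---|
| `persym.instruments` | Scoring/validation of the instrument battery: Chalder fatigue scale (0–3 Likert, total 0–33), MRC dyspnea grade, P4 pain scale, HADS, EQ-5D, free-text symptom VAS |
| `persym.outcome` | Subgroup baseline references, standardization, the respective primary-outcome table, label→core-symptom recoding for sensitivity analysis |
| `persym.randomization` | Marginal (Pocock–Simon) minimization with an 80:20 deterministic:random mix, audit log, balance simulation vs simple randomization |
| `persym.analysis` | Baseline-adjusted ANCOVA treatment effects, per-visit random-intercept model for 'other' symptom ratings, subgroup interaction (forest) tables, noncentral-t power/sample size, QALY AUC, productivity change |
| `persym.sensitivity` | MICE (PMM, within-arm) with Rubin/Barnard–Rubin pooling, inverse-probability-of-follow-up weighting, weight-change interaction ANCOVA |
| `persym.simulate` | Synthetic trial generator with known ground truth: cohort mix, minimization allocation, correlated follow-up with injected standardized effects, secondary outcomes, monotone deprivation-skewed attrition |
| `persym.cli` / `persym.io` | `persym` command-line surface and atomic CSV/JSON bundles with seed/config-hash manifests |

## CLI

```bash
persym simulate --n 234 --seed 7 --out scratch/trial        # synthetic trial
persym score    --main scratch/trial/main.csv \
                --other scratch/trial/other_symptoms.csv \
                --cohort scratch/trial/participants.csv --out scratch/scores
persym analyze  --main scratch/trial/main.csv \
                --other scratch/trial/other_symptoms.csv \
                --cohort scratch/trial/participants.csv \
                --out scratch/results --seed 7 --imputations 100
persym power    --delta 0.5 --power 0.90      # -> 86 per group
persym power    --delta 0.5 --n1 97 --n2 117  # -> 0.952
persym randomize --input profiles.csv --seed 3 --out alloc_log.csv
persym report   --bundle scratch/results
```

Every output directory is written atomically and carries a `manifest.json`
with the seed and a config hash; identical configs reproduce byte-identical
CSVs.

## Notes

- Scoring conventions: Chalder is Likert-scored (bimodal exposed as an
  option); instruments with any missing item are treated as missing (no
  proration); all instruments are oriented so higher = worse.
- Standardization references pool both arms and, for the 'other' stratum,
  pool all choosers' baseline main-symptom VAS (a per-label mode exists
  behind a flag). Degenerate strata (n < 2 or zero s.d.) raise by default;
  an explicitly labelled fallback borrows a pooled min-max-rescaled s.d.
- Main analyses are complete-case; missing data are addressed only in the
  sensitivity module (MICE, IPW).
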