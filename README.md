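# hrfph

Severity scoring for persistent pulmonary hypertension of the newborn
(PPHN), for neonatologists, pediatric cardiologists and clinical
researchers who need a single ordinal scale combining hypoxemic
respiratory failure (HRF) and echocardiographic pulmonary hypertension
(PH) — e.g. as inclusion criteria or endpoints in trials where death/ECLS
is too rare to power.

## The score

The HRF/PH score (0–15) is the sum of two sub-scores taken at the first
echocardiogram:

* **Oxygenation (HRF), 0–5.** Nasal cannula / HFNC: 0, or 1 if flow ≥ 2 LPM
  or FiO₂ ≥ 0.3. CPAP/NIPPV/IMV/HFOV: 2–5 by banded severity index —
  the oxygenation index **OI = FiO₂·100·MAP / PaO₂** when an arterial gas
  exists within 4 h of the echo, else the oxygen saturation index
  **OSI = FiO₂·100·MAP / SpO₂** from the preductal SpO₂ (right upper limb
  preferred). OI < 10 (OSI < 5) scores 2, increasing incrementally.
* **Echo (PH), 0–10.** IVS position grade (0–3) + TAPSE grade (0–3) +
  RVsP grade (0–3, from the TR jet via **RVsP = 4v²** relative to systemic
  systolic BP) + 1 for RV dysfunction. With no measurable TR jet, 2×IVS
  replaces the IVS + RVsP contribution.

Totals are categorised mild (0–5), moderate (6–10), severe (11–15). The
package also computes the vasoactive-inotropic score (VIS), severity-by-
outcome contingency tables with exact Freeman–Halton Fisher tests, robust
(HC1) linear regression for continuous outcomes, a deterministic 83-patient
cohort reconstructed from published category-level marginals, and a seeded
stochastic cohort simulator. Every threshold lives in a YAML-serialisable
`ScoreConfig`. See `docs/methods.md` for the full model description.

## Worked example

```python
from hrfph import (
    OxygenationObservation, EchoObservation, SupportMode, score_observation,
)

oxy = OxygenationObservation(
    mode=SupportMode.IMV, fio2=0.80, map_cmh2o=14,
    pao2_mmhg=42, gas_offset_hours=1.5,
)
echo = EchoObservation(
    ivs_grade=2, tapse_mm=7.2, tr_velocity_ms=3.4,
    rv_dysfunction=True, systolic_bp_mmhg=58,
)
result = score_observation(oxy, echo)
print(result.total, result.category.value)
print(result.hrf, result.ph)
for entry in result.audit:
    print(f"  {entry.component}: {entry.value} -> {entry.band} = {entry.grade}")
```

prints

```
12 SEVERE
5 7
  oxygenation:OI: 26.666666666666668 -> [25, inf) = 5
  echo:IVS: 2 -> ordinal 0-3 = 2
  echo:TAPSE: 7.2 -> [6, 8) mm = 2
  echo:RVsP/SBP: 0.7972413793103448 -> [0.666667, 1) = 2
  echo:RV_dysfunction: present -> present/absent = 1
```

The OI of 0.8·100·14/42 = 26.7 lands in the top oxygenation band
(5 points); the echo adds IVS 2 + TAPSE 2 + near-systemic RVsP 2 +
dysfunction 1 = 7, for a total of 12 — severe PPHN. The audit trail records
each band decision for chart review.

From the shell, the same pipeline over a CSV cohort:

```sh
hrfph fixture --out cohort.csv           # deterministic 83-patient cohort
hrfph score --in cohort.csv --out scored.csv
hrfph analyze --in cohort.csv --out report.csv   # + report.json
hrfph simulate --out sim.csv --seed 7 --n 2000
```

`report.csv` tabulates each outcome by severity category with Fisher exact
p-values, e.g. the death-or-ECLS row `0/5 (0%), 12/65 (18%), 10/13 (77%),
p = 5.1e-05`.

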