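# Methods

## The score

`hrfph` implements a 0–15 bedside severity score for persistent pulmonary
hypertension of the newborn (PPHN), combining hypoxemic respiratory failure
(HRF) and echocardiographic pulmonary hypertension (PH) into one ordinal
scale, scored once from the first echocardiogram.

**Oxygenation (HRF) sub-score, 0–5.** Infants on no support, nasal cannula or
HFNC score 0, or 1 when flow ≥ 2 LPM or FiO₂ ≥ 0.30. Infants on CPAP, NIPPV,
invasive ventilation or HFOV score 2–5 by band lookup of a severity index:
the oxygenation index OI = FiO₂ × 100 × MAP / PaO₂ when an arterial gas
exists within `gas_window_hours` (default 4 h) of the echo, otherwise the
oxygen saturation index OSI = FiO₂ × 100 × MAP / SpO₂ from the preductal
saturation (site preference: right upper limb > left upper limb > lower
limb; same-site ties resolved by proximity to the echo time, then by the
later reading). FiO₂ is a fraction (readers reject percent-scale values
loudly), MAP is mean airway pressure in cmH₂O, PaO₂ in mmHg, SpO₂ in %.

**Echo (PH) sub-score, 0–10.** Four components: the interventricular-septum
position grade (0–3, the cardiologist's ordinal read of the parasternal
short axis), a TAPSE grade (0–3, lower excursion worse), an RVsP grade (0–3)
from the peak TR-jet velocity via the simplified Bernoulli equation
RVsP = 4v² taken relative to the systemic systolic pressure, and RV
dysfunction (1 point when present). When no TR jet is measurable the IVS
grade is doubled and *replaces* the combined IVS + RVsP contribution. We
read the doubling rule this way, rather than as an addition on top of an
intact IVS term, because the additive reading would allow totals above 15
and contradict the score's stated 0–15 range; under this reading the
fallback agrees exactly with the jet-based path whenever the RVsP grade
equals the IVS grade (a tested invariant).

**Total and categories.** Total = HRF + PH, an integer in 0–15 (no rounding
can arise); categories are mild (0–5), moderate (6–10), severe (11–15), all
bounds inclusive.

## Band tables

Only the first oxygenation band (OSI < 5 or OI < 10 → score 2) is fixed by
the score's published description; the remaining interior cut points are
design choices, kept in a versioned `ScoreConfig` (YAML-serialisable,
unknown keys rejected) so they can be overridden without code changes:

| table | default bands | rationale |
|---|---|---|
| OI | [0,10)→2, [10,15)→3, [15,25)→4, [25,∞)→5 | anchored to the printed first band; the 15/25 cuts track the usual moderate/severe OI thresholds |
| OSI | [0,5)→2, [5,7.5)→3, [7.5,12.5)→4, [12.5,∞)→5 | OSI ≈ OI/2 convention |
| TAPSE (mm) | [10,∞)→0, [8,10)→1, [6,8)→2, [0,6)→3 | term-neonate reference values |
| RVsP/SBP | [0,0.5)→0, [0.5,⅔)→1, [⅔,1)→2, [1,∞)→3 | sub-half-systemic / mild / near-systemic / systemic-or-suprasystemic |

All bands are lower-inclusive, upper-exclusive, the top band closed above,
so each table tiles [0, ∞) with no gaps or overlaps by construction (a value
exactly on a cut belongs to the higher band — OI = 10 scores 3).

**VIS.** The vasoactive-inotropic score uses the standard weights
dopamine + dobutamine + 10·milrinone + 100·epinephrine + 100·norepinephrine
+ 10000·vasopressin (catecholamines and milrinone in µg/kg/min, vasopressin
in U/kg/min), configurable via `ScoreConfig.vis`.

## Cohort statistics

Dichotomous outcomes are tabulated by severity category and tested with
Fisher's exact test; continuous outcomes are summarised as median/IQR
(linear interpolation between order statistics) and compared across the
category ordinal (0/1/2) by OLS with HC1 sandwich standard errors
(statsmodels). Percentages are rounded half-away-from-zero for display.

`fisher_exact` handles any r × c table by full Freeman–Halton enumeration in
exact integer arithmetic: conditional on the margins each table has
probability proportional to the multinomial weight W = n!/∏aᵢⱼ!, and the
two-sided p under the point-probability rule is ΣW over tables with
W ≤ W_obs divided by ΣW over all tables. Because the comparison is between
integers there is no floating-point tie tolerance; on 2 × 2 tables the
procedure coincides exactly with the hypergeometric closed form. Rows and
columns with zero totals are dropped; a table reduced to a single row or
column is uninformative (p = 1); enumeration is guarded at n ≤ 500.
Exact *logistic* regression is deliberately not implemented: dichotomous
associations are tested by the Fisher exact test on the same table, and an
ordinary maximum-likelihood logistic fit is available, explicitly flagged
non-exact.

## Synthetic cohorts

Patient-level data behind the published cohort are not deposited, so the
package carries two synthetic substitutes.

**Deterministic fixture** (`reconstruct_fixture`): an 83-patient cohort
matching every published category-level marginal exactly — category sizes
(5, 65, 13); per-category counts for death-or-ECLS (0, 12, 10), ECLS
(0, 8, 8), death (0, 7, 7), iNO (1, 50, 13), vasoactive infusions
(0, 42, 13), invasive ventilation (1, 49, 13), HFOV (0, 41, 13); 53 males,
30 meconium aspirations, 5 lung malformations; and 8 of the 14 deaths on
ECLS, realised per category by inclusion–exclusion (moderate overlap 3,
severe 5: within a category ECLS fills the first *e* records and deaths
occupy records *e − overlap* … *e − overlap + d*). Each record carries raw
physiologic measurements (band midpoints) that score exactly to its
assigned total, so `analyze` runs the genuine pipeline, not a lookup.
Within-category score values (mild {2,3,4,5,5}; moderate cycling 6–10;
severe alternating 11/12) and the continuous outcome values (quartile ramps
through the published median/IQR anchors, deaths excluded as in the
published denominators) are *reconstructions, not targets*: only
category-level counts are published, and two IQR anchors (moderate ICU LOS,
severe VIS) are garbled in our source rendering of the table and were read
conservatively.

**Stochastic simulator** (`simulate_cohort`): draws a generating category
(default mixing 0.06/0.78/0.16), a target total from that category's score
range (2–5 / 6–10 / 11–12, the observed support), decomposes it into
component grades, and jitters each raw measurement around its band midpoint
with sd = `band_noise` × band half-width (default 0.35, keeping ≈ 99.6% of
draws inside the intended band — "well-separated" categories). About 30% of
pressure-support records take the OSI pathway and 15% of eligible records
have no TR jet (applied only when the fallback is score-neutral, i.e. RVsP
grade = IVS grade). Outcomes are Bernoulli with per-category probabilities
defaulting to the published rates, hence monotone in category by
construction. The generator returns a category-recovery diagnostic (the
fraction of records whose full-pipeline score lands back in the generating
category; ≈ 99.8% at the defaults). What passing simulation tests show is
internal consistency of the scoring pipeline under controlled noise — not
that real echocardiographic measurements are this well separated, and not
anything about inter-observer variability, missing components beyond TAPSE
and the TR jet, or the timing drift of PPHN physiology.

## Numerical and interface choices

* Problem sizes: the fixture is the published cohort size (83); simulation
  checks run at n = 2000, where the Monte-Carlo error of a rate is under
  about 2 percentage points per category.
* Band lookups use `bisect_right`, making lower-inclusive semantics exact
  for floats that land on a cut.
* CSV dialect: comma-separated UTF-8, `.` decimal point, hours/days as
  plain numbers; empty cell = missing (never zero), `NA` accepted on read,
  never written; unknown columns are preserved and round-tripped; all row
  errors are collected and reported with row numbers in one exception.
* `score` is pure: same file + config → byte-identical output.
* Degenerate inputs: OI/OSI with MAP = 0 are 0 (bottom band); SpO₂ and PaO₂
  must be strictly positive; a TR velocity of exactly 0 is rejected rather
  than treated as jet-absent (absence is the empty cell).

## Known limitations

* The interior OI/OSI, TAPSE and RVsP-ratio cut points above the first band
  are reconstructions and should be overridden via `ScoreConfig` where a
  site's reference standards differ.
* Fisher's exact test, not conditional-exact logistic regression, is the
  exact procedure for dichotomous outcomes here; p-values for ordered
  alternatives (trend tests) are not implemented.
* The fixture's patient-level continuous outcomes are display
  reconstructions; analyses of them (e.g. the OLS p-values) characterise
  the reconstruction, not the original patients.
* The published p = 0.02 for lung malformation is not recoverable from the
  published counts by Fisher's exact test (which gives 0.053, confirmed
  against an independent implementation); the package reports the computed
  value.
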