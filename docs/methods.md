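# Methods

## Problem and model

Two national trauma registries can document the same patient: a pelvic-injury
register (PIR dialect here) enrolling pelvic ring and acetabular fractures
with a surgical focus, and a multiple-trauma register (TR dialect) enrolling
ICU-level trauma cases with AIS-coded injuries. Both are anonymous, so
patients re-identifiable across registries must be found without personal
identifiers. This package implements a deterministic (exact-key) linkage:

* **Match code.** The five master-data components both registries share —
  hospital code, admission date, discharge date, age in completed years, and
  sex — compared with exact equality and no tolerance. Age may be stored as
  an age or a birthdate; a birthdate is converted to the floor of completed
  years at admission, which is the only convention under which the two
  storage forms agree exactly.
* **Eligibility cascade.** Before linkage each registry is reduced to the
  population the other could contain: hospitals contributing to both
  registries; trauma-registry cases carrying at least one AIS-1998 code with
  pre-dot prefix 856 (pelvic ring/acetabular fracture); and hospital-years
  in which both registries received data. The contribution year is the
  admission year — the one date field both registries must hold and the
  event that triggers enrolment (accident and discharge year were the
  alternatives; the choice is documented, not empirically identifiable).
  Year overlap is existence-based: one record on each side of a
  (hospital, year) cell suffices.
* **Deduplication.** Within one registry, all members of any key-sharing
  group are excluded — with anonymous rows there is no ground for keeping
  one member over another, and a retained member could otherwise produce an
  arbitrary cross-registry match. After this step keys are unique per side
  and the join is provably one-to-one.
* **Funnel.** Linkage rates are 100·linked/eligible per registry, where
  eligible is the post-cascade (pre-dedup) count, rounded half-up to one
  decimal. All percentages in the package round half-up on the decimal
  representation, matching how registries print their tables.

## Concordance evaluation

For variables documented in both registries (ISS, initial haemoglobin,
initial systolic blood pressure, vital status) agreement is evaluated on the
linked cohort, restricted to pairs complete on both sides (no imputation;
missing is an empty cell, never zero — completion rates depend on this).

* **Exact match** means identity at the registry's entry precision: whole
  points for ISS, whole mmHg for blood pressure, 0.1 g/dl for haemoglobin.
  Comparing at entry precision avoids float-representation false negatives.
* **Tolerance match** means |Δ| ≤ tol with an inclusive boundary (tolerances:
  ISS ±9 points, haemoglobin ±1 g/dl, blood pressure ±10 mmHg; vital status
  exact only). A numerical guard of 1e-9 keeps the boundary inclusive under
  binary floats. Exact match implies tolerance match by construction.
* **Tests.** Continuous variables: Wilcoxon signed-rank on the paired
  differences (the data are paired per patient, so the signed-rank variant
  is the defensible reading of "Wilcoxon test"). Zero differences are
  dropped; for ≤ 25 nonzero pairs the exact null distribution of the
  positive-rank sum is computed by subset-sum convolution over doubled
  midranks, otherwise a normal approximation with continuity and tie
  correction is used; all-zero differences return p = 1 by convention.
  Categorical variables: Pearson chi-square on the 2×2
  registry-by-outcome table without continuity correction (identical
  margins then give p = 1 exactly); degenerate tables return p = 1.
* **Cohort summary.** Mortality, Tile/OTA distribution and the
  complex-pelvic-injury share are taken from the pelvic-registry side
  (its surgeons classify the fracture and close the record); the injury
  mechanism, when present, from the trauma-registry payload. Where the two
  registries disagree on vital status, both values still appear in the
  concordance table.

## Synthetic twin registries

`traumalink.synthetic.generate` draws each simulated patient once with
latent clinical values and then emits per-registry copies, so the planted
ground truth (who is co-documented, which rows are duplicates) is exact.
Defaults describe a six-year window (2004–2009) over 19 hospitals with
asymmetric enrolment (p_in_pir = 0.80, p_in_tr = 0.35 — pelvic-registry
enrolment is the rule, trauma-registry enrolment requires ICU-level care),
hospital-year contribution gaps (90 % activity per registry-year), and
within-registry duplication at 0.3 %.

Entry discrepancies follow TR = PIR + Δ with Δ_ISS ~ round(N(0, 9.166)),
Δ_Hb ~ N(1.0, 1.5) g/dl and Δ_BP ~ N(9, 20) mmHg. The ISS spread is chosen
so that P(|Δ| ≤ 9) = 2Φ(9.5/9.166) − 1 ≈ 0.70; the haemoglobin and
blood-pressure location shifts mirror the systematic between-registry
offsets such comparisons report. Missingness defaults (83 % on pelvic-side
haemoglobin/blood pressure — these fields are mandatory there only for
complex injuries — versus 11 %/5 % on the trauma side) reproduce realistic
completion asymmetry. Key errors perturb at most one component per affected
record (a date by ±1 day or age by ±1, applied on the trauma-registry copy),
which makes link sensitivity analytically ≈ 1 − e at error rate e — the
recovery oracle used in the tests.

What the generator does **not** emulate: real hospital case-mix, seasonal
admission patterns, correlated missingness, ICD/AIS coding drift, and —
importantly — the point mass of *identical* double entries that arises when
both registries transcribe the same source document. Continuous discrepancy
models therefore understate exact-match rates (simulated exact ISS agreement
is ~5 %, versus double-digit rates in real twin-registry comparisons), and
the default Hb/BP models give within-tolerance rates of roughly 50 %/37 %
rather than the ~66 %/44 % a real comparison reported. Passing tests
demonstrate correct pipeline mechanics and calibrated tolerance-band
behaviour for ISS, not a full generative model of registry entry error.

## The worked-example instance

`paper_funnel_fixture()` is a fixed-seed (20130305) instance constructed
top-down from published stage counts of a real two-registry linkage:
4,323 / 34,134 initial records; 3,329 pelvic-registry records in the 19
shared hospitals; 1,974 trauma-registry pelvic cases there; 2,671 / 947 in
overlapping hospital-years; 10 within-registry duplicate rows (planted as
3 + 2 pairs, all excluded under the exclude-all policy); 420 linked pairs
from 15 hospitals — giving linkage rates of 15.7 % and 44.4 %. The linked
cohort carries 42 deaths, 77 complex pelvic injuries, a Tile mix of
83/124/153/60 (A/B/C/isolated acetabulum-sacrum), pelvic-side Hb/BP complete
on exactly 73 records and trauma-side BP/Hb on 375/400. Counts are allocated
to hospital×year cells first and records emitted second; within a cell each
side's admission days occupy disjoint ranges, so match keys collide exactly
where planted and nowhere else (no tuning or search is involved). Whether
the original "10 duplicates" were within-registry rows or duplicate
cross-matches is not documented; the fixture plants them as within-registry
rows.

## Numerical and degenerate-input choices

* Half-up rounding operates on `repr(float)` via `decimal.Decimal`, so
  printed-value ties (e.g. 44.35) round up deterministically.
* Empty eligible populations yield 0 % linkage rates; linked records with an
  empty eligible population raise a consistency error.
* Concordance with fewer than two complete pairs raises an
  insufficient-data signal rather than returning an unstable percentage;
  the pipeline skips (and logs) such variables.
* Sensitivity/PPV with an empty truth or empty link set: sensitivity is 1
  on empty truth (nothing to find), PPV is 1 on an empty link set (no false
  positives were produced).
* CSV readers are total: every row is accepted or appears in the reject
  diagnostics with a row index and reason; schema errors (missing required
  columns) fail the whole read.

## Problem sizes

The worked-example instance is full-scale (38,457 rows) and runs the whole
pipeline in a few seconds. Oracle-equivalence tests use 200 random instances
of up to 100 records per side against nested-loop joins, exact signed-rank
p-values are checked against exhaustive 2^n sign enumeration up to n = 12,
and parameter-recovery tests use n = 420 (ISS tolerance band, 10–50
replicates) and n = 5,000 (key-error sensitivity).

## Known limitations

* Deterministic linkage only: no probabilistic weighting, no tolerance on
  key components, no encrypted-identifier workflow. Patients whose key
  fields differ between registries by any amount are unrecoverable by
  design.
* ISS is carried as a recorded value; it is never recomputed from AIS codes,
  and no AIS-1998↔2005 mapping is attempted.
* Hospital codes are assumed pre-harmonized (the trauma registry's code
  injected into the pelvic extract upstream); there is no fuzzy code
  reconciliation.
* No multiple-testing correction is applied across concordance variables.
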