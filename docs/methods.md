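# Methods

`myeloflow` implements a flow-cytometric analysis chain for the Ki-67
proliferation index and the Bcl-2 anti-apoptotic index of myeloid
bone-marrow populations, together with a calibrated synthetic-data
generator that makes every stage testable against known ground truth.
This note records the models, the tunable parameters and the design
choices that were genuinely open.

## The analysis chain

A bone-marrow aspirate is stained in seven tubes; two tube groups share
*backbone markers* (tubes 1/2/5: FSC, SSC, CD13, CD34, CD45, CD117,
HLA-DR; tubes 3/4/6/7: FSC, SSC, CD33, CD45, CD117, HLA-DR) so that
events from different tubes can be matched.  Per sample the chain is:

1. **Debris and doublet exclusion.**  Debris is removed below a density
   valley on FSC; doublets are removed outside a band on the
   integral/peak forward-scatter ratio.  *Relevant events* — the
   denominator of all population fractions — are the events surviving
   debris exclusion alone (doublets and erythroid cells retained).
2. **Hierarchical population gating** of CD34+ blasts (CD45-dim,
   CD34+), erythroid cells (CD45−, minus CD13+, minus CD117− HLA-DR+
   lymphoid, minus platelets CD36+CD71−, proliferating non-erythroid
   CD36−CD71+ and non-nucleated red cells CD71+CD235a−), myeloid
   granulocytic cells (SSC-high CD45-dim, minus CD14+ mature monocytes,
   autofluorescent eosinophils and CD117− HLA-DR+ immature monocytes)
   and total monocytes (backgated from mature CD14+ seeds in SSC vs
   CD45, minus CD13-high myeloid and CD10+CD11b− lymphoid events).
3. **Positivity gating** of Ki-67 (FITC) and Bcl-2 (PE-CF594) per
   population under four strategies: control-anchored rectangle,
   control-anchored adaptive polygon, and fixed thresholds at exactly
   40 and 100 FU.  The index is the exact ratio of integer counts.
4. **Cohort statistics**: for every cohort pair × population × marker ×
   strategy, Student's independent t-test when both groups pass
   Shapiro–Wilk at α = 0.05, otherwise Mann–Whitney U (exhaustively
   enumerated when both groups have ≤ 8 values, normal approximation
   with tie/continuity correction otherwise).  Stars: `*` p < 0.05,
   `**` p < 0.01, `***` p < 0.001, strict inequalities, no
   multiple-testing correction.

QC rules are enforced exactly at their boundaries: ≥ 100,000 relevant
events per sample (ideally 500,000), ≥ 100 positive cells per index
(otherwise flagged `insufficient_positives`), ≥ 1000 events per
population for merge eligibility.  An empty population reports a
*missing* index, never zero, and missing indices are excluded from
statistics rather than imputed.

## Deterministic surrogates for manual gates

Manual gate placement is replaced by reproducible estimators:

* **Density-valley thresholds.**  1-D cutoffs sit at the
  minimum-density point of a Gaussian-KDE-smoothed density of log10
  intensities (Silverman bandwidth, 512-point grid).  The KDE is
  estimated on an order-statistic sketch of at most 30,000 points,
  which is deterministic and invariant to event order.  Modes below 3%
  of the tallest mode are ignored; unimodal distributions fall back to
  fixed constants (100 FU for lineage-marker positivity).  Band
  classification uses fixed anchors: CD45 modes below 60 FU are
  "negative", above 450 FU "lymphocyte-bright"; FSC modes below 60 FU
  are debris candidates; SSC modes above 250 FU are granulocytic.  The
  SSC cut is the valley immediately left of the first granulocytic
  mode — not the globally deepest valley, which can belong to the
  platelet/erythrocyte region.
* **Doublet band.**  Singlets have integral/peak scatter ratio within
  median ± 4·MAD.  A 3·MAD band (≡ ±2.02 σ for a near-normal ratio)
  would discard ~4% of true singlets; 4·MAD discards ~0.7% while still
  removing doublets, whose ratio is ≈ 2.
* **Monocyte backgate.**  Mature CD14+ seeds (≥ 50 events required)
  define a bounding box (1st–99th percentiles, log-expanded 15%) in SSC
  vs CD45; with too few seeds a fixed band (SSC 90–280, CD45 140–420 FU)
  is used and a `DegenerateSeedWarning` raised.  The CD13-high
  exclusion cutoff is the valley between the two brightest CD13 modes,
  floored at 200 FU so a granulocyte-poor sample cannot cut into the
  monocytes themselves.
* **Eosinophil exclusion.**  Eosinophils are identified by jointly high
  FITC *and* PE signal beyond the 99.5th percentile of each channel,
  with each channel's percentile conditioned on the other channel being
  below its 90th percentile so the autofluorescent cloud cannot inflate
  its own cutoff.  The same exclusion is applied inside the monocyte
  region: without it, the eosinophil SSC tail contaminates the
  backgated box and corrupts the isotype-control percentile there.
* **Precedence.**  The four final masks are made pairwise disjoint in
  the order blast → erythroid → myeloid → monocytic, which resolves the
  small overlaps a purely geometric chain leaves (e.g. blasts inside
  the monocyte box).

All constants live in `GatingConfig`; changing them cannot break the
containment (every child mask ⊆ its parent) or exclusivity invariants,
which hold by construction.

## Positivity strategies and controls

Control-anchored cutoffs are an exact order statistic (default the
99.5th percentile, computed as `sorted[ceil(p·n)−1]`) of the control
distribution.  The control is the IgG1 isotype channel of the *same
population's* events (tubes share latent cells, so isotype channels are
aligned event-wise); `internal_negative` mode instead uses the marker
channel's own sub-valley negative cloud.  Populations with fewer than
100 control events borrow the singlet-wide control and are flagged
`control_fallback`.  When tubes are merged, the isotype control is the
preferred anchor because imputation adds a small noise floor to the
marker channels.

The **polygon** strategy bins the population's SSC into 8 equal-count
bins and follows the control's per-bin percentile, closed into a simple
staircase polygon (exported as Gating-ML 2.0).  A 99.5th percentile is
meaningless from a handful of events, so bins with fewer than 100
control events are unpopulated; with fewer than 3 populated bins the
gate degrades to the rectangle with a warning.  With a flat control the
polygon's acceptance region equals the rectangle's.  Whether a manual
polygon would be drawn on marker-vs-SSC or marker-vs-marker axes is not
determinable; marker-vs-SSC is used.

## Tube merging

`merge_and_calculate` standardizes backbone channels by median/MAD
(robust to population skew), then imputes each missing marker for every
reference-tube event as the mean of its k nearest donor events
(Euclidean in standardized backbone space; k = 1 default).  Ties at the
k-th distance break on standardized coordinates, then lowest donor
index, so donor event order cannot change the result.  Imputed channels
carry provenance (`imputed:<tube>`) in the merged table's metadata.
Imputation noise is scored by hiding a marker measured in ≥ 2 tubes and
comparing imputed against measured values: median absolute error in FU
(acceptance default ≤ 15 FU on self-consistency runs) plus the
two-sample Kolmogorov–Smirnov distance.  The reference tube and k are
configuration choices; nearest-neighbour imputation is the minimal
faithful surrogate of the proprietary merge function, with no claim of
bit-compatibility.

## The synthetic-data generator

Each case draws latent single cells from the marrow populations
(blasts, erythroid, myeloid, monocytic — the last split 80/20 into
mature CD14+ and immature CD14− HLA-DR+ — plus lymphoid, eosinophils,
platelets, debris and doublets).  Channel intensities are log-normal on
a linear FU scale around population/state means (log-sd 0.35 for
lineage markers), calibrated so that negative populations centre near
15–30 FU, dim signals near 80–130 FU and bright positives at
300–600 FU.  That calibration is what makes the fixed 40/100 FU
thresholds meaningful: the instrument scale on which those cutoffs were
originally defined is not recoverable, so the generator *defines* a
scale on which 40 FU sits at the top of the negative cloud (the
behaviour the threshold was chosen to have) and 100 FU admits only
bright positives.

Ki-67/Bcl-2 positivity is a latent per-event Bernoulli flag (negative
events at 20 FU log-sd 0.35, positives at 300 FU log-sd 0.5); isotype
channels are always negative-distributed.  Eosinophils add a shared
log-normal autofluorescence component (mean 3000 FU) to all four
intracellular channels — bright enough that the joint-tail exclusion
removes them essentially completely, as real eosinophil
autofluorescence dominates the FITC detector.  Per-population additive
FU offsets (`autofluorescence_shift`) emulate cohort-level
autofluorescence drift; they apply equally to the marker and isotype
channels, which is why control-anchored strategies are robust to them
and fixed thresholds are not.

Population fractions come from the packaged per-case tables (50
non-malignant, 25 MDS, 27 AML rows).  The four printed fractions are
kept exactly; default nuisance fractions (eosinophils 1.5%, platelets
2%, doublets 1% of relevant events; debris 5% of total; lymphoid the
remainder) are squeezed into whatever the printed rows leave free.  A
few printed rows sum above 100% — impossible for fractions of one
denominator — and are rescaled proportionally to 100 (the realized
ground truth records what was actually drawn).  Every tube of a case
measures the same latent cells in the same order with independent
multiplicative per-tube noise (log-sd 0.05); `generate_combined` yields
the union of all channels, the ideal-merge table the pipeline gates by
default.

Default latent positive fractions per cohort (e.g. blast Ki-67 0.20 /
0.30 / 0.40 and blast Bcl-2 0.35 / 0.50 / 0.70 for non-malignant / MDS
/ AML-like cases) are simulation defaults chosen to give each cohort a
distinct profile; they are not measurements.

Cohort scaffolding: sizes 50/25/27; sexes exactly 25M/25F, 16M/9F,
13M/14F; ages uniform over each cohort's range (45–89, 58–94, 50–87)
then centre-adjusted so the cohort median is exactly 70, 75 and 72 —
the middle order statistics are pinned to the median and any values on
the wrong side of it are pulled onto it, leaving the range intact.

### What the generator does not emulate

Log-amplifier artefacts and negative compensated values; spectral
spillover (tubes are generated pre-compensated; compensation is
exercised separately); correlated marker expression within a population
beyond the shared eosinophil autofluorescence; staining chemistry,
carryover and batch effects; the measured per-case Ki-67/Bcl-2 index
values of the underlying study, which would require its deposited raw
data and manual gates.  Passing the recovery suites therefore shows
that the chain is correct and well-calibrated on data obeying this
model, not that it reproduces any laboratory's measured indices.

## Problem sizes and numerical choices

Recovery checks run on 10-case cohorts at 100,000 events per case —
the acquisition minimum, and large enough that binomial noise is well
below the tolerances (blast/erythroid/myeloid/monocytic recovered
within 1.5/2/3/3 percentage points MAE; control-anchored indices within
0.02 of latent truth).  Unit tests use 5,000–50,000-event cases, which
the QC stage duly flags as below the acquisition minimum.  The
strategy-bias contrast uses two 8-case cohorts at 20,000 events with a
+60 FU myeloid shift; fixed40 shifts the myeloid index by far more than
0.10 while control-anchored strategies move < 0.03.  All randomness
flows from explicit integer seeds; a run seed fans out to per-case
child seeds by CRC-32 of `"{seed}:{case_id}"` masked to 31 bits.

## Known limitations

* Gate surrogates assume roughly log-normal, mildly overlapping
  populations; heavily transfused or pathological samples with merged
  modes will trip the fixed fallbacks, which are blunt.
* The FCS layer reads list-mode FCS 3.0/3.1 (and the two-dataset LMD
  layout, preferring the FCS 3.0 dataset) with uniform 16/32-bit
  integer or float data; exotic bit widths and FCS 2.0 writing are out
  of scope.
* Fractions are reported against relevant events; a study table whose
  denominator was defined differently will differ systematically.
* The Mann–Whitney exact path enumerates up to C(16,8) = 12,870 splits;
  larger groups use the asymptotic approximation.
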