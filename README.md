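# myeloflow

Flow-cytometric analysis of proliferation (Ki-67) and apoptosis
resistance (Bcl-2) in myeloid bone-marrow populations — for
hematology/immunology labs and methods researchers who need the whole
chain reproducible: FCS/LMD event I/O, hierarchical population gating,
positivity gating under competing strategies, backbone-marker tube
merging, QC, and cohort statistics, plus a calibrated synthetic-data
generator with per-event ground truth so every stage can be validated
without access to patient data.

## The science

For a gated cell population *P* with *n* cells, of which *k* exceed the
positivity boundary on the Ki-67 (FITC) channel, the **Ki-67
proliferation index** is the exact ratio

    PI(P) = k / n,

and likewise the **Bcl-2 anti-apoptotic index** on the PE-CF594
channel.  Populations are gated hierarchically after debris/doublet
exclusion: CD34+ blasts (CD45-dim, CD34+), erythroid cells (CD45−, with
sequential exclusion of CD13+, CD117− HLA-DR+, CD36+CD71−, CD36−CD71+
and CD71+CD235a− events), granulocytic myeloid cells (SSC-high,
CD45-dim, minus monocytes and autofluorescent eosinophils) and total
monocytes (backgated from mature CD14+ seeds).  Fractions are reported
against *relevant events* — everything surviving debris exclusion.

The decisive methodological question is where the positivity boundary
comes from.  Four strategies are implemented:

| strategy    | boundary                                                      |
|-------------|---------------------------------------------------------------|
| `rectangle` | 99.5th percentile of the population's isotype control          |
| `polygon`   | per-SSC-bin control percentile (adaptive staircase boundary)   |
| `fixed40`   | 40 FU, ignoring controls                                       |
| `fixed100`  | 100 FU, ignoring controls                                      |

Control-anchored boundaries move with a population's autofluorescence;
fixed thresholds do not — so a cohort-level autofluorescence shift
masquerades as a biological index difference under `fixed40`/`fixed100`
while `rectangle`/`polygon` stay unbiased.  The test suite demonstrates
this bias quantitatively on cohorts with identical latent indices.

Samples with too few events per tube can be analysed jointly:
`merge_and_calculate` imputes markers across tubes through
nearest-neighbour matching in standardized backbone-marker space
(FSC/SSC/CD33 or CD13/CD45/CD117/HLA-DR), with eligibility (≥ 1000
events per population) and a held-out-marker noise score.

## Worked example

```python
import myeloflow as mf
from myeloflow.positivity import GatedSample, compute_all_indices

# an MDS-like case built from the packaged per-case fraction tables
prof = mf.profile_from_table_row("MDS", 10, n_events=100_000)
table, truth = mf.generate_combined(prof, seed=1)

relevant = mf.count_relevant_events(table)
masks = mf.gate_all(table)
print("relevant events:", relevant)
print("fractions:", mf.population_fractions(masks, relevant).rounded())

for r in compute_all_indices(GatedSample(table=table, masks=masks)):
    if r.population == "blast" and r.marker == "Ki-67":
        print(f"{r.strategy:9s} blast Ki-67 index = {r.fraction:.4f}")
print("latent blast Ki-67:", round(truth.true_positive_fractions[('blast', 'Ki-67')], 4))
```

prints

```
relevant events: 95018
fractions: {'blast': 8.3, 'erythroid': 18.6, 'myeloid': 24.4, 'monocytic': 1.8}
polygon   blast Ki-67 index = 0.2975
rectangle blast Ki-67 index = 0.2977
fixed40   blast Ki-67 index = 0.3102
fixed100  blast Ki-67 index = 0.2893
latent blast Ki-67: 0.2928
```

The case was configured from the fixture row with 8.5% blasts; gating
recovers 8.3% of 95,018 relevant events, and the control-anchored
strategies land within half a point of the latent Ki-67 fraction while
`fixed40` overshoots (it admits the top of the negative cloud) and
`fixed100` undershoots (it demands bright positives only).

A command-line interface covers the same stages
(`myeloflow simulate | merge | gate | indices | compare | report |
run-all`); `run-all` writes deterministic, config-hash-stamped CSVs,
median+IQR figures and a p-value table for a full synthetic cohort.

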