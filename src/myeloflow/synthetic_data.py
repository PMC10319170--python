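"""Synthetic multi-tube bone-marrow cytometry cohorts with ground truth.

The generator emulates the structure of diagnostic bone-marrow
acquisitions so that every downstream stage (gating, positivity
strategies, tube merging, cohort statistics) can be exercised and
scored against known truth without any external data:

* latent single cells belong to one of the marrow populations —
  CD34+ blasts, erythroid, myeloid (granulocytic), monocytic (mature
  CD14+ and immature CD14− HLA-DR+), lymphoid, eosinophils, platelets —
  plus debris and doublet nuisance events;
* per-population target fractions come from the packaged per-case
  fixture tables (one row per study case: 50 non-malignant, 25 MDS,
  27 AML) or from a hand-built :class:`CaseProfile`;
* channel intensities are drawn log-normally on a linear FU scale
  around population- and positivity-specific means, calibrated so that
  negative populations centre near 20 FU and bright positives at
  300–800 FU, which makes the fixed 40/100 FU positivity cutoffs
  meaningful;
* every tube of a case measures the *same* latent cells (same event
  order) on its own marker subset, with independent per-tube
  measurement noise — the property that makes backbone merging work;
* Ki-67/Bcl-2 positivity is a latent per-event Bernoulli flag with
  configurable per-population true fractions, returned as ground truth.

Cohort scaffolding reproduces the study demographics: cohort sizes
50/25/27, sex counts 25M/25F, 16M/9F and 13M/14F, and ages drawn
uniformly over each cohort's printed range and then centre-adjusted so
the cohort median equals the printed median (70, 75 and 72 years).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .fcs_io import EventTable, PanelDefinition
from .panels import default_panel

__all__ = [
    "POPULATIONS",
    "MAIN_POPULATIONS",
    "NUISANCE_DEFAULTS",
    "CaseProfile",
    "GroundTruth",
    "CohortConfig",
    "load_fraction_fixture",
    "profile_from_table_row",
    "default_positive_fractions",
    "generate_case",
    "generate_combined",
    "generate_cohort",
    "case_seed",
]

MAIN_POPULATIONS = ("blast", "erythroid", "myeloid", "monocytic")
POPULATIONS = MAIN_POPULATIONS + ("lymphoid", "eosinophil", "platelet", "debris", "doublet")

COHORTS = ("non_malignant", "MDS", "AML")

#: Default nuisance fractions, in percent of relevant (non-debris) events.
NUISANCE_DEFAULTS = {"eosinophil": 1.5, "platelet": 2.0, "doublet": 1.0}
DEBRIS_DEFAULT = 5.0  # percent of total acquired events

# Mean linear-FU intensity per (population, marker).  Lineage negatives
# centre near 15–30 FU, positives at 300–600 FU; log-normal spread 0.35
# gives mild overlap between adjacent populations.
_P = {
    #            FSC   SSC  CD45 CD34 CD13 CD33 CD117 HLADR CD14 CD10 CD11b CD36 CD71 CD235a
    "blast":     (250,   80,  90, 400,  30,  60, 350,  300,  15,  20,  20,   20,  25,  15),
    "erythroid": (150,   30,  15,  20,  20,  15,  20,   15,  15,  20,  20,  350, 450, 400),
    "myeloid":   (350,  450, 120,  20, 500, 300,  20,   25,  25,  30, 400,   20,  25,  15),
    "mono_mat":  (300,  150, 250,  20, 100, 500,  20,  400, 500,  20, 350,  150,  25,  15),
    "mono_imm":  (280,  140, 220,  20, 100, 450,  20,  400,  40,  20, 250,  150,  25,  15),
    "lymphoid":  (200,   60, 600,  20,  20,  20,  20,  250,  15, 300,  25,   20,  25,  15),
    "eosinophil":(350,  600, 130,  20, 300, 100,  20,   25,  25,  20, 300,   20,  25,  15),
    "platelet":  (100,   15,  15,  20,  20,  20,  20,   15,  15,  20,  20,  400,  20,  15),
    "debris":    ( 12,   10,  15,  15,  15,  15,  15,   15,  15,  15,  15,   15,  15,  15),
}
_MARKER_ORDER = (
    "FSC", "SSC", "CD45", "CD34", "CD13", "CD33", "CD117", "HLA-DR",
    "CD14", "CD10", "CD11b", "CD36", "CD71", "CD235a",
)
PHENOTYPES = {pop: dict(zip(_MARKER_ORDER, means)) for pop, means in _P.items()}

LINEAGE_SIGMA = 0.35
PEAK_RATIO_SIGMA = 0.02      # FS-PEAK tracks FSC-INT this tightly for singlets
TUBE_NOISE_SIGMA = 0.05      # independent per-tube remeasurement noise (log scale)
INTRACELLULAR_NEG_MEAN = 20.0
INTRACELLULAR_NEG_SIGMA = 0.35
INTRACELLULAR_POS_MEAN = 300.0
INTRACELLULAR_POS_SIGMA = 0.5
EOSINOPHIL_AUTOFLUOR_MEAN = 3000.0  # joint FITC/PE autofluorescence
MONO_IMMATURE_FRACTION = 0.2

INTRACELLULAR_CHANNELS = ("Ki-67-FITC", "Bcl-2-PE-CF594", "IgG1-FITC", "IgG1-PE-CF594")
_MARKER_FOR_INTRACELLULAR = {
    "Ki-67-FITC": "Ki-67",
    "Bcl-2-PE-CF594": "Bcl-2",
    "IgG1-FITC": None,
    "IgG1-PE-CF594": None,
}


def default_positive_fractions(cohort: str) -> dict[tuple[str, str], float]:
    """Default latent Ki-67/Bcl-2 positive fractions per population.

    These are the package's own simulation defaults (higher blast Ki-67
    and Bcl-2 in AML-like cases); they are not measurements.
    """
    table = {
        "non_malignant": {
            ("blast", "Ki-67"): 0.20, ("erythroid", "Ki-67"): 0.35,
            ("myeloid", "Ki-67"): 0.20, ("monocytic", "Ki-67"): 0.25,
            ("blast", "Bcl-2"): 0.35, ("erythroid", "Bcl-2"): 0.10,
            ("myeloid", "Bcl-2"): 0.25, ("monocytic", "Bcl-2"): 0.40,
        },
        "MDS": {
            ("blast", "Ki-67"): 0.30, ("erythroid", "Ki-67"): 0.40,
            ("myeloid", "Ki-67"): 0.25, ("monocytic", "Ki-67"): 0.30,
            ("blast", "Bcl-2"): 0.50, ("erythroid", "Bcl-2"): 0.15,
            ("myeloid", "Bcl-2"): 0.30, ("monocytic", "Bcl-2"): 0.45,
        },
        "AML": {
            ("blast", "Ki-67"): 0.40, ("erythroid", "Ki-67"): 0.30,
            ("myeloid", "Ki-67"): 0.30, ("monocytic", "Ki-67"): 0.35,
            ("blast", "Bcl-2"): 0.70, ("erythroid", "Bcl-2"): 0.20,
            ("myeloid", "Bcl-2"): 0.40, ("monocytic", "Bcl-2"): 0.50,
        },
    }
    if cohort not in table:
        raise KeyError(f"unknown cohort {cohort!r}; expected one of {COHORTS}")
    out = dict(table[cohort])
    for pop in ("lymphoid", "eosinophil", "platelet"):
        out[(pop, "Ki-67")] = 0.05
        out[(pop, "Bcl-2")] = 0.30 if pop == "lymphoid" else 0.05
    return out


@dataclass
class CaseProfile:
    """Configuration of one synthetic bone-marrow case."""

    case_id: str
    cohort: str
    age: int = 70
    sex: str = "F"
    #: percent of relevant events per population; the four main populations
    #: plus optional overrides for lymphoid/eosinophil/platelet/doublet;
    #: "debris" is percent of total acquired events.
    target_fractions: dict[str, float] = field(default_factory=dict)
    true_positive_fractions: dict[tuple[str, str], float] = field(default_factory=dict)
    n_events: int = 100_000
    #: additive FU offset applied to the intracellular (Ki-67/Bcl-2 and
    #: isotype) channels of a population, emulating autofluorescence drift.
    autofluorescence_shift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        for key, val in self.target_fractions.items():
            if val < 0:
                raise ValueError(f"negative fraction for {key!r}")
        for key, val in self.true_positive_fractions.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"true positive fraction for {key} outside [0, 1]")
        main = sum(self.target_fractions.get(p, 0.0) for p in MAIN_POPULATIONS)
        nuis = sum(
            self.target_fractions.get(p, NUISANCE_DEFAULTS.get(p, 0.0))
            for p in ("eosinophil", "platelet", "doublet")
            if p in self.target_fractions
        )
        if main + nuis > 100.0 + 20.0:
            # printed study rows can exceed 100 by a little; anything far
            # beyond is a configuration error
            raise ValueError(f"population fractions sum to {main + nuis:.1f}%")
        if not self.true_positive_fractions:
            self.true_positive_fractions = default_positive_fractions(self.cohort)

    def composition(self) -> tuple[dict[str, float], float]:
        """Resolve per-population fractions of *relevant* events (percent).

        Returns ``(relevant_composition, debris_percent_of_total)``.
        The four main populations keep their configured values exactly;
        lymphoid absorbs the remainder after the nuisance defaults.  When
        the configured main fractions alone exceed 100 (a few printed
        study rows do), everything is rescaled proportionally to 100.
        """
        tf = self.target_fractions
        main = {p: float(tf.get(p, 0.0)) for p in MAIN_POPULATIONS}
        s_main = sum(main.values())
        nuis = {
            p: float(tf.get(p, NUISANCE_DEFAULTS[p]))
            for p in ("eosinophil", "platelet", "doublet")
        }
        budget = 100.0 - s_main
        comp = dict(main)
        if budget <= 0.0:
            scale = 100.0 / s_main
            comp = {p: v * scale for p, v in main.items()}
            comp.update({p: 0.0 for p in nuis})
            comp["lymphoid"] = 0.0
        else:
            s_nuis = sum(nuis.values())
            if s_nuis > budget:
                nuis = {p: v * budget / s_nuis for p, v in nuis.items()}
                s_nuis = budget
            lymph = tf.get("lymphoid", budget - s_nuis)
            total = s_main + s_nuis + lymph
            if total > 100.0:
                lymph = max(0.0, 100.0 - s_main - s_nuis)
            comp.update(nuis)
            comp["lymphoid"] = lymph
        debris = float(tf.get("debris", DEBRIS_DEFAULT))
        return comp, debris


@dataclass
class GroundTruth:
    """Latent truth for one generated case (the oracle for recovery tests)."""

    labels: np.ndarray              # population label per event
    ki67: np.ndarray                # latent Ki-67 positivity per event
    bcl2: np.ndarray                # latent Bcl-2 positivity per event
    true_fractions: dict[str, float]               # percent of relevant events
    true_positive_fractions: dict[tuple[str, str], float]  # realized, per population

    @property
    def n_events(self) -> int:
        return len(self.labels)

    @property
    def relevant(self) -> np.ndarray:
        return self.labels != "debris"


@dataclass
class CohortConfig:
    """Cohort scaffolding: sizes, demographics and per-case event counts."""

    sizes: dict[str, int] = field(
        default_factory=lambda: {"non_malignant": 50, "MDS": 25, "AML": 27}
    )
    #: cohort → (median age, min age, max age), per the study demographics
    ages: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: {
            "non_malignant": (70, 45, 89),
            "MDS": (75, 58, 94),
            "AML": (72, 50, 87),
        }
    )
    #: cohort → (n male, n female)
    sex_counts: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "non_malignant": (25, 25),
            "MDS": (16, 9),
            "AML": (13, 14),
        }
    )
    n_events: int = 100_000

    def __post_init__(self) -> None:
        for cohort, n in self.sizes.items():
            if n <= 0:
                raise ValueError(f"cohort size for {cohort!r} must be positive")
            med, lo, hi = self.ages[cohort]
            if not lo <= med <= hi:
                raise ValueError(f"age median outside range for {cohort!r}")


def load_fraction_fixture(cohort: str) -> pd.DataFrame:
    """Per-case population fractions of one study cohort, as printed.

    Columns: ``case`` (1-based case number), ``blast_pct``,
    ``erythroid_pct``, ``myeloid_pct``, ``monocytic_pct``.
    """
    if cohort not in COHORTS:
        raise KeyError(f"unknown cohort {cohort!r}; expected one of {COHORTS}")
    ref = resources.files("myeloflow.data") / f"fractions_{cohort}.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def profile_from_table_row(
    cohort: str,
    case: int,
    n_events: int = 100_000,
    **overrides,
) -> CaseProfile:
    """Build a :class:`CaseProfile` from one fixture-table row."""
    tab = load_fraction_fixture(cohort)
    row = tab.loc[tab["case"] == case]
    if row.empty:
        raise KeyError(f"no case {case} in cohort {cohort!r}")
    row = row.iloc[0]
    fractions = {
        "blast": float(row["blast_pct"]),
        "erythroid": float(row["erythroid_pct"]),
        "myeloid": float(row["myeloid_pct"]),
        "monocytic": float(row["monocytic_pct"]),
    }
    fractions.update(overrides.pop("target_fractions", {}))
    return CaseProfile(
        case_id=f"{cohort}-{case:02d}",
        cohort=cohort,
        target_fractions=fractions,
        n_events=n_events,
        **overrides,
    )


def case_seed(seed: int, case_id: str) -> int:
    """Stable per-case child seed derived from the run seed and case id."""
    return zlib.crc32(f"{seed}:{case_id}".encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Event synthesis


def _lognormal(rng: np.random.Generator, mean: float, sigma: float, n: int) -> np.ndarray:
    return mean * np.exp(rng.normal(0.0, sigma, n))


def _draw_block(
    rng: np.random.Generator,
    pop: str,
    n: int,
    profile: CaseProfile,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Latent channel values for *n* events of one population.

    Returns (channel → values, ki67 flags, bcl2 flags).  ``monocytic``
    draws a mature/immature mixture; ``doublet`` sums two cells.
    """
    if pop == "doublet":
        # a doublet is two cells of one population measured as one event
        source = rng.choice(
            ["myeloid", "lymphoid", "erythroid", "monocytic"], size=1,
        )[0] if n else "myeloid"
        a, ki, bcl = _draw_block(rng, source, n, profile)
        b, _, _ = _draw_block(rng, source, n, profile)
        out = {ch: a[ch] + b[ch] for ch in a if ch != "FS-PEAK"}
        out["FS-PEAK"] = np.maximum(a["FS-PEAK"], b["FS-PEAK"])
        return out, ki, bcl

    if pop == "monocytic":
        n_imm = rng.binomial(n, MONO_IMMATURE_FRACTION) if n else 0
        pheno_names = ["mono_mat"] * (n - n_imm) + ["mono_imm"] * n_imm
        parts = []
        for name, m in (("mono_mat", n - n_imm), ("mono_imm", n_imm)):
            parts.append((name, m))
    else:
        parts = [(pop, n)]

    cols: dict[str, list[np.ndarray]] = {}
    for pheno, m in parts:
        means = PHENOTYPES[pheno]
        for marker, mean in means.items():
            ch = {"FSC": "FSC-INT", "SSC": "SSC-INT"}.get(marker, marker)
            cols.setdefault(ch, []).append(_lognormal(rng, mean, LINEAGE_SIGMA, m))
    out = {ch: np.concatenate(blocks) if len(blocks) > 1 else blocks[0]
           for ch, blocks in cols.items()}
    out["FS-PEAK"] = out["FSC-INT"] * np.exp(rng.normal(0.0, PEAK_RATIO_SIGMA, n))

    tpf = profile.true_positive_fractions
    ki = rng.random(n) < tpf.get((pop, "Ki-67"), 0.0)
    bcl = rng.random(n) < tpf.get((pop, "Bcl-2"), 0.0)

    shift = profile.autofluorescence_shift.get(pop, 0.0)
    autofluor = (
        _lognormal(rng, EOSINOPHIL_AUTOFLUOR_MEAN, LINEAGE_SIGMA, n)
        if pop == "eosinophil"
        else np.zeros(n)
    )
    for ch in INTRACELLULAR_CHANNELS:
        marker = _MARKER_FOR_INTRACELLULAR[ch]
        if marker == "Ki-67":
            pos = ki
        elif marker == "Bcl-2":
            pos = bcl
        else:
            pos = np.zeros(n, dtype=bool)
        vals = np.where(
            pos,
            _lognormal(rng, INTRACELLULAR_POS_MEAN, INTRACELLULAR_POS_SIGMA, n),
            _lognormal(rng, INTRACELLULAR_NEG_MEAN, INTRACELLULAR_NEG_SIGMA, n),
        )
        vals = vals + autofluor * np.exp(rng.normal(0.0, 0.1, n)) + shift
        out[ch] = vals
    return out, ki, bcl


#: channels every latent cell carries (union of all tube channels)
ALL_CHANNELS = [
    "FSC-INT", "SSC-INT", "FS-PEAK",
    "CD45-KO", "CD34-ECD", "CD13-APC-A700", "CD33-APC", "CD117-PC5.5",
    "HLA-DR-PB", "CD14-APC-A750", "CD10-PE-Cy7", "CD11b-APC-A700",
    "CD36-PE-Cy7", "CD71-APC-A750", "CD235a-APC-A700",
    "Ki-67-FITC", "Bcl-2-PE-CF594", "IgG1-FITC", "IgG1-PE-CF594",
]
_LATENT_FOR_CHANNEL = {
    "FSC-INT": "FSC-INT", "SSC-INT": "SSC-INT", "FS-PEAK": "FS-PEAK",
    "CD45-KO": "CD45", "CD34-ECD": "CD34", "CD13-APC-A700": "CD13",
    "CD13-ECD": "CD13", "CD33-APC": "CD33", "CD117-PC5.5": "CD117",
    "HLA-DR-PB": "HLA-DR", "CD14-APC-A750": "CD14", "CD10-PE-Cy7": "CD10",
    "CD11b-APC-A700": "CD11b", "CD11b-APC-A750": "CD11b",
    "CD36-PE-Cy7": "CD36", "CD71-APC-A750": "CD71",
    "CD235a-APC-A700": "CD235a",
    "Ki-67-FITC": "Ki-67-FITC", "Bcl-2-PE-CF594": "Bcl-2-PE-CF594",
    "IgG1-FITC": "IgG1-FITC", "IgG1-PE-CF594": "IgG1-PE-CF594",
}


def _latent_case(
    profile: CaseProfile, seed: int
) -> tuple[dict[str, np.ndarray], GroundTruth, np.random.Generator]:
    rng = np.random.default_rng(seed)
    comp, debris_pct = profile.composition()
    n = profile.n_events
    pops = list(comp) + ["debris"]
    probs = np.array(
        [comp[p] / 100.0 * (1.0 - debris_pct / 100.0) for p in comp] + [debris_pct / 100.0]
    )
    probs = probs / probs.sum()
    counts = rng.multinomial(n, probs)

    blocks, labels, ki_parts, bcl_parts = [], [], [], []
    for pop, m in zip(pops, counts):
        block, ki, bcl = _draw_block(rng, pop, int(m), profile)
        blocks.append(block)
        labels.append(np.full(int(m), pop, dtype=object))
        ki_parts.append(ki)
        bcl_parts.append(bcl)

    latent = {
        ch: np.concatenate([
            b.get(ch, _lognormal(rng, 15.0, LINEAGE_SIGMA, len(lab)))
            for b, lab in zip(blocks, labels)
        ])
        for ch in set().union(*(set(b) for b in blocks))
    }
    labels = np.concatenate(labels)
    ki = np.concatenate(ki_parts)
    bcl = np.concatenate(bcl_parts)

    order = rng.permutation(n)
    latent = {ch: v[order] for ch, v in latent.items()}
    labels, ki, bcl = labels[order], ki[order], bcl[order]

    relevant = labels != "debris"
    n_rel = int(relevant.sum())
    true_fractions = {
        p: 100.0 * float((labels == p).sum()) / n_rel for p in comp
    }
    tpf_realized: dict[tuple[str, str], float] = {}
    for p in MAIN_POPULATIONS:
        sel = labels == p
        cnt = int(sel.sum())
        if cnt:
            tpf_realized[(p, "Ki-67")] = float(ki[sel].sum()) / cnt
            tpf_realized[(p, "Bcl-2")] = float(bcl[sel].sum()) / cnt
    gt = GroundTruth(
        labels=labels.astype(str),
        ki67=ki,
        bcl2=bcl,
        true_fractions=true_fractions,
        true_positive_fractions=tpf_realized,
    )
    return latent, gt, rng


def _measure(
    latent: dict[str, np.ndarray],
    channels: list[str],
    rng: np.random.Generator,
    sample_id: str,
    tube_id: str,
    seed: int,
) -> EventTable:
    n = len(next(iter(latent.values())))
    cols = []
    for ch in channels:
        base = latent[_LATENT_FOR_CHANNEL.get(ch, ch)]
        cols.append(base * np.exp(rng.normal(0.0, TUBE_NOISE_SIGMA, n)))
    values = np.column_stack(cols) if cols else np.empty((n, 0))
    return EventTable(
        sample_id=sample_id,
        tube_id=tube_id,
        channels=list(channels),
        values=values,
        metadata={"SEED": str(seed), "SYNTHETIC": "1"},
    )


def generate_case(
    profile: CaseProfile,
    panel: PanelDefinition | None = None,
    seed: int = 0,
) -> tuple[dict[str, EventTable], GroundTruth]:
    """Generate every tube of one case from a single set of latent cells.

    All tubes share event count, event order and ground truth; each tube
    carries its panel's channels with independent measurement noise.
    """
    panel = panel or default_panel()
    latent, gt, rng = _latent_case(profile, seed)
    tubes = {
        tid: _measure(latent, panel.tube_channels(tid), rng, profile.case_id, tid, seed)
        for tid in panel.tubes
    }
    return tubes, gt


def generate_combined(
    profile: CaseProfile,
    seed: int = 0,
) -> tuple[EventTable, GroundTruth]:
    """One table carrying the union of all panel channels (ideal merge)."""
    latent, gt, rng = _latent_case(profile, seed)
    table = _measure(latent, ALL_CHANNELS, rng, profile.case_id, "combined", seed)
    return table, gt


def _cohort_ages(
    rng: np.random.Generator, n: int, median: int, lo: int, hi: int
) -> np.ndarray:
    """Uniform integer ages over [lo, hi], centre-adjusted to an exact median."""
    ages = rng.integers(lo, hi + 1, size=n)
    ages.sort()
    m = n // 2
    # anchor the middle order statistics at the target and pull any
    # misplaced values in either half onto it, so the multiset median is
    # exactly the printed median while the range stays untouched
    ages[:m] = np.minimum(ages[:m], median)
    ages[m:] = np.maximum(ages[m:], median)
    ages[m] = median
    if n % 2 == 0:
        ages[m - 1] = median
    return rng.permutation(ages)


def generate_cohort(
    config: CohortConfig | None = None,
    panel: PanelDefinition | None = None,
    seed: int = 0,
    with_events: bool = False,
    cohorts: tuple[str, ...] = COHORTS,
) -> tuple[list[CaseProfile], pd.DataFrame]:
    """Build case profiles and a metadata table for the default cohorts.

    One case per fixture row (truncated or recycled to the configured
    size).  With ``with_events=True`` each returned profile gains
    ``tubes``/``ground_truth`` attributes generated from its stable
    per-case child seed.
    """
    config = config or CohortConfig()
    panel = panel or default_panel()
    rng = np.random.default_rng(seed)
    profiles: list[CaseProfile] = []
    rows = []
    for cohort in cohorts:
        size = config.sizes[cohort]
        fixture = load_fraction_fixture(cohort)
        med, lo, hi = config.ages[cohort]
        ages = _cohort_ages(rng, size, med, lo, hi)
        n_m, n_f = config.sex_counts[cohort]
        sexes = rng.permutation(np.array(["M"] * n_m + ["F"] * n_f))[:size]
        for i in range(size):
            case = int(fixture["case"].iloc[i % len(fixture)])
            prof = profile_from_table_row(cohort, case, n_events=config.n_events)
            prof.age = int(ages[i])
            prof.sex = str(sexes[i]) if i < len(sexes) else "F"
            profiles.append(prof)
            rows.append(
                {"case_id": prof.case_id, "cohort": cohort, "age": prof.age,
                 "sex": prof.sex, "seed": case_seed(seed, prof.case_id)}
            )
            if with_events:
                tubes, gt = generate_case(prof, panel, case_seed(seed, prof.case_id))
                prof.tubes = tubes          # type: ignore[attr-defined]
                prof.ground_truth = gt      # type: ignore[attr-defined]
    return profiles, pd.DataFrame(rows)
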