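"""Backbone-marker tube merging ("merge and calculate" surrogate).

When a sample's tubes each carry too few events for a population, tubes
sharing a set of backbone markers can be analysed jointly: events of a
reference tube gain *imputed* values for markers measured only in other
tubes, matched through their position in standardized backbone space.
This module implements the open surrogate of that commercial function:

* backbone channels are standardized per channel by median/MAD (robust
  to population skew);
* each reference event's imputed value for a missing marker is the mean
  of its ``k`` nearest donor events (Euclidean distance in standardized
  backbone space, ``k=1`` by default), with deterministic tie-breaking;
* a population is eligible for merged analysis only when it holds at
  least 1000 events;
* the imputation noise is quantified by hiding a marker that *is*
  measured in the reference tube, imputing it from a donor tube, and
  scoring the median absolute error (FU) and the empirical-CDF
  (Kolmogorov–Smirnov) distance against the measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import ks_2samp

from .fcs_io import EventTable

__all__ = [
    "MERGE_MIN_EVENTS",
    "MergeReport",
    "NoiseScore",
    "check_merge_eligibility",
    "merge_and_calculate",
    "merge_noise_metric",
    "robust_standardize",
]

#: minimum events for a population to be eligible for merged analysis
MERGE_MIN_EVENTS = 1000

#: default acceptance bound for self-consistency noise checks, FU
NOISE_MAE_TOLERANCE_FU = 15.0


@dataclass
class NoiseScore:
    """Imputation-noise assessment for one held-out marker."""

    marker: str
    holdout_tube: str
    donor_tube: str
    median_abs_error_fu: float
    cdf_distance: float

    def acceptable(self, mae_tolerance: float = NOISE_MAE_TOLERANCE_FU) -> bool:
        return self.median_abs_error_fu <= mae_tolerance


@dataclass
class MergeReport:
    """Provenance and QC of one merge operation."""

    reference_tube: str
    donor_tubes: list[str]
    backbone_markers: list[str]
    imputed_channels: dict[str, str]            # channel → donor tube
    eligibility: dict[str, bool] = field(default_factory=dict)
    excluded_populations: list[str] = field(default_factory=list)
    noise: dict[str, NoiseScore] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def check_merge_eligibility(
    population_counts: dict[str, int], minimum: int = MERGE_MIN_EVENTS
) -> dict[str, bool]:
    """True per population iff it holds at least *minimum* (1000) events."""
    out = {}
    for pop, n in population_counts.items():
        if n < 0:
            raise ValueError(f"negative event count for {pop!r}")
        out[pop] = n >= minimum
    return out


def robust_standardize(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Median/MAD standardization; returns (z, median, scale)."""
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    scale = mad if mad > 0 else (float(np.std(x)) or 1.0)
    return (x - med) / scale, med, scale


def _backbone_matrix(table: EventTable, backbone: list[str]) -> np.ndarray:
    cols = []
    for marker in backbone:
        if marker.upper() in ("FS-PEAK",):
            continue
        z, _, _ = robust_standardize(table.column(marker))
        cols.append(z)
    return np.column_stack(cols)


def _nearest_neighbours(
    donor_z: np.ndarray, query_z: np.ndarray, k: int
) -> np.ndarray:
    """Indices (query × k) of nearest donors with deterministic tie-breaks.

    Ties at the k-th distance are resolved by the donor's standardized
    backbone coordinates (lexicographic) and then by lowest original
    index, so permuting donor event order cannot change the result.
    """
    tree = cKDTree(donor_z)
    extra = min(len(donor_z), k + 8)
    dist, idx = tree.query(query_z, k=extra)
    if extra == 1:
        dist, idx = dist[:, None], idx[:, None]
    out = np.asarray(idx[:, :k], dtype=np.intp).reshape(len(query_z), k)
    if extra > k:
        # only rows with a distance tie across the k-boundary need care
        tied = np.isclose(dist[:, k - 1], dist[:, k], rtol=1e-12, atol=1e-12)
        for i in np.where(tied)[0]:
            cand = sorted(
                range(extra),
                key=lambda j: (
                    round(float(dist[i, j]), 12),
                    tuple(donor_z[idx[i, j]]),
                    int(idx[i, j]),
                ),
            )
            out[i] = idx[i, np.asarray(cand[:k])]
    return out


def merge_and_calculate(
    tubes: dict[str, EventTable],
    backbone_markers: list[str] | set[str],
    k: int = 1,
    reference: str | None = None,
    population_counts: dict[str, int] | None = None,
    population_masks: dict[str, np.ndarray] | None = None,
) -> tuple[EventTable, MergeReport]:
    """Merge a sample's tubes onto a reference tube via backbone markers.

    Every reference event keeps its measured channels and gains imputed
    values for channels measured only in donor tubes: the mean of its
    ``k`` nearest donor events in standardized backbone space.  Channel
    provenance (measured vs imputed, with donor tube) is recorded in the
    merged table's metadata and the :class:`MergeReport`.

    When ``population_counts``/``population_masks`` (on the reference
    tube) are given, ineligible populations (< 1000 events) are dropped
    from the merged output with a warning in the report.
    """
    backbone = sorted({m for m in backbone_markers} - {"FS", "FS-PEAK"})
    tube_ids = list(tubes)
    if reference is None:
        reference = tube_ids[0]
    ref = tubes[reference]
    for tid, t in tubes.items():
        missing = [m for m in backbone if not t.has_marker(m)]
        if missing:
            raise ValueError(
                f"tube {tid!r} lacks backbone markers {missing}: backbone mismatch"
            )

    report = MergeReport(
        reference_tube=reference,
        donor_tubes=[t for t in tube_ids if t != reference],
        backbone_markers=list(backbone),
        imputed_channels={},
    )

    keep = np.ones(ref.n_events, dtype=bool)
    if population_counts is not None:
        report.eligibility = check_merge_eligibility(population_counts)
        for pop, ok in report.eligibility.items():
            if not ok:
                report.excluded_populations.append(pop)
                report.warnings.append(
                    f"population {pop!r} ineligible for merged analysis "
                    f"({population_counts[pop]} < {MERGE_MIN_EVENTS} events)"
                )
                if population_masks and pop in population_masks:
                    keep &= ~np.asarray(population_masks[pop], bool)

    ref_z_full = _backbone_matrix(ref, backbone)
    ref_z = ref_z_full[keep]
    channels = list(ref.channels)
    values = [ref.values[keep]]
    provenance = {ch: "measured" for ch in channels}

    for tid in report.donor_tubes:
        donor = tubes[tid]
        new_chs = [ch for ch in donor.channels if ch not in channels]
        if not new_chs:
            continue
        donor_z = _backbone_matrix(donor, backbone)
        nn = _nearest_neighbours(donor_z, ref_z, k)
        cols = []
        for ch in new_chs:
            col = donor.values[:, donor.channels.index(ch)]
            cols.append(col[nn].mean(axis=1))
            provenance[ch] = f"imputed:{tid}"
            report.imputed_channels[ch] = tid
        channels += new_chs
        values.append(np.column_stack(cols))

    merged = EventTable(
        sample_id=ref.sample_id,
        tube_id=f"merged({'+'.join(tube_ids)})",
        channels=channels,
        values=np.hstack(values),
        metadata={
            **ref.metadata,
            **{f"PROVENANCE_{ch}": provenance[ch] for ch in channels},
        },
    )
    return merged, report


def merge_noise_metric(
    tubes: dict[str, EventTable],
    holdout_marker: str,
    k: int = 1,
    reference: str | None = None,
    backbone_markers: list[str] | set[str] | None = None,
) -> NoiseScore:
    """Noise introduced by imputation, assessed on a held-out marker.

    The marker must be measured in at least two tubes: it is hidden in
    the reference tube, imputed from a donor tube, and compared with the
    measured values.  Returns the median absolute error in FU and the
    two-sample empirical-CDF (KS) distance.
    """
    carriers = [tid for tid, t in tubes.items() if t.has_marker(holdout_marker)]
    if len(carriers) < 2:
        raise ValueError(
            f"marker {holdout_marker!r} measured in {len(carriers)} tube(s); need >= 2"
        )
    if reference is None:
        reference = carriers[0]
    donor_id = next(t for t in carriers if t != reference)
    ref, donor = tubes[reference], tubes[donor_id]
    if backbone_markers is None:
        backbone_markers = [
            "FSC", "SSC", "CD45", "CD117", "HLA-DR",
        ] + (["CD33"] if ref.has_marker("CD33") and donor.has_marker("CD33") else [])
        backbone_markers = [
            m for m in backbone_markers if ref.has_marker(m) and donor.has_marker(m)
        ]
    backbone = sorted(set(backbone_markers) - {holdout_marker})

    ref_z = _backbone_matrix(ref, backbone)
    donor_z = _backbone_matrix(donor, backbone)
    nn = _nearest_neighbours(donor_z, ref_z, k)
    imputed = donor.column(holdout_marker)[nn].mean(axis=1)
    measured = ref.column(holdout_marker)
    mae = float(np.median(np.abs(imputed - measured)))
    ks = float(ks_2samp(imputed, measured, method="asymp").statistic)
    return NoiseScore(
        marker=holdout_marker,
        holdout_tube=reference,
        donor_tube=donor_id,
        median_abs_error_fu=mae,
        cdf_distance=ks,
    )
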