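"""Ki-67 / Bcl-2 positivity gating and index computation.

The Ki-67 proliferation index and the Bcl-2 anti-apoptotic index of a
cell population are the fractions of its cells positive for the
respective marker.  Four gating strategies decide positivity:

``rectangle``
    marker intensity above a control-derived cutoff (an axis-aligned
    box over the full SSC range);
``polygon``
    an adaptive boundary that follows the control distribution per SSC
    bin — the deterministic surrogate of a manually drawn polygon that
    hugs the negative cloud;
``fixed40`` / ``fixed100``
    predefined cutoffs at exactly 40 and 100 FU, ignoring controls.

Control-derived cutoffs come from the IgG1 isotype control channels (or
the marker-negative events as internal biological controls), taken as a
high order statistic (default 99.5th percentile) of the control
distribution; when tubes are merged, the isotype control is preferred
because merging introduces a small amount of imputation noise.

Fractions are exact ratios of integer counts.  QC flags follow the
acquisition rules: fewer than 100 positive cells → ``insufficient_
positives``; an empty population → ``insufficient_population`` with the
fraction reported as missing, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fcs_io import EventTable
from .gating import Gate, PopulationMask, positivity_threshold

__all__ = [
    "STRATEGIES",
    "MARKERS",
    "PositivityConfig",
    "StrategyThresholds",
    "IndexResult",
    "GatedSample",
    "ControlInsufficiencyError",
    "control_threshold",
    "build_strategy_gate",
    "positive_fraction",
    "compute_all_indices",
    "indices_to_frame",
]

STRATEGIES = ("polygon", "rectangle", "fixed40", "fixed100")
MARKERS = ("Ki-67", "Bcl-2")

FIXED_LOW_FU = 40.0
FIXED_HIGH_FU = 100.0

#: marker → default isotype-control channel
CONTROL_CHANNELS = {"Ki-67": "IgG1-FITC", "Bcl-2": "IgG1-PE-CF594"}


class ControlInsufficiencyError(ValueError):
    """Too few control events to anchor a threshold."""


@dataclass
class PositivityConfig:
    control_percentile: float = 99.5
    control_source: str = "isotype"        # or "internal_negative"
    min_control_events: int = 100          # per-population control minimum
    n_ssc_bins: int = 8
    # a 99.5th-percentile boundary needs a real tail sample per bin; below
    # this the bin is unpopulated and the polygon falls back to a rectangle
    min_bin_control: int = 100
    min_positive_cells: int = 100          # acquisition rule for a reliable index


@dataclass
class StrategyThresholds:
    """Control-derived and fixed cutoffs used by the four strategies."""

    control_cutoffs: dict[str, float] = field(default_factory=dict)
    fixed_low: float = FIXED_LOW_FU
    fixed_high: float = FIXED_HIGH_FU
    control_source: str = "isotype"

    def __post_init__(self) -> None:
        if not 0 < self.fixed_low < self.fixed_high:
            raise ValueError("fixed cutoffs must satisfy 0 < low < high")
        for marker, cut in self.control_cutoffs.items():
            if cut <= 0:
                raise ValueError(f"control cutoff for {marker!r} must be positive")


@dataclass
class IndexResult:
    """One positive-fraction measurement."""

    sample_id: str
    population: str
    marker: str
    strategy: str
    positive: int
    total: int
    fraction: float | None
    qc: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.positive > self.total:
            raise ValueError("positive count exceeds total")
        if self.fraction is not None and self.total > 0:
            assert abs(self.fraction - self.positive / self.total) < 1e-12


@dataclass
class GatedSample:
    """An event table with its population masks and control channels."""

    table: EventTable
    masks: dict[str, PopulationMask]
    control_channels: dict[str, str] = field(
        default_factory=lambda: dict(CONTROL_CHANNELS)
    )
    control_table: EventTable | None = None  # defaults to `table` (same events)
    cohort: str = ""


def _order_statistic(values: np.ndarray, percentile: float) -> float:
    """The ceil(p/100 * n)-th smallest value — an exact order statistic."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    k = min(n - 1, max(0, int(np.ceil(percentile / 100.0 * n)) - 1))
    return float(v[k])


def control_threshold(
    control_events: EventTable | np.ndarray,
    marker: str | None = None,
    percentile: float = 99.5,
    min_events: int = 500,
) -> float:
    """Control-anchored positivity cutoff in FU.

    The cutoff is the stated order statistic (default the 99.5th
    percentile) of the control distribution — the isotype control or the
    marker-negative population.  Raises
    :class:`ControlInsufficiencyError` below ``min_events`` events.
    """
    if isinstance(control_events, EventTable):
        if marker is None:
            raise ValueError("marker required with an EventTable control")
        values = control_events.column(marker)
    else:
        values = np.asarray(control_events, dtype=float)
    if len(values) < min_events:
        raise ControlInsufficiencyError(
            f"{len(values)} control events < required {min_events}"
        )
    return _order_statistic(values, percentile)


def build_strategy_gate(
    threshold: float,
    strategy: str,
    marker_channel: str,
    ssc_channel: str = "SSC-INT",
    population_ssc: np.ndarray | None = None,
    control_marker: np.ndarray | None = None,
    control_ssc: np.ndarray | None = None,
    cfg: PositivityConfig | None = None,
) -> Gate:
    """Construct the positivity gate for one strategy.

    ``rectangle`` accepts marker ≥ *threshold* over the full SSC range;
    ``polygon`` follows the control's per-SSC-bin percentile (equal-count
    bins of the population's SSC), closed into a simple staircase
    polygon; ``fixed40``/``fixed100`` are 1-D thresholds at exactly 40
    and 100 FU regardless of controls.  A polygon request with fewer
    than 3 populated SSC bins falls back to the rectangle with a
    warning flag on the gate.
    """
    cfg = cfg or PositivityConfig()
    if strategy == "fixed40":
        return Gate("threshold1d", (marker_channel,), (FIXED_LOW_FU, "above"))
    if strategy == "fixed100":
        return Gate("threshold1d", (marker_channel,), (FIXED_HIGH_FU, "above"))
    if strategy == "rectangle":
        return Gate(
            "rectangle",
            (marker_channel, ssc_channel),
            {marker_channel: (threshold, np.inf), ssc_channel: (-np.inf, np.inf)},
        )
    if strategy != "polygon":
        raise ValueError(f"unknown strategy {strategy!r}")

    if population_ssc is None or control_marker is None or control_ssc is None:
        raise ValueError("polygon strategy needs population SSC and control arrays")
    edges = np.quantile(population_ssc, np.linspace(0, 1, cfg.n_ssc_bins + 1))
    edges = np.unique(edges)
    edges[0], edges[-1] = -np.inf, np.inf
    n_bins = len(edges) - 1
    cuts = np.full(n_bins, threshold)
    populated = 0
    bin_of_control = np.clip(np.searchsorted(edges, control_ssc, side="right") - 1, 0, n_bins - 1)
    for j in range(n_bins):
        sel = bin_of_control == j
        if int(sel.sum()) >= cfg.min_bin_control:
            cuts[j] = _order_statistic(control_marker[sel], cfg.control_percentile)
            populated += 1
    if populated < 3:
        gate = build_strategy_gate(threshold, "rectangle", marker_channel, ssc_channel)
        gate.warnings = ["fewer than 3 populated SSC bins; rectangle fallback"]  # type: ignore[attr-defined]
        return gate

    # staircase boundary closed into a simple polygon (SSC on x, marker on y)
    span = np.concatenate([control_ssc, population_ssc])
    x_lo, x_hi = float(np.min(span)) - 1.0, float(np.max(span)) + 1.0
    top = max(float(np.max(control_marker)), threshold, FIXED_HIGH_FU) * 1e3
    xs = np.concatenate([[x_lo], np.clip(edges[1:-1], x_lo, x_hi), [x_hi]])
    verts = []
    for j in range(n_bins):
        verts.append((xs[j], cuts[j]))
        verts.append((xs[j + 1], cuts[j]))
    verts += [(x_hi, top), (x_lo, top)]
    gate = Gate("polygon", (ssc_channel, marker_channel), np.array(verts))
    gate.bin_edges = edges          # type: ignore[attr-defined]
    gate.bin_cuts = cuts            # type: ignore[attr-defined]
    return gate


def _gate_positive(gate: Gate, table: EventTable) -> np.ndarray:
    """Positivity membership; adaptive polygons use their exact staircase."""
    if gate.kind == "polygon" and hasattr(gate, "bin_edges"):
        ssc = table.column(gate.axes[0])
        marker = table.column(gate.axes[1])
        edges = gate.bin_edges       # type: ignore[attr-defined]
        cuts = gate.bin_cuts         # type: ignore[attr-defined]
        b = np.clip(np.searchsorted(edges, ssc, side="right") - 1, 0, len(cuts) - 1)
        return marker >= cuts[b]
    return gate.contains(table)


def positive_fraction(
    table: EventTable,
    mask: PopulationMask | np.ndarray,
    marker: str,
    gate: Gate,
    strategy: str = "",
    cfg: PositivityConfig | None = None,
) -> IndexResult:
    """Exact positive fraction of a population under one gate.

    An empty population yields ``fraction=None`` with the
    ``insufficient_population`` flag — missing, never zero.  Fewer than
    100 positive cells raises the ``insufficient_positives`` flag.
    """
    cfg = cfg or PositivityConfig()
    m = mask.mask if isinstance(mask, PopulationMask) else np.asarray(mask, bool)
    total = int(m.sum())
    name = mask.name if isinstance(mask, PopulationMask) else ""
    if total == 0:
        return IndexResult(
            table.sample_id, name, marker, strategy, 0, 0, None,
            qc=["insufficient_population"],
        )
    pos = int((_gate_positive(gate, table) & m).sum())
    qc = []
    if pos < cfg.min_positive_cells:
        qc.append("insufficient_positives")
    return IndexResult(table.sample_id, name, marker, strategy, pos, total, pos / total, qc)


def compute_all_indices(
    sample: GatedSample,
    thresholds: StrategyThresholds | None = None,
    cfg: PositivityConfig | None = None,
) -> list[IndexResult]:
    """All 32 index measurements of a sample (4 populations × 2 markers
    × 4 strategies).

    Control-anchored strategies derive their cutoff per population from
    that population's events on the control channel (the isotype channel
    by default, the marker channel itself for ``internal_negative``
    controls); a population with too few control events borrows the
    singlet-wide control and is flagged ``control_fallback``.  A
    precomputed :class:`StrategyThresholds` bypasses the per-population
    derivation.
    """
    cfg = cfg or PositivityConfig()
    table = sample.table
    control_table = sample.control_table or table
    ssc_ch = table.channel_name("SSC")
    results: list[IndexResult] = []
    singlets = sample.masks["singlets"]
    for pop in ("blast", "erythroid", "myeloid", "monocytic"):
        mask = sample.masks[pop]
        for marker in MARKERS:
            marker_ch = table.channel_name(marker)
            internal = cfg.control_source == "internal_negative"
            if internal:
                # the marker-negative cloud of the population itself
                ctrl_ch = control_table.channel_name(marker)
            else:
                ctrl_ch = control_table.channel_name(sample.control_channels[marker])
            ctrl_all = control_table.column(ctrl_ch)
            qc_extra: list[str] = []
            ctrl_vals = ctrl_all[mask.mask]
            ctrl_ssc = control_table.column(ssc_ch)[mask.mask]
            if thresholds is not None and marker in thresholds.control_cutoffs:
                cut = thresholds.control_cutoffs[marker]
            else:
                if len(ctrl_vals) < cfg.min_control_events:
                    ctrl_vals = ctrl_all[singlets.mask]
                    ctrl_ssc = control_table.column(ssc_ch)[singlets.mask]
                    qc_extra.append("control_fallback")
                if internal and len(ctrl_vals):
                    neg_cut = positivity_threshold(ctrl_vals, fallback=np.inf)
                    keep = ctrl_vals < neg_cut
                    ctrl_vals, ctrl_ssc = ctrl_vals[keep], ctrl_ssc[keep]
                if len(ctrl_vals) == 0:
                    cut = FIXED_LOW_FU
                else:
                    cut = _order_statistic(ctrl_vals, cfg.control_percentile)
            for strategy in STRATEGIES:
                gate = build_strategy_gate(
                    cut,
                    strategy,
                    marker_ch,
                    ssc_ch,
                    population_ssc=table.column(ssc_ch)[mask.mask]
                    if mask.count else np.array([0.0]),
                    control_marker=ctrl_vals if len(ctrl_vals) else np.array([cut]),
                    control_ssc=ctrl_ssc if len(ctrl_ssc) else np.array([0.0]),
                    cfg=cfg,
                )
                res = positive_fraction(table, mask, marker, gate, strategy, cfg)
                res.qc.extend(qc_extra)
                results.append(res)
    return results


def indices_to_frame(
    results: list[IndexResult], cohort_by_sample: dict[str, str] | None = None
) -> pd.DataFrame:
    """Long-format index table (one row per measurement)."""
    rows = []
    for r in results:
        rows.append(
            {
                "sample_id": r.sample_id,
                "cohort": (cohort_by_sample or {}).get(r.sample_id, ""),
                "population": r.population,
                "marker": r.marker,
                "strategy": r.strategy,
                "positive": r.positive,
                "total": r.total,
                "fraction": np.nan if r.fraction is None else r.fraction,
                "qc": ";".join(r.qc),
            }
        )
    return pd.DataFrame(rows)
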