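"""Hierarchical gating of myeloid bone-marrow populations.

The strategy mirrors routine diagnostic practice: debris and doublets
are removed first, then four populations are gated from the singlet
events —

* **CD34+ blasts**: CD45-dim band (between the CD45-negative and the
  bright lymphocyte modes) and CD34 positivity;
* **erythroid cells**: CD45-negative events, minus CD13-positive cells,
  minus CD117− HLA-DR+ lymphoid cells, minus platelets (CD36+ CD71−),
  proliferating non-erythroid cells (CD36− CD71+) and non-nucleated red
  cells (CD71+ CD235a−);
* **myeloid (granulocytic) cells**: high SSC with dim/intermediate
  CD45, minus mature CD14+ monocytes, minus eosinophils (jointly high
  FITC/PE autofluorescence), minus immature CD117− HLA-DR+ monocytes;
* **monocytic cells**: backgated — mature CD14+, SSC-intermediate
  monocytes seed a region in SSC vs CD45 that captures the total
  monocyte population, after which CD13-high myeloid and CD10+ CD11b−
  lymphoid events are excluded.

Manual gate placement is replaced by a deterministic surrogate: 1-D
thresholds sit at valleys of a kernel-smoothed density of the log
intensities (Silverman bandwidth), with fixed fallback constants when a
distribution is not bimodal.  All tunable constants live in
:class:`GatingConfig`; changing them must never break the containment
and exclusivity invariants, which hold by construction.

Population fractions are reported against the *relevant event* count:
events remaining after debris exclusion alone, with erythroid cells and
doublets retained.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .fcs_io import EventTable

__all__ = [
    "Gate",
    "PopulationMask",
    "PopulationFractions",
    "GatingConfig",
    "EmptySampleError",
    "DegenerateSeedWarning",
    "log_density",
    "find_modes_valleys",
    "min_density_valley",
    "positivity_threshold",
    "exclude_debris_doublets",
    "count_relevant_events",
    "relevant_mask",
    "gate_cd34_blasts",
    "gate_erythroid",
    "gate_myeloid",
    "gate_monocytes",
    "gate_all",
    "population_fractions",
    "audit_table",
]


class EmptySampleError(ValueError):
    """Raised when a fraction denominator would be zero."""


class DegenerateSeedWarning(UserWarning):
    """Fewer mature-monocyte seed events than required for backgating."""


@dataclass
class Gate:
    """A geometric gate: rectangle, polygon or 1-D threshold.

    ``geometry`` is ``{axis: (min, max)}`` for rectangles, an ordered
    ``(n, 2)`` vertex array for polygons and ``(cutoff, side)`` with
    ``side in {"above", "below"}`` for 1-D thresholds.
    """

    kind: str
    axes: tuple[str, ...]
    geometry: object

    def __post_init__(self) -> None:
        if self.kind not in ("rectangle", "polygon", "threshold1d"):
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if self.kind == "polygon":
            verts = np.asarray(self.geometry, dtype=float)
            if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
                raise ValueError("polygon needs >= 3 (x, y) vertices")
            self.geometry = verts
        if self.kind == "rectangle":
            for ax, (lo, hi) in dict(self.geometry).items():
                if not lo < hi:
                    raise ValueError(f"rectangle axis {ax!r}: min must be < max")

    def contains(self, table: EventTable) -> np.ndarray:
        """Boolean membership of every event of *table*."""
        if self.kind == "threshold1d":
            cutoff, side = self.geometry
            x = table.column(self.axes[0])
            return x > cutoff if side == "above" else x < cutoff
        if self.kind == "rectangle":
            mask = np.ones(table.n_events, dtype=bool)
            for ax, (lo, hi) in dict(self.geometry).items():
                x = table.column(ax)
                mask &= (x >= lo) & (x <= hi)
            return mask
        from matplotlib.path import Path as _MplPath

        pts = np.column_stack([table.column(self.axes[0]), table.column(self.axes[1])])
        return _MplPath(np.asarray(self.geometry)).contains_points(pts)


@dataclass
class PopulationMask:
    """Named boolean event membership with a parent reference."""

    name: str
    mask: np.ndarray
    parent: "PopulationMask | None" = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.parent is not None:
            if len(self.parent.mask) != len(self.mask):
                raise ValueError("mask length differs from parent")
            if np.any(self.mask & ~self.parent.mask):
                raise ValueError(f"mask {self.name!r} is not contained in its parent")

    def __len__(self) -> int:
        return len(self.mask)

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    def child(self, name: str, mask: np.ndarray) -> "PopulationMask":
        return PopulationMask(name, np.asarray(mask, bool) & self.mask, parent=self)

    def chain(self) -> list["PopulationMask"]:
        node, out = self, []
        while node is not None:
            out.append(node)
            node = node.parent
        return out[::-1]


@dataclass
class PopulationFractions:
    """Counts and percentages of relevant events for the four populations."""

    counts: dict[str, int]
    relevant_count: int

    @property
    def fractions(self) -> dict[str, float]:
        return {p: 100.0 * c / self.relevant_count for p, c in self.counts.items()}

    def rounded(self) -> dict[str, float]:
        """Fractions reported to 0.1 percent, as in the study tables."""
        return {p: round(f, 1) for p, f in self.fractions.items()}


@dataclass
class GatingConfig:
    """Every smoothing constant and fallback of the gating surrogate."""

    kde_grid: int = 512
    kde_max_points: int = 30_000
    kde_rel_mode_height: float = 0.03     # min mode height relative to the global mode
    debris_ceiling: float = 60.0          # FU; FSC modes below this are debris
    cd45_neg_ceiling: float = 60.0        # FU; CD45 modes below this are negative
    cd45_bright_floor: float = 450.0      # FU; CD45 modes above this are lymphocyte-bright
    ssc_high_floor: float = 250.0         # FU; SSC modes above this count as granulocytic
    ssc_rel_mode_height: float = 0.05
    doublet_mad_k: float = 4.0            # singlet band = median +/- k * MAD of INT/PEAK ratio
    marker_threshold_fallback: float = 100.0   # FU, used when a marker is not bimodal
    eosinophil_tail_q: float = 0.995      # joint FITC/PE upper-tail quantile
    eosinophil_cond_q: float = 0.90       # conditioning quantile for the joint tail
    min_mono_seeds: int = 50
    mono_box_pad: float = 0.15            # log-scale expansion of the seed bounding box
    cd13_high_floor: float = 200.0        # FU; CD13-high exclusion never cuts below this
    mono_fallback_box: tuple[tuple[float, float], tuple[float, float]] = (
        (90.0, 280.0),    # SSC band
        (140.0, 420.0),   # CD45 band
    )


# ---------------------------------------------------------------------------
# Density-valley machinery


def _log_sketch(x: np.ndarray, max_points: int) -> np.ndarray:
    """Evenly spaced order statistics of log10(x) — deterministic and
    invariant to event order."""
    x = np.asarray(x, dtype=float)
    x = np.log10(np.clip(x, 1e-3, None))
    x = np.sort(x)
    if len(x) > max_points:
        idx = np.linspace(0, len(x) - 1, max_points).round().astype(int)
        x = x[idx]
    return x


def log_density(
    x: np.ndarray, grid: int = 512, max_points: int = 30_000
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel-smoothed density of log10 intensities (Silverman bandwidth).

    Returns ``(locations_in_FU, density)`` on an even log-space grid.
    """
    s = _log_sketch(x, max_points)
    lo, hi = s[0] - 0.05, s[-1] + 0.05
    g = np.linspace(lo, hi, grid)
    if s[-1] - s[0] < 1e-9:   # degenerate: all values equal
        d = np.zeros(grid)
        d[np.argmin(np.abs(g - s[0]))] = 1.0
        return 10.0 ** g, d
    kde = gaussian_kde(s, bw_method="silverman")
    return 10.0 ** g, kde(g)


def find_modes_valleys(
    x: np.ndarray,
    rel_mode_height: float = 0.03,
    grid: int = 512,
    max_points: int = 30_000,
) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Locate density modes and valleys of a 1-D intensity distribution.

    Returns ``(mode_locations, valley_locations, (grid, density))`` in
    FU.  Modes below ``rel_mode_height`` times the tallest mode are
    discarded; valleys are all interior local minima.
    """
    locs, dens = log_density(x, grid=grid, max_points=max_points)
    d1 = np.diff(dens)
    sign = np.sign(d1)
    sign[sign == 0] = 1
    turns = np.diff(sign)
    max_idx = np.where(turns < 0)[0] + 1
    min_idx = np.where(turns > 0)[0] + 1
    if len(max_idx):
        keep = dens[max_idx] >= rel_mode_height * dens[max_idx].max()
        max_idx = max_idx[keep]
    return locs[max_idx], locs[min_idx], (locs, dens)


def min_density_valley(
    grid: np.ndarray, density: np.ndarray, lo: float, hi: float
) -> float | None:
    """Location of the minimum-density point strictly between *lo* and *hi*."""
    sel = (grid > lo) & (grid < hi)
    if not np.any(sel):
        return None
    idx = np.where(sel)[0]
    return float(grid[idx[np.argmin(density[idx])]])


def positivity_threshold(
    values: np.ndarray,
    fallback: float = 100.0,
    rel_mode_height: float = 0.03,
    cfg: GatingConfig | None = None,
) -> float:
    """Marker positivity cutoff: the minimum-density valley between the
    lowest and the highest mode, or a fixed fallback when unimodal."""
    if cfg is not None:
        rel_mode_height = cfg.kde_rel_mode_height
    modes, _, (grid, dens) = find_modes_valleys(values, rel_mode_height)
    if len(modes) < 2:
        return float(fallback)
    v = min_density_valley(grid, dens, modes[0], modes[-1])
    return float(fallback) if v is None else v


def _debris_threshold(fsc: np.ndarray, cfg: GatingConfig) -> float | None:
    """FSC cutoff below which events are debris; None when no debris mode."""
    modes, _, (grid, dens) = find_modes_valleys(fsc, cfg.kde_rel_mode_height)
    low = modes[modes < cfg.debris_ceiling]
    high = modes[modes >= cfg.debris_ceiling]
    if len(low) == 0 or len(high) == 0:
        return None
    return min_density_valley(grid, dens, low[-1], high[0])


def _cd45_bands(cd45: np.ndarray, cfg: GatingConfig) -> tuple[float, float]:
    """(lower, upper) CD45 bounds of the dim/intermediate band."""
    modes, _, (grid, dens) = find_modes_valleys(cd45, cfg.kde_rel_mode_height)
    if len(modes) < 2:
        return float(np.quantile(cd45, 0.05)), float(np.quantile(cd45, 0.995))
    neg = modes[modes < cfg.cd45_neg_ceiling]
    bright = modes[modes > cfg.cd45_bright_floor]
    mid = modes[(modes >= cfg.cd45_neg_ceiling) & (modes <= cfg.cd45_bright_floor)]
    lo = 0.0
    if len(neg) and len(mid):
        v = min_density_valley(grid, dens, neg[-1], mid[0])
        lo = v if v is not None else 0.0
    elif len(neg) and len(bright):
        v = min_density_valley(grid, dens, neg[-1], bright[0])
        lo = v if v is not None else 0.0
    hi = np.inf
    if len(bright) and (len(mid) or len(neg)):
        left = mid[-1] if len(mid) else neg[-1]
        v = min_density_valley(grid, dens, left, bright[0])
        hi = v if v is not None else np.inf
    return float(lo), float(hi)


def _ssc_cut(ssc: np.ndarray, cfg: GatingConfig) -> float:
    """SSC cutoff above which events count as high-SSC granulocytic."""
    modes, _, (grid, dens) = find_modes_valleys(ssc, cfg.ssc_rel_mode_height)
    high = modes[modes >= cfg.ssc_high_floor]
    if len(high) == 0:
        return float(np.quantile(ssc, 0.99))
    hmode = high[0]
    left = modes[modes < hmode]
    lo = left[-1] if len(left) else float(np.min(ssc))
    v = min_density_valley(grid, dens, lo, hmode)
    return float(np.quantile(ssc, 0.99)) if v is None else v


# ---------------------------------------------------------------------------
# Gating steps


def _all_events_mask(ev: EventTable) -> PopulationMask:
    return PopulationMask("all", np.ones(ev.n_events, dtype=bool))


def _require(ev: EventTable, markers: list[str]) -> None:
    missing = [m for m in markers if not ev.has_marker(m)]
    if missing:
        raise KeyError(f"required channels absent: {missing}")


def relevant_mask(ev: EventTable, cfg: GatingConfig | None = None) -> np.ndarray:
    """Events surviving debris exclusion on FSC alone (doublets and
    erythroid cells retained) — the relevant-event definition."""
    cfg = cfg or GatingConfig()
    _require(ev, ["FSC", "SSC"])
    fsc = ev.column("FSC")
    thr = _debris_threshold(fsc, cfg)
    if thr is None:
        return np.ones(ev.n_events, dtype=bool)
    return fsc > thr


def count_relevant_events(ev: EventTable, cfg: GatingConfig | None = None) -> int:
    """Number of relevant events (post-debris, erythroid retained)."""
    return int(relevant_mask(ev, cfg).sum())


def exclude_debris_doublets(
    ev: EventTable, cfg: GatingConfig | None = None
) -> PopulationMask:
    """Singlet mask: debris removed on an FSC density valley, doublets
    removed on the integral/peak forward-scatter ratio band."""
    cfg = cfg or GatingConfig()
    _require(ev, ["FSC", "SSC"])
    keep = relevant_mask(ev, cfg)
    if ev.has_marker("FS-PEAK"):
        ratio = ev.column("FSC") / np.clip(ev.column("FS-PEAK"), 1e-9, None)
        r = ratio[keep]
        med = np.median(r)
        mad = np.median(np.abs(r - med))
        band = cfg.doublet_mad_k * max(mad, 1e-12)
        keep = keep & (np.abs(ratio - med) <= band)
    return PopulationMask("singlets", keep, parent=_all_events_mask(ev))


def gate_cd34_blasts(
    ev: EventTable, singlets: PopulationMask, cfg: GatingConfig | None = None
) -> PopulationMask:
    """CD34-positive blasts: CD45-dim band plus CD34 positivity."""
    cfg = cfg or GatingConfig()
    _require(ev, ["CD45", "CD34"])
    cd45 = ev.column("CD45")
    cd34 = ev.column("CD34")
    s = singlets.mask
    lo, hi = _cd45_bands(cd45[s], cfg)
    thr34 = positivity_threshold(cd34[s], cfg.marker_threshold_fallback, cfg=cfg)
    band = singlets.child("cd45_dim", (cd45 >= lo) & (cd45 < hi))
    return band.child("blast", cd34 > thr34)


def gate_erythroid(
    ev: EventTable, singlets: PopulationMask, cfg: GatingConfig | None = None
) -> PopulationMask:
    """Erythroid cells via the sequential exclusion chain.

    CD45-negative events → remove CD13-positive (CD33 when the panel
    carries no CD13) → remove CD117− HLA-DR+ lymphoid → remove platelets
    (CD36+ CD71−), proliferating non-erythroid (CD36− CD71+) and
    non-nucleated red cells (CD71+ CD235a−).  Every intermediate mask
    stays reachable through the parent chain.
    """
    cfg = cfg or GatingConfig()
    myelo_marker = "CD13" if ev.has_marker("CD13") else "CD33"
    _require(ev, ["CD45", myelo_marker, "CD117", "HLA-DR", "CD36", "CD71", "CD235a"])
    s = singlets.mask
    cd45 = ev.column("CD45")
    lo, _ = _cd45_bands(cd45[s], cfg)
    m = singlets.child("cd45_negative", cd45 < lo)

    fb = cfg.marker_threshold_fallback
    thr13 = positivity_threshold(ev.column(myelo_marker)[s], fb, cfg=cfg)
    m = m.child("minus_cd13_pos", ~(ev.column(myelo_marker) > thr13))

    thr117 = positivity_threshold(ev.column("CD117")[s], fb, cfg=cfg)
    thrdr = positivity_threshold(ev.column("HLA-DR")[s], fb, cfg=cfg)
    lymphoid = (ev.column("CD117") <= thr117) & (ev.column("HLA-DR") > thrdr)
    m = m.child("minus_lymphoid", ~lymphoid)

    thr36 = positivity_threshold(ev.column("CD36")[s], fb, cfg=cfg)
    thr71 = positivity_threshold(ev.column("CD71")[s], fb, cfg=cfg)
    thr235 = positivity_threshold(ev.column("CD235a")[s], fb, cfg=cfg)
    cd36, cd71, cd235 = ev.column("CD36"), ev.column("CD71"), ev.column("CD235a")
    m = m.child("minus_platelets", ~((cd36 > thr36) & (cd71 <= thr71)))
    m = m.child("minus_proliferating_nonery", ~((cd36 <= thr36) & (cd71 > thr71)))
    m = m.child("minus_nonnucleated_rbc", ~((cd71 > thr71) & (cd235 <= thr235)))
    return PopulationMask("erythroid", m.mask, parent=m.parent)


def _fitc_pe_channels(ev: EventTable) -> tuple[str, str]:
    fitc = "Ki-67" if ev.has_marker("Ki-67") else "IgG1-FITC"
    pe = "Bcl-2" if ev.has_marker("Bcl-2") else "IgG1-PE-CF594"
    return fitc, pe


def _autofluor_tail(ev: EventTable, mask: np.ndarray, cfg: GatingConfig) -> np.ndarray:
    """Eosinophil-like autofluorescence: events in the upper FITC *or* PE
    tail, with each channel's tail quantile conditioned on the other
    channel being unremarkable (so the autofluorescent cloud itself does
    not inflate the cutoff)."""
    fitc_m, pe_m = _fitc_pe_channels(ev)
    fitc = ev.column(fitc_m)
    pe = ev.column(pe_m)
    if mask.sum() < 20:
        return np.zeros(ev.n_events, dtype=bool)
    cond_f = fitc[mask] <= np.quantile(fitc[mask], cfg.eosinophil_cond_q)
    cond_p = pe[mask] <= np.quantile(pe[mask], cfg.eosinophil_cond_q)
    qf = np.quantile(fitc[mask][cond_p], cfg.eosinophil_tail_q)
    qp = np.quantile(pe[mask][cond_f], cfg.eosinophil_tail_q)
    return (fitc > qf) & (pe > qp)


def gate_myeloid(
    ev: EventTable, singlets: PopulationMask, cfg: GatingConfig | None = None
) -> PopulationMask:
    """Granulocytic cells: high SSC, dim CD45, minus mature monocytes,
    eosinophils (joint FITC/PE autofluorescence tail) and immature
    CD117− HLA-DR+ monocytes."""
    cfg = cfg or GatingConfig()
    _require(ev, ["SSC", "CD45", "CD14", "CD117", "HLA-DR"])
    s = singlets.mask
    ssc = ev.column("SSC")
    cd45 = ev.column("CD45")
    lo, hi = _cd45_bands(cd45[s], cfg)
    cut = _ssc_cut(ssc[s], cfg)
    m = singlets.child("ssc_high_cd45_dim", (ssc > cut) & (cd45 >= lo) & (cd45 < hi))

    thr14 = positivity_threshold(
        ev.column("CD14")[s], cfg.marker_threshold_fallback, cfg=cfg
    )
    m = m.child("minus_mature_monocytes", ~(ev.column("CD14") > thr14))

    m = m.child("minus_eosinophils", ~_autofluor_tail(ev, m.mask, cfg))

    fb = cfg.marker_threshold_fallback
    thr117 = positivity_threshold(ev.column("CD117")[s], fb, cfg=cfg)
    thrdr = positivity_threshold(ev.column("HLA-DR")[s], fb, cfg=cfg)
    imm = (ev.column("CD117") <= thr117) & (ev.column("HLA-DR") > thrdr)
    m = m.child("minus_immature_monocytes", ~imm)
    return PopulationMask("myeloid", m.mask, parent=m.parent)


def gate_monocytes(
    ev: EventTable, singlets: PopulationMask, cfg: GatingConfig | None = None
) -> PopulationMask:
    """Total monocytes by backgating from mature CD14+ seeds.

    The seed population's bounding box in SSC vs CD45 (log-expanded) is
    the total-monocyte region; CD13-high myeloid and CD10+ CD11b−
    lymphoid events are then excluded.  With fewer than
    ``cfg.min_mono_seeds`` seeds a fixed SSC/CD45 band is used and a
    :class:`DegenerateSeedWarning` is raised.
    """
    cfg = cfg or GatingConfig()
    _require(ev, ["SSC", "CD45", "CD14", "CD13", "CD10", "CD11b"])
    s = singlets.mask
    ssc = ev.column("SSC")
    cd45 = ev.column("CD45")
    cd14 = ev.column("CD14")
    warns: list[str] = []

    thr14 = positivity_threshold(cd14[s], cfg.marker_threshold_fallback, cfg=cfg)
    cut = _ssc_cut(ssc[s], cfg)
    seeds = s & (cd14 > thr14) & (ssc <= np.quantile(ssc[s], 0.995))
    if int(seeds.sum()) >= cfg.min_mono_seeds:
        pad = 1.0 + cfg.mono_box_pad
        ssc_lo, ssc_hi = np.quantile(ssc[seeds], [0.01, 0.99])
        cd45_lo, cd45_hi = np.quantile(cd45[seeds], [0.01, 0.99])
        box = ((ssc_lo / pad, ssc_hi * pad), (cd45_lo / pad, cd45_hi * pad))
    else:
        msg = (
            f"only {int(seeds.sum())} mature-monocyte seed events "
            f"(< {cfg.min_mono_seeds}); falling back to a fixed SSC/CD45 band"
        )
        _warnings.warn(msg, DegenerateSeedWarning, stacklevel=2)
        warns.append(msg)
        box = cfg.mono_fallback_box
    (b_ssc_lo, b_ssc_hi), (b45_lo, b45_hi) = box
    in_box = (ssc >= b_ssc_lo) & (ssc <= b_ssc_hi) & (cd45 >= b45_lo) & (cd45 <= b45_hi)
    m = singlets.child("monocyte_region", in_box)
    # eosinophil autofluorescence also contaminates the backgated region
    m = m.child("minus_eosinophils", ~_autofluor_tail(ev, m.mask, cfg))

    # CD13-high exclusion targets granulocytic spillover into the box; the
    # cutoff sits at the valley between the two brightest CD13 modes
    # (monocyte-moderate vs granulocyte-high), floored so that a sample
    # without granulocytes cannot cut into the monocytes themselves
    cd13 = ev.column("CD13") if ev.has_marker("CD13") else ev.column("CD33")
    modes13, _, (grid13, dens13) = find_modes_valleys(cd13[s], cfg.kde_rel_mode_height)
    if len(modes13) >= 2:
        v13 = min_density_valley(grid13, dens13, modes13[-2], modes13[-1])
    else:
        v13 = None
    if v13 is None and m.count >= 20:
        v13 = float(np.quantile(cd13[m.mask], 0.995))
    thr13_high = max(v13 or cfg.marker_threshold_fallback, cfg.cd13_high_floor)
    m = m.child("minus_myeloid", ~(cd13 > thr13_high))

    fb = cfg.marker_threshold_fallback
    thr10 = positivity_threshold(ev.column("CD10")[s], fb, cfg=cfg)
    thr11b = positivity_threshold(ev.column("CD11b")[s], fb, cfg=cfg)
    lymphoid = (ev.column("CD10") > thr10) & (ev.column("CD11b") <= thr11b)
    m = m.child("minus_lymphoid", ~lymphoid)
    out = PopulationMask("monocytic", m.mask, parent=m.parent, warnings=warns)
    return out


def gate_all(
    ev: EventTable, cfg: GatingConfig | None = None
) -> dict[str, PopulationMask]:
    """Run the full strategy; final population masks are made pairwise
    disjoint by precedence (blast > erythroid > myeloid > monocytic)."""
    cfg = cfg or GatingConfig()
    singlets = exclude_debris_doublets(ev, cfg)
    blast = gate_cd34_blasts(ev, singlets, cfg)
    ery = gate_erythroid(ev, singlets, cfg)
    mye = gate_myeloid(ev, singlets, cfg)
    mono = gate_monocytes(ev, singlets, cfg)

    taken = blast.mask.copy()
    ery = PopulationMask("erythroid", ery.mask & ~taken, parent=ery.parent)
    taken |= ery.mask
    mye = PopulationMask("myeloid", mye.mask & ~taken, parent=mye.parent,
                         warnings=mye.warnings)
    taken |= mye.mask
    mono = PopulationMask("monocytic", mono.mask & ~taken, parent=mono.parent,
                          warnings=mono.warnings)
    return {
        "singlets": singlets,
        "blast": blast,
        "erythroid": ery,
        "myeloid": mye,
        "monocytic": mono,
    }


def population_fractions(
    masks: dict[str, PopulationMask], relevant_count: int
) -> PopulationFractions:
    """Percentages of relevant events for the four final populations."""
    if relevant_count <= 0:
        raise EmptySampleError("no relevant events: empty sample")
    counts = {
        p: masks[p].count for p in ("blast", "erythroid", "myeloid", "monocytic")
    }
    return PopulationFractions(counts=counts, relevant_count=relevant_count)


def audit_table(masks: dict[str, PopulationMask]) -> pd.DataFrame:
    """Audit trail: event index → slash-joined population path per gate."""
    rows = {}
    for name, mask in masks.items():
        if name == "singlets":
            continue
        path = "/".join(node.name for node in mask.chain())
        idx = np.where(mask.mask)[0]
        for i in idx:
            rows.setdefault(int(i), []).append(path)
    return pd.DataFrame(
        {
            "event_index": list(rows),
            "population_path": [";".join(v) for v in rows.values()],
        }
    ).sort_values("event_index", ignore_index=True)
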