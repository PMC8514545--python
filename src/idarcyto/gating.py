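"""Hierarchical gating of the 8-color myeloid panel.

The default gate tree reproduces the sequential template used for this
panel: singlets on FSC-A/FSC-H, neutrophil/mononuclear split on SSC/CD45,
HLA-DR+ selection, a total-monocyte gate with a dendritic-cell gate
(HLA-DR+ CD14- CD16-), exclusion of residual CD14- CD91- lymphoid events,
isolation of CD91low monocytes (M7) and CD14low nonclassical monocytes
(M6), a five-way beta7 x CD16 split of CD14+ CD91+ monocytes (M1..M5),
and a CD91/CD123 split of the DC gate into mDC and pDC.

Gating operates on arcsinh-transformed fluorescence (default cofactor
150) and raw scatter.  Manual per-sample gate adjustment is replaced by
deterministic density-valley placement of the designated 1D thresholds
with a quantile fallback (`auto_adjust_gates`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter1d

from .panel import FLUORO_CHANNELS, SCATTER_CHANNELS, TERMINAL_POPULATIONS

Bound = float | str | None  # float, named threshold, or unbounded


@dataclass
class Gate:
    """One rectangular (or ratio-band) gate evaluated within its parent."""

    name: str
    parent: str  # gate name or "ROOT"
    channel_x: str
    channel_y: str | None = None
    x_min: Bound = None
    x_max: Bound = None
    y_min: Bound = None
    y_max: Bound = None
    mode: str = "keep"  # keep events inside, or "exclude" them
    kind: str = "rect"  # "rect" or "ratio" (channel_y / channel_x band)


@dataclass
class AutoThreshold:
    """A 1D boundary placed at the deepest density valley within a window."""

    channel: str
    parent: str
    window: tuple[float, float]
    default: float
    fallback_quantile: float = 0.5


@dataclass
class GateTree:
    """Ordered gates + named thresholds + transform specification."""

    gates: list[Gate]
    thresholds: dict[str, float]
    auto: dict[str, AutoThreshold]
    cofactor: float = 150.0
    flags: list[str] = field(default_factory=list)

    def copy(self) -> "GateTree":
        return GateTree(
            gates=[dataclasses.replace(g) for g in self.gates],
            thresholds=dict(self.thresholds),
            auto=dict(self.auto),
            cofactor=self.cofactor,
            flags=list(self.flags),
        )

    def gate(self, name: str) -> Gate:
        for g in self.gates:
            if g.name == name:
                return g
        raise KeyError(name)

    def validate(self) -> None:
        seen = {"ROOT"}
        for g in self.gates:
            if g.parent not in seen:
                raise ValueError(f"gate {g.name}: parent {g.parent} not defined before it")
            seen.add(g.name)
            for lo, hi, ax in ((g.x_min, g.x_max, "x"), (g.y_min, g.y_max, "y")):
                lo_v = self._resolve(lo)
                hi_v = self._resolve(hi)
                if lo_v is not None and hi_v is not None and not lo_v < hi_v:
                    raise ValueError(f"gate {g.name}: degenerate {ax} bounds [{lo_v}, {hi_v}]")

    def _resolve(self, b: Bound) -> float | None:
        if b is None:
            return None
        if isinstance(b, str):
            return self.thresholds[b]
        return float(b)


@dataclass
class PopulationMap:
    """Event-index sets per named population (0-based indices)."""

    populations: dict[str, np.ndarray]
    n_events: int
    flags: list[str] = field(default_factory=list)

    def count(self, name: str) -> int:
        return int(len(self.populations[name]))

    def __getitem__(self, name: str) -> np.ndarray:
        return self.populations[name]


# ---------------------------------------------------------------------------
# Transforms and compensation
# ---------------------------------------------------------------------------

def transform_events(events: pd.DataFrame, cofactor: float = 150.0) -> pd.DataFrame:
    """arcsinh-transform fluorescence channels; scatter passes through."""
    out = events.copy()
    for ch in FLUORO_CHANNELS:
        out[ch] = np.arcsinh(events[ch].to_numpy() / cofactor)
    return out


def apply_compensation(events: pd.DataFrame, spillover: np.ndarray) -> pd.DataFrame:
    """Linear unmixing: solve recorded = compensated @ spillover.T.

    Scatter channels are untouched.  Raises ``ValueError`` for a singular
    or wrongly shaped matrix.
    """
    s = np.asarray(spillover, dtype=float)
    n = len(FLUORO_CHANNELS)
    if s.shape != (n, n):
        raise ValueError(f"spillover must be {n}x{n}, got {s.shape}")
    if np.linalg.matrix_rank(s) < n:
        raise ValueError("spillover matrix is singular; invalid compensation input")
    recorded = events[list(FLUORO_CHANNELS)].to_numpy()
    compensated = np.linalg.solve(s, recorded.T).T
    out = events.copy()
    out[list(FLUORO_CHANNELS)] = compensated
    return out


# ---------------------------------------------------------------------------
# Default tree
# ---------------------------------------------------------------------------

#: Default named thresholds in transformed (arcsinh x/150) units.
DEFAULT_THRESHOLDS: dict[str, float] = {
    "hladr_pos": 2.5,   # HLA-DR+/- within mononuclear cells
    "cd14_neg": 2.0,    # CD14-: DC gate / lymphoid exclusion boundary
    "cd16_neg": 1.5,    # CD16-: DC gate boundary
    "cd91_low": 2.7,    # CD91low vs CD91+ (M7 boundary; also mDC/pDC split)
    "cd14_pos": 4.3,    # CD14low vs CD14+ (M6 boundary)
    "itgb7": 2.2,       # beta7- vs beta7+
    "cd16_low": 1.5,    # CD16- vs CD16low (M1 vs M2)
    "cd16_pos": 3.5,    # CD16low vs CD16+ (M2 vs M3; M4 vs M5)
    "cd123_pos": 3.5,   # pDC CD123 boundary
}

#: Scatter-space geometry (raw units).
DEFAULT_SCATTER = {
    "singlet_ratio": (0.8, 1.2),
    "ssc_split": 80_000.0,
    "neut_cd45": (2.5, 5.0),     # transformed CD45 window for neutrophils
    "mono_cd45_min": 4.2,        # transformed CD45 floor for mononuclear cells
}

#: Thresholds that auto-adjustment may move, in placement order.
DEFAULT_AUTO: dict[str, AutoThreshold] = {
    # fallback quantiles approximate the expected negative-side mass of
    # each boundary within its parent population
    "hladr_pos": AutoThreshold("HLADR", "MONONUCLEAR", (1.2, 3.8), 2.5, 0.75),
    "cd91_low": AutoThreshold("CD91", "MONO_NONLYMPH", (1.9, 3.5), 2.7, 0.02),
    "cd14_pos": AutoThreshold("CD14", "MONO_NONLYMPH", (3.4, 5.2), 4.3, 0.05),
    "itgb7": AutoThreshold("ITGB7", "CD14POS_CD91POS", (1.4, 3.0), 2.2, 0.95),
    "cd16_low": AutoThreshold("CD16", "CD14POS_CD91POS", (0.9, 2.1), 1.5, 0.85),
    "cd16_pos": AutoThreshold("CD16", "CD14POS_CD91POS", (2.9, 4.1), 3.5, 0.92),
}


def build_default_gate_tree(
    thresholds: dict[str, float] | None = None,
    scatter: dict | None = None,
    cofactor: float = 150.0,
    auto: dict[str, AutoThreshold] | None = None,
) -> GateTree:
    """Construct the default hierarchical gate tree for the panel."""
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    sc = dict(DEFAULT_SCATTER)
    if scatter:
        sc.update(scatter)
    rlo, rhi = sc["singlet_ratio"]
    ssc = sc["ssc_split"]
    ncd45_lo, ncd45_hi = sc["neut_cd45"]

    gates = [
        Gate("SINGLETS", "ROOT", "FSC-A", "FSC-H", x_min=rlo, x_max=rhi, kind="ratio"),
        Gate("NEUTROPHILS", "SINGLETS", "SSC-A", "CD45",
             x_min=ssc, y_min=ncd45_lo, y_max=ncd45_hi),
        Gate("MONONUCLEAR", "SINGLETS", "SSC-A", "CD45",
             x_max=ssc, y_min=sc["mono_cd45_min"]),
        Gate("HLADR_POS", "MONONUCLEAR", "HLADR", "CD14", x_min="hladr_pos"),
        Gate("DC_GATE", "HLADR_POS", "CD14", "CD16",
             x_max="cd14_neg", y_max="cd16_neg"),
        # total monocytes = HLA-DR+ cells outside the CD14-CD16- DC corner
        Gate("MONOCYTES_TOTAL", "HLADR_POS", "CD14", "CD16",
             x_max="cd14_neg", y_max="cd16_neg", mode="exclude"),
        # eliminate residual CD14- CD91- lymphoid events
        Gate("MONO_NONLYMPH", "MONOCYTES_TOTAL", "CD14", "CD91",
             x_max="cd14_neg", y_max="cd91_low", mode="exclude"),
        Gate("M7", "MONO_NONLYMPH", "CD91", None, x_max="cd91_low"),
        Gate("CD91_POS", "MONO_NONLYMPH", "CD91", None, x_min="cd91_low"),
        Gate("M6", "CD91_POS", "CD14", "ITGB7", x_max="cd14_pos", y_max="itgb7"),
        Gate("CD14POS_CD91POS", "CD91_POS", "CD14", None, x_min="cd14_pos"),
        Gate("M1", "CD14POS_CD91POS", "ITGB7", "CD16", x_max="itgb7", y_max="cd16_low"),
        Gate("M2", "CD14POS_CD91POS", "ITGB7", "CD16",
             x_max="itgb7", y_min="cd16_low", y_max="cd16_pos"),
        Gate("M3", "CD14POS_CD91POS", "ITGB7", "CD16", x_max="itgb7", y_min="cd16_pos"),
        Gate("M4", "CD14POS_CD91POS", "ITGB7", "CD16", x_min="itgb7", y_max="cd16_pos"),
        Gate("M5", "CD14POS_CD91POS", "ITGB7", "CD16", x_min="itgb7", y_min="cd16_pos"),
        Gate("MDC", "DC_GATE", "CD91", "CD123", x_min="cd91_low", y_max="cd123_pos"),
        Gate("PDC", "DC_GATE", "CD91", "CD123", x_max="cd91_low", y_min="cd123_pos"),
    ]
    tree = GateTree(gates=gates, thresholds=thr,
                    auto=dict(DEFAULT_AUTO if auto is None else auto),
                    cofactor=cofactor)
    tree.validate()
    return tree


def terminal_populations(tree: GateTree) -> list[str]:
    return [g.name for g in tree.gates if g.name in TERMINAL_POPULATIONS]


# ---------------------------------------------------------------------------
# Application
# ---------------------------------------------------------------------------

def _gate_mask(g: Gate, tree: GateTree, tdata: pd.DataFrame, parent: np.ndarray) -> np.ndarray:
    if g.kind == "ratio":
        x = tdata[g.channel_x].to_numpy()
        y = tdata[g.channel_y].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(x > 0, y / np.where(x > 0, x, 1.0), np.inf)
        inside = (ratio >= tree._resolve(g.x_min)) & (ratio <= tree._resolve(g.x_max))
    else:
        inside = np.ones(len(tdata), dtype=bool)
        for ch, lo, hi in ((g.channel_x, g.x_min, g.x_max), (g.channel_y, g.y_min, g.y_max)):
            if ch is None:
                continue
            v = tdata[ch].to_numpy()
            lo_v, hi_v = tree._resolve(lo), tree._resolve(hi)
            if lo_v is not None:
                inside &= v >= lo_v
            if hi_v is not None:
                inside &= v < hi_v
    if g.mode == "exclude":
        return parent & ~inside
    return parent & inside


def apply_gate_tree(events: pd.DataFrame, tree: GateTree) -> PopulationMap:
    """Descend the tree and return event-index sets per population."""
    if len(events) == 0:
        raise ValueError("empty event table")
    missing = [ch for ch in SCATTER_CHANNELS + FLUORO_CHANNELS if ch not in events.columns]
    if missing:
        raise ValueError(f"event table missing channels: {missing}")
    tree.validate()
    tdata = transform_events(events, tree.cofactor)
    masks: dict[str, np.ndarray] = {"ROOT": np.ones(len(events), dtype=bool)}
    for g in tree.gates:
        masks[g.name] = _gate_mask(g, tree, tdata, masks[g.parent])
    pops = {name: np.flatnonzero(m) for name, m in masks.items() if name != "ROOT"}
    pops["LEUKOCYTES"] = pops["SINGLETS"]
    return PopulationMap(populations=pops, n_events=len(events), flags=list(tree.flags))


# ---------------------------------------------------------------------------
# Automated threshold placement
# ---------------------------------------------------------------------------

def find_density_valley(
    values: np.ndarray,
    window: tuple[float, float],
    default: float,
    fallback_quantile: float = 0.5,
    bins: int = 128,
    smooth_bins: float = 3.0,
    min_events: int = 50,
) -> tuple[float, bool]:
    """Deepest interior minimum of the smoothed density inside ``window``.

    Returns ``(threshold, used_fallback)``.  With too few events the
    default is returned; with a unimodal marginal (no interior minimum)
    the configured quantile of the data, clipped to the window, is used.
    Both fallback paths are reported via the second return value.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < min_events:
        return default, True
    lo, hi = window
    grid_lo, grid_hi = lo - 0.75, hi + 0.75
    hist, edges = np.histogram(values, bins=bins, range=(grid_lo, grid_hi))
    dens = gaussian_filter1d(hist.astype(float), smooth_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if dens.sum() <= 0:
        return default, True
    dmax = dens.max()
    # a bin is a valid valley position when clearly higher density exists
    # on BOTH flanks (anywhere in the grid) relative to the bin itself
    left_peak = np.maximum.accumulate(np.concatenate([[0.0], dens[:-1]]))
    right_peak = np.maximum.accumulate(np.concatenate([[0.0], dens[::-1][:-1]]))[::-1]
    floor = 1.2 * dens + 0.002 * dmax
    valid = (
        (centers >= lo) & (centers <= hi)
        & (left_peak >= floor) & (right_peak >= floor)
    )
    if not valid.any():
        q = float(np.quantile(values, fallback_quantile))
        return float(np.clip(q, lo, hi)), True
    m0 = dens[valid].min()
    # contiguous run of (near-)minimal valid bins around the argmin; the
    # cut goes at the run center so wide empty valleys split mid-gap
    tol = 1.05 * m0 + 1e-12
    argmin = int(np.flatnonzero(valid)[np.argmin(dens[valid])])
    start = argmin
    while start - 1 >= 0 and valid[start - 1] and dens[start - 1] <= tol:
        start -= 1
    stop = argmin
    while stop + 1 < len(dens) and valid[stop + 1] and dens[stop + 1] <= tol:
        stop += 1
    return float(0.5 * (centers[start] + centers[stop])), False


def auto_adjust_gates(events: pd.DataFrame, tree: GateTree) -> GateTree:
    """Place every auto threshold at the density valley within its parent.

    Thresholds are adjusted in declared order, re-gating after each so
    that downstream parents reflect upstream boundaries.  Fallbacks are
    recorded in the returned tree's ``flags``.
    """
    adj = tree.copy()
    for name, spec in adj.auto.items():
        pops = apply_gate_tree(events, adj)
        parent_idx = pops[spec.parent]
        if len(parent_idx) == 0:
            adj.flags.append(f"auto_threshold_empty_parent:{name}")
            adj.thresholds[name] = spec.default
            continue
        vals = np.arcsinh(
            events[spec.channel].to_numpy()[parent_idx] / adj.cofactor
        )
        thr, fell_back = find_density_valley(
            vals, spec.window, spec.default, spec.fallback_quantile
        )
        if fell_back:
            adj.flags.append(f"auto_threshold_fallback:{name}")
        adj.thresholds[name] = thr
    return adj


# ---------------------------------------------------------------------------
# Gating config serialization
# ---------------------------------------------------------------------------

def tree_to_yaml(tree: GateTree, path) -> None:
    d = {
        "cofactor": tree.cofactor,
        "thresholds": tree.thresholds,
        "auto": {
            k: {"channel": a.channel, "parent": a.parent,
                "window": list(a.window), "default": a.default,
                "fallback_quantile": a.fallback_quantile}
            for k, a in tree.auto.items()
        },
        "gates": [dataclasses.asdict(g) for g in tree.gates],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def tree_from_yaml(path) -> GateTree:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    tree = GateTree(
        gates=[Gate(**g) for g in d["gates"]],
        thresholds=d["thresholds"],
        auto={
            k: AutoThreshold(a["channel"], a["parent"], tuple(a["window"]),
                             a["default"], a.get("fallback_quantile", 0.5))
            for k, a in d["auto"].items()
        },
        cofactor=d.get("cofactor", 150.0),
    )
    tree.validate()
    return tree
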