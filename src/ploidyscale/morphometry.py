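"""Per-neuron 3-D morphometry and population scaling statistics.

Neurites are measured as chains of conical frusta between consecutive
nodes; the cell body is modeled as a sphere of the (volume-equivalent)
soma radius.  Path lengths are referenced to the soma *surface*: the
stretch of a stem edge that lies inside the soma sphere is not counted
as neurite length, so a neuron whose first neurite node sits on the
soma surface has stem length 0 up to that node.

Population-level routines compute triploid/diploid fold changes with
bootstrap confidence intervals, classify each property as sub-, iso- or
super-scaling relative to the ploidy fold, compare length-weighted
diameter distributions with a permutation Kolmogorov-Smirnov test, and
test the stability of the neurite share trend with a CUSUM test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .swc import NeuronTree

__all__ = [
    "SegmentMetrics",
    "MorphometryRecord",
    "ScalingResult",
    "segment_metrics",
    "compartment_summary",
    "length_by_diameter",
    "weighted_ks",
    "sholl",
    "population_folds",
    "classify_scaling",
    "neurite_share_trend",
    "frustum_volume",
    "frustum_lateral_area",
]

RECORD_PROPERTIES = (
    "soma_volume", "soma_surface", "neurite_volume", "neurite_surface",
    "total_volume", "total_surface", "total_neurite_length",
    "mean_neurite_diameter", "max_radius", "n_terminal_points",
    "max_branch_level",
)


def frustum_volume(r1: float, r2: float, length: float) -> float:
    """Volume of a conical frustum with end radii r1, r2 and axial length."""
    return np.pi * length / 3.0 * (r1 * r1 + r1 * r2 + r2 * r2)


def frustum_lateral_area(r1: float, r2: float, length: float) -> float:
    """Lateral (side) surface area of a conical frustum."""
    slant = np.hypot(length, r2 - r1)
    return np.pi * (r1 + r2) * slant


@dataclass
class SegmentMetrics:
    """Per-edge geometry of one neuron's neurite arbor (parallel arrays)."""

    child: np.ndarray            # child node index of each edge
    parent: np.ndarray
    length: np.ndarray           # μm, soma-surface referenced on stems
    mean_diameter: np.ndarray    # μm, r1 + r2
    lateral_area: np.ndarray     # μm²
    volume: np.ndarray           # μm³
    branch_level: np.ndarray     # centrifugal order, stems = 1
    is_stem: np.ndarray          # True where the parent is a soma node

    def __len__(self) -> int:
        return len(self.child)


@dataclass
class MorphometryRecord:
    soma_volume: float
    soma_surface: float
    neurite_volume: float
    neurite_surface: float
    total_volume: float
    total_surface: float
    total_neurite_length: float
    mean_neurite_diameter: float      # length-weighted
    mean_neurite_diameter_unweighted: float
    max_radius: float
    n_terminal_points: int
    max_branch_level: int
    neurite_to_soma_volume_ratio: float
    neurite_to_soma_surface_ratio: float
    neurite_to_soma_av_ratio: float
    no_neurites: bool = False
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in RECORD_PROPERTIES}
        d.update(
            neurite_to_soma_volume_ratio=self.neurite_to_soma_volume_ratio,
            neurite_to_soma_surface_ratio=self.neurite_to_soma_surface_ratio,
            neurite_to_soma_av_ratio=self.neurite_to_soma_av_ratio,
        )
        d.update(self.metadata)
        return d


@dataclass
class ScalingResult:
    property_name: str
    fold_change: float
    reference_fold: float
    tolerance: float
    scaling_class: str  # {"subscaling", "scaling", "superscaling"}


def segment_metrics(tree: NeuronTree) -> SegmentMetrics:
    """Frustum geometry and centrifugal branch order for every neurite edge.

    An edge joins each non-soma node to its parent.  Stems (parent is a
    soma node) are measured from the soma surface: the chord length is
    reduced by the soma radius (clamped at zero) and the soma-side radius
    is taken from the child, so a stem is a cylinder stub rather than a
    cone anchored at the soma centre.
    """
    soma = tree.soma_mask()
    r_soma = tree.soma_radius()
    children = tree.children()

    # centrifugal order: stems start at 1, +1 after each neurite branch point
    level = np.zeros(tree.n_nodes, dtype=int)
    order = []
    stack = [(tree.root, 0)]
    while stack:
        node, lev = stack.pop()
        kids = children[node]
        for k in kids:
            if soma[k]:
                stack.append((k, 0))
                continue
            if soma[node]:
                klev = 1
            else:
                n_sib = sum(1 for s in children[node] if not soma[s])
                klev = lev + 1 if n_sib > 1 else lev
            level[k] = klev
            order.append(k)
            stack.append((k, klev))

    child_idx, parent_idx = [], []
    lengths, diams, areas, vols, levels, stems = [], [], [], [], [], []
    for k in order:
        p = int(tree.parent_id[k])
        chord = float(np.linalg.norm(tree.xyz[k] - tree.xyz[p]))
        if soma[p]:
            length = max(chord - r_soma, 0.0)
            r1 = r2 = float(tree.radius[k])
            is_stem = True
        else:
            length = chord
            r1 = float(tree.radius[p])
            r2 = float(tree.radius[k])
            is_stem = False
        child_idx.append(k)
        parent_idx.append(p)
        lengths.append(length)
        diams.append(r1 + r2)
        areas.append(frustum_lateral_area(r1, r2, length))
        vols.append(frustum_volume(r1, r2, length))
        levels.append(level[k])
        stems.append(is_stem)

    return SegmentMetrics(
        np.asarray(child_idx, dtype=int), np.asarray(parent_idx, dtype=int),
        np.asarray(lengths), np.asarray(diams), np.asarray(areas),
        np.asarray(vols), np.asarray(levels, dtype=int),
        np.asarray(stems, dtype=bool),
    )


def compartment_summary(tree: NeuronTree) -> MorphometryRecord:
    """Whole-neuron size parameters: compartment volumes, surfaces, lengths.

    The soma is a sphere of the root soma radius (multi-node somata use
    the volume-equivalent radius); neurite quantities are frustum sums.
    """
    r = tree.soma_radius()
    soma_volume = 4.0 / 3.0 * np.pi * r**3
    soma_surface = 4.0 * np.pi * r**2

    seg = segment_metrics(tree)
    centroid = tree.soma_centroid()
    max_radius = float(np.max(np.linalg.norm(tree.xyz - centroid, axis=1)))

    no_neurites = len(seg) == 0
    if no_neurites:
        neurite_volume = neurite_surface = total_len = 0.0
        mean_d = mean_d_unw = 0.0
        n_term = 0
        max_level = 0
    else:
        neurite_volume = float(seg.volume.sum())
        neurite_surface = float(seg.lateral_area.sum())
        total_len = float(seg.length.sum())
        wsum = seg.length.sum()
        mean_d = float((seg.length * seg.mean_diameter).sum() / wsum) if wsum > 0 else 0.0
        mean_d_unw = float(seg.mean_diameter.mean())
        soma = tree.soma_mask()
        children = tree.children()
        n_term = sum(
            1 for i in range(tree.n_nodes)
            if not soma[i] and not any(not soma[c] for c in children[i])
        )
        max_level = int(seg.branch_level.max())

    tv = soma_volume + neurite_volume
    ts = soma_surface + neurite_surface
    av_neur = neurite_surface / neurite_volume if neurite_volume > 0 else np.nan
    av_soma = soma_surface / soma_volume
    return MorphometryRecord(
        soma_volume=soma_volume,
        soma_surface=soma_surface,
        neurite_volume=neurite_volume,
        neurite_surface=neurite_surface,
        total_volume=tv,
        total_surface=ts,
        total_neurite_length=total_len,
        mean_neurite_diameter=mean_d,
        mean_neurite_diameter_unweighted=mean_d_unw,
        max_radius=max_radius,
        n_terminal_points=n_term,
        max_branch_level=max_level,
        neurite_to_soma_volume_ratio=neurite_volume / soma_volume,
        neurite_to_soma_surface_ratio=neurite_surface / soma_surface,
        neurite_to_soma_av_ratio=av_neur / av_soma if neurite_volume > 0 else np.nan,
        no_neurites=no_neurites,
        metadata=dict(tree.metadata),
    )


# ---------------------------------------------------------------------------
# length-by-diameter distributions and the weighted KS test


def length_by_diameter(segments: list[SegmentMetrics], grid: np.ndarray) -> np.ndarray:
    """Cumulative fraction of pooled neurite length at diameters ≤ grid.

    ``segments`` is a list of per-neuron :class:`SegmentMetrics`; the
    returned array has one value per grid point, ending at 1 once the
    grid covers every segment diameter.
    """
    if not segments or all(len(s) == 0 for s in segments):
        raise ValueError("length_by_diameter needs at least one segment")
    d = np.concatenate([s.mean_diameter for s in segments])
    w = np.concatenate([s.length for s in segments])
    grid = np.asarray(grid, dtype=float)
    order = np.argsort(d)
    d, w = d[order], w[order]
    cw = np.cumsum(w)
    total = cw[-1]
    idx = np.searchsorted(d, grid, side="right")
    frac = np.where(idx > 0, cw[np.maximum(idx - 1, 0)], 0.0) / total
    return frac


def _weighted_ecdf_on(values, weights, support):
    order = np.argsort(values)
    v, w = values[order], np.cumsum(weights[order])
    idx = np.searchsorted(v, support, side="right")
    cdf = np.where(idx > 0, w[np.maximum(idx - 1, 0)], 0.0) / w[-1]
    return cdf


def _weighted_ks_stat(va, wa, vb, wb) -> float:
    support = np.concatenate([va, vb])
    return float(np.max(np.abs(
        _weighted_ecdf_on(va, wa, support) - _weighted_ecdf_on(vb, wb, support)
    )))


def weighted_ks(
    group_a: list[tuple[np.ndarray, np.ndarray]],
    group_b: list[tuple[np.ndarray, np.ndarray]],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Length-weighted two-sample KS test with neuron-label permutation.

    Each group is a list of per-neuron ``(values, weights)`` pairs
    (diameters weighted by segment length).  D is the max vertical gap
    between the two weighted ECDFs; the two-sided p-value permutes
    whole neurons between groups, respecting within-neuron dependence.
    With unit weights and one neuron per observation this reduces to
    the classical two-sample KS statistic.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    import warnings
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation p-value")
    neurons = [(np.asarray(v, float), np.asarray(w, float)) for v, w in group_a]
    neurons += [(np.asarray(v, float), np.asarray(w, float)) for v, w in group_b]
    na = len(group_a)
    labels = np.arange(len(neurons))

    def stat(lab_a):
        in_a = np.zeros(len(neurons), dtype=bool)
        in_a[lab_a] = True
        va = np.concatenate([neurons[i][0] for i in range(len(neurons)) if in_a[i]])
        wa = np.concatenate([neurons[i][1] for i in range(len(neurons)) if in_a[i]])
        vb = np.concatenate([neurons[i][0] for i in range(len(neurons)) if not in_a[i]])
        wb = np.concatenate([neurons[i][1] for i in range(len(neurons)) if not in_a[i]])
        return _weighted_ks_stat(va, wa, vb, wb)

    d_obs = stat(labels[:na])
    if d_obs == 0.0:
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if stat(perm[:na]) >= d_obs - 1e-15:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return d_obs, float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Sholl profiles


def sholl(tree: NeuronTree, step: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Sholl intersection profile around the soma centroid.

    Counts, for each radius ``step, 2*step, ...`` up to the neuron's
    maximal radial extent, the number of neurite edges crossing the
    sphere of that radius.  An edge with endpoint distances d1 < d2
    crosses radius r when ``d1 < r <= d2`` (strict on the inner side,
    so a sphere tangent at an inner endpoint is not counted twice).
    Stem edges are anchored at the soma centroid for crossing purposes.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    centroid = tree.soma_centroid()
    soma = tree.soma_mask()
    dist = np.linalg.norm(tree.xyz - centroid, axis=1)
    edges = []
    for i in range(tree.n_nodes):
        p = tree.parent_id[i]
        if p < 0 or soma[i]:
            continue
        d_parent = 0.0 if soma[p] else dist[p]
        lo, hi = sorted((d_parent, dist[i]))
        edges.append((lo, hi))
    if not edges:
        return np.array([]), np.array([], dtype=int)
    max_r = max(hi for _, hi in edges)
    radii = np.arange(step, max_r + step * 0.5, step)
    lo = np.array([e[0] for e in edges])
    hi = np.array([e[1] for e in edges])
    counts = np.array([int(np.sum((lo < r) & (r <= hi))) for r in radii])
    return radii, counts


# ---------------------------------------------------------------------------
# population folds, scaling classes, neurite-share trend


def population_folds(
    diploid_records: list[MorphometryRecord],
    triploid_records: list[MorphometryRecord],
    properties: tuple[str, ...] = RECORD_PROPERTIES,
    n_boot: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Triploid/diploid fold change per property with bootstrap CIs.

    fold = mean(triploid) / mean(diploid); 95% percentile bootstrap over
    neurons; Welch t-test p-value per property.
    """
    if len(diploid_records) < 2 or len(triploid_records) < 2:
        raise ValueError("need at least 2 records per group")
    rng = np.random.default_rng(seed)
    rows = []
    for prop in properties:
        a = np.array([float(getattr(r, prop)) for r in diploid_records])
        b = np.array([float(getattr(r, prop)) for r in triploid_records])
        fold = b.mean() / a.mean()
        boots = np.empty(n_boot)
        for i in range(n_boot):
            ia = rng.integers(0, len(a), len(a))
            ib = rng.integers(0, len(b), len(b))
            boots[i] = b[ib].mean() / a[ia].mean()
        lo, hi = np.percentile(boots, [2.5, 97.5])
        t, p = stats.ttest_ind(b, a, equal_var=False)
        rows.append(dict(
            property=prop, fold=fold, ci_low=lo, ci_high=hi,
            n_diploid=len(a), n_triploid=len(b), t_stat=t, p_value=p,
        ))
    return pd.DataFrame(rows)


def classify_scaling(
    fold: float, reference_fold: float = 1.5, tolerance: float = 0.1,
    property_name: str = "",
) -> ScalingResult:
    """Sub/iso/super-scaling of a fold change against the ploidy fold."""
    if fold <= 0:
        raise ValueError("fold must be positive")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    if fold < reference_fold - tolerance:
        cls = "subscaling"
    elif fold > reference_fold + tolerance:
        cls = "superscaling"
    else:
        cls = "scaling"
    return ScalingResult(property_name, fold, reference_fold, tolerance, cls)


def neurite_share_trend(
    records: list[MorphometryRecord],
    share: str = "surface",
) -> dict:
    """Linear trend of neurite share vs total volume with a CUSUM stability test.

    Pools diploid and triploid neurons, regresses the neurite fraction of
    total volume or surface on total volume (OLS, 95% band) and runs an
    OLS-CUSUM structural-stability test along increasing total volume,
    with p-value from the Brownian-bridge sup boundary.
    """
    import statsmodels.api as sm
    from statsmodels.stats.diagnostic import breaks_cusumolsresid

    if len(records) < 10:
        raise ValueError("need at least 10 records")
    x = np.array([r.total_volume for r in records])
    if share == "surface":
        y = np.array([r.neurite_surface / r.total_surface for r in records])
    elif share == "volume":
        y = np.array([r.neurite_volume / r.total_volume for r in records])
    else:
        raise ValueError("share must be 'surface' or 'volume'")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x variance")
    order = np.argsort(x)
    x, y = x[order], y[order]
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X).summary_frame(alpha=0.05)
    if np.std(fit.resid) < 1e-12:  # perfect fit: trivially stable
        cusum_stat, cusum_p = 0.0, 1.0
    else:
        cusum_stat, cusum_p, _ = breaks_cusumolsresid(fit.resid, ddof=2)
    return dict(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_p=float(fit.pvalues[1]),
        band_low=pred["mean_ci_lower"].to_numpy(),
        band_high=pred["mean_ci_upper"].to_numpy(),
        x=x, y=y, fitted=fit.fittedvalues,
        cusum_stat=float(cusum_stat),
        cusum_p=float(cusum_p),
    )


def records_to_frame(records: list[MorphometryRecord]) -> pd.DataFrame:
    """Tidy one-row-per-neuron table of morphometry records."""
    return pd.DataFrame([r.as_dict() for r in records])
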