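"""Weighted co-expression module networks, eigengenes and the module graph.

The module pipeline follows the standard weighted-correlation-network
recipe: Pearson correlation of log-RFU within a sample subset, a
soft-threshold power chosen by scale-free topology fit, topological
overlap (TOM) similarity, average-linkage hierarchical clustering of
1 - TOM with a flat height cut, and dissolution of clusters below the
minimum module size into a "null" module of unassigned aptamers.  Each
module is summarized by its eigengene (first principal component of the
z-standardized member submatrix) and an average standardized expression
difference between groups.  Two groups' module sets are compared in a
graph whose within-group edges mark eigengene correlation > 0.8 and
whose cross-group edges mark membership Jaccard overlap > 0.10.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cut_tree, fcluster
from scipy.spatial.distance import squareform

logger = logging.getLogger("centproteo")

__all__ = [
    "ModuleSet",
    "correlation_matrix",
    "soft_threshold_select",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "module_group_difference",
    "build_module_graph",
]


@dataclass
class ModuleSet:
    """Module memberships of one group plus per-module summaries."""

    group: str
    memberships: dict               # module id -> set of aptamer ids
    null_module: set                # unassigned aptamers
    eigengenes: pd.DataFrame = None  # samples x modules
    avg_std_diff: dict = field(default_factory=dict)
    universe: set = field(default_factory=set)

    def __post_init__(self):
        assigned = set().union(*self.memberships.values()) if self.memberships else set()
        if not self.universe:
            self.universe = assigned | self.null_module
        # memberships + null module must partition the universe
        total = sum(len(v) for v in self.memberships.values()) + len(self.null_module)
        if assigned | self.null_module != self.universe or total != len(self.universe):
            raise ValueError("module memberships and null module must "
                             "partition the aptamer universe")

    @property
    def sizes(self) -> dict:
        return {k: len(v) for k, v in self.memberships.items()}


def correlation_matrix(expression: pd.DataFrame, sample_subset) -> pd.DataFrame:
    """Pearson correlation of log-RFU across the subset, aptamer x aptamer.

    Zero-variance aptamers get correlation 0 to every other (diagonal
    stays 1), with a warning.
    """
    sub = expression.loc[sample_subset]
    if sub.shape[0] < 10:
        raise ValueError("need at least 10 samples for a correlation network")
    logx = np.log(sub.to_numpy())
    sd = logx.std(axis=0, ddof=1)
    flat = sd <= 0
    if flat.any():
        logger.warning("%d zero-variance aptamers: correlations set to 0",
                       int(flat.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(logx, rowvar=False)
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(np.nan_to_num(corr), -1.0, 1.0)
    return pd.DataFrame(corr, index=expression.columns, columns=expression.columns)


def _scale_free_fit(adj: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log degree-distribution regression (scale-free fit)."""
    k = adj.sum(axis=0) - np.diag(adj)
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    dk, pk = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() > 0:
            dk.append(k[mask].mean())
            pk.append(mask.mean())
    dk, pk = np.array(dk), np.array(pk)
    ok = (dk > 0) & (pk > 0)
    if ok.sum() < 3:
        return 0.0
    x, y = np.log10(dk[ok]), np.log10(pk[ok])
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2) if np.isfinite(r) else 0.0


def soft_threshold_select(corr: pd.DataFrame, powers=range(1, 13),
                          target_fit: float = 0.8) -> dict:
    """Pick the soft-threshold power for the unsigned adjacency |r|^beta.

    The smallest power whose scale-free topology fit R^2 reaches
    ``target_fit`` wins; if none reaches it, the power with maximal R^2.
    Returns the power, the adjacency at that power, and the fit table.
    """
    absr = np.abs(corr.to_numpy())
    fits = {}
    for beta in powers:
        fits[beta] = _scale_free_fit(absr**beta)
    chosen = None
    for beta in powers:
        if fits[beta] >= target_fit:
            chosen = beta
            break
    if chosen is None:
        chosen = max(fits, key=fits.get)
    logger.info("soft threshold beta=%d (fit R^2=%.3f)", chosen, fits[chosen])
    return {
        "power": chosen,
        "adjacency": pd.DataFrame(absr**chosen, index=corr.index,
                                  columns=corr.columns),
        "fit_table": pd.Series(fits, name="scale_free_r2"),
    }


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """TOM similarity: shared-neighborhood strength of each node pair.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    k the connectivity (row sum excluding the diagonal); TOM_ii = 1.
    """
    A = adjacency.to_numpy(dtype=float).copy()
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=0)
    shared = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + A) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(np.nan_to_num(tom), 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(tom: pd.DataFrame, min_module_size: int = 20,
                   max_module_fraction: float = 0.5,
                   corr: pd.DataFrame | None = None,
                   coherence_factor: float = 2.0,
                   group: str = "") -> ModuleSet:
    """Module detection: adaptive flat cut of the TOM dendrogram + refinement.

    Average-linkage clustering of 1 - TOM; the flat cut height (scanned
    over midpoints of consecutive merge heights) is the one that
    maximizes the number of *coherent* clusters — clusters with at
    least ``min_module_size`` and at most ``max_module_fraction`` of
    the universe members whose mean within-cluster similarity is at
    least ``coherence_factor`` times the background mean (similarity =
    |correlation| when ``corr`` is given, TOM otherwise).  Ties break
    toward the lowest cut, which yields conservative module cores; a
    refinement pass then assigns each unassigned aptamer to the module
    it is most similar to, provided that mean similarity also clears
    the coherence bar.  Everything else is the null module.  Incoherent
    chained background clusters never become modules, so a pure-noise
    matrix returns every aptamer unassigned.  Modules are labeled
    M1, M2, ... by decreasing size.  Fully deterministic.
    """
    ids = tom.index
    m = len(ids)
    sim = np.abs(corr.to_numpy()) if corr is not None else tom.to_numpy().copy()
    np.fill_diagonal(sim, np.nan)
    background = float(np.nanmean(sim))
    bar = coherence_factor * background
    D = 1.0 - tom.to_numpy()
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    if np.allclose(D, D[0, 0]):
        # degenerate: no structure at all
        return ModuleSet(group, {}, set(ids))
    Z = average(squareform(D, checks=False))
    heights = np.unique(Z[:, 2])
    cuts = (heights[:-1] + heights[1:]) / 2.0
    max_size = max(min_module_size, int(max_module_fraction * m))

    def coherent_clusters(labels: np.ndarray) -> list[np.ndarray]:
        out = []
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            if min_module_size <= len(idx) <= max_size:
                if np.nanmean(sim[np.ix_(idx, idx)]) >= bar:
                    out.append(idx)
        return out

    best_labels, best_count = None, 0
    if len(cuts):
        all_labels = cut_tree(Z, height=cuts)  # (n_obs, n_cuts)
        for row in range(len(cuts)):
            count = len(coherent_clusters(all_labels[:, row]))
            if count > best_count:
                best_count = count
                best_labels = all_labels[:, row]
    if best_labels is None:
        return ModuleSet(group, {}, set(ids))
    cores = coherent_clusters(best_labels)
    # refinement: pull in unassigned aptamers strongly tied to one core
    assigned = np.zeros(m, dtype=bool)
    for idx in cores:
        assigned[idx] = True
    free = np.flatnonzero(~assigned)
    if len(free) and cores:
        sim0 = np.nan_to_num(sim)
        mean_to_core = np.column_stack([sim0[np.ix_(free, idx)].mean(axis=1)
                                        for idx in cores])
        best_core = mean_to_core.argmax(axis=1)
        best_val = mean_to_core.max(axis=1)
        for f, bc, bv in zip(free, best_core, best_val):
            if bv >= bar:
                cores[bc] = np.append(cores[bc], f)
    cores = [c for c in cores if len(c) <= max_size]
    order = sorted(range(len(cores)),
                   key=lambda i: (-len(cores[i]), int(cores[i].min())))
    memberships = {f"M{rank + 1}": set(ids[cores[i]])
                   for rank, i in enumerate(order)}
    covered = set().union(*memberships.values()) if memberships else set()
    null_module = set(ids) - covered
    logger.info("detect_modules(%s): %d modules, null=%d",
                group, len(memberships), len(null_module))
    return ModuleSet(group, memberships, null_module, universe=set(ids))


def module_eigengene(expression: pd.DataFrame, members, sample_subset) -> pd.Series:
    """First principal component of the z-standardized member submatrix.

    Scaled to unit variance and sign-oriented to correlate positively
    with the module's mean z profile.
    """
    members = sorted(members)
    if not members:
        raise ValueError("empty module")
    sub = expression.loc[sample_subset, members]
    if sub.shape[0] < 2:
        raise ValueError("eigengene needs at least two samples")
    logx = np.log(sub.to_numpy())
    z = (logx - logx.mean(axis=0)) / np.where(logx.std(axis=0, ddof=1) > 0,
                                              logx.std(axis=0, ddof=1), 1.0)
    u, s, _vt = np.linalg.svd(z, full_matrices=False)
    eig = u[:, 0]
    eig = eig / eig.std(ddof=1)
    mean_profile = z.mean(axis=1)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=sub.index, name="eigengene")


def module_group_difference(expression: pd.DataFrame, members,
                            samples: pd.DataFrame, focal_group,
                            other_group=None) -> float:
    """Average standardized expression difference, focal minus other.

    Each aptamer's log-RFU is z-standardized over all samples; the
    score averages (mean z in the focal group - mean z in the other
    samples) over module members.  Swapping the orientation negates the
    value exactly when the two groups partition the samples.
    """
    members = sorted(members)
    if not members:
        raise ValueError("empty module")
    if isinstance(focal_group, str):
        focal_mask = (samples["group"] == focal_group).to_numpy()
    else:
        focal_mask = samples["group"].isin(focal_group).to_numpy()
    if other_group is None:
        other_mask = ~focal_mask
    elif isinstance(other_group, str):
        other_mask = (samples["group"] == other_group).to_numpy()
    else:
        other_mask = samples["group"].isin(other_group).to_numpy()
    if focal_mask.sum() == 0 or other_mask.sum() == 0:
        raise ValueError("both groups must be non-empty")
    logx = np.log(expression.loc[samples.index, members].to_numpy())
    sd = logx.std(axis=0, ddof=1)
    z = (logx - logx.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    return float((z[focal_mask].mean(axis=0) - z[other_mask].mean(axis=0)).mean())


def build_module_graph(modules_a: ModuleSet, modules_b: ModuleSet,
                       me_cor_threshold: float = 0.8,
                       jaccard_threshold: float = 0.10) -> nx.Graph:
    """Two-layer module graph of two groups' module sets.

    Nodes are (group, module id) with size and avg_std_diff attributes.
    Within-group edges connect modules whose eigengene correlation
    exceeds ``me_cor_threshold`` in absolute value; cross-group edges
    connect modules whose membership Jaccard index exceeds
    ``jaccard_threshold``.  Null modules never appear.
    """
    if modules_a.universe != modules_b.universe:
        raise ValueError("module sets must share the aptamer universe")
    G = nx.Graph()
    for ms in (modules_a, modules_b):
        for mid, members in ms.memberships.items():
            G.add_node((ms.group, mid), size=len(members),
                       avg_std_diff=ms.avg_std_diff.get(mid),
                       group=ms.group)
    for ms, kind in ((modules_a, "within_a"), (modules_b, "within_b")):
        if ms.eigengenes is None or ms.eigengenes.shape[1] < 2:
            continue
        me = ms.eigengenes
        corr = me.corr().to_numpy()
        mods = list(me.columns)
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                if abs(corr[i, j]) > me_cor_threshold:
                    G.add_edge((ms.group, mods[i]), (ms.group, mods[j]),
                               kind="eigengene_correlation",
                               weight=float(corr[i, j]))
    for mid_a, mem_a in modules_a.memberships.items():
        for mid_b, mem_b in modules_b.memberships.items():
            jac = len(mem_a & mem_b) / len(mem_a | mem_b)
            if jac > jaccard_threshold:
                G.add_edge((modules_a.group, mid_a), (modules_b.group, mid_b),
                           kind="jaccard_overlap", weight=float(jac))
    return G
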