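"""Weighted gene coexpression network construction and module detection.

The network is unsigned: adjacency = |Pearson correlation|^beta with a
soft-thresholding power beta (default 4).  Gene-gene similarity is the
topological overlap (shared-neighbor) measure; modules are branches of an
average-linkage dendrogram of 1 - TOM, cut by a deterministic
variable-height procedure that honors a minimum module size and a
deep-split aggressiveness level, with diffuse branches left unassigned
(label 0).  Module eigengenes (first principal component of the
standardized module expression) summarize modules and are correlated with
binary traits.

Expression matrices are samples x genes throughout this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

# relative-gap acceptance threshold per deep-split level: higher deep split
# accepts weaker dendrogram gaps, i.e. splits more aggressively
_GAP_TAU = {0: 0.5, 1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}


@dataclass(frozen=True)
class NetworkConfig:
    beta: float = 4.0
    min_module_size: int = 30
    deep_split: int = 2
    merge_cut_height: float = 0.25
    cohesion_max_dissim: float = 0.90  # branches looser than this stay unassigned
    core_conn_frac: float = 0.5  # member retention threshold vs core connectivity

    def __post_init__(self):
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0.0 < self.merge_cut_height < 1.0:
            raise ValueError("merge cut height must lie in (0, 1)")
        if self.deep_split not in _GAP_TAU:
            raise ValueError("deep_split must be in 0..4")


@dataclass
class ModulePartition:
    """Gene -> module label (0 = unassigned) with eigengenes per module."""

    labels: pd.Series
    eigengenes: pd.DataFrame | None = None  # samples x modules

    @property
    def module_sizes(self) -> pd.Series:
        assigned = self.labels[self.labels != 0]
        return assigned.value_counts().sort_index()

    def genes_in(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]


# ---------------------------------------------------------------------------
# gene / sample quality filtering
# ---------------------------------------------------------------------------


def good_genes_filter(expr: pd.DataFrame, max_missing_frac: float = 0.5) -> pd.Index:
    """Genes without excessive missing data or zero variance.

    Mirrors the usual pre-network cleanup: a gene is dropped when more than
    ``max_missing_frac`` of its values are missing or its observed values
    are constant.
    """
    miss = expr.isna().mean(axis=0)
    var = expr.var(axis=0, ddof=1)
    keep = (miss <= max_missing_frac) & var.gt(0).fillna(False)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("good_genes_filter dropped %d of %d genes", dropped, expr.shape[1])
    if not keep.any():
        raise ValueError("all genes dropped by quality filter")
    return expr.columns[keep]


def detect_sample_outliers(
    expr: pd.DataFrame, cut_height_quantile: float = 0.99
) -> list[str]:
    """Samples sitting alone on high dendrogram branches.

    Average-linkage clustering on Euclidean sample distance; branches that
    join the tree above the given quantile of merge heights and contain a
    single sample are flagged.
    """
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 samples for outlier detection")
    z = linkage(expr.to_numpy(float), method="average", metric="euclidean")
    heights = z[:, 2]
    h = float(np.quantile(heights, cut_height_quantile))
    labels = fcluster(z, t=h, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    singletons = set(sizes.index[sizes == 1])
    return [s for s, lab in zip(expr.index, labels) if lab in singletons]


# ---------------------------------------------------------------------------
# adjacency / topological overlap
# ---------------------------------------------------------------------------


def _abs_correlation(expr: pd.DataFrame) -> np.ndarray:
    if expr.isna().any().any():
        cor = expr.corr(min_periods=3).to_numpy()  # pairwise complete
        cor = np.nan_to_num(cor, nan=0.0)
        np.fill_diagonal(cor, 1.0)
    else:
        x = expr.to_numpy(float)
        sd = x.std(axis=0)
        if (sd == 0).any():
            raise ValueError("zero-variance gene; run good_genes_filter first")
        cor = np.corrcoef(x, rowvar=False)
    return np.abs(np.clip(cor, -1.0, 1.0))


def adjacency(expr: pd.DataFrame, beta: float = 4.0) -> np.ndarray:
    """Unsigned soft-thresholded adjacency |cor|^beta with unit diagonal."""
    a = _abs_correlation(expr) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_scan(expr: pd.DataFrame, betas=range(1, 11), n_bins: int = 10) -> pd.DataFrame:
    """Scale-independence fit and mean connectivity for candidate powers.

    For each beta the connectivity is k_i = sum_{j != i} a_ij; the fit index
    is the R^2 of log10(frequency) on log10(binned k), sign-flipped when the
    slope is positive, so values near 1 indicate scale-free topology.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 genes")
    abs_cor = _abs_correlation(expr)
    rows = []
    for beta in betas:
        a = abs_cor ** beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        rows.append(
            {
                "beta": float(beta),
                "r_squared": _scale_free_r2(k, n_bins),
                "mean_connectivity": float(k.mean()),
            }
        )
    return pd.DataFrame(rows)


def _scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    if np.ptp(k) <= 0:
        return float("nan")  # degenerate: every gene equally connected
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        kb = float(k[mask].mean())
        if kb <= 0:
            continue
        xs.append(np.log10(kb))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return float("nan")
    fit = stats.linregress(xs, ys)
    r2 = float(fit.rvalue ** 2)
    return r2 if fit.slope < 0 else -r2


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k excluding the diagonal; TOM_ii = 1.
    """
    a = np.asarray(adj, float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency values must lie in [0, 1]")
    if not np.allclose(np.diag(a), 1.0):
        raise ValueError("adjacency must have unit diagonal")
    l = a @ a  # includes u = i and u = j terms, each equal to a_ij
    numer = l - 2.0 * a + a  # = shared-neighbor sum + direct adjacency
    k = a.sum(axis=0) - 1.0
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numer / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return tom


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------


class _Dendrogram:
    """Array-backed view of a scipy linkage tree (no recursion limits)."""

    def __init__(self, z: np.ndarray, n: int):
        self.n = n
        self.left = z[:, 0].astype(int)
        self.right = z[:, 1].astype(int)
        self.dist = z[:, 2]

    def leaves(self, node: int) -> np.ndarray:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < self.n:
                out.append(v)
            else:
                i = v - self.n
                stack.extend((self.left[i], self.right[i]))
        return np.array(sorted(out))

    def subtree_heights(self, node: int) -> np.ndarray:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v >= self.n:
                i = v - self.n
                out.append(self.dist[i])
                stack.extend((self.left[i], self.right[i]))
        return np.sort(np.array(out))

    def cut_below(self, node: int, height: float) -> list[int]:
        """Maximal subnodes of ``node`` merging at or below ``height``."""
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < self.n or self.dist[v - self.n] <= height:
                out.append(v)
            else:
                i = v - self.n
                stack.extend((self.left[i], self.right[i]))
        return out


def _strong_gap(heights: np.ndarray, tau: float) -> float | None:
    """Cut height at the largest merge-height gap, if strong enough."""
    hs = np.unique(heights)
    if hs.size < 2:
        return None
    gaps = np.diff(hs)
    i = int(np.argmax(gaps))
    hi = hs[i + 1]
    if hi <= 0 or gaps[i] / hi < tau:
        return None
    return float((hs[i] + hi) / 2.0)


def cut_modules(tom: np.ndarray, config: NetworkConfig = NetworkConfig(),
                genes: pd.Index | None = None) -> ModulePartition:
    """Deterministic variable-height branch cut of the 1 - TOM dendrogram.

    Top-down traversal of the average-linkage tree: a branch becomes a
    module when it is cohesive (mean internal dissimilarity at most
    ``cohesion_max_dissim``) and shows no strong internal merge-height gap;
    a branch with a strong gap (strength threshold set by ``deep_split``)
    is cut there and its pieces revisited; a diffuse branch is bisected at
    its root.  Branches smaller than the minimum module size stay
    unassigned.  Labels are ordered by descending module size, 0 meaning
    unassigned.
    """
    n = tom.shape[0]
    if genes is None:
        genes = pd.Index([f"g{i}" for i in range(n)])
    if n < config.min_module_size:
        logger.warning("fewer genes (%d) than min module size; nothing assigned", n)
        return ModulePartition(labels=pd.Series(0, index=genes))
    d = 1.0 - np.asarray(tom, float)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    tree = _Dendrogram(z, n)
    tau = _GAP_TAU[config.deep_split]

    accepted: list[np.ndarray] = []
    stack = [2 * n - 2]  # root
    while stack:
        node = stack.pop()
        leaves = tree.leaves(node)
        if leaves.size < config.min_module_size:
            continue  # too small to be a module; stays unassigned
        heights = tree.subtree_heights(node)
        sub = d[np.ix_(leaves, leaves)]
        mean_within = sub[np.triu_indices(leaves.size, k=1)].mean()
        cut = _strong_gap(heights, tau)
        if cut is not None:
            stack.extend(tree.cut_below(node, cut))
        elif mean_within <= config.cohesion_max_dissim:
            accepted.append(leaves)
        elif node >= n:  # diffuse: descend into the two child branches
            i = node - n
            stack.extend((tree.left[i], tree.right[i]))

    tom_arr = np.asarray(tom, float)
    refined = [
        _refine_members(tom_arr, br, config) for br in accepted
    ]
    refined = [br for br in refined if br.size >= config.min_module_size]
    refined.sort(key=lambda b: (-b.size, int(b[0])))

    labels = np.zeros(n, dtype=int)
    for m, br in enumerate(refined, start=1):
        labels[br] = m
    return ModulePartition(labels=pd.Series(labels, index=genes, name="module"))


def _refine_members(tom: np.ndarray, members: np.ndarray,
                    config: NetworkConfig) -> np.ndarray:
    """Drop weakly connected members of a candidate module branch.

    A gene stays only while its mean topological overlap with the module is
    at least ``core_conn_frac`` of the core connectivity (the mean over the
    best-connected ``min_module_size`` members), so background genes picked
    up by the dendrogram branch are shed.  Iterated to a fixed point.
    """
    for _ in range(20):
        size = members.size
        if size < config.min_module_size:
            break
        sub = tom[np.ix_(members, members)]
        conn = (sub.sum(axis=1) - 1.0) / max(size - 1, 1)
        core = float(np.sort(conn)[-min(config.min_module_size, size):].mean())
        keep = conn >= config.core_conn_frac * core
        if keep.all():
            break
        members = members[keep]
    return members


# ---------------------------------------------------------------------------
# eigengenes, merging, trait correlation
# ---------------------------------------------------------------------------


def module_eigengene(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component per module, unit variance, sign-oriented.

    Genes are z-scored before decomposition; the eigengene sign is chosen
    so its mean correlation with member genes is positive.
    """
    eig = {}
    for m in sorted(set(labels) - {0}):
        genes = labels.index[labels == m]
        if len(genes) == 0:
            raise ValueError(f"module {m} is empty")
        x = expr[genes].to_numpy(float)
        mu, sd = x.mean(axis=0), x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        zmat = (x - mu) / sd
        u, s, _ = np.linalg.svd(zmat, full_matrices=False)
        e = u[:, 0]
        if np.mean(zmat.T @ e) < 0:
            e = -e
        e = e / e.std(ddof=1)
        eig[m] = e
    out = pd.DataFrame(eig, index=expr.index)
    out.columns = [f"ME{m}" for m in out.columns]
    return out


def merge_similar_modules(
    partition: ModulePartition, expr: pd.DataFrame, cut_height: float = 0.25
) -> ModulePartition:
    """Merge modules whose eigengene dissimilarity is below ``cut_height``.

    Iterates to a fixed point: after merging, eigengenes are recomputed and
    re-checked, so no pair of final eigengenes correlates above
    1 - cut_height.  Labels are renumbered by descending size.
    """
    labels = partition.labels.copy()
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            break
        eig = module_eigengene(expr, labels)
        cor = eig.corr().to_numpy()
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1.0 - cor[i, j] >= cut_height:
            break
        keep, absorb = mods[min(i, j)], mods[max(i, j)]
        labels[labels == absorb] = keep
    # renumber by descending size (ties: previous label order)
    sizes = labels[labels != 0].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    mapping = {old: new for new, old in enumerate(order, start=1)}
    mapping[0] = 0
    new_labels = labels.map(mapping)
    eig = module_eigengene(expr, new_labels) if (new_labels != 0).any() else None
    return ModulePartition(labels=new_labels, eigengenes=eig)


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson r and p of each module eigengene against each binary trait."""
    n = eigengenes.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    rows = []
    for me in eigengenes.columns:
        for tr in traits.columns:
            t = traits[tr].astype(float)
            if t.std(ddof=1) == 0:
                logger.warning("trait %s is constant; correlation undefined", tr)
                rows.append({"module": me, "trait": tr, "r": np.nan, "p": np.nan,
                             "significant": False})
                continue
            r, p = stats.pearsonr(eigengenes[me], t)
            rows.append({"module": me, "trait": tr, "r": float(r), "p": float(p),
                         "significant": bool(p < alpha)})
    return pd.DataFrame(rows)
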