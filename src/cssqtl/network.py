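"""Weighted gene co-expression network analysis.

Unsigned soft-threshold adjacency ``a_ij = |cor(x_i, x_j)|**beta``, per-gene
connectivity ``k_i = sum_{j != i} a_ij``, topological overlap

    w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu * a_uj,

average-linkage hierarchical clustering on ``1 - w``, branch cutting at a
fixed height with a minimum module size ("tree" variant of dynamic cutting),
module eigengenes (first principal component of the standardized module
expression), and eigengene–trait significance via the Pearson correlation
t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data import ExpressionMatrix
from .stats import pearson_p_from_r

# module label palette, assigned in order of decreasing module size
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]
UNASSIGNED = "unassigned"


def _as_gene_matrix(x) -> tuple[pd.DataFrame, np.ndarray]:
    """Accepts an ExpressionMatrix or a probes x samples DataFrame."""
    frame = x.intensities if isinstance(x, ExpressionMatrix) else x
    return frame, frame.to_numpy(dtype=float)


def select_variable_genes(x: ExpressionMatrix, top_n: int) -> ExpressionMatrix:
    """Keep the ``top_n`` probes by across-sample variance (ties by probe id)."""
    if top_n <= 1:
        raise ValueError("top_n must be > 1")
    if top_n > x.n_probes:
        raise ValueError("top_n exceeds number of probes")
    var = x.intensities.var(axis=1, ddof=1)
    order = sorted(x.probes, key=lambda p: (-var[p], p))
    keep = sorted(order[:top_n], key=x.probes.index)  # preserve original order
    return x.subset_probes(keep, variable_gene_top_n=top_n)


@dataclass
class Network:
    """Soft-threshold adjacency with connectivity and (optionally) TOM."""

    genes: list[str]
    beta: int
    adjacency: np.ndarray
    k: np.ndarray
    tom: np.ndarray | None = None


def adjacency(x, beta: int = 7, mode: str = "unsigned") -> Network:
    """Unsigned weighted adjacency ``|cor|**beta`` with unit diagonal."""
    if beta < 1 or int(beta) != beta:
        raise ValueError("beta must be a positive integer")
    if mode != "unsigned":
        raise ValueError("only the unsigned network is implemented")
    frame, vals = _as_gene_matrix(x)
    if vals.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = vals.std(axis=1)
    if np.any(sd == 0):
        bad = frame.index[sd == 0][0]
        raise ValueError(f"zero-variance gene: {bad!r}")
    corr = np.corrcoef(vals)
    adj = np.abs(np.clip(corr, -1.0, 1.0)) ** beta
    np.fill_diagonal(adj, 1.0)
    k = adj.sum(axis=1) - 1.0
    return Network(list(frame.index.astype(str)), int(beta), adj, k)


def topological_overlap(net: Network) -> Network:
    """Fill ``net.tom`` with the topological overlap matrix."""
    a = net.adjacency
    # l_ij = sum_u a_iu a_uj over u != i, j; diagonal of a is 1
    l = a @ a - 2.0 * a
    denom = np.minimum.outer(net.k, net.k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    net.tom = np.clip(tom, 0.0, 1.0)
    return net


@dataclass
class ModuleAssignment:
    """Gene -> module labels plus module bookkeeping."""

    labels: pd.Series  # index gene, value color label or "unassigned"
    linkage: np.ndarray = field(repr=False)
    cut_height: float = 0.99
    min_module_size: int = 25

    @property
    def module_names(self) -> list[str]:
        sizes = self.sizes
        return [m for m in sizes.index if m != UNASSIGNED]

    @property
    def sizes(self) -> pd.Series:
        counts = self.labels.value_counts()
        assigned = counts[counts.index != UNASSIGNED]
        out = assigned.sort_values(ascending=False)
        if UNASSIGNED in counts.index:
            out = pd.concat([out, counts[[UNASSIGNED]]])
        return out

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def cluster_and_cut(
    net: Network,
    min_module_size: int = 25,
    cut_height: float = 0.99,
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a relative branch cut.

    The dendrogram is cut at ``cut_height`` of the way between the 5th
    percentile and the maximum of the joining heights (the scale-adaptive
    default of the standard branch-cutting procedure; soft thresholding
    compresses dissimilarities toward 1, so an absolute cut is brittle).
    Branches below the cut become candidate modules; candidates smaller than
    ``min_module_size`` are labelled "unassigned".  Color labels are assigned
    by descending module size (ties broken by first member id).
    """
    if net.tom is None:
        raise ValueError("network has no TOM; call topological_overlap first")
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if not 0.0 < cut_height <= 1.0:
        raise ValueError("cut_height must be in (0, 1]")
    diss = 1.0 - net.tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    Z = linkage(squareform(diss, checks=False), method="average")
    heights = Z[:, 2]
    lo = float(np.quantile(heights, 0.05))
    hi = float(heights.max())
    # degenerate dendrogram (all joins at one height): everything is one branch
    cut = hi if hi - lo < 1e-10 else lo + cut_height * (hi - lo)
    raw = fcluster(Z, t=cut, criterion="distance")
    genes = pd.Index(net.genes)
    labels = pd.Series(UNASSIGNED, index=genes, dtype=object, name="module")
    clusters = []
    for cid in np.unique(raw):
        members = genes[raw == cid]
        if len(members) >= min_module_size:
            clusters.append((len(members), str(members[0]), members))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    for rank, (_, _, members) in enumerate(clusters):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        labels.loc[members] = color
    return ModuleAssignment(labels, Z, cut_height, min_module_size)


def module_eigengene(x, modules: ModuleAssignment | dict) -> pd.DataFrame:
    """First-PC eigengene per module, unit variance, sign-aligned.

    Genes are z-scored across samples; the eigengene is the first principal
    component of the samples x genes block, scaled to unit variance and
    oriented so it correlates non-negatively with the module's mean
    standardized expression.
    """
    frame, vals = _as_gene_matrix(x)
    if isinstance(modules, ModuleAssignment):
        groups = {m: modules.members(m) for m in modules.module_names}
    else:
        groups = dict(modules)
    out = {}
    for name, members in groups.items():
        if len(members) == 0:
            raise ValueError(f"module {name!r} is empty")
        block = frame.loc[members].to_numpy(dtype=float)  # genes x samples
        mean = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError(f"zero-variance gene in module {name!r}")
        z = (block - mean) / sd
        u, s, _ = np.linalg.svd(z.T, full_matrices=False)
        pc = u[:, 0] * s[0]
        pc = pc / pc.std(ddof=1)
        reference = z.mean(axis=0)
        sign = np.sign(np.dot(pc, reference))
        out[name] = pc * (sign if sign != 0 else 1.0)
    return pd.DataFrame(out, index=frame.columns)


def eigengene_significance(eigengenes: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and two-sided p for every module x trait pair.

    Rows are modules; columns are a MultiIndex (trait, {"r", "p"}).
    """
    common = eigengenes.index.intersection(traits.index)
    if len(common) < 4:
        raise ValueError("need at least 4 aligned samples")
    E = eigengenes.loc[common]
    T = traits.loc[common]
    n = len(common)
    cols = {}
    for trait in T.columns:
        y = T[trait].to_numpy(dtype=float)
        rs, ps = [], []
        for module in E.columns:
            e = E[module].to_numpy(dtype=float)
            r = float(np.corrcoef(e, y)[0, 1])
            rs.append(r)
            ps.append(pearson_p_from_r(r, n))
        cols[(trait, "r")] = rs
        cols[(trait, "p")] = ps
    return pd.DataFrame(cols, index=E.columns)


def within_module_connectivity(net: Network, modules: ModuleAssignment) -> pd.DataFrame:
    """Whole-network and within-module connectivity per gene."""
    genes = pd.Index(net.genes)
    k_within = np.full(len(genes), np.nan)
    for name in modules.module_names:
        idx = genes.get_indexer(modules.members(name))
        sub = net.adjacency[np.ix_(idx, idx)]
        k_within[idx] = sub.sum(axis=1) - 1.0
    return pd.DataFrame(
        {
            "module": modules.labels.loc[genes].to_numpy(),
            "k_total": net.k,
            "k_within": k_within,
        },
        index=genes,
    )


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------

class CoexpressionNetwork:
    """Weighted co-expression network model for an expression matrix.

    Parameters
    ----------
    expr : ExpressionMatrix (normalized stage) or probes x samples DataFrame.
    beta : soft-threshold power.
    top_n : optional variance filter applied before network construction.
    """

    def __init__(self, expr, beta: int = 7, top_n: int | None = None):
        if top_n is not None and isinstance(expr, ExpressionMatrix):
            expr = select_variable_genes(expr, top_n)
        self.expr = expr
        self.beta = beta
        self.network = topological_overlap(adjacency(expr, beta=beta))

    def fit(self, min_module_size: int = 25, cut_height: float = 0.99) -> "ModuleResults":
        modules = cluster_and_cut(self.network, min_module_size, cut_height)
        eig = module_eigengene(self.expr, modules)
        return ModuleResults(self, modules, eig)


@dataclass
class ModuleResults:
    model: CoexpressionNetwork
    modules: ModuleAssignment
    eigengenes: pd.DataFrame

    def significance(self, traits: pd.DataFrame, include_unassigned: bool = False
                     ) -> pd.DataFrame:
        """Eigengene-significance table; unassigned genes are excluded from
        modules by construction and get no eigengene unless requested."""
        eig = self.eigengenes
        if include_unassigned and UNASSIGNED in set(self.modules.labels):
            extra = module_eigengene(
                self.model.expr, {UNASSIGNED: self.modules.members(UNASSIGNED)}
            )
            eig = pd.concat([eig, extra], axis=1)
        return eigengene_significance(eig, traits)

    def connectivity(self) -> pd.DataFrame:
        return within_module_connectivity(self.model.network, self.modules)

    def summary(self) -> str:
        sizes = self.modules.sizes
        lines = [
            f"Co-expression network: {len(self.modules.labels)} genes, "
            f"beta = {self.model.beta}",
            f"  modules ({len(self.modules.module_names)}, min size "
            f"{self.modules.min_module_size}, cut height {self.modules.cut_height:g}):",
        ]
        for name, size in sizes.items():
            lines.append(f"    {name:<14} {size}")
        return "\n".join(lines)

    def plot_dendrogram(self, ax=None):
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import dendrogram

        if ax is None:
            _, ax = plt.subplots()
        dendrogram(self.modules.linkage, no_labels=True, ax=ax,
                   color_threshold=self.modules.cut_height)
        ax.set_ylabel("1 - topological overlap (average linkage)")
        return ax
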