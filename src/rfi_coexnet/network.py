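"""Weighted co-expression network construction, module detection, eigengenes.

The network is built from scratch on top of numpy/scipy primitives:

1. Pearson correlation between all gene pairs across samples.
2. Soft-threshold scan: for each candidate power beta, raise the (signed
   or absolute) correlation to beta, compute per-gene connectivity
   k_i = sum_j a_ij, and measure how well the degree distribution follows a
   power law (the scale-free topology fit index — R^2 of the log-log
   regression of binned degree frequency on connectivity, signed by the
   slope).  The recommended power is the smallest one reaching R^2 >= 0.8,
   falling back to the argmax.
3. Adjacency at the chosen power, topological overlap matrix (TOM),
   average-linkage clustering on 1 - TOM, and a height-sweep tree cut with
   a minimum module size; leftover genes are labelled "grey".
4. Module eigengenes (first principal component of the standardised member
   genes, unit variance, sign-aligned with the module mean profile) and
   iterative merging of modules whose eigengenes are closer than a
   dissimilarity threshold.

Modules are named by colour in descending size order over a fixed list, so
"turquoise" is always the largest module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression import ExpressionMatrix

__all__ = [
    "NetworkParams",
    "SoftThresholdScan",
    "MODULE_COLORS",
    "GREY",
    "pairwise_correlation",
    "adjacency",
    "soft_threshold_scan",
    "tom_similarity",
    "cluster_genes",
    "cut_modules",
    "module_eigengenes",
    "merge_close_modules",
    "detect_modules",
]

GREY = "grey"

# Size-ordered colour vocabulary for naming detected modules.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
    "darkolivegreen", "darkmagenta", "sienna", "yellowgreen", "skyblue3",
    "plum", "orangered", "mediumpurple",
]


@dataclass(frozen=True)
class NetworkParams:
    """Knobs of network construction and module detection."""

    power: int | None = None  # None -> pick from the soft-threshold scan
    network_type: str = "unsigned"  # or "signed"
    min_module_size: int = 50
    merge_cut_height: float = 0.15
    powers_to_scan: tuple[int, ...] = tuple(range(1, 21))
    log_transform: bool = False  # correlate log2(TPM + 1) instead of raw TPM

    def __post_init__(self) -> None:
        if self.power is not None and self.power < 1:
            raise ValueError("power must be >= 1")
        if self.network_type not in ("unsigned", "signed"):
            raise ValueError("network_type must be 'unsigned' or 'signed'")
        if not 0 <= self.merge_cut_height <= 1:
            raise ValueError("merge_cut_height must lie in [0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


@dataclass
class SoftThresholdScan:
    """Per-power scale-free fit diagnostics."""

    table: pd.DataFrame  # columns: power, scale_free_r2, slope, mean_connectivity
    recommended_power: int


def _expr_array(expr: ExpressionMatrix, log_transform: bool) -> np.ndarray:
    x = expr.values.to_numpy(float)
    if log_transform:
        x = np.log2(x + 1.0)
    return x


def pairwise_correlation(expr: ExpressionMatrix, log_transform: bool = False) -> pd.DataFrame:
    """Gene-gene Pearson correlation matrix (symmetric, unit diagonal)."""
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation")
    x = _expr_array(expr, log_transform)
    sd = x.std(axis=1, ddof=1)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        names = [expr.gene_ids[i] for i in zero_var[:10]]
        raise ValueError(f"zero-variance genes cannot be correlated: {names}")
    cor = np.corrcoef(x)
    np.clip(cor, -1.0, 1.0, out=cor)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=expr.gene_ids, columns=expr.gene_ids)


def adjacency(cor: pd.DataFrame, power: int, network_type: str = "unsigned") -> pd.DataFrame:
    """Soft-threshold the correlation matrix into edge weights in [0, 1].

    unsigned: a_ij = |cor_ij| ** beta; signed: a_ij = ((1 + cor_ij)/2) ** beta.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    c = cor.to_numpy(float)
    if network_type == "unsigned":
        a = np.abs(c) ** power
    elif network_type == "signed":
        a = ((1.0 + c) / 2.0) ** power
    else:
        raise ValueError(f"unknown network_type {network_type!r}")
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=cor.index, columns=cor.columns)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit index and slope from the connectivity vector.

    Bins k into ``n_bins`` equal-width bins, regresses log10(mean frequency)
    on log10(mean k) over non-empty bins, and signs R^2 by -sign(slope) so
    that a decreasing (power-law-like) degree distribution scores positive.
    Returns (nan, nan) when fewer than 2 usable bins exist.
    """
    k = np.asarray(k, float)
    if k.max() == k.min():
        return float("nan"), float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    n = k.size
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0 or members.mean() <= 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_p.append(np.log10(members.size / n))
    if len(log_k) < 2:
        return float("nan"), float("nan")
    log_k = np.asarray(log_k)
    log_p = np.asarray(log_p)
    slope, intercept = np.polyfit(log_k, log_p, 1)
    fitted = slope * log_k + intercept
    ss_res = float(((log_p - fitted) ** 2).sum())
    ss_tot = float(((log_p - log_p.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return float(r2 * -np.sign(slope)), float(slope)


def soft_threshold_scan(
    expr: ExpressionMatrix,
    powers: tuple[int, ...] = tuple(range(1, 21)),
    network_type: str = "unsigned",
    log_transform: bool = False,
    r2_target: float = 0.8,
) -> SoftThresholdScan:
    """Scan candidate soft-threshold powers and recommend one.

    Recommends the smallest power whose scale-free fit index reaches
    ``r2_target``.  If none does, the index curve is taken to have
    reached its stable level at the first power where the gain over the
    next power drops below 0.02 while the index is already >= 0.5 —
    chasing the global maximum instead would push the power so high that
    the network's topological overlap collapses toward zero.  Falls back
    to the argmax when no plateau exists.
    """
    if not powers:
        raise ValueError("powers must be non-empty")
    cor = pairwise_correlation(expr, log_transform).to_numpy()
    base = np.abs(cor) if network_type == "unsigned" else (1.0 + cor) / 2.0
    np.fill_diagonal(base, 0.0)  # exclude self-edges from connectivity
    rows = []
    for beta in powers:
        a = base**beta
        k = a.sum(axis=1)
        r2, slope = _scale_free_fit(k)
        rows.append((beta, r2, slope, float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "scale_free_r2", "slope", "mean_connectivity"])
    ok = table[table["scale_free_r2"] >= r2_target]
    if len(ok):
        recommended = int(ok["power"].iloc[0])
    else:
        r2 = table["scale_free_r2"].to_numpy()
        recommended = None
        for i in range(len(r2)):
            if not np.isfinite(r2[i]) or r2[i] < 0.5:
                continue
            if i == len(r2) - 1 or r2[i + 1] - r2[i] < 0.02:
                recommended = int(table["power"].iloc[i])
                break
        if recommended is None:
            recommended = int(table.loc[table["scale_free_r2"].idxmax(), "power"])
    return SoftThresholdScan(table=table, recommended_power=recommended)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a weighted adjacency.

    For i != j:  tom_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with l_ij = sum_{u != i,j} a_iu * a_uj and k_i = sum_{u != i} a_iu;
    the diagonal is 1.  Values lie in [0, 1] for adjacencies in [0, 1].
    """
    a = adj.to_numpy(float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # includes u=i and u=j terms, both zero since diag(a)=0
    num = l + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def cluster_genes(tom: pd.DataFrame) -> np.ndarray:
    """Average-linkage dendrogram on the dissimilarity 1 - TOM."""
    diss = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    return hierarchy.average(squareform(diss, checks=False))


def cut_modules(
    linkage: np.ndarray,
    tom: pd.DataFrame,
    min_module_size: int = 50,
    cut_height_ceiling: float = 0.99,
) -> pd.Series:
    """Detect modules from the dendrogram by a height-sweep tree cut.

    The dendrogram is cut at a descending sweep of heights (99th down to
    50th percentile of the merge heights), capped at an absolute ceiling
    of ``cut_height_ceiling`` on the 1 - TOM scale.  The ceiling is what
    rejects unstructured data: at the soft-threshold powers the scan
    recommends, a pure-noise TOM is numerically ~0, its dendrogram lives
    entirely above 0.99, and no cut below the ceiling produces any
    cluster — everything stays grey.  Real modules form far below it.

    Each admissible cut yields clusters; the cut producing the most
    clusters of size >= ``min_module_size`` wins (ties go to the highest
    such cut, which keeps modules maximal).  Genes in undersized clusters
    are labelled grey, then a single reassignment round attaches each
    grey gene to its nearest module when its mean TOM to that module
    exceeds the module's median intra-module TOM.

    Returns a gene -> colour Series; non-grey modules are named in
    descending size order over the fixed colour list.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    genes = tom.index
    heights = linkage[:, 2]
    cut_heights = np.unique(np.percentile(heights, np.linspace(99, 50, 25)))[::-1]
    # the ceiling itself is always a candidate: at high powers most merge
    # heights sit above it even when tight module cores exist below
    cut_heights = np.concatenate(
        [[cut_height_ceiling], cut_heights[cut_heights <= cut_height_ceiling]]
    )

    best_labels, best_keep, best_score = None, set(), (-1, -np.inf)
    for h in cut_heights:
        labels = hierarchy.fcluster(linkage, t=h, criterion="distance")
        sizes = np.bincount(labels)
        valid = {c for c in range(1, sizes.size) if sizes[c] >= min_module_size}
        score = (len(valid), h)
        if score > best_score:
            best_score, best_labels, best_keep = score, labels, valid
    labels, keep = best_labels, best_keep

    assigned = np.array([lab if lab in keep else 0 for lab in labels])

    # One round of TOM-nearest reassignment for unassigned genes.
    if keep and (assigned == 0).any():
        t = tom.to_numpy(float)
        module_idx = {c: np.flatnonzero(assigned == c) for c in keep}
        median_intra = {}
        for c, idx in module_idx.items():
            block = t[np.ix_(idx, idx)]
            off = block[~np.eye(len(idx), dtype=bool)]
            median_intra[c] = np.median(off) if off.size else 0.0
        for g in np.flatnonzero(assigned == 0):
            best_c, best_t = 0, -np.inf
            for c, idx in module_idx.items():
                mean_t = t[g, idx].mean()
                if mean_t > best_t:
                    best_c, best_t = c, mean_t
            if best_c and best_t > median_intra[best_c]:
                assigned[g] = best_c

    return _labels_to_colors(assigned, genes)


def _labels_to_colors(assigned: np.ndarray, genes: pd.Index) -> pd.Series:
    """Map integer cluster labels (0 = unassigned) to size-ordered colours."""
    sizes = pd.Series(assigned[assigned != 0]).value_counts()
    # Descending size; ties broken by label for determinism.
    ordered = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    if len(ordered) > len(MODULE_COLORS):
        palette = MODULE_COLORS + [f"module{i}" for i in range(len(MODULE_COLORS), len(ordered))]
    else:
        palette = MODULE_COLORS
    color_of = {c: palette[i] for i, c in enumerate(ordered)}
    color_of[0] = GREY
    return pd.Series([color_of[c] for c in assigned], index=genes, name="module")


def module_eigengenes(
    expr: ExpressionMatrix, modules: pd.Series, log_transform: bool = False
) -> tuple[pd.DataFrame, pd.Series]:
    """First-principal-component eigengene of every non-grey module.

    Member genes are standardised across samples (mean 0, sample SD 1); the
    eigengene is the first left singular vector of the samples x genes
    block, rescaled to unit sample variance and sign-aligned so that it
    correlates non-negatively with the module's mean standardised profile.

    Returns (eigengenes, variance_explained): eigengenes is samples x
    modules, variance_explained the per-module proportion from the first
    component.
    """
    x = _expr_array(expr, log_transform)
    genes = pd.Index(expr.gene_ids)
    me, varexp = {}, {}
    for color in modules[modules != GREY].unique():
        idx = genes.get_indexer(modules.index[modules == color])
        block = x[idx, :].T  # samples x genes
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError(f"module {color} contains a zero-variance gene")
        z = (block - mu) / sd
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        scores = u[:, 0]
        scores = scores / scores.std(ddof=1)
        mean_profile = z.mean(axis=1)
        # Orient toward the module mean; for perfectly antagonistic modules
        # (constant mean) fall back to the first member gene, then to a
        # fixed sign, so orientation is always deterministic.
        for ref in (mean_profile, z[:, 0]):
            align = float(scores @ (ref - ref.mean()))
            if abs(align) > 1e-12:
                if align < 0:
                    scores = -scores
                break
        else:
            if scores[np.argmax(np.abs(scores))] < 0:
                scores = -scores
        me[color] = scores
        varexp[color] = float(s[0] ** 2 / (s**2).sum())
    order = sorted(me, key=lambda c: -int((modules == c).sum()))
    eigengenes = pd.DataFrame({c: me[c] for c in order}, index=expr.sample_ids)
    return eigengenes, pd.Series({c: varexp[c] for c in order}, name="variance_explained")


def merge_close_modules(
    expr: ExpressionMatrix,
    modules: pd.Series,
    merge_cut_height: float = 0.15,
    log_transform: bool = False,
) -> tuple[pd.Series, pd.DataFrame, pd.Series]:
    """Merge modules whose eigengenes are closer than ``merge_cut_height``.

    Iterates: compute eigengene dissimilarity 1 - cor(ME_a, ME_b), cluster
    the eigengenes with average linkage, merge every group joined below the
    threshold, recompute eigengenes, and repeat until stable.  Grey is
    never merged.  After convergence the merged modules are renamed by
    descending size.
    """
    current = modules.copy()
    for _ in range(50):  # convergence is fast; bound for safety
        colors = [c for c in current.unique() if c != GREY]
        if len(colors) < 2:
            break
        eig, _ = module_eigengenes(expr, current, log_transform)
        cor = np.corrcoef(eig[colors].to_numpy().T)
        diss = np.clip(1.0 - cor, 0.0, None)
        np.fill_diagonal(diss, 0.0)
        link = hierarchy.average(squareform((diss + diss.T) / 2.0, checks=False))
        groups = hierarchy.fcluster(link, t=merge_cut_height, criterion="distance")
        if len(set(groups)) == len(colors):
            break
        merged = current.copy()
        for gid in set(groups):
            members = [colors[i] for i in range(len(colors)) if groups[i] == gid]
            if len(members) > 1:
                # keep the largest member's position; name fixed afterwards
                merged[merged.isin(members)] = members[0]
        current = merged
    # Re-label by descending size over the colour list.
    non_grey = [c for c in current.unique() if c != GREY]
    as_int = np.zeros(len(current), dtype=int)
    for i, c in enumerate(sorted(non_grey, key=lambda c: (-int((current == c).sum()), c)), start=1):
        as_int[(current == c).to_numpy()] = i
    relabelled = _labels_to_colors(as_int, current.index)
    eig, varexp = (
        module_eigengenes(expr, relabelled, log_transform)
        if (relabelled != GREY).any()
        else (pd.DataFrame(index=expr.sample_ids), pd.Series(dtype=float))
    )
    return relabelled, eig, varexp


def detect_modules(
    expr: ExpressionMatrix, params: NetworkParams = NetworkParams()
) -> dict:
    """End-to-end module detection; returns all intermediate artifacts.

    Runs correlation -> (optional soft-threshold scan) -> adjacency -> TOM
    -> clustering -> tree cut -> eigengenes -> merging, and returns a dict
    with keys ``scan``, ``power``, ``adjacency``, ``tom``, ``linkage``,
    ``modules`` (post-merge), ``eigengenes``, ``variance_explained``.
    """
    scan = None
    power = params.power
    if power is None:
        scan = soft_threshold_scan(
            expr, params.powers_to_scan, params.network_type, params.log_transform
        )
        power = scan.recommended_power
    cor = pairwise_correlation(expr, params.log_transform)
    adj = adjacency(cor, power, params.network_type)
    tom = tom_similarity(adj)
    link = cluster_genes(tom)
    modules = cut_modules(link, tom, params.min_module_size)
    if (modules != GREY).any():
        modules, eigengenes, varexp = merge_close_modules(
            expr, modules, params.merge_cut_height, params.log_transform
        )
    else:
        eigengenes = pd.DataFrame(index=expr.sample_ids)
        varexp = pd.Series(dtype=float)
    return {
        "scan": scan,
        "power": power,
        "adjacency": adj,
        "tom": tom,
        "linkage": link,
        "modules": modules,
        "eigengenes": eigengenes,
        "variance_explained": varexp,
    }
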