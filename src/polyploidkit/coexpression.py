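"""Mutual-rank co-expression networks, modules and metamodules.

Pipeline: low-expression genes (count < 5 in >= 30 conditions) are dropped;
counts are variance-stabilised (median-of-ratios size factors followed by
log2(count/sf + 1)); pairwise Pearson correlations (PCC) are converted to
mutual ranks MR(i,j) = sqrt(rank_i(j) * rank_j(i)) and then to edge weights
with the geometric decay w = exp(-(MR - 1)/x). Five networks are built at
x in {5, 10, 25, 50, 100}; edges with PCC < 0.6 or weight < 0.01 are
excluded. Modules are grown greedily by cohesiveness
f(V) = w_in / (w_in + w_bound + p*|V|) with penalty p = 2 and merged at
overlap >= 0.8; modules with p-value > 0.1 or quality < 0.2 are excluded.
Retained modules from all five networks are collapsed into metamodules of
non-overlapping gene sets.

The decay exponent is read as (MR - 1)/x, a geometric decay that equals 1
for reciprocal best partners (MR = 1); rank ties are averaged (fractional
ranks) so MR is symmetric and deterministic.
"""
from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .model import ExpressionMatrix

__all__ = [
    "DEFAULT_XS",
    "filter_low_expression",
    "transform_counts",
    "pcc_matrix",
    "mutual_rank",
    "build_networks",
    "Module",
    "detect_modules",
    "Metamodule",
    "collapse_metamodules",
    "annotate_metamodules",
]

DEFAULT_XS = (5, 10, 25, 50, 100)
PCC_MIN = 0.6
WEIGHT_MIN = 0.01
COHESIVENESS_PENALTY = 2.0
OVERLAP_MERGE = 0.8
QUALITY_MIN = 0.2
P_MAX = 0.1
METAMODULE_JACCARD = 0.5


def filter_low_expression(matrix: ExpressionMatrix, min_count: int = 5,
                          min_conditions: int = 30) -> list[str]:
    """Gene ids surviving the low-expression filter.

    A gene is removed iff its count is below ``min_count`` in at least
    ``min_conditions`` libraries. With fewer libraries than
    ``min_conditions`` the rule cannot fire; all genes are kept with a
    warning.
    """
    n_libs = len(matrix.library_ids)
    if n_libs < min_conditions:
        _warnings.warn(
            f"only {n_libs} libraries < min_conditions={min_conditions}; "
            "low-expression filter keeps all genes", stacklevel=2)
        return matrix.gene_ids
    low = (matrix.counts < min_count).sum(axis=1)
    keep = low < min_conditions
    return list(matrix.counts.index[keep])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    Per-gene geometric means are taken over genes detected in every
    library; each library's factor is the median ratio of its counts to
    those geometric means.
    """
    if (counts.sum(axis=0) == 0).any():
        bad = counts.columns[counts.sum(axis=0) == 0][0]
        raise ValidationError(f"library {bad!r} has all-zero counts")
    usable = (counts > 0).all(axis=1)
    if not usable.any():
        raise ValidationError("no gene detected in every library; size factors undefined")
    log_counts = np.log(counts.loc[usable].to_numpy(dtype=float))
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_counts - log_geomean, axis=0))
    return pd.Series(sf, index=counts.columns)


def transform_counts(matrix: ExpressionMatrix,
                     gene_subset=None) -> pd.DataFrame:
    """Variance-stabilised expression: log2(count / size_factor + 1).

    Monotone in count within a library and invariant to uniform depth
    changes through the median-of-ratios size factors.
    """
    counts = matrix.counts if gene_subset is None else matrix.counts.loc[list(gene_subset)]
    sf = size_factors(counts)
    return np.log2(counts.div(sf, axis=1) + 1.0)


def pcc_matrix(stabilized: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Pearson correlation across libraries.

    Zero-variance genes carry no correlation signal and are dropped with a
    warning.
    """
    if stabilized.shape[1] < 3:
        raise ValidationError("need at least 3 libraries for correlations")
    var = stabilized.var(axis=1)
    if (var == 0).any():
        dropped = list(stabilized.index[var == 0])
        _warnings.warn(f"dropping {len(dropped)} zero-variance gene(s)", stacklevel=2)
        stabilized = stabilized.loc[var > 0]
    genes = list(stabilized.index)
    r = np.corrcoef(stabilized.to_numpy(dtype=float))
    r = np.atleast_2d(r)
    return pd.DataFrame(r, index=genes, columns=genes)


def mutual_rank(pcc: pd.DataFrame) -> pd.DataFrame:
    """Mutual rank MR(i,j) = sqrt(rank_i(j) * rank_j(i)).

    rank_i(j) is the 1-based rank of j among i's partners ordered by
    descending PCC with self excluded and ties averaged. The diagonal is
    set to NaN (MR of a gene with itself is undefined).
    """
    n = pcc.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 genes for mutual ranks")
    vals = pcc.to_numpy(dtype=float)
    ranks = np.empty_like(vals)
    for i in range(n):
        row = np.delete(vals[i], i)
        r = stats.rankdata(-row)  # descending, ties averaged
        ranks[i, :i] = r[:i]
        ranks[i, i + 1:] = r[i:]
        ranks[i, i] = np.nan
    mr = np.sqrt(ranks * ranks.T)
    return pd.DataFrame(mr, index=pcc.index, columns=pcc.columns)


def build_networks(pcc: pd.DataFrame, mr: pd.DataFrame,
                   xs=DEFAULT_XS, pcc_min: float = PCC_MIN,
                   w_min: float = WEIGHT_MIN) -> dict[int, pd.DataFrame]:
    """Edge lists for each decay constant x.

    Per x, the weight is w = exp(-(MR - 1)/x); edges failing pcc >= pcc_min
    or w >= w_min are excluded. For fixed MR the weight is non-decreasing
    in x, so edge sets are nested across increasing x.
    """
    genes = list(pcc.index)
    iu = np.triu_indices(len(genes), k=1)
    pcc_v = pcc.to_numpy()[iu]
    mr_v = mr.to_numpy()[iu]
    ga = np.asarray(genes)[iu[0]]
    gb = np.asarray(genes)[iu[1]]
    networks = {}
    for x in xs:
        w = np.exp(-(mr_v - 1.0) / x)
        keep = (pcc_v >= pcc_min) & (w >= w_min)
        networks[int(x)] = pd.DataFrame({
            "gene_a": ga[keep], "gene_b": gb[keep],
            "pcc": pcc_v[keep], "mr": mr_v[keep],
            "weight": w[keep], "x": int(x),
        })
    return networks


# ---------------------------------------------------------------------------
# Greedy-cohesiveness module detection


@dataclass
class Module:
    module_id: str
    x: int
    genes: frozenset
    quality: float
    p_value: float


def _cohesiveness(w_in: float, w_bound: float, size: int,
                  penalty: float = COHESIVENESS_PENALTY) -> float:
    denom = w_in + w_bound + penalty * size
    return w_in / denom if denom > 0 else 0.0


class _Graph:
    def __init__(self, edges: pd.DataFrame):
        self.adj: dict[str, dict[str, float]] = {}
        for a, b, w in zip(edges["gene_a"], edges["gene_b"], edges["weight"]):
            self.adj.setdefault(a, {})[b] = float(w)
            self.adj.setdefault(b, {})[a] = float(w)

    def node_weight(self, v: str) -> float:
        return sum(self.adj[v].values())


def _grow_cluster(graph: _Graph, seed: str, penalty: float) -> frozenset:
    """Grow a cluster from a seed by best-improvement add/remove moves on
    cohesiveness; deterministic through lexicographic tie-breaks."""
    cluster = {seed}
    w_in = 0.0
    w_bound = graph.node_weight(seed)
    f = _cohesiveness(w_in, w_bound, 1, penalty)
    while True:
        best_move = None  # (f_new, kind, node)
        boundary_nodes = sorted({u for v in cluster for u in graph.adj[v]} - cluster)
        for u in boundary_nodes:
            delta_in = sum(w for n, w in graph.adj[u].items() if n in cluster)
            delta_out = graph.node_weight(u) - delta_in
            f_new = _cohesiveness(w_in + delta_in,
                                  w_bound - delta_in + delta_out,
                                  len(cluster) + 1, penalty)
            cand = (f_new, "add", u)
            if best_move is None or cand > best_move:
                best_move = cand
        if len(cluster) > 1:
            for v in sorted(cluster):
                delta_in = sum(w for n, w in graph.adj[v].items() if n in cluster)
                delta_out = graph.node_weight(v) - delta_in
                f_new = _cohesiveness(w_in - delta_in,
                                      w_bound + delta_in - delta_out,
                                      len(cluster) - 1, penalty)
                cand = (f_new, "remove", v)
                if best_move is None or cand > best_move:
                    best_move = cand
        if best_move is None or best_move[0] <= f + 1e-12:
            break
        f_new, kind, node = best_move
        delta_in = sum(w for n, w in graph.adj[node].items() if n in cluster - {node})
        delta_out = graph.node_weight(node) - delta_in
        if kind == "add":
            cluster.add(node)
            w_in += delta_in
            w_bound += delta_out - delta_in
        else:
            cluster.remove(node)
            w_in -= delta_in
            w_bound += delta_in - delta_out
        f = f_new
    return frozenset(cluster)


def _overlap_score(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def _module_significance(graph: _Graph, cluster: frozenset) -> float:
    """One-sided Mann-Whitney rank-sum p-value that the cluster's vertices
    carry more weight inside the module than across its boundary.

    Per vertex the in-weight (edges to other members) is compared with the
    boundary weight (edges leaving the module); a well-separated module has
    systematically larger in-weights. Defined on binary-weight graphs too,
    where per-edge weights alone carry no signal."""
    in_w, bound_w = [], []
    for v in cluster:
        wi = wb = 0.0
        for u, w in graph.adj[v].items():
            if u in cluster:
                wi += w
            else:
                wb += w
        in_w.append(wi)
        bound_w.append(wb)
    if not any(in_w):
        return 1.0
    # exact null distribution: the asymptotic approximation is badly
    # anti-conservative at the 2-4 vertex sizes chance subgraphs produce
    res = stats.mannwhitneyu(in_w, bound_w, alternative="greater", method="exact")
    return float(res.pvalue)


def detect_modules(edges: pd.DataFrame, x: int | None = None,
                   penalty: float = COHESIVENESS_PENALTY,
                   overlap_merge: float = OVERLAP_MERGE,
                   quality_min: float = QUALITY_MIN,
                   p_max: float = P_MAX) -> list[Module]:
    """Detect co-expressed modules by greedy cohesiveness growth.

    Seeds are taken in descending node-weight order among nodes not yet in
    a candidate module; clusters are grown by best-improvement add/remove
    moves, overlapping candidates (overlap score >= ``overlap_merge``) are
    merged, and the quality (final cohesiveness) and significance
    (rank-sum of in-module vs boundary edge weights) filters are applied
    inclusively: retained iff p <= p_max and quality >= quality_min.
    """
    if edges.empty:
        return []
    x = int(edges["x"].iloc[0]) if x is None and "x" in edges else (x or 0)
    graph = _Graph(edges)
    covered: set[str] = set()
    candidates: list[frozenset] = []
    for seed in sorted(graph.adj, key=lambda v: (-graph.node_weight(v), v)):
        if seed in covered:
            continue
        cluster = _grow_cluster(graph, seed, penalty)
        if len(cluster) >= 2 and cluster not in candidates:
            candidates.append(cluster)
        covered |= cluster

    # merge highly overlapping candidates until fixed point
    merged = True
    while merged:
        merged = False
        for i in range(len(candidates)):
            for j in range(i + 1, len(candidates)):
                if _overlap_score(candidates[i], candidates[j]) >= overlap_merge:
                    union = candidates[i] | candidates[j]
                    candidates = [c for k, c in enumerate(candidates) if k not in (i, j)]
                    if union not in candidates:
                        candidates.append(union)
                    merged = True
                    break
            if merged:
                break

    modules = []
    for k, cluster in enumerate(sorted(candidates, key=lambda c: sorted(c))):
        w_in = sum(w for v in cluster for u, w in graph.adj[v].items()
                   if u in cluster and v < u)
        w_bound = sum(w for v in cluster for u, w in graph.adj[v].items()
                      if u not in cluster)
        quality = _cohesiveness(w_in, w_bound, len(cluster), penalty)
        p = _module_significance(graph, cluster)
        if p <= p_max and quality >= quality_min:
            modules.append(Module(module_id=f"x{x}_m{k:03d}", x=x,
                                  genes=cluster, quality=quality, p_value=p))
    return modules


# ---------------------------------------------------------------------------
# Metamodules


@dataclass
class Metamodule:
    metamodule_id: str
    genes: frozenset
    module_ids: list[str]
    fruit_elevated: bool | None = None
    sm_domain_hit: bool | None = None
    sm_domains: frozenset = field(default_factory=frozenset)


def collapse_metamodules(modules: list[Module],
                         jaccard_min: float = METAMODULE_JACCARD) -> list[Metamodule]:
    """Collapse modules from all networks into non-overlapping metamodules.

    Modules are linked when their gene-set Jaccard index >= ``jaccard_min``;
    connected components of that overlap graph become metamodules. Each
    gene is assigned to exactly one metamodule: the component whose modules
    contain it most often, ties broken by the component with the larger
    summed overlap-edge weight, then by smaller component index.
    """
    if not modules:
        return []
    n = len(modules)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edge_weight_sum = [0.0] * n
    for i in range(n):
        for j in range(i + 1, n):
            a, b = modules[i].genes, modules[j].genes
            jac = len(a & b) / len(a | b)
            if jac >= jaccard_min:
                edge_weight_sum[i] += jac
                edge_weight_sum[j] += jac
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    comp_list = [sorted(v) for _, v in sorted(comps.items())]
    comp_weight = [sum(edge_weight_sum[i] for i in comp) for comp in comp_list]

    # gene -> component assignment
    assignment: dict[str, int] = {}
    gene_votes: dict[str, dict[int, int]] = {}
    for ci, comp in enumerate(comp_list):
        for mi in comp:
            for g in modules[mi].genes:
                gene_votes.setdefault(g, {}).setdefault(ci, 0)
                gene_votes[g][ci] += 1
    for g, votes in gene_votes.items():
        assignment[g] = min(votes, key=lambda ci: (-votes[ci], -comp_weight[ci], ci))

    metamodules = []
    for ci, comp in enumerate(comp_list):
        genes = frozenset(g for g, a in assignment.items() if a == ci)
        if not genes:
            continue
        metamodules.append(Metamodule(
            metamodule_id=f"MM{ci + 1:04d}",
            genes=genes,
            module_ids=[modules[mi].module_id for mi in comp]))
    return metamodules


def annotate_metamodules(metamodules: list[Metamodule], fpkm: pd.DataFrame,
                         fruit_libraries: list[str],
                         domain_map: pd.DataFrame | None = None,
                         sm_domains=None) -> list[Metamodule]:
    """Flag fruit-elevated and specialized-metabolism metamodules in place.

    Fruit-elevated: mean member FPKM over fruit libraries strictly greater
    than over non-fruit libraries. SM hit: any member gene maps to a domain
    in ``sm_domains`` (flags stay None without a domain map).
    """
    fruit = [l for l in fpkm.columns if l in set(fruit_libraries)]
    nonfruit = [l for l in fpkm.columns if l not in set(fruit_libraries)]
    if not fruit or not nonfruit:
        raise ValidationError("need both fruit and non-fruit libraries to annotate")
    gene_domains: dict[str, set] = {}
    if domain_map is not None:
        for g, d in zip(domain_map["gene_id"], domain_map["domain_id"]):
            gene_domains.setdefault(g, set()).add(d)
    sm = set(sm_domains) if sm_domains is not None else None
    for mm in metamodules:
        members = [g for g in mm.genes if g in fpkm.index]
        if members:
            mm.fruit_elevated = bool(
                fpkm.loc[members, fruit].to_numpy().mean()
                > fpkm.loc[members, nonfruit].to_numpy().mean())
        if domain_map is not None and sm is not None:
            hits = frozenset(d for g in mm.genes
                             for d in gene_domains.get(g, ()) if d in sm)
            mm.sm_domains = hits
            mm.sm_domain_hit = bool(hits)
    return metamodules


def sm_domain_list() -> list[str]:
    """Packaged default list of Pfam domains associated with specialized
    metabolism (user-replaceable via the domain-list file)."""
    from importlib.resources import files
    text = files("polyploidkit.data").joinpath("sm_domains.txt").read_text()
    return [line.split("#")[0].strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]
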