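"""JTT maximum-likelihood pairwise distances, neighbor joining, bootstrap.

The tree-building surrogate used throughout is: per-pair ML distances under
the JTT model (uniform rates, pairwise or complete deletion of gapped
columns) followed by Saitou-Nei neighbor joining, with nonparametric column
bootstrap for internal-edge support.  This reproduces the topology and
cluster-coherence level of analysis; it is not a full ML topology search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .errors import LookupMissingError, UndefinedDistanceError, ValidationError
from .jtt import JTTModel, default_model
from .seqio import GAP, MasterAlignment

T_MAX_DEFAULT = 10.0


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(self.d)):
            raise ValidationError("non-finite distances")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValidationError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValidationError("nonzero diagonal")
        if np.any(self.d < 0):
            raise ValidationError("negative distances")


def _pair_counts(a: str, b: str, model: JTTModel) -> np.ndarray:
    """20x20 matrix of aligned residue-pair counts over shared columns."""
    idx = {ch: i for i, ch in enumerate(model_order())}
    N = np.zeros((20, 20))
    for x, y in zip(a, b):
        i = idx.get(x)
        j = idx.get(y)
        if i is not None and j is not None:
            N[i, j] += 1.0
    return N


def model_order() -> str:
    from .jtt import JTT_ORDER
    return JTT_ORDER


def jtt_pairwise_distance(a_aligned: str, b_aligned: str,
                          model: JTTModel | None = None,
                          t_max: float = T_MAX_DEFAULT) -> float:
    """ML distance (substitutions/site) between two rows of an alignment.

    Maximises sum over shared non-gap columns of log[pi_a * P(t)_{ab}] by
    bounded scalar optimisation on (0, t_max].  A saturated pair returns
    t_max with a warning rather than infinity.
    """
    if len(a_aligned) != len(b_aligned):
        raise ValidationError("aligned rows differ in length")
    model = model or default_model()
    N = _pair_counts(a_aligned, b_aligned, model)
    n_shared = N.sum()
    if n_shared == 0:
        raise UndefinedDistanceError("no shared residue columns")
    if np.trace(N) == n_shared:
        return 0.0
    mask = N > 0

    def neg_ll(t: float) -> float:
        P = model.transition_matrix(t)
        return -float(np.sum(N[mask] * np.log(np.maximum(P[mask], 1e-300))))

    res = minimize_scalar(neg_ll, bounds=(1e-9, t_max), method="bounded",
                          options={"xatol": 1e-8})
    t_hat = float(res.x)
    if t_hat > t_max * 0.999:
        warnings.warn("pairwise distance saturated; returning t_max", stacklevel=2)
        return t_max
    return t_hat


def distance_matrix(master: MasterAlignment, model: JTTModel | None = None,
                    deletion: str = "pairwise",
                    t_max: float = T_MAX_DEFAULT) -> DistanceMatrix:
    """All-pairs JTT ML distances from a master alignment.

    ``deletion`` = "pairwise" (per-pair shared columns, default) or
    "complete" (drop every column containing any gap first).
    """
    rows = master.rows
    if deletion == "complete":
        keep = [j for j in range(master.length)
                if all(r[j] != GAP and r[j] != "X" for r in rows)]
        rows = ["".join(r[j] for j in keep) for r in rows]
    elif deletion != "pairwise":
        raise ValidationError(f"unknown deletion mode {deletion!r}")
    model = model or default_model()
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jtt_pairwise_distance(rows[i], rows[j], model, t_max)
    return DistanceMatrix(labels=list(master.ids), d=d)


# ---------------------------------------------------------------------------
# Neighbor joining

def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic label-order tie-breaks.

    Negative branch lengths are clamped to zero with the deficit shifted to
    the sister edge, so the path length between the joined pair is preserved.
    """
    n = len(D.labels)
    if n < 3:
        raise ValidationError("neighbor joining needs >= 3 taxa")
    tns = dendropy.TaxonNamespace()
    nodes: dict[int, dendropy.Node] = {}
    labels: dict[int, str] = {}
    for k, lab in enumerate(D.labels):
        nd = dendropy.Node()
        nd.taxon = tns.new_taxon(label=lab)
        nodes[k] = nd
        labels[k] = lab
    active = list(range(n))
    d = {(i, j): D.d[i, j] for i in range(n) for j in range(n) if i != j}
    nxt = n

    def dist(i: int, j: int) -> float:
        return d[(i, j)] if i != j else 0.0

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                key = (q, min(labels[i], labels[j]), max(labels[i], labels[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = dist(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        u = dendropy.Node()
        ci, cj = nodes[i], nodes[j]
        u.add_child(ci)
        u.add_child(cj)
        ci.edge.length = max(li, 0.0)
        cj.edge.length = max(lj, 0.0)
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dist(i, k) + dist(j, k) - dij)
            d[(nxt, k)] = d[(k, nxt)] = max(duk, 0.0)
        nodes[nxt] = u
        labels[nxt] = min(labels[i], labels[j])
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    i, j, k = active
    root = dendropy.Node()
    li = 0.5 * (dist(i, j) + dist(i, k) - dist(j, k))
    lj = 0.5 * (dist(i, j) + dist(j, k) - dist(i, k))
    lk = 0.5 * (dist(i, k) + dist(j, k) - dist(i, j))
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=True)
    return tree


# ---------------------------------------------------------------------------
# Bipartitions, bootstrap, collapsing, coherence

def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _normalize(side: frozenset, all_leaves: frozenset, ref: str) -> frozenset:
    return side if ref not in side else all_leaves - side


def bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Internal (non-trivial) bipartitions, keyed by the side excluding a
    fixed reference leaf; values are the child nodes defining each edge."""
    all_leaves = frozenset(leaf_labels(tree))
    ref = min(all_leaves)
    out: dict[frozenset, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        under = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(under) <= 1 or len(all_leaves - under) <= 1:
            continue
        out[_normalize(under, all_leaves, ref)] = node
    return out


def get_support(node: dendropy.Node) -> float | None:
    sup = getattr(node, "support", None)
    if sup is not None:
        return float(sup)
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            return None
    return None


def bootstrap_support(master: MasterAlignment, n_reps: int, seed: int,
                      model: JTTModel | None = None,
                      deletion: str = "pairwise",
                      t_max: float = T_MAX_DEFAULT,
                      max_redraws: int = 100) -> dendropy.Tree:
    """NJ tree on the full alignment with % column-bootstrap edge support."""
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    model = model or default_model()
    tree = neighbor_joining(distance_matrix(master, model, deletion, t_max))
    bips = bipartitions(tree)
    counts = {b: 0 for b in bips}
    rng = np.random.default_rng(seed)
    L = master.length
    done = redraws = 0
    while done < n_reps:
        cols = rng.integers(0, L, size=L)
        rep = MasterAlignment(
            ids=list(master.ids),
            rows=["".join(row[c] for c in cols) for row in master.rows])
        try:
            rep_tree = neighbor_joining(distance_matrix(rep, model, deletion, t_max))
        except UndefinedDistanceError:
            redraws += 1
            if redraws > max_redraws:
                raise
            warnings.warn("bootstrap replicate had an undefined pair; redrawn",
                          stacklevel=2)
            continue
        rep_bips = set(bipartitions(rep_tree))
        for b in counts:
            if b in rep_bips:
                counts[b] += 1
        done += 1
    for b, node in bips.items():
        sup = 100.0 * counts[b] / n_reps
        node.support = sup
        node.label = f"{sup:g}"
    return tree


def collapse_low_support(tree: dendropy.Tree, threshold: float) -> dendropy.Tree:
    """Contract every internal edge whose support is below ``threshold``."""
    out = tree.clone(depth=1)
    changed = True
    while changed:
        changed = False
        for node in list(out.preorder_node_iter()):
            if node.parent_node is None or node.is_leaf():
                continue
            sup = get_support(node)
            if sup is not None and sup < threshold:
                parent = node.parent_node
                for ch in list(node.child_nodes()):
                    node.remove_child(ch)
                    parent.add_child(ch)
                parent.remove_child(node)
                changed = True
    return out


def clade_coherence(tree: dendropy.Tree, grouping: dict[str, str]) -> dict[str, bool]:
    """Per-group unrooted monophyly: does the group form one side of some
    bipartition (trivial groups of size 1, or the full leaf set, count)."""
    all_leaves = frozenset(leaf_labels(tree))
    missing = all_leaves - set(grouping)
    if missing:
        raise LookupMissingError(f"leaves without group assignment: {sorted(missing)[:5]}")
    groups: dict[str, set[str]] = {}
    for leaf, g in grouping.items():
        if leaf in all_leaves:
            groups.setdefault(g, set()).add(leaf)
    if not groups:
        raise LookupMissingError("no groups present in tree")
    ref = min(all_leaves)
    sides = set(bipartitions(tree))
    out: dict[str, bool] = {}
    for g, members in groups.items():
        fs = frozenset(members)
        if len(fs) <= 1 or fs == all_leaves or len(all_leaves - fs) == 1:
            out[g] = True
        else:
            out[g] = _normalize(fs, all_leaves, ref) in sides
    return out
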