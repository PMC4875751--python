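"""Synthetic ortholog families with planted role signal, plus truth records.

The generator emulates the statistical structure the analysis pipeline
assumes: families of 10-40 orthologous proteins ~160-175 residues long,
evolved along an order-structured tree under the JTT model, split into two
role groups (global / local) with (i) a small set of planted
role-diagnostic columns retained with a configurable probability, and
(ii) group-level terminal-tail presence/absence — conserved N-terminal tail
and C-terminal motif block in the "global" orders only, mirroring the
shorter and more variable termini of locally-acting orthologs.  Indels are
modelled only as these terminal extensions; internal columns never gap, so
the generator knows the true master alignment exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import dendropy
import numpy as np

from .errors import ValidationError
from .jtt import JTT_ORDER, JTTModel, default_model
from .seqio import GAP, MasterAlignment, ProteinSequence

#: Default planted scheme: 8 diagnostic columns with the global/local residues.
DEFAULT_PLANTED = [
    (14, "D", "A", 0.95), (21, "N", "K", 0.95), (36, "E", "D", 0.95),
    (40, "R", "K", 0.95), (60, "F", "V", 0.95), (80, "F", "V", 0.95),
    (128, "S", "A", 0.95), (136, "D", "T", 0.95),
]


@dataclass
class SimulationConfig:
    n_orders: int = 4
    species_per_order: int = 10
    seq_length: int = 171
    tree_height: float = 0.5          # substitutions/site, root to tip
    duplication_depth: float = 1.5    # for paralog pairs
    planted_positions: list[tuple[int, str, str, float]] = dc_field(
        default_factory=lambda: list(DEFAULT_PLANTED))
    order_roles: tuple[str, ...] = ("global", "global", "local", "global")
    n_tail_len: int = 12
    c_motif: str = "LVIKTR"
    c_motif_start: int = 159
    motif_retention: float = 0.95
    c_trim_len: int = 6               # extra C-terminal columns absent in local
    gamma_alpha: float | None = None
    neutral: bool = False             # pure JTT evolution: no planting, no tails
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.order_roles) < self.n_orders:
            raise ValidationError("order_roles shorter than n_orders")
        for col, rg, rl, ret in self.planted_positions:
            if not 1 <= col <= self.seq_length:
                raise ValidationError(f"planted column {col} > seq_length")
            if not 0.0 <= ret <= 1.0:
                raise ValidationError("retention must lie in [0, 1]")
        if self.c_motif_start + len(self.c_motif) - 1 > self.seq_length:
            raise ValidationError("c_motif extends past seq_length")


@dataclass
class TruthRecord:
    tree_newick: str
    order_by_id: dict[str, str]
    role_by_id: dict[str, str]
    planted: list[tuple[int, str, str, float]]
    realized: dict[str, dict[int, str]]
    family_by_id: dict[str, str] = dc_field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        obj = {"tree_newick": self.tree_newick, "order_by_id": self.order_by_id,
               "role_by_id": self.role_by_id,
               "planted": [list(p) for p in self.planted],
               "realized": {k: {str(c): r for c, r in v.items()}
                            for k, v in self.realized.items()},
               "family_by_id": self.family_by_id}
        Path(path).write_text(json.dumps(obj, indent=2))


@dataclass
class SimulatedFamily:
    alignment: MasterAlignment   # true master alignment (gaps only at termini)
    truth: TruthRecord

    @property
    def sequences(self) -> list[ProteinSequence]:
        return [ProteinSequence(id=i, residues=r.replace(GAP, ""))
                for i, r in zip(self.alignment.ids, self.alignment.rows)]

    def group_ids(self, role: str) -> list[str]:
        return [i for i in self.alignment.ids if self.truth.role_by_id[i] == role]


# ---------------------------------------------------------------------------
# Sequence evolution primitives

def sample_equilibrium(length: int, rng: np.random.Generator,
                       model: JTTModel | None = None) -> np.ndarray:
    model = model or default_model()
    return rng.choice(20, size=length, p=model.pi)


def evolve_branch(parent: np.ndarray, t: float, rng: np.random.Generator,
                  model: JTTModel | None = None,
                  site_rates: np.ndarray | None = None) -> np.ndarray:
    """Evolve integer-coded states along one branch of length t."""
    model = model or default_model()
    if site_rates is None:
        P = model.transition_matrix(t)
        cum = np.cumsum(P, axis=1)
        u = rng.random(parent.shape[0])
        return (cum[parent] < u[:, None]).sum(axis=1).astype(parent.dtype)
    child = np.empty_like(parent)
    for r in np.unique(site_rates):
        idx = site_rates == r
        P = model.transition_matrix(t * float(r))
        cum = np.cumsum(P, axis=1)
        u = rng.random(int(idx.sum()))
        child[idx] = (cum[parent[idx]] < u[:, None]).sum(axis=1)
    return child


def _gamma_site_rates(length: int, alpha: float | None,
                      rng: np.random.Generator, k: int = 4) -> np.ndarray | None:
    """Discrete-gamma rate multipliers (k categories, mean 1), or None."""
    if alpha is None:
        return None
    from scipy.stats import gamma as gamma_dist
    quantiles = (np.arange(k) + 0.5) / k
    rates = gamma_dist.ppf(quantiles, a=alpha, scale=1.0 / alpha)
    rates /= rates.mean()
    return rates[rng.integers(0, k, size=length)]


def _scaled_yule(n_leaves: int, height: float,
                 rng: np.random.Generator) -> dendropy.Tree:
    """Ultrametric Yule clade rescaled so every leaf sits at ``height``.

    A final exponential hold time after the last speciation keeps cherry
    edges strictly positive (cutting exactly at the n-th split would leave
    zero-length, unresolvable cherries).
    """
    tree = dendropy.Tree()
    root = tree.seed_node
    root.depth = 0.0
    if n_leaves == 1:
        root.depth = height
        return tree
    active = []
    for _ in range(2):
        ch = dendropy.Node()
        root.add_child(ch)
        active.append(ch)
    t = 0.0
    while len(active) < n_leaves:
        k = len(active)
        t += rng.exponential(1.0 / k)
        nd = active.pop(int(rng.integers(k)))
        nd.depth = t
        for _ in range(2):
            ch = dendropy.Node()
            nd.add_child(ch)
            active.append(ch)
    total = t + rng.exponential(1.0 / n_leaves)
    for lf in active:
        lf.depth = total
    scale = height / total if total > 0 else 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = (node.depth - node.parent_node.depth) * scale
    return tree


def _evolve_tree(tree: dendropy.Tree, root_states: np.ndarray,
                 rng: np.random.Generator, model: JTTModel,
                 site_rates: np.ndarray | None) -> dict[str, np.ndarray]:
    states = {id(tree.seed_node): root_states}
    leaves: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = node.edge.length or 0.0
        child = evolve_branch(states[id(node.parent_node)], t, rng, model, site_rates)
        states[id(node)] = child
        if node.is_leaf():
            leaves[node.taxon.label] = child
    return leaves


def _decode(states: np.ndarray) -> str:
    return "".join(JTT_ORDER[s] for s in states)


# ---------------------------------------------------------------------------
# Family simulation

def _build_order_tree(config: SimulationConfig, rng: np.random.Generator,
                      prefix: str = "") -> dendropy.Tree:
    """Backbone over orders, each order a Yule radiation of its species."""
    clade_height = config.tree_height / 2.0
    backbone = config.tree_height / 4.0
    tns = dendropy.TaxonNamespace()
    items: list[dendropy.Node] = []
    for k in range(config.n_orders):
        sub = _scaled_yule(config.species_per_order, clade_height, rng)
        for idx, lf in enumerate(sub.leaf_node_iter(), start=1):
            lf.taxon = tns.new_taxon(
                label=f"{prefix}o{k + 1}s{idx:02d}")
        items.append(sub.seed_node)
    # balanced binary backbone over the order clades
    while len(items) > 1:
        nxt: list[dendropy.Node] = []
        for i in range(0, len(items) - 1, 2):
            parent = dendropy.Node()
            for ch in (items[i], items[i + 1]):
                parent.add_child(ch)
                ch.edge.length = backbone
            nxt.append(parent)
        if len(items) % 2:
            nxt.append(items[-1])
        items = nxt
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = items[0]
    tree.is_rooted = True
    return tree


def _apply_signal(alignment_rows: dict[str, list[str]], config: SimulationConfig,
                  role_by_id: dict[str, str], rng: np.random.Generator,
                  model: JTTModel) -> dict[str, dict[int, str]]:
    """Plant diagnostic columns + C-motif; gap terminal regions per role.

    The variable N-terminal fray never reaches the first planted column:
    locally-acting orthologs have shorter, more variable N-termini but do
    carry residues at the diagnostic positions themselves.
    """
    realized: dict[str, dict[int, str]] = {}
    motif_cols = range(config.c_motif_start,
                       config.c_motif_start + len(config.c_motif))
    first_planted = min((p[0] for p in config.planted_positions),
                        default=config.seq_length + 1)
    for sid, row in alignment_rows.items():
        role = role_by_id[sid]
        for col, res_g, res_l, ret in config.planted_positions:
            target = res_g if role == "global" else res_l
            if rng.random() < ret:
                row[col - 1] = target
            else:
                row[col - 1] = JTT_ORDER[int(rng.choice(20, p=model.pi))]
        if role == "global":
            for k, col in enumerate(motif_cols):
                if rng.random() < config.motif_retention:
                    row[col - 1] = config.c_motif[k]
            trim = int(rng.integers(0, 3))  # small variable N-terminal fray
            for col in range(1, trim + 1):
                row[col - 1] = GAP
        else:
            n_gap = min(config.n_tail_len + int(rng.integers(0, 4)),
                        first_planted - 1)
            for col in range(1, n_gap + 1):
                row[col - 1] = GAP
            c_gap = config.c_trim_len + int(rng.integers(0, 3))
            for col in range(config.seq_length - c_gap + 1, config.seq_length + 1):
                row[col - 1] = GAP
        realized[sid] = {col: row[col - 1]
                         for col, _, _, _ in config.planted_positions}
    return realized


def simulate_family(config: SimulationConfig) -> SimulatedFamily:
    """One ortholog family with planted role signal and a truth record."""
    rng = np.random.default_rng(config.seed)
    model = default_model()
    tree = _build_order_tree(config, rng)
    site_rates = _gamma_site_rates(config.seq_length, config.gamma_alpha, rng)
    root = sample_equilibrium(config.seq_length, rng, model)
    leaves = _evolve_tree(tree, root, rng, model, site_rates)
    ids = sorted(leaves)
    order_by_id = {sid: "order" + sid[sid.rindex("o") + 1] for sid in ids}
    role_by_id = {sid: config.order_roles[int(order_by_id[sid][-1]) - 1]
                  for sid in ids}
    rows = {sid: list(_decode(leaves[sid])) for sid in ids}
    if config.neutral:
        realized: dict[str, dict[int, str]] = {}
        planted: list[tuple[int, str, str, float]] = []
    else:
        realized = _apply_signal(rows, config, role_by_id, rng, model)
        planted = list(config.planted_positions)
    aln = MasterAlignment(ids=ids, rows=["".join(rows[i]) for i in ids])
    truth = TruthRecord(
        tree_newick=tree.as_string(schema="newick").strip(),
        order_by_id=order_by_id, role_by_id=role_by_id,
        planted=planted, realized=realized)
    return SimulatedFamily(alignment=aln, truth=truth)


def simulate_planted_columns(n_A: int, n_B: int, n_positions: int,
                             planted: list[tuple[int, str, str, float]],
                             seed: int = 0,
                             dirichlet_alpha: float = 0.5) -> tuple[MasterAlignment, list[str], list[str]]:
    """Two groups with iid shared-distribution columns plus planted signal.

    Background columns are drawn, for both groups alike, from a per-column
    residue distribution sampled from Dirichlet(alpha) — the same null as
    the two-sample calibration — and the planted columns are overwritten
    with the group residue at the given retention.  This isolates detector
    performance from phylogenetic autocorrelation: in tree-evolved families
    drift-fixed columns are genuinely group-separating and are reported as
    candidates exactly as a real analysis would report them.
    """
    rng = np.random.default_rng(seed)
    model = default_model()
    ids_A = [f"A{k:02d}" for k in range(1, n_A + 1)]
    ids_B = [f"B{k:02d}" for k in range(1, n_B + 1)]
    cols = np.empty((n_A + n_B, n_positions), dtype="U1")
    for j in range(n_positions):
        probs = rng.dirichlet(np.full(20, dirichlet_alpha))
        draws = rng.choice(20, size=n_A + n_B, p=probs)
        cols[:, j] = [JTT_ORDER[s] for s in draws]
    for col, res_g, res_l, ret in planted:
        if not 1 <= col <= n_positions:
            raise ValidationError(f"planted column {col} > n_positions")
        for i in range(n_A + n_B):
            target = res_g if i < n_A else res_l
            if rng.random() < ret:
                cols[i, col - 1] = target
            else:
                cols[i, col - 1] = JTT_ORDER[int(rng.choice(20, p=model.pi))]
    rows = ["".join(cols[i]) for i in range(n_A + n_B)]
    aln = MasterAlignment(ids=ids_A + ids_B, rows=rows)
    return aln, ids_A, ids_B


def simulate_paralog_pair(config: SimulationConfig,
                          block_span: tuple[int, int] = (106, 124),
                          block_retention: float = 0.98) -> SimulatedFamily:
    """Two paralog clades joined by a deep duplication.

    Each clade is an order-structured family; each carries a distinct
    planted family-identifying block over ``block_span`` (19 columns by
    default, mirroring the length of real family-diagnostic segments).
    Such blocks are near-invariant within a family — that is what makes
    them usable for annotation — so they are planted at high retention.
    Clade coherence and segment extraction both get known truth.
    """
    clade_height = config.tree_height / 2.0
    if config.duplication_depth <= clade_height + config.tree_height / 4.0:
        raise ValidationError("duplication_depth must exceed clade height")
    rng = np.random.default_rng(config.seed)
    model = default_model()
    tns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    fam_ids: dict[str, str] = {}
    subtrees = []
    for fam in ("fam1", "fam2"):
        sub = _build_order_tree(config, rng, prefix=fam + "_")
        clade_root = sub.seed_node
        root.add_child(clade_root)
        clade_root.edge.length = (config.duplication_depth
                                  - config.tree_height / 2.0)
        subtrees.append(sub)
        for lf in sub.leaf_node_iter():
            fam_ids[lf.taxon.label] = fam
            tns.new_taxon(label=lf.taxon.label)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    site_rates = _gamma_site_rates(config.seq_length, config.gamma_alpha, rng)
    root_states = sample_equilibrium(config.seq_length, rng, model)
    leaves = _evolve_tree(tree, root_states, rng, model, site_rates)
    ids = sorted(leaves)
    order_by_id = {sid: "order" + sid[sid.rindex("o") + 1] for sid in ids}
    role_by_id = {sid: config.order_roles[int(order_by_id[sid][-1]) - 1]
                  for sid in ids}
    rows = {sid: list(_decode(leaves[sid])) for sid in ids}
    # distinct family-identifying blocks
    lo, hi = block_span
    block_cols = list(range(lo, hi + 1))
    blocks = {}
    for fam in ("fam1", "fam2"):
        blocks[fam] = [JTT_ORDER[int(rng.choice(20, p=model.pi))] for _ in block_cols]
    # ensure the blocks actually differ column by column
    for k in range(len(block_cols)):
        while blocks["fam2"][k] == blocks["fam1"][k]:
            blocks["fam2"][k] = JTT_ORDER[int(rng.choice(20, p=model.pi))]
    for sid in ids:
        fam = fam_ids[sid]
        for k, col in enumerate(block_cols):
            if rng.random() < block_retention:
                rows[sid][col - 1] = blocks[fam][k]
    realized = _apply_signal(rows, config, role_by_id, rng, model)
    for sid in ids:
        for k, col in enumerate(block_cols):
            realized.setdefault(sid, {})[col] = rows[sid][col - 1]
    aln = MasterAlignment(ids=ids, rows=["".join(rows[i]) for i in ids])
    truth = TruthRecord(
        tree_newick=tree.as_string(schema="newick").strip(),
        order_by_id=order_by_id, role_by_id=role_by_id,
        planted=[(c, blocks["fam1"][k], blocks["fam2"][k], block_retention)
                 for k, c in enumerate(block_cols)],
        realized=realized, family_by_id=fam_ids)
    return SimulatedFamily(alignment=aln, truth=truth)
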