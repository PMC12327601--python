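"""Reaction-network construction and pathway-DAG extraction.

Measured mass features (with neutral-mass hypotheses from annotation) become
nodes of a reaction network. Two nodes are connected when their neutral-mass
difference matches the mass transition of a reaction rule within tolerance,
in both orientations for bidirectional rules. A candidate connection is kept
only when at least one transcript correlated (or co-clustered) with either
feature encodes a protein family associated with the rule — the edge's
enzyme support.

Where no single rule explains a mass difference, an optional *ghost* node —
a virtual, unmeasured intermediate — can bridge two measured nodes whenever
two rule transitions sum to their mass difference.

Rooted at an initial metabolite, the network is reduced to a directed
acyclic graph: only edges advancing the reaction distance from the root are
retained, and residual cycles among equidistant nodes are broken by deleting
the edge with the weakest enzyme-metabolite correlation. The longest path
from the root is the pathway prediction; the procedure is repeated on the
reversed network rooted at the terminal metabolite, yielding two predictions
per input structure.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.Descriptors import ExactMolWt

from .core_data import ReactionRule, TranscriptAnnotation, ValidationError
from .rules import TransitionIndex

logger = logging.getLogger(__name__)

#: absolute mass-agreement ceiling for in-silico products (Da)
PRODUCT_MASS_TOL = 0.005

MEASURED = "measured"
GHOST = "ghost"

PAIR_COLUMNS = ["substrate_node", "product_node", "rule_id", "direction", "transition"]
EDGE_COLUMNS = PAIR_COLUMNS + ["support_transcripts", "edge_support"]


@dataclass(frozen=True)
class MassSignatureNode:
    """A network node: a measured mass signature or a ghost intermediate."""

    node_id: str
    kind: str  # measured | ghost
    mass: float  # neutral, Da
    source_feature: str | None = None
    structures: tuple[str, ...] = ()
    derivation: tuple[str, str] | None = None  # (anchor node_id, rule_id) for ghosts

    def __post_init__(self):
        if self.kind == MEASURED and self.source_feature is None:
            raise ValidationError(f"measured node {self.node_id} lacks a source feature")
        if self.kind == GHOST and self.derivation is None:
            raise ValidationError(f"ghost node {self.node_id} lacks a derivation")


@dataclass
class PathwayDAG:
    """Rooted acyclic reaction graph."""

    root: str
    graph: nx.MultiDiGraph

    def __post_init__(self):
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValidationError("pathway graph contains a directed cycle")


def _mass_key(mass: float) -> float:
    return round(mass, 4)


def feature_nodes(
    features,
    candidates: pd.DataFrame | None = None,
    fallback_adducts=(),
) -> list[MassSignatureNode]:
    """One measured node per feature per distinct neutral-mass hypothesis.

    Annotated features contribute the neutral masses (and structures) of
    their candidates, deduplicated by rounded mass. Unannotated features
    fall back to the neutral masses implied by ``fallback_adducts`` (they
    then carry no structure hypotheses but can still anchor transitions).
    """
    from .annotate import neutral_mass  # local import avoids a cycle

    nodes: list[MassSignatureNode] = []
    annotated: dict[str, dict[float, set[str]]] = {}
    if candidates is not None and len(candidates):
        for row in candidates.itertuples(index=False):
            key = _mass_key(row.neutral_mass)
            annotated.setdefault(row.feature_id, {}).setdefault(key, set()).add(row.smiles)
    for fid, mz in features.mz.items():
        if fid in annotated:
            for key, smis in sorted(annotated[fid].items()):
                nodes.append(
                    MassSignatureNode(
                        node_id=f"{fid}@{key:.4f}",
                        kind=MEASURED,
                        mass=key,
                        source_feature=fid,
                        structures=tuple(sorted(smis)),
                    )
                )
        else:
            seen: set[float] = set()
            for adduct in fallback_adducts:
                m = neutral_mass(float(mz), adduct)
                if m <= 0:
                    continue
                key = _mass_key(m)
                if key in seen:
                    continue
                seen.add(key)
                nodes.append(
                    MassSignatureNode(
                        node_id=f"{fid}@{key:.4f}",
                        kind=MEASURED,
                        mass=key,
                        source_feature=fid,
                    )
                )
    return nodes


def match_mass_pairs(
    nodes: list[MassSignatureNode],
    index: TransitionIndex,
    tol_da: float = 0.002,
) -> pd.DataFrame:
    """All ordered node pairs whose neutral-mass difference matches an
    indexed transition within ``tol_da``; a pair may carry several rules."""
    rows = []
    for a, b in itertools.permutations(nodes, 2):
        diff = b.mass - a.mass
        for rule_id, direction in index.lookup(diff, tol_da):
            rows.append(
                {
                    "substrate_node": a.node_id,
                    "product_node": b.node_id,
                    "rule_id": rule_id,
                    "direction": direction,
                    "transition": diff,
                }
            )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS).sort_values(
        PAIR_COLUMNS[:4], ignore_index=True
    )


def insert_ghosts(
    pairs: pd.DataFrame,
    nodes: list[MassSignatureNode],
    index: TransitionIndex,
    mode: str = "auto",
    tol_da: float = 0.002,
) -> tuple[pd.DataFrame, list[MassSignatureNode]]:
    """Bridge measured node pairs through one virtual intermediate.

    For measured A, C with no single-rule link, if transitions t1 + t2 equal
    mass(C) - mass(A) within tolerance, a ghost node B at mass(A) + t1 is
    inserted with edges A->B->C. In ``auto`` mode ghosts are generated only
    for nodes that received no substrate/product assignment; ``always``
    considers every unlinked pair; ``off`` is the identity. One ghost per
    (A, C) pair and one generation round per call.
    """
    if mode not in ("off", "auto", "always"):
        raise ValidationError(f"unknown ghost mode {mode!r}")
    if mode == "off":
        return pairs, []
    assigned = set(pairs["substrate_node"]) | set(pairs["product_node"])
    linked = set(zip(pairs["substrate_node"], pairs["product_node"]))
    measured = [n for n in nodes if n.kind == MEASURED]
    ghost_nodes: dict[str, MassSignatureNode] = {}
    new_rows = []
    for a, c in itertools.permutations(measured, 2):
        if (a.node_id, c.node_id) in linked:
            continue
        if mode == "auto" and a.node_id in assigned and c.node_id in assigned:
            continue
        diff = c.mass - a.mass
        bridge = None
        for t1, rid1, dir1 in index.entries:
            for rid2, dir2 in index.lookup(diff - t1, tol_da):
                cand = (rid1, rid2, t1, dir1, dir2)
                if bridge is None or cand[:2] < bridge[:2]:
                    bridge = cand
        if bridge is None:
            continue
        rid1, rid2, t1, dir1, dir2 = bridge
        gmass = _mass_key(a.mass + t1)
        gid = f"ghost@{gmass:.4f}"
        if gid not in ghost_nodes:
            ghost_nodes[gid] = MassSignatureNode(
                node_id=gid,
                kind=GHOST,
                mass=gmass,
                derivation=(a.node_id, rid1),
            )
        new_rows.append(
            {
                "substrate_node": a.node_id,
                "product_node": gid,
                "rule_id": rid1,
                "direction": dir1,
                "transition": gmass - a.mass,
            }
        )
        new_rows.append(
            {
                "substrate_node": gid,
                "product_node": c.node_id,
                "rule_id": rid2,
                "direction": dir2,
                "transition": c.mass - gmass,
            }
        )
    if not new_rows:
        return pairs, []
    new_df = pd.DataFrame(new_rows, columns=PAIR_COLUMNS)
    frames = [pairs, new_df] if len(pairs) else [new_df]
    extended = pd.concat(frames, ignore_index=True).drop_duplicates(
        subset=PAIR_COLUMNS[:4], ignore_index=True
    )
    extended = extended.sort_values(PAIR_COLUMNS[:4], ignore_index=True)
    return extended, sorted(ghost_nodes.values(), key=lambda n: n.node_id)


def attach_enzyme_support(
    pairs: pd.DataFrame,
    network: pd.DataFrame,
    annotations: list[TranscriptAnnotation],
    rules: dict[str, ReactionRule],
    clusters=None,
    cluster_restrict: bool = True,
) -> pd.DataFrame:
    """Retain pairs backed by omics evidence and record their support.

    A pair becomes a reaction edge iff at least one transcript (i) is
    correlated with the substrate or product feature in the decay-weighted
    ``network`` (columns transcript_id, feature_id, weight) — and, with
    ``cluster_restrict``, also co-clustered with that feature in one of the
    ``clusters`` — and (ii) carries a Pfam associated with the rule.
    ``edge_support`` is the maximum supporting edge weight. Ghost-adjacent
    edges inherit the evidence of their measured endpoint.
    """
    pfams_of: dict[str, set[str]] = {
        a.transcript_id: set(a.pfam_ids) for a in annotations
    }
    partners: dict[str, dict[str, float]] = {}
    for t, f, w in network[["transcript_id", "feature_id", "weight"]].itertuples(index=False):
        partners.setdefault(f, {})[t] = max(float(w), partners.get(f, {}).get(t, 0.0))
    co_clustered: dict[str, set[str]] | None = None
    if cluster_restrict and clusters is not None:
        co_clustered = {}
        for c in clusters:
            for f in c.features:
                co_clustered.setdefault(f, set()).update(c.transcripts)

    node_feature = {}  # node id -> source feature (None for ghosts)

    def feature_of(node_id: str) -> str | None:
        if node_id in node_feature:
            return node_feature[node_id]
        fid = None if node_id.startswith("ghost@") else node_id.rsplit("@", 1)[0]
        node_feature[node_id] = fid
        return fid

    rows = []
    for row in pairs.itertuples(index=False):
        rule = rules.get(row.rule_id)
        if rule is None:
            continue
        rule_pfams = rule.pfam_ids
        supporters: dict[str, float] = {}
        for node_id in (row.substrate_node, row.product_node):
            fid = feature_of(node_id)
            if fid is None:
                continue
            for t, w in partners.get(fid, {}).items():
                if not (pfams_of.get(t, set()) & rule_pfams):
                    continue
                if co_clustered is not None and t not in co_clustered.get(fid, set()):
                    continue
                supporters[t] = max(supporters.get(t, 0.0), w)
        if not supporters:
            continue
        rows.append(
            {
                **{c: getattr(row, c) for c in PAIR_COLUMNS},
                "support_transcripts": ";".join(sorted(supporters)),
                "edge_support": max(supporters.values()),
            }
        )
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


# ---------------------------------------------------------------------------
# Substructure prescreen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubstructureKey:
    name: str
    smarts: str
    parents: tuple[str, ...] = ()


@dataclass
class SubstructureHierarchy:
    """Divide-and-conquer substructure DAG: atoms -> simple bonds -> composed
    patterns. A structure is tested for a key only when all of the key's
    parents matched, so complex queries run only on plausible molecules."""

    keys: tuple[SubstructureKey, ...]

    def __post_init__(self):
        names = {k.name for k in self.keys}
        for k in self.keys:
            missing = set(k.parents) - names
            if missing:
                raise ValidationError(f"key {k.name}: unknown parent(s) {missing}")
        self._patterns = {k.name: Chem.MolFromSmarts(k.smarts) for k in self.keys}

    def pattern(self, name: str):
        return self._patterns[name]


def default_hierarchy() -> SubstructureHierarchy:
    return SubstructureHierarchy(
        keys=(
            # atoms
            SubstructureKey("C", "[#6]"),
            SubstructureKey("N", "[#7]"),
            SubstructureKey("O", "[#8]"),
            SubstructureKey("S", "[#16]"),
            SubstructureKey("P", "[#15]"),
            SubstructureKey("c_arom", "[c]", ("C",)),
            # simple bonds
            SubstructureKey("C-C", "[#6]-[#6]", ("C",)),
            SubstructureKey("C=C", "[#6]=[#6]", ("C",)),
            SubstructureKey("C#C", "[#6]#[#6]", ("C",)),
            SubstructureKey("C-N", "[#6]-[#7]", ("C", "N")),
            SubstructureKey("C=N", "[#6]=[#7]", ("C", "N")),
            SubstructureKey("C-O", "[#6]-[#8]", ("C", "O")),
            SubstructureKey("C=O", "[#6]=[#8]", ("C", "O")),
            SubstructureKey("c:c", "c:c", ("c_arom",)),
            SubstructureKey("O-H", "[OX2H]", ("O",)),
            SubstructureKey("N-H", "[#7;!H0]", ("N",)),
            # composed
            SubstructureKey("N=C-N", "[#7]=[#6]-[#7]", ("C=N", "C-N")),
            SubstructureKey("carboxyl", "[CX3](=O)[OX2H1,OX1-]", ("C=O", "C-O")),
            SubstructureKey("benzene", "c1ccccc1", ("c:c",)),
            SubstructureKey("phenol_OH", "c[OX2H]", ("c:c", "O-H")),
            SubstructureKey("conj_diene", "[#6]=[#6]-[#6]=[#6]", ("C=C",)),
        )
    )


def substructure_prescreen(
    structures: list[str],
    hierarchy: SubstructureHierarchy | None = None,
) -> dict[str, set[str]]:
    """Admissible substructure keys per structure, computed top-down: a key
    is tested only if all its parents passed. Unparseable SMILES are skipped
    with a warning."""
    hierarchy = hierarchy or default_hierarchy()
    out: dict[str, set[str]] = {}
    for smi in structures:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            logger.warning("prescreen: unparseable SMILES %r, skipped", smi)
            continue
        passed: set[str] = set()
        for key in hierarchy.keys:  # keys are topologically ordered
            if any(p not in passed for p in key.parents):
                continue
            if mol.HasSubstructMatch(hierarchy.pattern(key.name)):
                passed.add(key.name)
        out[smi] = passed
    return out


_BOND_KEYS = {
    (6, 6, Chem.BondType.SINGLE): "C-C",
    (6, 6, Chem.BondType.DOUBLE): "C=C",
    (6, 6, Chem.BondType.TRIPLE): "C#C",
    (6, 7, Chem.BondType.SINGLE): "C-N",
    (6, 7, Chem.BondType.DOUBLE): "C=N",
    (6, 8, Chem.BondType.SINGLE): "C-O",
    (6, 8, Chem.BondType.DOUBLE): "C=O",
}

_ATOM_KEYS = {6: "C", 7: "N", 8: "O", 16: "S", 15: "P"}


def rule_requirements(rule: ReactionRule, hierarchy: SubstructureHierarchy) -> set[str]:
    """Hierarchy keys provably required by the rule's reactant template.

    Only unambiguous template constraints (definite atomic numbers and bond
    orders) become requirements, so the prescreen can only prune structures
    the template could never match — never introduce false negatives.
    """
    rxn = AllChem.ReactionFromSmarts(rule.smarts)
    template = rxn.GetReactantTemplate(0)
    names = {k.name for k in hierarchy.keys}
    req: set[str] = set()
    for atom in template.GetAtoms():
        key = _ATOM_KEYS.get(atom.GetAtomicNum())
        if key and key in names:
            req.add(key)
        if atom.GetAtomicNum() == 6 and atom.GetIsAromatic() and "c_arom" in names:
            req.add("c_arom")
    for bond in template.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        za, zb = a.GetAtomicNum(), b.GetAtomicNum()
        if za == 0 or zb == 0:
            continue
        if bond.GetIsAromatic() or bond.GetBondType() == Chem.BondType.AROMATIC:
            if za == zb == 6 and "c:c" in names:
                req.add("c:c")
            continue
        if a.GetIsAromatic() or b.GetIsAromatic():
            # default SMARTS bonds next to aromatic atoms are ambiguous
            continue
        key = _BOND_KEYS.get((min(za, zb), max(za, zb), bond.GetBondType()))
        if key and key in names:
            req.add(key)
    return req


def admissible_rules(
    smiles: str,
    rules: list[ReactionRule],
    prescreen: dict[str, set[str]],
    hierarchy: SubstructureHierarchy | None = None,
) -> list[ReactionRule]:
    """Rules whose template requirements are covered by the structure's
    admissible key set."""
    hierarchy = hierarchy or default_hierarchy()
    keys = prescreen.get(smiles)
    if keys is None:
        return []
    out = []
    for rule in rules:
        if rule_requirements(rule, hierarchy) <= keys:
            out.append(rule)
    return out


# ---------------------------------------------------------------------------
# In-silico products
# ---------------------------------------------------------------------------


def apply_rule(smiles: str, rule: ReactionRule) -> list[str]:
    """All distinct products of applying the rule template to a structure,
    canonicalized and deduplicated. Products whose monoisotopic mass does
    not equal substrate mass + transition (within 0.005 Da) are discarded.
    A non-matching template yields an empty list, not an error."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable substrate SMILES {smiles!r}")
    rxn = AllChem.ReactionFromSmarts(rule.smarts)
    if rxn.GetNumReactantTemplates() != 1:
        raise ValidationError(f"rule {rule.rule_id} is not single-substrate")
    expected = ExactMolWt(mol) + rule.mass_transition
    products: set[str] = set()
    for prods in rxn.RunReactants((mol,)):
        for prod in prods:
            try:
                Chem.SanitizeMol(prod)
            except Exception:
                continue
            if abs(ExactMolWt(prod) - expected) > PRODUCT_MASS_TOL:
                logger.warning(
                    "rule %s on %s: product mass off transition, discarded",
                    rule.rule_id, smiles,
                )
                continue
            products.add(Chem.MolToSmiles(prod))
    return sorted(products)


# ---------------------------------------------------------------------------
# Network assembly, DAG extraction, longest paths
# ---------------------------------------------------------------------------


def build_network(
    reaction_edges: pd.DataFrame,
    nodes: list[MassSignatureNode],
) -> nx.MultiDiGraph:
    """Multigraph over mass-signature nodes; parallel edges carry distinct
    rules. Only nodes referenced by at least one edge (plus isolated
    measured nodes passed in) are attached with their attributes."""
    g = nx.MultiDiGraph()
    by_id = {n.node_id: n for n in nodes}
    for n in nodes:
        g.add_node(
            n.node_id,
            kind=n.kind,
            mass=n.mass,
            source_feature=n.source_feature,
            structures=n.structures,
        )
    for row in reaction_edges.itertuples(index=False):
        for nid in (row.substrate_node, row.product_node):
            if nid not in g:
                g.add_node(nid, kind=GHOST, mass=float(nid.rsplit("@", 1)[1]),
                           source_feature=None, structures=())
        g.add_edge(
            row.substrate_node,
            row.product_node,
            key=row.rule_id,
            rule_id=row.rule_id,
            direction=row.direction,
            transition=row.transition,
            support_transcripts=getattr(row, "support_transcripts", ""),
            edge_support=float(getattr(row, "edge_support", 1.0)),
        )
    return g


def default_roots(network: nx.MultiDiGraph) -> list[str]:
    """Default initial metabolites when the user names none: in each
    connected component with at least one reaction edge, the measured node
    whose rooted DAG admits the longest outgoing pathway (ties broken by
    total edge support, then node id)."""
    roots = []
    for comp in nx.weakly_connected_components(network):
        cand = [
            n for n in comp
            if network.nodes[n].get("kind") == MEASURED and network.degree(n) > 0
        ]
        best = None
        for n in sorted(cand):
            pw = longest_path(to_dag(network, n))
            # support rounded so float addition order cannot flip ties;
            # exact ties then resolve to the smallest node id
            key = (len(pw), round(pw.total_support, 9))
            if best is None or key > best[0]:
                best = (key, n)
        if best is not None:
            roots.append(best[1])
    return sorted(roots)


def to_dag(network: nx.MultiDiGraph, root: str) -> PathwayDAG:
    """Reduce the reaction network to a DAG rooted at ``root``.

    Reaction distance is the unweighted BFS distance from the root in the
    underlying undirected graph. Edges are kept only if they advance that
    distance by one; edges between equidistant nodes are kept provisionally
    and residual cycles among them are broken by deleting the edge with the
    minimum edge support (ties: lexicographically smallest
    (substrate, product, rule)). The result is acyclic and restricted to
    nodes reachable from the root.
    """
    if root not in network:
        raise ValidationError(f"root {root!r} not in network")
    dist = nx.single_source_shortest_path_length(network.to_undirected(as_view=True), root)
    h = nx.MultiDiGraph()
    h.add_nodes_from((n, network.nodes[n]) for n in network if n in dist)
    for u, v, k, data in network.edges(keys=True, data=True):
        if u not in dist or v not in dist:
            continue
        if dist[v] == dist[u] + 1 or dist[v] == dist[u]:
            h.add_edge(u, v, key=k, **data)
    while True:
        try:
            cycle = nx.find_cycle(h)
        except nx.NetworkXNoCycle:
            break
        # among the cycle's edges, delete the weakest; break support ties
        # by the lexicographically smallest (substrate, product, rule)
        weakest = min(h.edges[e].get("edge_support", 0.0) for e in cycle)
        victims = [e for e in cycle if h.edges[e].get("edge_support", 0.0) == weakest]
        victim = min(victims, key=lambda e: (e[0], e[1], e[2]))
        h.remove_edge(*victim)
    keep = {root} | nx.descendants(h, root)
    h.remove_nodes_from([n for n in list(h) if n not in keep])
    return PathwayDAG(root=root, graph=h)


@dataclass
class Pathway:
    """An ordered pathway prediction: nodes and the edges joining them."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, str], ...]  # (substrate, product, rule_id)
    total_support: float

    def __len__(self) -> int:
        return len(self.edges)


def longest_path(dag: PathwayDAG) -> Pathway:
    """Maximum-edge-count path from the root, by dynamic programming over a
    topological order. Ties broken by larger summed edge support, then by
    lexicographically smallest node sequence."""
    g = dag.graph
    best: dict[str, tuple[int, float, tuple, tuple]] = {
        dag.root: (0, 0.0, (dag.root,), ())
    }
    for u in nx.topological_sort(g):
        if u not in best:
            continue
        cnt, sup, path, edges = best[u]
        for _, v, k, data in sorted(g.out_edges(u, keys=True, data=True)):
            w = float(data.get("edge_support", 0.0))
            cand = (cnt + 1, sup + w, path + (v,), edges + ((u, v, k),))
            cur = best.get(v)
            if cur is None or _path_better(cand, cur):
                best[v] = cand
    winner = max(best.values(), key=lambda t: (t[0], t[1], _neg_lex(t[2])))
    return Pathway(nodes=winner[2], edges=winner[3], total_support=winner[1])


def _neg_lex(path: tuple) -> tuple:
    # max() helper: prefer lexicographically smaller paths on full ties
    return tuple(-ord(c) for c in "\x00".join(path))


def _path_better(cand, cur) -> bool:
    if cand[0] != cur[0]:
        return cand[0] > cur[0]
    if cand[1] != cur[1]:
        return cand[1] > cur[1]
    return cand[2] < cur[2]


def predict_pathways(network: nx.MultiDiGraph, root: str) -> tuple[Pathway, Pathway]:
    """The two pathway predictions for an initial metabolite: the longest
    path of the root-anchored DAG, and the (re-reversed) longest path of the
    reversed network rooted at the forward path's terminal metabolite."""
    forward = longest_path(to_dag(network, root))
    terminal = forward.nodes[-1]
    rdag = to_dag(network.reverse(copy=True), terminal)
    back = longest_path(rdag)
    reverse = Pathway(
        nodes=tuple(reversed(back.nodes)),
        edges=tuple((v, u, k) for u, v, k in reversed(back.edges)),
        total_support=back.total_support,
    )
    return forward, reverse


# ---------------------------------------------------------------------------
# Iterative extension
# ---------------------------------------------------------------------------


def iterate_prediction(
    network: nx.MultiDiGraph,
    nodes: list[MassSignatureNode],
    rules: list[ReactionRule],
    rounds: int = 1,
    tol_da: float = 0.002,
    support_fn=None,
    hierarchy: SubstructureHierarchy | None = None,
) -> nx.MultiDiGraph:
    """Extend the network by applying rules to frontier structures.

    Each round applies every admissible rule (after the substructure
    prescreen) to the structures on current nodes, maps each in-silico
    product back onto a measured node of matching neutral mass, and adds the
    corresponding edge (with the product SMILES recorded on the target
    node). ``support_fn(substrate_feature, product_feature, rule)`` may veto
    edges or supply (transcripts, edge_support); by default edges are
    accepted with support 1.0. The network grows monotonically; a fixpoint
    or the round limit terminates. ``rounds=1`` equals a single pass.
    """
    if rounds < 1:
        raise ValidationError("rounds must be >= 1")
    hierarchy = hierarchy or default_hierarchy()
    g = network.copy()
    by_mass: dict[float, list[MassSignatureNode]] = {}
    for n in nodes:
        by_mass.setdefault(_mass_key(n.mass), []).append(n)
        if n.node_id not in g:
            g.add_node(n.node_id, kind=n.kind, mass=n.mass,
                       source_feature=n.source_feature, structures=n.structures)
    mass_keys = sorted(by_mass)

    def nodes_near(mass: float):
        out = []
        for key in mass_keys:
            if abs(key - mass) <= tol_da + 5e-5:
                out.extend(by_mass[key])
        return out

    for _ in range(rounds):
        grew = False
        frontier = [
            (nid, smi)
            for nid in sorted(g.nodes)
            for smi in g.nodes[nid].get("structures", ())
        ]
        pres = substructure_prescreen(sorted({s for _, s in frontier}), hierarchy)
        for nid, smi in frontier:
            for rule in admissible_rules(smi, rules, pres, hierarchy):
                for prod in apply_rule(smi, rule):
                    pmass = ExactMolWt(Chem.MolFromSmiles(prod))
                    for target in nodes_near(pmass):
                        if target.node_id == nid or g.has_edge(nid, target.node_id, rule.rule_id):
                            continue
                        sup = (None, 1.0)
                        if support_fn is not None:
                            sup = support_fn(
                                g.nodes[nid].get("source_feature"),
                                target.source_feature,
                                rule,
                            )
                            if sup is None:
                                continue
                        g.add_edge(
                            nid,
                            target.node_id,
                            key=rule.rule_id,
                            rule_id=rule.rule_id,
                            direction="forward",
                            transition=rule.mass_transition,
                            support_transcripts=";".join(sup[0] or ()),
                            edge_support=float(sup[1]),
                        )
                        structs = set(g.nodes[target.node_id].get("structures", ()))
                        if prod not in structs:
                            structs.add(prod)
                            g.nodes[target.node_id]["structures"] = tuple(sorted(structs))
                        grew = True
        if not grew:
            break
    return g


def network_to_frames(g: nx.MultiDiGraph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables (Cytoscape-importable CSV shapes)."""
    node_rows = [
        {
            "node_id": n,
            "kind": d.get("kind"),
            "mass": d.get("mass"),
            "source_feature": d.get("source_feature"),
            "structures": ";".join(d.get("structures", ())),
        }
        for n, d in sorted(g.nodes(data=True))
    ]
    edge_rows = [
        {
            "substrate_node": u,
            "product_node": v,
            "rule_id": d.get("rule_id", k),
            "direction": d.get("direction"),
            "transition": d.get("transition"),
            "support_transcripts": d.get("support_transcripts", ""),
            "edge_support": d.get("edge_support", float("nan")),
        }
        for u, v, k, d in sorted(g.edges(keys=True, data=True))
    ]
    return (
        pd.DataFrame(node_rows, columns=["node_id", "kind", "mass", "source_feature", "structures"]),
        pd.DataFrame(edge_rows, columns=EDGE_COLUMNS),
    )
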