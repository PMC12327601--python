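"""Reaction-likelihood scoring from atom-level site-of-metabolism scores.

Each substrate atom can carry a score in [0, 1] for being a site of
metabolism (supplied externally per structure, e.g., exported from a
site-of-metabolism predictor, or from a built-in heuristic baseline used
for pipeline testing). The reaction center is the set of substrate atoms
whose bonding changes between substrate and product (bond formed, broken,
or order changed). The reaction likelihood of a substrate -> product
transformation is the maximum atom score within the reaction center.

Score populations (e.g., experimentally characterized vs randomly paired
enzyme-substrate transformations) are compared with a two-sided
Mann-Whitney U test: exact when the sample product n1*n2 is small and the
data are tie-free, normal approximation with tie correction otherwise.

Atom indices refer to heavy atoms in RDKit's canonical input order;
hydrogens are not indexed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, rdFMCS
from scipy import stats

from .core_data import ReactionRule, ValidationError

logger = logging.getLogger(__name__)

EXACT_LIMIT = 400  # exact Mann-Whitney enumeration up to n1 * n2 = 400


@dataclass(frozen=True)
class AtomScoreVector:
    """Per-atom site-of-metabolism scores for one structure."""

    structure_id: str
    scores: dict  # atom_index -> score in [0, 1]

    def __post_init__(self):
        for idx, s in self.scores.items():
            if not 0.0 <= s <= 1.0:
                raise ValidationError(
                    f"{self.structure_id}: atom {idx} score {s} outside [0, 1]"
                )


def read_atom_scores(path, sep: str = ",") -> dict[str, AtomScoreVector]:
    """CSV with columns structure_id, atom_index, score -> score vectors."""
    df = pd.read_csv(path, sep=sep)
    out = {}
    for sid, grp in df.groupby("structure_id", sort=True):
        out[str(sid)] = AtomScoreVector(
            structure_id=str(sid),
            scores={int(r.atom_index): float(r.score) for r in grp.itertuples(index=False)},
        )
    return out


def heuristic_atom_scores(smiles: str, mode: str = "uniform") -> AtomScoreVector:
    """Baseline provider for pipeline testing: ``uniform`` gives every heavy
    atom 0.5; ``degree`` scales heavy-atom degree into (0, 1]."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable SMILES {smiles!r}")
    n = mol.GetNumAtoms()
    if mode == "uniform":
        scores = {i: 0.5 for i in range(n)}
    elif mode == "degree":
        degs = [mol.GetAtomWithIdx(i).GetDegree() for i in range(n)]
        top = max(degs) or 1
        scores = {i: d / top for i, d in enumerate(degs)}
    else:
        raise ValidationError(f"unknown heuristic mode {mode!r}")
    return AtomScoreVector(structure_id=smiles, scores=scores)


# ---------------------------------------------------------------------------
# Reaction centers
# ---------------------------------------------------------------------------


def _template_bond_sig(template, mapno_to_idx):
    """Map number -> {(other mapno, bond type)} within a reaction template."""
    sig: dict[int, set] = {m: set() for m in mapno_to_idx}
    for bond in template.GetBonds():
        ma = bond.GetBeginAtom().GetAtomMapNum()
        mb = bond.GetEndAtom().GetAtomMapNum()
        if ma and mb:
            sig[ma].add((mb, bond.GetBondType()))
            sig[mb].add((ma, bond.GetBondType()))
    return sig


def _changed_mapnos(rxn) -> set[int]:
    """Mapped template atoms whose bonding differs between the reactant and
    product sides: bond set to other mapped atoms changed, atom deleted, or
    an unmapped (added/removed) atom attached."""
    reactant = rxn.GetReactantTemplate(0)
    r_maps = {a.GetAtomMapNum(): a.GetIdx() for a in reactant.GetAtoms() if a.GetAtomMapNum()}
    p_maps: dict[int, int] = {}
    changed: set[int] = set()
    for t in range(rxn.GetNumProductTemplates()):
        product = rxn.GetProductTemplate(t)
        for a in product.GetAtoms():
            if a.GetAtomMapNum():
                p_maps[a.GetAtomMapNum()] = a.GetIdx()
        # unmapped product atoms are created by the rule: their mapped
        # neighbours gain a bond
        for a in product.GetAtoms():
            if not a.GetAtomMapNum():
                for nb in a.GetNeighbors():
                    if nb.GetAtomMapNum():
                        changed.add(nb.GetAtomMapNum())
    # unmapped reactant atoms are destroyed: their mapped neighbours lose one
    for a in reactant.GetAtoms():
        if not a.GetAtomMapNum():
            for nb in a.GetNeighbors():
                if nb.GetAtomMapNum():
                    changed.add(nb.GetAtomMapNum())
    r_sig = _template_bond_sig(reactant, r_maps)
    p_sigs: dict[int, set] = {m: set() for m in p_maps}
    for t in range(rxn.GetNumProductTemplates()):
        product = rxn.GetProductTemplate(t)
        local = {a.GetAtomMapNum(): a.GetIdx() for a in product.GetAtoms() if a.GetAtomMapNum()}
        for m, s in _template_bond_sig(product, local).items():
            p_sigs.setdefault(m, set()).update(s)
    for m in r_maps:
        if m not in p_maps:
            changed.add(m)  # deleted by the rule
        elif r_sig.get(m, set()) != p_sigs.get(m, set()):
            changed.add(m)
    return changed


def reaction_center(substrate: str, product: str, rule: ReactionRule) -> frozenset[int]:
    """Substrate atom indices whose bonding changes in substrate -> product.

    Primary route: the rule's own atom-mapped template — run the reaction,
    pick the product instance matching ``product``, and trace the changed
    mapped atoms back to substrate indices (plus atoms deleted by the rule
    and their attachment atoms). Fallback when mapping cannot place the
    product: atoms outside the substrate/product maximum common substructure
    plus their attachment atoms.
    """
    sub = Chem.MolFromSmiles(substrate)
    prod = Chem.MolFromSmiles(product)
    if sub is None or prod is None:
        raise ValidationError("unparseable substrate or product SMILES")
    if Chem.MolToSmiles(sub) == Chem.MolToSmiles(prod):
        raise ValidationError("empty center: substrate and product are identical")
    target = Chem.MolToSmiles(prod)
    rxn = AllChem.ReactionFromSmarts(rule.smarts)
    changed = _changed_mapnos(rxn)
    center: set[int] = set()
    if changed:
        for prods in rxn.RunReactants((sub,)):
            for p in prods:
                try:
                    Chem.SanitizeMol(p)
                except Exception:
                    continue
                if Chem.MolToSmiles(p) != target:
                    continue
                present: set[int] = set()
                for a in p.GetAtoms():
                    if a.HasProp("react_atom_idx"):
                        ridx = a.GetIntProp("react_atom_idx")
                        present.add(ridx)
                        if (
                            a.HasProp("old_mapno")
                            and a.GetIntProp("old_mapno") in changed
                        ):
                            center.add(ridx)
                # substrate atoms deleted by the rule, and their neighbours
                deleted = set(range(sub.GetNumAtoms())) - present
                for idx in deleted:
                    center.add(idx)
                    for nb in sub.GetAtomWithIdx(idx).GetNeighbors():
                        center.add(nb.GetIdx())
                if center:
                    return frozenset(center)
    return _mcs_center(sub, prod)


def _mcs_center(sub, prod) -> frozenset[int]:
    """Fallback: substrate atoms outside the maximum common substructure,
    plus their attachment atoms inside it."""
    mcs = rdFMCS.FindMCS(
        [sub, prod], bondCompare=rdFMCS.BondCompare.CompareOrderExact, timeout=5
    )
    core = Chem.MolFromSmarts(mcs.smartsString) if mcs.smartsString else None
    sub_match = sub.GetSubstructMatch(core) if core is not None else ()
    prod_match = prod.GetSubstructMatch(core) if core is not None else ()
    outside = set(range(sub.GetNumAtoms())) - set(sub_match)
    center = set(outside)
    for idx in outside:  # atoms removed: their attachment atoms change too
        for nb in sub.GetAtomWithIdx(idx).GetNeighbors():
            center.add(nb.GetIdx())
    # atoms added in the product: the substrate image of their attachment
    # atoms (via the core correspondence) gains a bond
    prod_added = set(range(prod.GetNumAtoms())) - set(prod_match)
    prod_to_sub = dict(zip(prod_match, sub_match))
    for idx in prod_added:
        for nb in prod.GetAtomWithIdx(idx).GetNeighbors():
            if nb.GetIdx() in prod_to_sub:
                center.add(prod_to_sub[nb.GetIdx()])
    if not center:
        raise ValidationError("empty center: no bonding difference found")
    return frozenset(center)


def reaction_likelihood(scores: AtomScoreVector, center: frozenset[int]) -> float:
    """Max site-of-metabolism score over the reaction-center atoms."""
    if not center:
        raise ValidationError("empty reaction center")
    missing = [i for i in sorted(center) if i not in scores.scores]
    if missing:
        raise ValidationError(
            f"{scores.structure_id}: no atom score for center atom(s) {missing}"
        )
    return max(scores.scores[i] for i in center)


# ---------------------------------------------------------------------------
# Score-population comparison
# ---------------------------------------------------------------------------


def compare_score_sets(known, random, exact_limit: int = EXACT_LIMIT) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing two score populations.

    Returns (U, p) with U the statistic of the first sample. The exact null
    distribution is enumerated when n1 * n2 <= ``exact_limit`` and the
    pooled data are tie-free; otherwise the normal approximation with tie
    correction (and continuity correction) is used.
    """
    known = np.asarray(known, dtype=float)
    random = np.asarray(random, dtype=float)
    if known.size == 0 or random.size == 0:
        raise ValidationError("both score sets must be nonempty")
    pooled = np.concatenate([known, random])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (known.size * random.size <= exact_limit and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(known, random, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
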