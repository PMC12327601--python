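"""Deterministic synthetic paired-omics data with a planted pathway.

The generator emulates the statistical structure of a treatment-response
paired metabolomics/transcriptomics experiment: a latent induction profile
(off in control samples, on in treated ones) drives both the transcripts of
a planted biosynthetic chain and the abundances of its metabolite features,
plus Gaussian noise; decoy transcripts and features vary independently.

The planted chain is built chemically: a parent scaffold is transformed
step by step (aromatic hydroxylations / desaturations) by real single-
substrate reaction SMARTS, so the feature m/z ladder obeys the rules' mass
transitions exactly and the full pipeline can re-derive the chain.

All randomness flows from one integer seed; regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.Descriptors import ExactMolWt

from .annotate import DEFAULT_ADDUCTS, PROTON, adducts_to_frame
from .core_data import (
    AdductSpec,
    EnzymeAssociation,
    ExpressionMatrix,
    FeatureTable,
    MetaboliteRecord,
    ReactionRule,
    TranscriptAnnotation,
    rules_to_frame,
)

#: reaction templates the generator draws from; each carries a distinct
#: mass transition so planted steps stay chemically distinguishable
MOVE_TYPES = {
    "hydroxylation": ("[cH:1]>>[c:1]O", 15.994915),
    "desaturation": ("[CH2:1][CH2:2]>>[CH:1]=[CH:2]", -2.015650),
    "methylation": ("[OX2H:1]>>[O:1]C", 14.015650),
    "acetylation": ("[OX2H:1]>>[O:1]C(C)=O", 42.010565),
}

PARENT_SCAFFOLD = "CCCCCCCCc1ccccc1"  # octylbenzene: room for every move type

ION_ADDUCT = AdductSpec("[M+H]+", "positive", 1, 1, PROTON)


@dataclass(frozen=True)
class PlantedPathway:
    """Ground truth: the ordered chain and who is responsible for each step."""

    structures: tuple[str, ...]
    rule_ids: tuple[str, ...]
    transcript_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]


@dataclass
class ToyDataset:
    expression: ExpressionMatrix
    features: FeatureTable
    rules: list[ReactionRule]
    metabolite_db: list[MetaboliteRecord]
    adducts: tuple[AdductSpec, ...]
    annotations: list[TranscriptAnnotation]
    truth: PlantedPathway
    seed: int

    def write(self, outdir) -> None:
        """Write the full CSV bundle (feature table, expression matrix,
        rules, metabolite DB, adducts, transcript annotations)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(outdir / "features.csv")
        self.expression.to_csv(outdir / "expression.csv")
        rules_to_frame(self.rules).to_csv(outdir / "rules.csv", index=False)
        pd.DataFrame(
            [
                {
                    "structure_id": m.structure_id,
                    "smiles": m.smiles,
                    "monoisotopic_mass": m.monoisotopic_mass,
                    "name": m.name,
                    "taxonomy": m.taxonomy,
                    "superclass": m.superclass,
                }
                for m in self.metabolite_db
            ]
        ).to_csv(outdir / "metabolites.csv", index=False)
        adducts_to_frame(self.adducts).to_csv(outdir / "adducts.csv", index=False)
        pd.DataFrame(
            [
                {
                    "transcript_id": a.transcript_id,
                    "pfam_ids": ";".join(a.pfam_ids),
                    "category": a.category,
                }
                for a in self.annotations
            ]
        ).to_csv(outdir / "transcript_annotations.csv", index=False)
        pd.DataFrame(
            {
                "step": range(len(self.truth.structures)),
                "structure": self.truth.structures,
                "rule_id": ("",) + self.truth.rule_ids,
                "transcript_id": ("",) + self.truth.transcript_ids,
                "feature_id": self.truth.feature_ids,
            }
        ).to_csv(outdir / "truth.csv", index=False)


def _first_product(smiles: str, smarts: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    rxn = AllChem.ReactionFromSmarts(smarts)
    products = set()
    for prods in rxn.RunReactants((mol,)):
        for p in prods:
            try:
                Chem.SanitizeMol(p)
            except Exception:
                continue
            products.add(Chem.MolToSmiles(p))
    return min(products) if products else None


def generate_pathway_chain(
    n_steps: int,
    seed: int,
    parent: str = PARENT_SCAFFOLD,
    moves: tuple[str, ...] | None = None,
) -> tuple[list[str], list[ReactionRule]]:
    """A parent scaffold transformed ``n_steps`` times into a chain of
    n_steps + 1 structures, with matching single-substrate rules.

    By default step types are drawn without replacement from ``MOVE_TYPES``
    in a seeded random order, so every planted step has a distinct mass
    transition and each edge of the chain is explained by exactly one rule.
    An explicit ``moves`` sequence (type names, repeats allowed, e.g. three
    hydroxylations) overrides the draw. Each step gets its own rule id and
    Pfam so enzyme support is step-specific; masses along the chain are
    guaranteed pairwise distinct.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if moves is None and n_steps > len(MOVE_TYPES):
        raise ValueError(
            f"at most {len(MOVE_TYPES)} distinct step types; pass `moves` for longer chains"
        )
    rng = np.random.default_rng(seed)
    chain = [Chem.MolToSmiles(Chem.MolFromSmiles(parent))]
    rules: list[ReactionRule] = []
    masses = {round(ExactMolWt(Chem.MolFromSmiles(parent)), 4)}
    remaining = list(MOVE_TYPES)
    for k in range(n_steps):
        if moves is not None:
            pool = [moves[k]]
        else:
            pool = [remaining[i] for i in rng.permutation(len(remaining))]
        nxt = None
        for name in pool:
            smarts = MOVE_TYPES[name][0]
            cand = _first_product(chain[-1], smarts)
            if cand is None:
                continue
            cand_mass = round(ExactMolWt(Chem.MolFromSmiles(cand)), 4)
            if cand_mass in masses:
                continue
            nxt = (name, smarts, cand, cand_mass)
            break
        if nxt is None:
            raise RuntimeError(f"cannot extend chain beyond step {k}")
        name, smarts, cand, cand_mass = nxt
        if moves is None:
            remaining.remove(name)
        sub_mass = ExactMolWt(Chem.MolFromSmiles(chain[-1]))
        prod_mass = ExactMolWt(Chem.MolFromSmiles(cand))
        rules.append(
            ReactionRule(
                rule_id=f"rr_step{k:02d}_{name}",
                smarts=smarts,
                substrate_mass=sub_mass,
                product_mass=prod_mass,
                mass_transition=prod_mass - sub_mass,
                diameter=2,
                direction="both",
                reaction_ids=(f"RXN{k:04d}",),
                enzyme_associations=(
                    EnzymeAssociation(
                        pfam_id=f"PF9{k:04d}", ec_number=f"1.14.{k}.1",
                        tier="strict", taxon="Plantae",
                    ),
                ),
            )
        )
        chain.append(cand)
        masses.add(cand_mass)
    return chain, rules


def decoy_rules() -> list[ReactionRule]:
    """Rules unrelated to the planted chain, at the looser tiers; they widen
    the loose rule space without explaining the planted transitions."""
    methylation = ReactionRule(
        rule_id="rr_decoy_methylation",
        smarts="[OX2H:1]>>[O:1]C",
        substrate_mass=100.0,
        product_mass=114.015650,
        mass_transition=14.015650,
        diameter=2,
        direction="both",
        enzyme_associations=(
            EnzymeAssociation("PF00891", "2.1.1.1", "medium", "Plantae"),
        ),
    )
    acetylation = ReactionRule(
        rule_id="rr_decoy_acetylation",
        smarts="[OX2H:1]>>[O:1]C(C)=O",
        substrate_mass=100.0,
        product_mass=142.010565,
        mass_transition=42.010565,
        diameter=2,
        direction="both",
        enzyme_associations=(
            EnzymeAssociation("PF02458", "2.3.1.1", "loose", "Plantae"),
        ),
    )
    return [methylation, acetylation]


def _latent_profile(n_samples: int) -> np.ndarray:
    """Step-response induction: off in the first half, on in the second."""
    half = n_samples // 2
    return np.concatenate([np.zeros(half), np.ones(n_samples - half)])


def generate_paired_omics(
    chain: tuple[list[str], list[ReactionRule]],
    n_samples: int = 24,
    n_decoy_transcripts: int = 24,
    n_decoy_features: int = 14,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> ToyDataset:
    """Paired expression/feature tables around a planted chain.

    The latent induction profile drives the planted transcripts (one per
    step, annotated with that step's Pfam) and the planted features (one per
    chain structure, ionized as [M+H]+), with additive Gaussian noise of
    ``noise_sd`` (in units of the induction amplitude). Decoy rows vary
    independently; decoy feature masses are rejected near any rule
    transition (alone or summed in pairs) of any other feature so they
    cannot fake a reaction edge.
    """
    if n_samples < 6:
        raise ValueError("n_samples must be >= 6")
    structures, rules = chain
    rng = np.random.default_rng(seed)
    samples = [f"s{i:02d}" for i in range(n_samples)]
    latent = _latent_profile(n_samples)

    # --- transcripts
    t_ids, t_rows = [], []
    path_transcripts = []
    for k in range(len(rules)):
        tid = f"t_path{k:02d}"
        path_transcripts.append(tid)
        base = rng.uniform(5.0, 10.0)
        amp = rng.uniform(2.0, 4.0)
        t_ids.append(tid)
        t_rows.append(base + amp * latent + rng.normal(0.0, noise_sd * amp, n_samples))
    for k in range(n_decoy_transcripts):
        base = rng.uniform(5.0, 10.0)
        t_ids.append(f"t_decoy{k:02d}")
        t_rows.append(base + rng.normal(0.0, 1.0, n_samples))
    expression = ExpressionMatrix(
        pd.DataFrame(np.clip(np.array(t_rows), 0.0, None), index=t_ids, columns=samples)
    )

    # --- features
    masses = [ExactMolWt(Chem.MolFromSmiles(s)) for s in structures]
    transitions = sorted({r.mass_transition for r in rules})
    forbidden = set(np.round(transitions, 3)) | {
        round(a + b, 3) for a in transitions for b in transitions
    }

    def clashes(m: float, existing: list[float]) -> bool:
        for e in existing:
            d = round(abs(m - e), 3)
            if any(abs(d - abs(f)) < 0.05 for f in forbidden):
                return True
            if d < 0.05:
                return True
        return False

    f_ids, f_mz, f_rows = [], [], []
    path_features = []
    for k, m in enumerate(masses):
        fid = f"f_path{k:02d}"
        path_features.append(fid)
        base = rng.uniform(80.0, 150.0)
        amp = rng.uniform(50.0, 120.0)
        f_ids.append(fid)
        f_mz.append(m + PROTON)
        f_rows.append(base + amp * latent + rng.normal(0.0, noise_sd * amp, n_samples))
    decoy_masses: list[float] = []
    while len(decoy_masses) < n_decoy_features:
        m = rng.uniform(150.0, 600.0)
        if not clashes(m, masses + decoy_masses):
            decoy_masses.append(m)
    for k, m in enumerate(decoy_masses):
        base = rng.uniform(80.0, 150.0)
        f_ids.append(f"f_decoy{k:02d}")
        f_mz.append(m + PROTON)
        f_rows.append(base + rng.normal(0.0, 20.0, n_samples))
    features = FeatureTable(
        mz=pd.Series(f_mz, index=f_ids),
        abundance=pd.DataFrame(
            np.clip(np.array(f_rows), 0.0, None), index=f_ids, columns=samples
        ),
        rt=pd.Series(np.round(rng.uniform(60.0, 900.0, len(f_ids)), 1), index=f_ids),
    )

    # --- metabolite DB: planted structures + far-away decoy records
    db = [
        MetaboliteRecord(
            structure_id=f"db_{k:03d}",
            smiles=s,
            monoisotopic_mass=masses[k],
            name=f"chain metabolite {k}",
            taxonomy="Plantae",
            superclass="synthetic",
        )
        for k, s in enumerate(structures)
    ]
    decoy_smiles = ["c1ccncc1", "OCC1OC(O)C(O)C(O)C1O", "CC(=O)Oc1ccccc1C(=O)O"]
    for k, smi in enumerate(decoy_smiles):
        m = ExactMolWt(Chem.MolFromSmiles(smi))
        if not clashes(m, masses + decoy_masses):
            db.append(
                MetaboliteRecord(
                    structure_id=f"db_decoy_{k:03d}",
                    smiles=smi,
                    monoisotopic_mass=m,
                    name=f"decoy metabolite {k}",
                    taxonomy="Plantae",
                    superclass="synthetic",
                )
            )

    # --- annotations: planted transcripts carry their rule's Pfam
    annotations = [
        TranscriptAnnotation(
            transcript_id=path_transcripts[k],
            pfam_ids=tuple(sorted(rules[k].pfam_ids)),
            category="tailoring",
        )
        for k in range(len(rules))
    ]
    annotations += [
        TranscriptAnnotation(
            transcript_id=f"t_decoy{k:02d}",
            pfam_ids=(f"PF0{k:04d}",),
            category="other",
        )
        for k in range(n_decoy_transcripts)
    ]

    truth = PlantedPathway(
        structures=tuple(structures),
        rule_ids=tuple(r.rule_id for r in rules),
        transcript_ids=tuple(path_transcripts),
        feature_ids=tuple(path_features),
    )
    return ToyDataset(
        expression=expression,
        features=features,
        rules=list(rules) + decoy_rules(),
        metabolite_db=db,
        adducts=(ION_ADDUCT,),
        annotations=annotations,
        truth=truth,
        seed=seed,
    )


def generate_toy_dataset(
    seed: int = 0,
    n_steps: int = 3,
    n_samples: int = 24,
    noise_sd: float = 0.2,
    **kwargs,
) -> ToyDataset:
    """Convenience wrapper: chain + paired omics in one call."""
    chain = generate_pathway_chain(n_steps, seed)
    return generate_paired_omics(
        chain, n_samples=n_samples, noise_sd=noise_sd, seed=seed, **kwargs
    )


def generate_score_sets(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Two likelihood-score populations: ``known`` from a high-median Beta,
    ``random`` from a low-median one; exercises the score comparison."""
    if n < 5:
        raise ValueError("n must be >= 5")
    rng = np.random.default_rng(seed)
    known = rng.beta(8.0, 2.0, n)
    random = rng.beta(2.0, 4.0, n)
    return known, random
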