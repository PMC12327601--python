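"""Domain types, readers/writers, and the single-file relational project store.

The two primary inputs are a mass-feature table (LC-MS features with m/z,
optional retention time, and per-sample abundances) and a transcript
expression matrix (normalized counts). Both are thin wrappers around pandas
DataFrames with validated invariants: unique ids, positive m/z, identical
ordered sample sets after alignment.

Reaction rules are single-substrate transformation templates (reaction
SMARTS) carrying a signed monoisotopic mass transition and tiered enzyme
(Pfam/EC) associations. Rules involving stereochemistry or more than one
substrate are filtered on load.
"""

from __future__ import annotations

import logging
import os
import sqlite3
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: tiers ordered by increasing coverage / decreasing annotation confidence
TIER_ORDER = ("strict", "medium", "loose")

SCHEMA_VERSION = 1


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class FeatureTable:
    """Mass features with m/z, optional retention time, per-sample abundance.

    Parameters
    ----------
    mz : pandas.Series
        Mass-to-charge values (Da/e), indexed by feature id. Must be > 0.
    abundance : pandas.DataFrame
        Features x samples, nonnegative reals; index must equal ``mz.index``.
    rt : pandas.Series, optional
        Retention times in seconds, same index.
    nonnegative : bool
        Enforce nonnegative abundances (raw inputs). Rescaled tables are
        constructed with ``nonnegative=False`` since centering produces
        negative values by design.
    """

    def __init__(
        self,
        mz: pd.Series,
        abundance: pd.DataFrame,
        rt: pd.Series | None = None,
        nonnegative: bool = True,
    ):
        mz = pd.Series(mz, dtype=float)
        if mz.index.has_duplicates:
            dupes = mz.index[mz.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature_id(s): {dupes}")
        if (mz <= 0).any():
            bad = mz.index[mz <= 0].tolist()
            raise ValidationError(f"non-positive m/z for feature(s): {bad}")
        if not abundance.index.equals(mz.index):
            abundance = abundance.reindex(mz.index)
            if abundance.isna().any().any():
                raise ValidationError("abundance index does not match feature ids")
        abundance = abundance.astype(float)
        if nonnegative and (abundance.to_numpy() < 0).any():
            rows = abundance.index[(abundance < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative abundance in row(s): {rows}")
        self.mz = mz
        self.abundance = abundance
        self.rt = None if rt is None else pd.Series(rt, dtype=float).reindex(mz.index)
        self._nonnegative = nonnegative

    @property
    def feature_ids(self) -> list[str]:
        return list(self.mz.index)

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)

    def __len__(self) -> int:
        return len(self.mz)

    def restrict_samples(self, samples: list[str]) -> "FeatureTable":
        return FeatureTable(self.mz, self.abundance[samples], self.rt, self._nonnegative)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"mz": self.mz})
        if self.rt is not None:
            out["rt"] = self.rt
        return pd.concat([out, self.abundance], axis=1).rename_axis("feature_id")

    def to_csv(self, path, sep: str = ",") -> None:
        # %.17g guarantees bit-exact float round trips through CSV
        self.to_frame().to_csv(path, sep=sep, float_format="%.17g")

    def __eq__(self, other) -> bool:  # full-precision round-trip identity
        if not isinstance(other, FeatureTable):
            return NotImplemented
        rt_eq = (self.rt is None) == (other.rt is None) and (
            self.rt is None or self.rt.equals(other.rt)
        )
        return self.mz.equals(other.mz) and self.abundance.equals(other.abundance) and rt_eq


class ExpressionMatrix:
    """Transcripts x samples normalized expression values (nonnegative)."""

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate transcript_id(s): {dupes}")
        if len(values) == 0:
            raise ValidationError("no transcripts")
        self.values = values.astype(float)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)

    def restrict_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[samples])

    def to_csv(self, path, sep: str = ",") -> None:
        self.values.rename_axis("transcript_id").to_csv(
            path, sep=sep, float_format="%.17g"
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values)


@dataclass(frozen=True)
class AdductSpec:
    """An ionization form [nM+X]^z shifting neutral mass M to observed m/z."""

    name: str
    mode: str  # "positive" | "negative"
    charge: int
    multimer: int
    mass_shift: float  # Da, signed

    def __post_init__(self):
        if self.mode not in ("positive", "negative"):
            raise ValidationError(f"adduct {self.name}: unknown mode {self.mode!r}")
        if self.charge == 0:
            raise ValidationError(f"adduct {self.name}: charge must be nonzero")
        if (self.charge > 0) != (self.mode == "positive"):
            raise ValidationError(f"adduct {self.name}: charge sign does not match mode")
        if self.multimer < 1:
            raise ValidationError(f"adduct {self.name}: multimer must be >= 1")


@dataclass(frozen=True)
class MetaboliteRecord:
    """A known structure with monoisotopic mass, from a natural-product DB."""

    structure_id: str
    smiles: str
    monoisotopic_mass: float
    name: str | None = None
    taxonomy: str | None = None
    superclass: str | None = None

    def __post_init__(self):
        if self.monoisotopic_mass <= 0:
            raise ValidationError(f"{self.structure_id}: monoisotopic_mass must be > 0")


@dataclass(frozen=True)
class EnzymeAssociation:
    pfam_id: str
    ec_number: str
    tier: str  # strict | medium | loose
    taxon: str | None = None


@dataclass
class ReactionRule:
    """Single-substrate reaction template with its mass transition.

    ``mass_transition`` is the signed monoisotopic mass difference
    product - substrate; it is recomputed on load and must agree with the
    stored substrate/product masses to 1e-6 Da.
    """

    rule_id: str
    smarts: str
    substrate_mass: float
    product_mass: float
    mass_transition: float
    diameter: int = 2
    direction: str = "both"  # forward | retro | both
    reaction_ids: tuple[str, ...] = ()
    enzyme_associations: tuple[EnzymeAssociation, ...] = ()

    def __post_init__(self):
        if abs(self.mass_transition - (self.product_mass - self.substrate_mass)) > 1e-6:
            raise ValidationError(
                f"rule {self.rule_id}: mass_transition {self.mass_transition} inconsistent "
                f"with product-substrate {self.product_mass - self.substrate_mass}"
            )
        if self.direction not in ("forward", "retro", "both"):
            raise ValidationError(f"rule {self.rule_id}: bad direction {self.direction!r}")

    @property
    def pfam_ids(self) -> set[str]:
        return {a.pfam_id for a in self.enzyme_associations}


@dataclass(frozen=True)
class TranscriptAnnotation:
    transcript_id: str
    pfam_ids: tuple[str, ...] = ()
    category: str = "other"  # scaffold | tailoring | other


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_FEATURE_META_COLS = ("feature_id", "mz", "rt")


def read_feature_table(
    path,
    sep: str = ",",
    id_col: str = "feature_id",
    mz_col: str = "mz",
    rt_col: str = "rt",
    metadata_cols: tuple[str, ...] = (),
) -> FeatureTable:
    """Read a mass-feature CSV; sample columns are every column not declared
    as metadata (id, m/z, retention time, plus ``metadata_cols``)."""
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if id_col not in df.columns or mz_col not in df.columns:
        raise ValidationError(f"feature table must have {id_col!r} and {mz_col!r} columns")
    meta = {id_col, mz_col, rt_col, *metadata_cols}
    sample_cols = [c for c in df.columns if c not in meta]
    if not sample_cols:
        raise ValidationError("feature table has no sample columns")
    df = df.set_index(id_col)
    rt = df[rt_col] if rt_col in df.columns else None
    try:
        abundance = df[sample_cols].astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric abundance value: {exc}") from exc
    return FeatureTable(df[mz_col].astype(float), abundance, rt)


def read_expression_matrix(path, sep: str = ",") -> ExpressionMatrix:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError("no transcripts") from exc
    if len(df) == 0:
        raise ValidationError("no transcripts")
    arr = df.apply(pd.to_numeric, errors="coerce")
    if arr.isna().any().any():
        bad = np.argwhere(arr.isna().to_numpy())[0]
        raise ValidationError(
            f"non-numeric expression value at transcript {df.index[bad[0]]!r}, "
            f"sample {df.columns[bad[1]]!r}"
        )
    return ExpressionMatrix(arr)


def align_samples(
    features: FeatureTable, expr: ExpressionMatrix
) -> tuple[FeatureTable, ExpressionMatrix]:
    """Restrict both tables to the shared sample ids, lexicographically ordered.

    Correlation needs at least three paired observations, so fewer than three
    shared samples is a hard error.
    """
    shared = sorted(set(features.samples) & set(expr.samples))
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} shared sample(s); need >= 3 for correlation"
        )
    return features.restrict_samples(shared), expr.restrict_samples(shared)


def read_adducts(path, sep: str = ",") -> list[AdductSpec]:
    df = pd.read_csv(path, sep=sep)
    return [
        AdductSpec(
            name=row["name"],
            mode=row["mode"],
            charge=int(row["charge"]),
            multimer=int(row.get("multimer", 1)),
            mass_shift=float(row["mass_shift"]),
        )
        for _, row in df.iterrows()
    ]


def read_metabolite_db(path, sep: str = ",", validate_smiles: bool = False) -> list[MetaboliteRecord]:
    """Read a metabolite structure table (CSV or single-file SQLite DB).

    With ``validate_smiles`` records whose SMILES does not parse are skipped
    with a warning (public structure dumps contain unparsable entries).
    """
    if _is_sqlite(path):
        with sqlite3.connect(path) as con:
            df = pd.read_sql("SELECT * FROM metabolites", con)
    else:
        df = pd.read_csv(path, sep=sep)
    records = []
    for _, row in df.iterrows():
        rec = MetaboliteRecord(
            structure_id=str(row["structure_id"]),
            smiles=str(row["smiles"]),
            monoisotopic_mass=float(row["monoisotopic_mass"]),
            name=row.get("name"),
            taxonomy=row.get("taxonomy"),
            superclass=row.get("superclass"),
        )
        if validate_smiles and Chem.MolFromSmiles(rec.smiles) is None:
            logger.warning("skipping %s: unparseable SMILES %r", rec.structure_id, rec.smiles)
            continue
        records.append(rec)
    return records


def read_transcript_annotations(path, sep: str = ",") -> list[TranscriptAnnotation]:
    df = pd.read_csv(path, sep=sep)
    out = []
    for _, row in df.iterrows():
        pfams = row.get("pfam_ids", "")
        pfams = tuple(p for p in str(pfams).split(";") if p and p != "nan")
        cat = row.get("category")
        if not isinstance(cat, str) or cat not in ("scaffold", "tailoring", "other"):
            cat = "other"
        out.append(TranscriptAnnotation(str(row["transcript_id"]), pfams, cat))
    return out


# ---------------------------------------------------------------------------
# Reaction rules
# ---------------------------------------------------------------------------

_STEREO_TOKENS = ("@", "/", "\\")


def _has_stereo(smarts: str) -> bool:
    return any(tok in smarts for tok in _STEREO_TOKENS)


def _parse_single_substrate(smarts: str):
    """Return the parsed reaction iff it has exactly one reactant template."""
    try:
        rxn = AllChem.ReactionFromSmarts(smarts)
    except Exception:
        return None
    if rxn is None or rxn.GetNumReactantTemplates() != 1:
        return None
    return rxn


def _tier_levels(tier: str) -> set[str]:
    if tier not in TIER_ORDER:
        raise ValidationError(f"unknown tier {tier!r}; expected one of {TIER_ORDER}")
    return set(TIER_ORDER[: TIER_ORDER.index(tier) + 1])


def load_rules(
    path,
    tier: str = "loose",
    taxa: list[str] | None = None,
    sep: str = ",",
) -> list[ReactionRule]:
    """Load reaction rules from a CSV (one row per rule-enzyme association)
    or a single-file SQLite database with a ``rules`` table of that shape.

    Filtering applied, in order: association tier (strict subset of medium
    subset of loose), optional taxonomy (association level), stereo rules,
    multi-substrate rules. The mass transition is recomputed from the stored
    substrate/product masses; inconsistent rules are skipped with a warning.
    """
    if _is_sqlite(path):
        with sqlite3.connect(path) as con:
            df = pd.read_sql("SELECT * FROM rules", con)
    else:
        df = pd.read_csv(path, sep=sep)
    levels = _tier_levels(tier)
    rules: list[ReactionRule] = []
    for rule_id, grp in df.groupby("rule_id", sort=True):
        first = grp.iloc[0]
        smarts = str(first["smarts"])
        if _has_stereo(smarts):
            logger.warning("rule %s: stereochemical SMARTS, skipped", rule_id)
            continue
        if _parse_single_substrate(smarts) is None:
            logger.warning("rule %s: unparseable or multi-substrate SMARTS, skipped", rule_id)
            continue
        sub_m = float(first["substrate_mass"])
        prod_m = float(first["product_mass"])
        transition = prod_m - sub_m
        if "mass_transition" in grp.columns and not pd.isna(first["mass_transition"]):
            stored = float(first["mass_transition"])
            if abs(stored - transition) > 1e-6:
                logger.warning(
                    "rule %s: stored mass_transition %.6f disagrees with recomputed %.6f, skipped",
                    rule_id, stored, transition,
                )
                continue
        assocs = []
        for _, row in grp.iterrows():
            if pd.isna(row.get("pfam_id")) or str(row.get("pfam_id")) == "":
                continue
            row_tier = str(row.get("tier", "loose"))
            if row_tier not in levels:
                continue
            taxon = row.get("taxon")
            taxon = None if pd.isna(taxon) else str(taxon)
            if taxa is not None and (taxon is None or taxon not in taxa):
                continue
            assocs.append(
                EnzymeAssociation(
                    pfam_id=str(row["pfam_id"]),
                    ec_number=str(row.get("ec_number", "")),
                    tier=row_tier,
                    taxon=taxon,
                )
            )
        if not assocs:
            continue
        reaction_ids = ()
        if "reaction_ids" in grp.columns and not pd.isna(first["reaction_ids"]):
            reaction_ids = tuple(str(first["reaction_ids"]).split(";"))
        rules.append(
            ReactionRule(
                rule_id=str(rule_id),
                smarts=smarts,
                substrate_mass=sub_m,
                product_mass=prod_m,
                mass_transition=transition,
                diameter=int(first.get("diameter", 2)),
                direction=str(first.get("direction", "both")),
                reaction_ids=reaction_ids,
                enzyme_associations=tuple(assocs),
            )
        )
    return rules


def rules_to_frame(rules: list[ReactionRule]) -> pd.DataFrame:
    """Flatten rules to the one-row-per-association relational shape."""
    rows = []
    for r in rules:
        for a in r.enzyme_associations or (EnzymeAssociation("", "", "loose"),):
            rows.append(
                {
                    "rule_id": r.rule_id,
                    "smarts": r.smarts,
                    "diameter": r.diameter,
                    "direction": r.direction,
                    "substrate_mass": r.substrate_mass,
                    "product_mass": r.product_mass,
                    "mass_transition": r.mass_transition,
                    "reaction_ids": ";".join(r.reaction_ids),
                    "pfam_id": a.pfam_id,
                    "ec_number": a.ec_number,
                    "tier": a.tier,
                    "taxon": a.taxon,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Project store
# ---------------------------------------------------------------------------


def _is_sqlite(path) -> bool:
    if not os.path.exists(path):
        return False
    with open(path, "rb") as fh:
        return fh.read(16).startswith(b"SQLite format 3")


class ProjectStore:
    """Single-file relational store for all intermediate pipeline tables.

    Tables (correlations, per-decay-rate weights, clusters, annotations,
    predictions, ...) persist as SQL tables; DataFrame round trips are
    bit-identical at full float precision because values are stored as
    native REAL/TEXT columns.
    """

    META_TABLE = "_pathseer_meta"

    def __init__(self, path, create: bool = True):
        exists = os.path.exists(path)
        if not exists and not create:
            raise FileNotFoundError(f"project store not found: {path}")
        self.path = str(path)
        self.con = sqlite3.connect(self.path)
        if not exists or self.META_TABLE not in self._table_names():
            self.con.execute(
                f"CREATE TABLE IF NOT EXISTS {self.META_TABLE} (key TEXT PRIMARY KEY, value TEXT)"
            )
            self.con.execute(
                f"INSERT OR REPLACE INTO {self.META_TABLE} VALUES ('schema_version', ?)",
                (str(SCHEMA_VERSION),),
            )
            self.con.commit()
        else:
            found = self.get_meta("schema_version")
            if found != str(SCHEMA_VERSION):
                raise ValidationError(
                    f"schema-version mismatch: expected {SCHEMA_VERSION}, found {found}"
                )

    def _table_names(self) -> set[str]:
        cur = self.con.execute("SELECT name FROM sqlite_master WHERE type='table'")
        return {row[0] for row in cur.fetchall()}

    def tables(self) -> list[str]:
        return sorted(t for t in self._table_names() if t != self.META_TABLE)

    def has_table(self, name: str) -> bool:
        return name in self._table_names()

    def save_table(self, name: str, df: pd.DataFrame) -> None:
        df.to_sql(name, self.con, if_exists="replace", index=False)
        self.con.commit()

    def load_table(self, name: str) -> pd.DataFrame:
        if not self.has_table(name):
            raise KeyError(f"table {name!r} absent from project store")
        return pd.read_sql(f'SELECT * FROM "{name}"', self.con)

    def set_meta(self, key: str, value: str) -> None:
        self.con.execute(
            f"INSERT OR REPLACE INTO {self.META_TABLE} VALUES (?, ?)", (key, str(value))
        )
        self.con.commit()

    def get_meta(self, key: str) -> str | None:
        cur = self.con.execute(f"SELECT value FROM {self.META_TABLE} WHERE key=?", (key,))
        row = cur.fetchone()
        return None if row is None else row[0]

    def close(self) -> None:
        self.con.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def save_project(path, tables: dict[str, pd.DataFrame]) -> ProjectStore:
    store = ProjectStore(path, create=True)
    for name, df in tables.items():
        store.save_table(name, df)
    return store


def load_project(path) -> ProjectStore:
    return ProjectStore(path, create=False)
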