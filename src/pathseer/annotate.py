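"""Structure annotation of mass features via adduct arithmetic + ppm matching.

An LC-MS feature is an ion: its observed m/z differs from the neutral
monoisotopic mass M of the underlying molecule by the adduct it formed
([M+H]+, [M+Na]+, [M-H]-, ...). For an adduct [nM+X]^z with total mass
shift s, the observed m/z is (n*M + s) / |z|, so

    M = (m/z * |z| - s) / n.

Each feature x adduct hypothesis yields a candidate neutral mass, which is
matched against a metabolite structure table within a relative tolerance in
parts per million (default 20 ppm, computed against the database mass).
Features with no candidate stay unannotated and remain eligible as ghost
anchors downstream.
"""

from __future__ import annotations

import bisect

import pandas as pd

from .core_data import AdductSpec, FeatureTable, MetaboliteRecord, ValidationError

DEFAULT_PPM = 20.0

PROTON = 1.007276
H2O = 18.010565

# Curated default list of commonly observed ESI adducts, positive and
# negative mode, including multimers; mass shifts in Da at the ion level.
_P = "positive"
_N = "negative"
DEFAULT_ADDUCTS: tuple[AdductSpec, ...] = tuple(
    AdductSpec(name, mode, charge, multimer, shift)
    for name, mode, charge, multimer, shift in [
        # -- positive, singly charged
        ("[M+H]+", _P, 1, 1, 1.007276),
        ("[M+NH4]+", _P, 1, 1, 18.033823),
        ("[M+Na]+", _P, 1, 1, 22.989218),
        ("[M+K]+", _P, 1, 1, 38.963158),
        ("[M+Li]+", _P, 1, 1, 7.015455),
        ("[M+CH3OH+H]+", _P, 1, 1, 33.033489),
        ("[M+ACN+H]+", _P, 1, 1, 42.033823),
        ("[M+ACN+Na]+", _P, 1, 1, 64.015765),
        ("[M+2ACN+H]+", _P, 1, 1, 83.060370),
        ("[M+IsoProp+H]+", _P, 1, 1, 61.065340),
        ("[M+DMSO+H]+", _P, 1, 1, 79.021220),
        ("[M+2Na-H]+", _P, 1, 1, 44.971160),
        ("[M+2K-H]+", _P, 1, 1, 76.919040),
        ("[M+H-H2O]+", _P, 1, 1, 1.007276 - H2O),
        ("[M+H-2H2O]+", _P, 1, 1, 1.007276 - 2 * H2O),
        # -- positive, multiply charged
        ("[M+2H]2+", _P, 2, 1, 2.014552),
        ("[M+H+Na]2+", _P, 2, 1, 23.996494),
        ("[M+H+NH4]2+", _P, 2, 1, 19.041099),
        ("[M+H+K]2+", _P, 2, 1, 39.970434),
        ("[M+2Na]2+", _P, 2, 1, 45.978436),
        ("[M+3H]3+", _P, 3, 1, 3.021828),
        ("[M+2H+Na]3+", _P, 3, 1, 25.003770),
        ("[M+H+2Na]3+", _P, 3, 1, 46.985712),
        ("[M+3Na]3+", _P, 3, 1, 68.967654),
        # -- positive, dimers/trimers
        ("[2M+H]+", _P, 1, 2, 1.007276),
        ("[2M+NH4]+", _P, 1, 2, 18.033823),
        ("[2M+Na]+", _P, 1, 2, 22.989218),
        ("[2M+K]+", _P, 1, 2, 38.963158),
        ("[2M+ACN+H]+", _P, 1, 2, 42.033823),
        ("[2M+ACN+Na]+", _P, 1, 2, 64.015765),
        ("[2M+H-H2O]+", _P, 1, 2, 1.007276 - H2O),
        ("[3M+H]+", _P, 1, 3, 1.007276),
        ("[3M+Na]+", _P, 1, 3, 22.989218),
        # -- negative, singly charged
        ("[M-H]-", _N, -1, 1, -1.007276),
        ("[M-H2O-H]-", _N, -1, 1, -1.007276 - H2O),
        ("[M+Cl]-", _N, -1, 1, 34.969402),
        ("[M+Br]-", _N, -1, 1, 78.918885),
        ("[M+FA-H]-", _N, -1, 1, 44.998201),
        ("[M+Hac-H]-", _N, -1, 1, 59.013851),
        ("[M+TFA-H]-", _N, -1, 1, 112.985586),
        ("[M+Na-2H]-", _N, -1, 1, 20.974666),
        ("[M+K-2H]-", _N, -1, 1, 36.948606),
        # -- negative, multiply charged
        ("[M-2H]2-", _N, -2, 1, -2.014552),
        ("[M-3H]3-", _N, -3, 1, -3.021828),
        # -- negative, dimers/trimers
        ("[2M-H]-", _N, -1, 2, -1.007276),
        ("[2M+FA-H]-", _N, -1, 2, 44.998201),
        ("[2M+Hac-H]-", _N, -1, 2, 59.013851),
        ("[3M-H]-", _N, -1, 3, -1.007276),
    ]
)

CANDIDATE_COLUMNS = [
    "feature_id", "adduct_name", "neutral_mass", "structure_id", "smiles", "ppm_error",
]


def neutral_mass(mz: float, adduct: AdductSpec) -> float:
    """Neutral monoisotopic mass implied by an observed m/z under an adduct:
    M = (m/z * |charge| - mass_shift) / multimer. May be nonpositive for an
    implausible hypothesis; callers discard those candidates."""
    if mz <= 0:
        raise ValidationError(f"m/z must be positive, got {mz}")
    return (mz * abs(adduct.charge) - adduct.mass_shift) / adduct.multimer


def predicted_mz(neutral: float, adduct: AdductSpec) -> float:
    """Inverse of :func:`neutral_mass`: the m/z this neutral mass would show
    under the adduct."""
    return (neutral * adduct.multimer + adduct.mass_shift) / abs(adduct.charge)


def ppm_error(observed_mass: float, db_mass: float) -> float:
    """Signed relative error in parts per million, against the database mass."""
    return (observed_mass - db_mass) / db_mass * 1e6


def annotate_features(
    features: FeatureTable,
    adducts=DEFAULT_ADDUCTS,
    db: list[MetaboliteRecord] = (),
    ppm: float = DEFAULT_PPM,
    manual: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Candidate structures for every feature x adduct within ppm tolerance.

    Returns a table with columns feature_id, adduct_name, neutral_mass,
    structure_id, smiles, ppm_error. One feature may receive many
    candidates; the candidate set is independent of database record order.
    ``manual`` maps feature_id -> structure_id and bypasses mass matching
    for those features (reported with adduct_name "manual", ppm_error 0).
    """
    if ppm <= 0:
        raise ValidationError(f"ppm tolerance must be positive, got {ppm}")
    if not db:
        raise ValidationError("metabolite database is empty")
    by_id = {rec.structure_id: rec for rec in db}
    recs = sorted(db, key=lambda r: (r.monoisotopic_mass, r.structure_id))
    masses = [r.monoisotopic_mass for r in recs]
    rows = []
    manual = manual or {}
    for fid, mz in features.mz.items():
        if fid in manual:
            rec = by_id[manual[fid]]
            rows.append(
                {
                    "feature_id": fid,
                    "adduct_name": "manual",
                    "neutral_mass": rec.monoisotopic_mass,
                    "structure_id": rec.structure_id,
                    "smiles": rec.smiles,
                    "ppm_error": 0.0,
                }
            )
            continue
        for adduct in adducts:
            m = neutral_mass(float(mz), adduct)
            if m <= 0:
                continue
            lo = m / (1 + ppm * 1e-6)
            hi = m / (1 - ppm * 1e-6)
            for i in range(bisect.bisect_left(masses, lo), bisect.bisect_right(masses, hi)):
                rec = recs[i]
                err = ppm_error(m, rec.monoisotopic_mass)
                if abs(err) <= ppm:
                    rows.append(
                        {
                            "feature_id": fid,
                            "adduct_name": adduct.name,
                            "neutral_mass": m,
                            "structure_id": rec.structure_id,
                            "smiles": rec.smiles,
                            "ppm_error": err,
                        }
                    )
    out = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    return out.sort_values(
        ["feature_id", "adduct_name", "structure_id"], ignore_index=True
    )


def adducts_to_frame(adducts) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": a.name,
                "mode": a.mode,
                "charge": a.charge,
                "multimer": a.multimer,
                "mass_shift": a.mass_shift,
            }
            for a in adducts
        ]
    )
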