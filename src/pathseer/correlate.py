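"""Transcript-feature correlation, mutual ranks, and decay-weighted networks.

Raw abundances are first rescaled row-wise by the median absolute deviation
(MAD), a robust analogue of the z-score: x -> (x - median(x)) / MAD(x) with
MAD(x) = median(|x_i - median(x)|). Rows with MAD = 0 carry no usable
variation and are dropped.

All transcript x feature Pearson correlations passing a minimum |r| are then
converted to mutual ranks: for a pair (t, f), MR = sqrt(rank_t(f) * rank_f(t))
where rank_t(f) is f's rank (descending |r|, average ties) among all features
correlated with t, and symmetrically for rank_f(t). MR = 1 means each is the
other's best partner.

Finally MR is mapped to an edge weight in (0, 1] by an exponential decay
w = exp(-(MR - 1) / DR) at several decay rates DR; edges below a weight
cutoff are excluded, yielding one network per decay rate. Small DR keeps
only near-reciprocal-best pairs; large DR admits progressively weaker ones,
so the networks nest as edge sets.
"""

from __future__ import annotations

import logging
from typing import Union

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_data import ExpressionMatrix, FeatureTable, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_DECAY_RATES = (5, 10, 25, 50)
DEFAULT_MIN_ABS_R = 0.1
DEFAULT_WEIGHT_CUTOFF = 0.01

#: columns of an edge table
EDGE_COLUMNS = ["transcript_id", "feature_id", "r", "p", "mr"]


def mad(values) -> float:
    """Median absolute deviation: median(|x_i - median(x)|)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("mad: empty vector")
    return float(np.median(np.abs(arr - np.median(arr))))


def mad_rescale(
    data: Union[ExpressionMatrix, FeatureTable],
) -> Union[ExpressionMatrix, FeatureTable]:
    """Rescale each row to (x - median) / MAD; rows with MAD = 0 are dropped."""
    if isinstance(data, FeatureTable):
        frame = data.abundance
    else:
        frame = data.values
    arr = frame.to_numpy(dtype=float)
    med = np.median(arr, axis=1, keepdims=True)
    madv = np.median(np.abs(arr - med), axis=1)
    keep = madv > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("mad_rescale: dropped %d constant row(s)", n_dropped)
    if not keep.any():
        raise ValidationError("no variable rows (all rows have MAD = 0)")
    scaled = (arr[keep] - med[keep]) / madv[keep, None]
    out = pd.DataFrame(scaled, index=frame.index[keep], columns=frame.columns)
    if isinstance(data, FeatureTable):
        mz = data.mz.loc[out.index]
        rt = None if data.rt is None else data.rt.loc[out.index]
        return FeatureTable(mz, out, rt, nonnegative=False)
    return ExpressionMatrix(out)


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for H0: rho = 0, via t = r sqrt((n-2)/(1-r^2)), df = n-2."""
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = r * r * df / (1.0 - r * r)
    # survival of the t distribution doubled; |r| = 1 -> p = 0 exactly
    p = np.where(np.abs(r) >= 1.0, 0.0, special.stdtr(df, -np.sqrt(np.maximum(t2, 0.0))) * 2.0)
    return p


def correlate_pairs(
    expr: ExpressionMatrix,
    feats: FeatureTable,
    min_abs_r: float = DEFAULT_MIN_ABS_R,
) -> pd.DataFrame:
    """All transcript x feature Pearson correlations with |r| >= min_abs_r.

    Returns an edge table with columns transcript_id, feature_id, r, p.
    Samples must already be aligned. Zero-variance rows (possible when
    rescaling was skipped) are excluded pairwise.
    """
    if feats.samples != expr.samples:
        raise ValidationError("samples not aligned; call align_samples first")
    n = len(expr.samples)
    if n < 3:
        raise ValidationError(f"need >= 3 samples, got {n}")
    X = expr.values.to_numpy(dtype=float)
    Y = feats.abundance.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xs = np.sqrt((Xc**2).sum(axis=1))
    ys = np.sqrt((Yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Xc @ Yc.T) / np.outer(xs, ys)
    R = np.clip(R, -1.0, 1.0)
    valid = np.outer(xs > 0, ys > 0)
    mask = valid & (np.abs(R) >= min_abs_r)
    ti, fi = np.nonzero(mask)
    r = R[ti, fi]
    edges = pd.DataFrame(
        {
            "transcript_id": np.asarray(expr.transcript_ids, dtype=object)[ti],
            "feature_id": np.asarray(feats.feature_ids, dtype=object)[fi],
            "r": r,
            "p": _pearson_p(r, n),
        }
    )
    return edges.sort_values(["transcript_id", "feature_id"], ignore_index=True)


def mutual_rank(edges: pd.DataFrame) -> pd.DataFrame:
    """Attach the mutual rank MR = sqrt(rank_t(f) * rank_f(t)) to each edge.

    Ranks are computed within each node's cross-omics partner list by
    descending |r|, with average ranks on ties. Result is independent of the
    input row order.
    """
    out = edges.copy()
    absr = out["r"].abs()
    rank_t = absr.groupby(out["transcript_id"]).rank(ascending=False, method="average")
    rank_f = absr.groupby(out["feature_id"]).rank(ascending=False, method="average")
    out["mr"] = np.sqrt(rank_t * rank_f)
    return out


def decay_weights(
    edges: pd.DataFrame,
    decay_rates=DEFAULT_DECAY_RATES,
    cutoff: float = DEFAULT_WEIGHT_CUTOFF,
) -> dict[int, pd.DataFrame]:
    """One decay-weighted network per decay rate.

    weight = exp(-(MR - 1) / DR); edges with weight < cutoff are excluded
    from that rate's network.
    """
    if "mr" not in edges.columns:
        raise ValidationError("edges lack mutual ranks; call mutual_rank first")
    networks: dict[int, pd.DataFrame] = {}
    for dr in decay_rates:
        if dr <= 0:
            raise ValidationError(f"decay rate must be positive, got {dr}")
        w = np.exp(-(edges["mr"] - 1.0) / dr)
        net = edges.assign(weight=w)
        networks[int(dr)] = net[net["weight"] >= cutoff].reset_index(drop=True)
    return networks


def coexpression_network(
    expr: ExpressionMatrix,
    min_abs_r: float = DEFAULT_MIN_ABS_R,
    decay_rate: int = 10,
    cutoff: float = DEFAULT_WEIGHT_CUTOFF,
) -> pd.DataFrame:
    """Transcript-transcript mutual-rank network (expression-only mode).

    Same MR/decay machinery applied within the transcriptome; used to merge
    functional clusters through coexpressed member genes. Returns columns
    transcript_a, transcript_b, r, mr, weight (a < b lexicographically).
    """
    X = expr.values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc**2).sum(axis=1))
    ok = norm > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Xc @ Xc.T) / np.outer(norm, norm)
    R = np.clip(R, -1.0, 1.0)
    np.fill_diagonal(R, 0.0)
    mask = np.outer(ok, ok) & (np.abs(R) >= min_abs_r)
    ids = np.asarray(expr.transcript_ids, dtype=object)
    ai, bi = np.nonzero(mask)
    df = pd.DataFrame({"a": ai, "b": bi, "r": R[ai, bi]})
    absr = df["r"].abs()
    rank_a = absr.groupby(df["a"]).rank(ascending=False, method="average")
    rank_b = absr.groupby(df["b"]).rank(ascending=False, method="average")
    # directed ranks collapse onto the symmetric pair
    df["mr"] = np.sqrt(rank_a * rank_b)
    df = df[df["a"] < df["b"]].copy()
    df["weight"] = np.exp(-(df["mr"] - 1.0) / decay_rate)
    df = df[df["weight"] >= cutoff]
    out = pd.DataFrame(
        {
            "transcript_a": ids[df["a"].to_numpy(dtype=int)],
            "transcript_b": ids[df["b"].to_numpy(dtype=int)],
            "r": df["r"].to_numpy(),
            "mr": df["mr"].to_numpy(),
            "weight": df["weight"].to_numpy(),
        }
    )
    return out.sort_values(["transcript_a", "transcript_b"], ignore_index=True)
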