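"""Normalization of digital-counting (nCounter-style) expression data.

Three sequential steps, each exposed separately and chained by
:func:`normalize_counts`:

1. **Positive-control scaling** — each lane is rescaled so its spike-in
   positive controls match the cohort average; by default the geometric
   mean of the controls is equalized across lanes, optionally a
   standard-curve (regression-on-ladder) variant.
2. **Background thresholding** — a per-lane background of
   ``mean + k*SD`` of the negative controls; endogenous counts at or
   below background are flagged and floored to it.
3. **Reference-gene scaling** — lanes rescaled so each lane's
   housekeeping geometric mean equals the cohort's grand geometric mean.

All steps operate on count-scale values; :func:`log_transform` then
produces the log2 matrix used by scoring and modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import (ENDOGENOUS, HOUSEKEEPING, NEGATIVE, POSITIVE,
                     ExpressionMatrix)

#: Nominal spike-in ladder (fM), highest first; a geometric 4-fold series.
POSITIVE_LADDER_FM = np.array([128.0, 32.0, 8.0, 2.0, 0.5, 0.125])


def _geomean(a: np.ndarray, axis=0) -> np.ndarray:
    return np.exp(np.mean(np.log(a), axis=axis))


def positive_control_normalize(
    raw: ExpressionMatrix, method: str = "geomean"
) -> tuple[ExpressionMatrix, pd.Series]:
    """Scale each lane by its spike-in positive controls.

    Returns the rescaled matrix and the per-sample scale factors.  With
    ``method="geomean"`` the factor is (grand geometric mean of per-lane
    positive-control geometric means) / (this lane's geometric mean), so
    the positive-control geometric means are equalized afterwards.  With
    ``method="curve"`` a per-lane regression through the origin of the
    control counts on the nominal ladder concentrations is used instead
    and slopes are equalized.
    """
    if raw.scale == "log2":
        raise ValueError("positive-control normalization applies to count-scale data")
    pos = raw.class_probes(POSITIVE)
    if len(pos) < 2:
        raise ValueError(f"need >= 2 Positive control probes, found {len(pos)}")
    counts = raw.values.loc[pos]
    bad = counts.le(0).any(axis=0)
    if bad.any():
        raise ValueError(
            "non-positive positive-control counts in sample(s): "
            f"{list(counts.columns[bad])}"
        )
    if method == "geomean":
        per_sample = pd.Series(_geomean(counts.to_numpy(), axis=0),
                               index=counts.columns)
        factors = _geomean(per_sample.to_numpy()) / per_sample
    elif method == "curve":
        # Nominal concentration assigned to probes by descending overall mean.
        ladder = POSITIVE_LADDER_FM
        if len(pos) != len(ladder):
            ratio = ladder[0] / ladder[1]
            ladder = ladder[0] / ratio ** np.arange(len(pos))
        order = counts.mean(axis=1).sort_values(ascending=False).index
        x = pd.Series(ladder, index=order).reindex(counts.index).to_numpy()
        # least-squares slope through the origin per lane
        slopes = counts.mul(x, axis=0).sum(axis=0) / float(np.sum(x * x))
        factors = _geomean(slopes.to_numpy()) / slopes
    else:
        raise ValueError(f"unknown method {method!r}")
    out = raw.values.mul(factors, axis=1)
    return raw.with_values(out, scale="normalized"), factors.rename("scale_factor")


def background_threshold(
    m: ExpressionMatrix, k_sd: float = 2.0
) -> tuple[ExpressionMatrix, pd.Series, pd.DataFrame]:
    """Per-lane background from negative controls; floor endogenous counts.

    background = mean + ``k_sd`` * SD (sample SD) of the negative-control
    counts in each lane.  Endogenous counts <= background are flagged and
    set to the background value (flooring, so no negative counts arise).
    Returns (matrix, per-sample background, boolean flag frame over
    endogenous probes).
    """
    if k_sd < 0:
        raise ValueError("k_sd must be >= 0")
    neg = m.class_probes(NEGATIVE)
    if len(neg) < 2:
        raise ValueError(f"need >= 2 Negative control probes, found {len(neg)}")
    negs = m.values.loc[neg]
    background = negs.mean(axis=0) + k_sd * negs.std(axis=0, ddof=1)
    background = background.rename("background")
    endo = m.endogenous_probes
    vals = m.values.copy()
    flags = vals.loc[endo].le(background, axis=1)
    vals.loc[endo] = vals.loc[endo].clip(lower=background, axis=1)
    return m.with_values(vals), background, flags


def reference_gene_normalize(
    m: ExpressionMatrix,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Scale lanes so housekeeping geometric means are equal across lanes."""
    if m.scale == "log2":
        raise ValueError("reference-gene normalization applies to count-scale data")
    hk = m.class_probes(HOUSEKEEPING)
    if len(hk) < 1:
        raise ValueError("need >= 1 Housekeeping probe")
    counts = m.values.loc[hk]
    zero = counts.le(0)
    if zero.any().any():
        probe = zero.index[zero.any(axis=1)][0]
        sample = zero.columns[zero.any(axis=0)][0]
        raise ValueError(
            f"non-positive housekeeping count (probe {probe!r}, sample {sample!r})"
        )
    per_sample = pd.Series(_geomean(counts.to_numpy(), axis=0), index=counts.columns)
    factors = _geomean(per_sample.to_numpy()) / per_sample
    out = m.values.mul(factors, axis=1)
    return m.with_values(out, scale="normalized"), factors.rename("scale_factor")


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount); marks the matrix scale as log2."""
    if m.scale == "log2":
        raise ValueError("matrix is already log2-scaled")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return m.with_values(np.log2(m.values + pseudocount), scale="log2")


@dataclass
class NormalizationInfo:
    """Per-lane diagnostics collected by :func:`normalize_counts`."""

    positive_factors: pd.Series
    background: pd.Series
    background_flags: pd.DataFrame
    housekeeping_factors: pd.Series
    k_sd: float
    pseudocount: float
    method: str

    @property
    def n_flagged(self) -> int:
        return int(self.background_flags.to_numpy().sum())


def normalize_counts(
    raw: ExpressionMatrix,
    k_sd: float = 2.0,
    pseudocount: float = 1.0,
    method: str = "geomean",
) -> tuple[ExpressionMatrix, NormalizationInfo]:
    """Full chain: positive controls -> background -> housekeeping -> log2."""
    m, pos_factors = positive_control_normalize(raw, method=method)
    m, background, flags = background_threshold(m, k_sd=k_sd)
    m, hk_factors = reference_gene_normalize(m)
    m = log_transform(m, pseudocount=pseudocount)
    info = NormalizationInfo(
        positive_factors=pos_factors,
        background=background,
        background_flags=flags,
        housekeeping_factors=hk_factors,
        k_sd=k_sd,
        pseudocount=pseudocount,
        method=method,
    )
    return m, info
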