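"""Per-sample signature scores and median dichotomization.

A signature is a named gene list, optionally with per-gene weights.
Unweighted signatures (CIN25, CIN70) are scored as the mean of per-gene
values — by default per-gene z-scores across the cohort; weighted
signatures (CIN4-style, Cox-coefficient weighted) as the weighted sum.
Scores are dichotomized at the cohort median: High means strictly above
the median, ties go Low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


@dataclass
class SignatureDefinition:
    """Named gene list with optional per-gene weights."""

    name: str
    genes: list[str]
    weights: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature gene list is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")
        if self.weights is not None and len(self.weights) != len(self.genes):
            raise ValueError("weights must align 1:1 with genes")

    @property
    def weighted(self) -> bool:
        return self.weights is not None

    def write(self, path) -> None:
        """One gene per line; a tab-separated weight column if weighted."""
        with open(path, "w") as fh:
            for i, g in enumerate(self.genes):
                if self.weights is None:
                    fh.write(f"{g}\n")
                else:
                    fh.write(f"{g}\t{self.weights[i]:.10g}\n")

    @classmethod
    def read(cls, path, name: str | None = None) -> "SignatureDefinition":
        genes: list[str] = []
        weights: list[float] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                genes.append(parts[0])
                if len(parts) > 1:
                    weights.append(float(parts[1]))
        if weights and len(weights) != len(genes):
            raise ValueError(f"{path}: some genes have weights, others do not")
        from pathlib import Path
        return cls(name=name or Path(path).stem, genes=genes,
                   weights=weights or None)


@dataclass
class SignatureScore:
    """Per-sample scores, optionally with High/Low groups set."""

    name: str
    scores: pd.Series
    group: pd.Series | None = None
    median_used: float | None = None

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.index

    def counts(self) -> dict[str, int]:
        if self.group is None:
            raise ValueError("groups not set; call dichotomize_at_median first")
        return {"High": int((self.group == "High").sum()),
                "Low": int((self.group == "Low").sum())}

    def standardized(self) -> "SignatureScore":
        """Rescale scores to zero mean and unit variance across the cohort.

        Continuous-marker hazard ratios are then per SD of signature
        score, making effect sizes comparable across signatures.
        """
        sd = self.scores.std(ddof=0)
        if sd == 0:
            raise ValueError("cannot standardize a constant score")
        z = (self.scores - self.scores.mean()) / sd
        return SignatureScore(name=self.name, scores=z, group=self.group,
                              median_used=None)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"score": self.scores})
        if self.group is not None:
            df["group"] = self.group
        df.index.name = "sample_id"
        return df


def score_signature(
    expr: ExpressionMatrix,
    sig: SignatureDefinition,
    standardize: bool = True,
) -> SignatureScore:
    """Score a signature on a log2 expression matrix.

    Unweighted: mean over the signature genes of the (optionally per-gene
    z-standardized) log2 expression.  Weighted: sum of weight * value.
    A zero-variance gene under standardization contributes 0 and raises a
    warning.  Missing genes raise, listing them.
    """
    if expr.scale != "log2":
        raise ValueError("expression must be log2-scaled before scoring")
    missing = [g for g in sig.genes if g not in expr.values.index]
    if missing:
        raise KeyError(f"signature {sig.name!r}: genes missing from matrix: {missing}")
    x = expr.values.loc[sig.genes]
    if standardize:
        mu = x.mean(axis=1)
        sd = x.std(axis=1, ddof=0)
        flat = sd == 0
        if flat.any():
            warnings.warn(
                f"signature {sig.name!r}: zero-variance gene(s) "
                f"{list(x.index[flat])} contribute 0 to the score"
            )
            sd = sd.replace(0, np.inf)
        x = x.sub(mu, axis=0).div(sd, axis=0)
    if sig.weights is None:
        scores = x.mean(axis=0)
    else:
        w = np.asarray(sig.weights, dtype=float)
        scores = pd.Series(w @ x.to_numpy(), index=x.columns)
    return SignatureScore(name=sig.name, scores=scores.rename(sig.name))


def dichotomize_at_median(s: SignatureScore) -> SignatureScore:
    """Assign High/Low at the cohort median; High means strictly above.

    The median is computed over all scored samples (the merged cohort);
    samples tied at the median go Low.  A degenerate all-identical score
    yields all Low with a warning.
    """
    if len(s.scores) < 2:
        raise ValueError("need >= 2 samples to dichotomize")
    med = float(s.scores.median())
    group = pd.Series(np.where(s.scores > med, "High", "Low"),
                      index=s.scores.index, name="group")
    if (group == "Low").all():
        warnings.warn(f"signature {s.name!r}: no sample above the median "
                      "(degenerate marker)")
    return replace(s, group=group, median_used=med)
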