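"""Probe-by-sample expression matrices with nCounter-style probe classes.

An :class:`ExpressionMatrix` holds a probe x sample grid of counts (raw,
normalized, or log2) together with a per-probe class label:
``Endogenous`` (targets), ``Positive`` / ``Negative`` (spike-in and
background controls) and ``Housekeeping`` (reference genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

ENDOGENOUS = "Endogenous"
POSITIVE = "Positive"
NEGATIVE = "Negative"
HOUSEKEEPING = "Housekeeping"
PROBE_CLASSES = (ENDOGENOUS, POSITIVE, NEGATIVE, HOUSEKEEPING)

SCALES = ("raw", "normalized", "log2")


@dataclass
class ExpressionMatrix:
    """Probe x sample expression values plus probe class annotation.

    Parameters
    ----------
    values
        DataFrame with probes as the index and samples as columns.
    probe_class
        Series mapping each probe id to one of :data:`PROBE_CLASSES`.
    scale
        One of ``raw``, ``normalized``, ``log2``.
    """

    values: pd.DataFrame
    probe_class: pd.Series
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        self.probe_class = self.probe_class.reindex(self.values.index)
        if self.probe_class.isna().any():
            missing = list(self.probe_class.index[self.probe_class.isna()])[:5]
            raise ValueError(f"probe_class missing for probes {missing}")
        bad = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if bad:
            raise ValueError(f"unknown probe classes {sorted(bad)}")
        if self.scale == "raw" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")

    # -- accessors ---------------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def class_probes(self, probe_class: str) -> pd.Index:
        """Probe ids belonging to one class."""
        return self.values.index[self.probe_class == probe_class]

    @property
    def endogenous_probes(self) -> pd.Index:
        return self.class_probes(ENDOGENOUS)

    @property
    def n_assayed_genes(self) -> int:
        """Number of genes assayed: endogenous targets + reference genes."""
        return int(((self.probe_class == ENDOGENOUS)
                    | (self.probe_class == HOUSEKEEPING)).sum())

    def subset_probes(self, probes) -> "ExpressionMatrix":
        probes = pd.Index(probes)
        missing = probes.difference(self.values.index)
        if len(missing):
            raise KeyError(f"probes not in matrix: {list(missing)}")
        return replace(self, values=self.values.loc[probes],
                       probe_class=self.probe_class.loc[probes])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = pd.Index(samples)
        missing = samples.difference(self.values.columns)
        if len(missing):
            raise KeyError(f"samples not in matrix: {list(missing)}")
        return replace(self, values=self.values[samples])

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return replace(self, values=values,
                       scale=self.scale if scale is None else scale)

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write a delimited probe x sample table with a probe_class column."""
        out = self.values.copy()
        out.insert(0, "probe_class", self.probe_class)
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, scale: str = "raw") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="probe_id")
        if "probe_class" not in df.columns:
            raise ValueError(f"{path}: no probe_class column")
        probe_class = df.pop("probe_class")
        return cls(values=df.astype(float), probe_class=probe_class,
                   scale=scale)

    @classmethod
    def from_rcc_dir(cls, directory) -> "ExpressionMatrix":
        """Read a directory of RCC-style lane files (one per sample).

        Each file is a delimited table with ``CodeClass``, ``Name`` and
        ``Count`` columns; the sample id is the file stem.
        """
        directory = Path(directory)
        lanes = {}
        classes: pd.Series | None = None
        for f in sorted(directory.glob("*.csv")) + sorted(directory.glob("*.rcc")):
            df = pd.read_csv(f)
            need = {"CodeClass", "Name", "Count"}
            if not need.issubset(df.columns):
                raise ValueError(f"{f}: expected columns {sorted(need)}")
            lane = df.set_index("Name")
            lanes[f.stem] = lane["Count"]
            cls_col = lane["CodeClass"]
            if classes is None:
                classes = cls_col
            elif not classes.equals(cls_col.reindex(classes.index)):
                raise ValueError(f"{f}: probe annotation differs between lanes")
        if not lanes:
            raise ValueError(f"no lane files found in {directory}")
        values = pd.DataFrame(lanes)
        return cls(values=values, probe_class=classes, scale="raw")
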