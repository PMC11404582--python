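"""Core data containers shared across the pipeline.

The universal exchange object is :class:`FeatureTable`, a features x samples
numeric matrix (microbial counts/relative abundances, or immune population
abundances) with optional per-feature annotations (taxonomy strings of the
form ``k__...;s__...`` or immune lineage labels). Sample-level factors
(gut segment, colonization status, tissue compartment, mouse) live in
:class:`SampleMetadata`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: The five gut segments in oral->aboral order.
SEGMENTS = ("duodenum", "jejunum", "ileum", "cecum", "colon")

#: Colonization states: conventionally colonized vs germ-free.
COLONIZATIONS = ("CONV", "GF")

_REL_TOL = 1e-8


class ModeError(ValueError):
    """Raised when an operation receives a table in the wrong mode."""


class DegenerateInputError(ValueError):
    """Raised on inputs the operation cannot meaningfully process."""


@dataclass
class FeatureTable:
    """A features x samples abundance matrix.

    Parameters
    ----------
    data
        DataFrame with feature ids as index and sample ids as columns.
        Values must be non-negative and finite.
    mode
        ``"counts"`` for integer read counts, ``"relative"`` for
        per-sample relative abundances (columns sum to 1), or
        ``"zscore"`` for standardized per-feature scores (may be negative).
    feature_annotations
        Optional per-feature annotation strings (taxonomy or lineage),
        indexed like ``data``.
    """

    data: pd.DataFrame
    mode: str = "counts"
    feature_annotations: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative", "zscore"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.data.index.is_unique:
            raise ValueError("feature ids must be unique")
        if not self.data.columns.is_unique:
            raise ValueError("sample ids must be unique")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValueError("non-finite values in feature table")
        if values.size and self.mode != "zscore" and (values < 0).any():
            raise ValueError("negative values in feature table")
        if self.mode == "relative" and self.data.shape[1]:
            sums = values.sum(axis=0)
            if np.any(np.abs(sums - 1.0) > _REL_TOL):
                raise ValueError(
                    "relative-mode columns must sum to 1 "
                    f"(worst deviation {np.max(np.abs(sums - 1.0)):.3g})"
                )
        if self.feature_annotations is not None:
            missing = self.data.index.difference(self.feature_annotations.index)
            if len(missing):
                raise ValueError(f"annotations missing for features: {list(missing)[:5]}")

    # -- basic views ---------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    # -- subsetting ----------------------------------------------------
    def select_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(
            self.data.loc[:, list(sample_ids)], self.mode, self.feature_annotations
        )

    def select_features(self, feature_ids) -> "FeatureTable":
        ann = self.feature_annotations
        if ann is not None:
            ann = ann.loc[list(feature_ids)]
        return FeatureTable(self.data.loc[list(feature_ids)], self.mode, ann)

    # -- I/O -----------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: first column feature id, header row sample ids."""
        out = self.data.copy()
        out.index.name = "feature_id"
        if self.feature_annotations is not None:
            out.insert(0, "annotation", self.feature_annotations.reindex(out.index))
        out.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, mode: str = "counts") -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ann = None
        if "annotation" in df.columns:
            ann = df.pop("annotation")
        return cls(df, mode, ann)


@dataclass
class SampleMetadata:
    """Per-sample experimental factors.

    ``frame`` is indexed by sample id with columns ``mouse_id``,
    ``segment`` (ordered categorical over :data:`SEGMENTS`),
    ``colonization`` (CONV/GF) and optionally ``compartment`` (LPL/IEL/other).
    """

    frame: pd.DataFrame
    segment_order: tuple[str, ...] = SEGMENTS

    def __post_init__(self) -> None:
        required = {"mouse_id", "segment", "colonization"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        bad = set(self.frame["segment"]) - set(self.segment_order)
        if bad:
            raise ValueError(f"segments outside the configured order: {sorted(bad)}")
        self.frame = self.frame.copy()
        self.frame["segment"] = pd.Categorical(
            self.frame["segment"], categories=list(self.segment_order), ordered=True
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)], self.segment_order)

    def segments_present(self) -> list[str]:
        present = set(self.frame["segment"].astype(str))
        return [s for s in self.segment_order if s in present]

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, segment_order: tuple[str, ...] = SEGMENTS) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", index_col=0), segment_order)


@dataclass
class DistanceMatrix:
    """Square symmetric pairwise distance matrix over samples."""

    values: np.ndarray
    sample_ids: list[str]
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.max(np.abs(v - v.T), initial=0.0) > 1e-12:
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.sample_ids), k=1)
        return self.values[iu]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids).to_csv(
            path, sep="\t", float_format="%.10g"
        )


@dataclass
class OrdinationResult:
    """Low-dimensional embedding from PCoA or PCA.

    ``coordinates`` is samples x axes; ``eigenvalues`` are sorted
    descending (negative PCoA eigenvalues are reported, never corrected);
    ``proportion_explained`` is computed over positive eigenvalues only.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    method: str

    def __post_init__(self) -> None:
        eig = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(eig) > 1e-9):
            raise ValueError("eigenvalues must be sorted descending")
        if self.proportion_explained.sum() > 1 + 1e-9:
            raise ValueError("proportion explained exceeds 1")

    def to_tsv(self, path: str | Path) -> None:
        self.coordinates.to_csv(path, sep="\t", float_format="%.10g")

    def eigen_summary(self) -> dict:
        return {
            "method": self.method,
            "eigenvalues": [float(e) for e in self.eigenvalues],
            "proportion_explained": [float(p) for p in self.proportion_explained],
        }


@dataclass
class QCReport:
    """Outcome of a filtering step: exact partition of the input set."""

    retained_samples: list[str] = field(default_factory=list)
    discarded_samples: dict[str, str] = field(default_factory=dict)  # id -> reason
    retained_features: list[str] = field(default_factory=list)
    discarded_features: dict[str, str] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "retained_samples": self.retained_samples,
                    "discarded_samples": self.discarded_samples,
                    "retained_features": self.retained_features,
                    "discarded_features": self.discarded_features,
                    "thresholds": self.thresholds,
                },
                indent=2,
            )
        )
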