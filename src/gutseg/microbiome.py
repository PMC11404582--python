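"""Microbiome preprocessing, diversity, core-taxa overlap, differential
abundance, and 16S qPCR absolute quantification.

QC follows the shotgun-profile cleaning rules used throughout: samples
below 500 reads are discarded; features must be detected in at least 10%
of the samples AND average at least 0.01% relative abundance to be
retained; samples dominated by the blank-sample contaminant are flagged
for the analyst (never auto-discarded). No rarefaction anywhere — all
diversity measures run on plain relative abundances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .containers import (
    DegenerateInputError,
    DistanceMatrix,
    FeatureTable,
    ModeError,
    OrdinationResult,
    QCReport,
)
from .stats import benjamini_hochberg, mann_whitney

__all__ = [
    "filter_low_depth_samples",
    "filter_rare_features",
    "flag_blank_overlap",
    "relative_abundance",
    "aggregate_by_rank",
    "shannon_index",
    "bray_curtis",
    "pcoa",
    "OverlapResult",
    "presence_overlap",
    "differential_features",
    "StandardCurve",
    "fit_standard_curve",
    "copies_per_gram",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIX = dict(zip(RANKS, ("k__", "p__", "c__", "o__", "f__", "g__", "s__")))


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def filter_low_depth_samples(
    counts: FeatureTable, min_reads: int = 500
) -> tuple[FeatureTable, QCReport]:
    """Discard samples with fewer than ``min_reads`` total reads.

    The boundary is retained: a sample with exactly ``min_reads`` reads
    passes ("less than 500 reads" are discarded).
    """
    if counts.mode != "counts":
        raise ModeError("depth filtering requires a counts table")
    depths = counts.data.sum(axis=0)
    keep = depths[depths >= min_reads].index.tolist()
    drop = depths[depths < min_reads].index.tolist()
    report = QCReport(
        retained_samples=keep,
        discarded_samples={s: "low_depth" for s in drop},
        retained_features=counts.feature_ids,
        thresholds={"min_reads": float(min_reads)},
    )
    return counts.select_samples(keep), report


def filter_rare_features(
    counts: FeatureTable,
    min_prevalence: float = 0.10,
    min_total_rel_abundance: float = 1e-4,
) -> tuple[FeatureTable, QCReport]:
    """Discard features failing the prevalence or abundance criterion.

    A feature is retained iff it is detected (count > 0) in at least
    ``ceil(min_prevalence * n_samples)`` samples AND its mean relative
    abundance across samples is at least ``min_total_rel_abundance``
    (default 0.01%). Both criteria are evaluated on the (already
    sample-filtered) input table.
    """
    if counts.mode != "counts":
        raise ModeError("rare-feature filtering requires a counts table")
    if counts.n_samples == 0 or counts.n_features == 0:
        raise DegenerateInputError("cannot filter an empty table")
    n = counts.n_samples
    vals = counts.values()
    depths = vals.sum(axis=0)
    if np.any(depths == 0):
        raise DegenerateInputError("all-zero sample present; depth-filter first")
    prevalence = (vals > 0).sum(axis=1)
    mean_rel = (vals / depths).mean(axis=1)
    min_count = math.ceil(min_prevalence * n)
    keep_mask = (prevalence >= min_count) & (mean_rel >= min_total_rel_abundance)
    keep, drop = [], {}
    for fid, ok, prev_ok in zip(
        counts.feature_ids, keep_mask, prevalence >= min_count
    ):
        if ok:
            keep.append(fid)
        else:
            drop[fid] = "low_prevalence" if not prev_ok else "low_abundance"
    report = QCReport(
        retained_samples=counts.sample_ids,
        retained_features=keep,
        discarded_features=drop,
        thresholds={
            "min_prevalence": min_prevalence,
            "min_total_rel_abundance": min_total_rel_abundance,
        },
    )
    return counts.select_features(keep), report


def flag_blank_overlap(
    counts: FeatureTable,
    blank_profile: FeatureTable,
    dominance_threshold: float = 0.25,
) -> QCReport:
    """Flag samples dominated by a feature detected in the blank control.

    A sample is flagged when any blank-detected feature exceeds
    ``dominance_threshold`` relative abundance in it. Flagging is advisory:
    nothing is discarded here.
    """
    blank_features = [
        f for f in blank_profile.feature_ids
        if (blank_profile.data.loc[f] > 0).any()
    ]
    flagged: dict[str, str] = {}
    if blank_features:
        vals = counts.values()
        depths = vals.sum(axis=0)
        rel = np.divide(vals, depths, out=np.zeros_like(vals), where=depths > 0)
        shared = [f for f in blank_features if f in counts.data.index]
        for f in shared:
            row = rel[counts.data.index.get_loc(f)]
            for sid, r in zip(counts.sample_ids, row):
                if r > dominance_threshold:
                    flagged[sid] = "blank_overlap"
    report = QCReport(
        retained_samples=[s for s in counts.sample_ids if s not in flagged],
        discarded_samples=flagged,
        retained_features=counts.feature_ids,
        thresholds={"dominance_threshold": dominance_threshold},
    )
    return report


# ---------------------------------------------------------------------------
# normalisation & aggregation
# ---------------------------------------------------------------------------

def relative_abundance(counts: FeatureTable) -> FeatureTable:
    """Convert counts to per-sample relative abundances (no rarefaction)."""
    if counts.mode != "counts":
        raise ModeError("input already relative")
    vals = counts.values()
    depths = vals.sum(axis=0)
    zero = [s for s, d in zip(counts.sample_ids, depths) if d == 0]
    if zero:
        raise DegenerateInputError(f"all-zero samples: {zero}")
    rel = vals / depths
    return FeatureTable(
        pd.DataFrame(rel, index=counts.data.index, columns=counts.data.columns),
        mode="relative",
        feature_annotations=counts.feature_annotations,
    )


def _rank_label(taxonomy: str, rank: str, feature: str) -> str:
    prefix = _RANK_PREFIX[rank]
    fields = [f.strip() for f in taxonomy.split(";")]
    hits = [f for f in fields if f.startswith(prefix)]
    if not hits:
        raise ValueError(f"taxonomy for {feature!r} lacks rank {rank!r}: {taxonomy!r}")
    label = hits[0][len(prefix):]
    return label if label else "unassigned"


def aggregate_by_rank(table: FeatureTable, rank: str) -> FeatureTable:
    """Sum features sharing a taxonomy label at ``rank``.

    Features without a label at that rank pool into ``"unassigned"``.
    Column sums are preserved.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if table.feature_annotations is None:
        raise ValueError("aggregation requires taxonomy annotations")
    labels = {
        f: _rank_label(str(table.feature_annotations[f]), rank, f)
        for f in table.feature_ids
    }
    grouped = table.data.groupby(pd.Series(labels), sort=True).sum()
    grouped.index.name = table.data.index.name
    return FeatureTable(grouped, mode=table.mode)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def shannon_index(rel: FeatureTable) -> pd.Series:
    """Per-sample Shannon diversity H = -sum p ln p (natural log)."""
    if rel.mode != "relative":
        raise ModeError("Shannon index requires relative abundances")
    vals = rel.values()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(vals > 0, vals * np.log(vals), 0.0)
    return pd.Series(-terms.sum(axis=0), index=rel.sample_ids, name="shannon")


def bray_curtis(rel: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples."""
    if rel.mode != "relative":
        raise ModeError("Bray-Curtis requires relative abundances")
    if rel.n_samples < 2:
        raise DegenerateInputError("need at least two samples")
    condensed = pdist(rel.values().T, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), rel.sample_ids, "braycurtis")


def pcoa(dist: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis (classical metric MDS).

    Double-centers -0.5 * D^2, eigendecomposes, and orders axes by
    eigenvalue. Negative eigenvalues are reported as-is (no correction);
    proportion explained is taken over positive eigenvalues only.
    Coordinates are returned for axes with positive eigenvalues.
    """
    d = dist.values
    if np.isnan(d).any():
        raise ValueError("NaN in distance matrix")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-12 * abs(eigvals).max(initial=0.0))
    n_pos = int(pos.sum())
    k = n_pos if n_axes is None else min(n_axes, n_pos)
    coords = eigvecs[:, :k] * np.sqrt(np.maximum(eigvals[:k], 0.0))
    pos_sum = eigvals[pos].sum()
    prop = np.where(eigvals > 0, eigvals / pos_sum, 0.0)[:k] if pos_sum > 0 else np.zeros(k)
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=dist.sample_ids,
            columns=[f"PCo{i + 1}" for i in range(k)],
        ),
        eigenvalues=eigvals,
        proportion_explained=prop,
        method="PCoA",
    )


# ---------------------------------------------------------------------------
# presence/absence overlap & core taxa
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    """Binary presence/absence overlap structure across sample groups.

    ``presence``: group -> set of detected features (value > 0 in >= 1
    sample of the group). ``intersections``: every nonempty group subset ->
    cardinality of the intersection of its presence sets.
    ``exclusive_regions``: Euler-diagram regions — subset -> number of
    features present in exactly those groups. ``core`` is the intersection
    over all groups; ``core_abundance_fraction`` gives, per group, the share
    of mean relative abundance carried by core features.
    """

    group_order: list[str]
    presence: dict[str, set[str]]
    intersections: dict[frozenset, int]
    exclusive_regions: dict[frozenset, int]
    core: set[str]
    core_abundance_fraction: dict[str, float]


def presence_overlap(
    table: FeatureTable,
    grouping: pd.Series | dict,
    group_order: list[str] | None = None,
) -> OverlapResult:
    """Compute detected-feature overlap between sample groups.

    Works identically for species-, KO-, or gene-level tables: only the
    binary presence/absence structure matters for the sets, while the
    core abundance fraction uses relative abundances (counts tables are
    converted per sample on the fly).
    """
    grouping = pd.Series(grouping)
    missing = [s for s in table.sample_ids if s not in grouping.index]
    if missing:
        raise KeyError(f"samples without a group assignment: {missing[:5]}")
    groups = group_order or sorted(set(grouping.loc[table.sample_ids]))

    vals = table.values()
    if table.mode == "counts":
        depths = vals.sum(axis=0)
        rel = np.divide(vals, depths, out=np.zeros_like(vals), where=depths > 0)
    else:
        rel = vals

    presence: dict[str, set[str]] = {}
    core_frac: dict[str, float] = {}
    features = np.array(table.feature_ids, dtype=object)
    group_mean_rel: dict[str, np.ndarray] = {}
    for g in groups:
        cols = [i for i, s in enumerate(table.sample_ids) if grouping[s] == g]
        if not cols:
            raise KeyError(f"group {g!r} has no samples")
        sub = vals[:, cols]
        presence[g] = set(features[(sub > 0).any(axis=1)])
        group_mean_rel[g] = rel[:, cols].mean(axis=1)

    core = set.intersection(*(presence[g] for g in groups)) if groups else set()

    membership: dict[str, frozenset] = {}
    for f in features:
        pat = frozenset(g for g in groups if f in presence[g])
        if pat:
            membership[f] = pat
    exclusive: dict[frozenset, int] = {}
    for pat in membership.values():
        exclusive[pat] = exclusive.get(pat, 0) + 1

    intersections: dict[frozenset, int] = {}
    for r in range(1, len(groups) + 1):
        for combo in itertools.combinations(groups, r):
            key = frozenset(combo)
            inter = set.intersection(*(presence[g] for g in combo))
            intersections[key] = len(inter)

    core_idx = [i for i, f in enumerate(features) if f in core]
    for g in groups:
        mean_rel = group_mean_rel[g]
        total = mean_rel.sum()
        core_frac[g] = float(mean_rel[core_idx].sum() / total) if total > 0 else 0.0

    return OverlapResult(
        group_order=list(groups),
        presence=presence,
        intersections=intersections,
        exclusive_regions=exclusive,
        core=core,
        core_abundance_fraction=core_frac,
    )


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

def differential_features(
    rel: FeatureTable,
    group_a: list[str],
    group_b: list[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-feature Mann-Whitney comparison of two sample sets with BH FDR.

    Returns a DataFrame indexed by feature with columns
    ``median_a, median_b, log2_fold_change, p, q, significant``. The fold
    change is log2 of (median_a + eps)/(median_b + eps) with eps one tenth
    of the smallest nonzero value in the table, to keep zero medians finite.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise DegenerateInputError("each group needs at least two samples")
    a = rel.data.loc[:, group_a].to_numpy(dtype=float)
    b = rel.data.loc[:, group_b].to_numpy(dtype=float)
    nonzero = rel.values()[rel.values() > 0]
    eps = float(nonzero.min()) / 10.0 if nonzero.size else 1e-12
    rows = []
    for i, fid in enumerate(rel.feature_ids):
        med_a, med_b = float(np.median(a[i])), float(np.median(b[i]))
        if np.all(a[i] == a[i][0]) and np.all(b[i] == b[i][0]) and a[i][0] == b[i][0]:
            p = 1.0
        else:
            p = mann_whitney(a[i], b[i], alternative="two-sided").p_value
        rows.append(
            {
                "feature": fid,
                "median_a": med_a,
                "median_b": med_b,
                "log2_fold_change": math.log2((med_a + eps) / (med_b + eps)),
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out


# ---------------------------------------------------------------------------
# 16S qPCR quantification
# ---------------------------------------------------------------------------

@dataclass
class StandardCurve:
    """Linear qPCR standard curve Ct = intercept + slope * log10(copies)."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")

    @property
    def efficiency(self) -> float:
        """Amplification efficiency: 1.0 means perfect doubling per cycle."""
        return 10 ** (-1.0 / self.slope) - 1.0

    def copies_from_ct(self, ct: float) -> float:
        return 10 ** ((ct - self.intercept) / self.slope)


def fit_standard_curve(standard_cts: pd.DataFrame) -> StandardCurve:
    """Least-squares fit of Ct against log10 template copies.

    ``standard_cts`` needs columns ``log10_copies`` and ``ct``; replicates
    enter as individual points. At least three distinct dilution levels
    are required.
    """
    x = standard_cts["log10_copies"].to_numpy(dtype=float)
    y = standard_cts["ct"].to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise DegenerateInputError("need >= 3 distinct dilution levels")
    res = sps.linregress(x, y)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
    )


def copies_per_gram(
    ct: float,
    curve: StandardCurve,
    dna_per_rxn_ng: float,
    total_dna_ng: float,
    mass_g: float,
) -> float:
    """16S rDNA copies per gram of intestinal content.

    Converts the reaction-level copy number from the standard curve to the
    whole DNA extract (total_dna_ng / dna_per_rxn_ng) and divides by the
    input mass. All scaling factors are explicit arguments.
    """
    if mass_g <= 0 or dna_per_rxn_ng <= 0 or total_dna_ng <= 0:
        raise ValueError("mass and DNA amounts must be positive")
    copies_rxn = curve.copies_from_ct(ct)
    return copies_rxn * (total_dna_ng / dna_per_rxn_ng) / mass_g
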