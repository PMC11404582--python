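"""Immune-profile ordination, dispersion, univariate testing, and the
four-category colonization-by-segment dependence classification.

Each immune population's relative abundance is modeled by OLS against
colonization status (CONV/GF), gut segment (5 ordered levels), and their
interaction. Features are then categorized by which model terms survive
BH FDR control: a significant interaction wins outright ("interaction");
otherwise both significant main effects give "main_effects"; a single
significant main effect gives "microbiome_only" (colonization) or
"segment_only"; nothing significant gives "none".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist

from .containers import (
    DegenerateInputError,
    FeatureTable,
    OrdinationResult,
    SampleMetadata,
)
from .stats import StatResult, benjamini_hochberg, fisher_one_sided, mann_whitney

logger = logging.getLogger(__name__)

__all__ = [
    "zscore_normalize",
    "pca",
    "intersample_dispersion",
    "univariate_colonization_tests",
    "DependenceFit",
    "fit_dependence_model",
    "CategoryAssignment",
    "classify_dependence",
    "EnrichmentResult",
    "category_enrichment",
]

_DEGENERATE_VAR = 1e-12


# ---------------------------------------------------------------------------
# ordination & dispersion
# ---------------------------------------------------------------------------

def zscore_normalize(table: FeatureTable, drop_constant: bool = False) -> FeatureTable:
    """Z-score each feature across samples (mean 0, sd 1, ddof=1).

    Zero-variance features raise (listing the offenders) unless
    ``drop_constant`` is set, in which case they are removed.
    """
    vals = table.values()
    sd = vals.std(axis=1, ddof=1)
    constant = [f for f, s in zip(table.feature_ids, sd) if not s > 0]
    if constant:
        if not drop_constant:
            raise DegenerateInputError(
                f"zero-variance features cannot be z-scored: {constant[:10]}"
            )
        keep = [f for f in table.feature_ids if f not in set(constant)]
        table = table.select_features(keep)
        vals = table.values()
        sd = vals.std(axis=1, ddof=1)
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    frame = pd.DataFrame(z, index=table.data.index, columns=table.data.columns)
    return FeatureTable(frame, mode="zscore",
                        feature_annotations=table.feature_annotations)


def pca(table: FeatureTable, n_axes: int = 2) -> OrdinationResult:
    """PCA of samples in feature space (expects z-scored input).

    Eigendecomposition of the feature covariance across samples via SVD;
    axes are ordered by explained variance, with a deterministic sign
    convention (largest-magnitude loading positive).
    """
    x = table.values().T  # samples x features
    n, p = x.shape
    if n_axes > min(n, p):
        raise ValueError(f"n_axes={n_axes} exceeds min(samples, features)={min(n, p)}")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # sign convention: per component, largest |loading| is positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    var = s ** 2 / (n - 1)
    total = xc.var(axis=0, ddof=1).sum()
    coords = u[:, :n_axes] * s[:n_axes]
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=table.sample_ids,
            columns=[f"PC{i + 1}" for i in range(n_axes)],
        ),
        eigenvalues=var,
        proportion_explained=(var / total)[:n_axes] if total > 0 else np.zeros(n_axes),
        method="PCA",
    )


def intersample_dispersion(
    table: FeatureTable,
    group_labels: pd.Series | dict,
    n_permutations: int = 0,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], StatResult]:
    """Within-group pairwise Euclidean distances and a two-group comparison.

    Computes all pairwise Euclidean distances between samples within each of
    the two groups and compares the distance distributions with a two-sided
    Mann-Whitney test. Pairwise distances are not independent, so that
    p-value is descriptive; set ``n_permutations`` > 0 to replace it with a
    label-permutation p-value on the difference of mean within-group
    distances.
    """
    labels = pd.Series(group_labels)
    groups = sorted(set(labels.loc[table.sample_ids]))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    x = table.values().T
    ids = table.sample_ids
    dists: dict[str, np.ndarray] = {}
    for g in groups:
        idx = [i for i, s in enumerate(ids) if labels[s] == g]
        if len(idx) < 2:
            raise DegenerateInputError(f"group {g!r} has fewer than 2 samples")
        dists[g] = pdist(x[idx], metric="euclidean")
    res = mann_whitney(dists[groups[0]], dists[groups[1]], alternative="two-sided")
    method = res.method + " (descriptive)"
    p = res.p_value
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        lab = np.array([labels[s] for s in ids])
        observed = abs(dists[groups[0]].mean() - dists[groups[1]].mean())
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(lab)
            means = []
            for g in groups:
                idx = np.where(perm == g)[0]
                means.append(pdist(x[idx], metric="euclidean").mean())
            if abs(means[0] - means[1]) >= observed - 1e-15:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
        method = f"permutation({n_permutations})"
    return dists, StatResult(res.statistic, p, method, res.n_x, res.n_y)


# ---------------------------------------------------------------------------
# univariate colonization testing
# ---------------------------------------------------------------------------

def univariate_colonization_tests(
    table: FeatureTable,
    meta: SampleMetadata,
    fdr: float = 0.1,
    stratify_by: tuple[str, ...] = ("segment",),
) -> pd.DataFrame:
    """Per-feature Mann-Whitney CONV-vs-GF tests, optionally per stratum.

    One test per (feature x stratum); BH correction is applied across all
    tests jointly. Strata missing one colonization group are skipped with a
    warning. Returns a long DataFrame with columns
    ``feature, <strata>, n_conv, n_gf, statistic, p, q, significant``.
    """
    mf = meta.frame.loc[table.sample_ids]
    if stratify_by:
        strata = list(mf.groupby(list(stratify_by), observed=True).groups.items())
    else:
        strata = [(("all",), mf.index)]
    rows = []
    for key, samples in strata:
        key = key if isinstance(key, tuple) else (key,)
        sub = mf.loc[samples]
        conv = sub.index[sub["colonization"] == "CONV"]
        gf = sub.index[sub["colonization"] == "GF"]
        if len(conv) == 0 or len(gf) == 0:
            logger.warning("stratum %s lacks a colonization group; skipped", key)
            continue
        a = table.data.loc[:, conv].to_numpy(dtype=float)
        b = table.data.loc[:, gf].to_numpy(dtype=float)
        for i, fid in enumerate(table.feature_ids):
            if np.all(a[i] == a[i][0]) and np.all(b[i] == b[i][0]) and a[i][0] == b[i][0]:
                stat, p = float(len(conv) * len(gf)) / 2, 1.0
            else:
                r = mann_whitney(a[i], b[i], alternative="two-sided")
                stat, p = r.statistic, r.p_value
            row = {"feature": fid}
            row.update({c: (str(k) if not isinstance(k, str) else k)
                        for c, k in zip(stratify_by or ("stratum",), key)})
            row.update({"n_conv": len(conv), "n_gf": len(gf),
                        "statistic": stat, "p": p})
            rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = benjamini_hochberg(out["p"].to_numpy())
        out["significant"] = out["q"] < fdr
    return out


def significant_class_counts(
    results: pd.DataFrame, annotations: pd.Series
) -> pd.Series:
    """Count features significant in >= 1 stratum, per broad lineage class."""
    if not len(results):
        return pd.Series(dtype=int)
    sig = results.loc[results["significant"], "feature"].unique()
    return annotations.loc[list(sig)].value_counts().sort_index()


# ---------------------------------------------------------------------------
# dependence model
# ---------------------------------------------------------------------------

@dataclass
class DependenceFit:
    """Term-wise F tests of the colonization-by-segment OLS model.

    The interaction is tested by a partial F (full vs additive model);
    the main effects are Type-II F tests within the additive model.
    """

    params: pd.Series
    f_interaction: float
    p_interaction: float
    f_colonization: float
    p_colonization: float
    f_segment: float
    p_segment: float
    df_resid: int
    degenerate: bool = False


@dataclass
class _Designs:
    """Shared design matrices for one metadata layout (treatment coding)."""

    full: np.ndarray
    additive: np.ndarray
    segment_only: np.ndarray
    colonization_only: np.ndarray
    full_names: list[str]
    cell_rows: pd.DataFrame  # one full-model row per (colonization, segment)


def _build_designs(meta: SampleMetadata, sample_ids: list[str]) -> _Designs:
    mf = meta.frame.loc[sample_ids]
    segs = meta.segments_present()
    cells = (
        mf.groupby(["colonization", "segment"], observed=True).size()
    )
    for colo in sorted(set(mf["colonization"])):
        for seg in segs:
            n_cell = cells.get((colo, seg), 0)
            if n_cell < 2:
                raise DegenerateInputError(
                    f"design cell ({colo}, {seg}) has {n_cell} observations; need >= 2"
                )
    gf = (mf["colonization"] == "GF").to_numpy(dtype=float)
    seg_dummies = np.column_stack(
        [(mf["segment"] == s).to_numpy(dtype=float) for s in segs[1:]]
    )
    n = len(mf)
    intercept = np.ones((n, 1))
    inter = seg_dummies * gf[:, None]
    full = np.column_stack([intercept, gf[:, None], seg_dummies, inter])
    additive = np.column_stack([intercept, gf[:, None], seg_dummies])
    seg_only = np.column_stack([intercept, seg_dummies])
    col_only = np.column_stack([intercept, gf[:, None]])
    names = (
        ["Intercept", "GF"]
        + [f"segment[{s}]" for s in segs[1:]]
        + [f"GF:segment[{s}]" for s in segs[1:]]
    )
    cell_rows = []
    for colo in ("CONV", "GF"):
        for seg in segs:
            g = 1.0 if colo == "GF" else 0.0
            sdum = [1.0 if seg == s else 0.0 for s in segs[1:]]
            row = [1.0, g] + sdum + [g * d for d in sdum]
            cell_rows.append(pd.Series(row, name=(colo, seg)))
    cells_df = pd.DataFrame(cell_rows)
    cells_df.index = pd.MultiIndex.from_tuples(
        cells_df.index, names=["colonization", "segment"]
    )
    return _Designs(full, additive, seg_only, col_only, names, cells_df)


def _fit_one(y: np.ndarray, d: _Designs) -> tuple[DependenceFit, "sm.regression.linear_model.RegressionResultsWrapper"]:
    full = sm.OLS(y, d.full).fit()
    params = pd.Series(full.params, index=d.full_names)
    n, k = d.full.shape
    if full.ssr / max(n - k, 1) < _DEGENERATE_VAR:
        fit = DependenceFit(
            params=params,
            f_interaction=np.nan, p_interaction=np.nan,
            f_colonization=np.nan, p_colonization=np.nan,
            f_segment=np.nan, p_segment=np.nan,
            df_resid=int(full.df_resid), degenerate=True,
        )
        return fit, full
    additive = sm.OLS(y, d.additive).fit()
    seg_only = sm.OLS(y, d.segment_only).fit()
    col_only = sm.OLS(y, d.colonization_only).fit()
    f_int, p_int, _ = full.compare_f_test(additive)
    f_col, p_col, _ = additive.compare_f_test(seg_only)
    f_seg, p_seg, _ = additive.compare_f_test(col_only)
    fit = DependenceFit(
        params=params,
        f_interaction=float(f_int), p_interaction=float(p_int),
        f_colonization=float(f_col), p_colonization=float(p_col),
        f_segment=float(f_seg), p_segment=float(p_seg),
        df_resid=int(full.df_resid),
    )
    return fit, full


def fit_dependence_model(
    y,
    colonization,
    segment,
    segment_order: tuple[str, ...] | None = None,
) -> DependenceFit:
    """Fit one immune population's colonization-by-segment OLS model.

    ``y`` is the abundance vector; ``colonization`` a CONV/GF factor;
    ``segment`` the segment factor. Every (colonization x segment) cell
    must hold at least two observations. The residual-variance floor
    flags exactly-constant responses as degenerate (no p-values).
    """
    y = np.asarray(y, dtype=float)
    colonization = pd.Series(list(colonization))
    segment = pd.Series(list(segment))
    order = segment_order or tuple(pd.unique(segment))
    ids = [f"s{i}" for i in range(len(y))]
    meta = SampleMetadata(
        pd.DataFrame(
            {"mouse_id": ids, "segment": segment.values,
             "colonization": colonization.values},
            index=ids,
        ),
        segment_order=tuple(order),
    )
    d = _build_designs(meta, ids)
    fit, _ = _fit_one(y, d)
    return fit


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class CategoryAssignment:
    """Per-feature dependence categories with the q-values behind them."""

    table: pd.DataFrame  # q_interaction, q_colonization, q_segment, category
    alpha: float
    family_structure: str = "per-term"

    def counts(self) -> pd.Series:
        return self.table["category"].value_counts()


def _decide(q_int: float, q_col: float, q_seg: float, alpha: float,
            force_assign: bool) -> str:
    if np.isnan(q_int):
        return "degenerate"
    if q_int < alpha:
        return "interaction"
    if q_col < alpha and q_seg < alpha:
        return "main_effects"
    if q_col < alpha:
        return "microbiome_only"
    if q_seg < alpha:
        return "segment_only"
    if force_assign:
        qs = {"interaction": q_int, "microbiome_only": q_col, "segment_only": q_seg}
        return min(qs, key=qs.get)
    return "none"


def classify_dependence(
    table: FeatureTable,
    meta: SampleMetadata,
    alpha: float = 0.05,
    family: str = "per-term",
    force_assign: bool = False,
) -> tuple[CategoryAssignment, pd.DataFrame]:
    """Categorize every immune population by its dependence structure.

    Fits the colonization-by-segment model per feature, applies BH FDR
    either separately within each term family (``family="per-term"``,
    default: interaction, colonization, segment each corrected across
    features) or jointly (``family="global"``), and assigns the category
    by rule precedence: significant interaction first, then both mains,
    then a single main, else "none" (or the smallest-q category when
    ``force_assign`` is set).

    Returns the assignment plus marginal means: model-estimated mean and
    standard error per (feature x colonization x segment) cell, which for a
    balanced design coincide with arithmetic cell means.
    """
    d = _build_designs(meta, table.sample_ids)
    fits: dict[str, DependenceFit] = {}
    mm_rows = []
    for fid in table.feature_ids:
        y = table.data.loc[fid].to_numpy(dtype=float)
        fit, full = _fit_one(y, d)
        fits[fid] = fit
        if not fit.degenerate:
            pred = full.get_prediction(d.cell_rows.to_numpy())
            for (colo, seg), mean, se in zip(
                d.cell_rows.index, pred.predicted_mean, pred.se_mean
            ):
                mm_rows.append(
                    {"feature": fid, "colonization": colo, "segment": seg,
                     "mean": float(mean), "se": float(se)}
                )
    marginal_means = pd.DataFrame(mm_rows)

    feats = table.feature_ids
    p_int = np.array([fits[f].p_interaction for f in feats])
    p_col = np.array([fits[f].p_colonization for f in feats])
    p_seg = np.array([fits[f].p_segment for f in feats])
    if family == "per-term":
        q_int = benjamini_hochberg(p_int)
        q_col = benjamini_hochberg(p_col)
        q_seg = benjamini_hochberg(p_seg)
    elif family == "global":
        stacked = benjamini_hochberg(np.concatenate([p_int, p_col, p_seg]))
        m = len(feats)
        q_int, q_col, q_seg = stacked[:m], stacked[m:2 * m], stacked[2 * m:]
    else:
        raise ValueError(f"unknown family structure {family!r}")

    rows = []
    for i, fid in enumerate(feats):
        rows.append(
            {
                "feature": fid,
                "p_interaction": p_int[i], "q_interaction": q_int[i],
                "p_colonization": p_col[i], "q_colonization": q_col[i],
                "p_segment": p_seg[i], "q_segment": q_seg[i],
                "category": _decide(q_int[i], q_col[i], q_seg[i], alpha,
                                    force_assign),
            }
        )
    assignment = CategoryAssignment(
        table=pd.DataFrame(rows).set_index("feature"),
        alpha=alpha,
        family_structure=family,
    )
    return assignment, marginal_means


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Fisher-exact overrepresentation of annotation labels per category."""

    table: pd.DataFrame  # category, label, 2x2 counts, odds_ratio, p


def category_enrichment(
    assignment: CategoryAssignment,
    labels: pd.Series | dict,
) -> EnrichmentResult:
    """Test each annotation label for overrepresentation in each category.

    ``labels`` maps feature -> label (string) or -> set of labels. For every
    (category, label) pair a 2x2 table of {in/out category} x {has/lacks
    label} is tested one-sided for enrichment.
    """
    labels = pd.Series(labels)
    label_sets = {
        f: (v if isinstance(v, (set, frozenset)) else {v})
        for f, v in labels.items()
    }
    cats = assignment.table["category"]
    all_labels = sorted(set().union(*label_sets.values())) if label_sets else []
    rows = []
    features = list(cats.index)
    for cat in sorted(set(cats)):
        in_cat = [f for f in features if cats[f] == cat]
        out_cat = [f for f in features if cats[f] != cat]
        for lab in all_labels:
            a = sum(1 for f in in_cat if lab in label_sets.get(f, set()))
            b = len(in_cat) - a
            c = sum(1 for f in out_cat if lab in label_sets.get(f, set()))
            dd = len(out_cat) - c
            odds, p = fisher_one_sided(a, b, c, dd)
            rows.append(
                {"category": cat, "label": lab, "in_with": a, "in_without": b,
                 "out_with": c, "out_without": dd, "odds_ratio": odds, "p": p}
            )
    return EnrichmentResult(table=pd.DataFrame(rows))
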