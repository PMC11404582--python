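"""Species-immune association analysis.

Immune abundances are first normalized against the germ-free baseline
(each population divided by its median in the GF group, so GF-relative
fold changes become comparable across populations), then correlated with
microbial species abundances across all matched samples pooled over
segments. Spearman rank correlation is the default; both relative and
absolute (16S-scaled) microbial abundances are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import DegenerateInputError, FeatureTable, SampleMetadata
from .stats import benjamini_hochberg

__all__ = ["gf_median_normalize", "CorrelationResult", "correlate_species_immune"]


def gf_median_normalize(
    immune: FeatureTable, meta: SampleMetadata
) -> tuple[FeatureTable, list[str]]:
    """Divide every immune value by its population's GF-group median.

    Returns the normalized table and the list of features excluded because
    their GF median was zero (division undefined). By construction the GF
    median of every retained output feature is 1.
    """
    gf_samples = [
        s for s in immune.sample_ids
        if meta.frame.loc[s, "colonization"] == "GF"
    ]
    if not gf_samples:
        raise DegenerateInputError("GF group is empty")
    med = immune.data.loc[:, gf_samples].median(axis=1)
    excluded = med.index[med == 0].tolist()
    kept = med.index[med != 0]
    out = immune.data.loc[kept].div(med.loc[kept], axis=0)
    ann = immune.feature_annotations
    if ann is not None:
        ann = ann.loc[kept]
    # normalized values are ratios; keep counts-mode semantics (nonnegative)
    return FeatureTable(out, mode="counts", feature_annotations=ann), excluded


@dataclass
class CorrelationResult:
    """All (species x immune population) correlations with BH q-values.

    ``table`` has one row per pair: ``species, population, r, p, q, n``;
    pairs with a constant input vector are listed in ``skipped``.
    """

    table: pd.DataFrame
    method: str
    skipped: list[tuple[str, str]]


def correlate_species_immune(
    microbes: FeatureTable,
    immune: FeatureTable,
    method: str = "spearman",
) -> CorrelationResult:
    """Correlate every microbial species with every immune population.

    Samples are matched by id (intersection of the two tables); at least
    four shared samples are required. BH correction runs across all
    non-degenerate pairs.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    shared = [s for s in microbes.sample_ids if s in set(immune.sample_ids)]
    if len(shared) < 4:
        raise DegenerateInputError(
            f"only {len(shared)} matched samples; need >= 4"
        )
    mx = microbes.data.loc[:, shared].to_numpy(dtype=float)
    ix = immune.data.loc[:, shared].to_numpy(dtype=float)
    corr = sps.spearmanr if method == "spearman" else sps.pearsonr
    rows, skipped = [], []
    for i, sp in enumerate(microbes.feature_ids):
        x = mx[i]
        x_const = np.all(x == x[0])
        for j, pop in enumerate(immune.feature_ids):
            y = ix[j]
            if x_const or np.all(y == y[0]):
                skipped.append((sp, pop))
                continue
            res = corr(x, y)
            rows.append(
                {"species": sp, "population": pop,
                 "r": float(res.statistic), "p": float(res.pvalue),
                 "n": len(shared)}
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return CorrelationResult(table=out, method=method, skipped=skipped)
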