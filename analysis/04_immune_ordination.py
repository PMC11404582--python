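#!/usr/bin/env python
"""Immune-profile ordination and colonization testing: z-score PCA,
within-group dispersion (CONV vs GF), and per-segment univariate
Mann-Whitney tests at FDR 0.1.

Reads results/data/, writes results/immune/.
"""

import json
from pathlib import Path

from gutseg.containers import FeatureTable, SampleMetadata
from gutseg.immune import (
    intersample_dispersion,
    pca,
    significant_class_counts,
    univariate_colonization_tests,
    zscore_normalize,
)

DATA = Path("results/data")
OUT = Path("results/immune")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = FeatureTable.from_tsv(DATA / "immune_abundances.tsv")
    meta = SampleMetadata.from_tsv(DATA / "immune_metadata.tsv")

    z = zscore_normalize(table, drop_constant=True)
    ords = pca(z, n_axes=2)
    ords.to_tsv(OUT / "pca_coordinates.tsv")
    (OUT / "pca_eigen.json").write_text(
        json.dumps(ords.eigen_summary(), indent=2))
    print(f"PCA: PC1/PC2 explain "
          f"{100 * ords.proportion_explained[0]:.1f}% / "
          f"{100 * ords.proportion_explained[1]:.1f}% of variance")

    dists, disp = intersample_dispersion(z, meta.frame["colonization"])
    print(f"within-group distances: CONV mean {dists['CONV'].mean():.2f}, "
          f"GF mean {dists['GF'].mean():.2f} "
          f"({disp.method}, p = {disp.p_value:.3g})")

    uni = univariate_colonization_tests(table, meta, fdr=0.1)
    uni.to_csv(OUT / "univariate_tests.tsv", sep="\t", index=False,
               float_format="%.10g")
    n_sig = uni.loc[uni["significant"], "feature"].nunique()
    print(f"univariate CONV-vs-GF: {n_sig} of {table.n_features} populations "
          "significant in >= 1 segment (FDR 0.1)")
    if table.feature_annotations is not None:
        counts = significant_class_counts(uni, table.feature_annotations)
        print("significant populations by broad class:", counts.to_dict())


if __name__ == "__main__":
    main()
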