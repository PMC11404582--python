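#!/usr/bin/env python
"""Species-immune association: immune abundances normalized to the GF
median, then Spearman-correlated with microbial relative abundances across
all segments (matched by mouse and segment), BH-corrected.

Reads results/data/ and results/microbiome/, writes results/association/.
"""

from pathlib import Path

from gutseg.association import correlate_species_immune, gf_median_normalize
from gutseg.containers import FeatureTable, SampleMetadata
from gutseg.microbiome import relative_abundance

DATA = Path("results/data")
MICRO = Path("results/microbiome")
OUT = Path("results/association")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    immune = FeatureTable.from_tsv(DATA / "immune_abundances.tsv")
    imm_meta = SampleMetadata.from_tsv(DATA / "immune_metadata.tsv")
    counts = FeatureTable.from_tsv(MICRO / "counts_qc.tsv")
    mic_meta = SampleMetadata.from_tsv(
        DATA / "microbiome_metadata.tsv").subset(counts.sample_ids)

    norm, excluded = gf_median_normalize(immune, imm_meta)
    if excluded:
        print(f"excluded {len(excluded)} populations with zero GF median")

    # match microbiome samples to CONV immune samples by (mouse, segment)
    key_to_imm = {
        (r["mouse_id"], str(r["segment"])): s
        for s, r in imm_meta.frame.iterrows()
        if r["colonization"] == "CONV"
    }
    rename = {
        s: key_to_imm[(r["mouse_id"], str(r["segment"]))]
        for s, r in mic_meta.frame.iterrows()
        if (r["mouse_id"], str(r["segment"])) in key_to_imm
    }
    rel = relative_abundance(counts)
    microbes = FeatureTable(
        rel.data.loc[:, list(rename)].rename(columns=rename), mode="relative")
    print(f"matched {microbes.n_samples} CONV samples across segments")

    res = correlate_species_immune(microbes, norm, method="spearman")
    res.table.to_csv(OUT / "correlations.tsv", sep="\t", index=False,
                     float_format="%.10g")
    n_sig = int((res.table["q"] < 0.05).sum())
    print(f"{len(res.table)} species-population pairs tested; "
          f"{n_sig} significant at q < 0.05; "
          f"{len(res.skipped)} degenerate pairs skipped")
    strongest = res.table.loc[res.table["r"].abs().idxmax()]
    print(f"strongest association: {strongest['species']} ~ "
          f"{strongest['population']} (rho = {strongest['r']:.2f}, "
          f"q = {strongest['q']:.3g})")


if __name__ == "__main__":
    main()
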