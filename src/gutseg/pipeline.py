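"""End-to-end orchestration: simulate -> QC -> diversity/overlap ->
classify -> enrich -> associate -> quantify, with a reproducibility
manifest.

Every stage writes its outputs as plain TSV/JSON under the run directory;
the manifest records the config hash, seed, and a checksum for every file,
so a rerun with the same config and seed reproduces all deterministic
outputs bitwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, immune, microbiome
from .containers import SEGMENTS, FeatureTable, SampleMetadata
from .synthetic import (
    ImmuneSimDesign,
    MicrobiomeSimDesign,
    QpcrSimDesign,
    simulate_immune_abundances,
    simulate_microbiome_counts,
    simulate_qpcr,
)

__all__ = ["RunConfig", "run_pipeline", "demo_config"]


@dataclass
class RunConfig:
    """Configuration of a full synthetic end-to-end run."""

    seed: int = 0
    out_dir: str = "results/run"
    immune_design: ImmuneSimDesign = field(default_factory=ImmuneSimDesign)
    microbiome_design: MicrobiomeSimDesign = field(
        default_factory=MicrobiomeSimDesign
    )
    qpcr_design: QpcrSimDesign = field(default_factory=QpcrSimDesign)
    min_reads: int = 500
    min_prevalence: float = 0.10
    min_total_rel_abundance: float = 1e-4
    blank_dominance_threshold: float = 0.25
    exclude_blank_flagged: bool = True
    alpha: float = 0.05
    univariate_fdr: float = 0.1
    differential_fdr: float = 0.05
    #: segments excluded from hypothesis testing (descriptive only)
    segment_exclusions: tuple[str, ...] = ("duodenum",)

    def __post_init__(self) -> None:
        for name in ("min_prevalence", "min_total_rel_abundance",
                     "blank_dominance_threshold", "alpha", "univariate_fdr",
                     "differential_fdr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion, got {v}")
        # derive per-generator seeds from the run seed
        rng = np.random.default_rng(self.seed)
        subs = rng.integers(0, 2**31 - 1, size=3)
        self.immune_design = dataclasses.replace(
            self.immune_design, seed=int(subs[0]))
        self.microbiome_design = dataclasses.replace(
            self.microbiome_design, seed=int(subs[1]))
        self.qpcr_design = dataclasses.replace(
            self.qpcr_design, seed=int(subs[2]))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["immune_design"]["category_mix"] = dict(
            d["immune_design"]["category_mix"])
        return d

    def config_hash(self) -> str:
        # the output location does not affect the run's scientific identity
        d = self.to_dict()
        d.pop("out_dir", None)
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, typ in (("immune_design", ImmuneSimDesign),
                         ("microbiome_design", MicrobiomeSimDesign),
                         ("qpcr_design", QpcrSimDesign)):
            if key in raw:
                sub = raw[key]
                for f in ("segments", "richness_per_segment", "dilution_points",
                          "sample_true_copies_per_g", "mass_g"):
                    if f in sub and isinstance(sub[f], list):
                        sub[f] = tuple(sub[f])
                raw[key] = typ(**sub)
        if "segment_exclusions" in raw:
            raw["segment_exclusions"] = tuple(raw["segment_exclusions"])
        return cls(**raw)


def demo_config(seed: int = 0, out_dir: str = "results/demo") -> RunConfig:
    """The fully synthetic study-shaped scenario: 5 segments x 2 colonization
    states x 6 mice, 82 immune populations, microbiome richness 80 -> 291."""
    return RunConfig(seed=seed, out_dir=out_dir)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in dependency order; returns the manifest dict.

    Stages never mutate their inputs; all intermediates land on disk under
    ``config.out_dir`` so any stage can be re-examined.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_tsv(df_or_table, name: str) -> Path:
        path = out / name
        if isinstance(df_or_table, (FeatureTable, SampleMetadata)):
            df_or_table.to_tsv(path)
        else:
            df_or_table.to_csv(path, sep="\t", float_format="%.10g")
        written.append(path)
        return path

    def save_json(obj, name: str) -> Path:
        path = out / name
        _write_json(obj, path)
        written.append(path)
        return path

    # ---- stage 1: simulation -------------------------------------------
    imm_table, imm_meta, imm_truth = simulate_immune_abundances(
        config.immune_design)
    mic_table, mic_meta, true_core, blank = simulate_microbiome_counts(
        config.microbiome_design)
    standards, qpcr_samples = simulate_qpcr(config.qpcr_design)

    save_tsv(imm_table, "immune_abundances.tsv")
    save_tsv(imm_meta, "immune_metadata.tsv")
    save_json(
        {
            "categories": imm_truth.categories.to_dict(),
            "colonization_effect": imm_truth.colonization_effect.to_dict(),
            "baseline": imm_truth.baseline,
        },
        "immune_ground_truth.json",
    )
    save_tsv(mic_table, "microbiome_counts.tsv")
    save_tsv(mic_meta, "microbiome_metadata.tsv")
    save_json(sorted(true_core), "true_core_species.json")
    save_tsv(standards, "qpcr_standards.tsv")
    save_tsv(qpcr_samples, "qpcr_samples.tsv")

    # ---- stage 2: microbiome QC ----------------------------------------
    depth_filtered, depth_report = microbiome.filter_low_depth_samples(
        mic_table, config.min_reads)
    blank_report = microbiome.flag_blank_overlap(
        depth_filtered, blank, config.blank_dominance_threshold)
    if config.exclude_blank_flagged and blank_report.discarded_samples:
        depth_filtered = depth_filtered.select_samples(
            blank_report.retained_samples)
    feat_filtered, feat_report = microbiome.filter_rare_features(
        depth_filtered, config.min_prevalence, config.min_total_rel_abundance)
    save_json(
        {
            "low_depth_discards": depth_report.discarded_samples,
            "blank_flagged": blank_report.discarded_samples,
            "feature_discards": feat_report.discarded_features,
            "n_samples_retained": feat_filtered.n_samples,
            "n_features_retained": feat_filtered.n_features,
        },
        "microbiome_qc_report.json",
    )

    # ---- stage 3: diversity, overlap, differential ---------------------
    rel = microbiome.relative_abundance(feat_filtered)
    mic_meta_kept = mic_meta.subset(rel.sample_ids)
    shannon = microbiome.shannon_index(rel)
    save_tsv(shannon.to_frame(), "alpha_diversity.tsv")
    bc = microbiome.bray_curtis(rel)
    save_tsv(
        pd.DataFrame(bc.values, index=bc.sample_ids, columns=bc.sample_ids),
        "bray_curtis.tsv",
    )
    ord_res = microbiome.pcoa(bc, n_axes=2)
    save_tsv(ord_res.coordinates, "pcoa_coordinates.tsv")
    save_json(ord_res.eigen_summary(), "pcoa_eigen.json")

    segment_of = mic_meta_kept.frame["segment"].astype(str)
    overlap = microbiome.presence_overlap(
        rel, segment_of, group_order=mic_meta_kept.segments_present())
    save_json(
        {
            "per_segment_detected": {g: len(s) for g, s in overlap.presence.items()},
            "core_size": len(overlap.core),
            "core_abundance_fraction": overlap.core_abundance_fraction,
        },
        "overlap_summary.json",
    )

    genus = microbiome.aggregate_by_rank(rel, "genus")
    testable = [
        s for s in genus.sample_ids
        if segment_of[s] not in config.segment_exclusions
    ]
    small = [s for s in testable if segment_of[s] in ("duodenum", "jejunum", "ileum")]
    large = [s for s in testable if segment_of[s] in ("cecum", "colon")]
    diff = microbiome.differential_features(
        genus.select_samples(small + large), small, large,
        fdr=config.differential_fdr)
    save_tsv(diff, "differential_genera.tsv")

    # ---- stage 4: immune ordination & classification -------------------
    z = immune.zscore_normalize(imm_table, drop_constant=True)
    imm_pca = immune.pca(z, n_axes=2)
    save_tsv(imm_pca.coordinates, "immune_pca.tsv")
    save_json(imm_pca.eigen_summary(), "immune_pca_eigen.json")

    colo_labels = imm_meta.frame["colonization"]
    dists, disp = immune.intersample_dispersion(z, colo_labels)
    save_json(
        {
            "mean_within_CONV": float(dists["CONV"].mean()),
            "mean_within_GF": float(dists["GF"].mean()),
            "statistic": disp.statistic,
            "p_value": disp.p_value,
            "method": disp.method,
        },
        "dispersion.json",
    )

    uni = immune.univariate_colonization_tests(
        imm_table, imm_meta, fdr=config.univariate_fdr)
    save_tsv(uni.set_index("feature"), "univariate_tests.tsv")

    assignment, marginal_means = immune.classify_dependence(
        imm_table, imm_meta, alpha=config.alpha)
    save_tsv(assignment.table, "dependence_categories.tsv")
    save_tsv(marginal_means.set_index("feature"), "marginal_means.tsv")

    enrich = immune.category_enrichment(
        assignment, imm_table.feature_annotations)
    save_tsv(enrich.table.set_index(["category", "label"]), "enrichment.tsv")

    # ---- stage 5: association ------------------------------------------
    norm_imm, excluded = association.gf_median_normalize(imm_table, imm_meta)
    # match microbiome samples to CONV immune samples via (mouse, segment)
    key_to_imm = {
        (r["mouse_id"], str(r["segment"])): s
        for s, r in imm_meta.frame.iterrows()
        if r["colonization"] == "CONV"
    }
    rename = {}
    for s, r in mic_meta_kept.frame.iterrows():
        key = (r["mouse_id"], str(r["segment"]))
        if key in key_to_imm:
            rename[s] = key_to_imm[key]
    microbes_matched = FeatureTable(
        rel.data.loc[:, list(rename)].rename(columns=rename), mode="relative",
    )
    corr = association.correlate_species_immune(microbes_matched, norm_imm)
    save_tsv(corr.table.set_index(["species", "population"]),
             "species_immune_correlations.tsv")

    # ---- stage 6: qPCR absolute quantification -------------------------
    curve = microbiome.fit_standard_curve(standards)
    quant_rows = []
    for _, row in qpcr_samples.iterrows():
        est = microbiome.copies_per_gram(
            row["ct"], curve,
            dna_per_rxn_ng=1.0,
            total_dna_ng=config.qpcr_design.dna_ratio,
            mass_g=row["mass_g"],
        )
        quant_rows.append(
            {"sample": row["sample"], "ct": row["ct"],
             "copies_per_g": est, "true_copies_per_g": row["true_copies_per_g"]}
        )
    save_tsv(pd.DataFrame(quant_rows).set_index("sample"), "qpcr_quantified.tsv")
    save_json(
        {"slope": curve.slope, "intercept": curve.intercept,
         "r_squared": curve.r_squared, "efficiency": curve.efficiency},
        "standard_curve.json",
    )

    # ---- manifest -------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "files": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(written)
        },
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
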