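"""Seeded synthetic immune, microbiome, and qPCR data generators.

The generators emulate the study design the analysis assumes: five ordered
gut segments (duodenum -> colon) x two colonization states (conventionally
colonized CONV vs germ-free GF) x 6 mice per group. Each generator carries
ground-truth labels so downstream recovery can be tested:

* immune population abundances whose means depend on colonization, segment,
  both, their interaction, or neither (known per-feature category);
* microbial species counts with an oral->aboral richness increase, a core
  species set present in all segments, log-normal relative abundances,
  variable sequencing depth (some samples below the 500-read QC threshold),
  and a single-feature blank contaminant;
* 16S qPCR standard-curve and sample Ct values with a known slope/intercept.

All outputs are deterministic functions of the design (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import COLONIZATIONS, SEGMENTS, FeatureTable, SampleMetadata

__all__ = [
    "ConfigurationError",
    "ImmuneSimDesign",
    "ImmuneGroundTruth",
    "MicrobiomeSimDesign",
    "QpcrSimDesign",
    "CATEGORIES",
    "simulate_immune_abundances",
    "simulate_microbiome_counts",
    "simulate_qpcr",
]

#: Dependence categories an immune population can belong to.
CATEGORIES = ("microbiome_only", "segment_only", "main_effects", "interaction", "none")

#: Category proportions mirroring the observed 82-population split
#: (25 colonization-only, 4 segment-only, 17 both mains, 36 interaction).
STUDY_CATEGORY_MIX = {
    "microbiome_only": 25 / 82,
    "segment_only": 4 / 82,
    "main_effects": 17 / 82,
    "interaction": 36 / 82,
    "none": 0.0,
}


class ConfigurationError(ValueError):
    """An inconsistent simulation design."""


# ---------------------------------------------------------------------------
# immune populations
# ---------------------------------------------------------------------------

@dataclass
class ImmuneSimDesign:
    """Design of the synthetic immune-population dataset.

    ``effect_scale`` is the mean absolute effect in abundance units;
    ``noise_sd`` the residual Gaussian standard deviation. The ratio
    effect_scale/noise_sd controls how recoverable the categories are.
    """

    n_populations: int = 82
    n_mice_per_group: int = 6
    segments: tuple[str, ...] = SEGMENTS
    category_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(STUDY_CATEGORY_MIX)
    )
    effect_scale: float = 4.0
    noise_sd: float = 1.0
    baseline_mean: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice_per_group < 2:
            raise ConfigurationError("need at least 2 mice per group")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.effect_scale < 0:
            raise ConfigurationError("effect_scale must be nonnegative")
        unknown = set(self.category_mix) - set(CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown categories in mix: {sorted(unknown)}")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"category_mix must sum to 1 (got {total})")
        if any(v < 0 for v in self.category_mix.values()):
            raise ConfigurationError("category_mix proportions must be nonnegative")


@dataclass
class ImmuneGroundTruth:
    """True effect structure behind a simulated immune table.

    Effects enter the mean as
    ``baseline + colonization_effect*I(GF) + segment_effect[g]
    + interaction_effect[g]*I(GF)``; segment and interaction vectors are
    zero-sum across segments.
    """

    categories: pd.Series  # feature -> category
    colonization_effect: pd.Series  # feature -> scalar
    segment_effects: pd.DataFrame  # features x segments
    interaction_effects: pd.DataFrame  # features x segments
    baseline: float

    def expected_mean(self, feature: str, colonization: str, segment: str) -> float:
        """Infinite-sample cell mean implied by the effects (pre-truncation)."""
        gf = 1.0 if colonization == "GF" else 0.0
        return float(
            self.baseline
            + gf * self.colonization_effect[feature]
            + self.segment_effects.loc[feature, segment]
            + gf * self.interaction_effects.loc[feature, segment]
        )


def _allocate_counts(mix: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder allocation of n features to categories."""
    cats = [c for c in CATEGORIES if mix.get(c, 0.0) > 0]
    raw = {c: mix[c] * n for c in cats}
    counts = {c: int(np.floor(raw[c])) for c in cats}
    short = n - sum(counts.values())
    for c in sorted(cats, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def _signed_zero_sum(rng: np.random.Generator, scale: float, g: int) -> np.ndarray:
    """Per-level effects of magnitude ``scale`` with random non-constant
    signs, centered to zero-sum so they cannot fold into an intercept."""
    while True:
        signs = rng.choice([-1.0, 1.0], size=g)
        if len(set(signs)) > 1:
            break
    v = signs * scale
    return v - v.mean()


def simulate_immune_abundances(
    design: ImmuneSimDesign,
) -> tuple[FeatureTable, SampleMetadata, ImmuneGroundTruth]:
    """Generate an immune-population abundance table with known dependence
    structure.

    Returns the features x samples table (one column per colonization x
    segment x mouse), the matching sample metadata, and the ground truth.
    Abundances are Gaussian around the category-implied cell means,
    truncated at zero.
    """
    rng = np.random.default_rng(design.seed)
    segs = list(design.segments)
    g = len(segs)
    n = design.n_mice_per_group

    features = [f"pop_{i + 1:03d}" for i in range(design.n_populations)]
    counts = _allocate_counts(design.category_mix, design.n_populations)
    cat_list: list[str] = []
    for c, k in counts.items():
        cat_list.extend([c] * k)
    cat_arr = np.array(cat_list, dtype=object)
    rng.shuffle(cat_arr)
    categories = pd.Series(cat_arr, index=features, name="true_category")

    col_eff = pd.Series(0.0, index=features)
    seg_eff = pd.DataFrame(0.0, index=features, columns=segs)
    int_eff = pd.DataFrame(0.0, index=features, columns=segs)
    for f in features:
        c = categories[f]
        if c in ("microbiome_only", "main_effects", "interaction"):
            col_eff[f] = rng.choice([-1.0, 1.0]) * design.effect_scale
        if c in ("segment_only", "main_effects", "interaction"):
            seg_eff.loc[f] = _signed_zero_sum(rng, design.effect_scale, g)
        if c == "interaction":
            int_eff.loc[f] = _signed_zero_sum(rng, design.effect_scale, g)

    sample_ids, seg_col, colo_col, mouse_col = [], [], [], []
    for colo in COLONIZATIONS:
        for seg in segs:
            for m in range(1, n + 1):
                sample_ids.append(f"{colo}_{seg}_m{m}")
                seg_col.append(seg)
                colo_col.append(colo)
                mouse_col.append(f"{colo}{m}")
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "mouse_id": mouse_col,
                "segment": seg_col,
                "colonization": colo_col,
                "compartment": "LPL",
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
        segment_order=tuple(segs),
    )

    gf = np.array([c == "GF" for c in colo_col], dtype=float)
    seg_idx = np.array([segs.index(s) for s in seg_col])
    means = (
        design.baseline_mean
        + np.outer(col_eff.to_numpy(), gf)
        + seg_eff.to_numpy()[:, seg_idx]
        + int_eff.to_numpy()[:, seg_idx] * gf[None, :]
    )
    values = means + rng.normal(0.0, design.noise_sd, size=means.shape)
    values = np.maximum(values, 0.0)

    # alternate broad lineage labels for enrichment/univariate summaries
    lineages = pd.Series(
        rng.choice(["adaptive", "innate"], size=len(features)),
        index=features,
        name="annotation",
    )
    table = FeatureTable(
        pd.DataFrame(values, index=features, columns=sample_ids),
        mode="counts",
        feature_annotations=lineages,
    )
    truth = ImmuneGroundTruth(
        categories=categories,
        colonization_effect=col_eff,
        segment_effects=seg_eff,
        interaction_effects=int_eff,
        baseline=design.baseline_mean,
    )
    return table, meta, truth


# ---------------------------------------------------------------------------
# microbiome counts
# ---------------------------------------------------------------------------

@dataclass
class MicrobiomeSimDesign:
    """Design of the synthetic microbial count table.

    Species pools are nested along the segment order, so richness increases
    oral->aboral (defaults follow the observed 80 -> 291 species gradient)
    and a ``core_size`` set of species is shared by all segments. Per-species
    relative abundances are log-normal; reads are multinomial at a log-normal
    depth, with ``low_depth_fraction`` of samples forced under 500 reads.
    """

    richness_per_segment: tuple[int, ...] = (80, 120, 150, 250, 291)
    core_size: int = 72
    n_samples_per_segment: int = 6
    segments: tuple[str, ...] = SEGMENTS
    depth_log10_mean: float = 4.0
    depth_log10_sd: float = 0.3
    low_depth_fraction: float = 0.2
    lognormal_sigma: float = 2.0
    core_boost: float = 10.0
    blank_contaminant: bool = True
    n_contaminated_samples: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        r = self.richness_per_segment
        if len(r) != len(self.segments):
            raise ConfigurationError("richness vector length must match segments")
        if any(b < a for a, b in zip(r, r[1:])):
            raise ConfigurationError("richness must be nondecreasing oral->aboral")
        if self.core_size > min(r):
            raise ConfigurationError(
                f"core_size {self.core_size} exceeds minimum richness {min(r)}"
            )
        if not 0.0 <= self.low_depth_fraction <= 1.0:
            raise ConfigurationError("low_depth_fraction must be a proportion")
        if self.n_samples_per_segment < 1:
            raise ConfigurationError("need at least one sample per segment")


_PHYLA = ("Bacillota", "Bacteroidota", "Pseudomonadota", "Actinomycetota",
          "Verrucomicrobiota")


def _taxonomy(i: int) -> str:
    phylum = _PHYLA[i % len(_PHYLA)]
    genus = f"Genus{i // 3 + 1}"
    return (
        f"k__Bacteria;p__{phylum};c__;o__;f__Family{i // 9 + 1};"
        f"g__{genus};s__Species{i + 1}"
    )


def simulate_microbiome_counts(
    design: MicrobiomeSimDesign,
) -> tuple[FeatureTable, SampleMetadata, set[str], FeatureTable]:
    """Generate nested-pool microbial counts plus a blank profile.

    Returns ``(counts, metadata, true_core, blank_profile)``. The first
    ``core_size`` species form the core and get a ``core_boost`` abundance
    multiplier so ample sequencing depth detects them in every segment. If
    ``blank_contaminant`` is set, the blank profile holds one contaminant
    feature that is also injected at ~80% relative abundance into
    ``n_contaminated_samples`` non-blank samples.
    """
    rng = np.random.default_rng(design.seed)
    segs = list(design.segments)
    richness = list(design.richness_per_segment)
    total_species = max(richness)
    species = [f"mOTU_{i + 1:04d}" for i in range(total_species)]
    core_n = design.core_size
    core = set(species[:core_n])

    # Species pools: every pool contains the core; non-core extras are the
    # first k_g entries of the shared non-core list EXCEPT for the first
    # (smallest) segment, whose extras come from the top of that list (the
    # last segment's exclusive range). This keeps pools realistically
    # overlapping while making the intersection of all pools exactly the
    # core set, so noise-free detection recovers true_core exactly.
    k = [r - core_n for r in richness]
    big = max(k)
    noncore_idx = np.arange(core_n, core_n + big)
    pools: list[np.ndarray] = []
    for si in range(len(segs)):
        if si == 0 and len(segs) > 1 and k[0] > 0:
            extras = noncore_idx[big - k[0]:]
        else:
            extras = noncore_idx[: k[si]]
        pools.append(np.concatenate([np.arange(core_n), extras]))

    sample_ids, seg_col = [], []
    for seg in segs:
        for k in range(1, design.n_samples_per_segment + 1):
            sample_ids.append(f"{seg}_s{k}")
            seg_col.append(seg)
    n_total = len(sample_ids)

    n_low = int(round(design.low_depth_fraction * n_total))
    low_idx = set(rng.choice(n_total, size=n_low, replace=False).tolist())

    counts = np.zeros((total_species, n_total), dtype=int)
    for si, seg in enumerate(segs):
        pool = pools[si]
        base = rng.lognormal(mean=0.0, sigma=design.lognormal_sigma,
                             size=pool.size)
        # persistent core taxa are not vanishingly rare: clip their base
        # abundance at the log-normal median before boosting
        base[:core_n] = np.maximum(base[:core_n], 1.0) * design.core_boost
        p = base / base.sum()
        for rep in range(design.n_samples_per_segment):
            j = si * design.n_samples_per_segment + rep
            if j in low_idx:
                depth = int(rng.integers(50, 500))
            else:
                depth = max(500, int(round(10 ** rng.normal(
                    design.depth_log10_mean, design.depth_log10_sd))))
            counts[pool, j] = rng.multinomial(depth, p)

    frame = pd.DataFrame(counts, index=species, columns=sample_ids)
    annotations = pd.Series([_taxonomy(i) for i in range(total_species)],
                            index=species, name="annotation")

    blank_frame = pd.DataFrame(index=pd.Index([], name="feature_id"),
                               columns=["blank"], dtype=float).fillna(0.0)
    if design.blank_contaminant:
        contaminant = "mOTU_contaminant"
        blank_frame = pd.DataFrame({"blank": [1000]}, index=[contaminant])
        row = np.zeros(n_total, dtype=int)
        hit = rng.choice(
            [j for j in range(n_total) if j not in low_idx],
            size=design.n_contaminated_samples, replace=False)
        for j in np.atleast_1d(hit):
            # 4x the sample's own reads => ~80% relative abundance
            row[j] = 4 * int(frame.iloc[:, j].sum())
        frame.loc[contaminant] = row
        annotations.loc[contaminant] = (
            "k__Bacteria;p__Pseudomonadota;c__;o__;f__ContaminantFamily;"
            "g__ContaminantGenus;s__ContaminantSpecies"
        )

    meta = SampleMetadata(
        pd.DataFrame(
            {
                "mouse_id": [f"CONV{k % design.n_samples_per_segment + 1}"
                             for k in range(n_total)],
                "segment": seg_col,
                "colonization": "CONV",
                "compartment": "other",
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
        segment_order=tuple(segs),
    )
    table = FeatureTable(frame, mode="counts", feature_annotations=annotations)
    blank = FeatureTable(blank_frame.astype(float), mode="counts")
    return table, meta, core, blank


# ---------------------------------------------------------------------------
# 16S qPCR
# ---------------------------------------------------------------------------

@dataclass
class QpcrSimDesign:
    """Design of the synthetic 16S qPCR experiment.

    The standard curve is a 10-fold serial dilution spanning 10^0..10^9
    template copies measured in triplicate; Ct values follow
    ``intercept + slope * log10(copies)`` with Gaussian noise. The default
    slope -3.3219 corresponds to 100% amplification efficiency.
    ``dna_ratio`` is total extracted DNA over DNA loaded per reaction.
    """

    slope: float = -3.3219
    intercept: float = 38.0
    dilution_points: tuple[float, ...] = tuple(float(k) for k in range(10))
    replicates: int = 3
    sample_true_copies_per_g: tuple[float, ...] = (1e11, 1e10, 1e8, 1e6)
    mass_g: tuple[float, ...] = (0.05, 0.05, 0.05, 0.05)
    dna_ratio: float = 100.0
    noise_sd_ct: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ConfigurationError("standard-curve slope must be negative")
        if self.replicates < 1:
            raise ConfigurationError("need at least one replicate")
        if len(self.sample_true_copies_per_g) != len(self.mass_g):
            raise ConfigurationError("sample copies and masses must align")
        if any(c <= 0 for c in self.sample_true_copies_per_g):
            raise ConfigurationError("sample copies must be positive")
        if any(m <= 0 for m in self.mass_g):
            raise ConfigurationError("sample masses must be positive")
        if self.noise_sd_ct < 0:
            raise ConfigurationError("noise_sd_ct must be nonnegative")


def simulate_qpcr(design: QpcrSimDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate standard-curve and sample Ct tables.

    Returns ``(standard_cts, sample_cts)``: the former with columns
    ``log10_copies, replicate, ct``; the latter with
    ``sample, ct, mass_g, true_copies_per_g``.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for lvl in design.dilution_points:
        for r in range(1, design.replicates + 1):
            ct = design.intercept + design.slope * lvl
            if design.noise_sd_ct > 0:
                ct += rng.normal(0.0, design.noise_sd_ct)
            rows.append({"log10_copies": lvl, "replicate": r, "ct": ct})
    standards = pd.DataFrame(rows)

    sample_rows = []
    for i, (copies_g, mass) in enumerate(
        zip(design.sample_true_copies_per_g, design.mass_g), start=1
    ):
        copies_rxn = copies_g * mass / design.dna_ratio
        if copies_rxn <= 0:
            raise ConfigurationError("nonpositive copies per reaction")
        ct = design.intercept + design.slope * np.log10(copies_rxn)
        if design.noise_sd_ct > 0:
            ct += rng.normal(0.0, design.noise_sd_ct)
        sample_rows.append(
            {"sample": f"sample_{i}", "ct": ct, "mass_g": mass,
             "true_copies_per_g": copies_g}
        )
    samples = pd.DataFrame(sample_rows)
    return standards, samples
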