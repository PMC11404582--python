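import numpy as np
import pandas as pd
import pytest

from gutseg.containers import FeatureTable, SampleMetadata, SEGMENTS
from gutseg.synthetic import (
    ImmuneSimDesign,
    MicrobiomeSimDesign,
    QpcrSimDesign,
    simulate_immune_abundances,
    simulate_microbiome_counts,
)


@pytest.fixture(scope="session")
def immune_dataset():
    """Default study-shaped immune simulation (82 populations)."""
    return simulate_immune_abundances(ImmuneSimDesign(seed=11))


@pytest.fixture(scope="session")
def microbiome_dataset():
    """Ample-depth microbial counts with the 80->291 richness gradient."""
    return simulate_microbiome_counts(
        MicrobiomeSimDesign(seed=1, low_depth_fraction=0.0)
    )


@pytest.fixture
def toy_counts():
    """3 features x 3 samples counts table with a taxonomy annotation."""
    data = pd.DataFrame(
        {"s1": [10, 30, 0], "s2": [5, 5, 10], "s3": [0, 0, 100]},
        index=["f1", "f2", "f3"],
    )
    ann = pd.Series(
        {
            "f1": "k__Bacteria;p__P1;c__;o__;f__F1;g__G1;s__S1",
            "f2": "k__Bacteria;p__P1;c__;o__;f__F1;g__G1;s__S2",
            "f3": "k__Bacteria;p__P2;c__;o__;f__F2;g__G2;s__S3",
        }
    )
    return FeatureTable(data, mode="counts", feature_annotations=ann)


def balanced_metadata(n_per_cell: int = 6, segments=SEGMENTS) -> SampleMetadata:
    rows, ids = [], []
    for colo in ("CONV", "GF"):
        for seg in segments:
            for m in range(1, n_per_cell + 1):
                ids.append(f"{colo}_{seg}_m{m}")
                rows.append({"mouse_id": f"{colo}{m}", "segment": seg,
                             "colonization": colo, "compartment": "LPL"})
    return SampleMetadata(pd.DataFrame(rows, index=ids),
                          segment_order=tuple(segments))


@pytest.fixture
def balanced_meta():
    return balanced_metadata()
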