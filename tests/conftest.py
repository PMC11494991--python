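import numpy as np
import pandas as pd
import pytest

from gmrc_screen.tables import FeatureTable, SampleMetadata, TaxonomyMap


def make_table(counts, taxa=None, samples=None) -> FeatureTable:
    counts = np.asarray(counts)
    taxa = taxa or [f"t{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    return FeatureTable(pd.DataFrame(counts, index=taxa, columns=samples))


def make_metadata(rows) -> SampleMetadata:
    """rows: (sample_id, culture_status, disease_status, treatment_id, replicate)."""
    return SampleMetadata(
        pd.DataFrame(
            [
                {
                    "sample_id": sid,
                    "group_label": sid.rsplit("_", 1)[0],
                    "culture_status": cult,
                    "disease_status": dis,
                    "treatment_id": treat,
                    "replicate": rep,
                }
                for sid, cult, dis, treat, rep in rows
            ]
        )
    )


def two_group_metadata(group_a, n_a, group_b, n_b) -> SampleMetadata:
    """Metadata for a plain A-vs-B comparison using group_label matching."""
    rows = []
    for g, n, dis in ((group_a, n_a, "control"), (group_b, n_b, "model")):
        for i in range(n):
            rows.append((f"{g}_{i + 1}", "uncultured", dis, "none", i + 1))
    return make_metadata(rows)


@pytest.fixture
def simple_taxonomy():
    return TaxonomyMap(
        {
            "otu1": ("k__Bacteria", "p__Firmicutes", "c__Bacilli", "o__Lactobacillales",
                     "f__Lactobacillaceae", "g__Lactobacillus"),
            "otu2": ("k__Bacteria", "p__Firmicutes", "c__Bacilli", "o__Lactobacillales",
                     "f__Lactobacillaceae", "g__Lactobacillus"),
            "otu3": ("k__Bacteria", "p__Bacteroidota", "c__Bacteroidia", "o__Bacteroidales",
                     "f__Bacteroidaceae", "g__Bacteroides"),
            "otu4": ("k__Bacteria", "p__Firmicutes", "c__Clostridia", "o__Oscillospirales",
                     "f__Oscillospiraceae", "g__"),
            "otu5": ("k__Bacteria", "p__Proteobacteria", "c__Gammaproteobacteria",
                     "o__Enterobacterales", "f__Enterobacteriaceae", "g__Escherichia-Shigella"),
        }
    )
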