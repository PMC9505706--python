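import numpy as np
import pandas as pd
import pytest

from taxrisk.taxa_io import OtuTable, SampleMetadata, TaxonLineage


@pytest.fixture
def small_otu_file(tmp_path):
    """2-sample x 3-OTU QIIME-classic table on disk."""
    path = tmp_path / "otu.tsv"
    path.write_text(
        "# Constructed fixture\n"
        "#OTU ID\tS1\tS2\ttaxonomy\n"
        "OTU1\t5\t0\tD_0__Bacteria;D_1__Firmicutes;D_2__Clostridia;"
        "D_3__Clostridiales;D_4__Lachnospiraceae;D_5__Blautia\n"
        "OTU2\t7\t2\tD_0__Bacteria;D_1__Firmicutes;D_2__Clostridia;"
        "D_3__Clostridiales;D_4__Lachnospiraceae;D_5__Blautia\n"
        "OTU3\t1\t3\tD_0__Bacteria;D_1__Bacteroidetes;D_2__Bacteroidia;"
        "D_3__Bacteroidales;D_4__Bacteroidaceae;D_5__Bacteroides\n"
    )
    return path


@pytest.fixture
def small_metadata_file(tmp_path):
    path = tmp_path / "meta.tsv"
    path.write_text(
        "sample_id\tgroup\nS1\tNormal\nS2\tHFD\nS3\tNormal\nS4\tHFD\n")
    return path


def _lineage(genus, family="F1", order="O1", class_="C1", phylum="P1"):
    return TaxonLineage("Bacteria", phylum, class_, order, family, genus)


@pytest.fixture
def toy_table():
    """3 OTUs, two sharing a genus, in-memory."""
    lineages = [_lineage("Blautia"), _lineage("Blautia"),
                _lineage("Bacteroides", family="F2", order="O2")]
    counts = np.array([[5, 7, 1], [0, 2, 3]])
    return OtuTable(["s1", "s2"], ["OTU1", "OTU2", "OTU3"], counts, lineages)


@pytest.fixture
def toy_metadata():
    return SampleMetadata({"s1": "HC", "s2": "IBD"})


@pytest.fixture
def two_group_frame():
    """50 vs 50 samples, 5 features, one strongly shifted."""
    rng = np.random.default_rng(42)
    base = rng.lognormal(0, 1, size=(100, 5))
    base[50:, 0] *= 8.0
    df = pd.DataFrame(base, index=[f"s{i}" for i in range(100)],
                      columns=[f"f{i}" for i in range(5)])
    meta = SampleMetadata({f"s{i}": ("ctrl" if i < 50 else "case")
                           for i in range(100)})
    return df, meta
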