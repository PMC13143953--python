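import numpy as np
import pandas as pd
import pytest

from mikkexpr import GenerativeConfig, generate_expression, generate_snp_data


@pytest.fixture(scope="session")
def default_config() -> GenerativeConfig:
    return GenerativeConfig(seed=7)


@pytest.fixture(scope="session")
def dataset(default_config):
    """One study-scale synthetic dataset (25 lines x 4 samples)."""
    expression, metadata = generate_expression(default_config)
    return expression, metadata


@pytest.fixture(scope="session")
def snp_dataset(default_config, dataset):
    _, metadata = dataset
    panel, counts, swap_log = generate_snp_data(default_config, metadata)
    return panel, counts, swap_log


@pytest.fixture()
def tiny_panel() -> pd.DataFrame:
    """Three-line panel of four exonic SNPs with distinct genotypes."""
    return pd.DataFrame(
        {
            "snp_id": ["s1", "s2", "s3", "s4"],
            "chrom": ["1", "3", "5", "7"],
            "pos": [100, 200, 300, 400],
            "region": ["exon"] * 4,
            "mean_depth": [30.0] * 4,
            "LA": [0, 0, 2, 2],
            "LB": [2, 2, 0, 0],
            "LC": [0, 2, 0, 2],
        }
    )


def perfect_counts(panel: pd.DataFrame, line: str, depth: int = 20) -> pd.DataFrame:
    """Allele counts that exactly reproduce one line's genotypes."""
    alt = (panel[line].to_numpy() / 2 * depth).astype(int)
    return pd.DataFrame(
        {
            "sample_id": "sample",
            "snp_id": panel["snp_id"],
            "ref_count": depth - alt,
            "alt_count": alt,
        }
    )
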