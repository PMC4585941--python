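import numpy as np
import pandas as pd
import pytest

from reporterpath import parse_network, pvalue_to_z

TOY_TSV = (
    "reaction\tmetabolites\tgenes\tpathways\n"
    "R1\tA // B\tg1\tP1\n"
    "R2\tB // C\tg2 // g3\tP1\n"
    "R3\tC // D\tg4\tP2\n"
)


@pytest.fixture
def toy_network_file(tmp_path):
    path = tmp_path / "network.tsv"
    path.write_text(TOY_TSV)
    return path


@pytest.fixture
def toy_network(toy_network_file):
    return parse_network(toy_network_file)


def make_gene_stats(p_values: dict, signs: dict | None = None) -> pd.DataFrame:
    """Build a gene statistic table directly from a gene -> p mapping."""
    genes = sorted(p_values)
    p = np.array([p_values[g] for g in genes], dtype=float)
    sign = np.array([(signs or {}).get(g, 1) for g in genes], dtype=int)
    return pd.DataFrame(
        {"p_value": p, "z": pvalue_to_z(p), "sign": sign},
        index=pd.Index(genes, name="gene"),
    )


def random_gene_stats(genes, rng) -> pd.DataFrame:
    """Uniform random p-values with random signs (a null transcriptome)."""
    p = {g: float(x) for g, x in zip(sorted(genes), rng.uniform(1e-6, 1 - 1e-6, len(genes)))}
    s = {g: int(x) for g, x in zip(sorted(genes), rng.choice([-1, 1], len(genes)))}
    return make_gene_stats(p, s)
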