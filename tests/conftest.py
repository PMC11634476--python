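import numpy as np
import pandas as pd
import pytest

from mrlink import SumstatsTable, SimConfig, simulate_chain
from mrlink.model import MRModel


def make_sumstats(rows, label="trait"):
    """Build a SumstatsTable from a list of row dicts (tests only)."""
    defaults = {"chrom": "1", "pos": 1000, "eaf": 0.3, "n": 10_000}
    full = []
    for i, row in enumerate(rows):
        r = dict(defaults)
        r.setdefault("pos", 1000 + i)
        r.update(row)
        full.append(r)
    df = pd.DataFrame(full)
    df["pos"] = df["pos"].astype("Int64")
    df["n"] = df["n"].astype("Int64")
    cols = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pval", "n"]
    return SumstatsTable(label, df[cols])


def make_harmonized(gamma, se_gamma, Gamma, se_Gamma):
    """HarmonizedSet straight from effect arrays (tests only)."""
    df = pd.DataFrame({
        "gamma": np.asarray(gamma, float),
        "se_gamma": np.asarray(se_gamma, float),
        "Gamma": np.asarray(Gamma, float),
        "se_Gamma": np.asarray(se_Gamma, float),
    })
    return MRModel.from_dataframe(df).data


def random_harmonized(rng, n_snp=8):
    g = rng.normal(0, 0.2, n_snp)
    g[np.abs(g) < 0.01] = 0.05
    return make_harmonized(
        g, rng.uniform(0.005, 0.02, n_snp),
        rng.normal(0, 0.1, n_snp), rng.uniform(0.005, 0.05, n_snp))


@pytest.fixture(scope="session")
def chain():
    """One clean simulated exposure/mediator/outcome trio, shared read-only."""
    return simulate_chain(SimConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)
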