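import numpy as np
import pandas as pd
import pytest

from gers.formats import GenotypePanel, GwasSumstats, harmonize
from gers.impute import impute_and_standardize
from gers.simulate import SimConfig, simulate_all
from gers.twas import run_twas


def make_panel(calls, chrom="1", pos_start=1000, pos_step=1000,
               a1="A", a2="G", prefix="S"):
    """Tiny GenotypePanel from an explicit call matrix."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    samples = pd.DataFrame({"FID": [f"{prefix}{i}" for i in range(n)],
                            "IID": [f"{prefix}{i}" for i in range(n)]})
    variants = pd.DataFrame({
        "chrom": [chrom] * m,
        "id": [f"v{j}" for j in range(m)],
        "pos": [pos_start + j * pos_step for j in range(m)],
        "a1": [a1] * m, "a2": [a2] * m})
    return GenotypePanel(samples, variants, calls)


def make_assocs(p_values, chrom="1", start0=1_000_000, spacing=2_000_000,
                width=100_000, z=None, panel="panelX"):
    """FeatureAssoc table with evenly spaced gene intervals."""
    p = np.asarray(p_values, float)
    if z is None:
        from scipy import stats
        z = stats.norm.isf(p / 2)
    return pd.DataFrame({
        "panel_id": panel,
        "feature_id": [f"F{i}" for i in range(len(p))],
        "gene_id": [f"G{i}" for i in range(len(p))],
        "chrom": str(chrom),
        "start": [start0 + i * spacing for i in range(len(p))],
        "end": [start0 + i * spacing + width for i in range(len(p))],
        "z_twas": z, "p_twas": p})


@pytest.fixture(scope="session")
def simdata():
    return simulate_all(SimConfig(n_ref=300, n_target=800, n_gwas=4000,
                                  n_genes=24, seed=7))


@pytest.fixture(scope="session")
def harm(simdata):
    return harmonize(simdata.sumstats, simdata.weight_sets, simdata.ref,
                     simdata.target,
                     hapmap3_ids=set(simdata.variants["id"]))


@pytest.fixture(scope="session")
def twas_table(harm):
    return pd.concat([run_twas(harm.sumstats, ws, harm.ref)
                      for ws in harm.weight_sets], ignore_index=True)


@pytest.fixture(scope="session")
def expr_pair(harm):
    """(target, reference) standardized expression for panel0."""
    return impute_and_standardize(harm.target, harm.ref, harm.weight_sets[0])
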