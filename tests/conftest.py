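import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import behavarch as ba
from behavarch.simulate import PanelSimConfig, TraitArchitecture, gen_genotypes, gen_phenotypes

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def qtl_table() -> pd.DataFrame:
    """Default synthetic compiled-QTL table (1007 loci, 10 categories)."""
    return ba.gen_qtl_table(ba.QtlSimConfig(seed=42))


@pytest.fixture(scope="session")
def small_panel():
    """200 inbred lines x 500 SNPs with one h2=0.5 trait."""
    causal = np.arange(0, 50)
    cfg = PanelSimConfig(
        n_lines=200,
        n_snps=500,
        traits=[TraitArchitecture("t0", causal, h2=0.5)],
        seed=7,
    )
    panel = gen_genotypes(cfg)
    phen = gen_phenotypes(panel, cfg)
    return panel, phen


@pytest.fixture()
def toy_outbred_panel():
    """3 lines x 2 SNPs with hand-checkable dosages (outbred coding)."""
    from behavarch.panel import GenotypePanel

    snps = pd.DataFrame(
        {"chrom": ["1", "1"], "pos": [100, 200], "a1": ["A", "C"], "a2": ["T", "G"]},
        index=pd.Index(["s1", "s2"], name="snp_id"),
    )
    dosages = np.array([[0.0, 2.0], [2.0, 0.0], [2.0, 2.0]])
    return GenotypePanel(
        line_ids=["l1", "l2", "l3"], snps=snps, dosages=dosages, inbred=False
    )
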