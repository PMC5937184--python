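import numpy as np
import pandas as pd

from behavarch.panel import GenotypePanel


def panel_from_dosages(dosages, inbred=False) -> GenotypePanel:
    """Wrap a raw dosage matrix in a panel with generic SNP metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snps = pd.DataFrame(
        {
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1) * 10,
            "a1": ["A"] * m,
            "a2": ["T"] * m,
        },
        index=pd.Index([f"s{j}" for j in range(m)], name="snp_id"),
    )
    return GenotypePanel(
        line_ids=[f"l{i}" for i in range(n)],
        snps=snps,
        dosages=dosages,
        inbred=inbred,
    )
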