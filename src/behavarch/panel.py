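"""Genotype panel container for inbred-line (or outbred) SNP dosage data.

The central in-memory object for the heritability and association modules:
a lines x SNPs dosage matrix (0/1/2 copies of the alternate allele, NaN for
missing) together with SNP metadata, mirroring what a plink bed/bim/fam
triple holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyPanelError, UnknownIdError


@dataclass
class GenotypePanel:
    """Lines x SNPs dosage matrix with SNP metadata.

    Parameters
    ----------
    line_ids : sequence of str
        One identifier per line (row of ``dosages``).
    snps : pandas.DataFrame
        SNP metadata indexed by SNP id with columns ``chrom``, ``pos``
        (1-based), ``a1`` (alternate/minor allele counted by the dosage)
        and ``a2`` (reference allele).
    dosages : ndarray, shape (n_lines, n_snps)
        Counts of the a1 allele in {0, 1, 2}; ``nan`` marks missing calls.
    inbred : bool
        True when lines are fully inbred, so dosages are effectively {0, 2}.
    """

    line_ids: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray
    inbred: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.line_ids = list(self.line_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.line_ids), len(self.snps)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.snps)} SNPs"
            )
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> pd.Index:
        return self.snps.index

    def allele_freqs(self) -> np.ndarray:
        """Per-SNP frequency of the counted (a1) allele on non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_freqs(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, snp_ids) -> "GenotypePanel":
        """Panel restricted to the named SNPs, preserving their stored order."""
        snp_ids = pd.Index(snp_ids)
        missing = snp_ids.difference(self.snps.index)
        if len(missing):
            raise UnknownIdError(f"unknown SNP ids: {list(missing[:5])!r}")
        keep = self.snps.index.isin(snp_ids)
        if not keep.any():
            raise EmptyPanelError("SNP subset is empty")
        return GenotypePanel(
            line_ids=self.line_ids,
            snps=self.snps.loc[keep].copy(),
            dosages=self.dosages[:, keep].copy(),
            inbred=self.inbred,
            metadata=dict(self.metadata),
        )

    def subset_lines(self, line_ids) -> "GenotypePanel":
        index = {lid: i for i, lid in enumerate(self.line_ids)}
        try:
            rows = [index[lid] for lid in line_ids]
        except KeyError as exc:
            raise UnknownIdError(f"unknown line id: {exc.args[0]!r}") from exc
        if not rows:
            raise EmptyPanelError("line subset is empty")
        return GenotypePanel(
            line_ids=[self.line_ids[i] for i in rows],
            snps=self.snps.copy(),
            dosages=self.dosages[rows, :].copy(),
            inbred=self.inbred,
            metadata=dict(self.metadata),
        )
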