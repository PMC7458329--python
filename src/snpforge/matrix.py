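"""Biallelic genotype call matrix with sample and SNP metadata.

Calls are stored as an integer-coded :class:`pandas.DataFrame` (samples x
SNPs): ``0`` = AA (homozygous major/ref design allele), ``1`` = AB, ``2`` =
BB, ``-1`` = NoCall.  Letter codes used in CSV interchange map 1:1 onto the
integer codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CALL_AA = 0
CALL_AB = 1
CALL_BB = 2
NO_CALL = -1

LETTER_TO_CODE = {"AA": CALL_AA, "AB": CALL_AB, "BB": CALL_BB, "NoCall": NO_CALL}
CODE_TO_LETTER = {v: k for k, v in LETTER_TO_CODE.items()}

#: columns every sample-metadata table carries
SAMPLE_META_COLUMNS = ("population", "region", "duplicate_of", "dqc")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs biallelic calls plus sample/SNP metadata.

    Parameters
    ----------
    calls
        Integer-coded calls, index = sample ids, columns = SNP ids.
    samples
        Metadata indexed by sample id with at least the columns
        ``population``, ``region``, ``duplicate_of`` and ``dqc``.
    snps
        Per-SNP metadata indexed by SNP id (at least a ``source`` column
        when array-performance stratification is wanted).
    """

    calls: pd.DataFrame
    samples: pd.DataFrame
    snps: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.calls.index.equals(self.samples.index):
            raise ValueError("calls index and sample metadata index differ")
        if not len(self.snps):
            self.snps = pd.DataFrame(index=self.calls.columns)
        elif not self.calls.columns.equals(self.snps.index):
            raise ValueError("calls columns and SNP metadata index differ")
        for col in SAMPLE_META_COLUMNS:
            if col not in self.samples.columns:
                self.samples[col] = np.nan
        bad = self.samples["duplicate_of"].dropna()
        unknown = set(bad) - set(self.samples.index)
        if unknown:
            raise ValueError(f"duplicate_of references unknown samples: {sorted(unknown)}")
        self.calls = self.calls.astype(np.int8)

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.calls.to_numpy()

    def populations(self) -> pd.Series:
        return self.samples["population"]

    def regions(self) -> pd.Series:
        return self.samples["region"]

    # -- views -----------------------------------------------------------
    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        ids = list(sample_ids)
        sub = self.samples.loc[ids].copy()
        # drop dangling duplicate links so the invariant keeps holding
        keep = set(ids)
        sub["duplicate_of"] = sub["duplicate_of"].where(sub["duplicate_of"].isin(keep))
        return GenotypeMatrix(self.calls.loc[ids].copy(), sub, self.snps.copy())

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        ids = list(snp_ids)
        snps = self.snps.loc[ids].copy() if len(self.snps) else self.snps
        return GenotypeMatrix(self.calls[ids].copy(), self.samples.copy(), snps)

    def unique_samples(self) -> "GenotypeMatrix":
        """Drop duplicated samples (those with a ``duplicate_of`` link)."""
        keep = self.samples.index[self.samples["duplicate_of"].isna()]
        return self.subset_samples(keep)

    # -- codecs ----------------------------------------------------------
    def to_letters(self) -> pd.DataFrame:
        return self.calls.replace(CODE_TO_LETTER)

    @staticmethod
    def letters_to_codes(df: pd.DataFrame) -> pd.DataFrame:
        def convert(x):
            if x in LETTER_TO_CODE:
                return LETTER_TO_CODE[x]
            try:
                code = int(x)
            except (TypeError, ValueError):
                raise ValueError(f"unknown genotype token {x!r}") from None
            if code not in CODE_TO_LETTER:
                raise ValueError(f"unknown genotype code {code}")
            return code

        return df.map(convert).astype(np.int8)
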