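"""Numeric genotype encoding and correlation-based PCA.

Alleles map to integers G=1, C=2, T=3, A=4 and missing calls to 0 — a
deliberately literal encoding kept for comparability, with mean imputation
available behind a flag.  Components are extracted from the correlation
matrix (columns standardized to unit variance); zero-variance SNP columns
are dropped and reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .haplogroup import MISSING

__all__ = ["EncodedGenotypeMatrix", "PCAResult", "encode", "run_pca", "ALLELE_CODES"]

logger = logging.getLogger(__name__)

ALLELE_CODES = {"G": 1, "C": 2, "T": 3, "A": 4}


@dataclass(frozen=True)
class EncodedGenotypeMatrix:
    """samples x SNPs integer matrix; entries in {0,1,2,3,4}."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    snp_ids: tuple[str, ...]


def encode(genotype_table: pd.DataFrame) -> EncodedGenotypeMatrix:
    """Encode an allele table (rows samples, columns SNPs) to integers.

    Accepts A/C/G/T plus the missing marker ``.`` (or empty/NaN); any other
    symbol raises an error naming the sample and SNP.
    """
    values = np.zeros(genotype_table.shape, dtype=np.int8)
    arr = genotype_table.to_numpy(dtype=object)
    for i, sample in enumerate(genotype_table.index):
        for j, snp in enumerate(genotype_table.columns):
            allele = arr[i, j]
            if allele is None or (isinstance(allele, float) and np.isnan(allele)):
                allele = MISSING
            allele = str(allele)
            if allele in (MISSING, ""):
                values[i, j] = 0
            elif allele in ALLELE_CODES:
                values[i, j] = ALLELE_CODES[allele]
            else:
                raise ValueError(
                    f"unexpected allele {allele!r} for sample {sample!r}, SNP {snp!r}"
                )
    return EncodedGenotypeMatrix(
        values=values,
        sample_ids=tuple(str(s) for s in genotype_table.index),
        snp_ids=tuple(str(s) for s in genotype_table.columns),
    )


@dataclass(frozen=True)
class PCAResult:
    """Scores, explained-variance proportions and dropped columns."""

    scores: np.ndarray  # (n_samples, n_components)
    explained: np.ndarray  # non-increasing, sums to <= 1
    components: np.ndarray  # (n_components, n_retained_columns)
    retained_snps: tuple[str, ...]
    dropped_snps: tuple[str, ...]


def run_pca(
    matrix: EncodedGenotypeMatrix | np.ndarray,
    n_components: int = 2,
    impute_missing: bool = False,
) -> PCAResult:
    """PCA of the column correlation matrix via SVD of the standardized
    data.

    Zero-variance columns are dropped (and logged) before scaling.  With
    ``impute_missing`` the zero codes are replaced by the column mean of
    the observed calls before standardization.  The sign of each component
    is fixed so its largest-magnitude loading is positive.
    """
    if isinstance(matrix, EncodedGenotypeMatrix):
        X = matrix.values.astype(float)
        snp_ids = list(matrix.snp_ids)
    else:
        X = np.asarray(matrix, dtype=float)
        snp_ids = [f"snp{j}" for j in range(X.shape[1])]
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")

    if impute_missing:
        X = X.copy()
        for j in range(X.shape[1]):
            observed = X[:, j] != 0
            if observed.any() and not observed.all():
                X[~observed, j] = X[observed, j].mean()

    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = tuple(s for s, k in zip(snp_ids, keep) if not k)
    if dropped:
        logger.info("dropping %d zero-variance SNP column(s)", len(dropped))
    retained = tuple(s for s, k in zip(snp_ids, keep) if k)
    if not len(retained):
        raise ValueError("no variable SNP columns left for PCA")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    n = Z.shape[0]
    U, S, Vt = np.linalg.svd(Z / np.sqrt(n - 1), full_matrices=False)
    eigvals = S**2
    explained = eigvals / len(retained)  # trace of the correlation matrix = p

    k = min(n_components, len(eigvals))
    components = Vt[:k]
    # deterministic sign: largest-magnitude loading positive
    for c in range(k):
        j = int(np.argmax(np.abs(components[c])))
        if components[c, j] < 0:
            components[c] = -components[c]
    scores = Z @ components.T
    return PCAResult(
        scores=scores,
        explained=explained[:k],
        components=components,
        retained_snps=retained,
        dropped_snps=dropped,
    )
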