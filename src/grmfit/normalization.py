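"""RNA-seq count normalization to TPM with RLE-style size factors.

Raw mapped counts are first length-normalized to reads per kilobase,

    X_t = (R_t / L_t) * 1e3,

then scaled to transcripts per million against the product of library size
and a relative-log-expression (RLE) normalization factor,

    TPM_t = X_t / (S_t * N_t) * 1e6.

When factors are not supplied they are derived from the median-of-ratios
(RLE) estimator: each sample's raw factor is the median, over genes with
all-positive counts, of the ratio of that sample's length-normalized count
to the gene's geometric mean across samples.  Raw RLE factors absorb
sequencing depth, while the TPM formula multiplies N_t by the library size
S_t, so — following the calcNormFactors convention — N_t is the raw factor
divided by S_t and rescaled to a unit geometric mean; S_t is the column sum
of X.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["length_normalize", "rle_size_factors", "normalize_counts"]


def length_normalize(counts: pd.DataFrame, lengths) -> pd.DataFrame:
    """Counts per 1000 bp of transcript: X = R / L * 1e3."""
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size != counts.shape[0]:
        raise ValueError("need one transcript length per gene")
    if np.any(lengths <= 0):
        raise ValueError("transcript lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    return counts.div(lengths, axis=0) * 1e3


def rle_size_factors(x: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean reference.

    Only genes with strictly positive values in every sample contribute.
    """
    arr = x.to_numpy(dtype=float)
    pos = (arr > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no gene has positive counts in all samples; cannot estimate factors")
    logs = np.log(arr[pos])
    ref = logs.mean(axis=1, keepdims=True)  # log geometric mean per gene
    factors = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(factors, index=x.columns, name="size_factor")


def normalize_counts(
    counts: pd.DataFrame,
    lengths,
    size_factors: pd.Series | np.ndarray | None = None,
    library_sizes: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Raw counts -> TPM table (genes x samples).

    `size_factors` / `library_sizes` may be given explicitly (e.g. to
    replicate factors computed elsewhere); explicit size factors are used as
    N_t verbatim.  Otherwise N_t comes from the RLE estimator on the
    length-normalized counts, made depth-free by dividing by the library
    size and rescaling to a unit geometric mean.
    """
    x = length_normalize(counts, lengths)
    if library_sizes is None:
        library_sizes = x.sum(axis=0).to_numpy()
    library_sizes = np.asarray(library_sizes, dtype=float)
    if size_factors is None:
        raw = rle_size_factors(x).to_numpy()
        rel = raw / library_sizes
        size_factors = rel / np.exp(np.mean(np.log(rel)))
    size_factors = np.asarray(size_factors, dtype=float)
    if np.any(size_factors <= 0) or np.any(library_sizes <= 0):
        raise ValueError("size factors and library sizes must be positive")
    return x.div(library_sizes * size_factors, axis=1) * 1e6
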