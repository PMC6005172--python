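"""Developmental-expression screen for confirmed transfers.

Counts from a 3'-end single-embryo RNA-seq timecourse (CEL-Seq style) are
normalized to transcripts per million (no length term under 3'-end
counting).  A gene counts as developmentally expressed when the sum over
time points of the median replicate tpm reaches a threshold (100 by
default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import IO

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "normalize_per_million",
    "developmental_expression_score",
    "classify_expressed",
    "expression_report",
    "DEFAULT_EXPRESSION_THRESHOLD",
]

logger = logging.getLogger(__name__)

DEFAULT_EXPRESSION_THRESHOLD = 100.0


@dataclass
class ExpressionMatrix:
    """Gene x sample counts plus per-sample time-point/replicate metadata.

    ``counts`` is a genes-by-samples DataFrame; ``sample_meta`` is indexed
    by sample with columns ``time_point`` (hours post fertilization) and
    ``replicate``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    normalized: bool = False

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in ("time_point", "replicate"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def time_points(self) -> list[float]:
        return sorted(self.sample_meta["time_point"].unique())

    @classmethod
    def from_tsv(cls, counts: IO[str] | str, meta: IO[str] | str) -> "ExpressionMatrix":
        """Load counts (genes x samples TSV) and sample metadata
        (sample, time_point, replicate TSV)."""
        cdf = pd.read_csv(counts, sep="\t", index_col=0)
        mdf = pd.read_csv(meta, sep="\t", index_col=0)
        return cls(cdf, mdf)


def normalize_per_million(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample scaling to transcripts per million.

    Each count is divided by its sample's total counted reads and
    multiplied by 1e6; there is no transcript-length normalization because
    3'-end protocols sequence one fragment per transcript.  All-zero
    samples are left at zero with a warning.
    """
    if mat.normalized:
        raise ValueError("matrix is already normalized")
    totals = mat.counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"samples with zero total counts left unscaled: "
            f"{list(totals.index[zero])}"
        )
    safe = totals.replace(0, 1.0)
    tpm = mat.counts / safe * 1e6
    return ExpressionMatrix(tpm, mat.sample_meta.copy(), normalized=True)


def developmental_expression_score(gene: str, mat: ExpressionMatrix) -> float:
    """Sum over time points of the median replicate tpm for one gene.

    Time points are data-driven (25 in the default fixture shape); even
    replicate counts use the midpoint median.
    """
    if not mat.normalized:
        raise ValueError("matrix must be normalized first")
    if gene not in mat.counts.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    row = mat.counts.loc[gene]
    tp = mat.sample_meta.loc[row.index, "time_point"]
    return float(row.groupby(tp).median().sum())


def classify_expressed(
    score: float, threshold: float = DEFAULT_EXPRESSION_THRESHOLD
) -> bool:
    """Expressed during development iff score >= threshold (inclusive)."""
    if score < 0:
        raise ValueError("score must be non-negative")
    return score >= threshold


def expression_report(
    mat: ExpressionMatrix,
    genes: list[str] | None = None,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene summed-median-tpm scores with the expressed flag."""
    if not mat.normalized:
        mat = normalize_per_million(mat)
    genes = genes if genes is not None else mat.genes
    rows = []
    for g in genes:
        score = developmental_expression_score(g, mat)
        rows.append(
            {"gene": g, "summed_median_tpm": score,
             "expressed": classify_expressed(score, threshold)}
        )
    return pd.DataFrame(rows).set_index("gene")
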