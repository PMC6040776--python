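"""TPM normalisation and the high-expression filter.

Expression is scaled as tags per million: TPM = count / N * 1e6, where N is
the library's *total* clean-read count (not the miRNA-mapped total). Cells
with zero counts are revised to 0.01 TPM after normalisation, so that
log-ratios stay finite. The analysis universe for clustering, differential
expression and the time-series step is the set of miRNAs exceeding 28 TPM
(strictly) in at least one library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import LibraryMeta

ZERO_TPM = 0.01
DEFAULT_TPM_THRESHOLD = 28.0


@dataclass
class ExpressionMatrix:
    """miRNA x library raw counts with per-library totals and, once
    normalised, the revised TPM layer."""

    counts: pd.DataFrame
    totals: pd.Series
    tpm: pd.DataFrame | None = None
    categories: pd.Series | None = None
    metas: dict[str, LibraryMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in self.counts.columns if c not in self.totals.index]
        if missing:
            raise ValueError(f"libraries without totals: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative raw counts")
        if (self.totals[self.counts.columns] <= 0).any():
            raise ValueError("library totals must be positive")

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @classmethod
    def from_tpm(
        cls,
        tpm: pd.DataFrame,
        totals: pd.Series,
        metas: dict[str, LibraryMeta] | None = None,
        zero_value: float = ZERO_TPM,
    ) -> "ExpressionMatrix":
        """Rebuild raw counts from a TPM table and library totals.

        count = round(TPM * N / 1e6); cells at the zero-revision value are
        restored to zero. Lets the exact count test run when only a
        normalised table is available.
        """
        values = tpm.to_numpy(dtype=float).copy()
        values[values == zero_value] = 0.0
        counts = np.rint(values * totals[tpm.columns].to_numpy() / 1e6).astype(int)
        return cls(
            counts=pd.DataFrame(counts, index=tpm.index, columns=tpm.columns),
            totals=totals,
            tpm=tpm.copy(),
            metas=metas or {},
        )

    def stage_matrix(self, breed: str) -> pd.DataFrame:
        """TPM trajectory per miRNA over this breed's stages (columns sorted
        by stage). Requires library metadata and a populated TPM layer."""
        if self.tpm is None:
            raise ValueError("TPM layer not populated; call tpm_normalize first")
        libs = sorted(
            (m for m in self.metas.values() if m.breed == breed),
            key=lambda m: m.stage,
        )
        if not libs:
            raise ValueError(f"no libraries for breed {breed!r}")
        out = self.tpm[[m.library_id for m in libs]].copy()
        out.columns = [m.stage for m in libs]
        return out


def tpm_normalize(
    matrix: ExpressionMatrix,
    metas: dict[str, LibraryMeta] | None = None,
    zero_value: float = ZERO_TPM,
) -> ExpressionMatrix:
    """Populate the TPM layer: count / N * 1e6, zeros revised to ``zero_value``.

    N is taken from library metadata (total clean reads) when supplied,
    otherwise from the matrix's stored totals.
    """
    metas = metas or matrix.metas
    if metas:
        missing = [c for c in matrix.counts.columns if c not in metas]
        if missing:
            raise ValueError(f"libraries without metadata: {missing}")
        totals = pd.Series(
            {lib: metas[lib].total_clean_reads for lib in matrix.counts.columns}
        )
    else:
        totals = matrix.totals
    tpm = matrix.counts / totals[matrix.counts.columns] * 1e6
    tpm = tpm.mask(matrix.counts == 0, zero_value)
    return ExpressionMatrix(
        counts=matrix.counts.copy(),
        totals=totals,
        tpm=tpm,
        categories=matrix.categories,
        metas=dict(metas) if metas else dict(matrix.metas),
    )


def high_expression_filter(
    matrix: ExpressionMatrix, threshold: float = DEFAULT_TPM_THRESHOLD
) -> ExpressionMatrix:
    """Keep miRNAs with TPM strictly above ``threshold`` in >= 1 library.

    The inequality is strict (a miRNA at exactly the threshold everywhere is
    removed); row order is preserved; filtering is idempotent.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if matrix.tpm is None:
        raise ValueError("TPM layer not populated; call tpm_normalize first")
    keep = (matrix.tpm > threshold).any(axis=1)
    return ExpressionMatrix(
        counts=matrix.counts.loc[keep].copy(),
        totals=matrix.totals,
        tpm=matrix.tpm.loc[keep].copy(),
        categories=(
            matrix.categories.loc[keep[keep].index]
            if matrix.categories is not None
            else None
        ),
        metas=dict(matrix.metas),
    )
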