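"""Expression normalization: read counts to copies per cell.

Gene-level read counts (fractional counts are accepted, so 1/n-weighted
multi-mapping reads are representable) are normalized to RPKM and then
placed on an absolute per-cell scale by anchoring to the 16S rRNA pool:
gene RPKM divided by the summed RPKM of the 16S genes, times the assumed
57,000 16S molecules per cell.  Of these ribosomes about 80% are busy
elongating, leaving 11,400 available for initiation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

DEFAULT_TOTAL_16S = 57_000.0  # 16S rRNA copies per cell
DEFAULT_BUSY_FRACTION = 0.80  # fraction of ribosomes engaged in elongation
DEFAULT_SRNA_RATIO = 2.0 / 3.0  # assumed [sRNA]/[mRNA] when unmeasured
DEFAULT_OCCUPANCY = 20.0  # ribosomes removed from the free pool per initiation


def rpkm(count: float, length_nt: float, total_mapped: float) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if length_nt <= 0:
        raise ValueError(f"gene length must be > 0, got {length_nt}")
    if total_mapped <= 0:
        raise ValueError(f"total mapped reads must be > 0, got {total_mapped}")
    if count < 0:
        raise ValueError(f"read count must be >= 0, got {count}")
    return count / ((length_nt / 1e3) * (total_mapped / 1e6))


def copies_from_rpkm(
    gene_rpkm: float, rrna_rpkm_sum: float, total_16s: float = DEFAULT_TOTAL_16S
) -> float:
    """Copies per cell on the 16S scale: gene_rpkm / rrna_rpkm_sum * total_16s."""
    if rrna_rpkm_sum <= 0:
        raise ValueError(f"summed 16S RPKM must be > 0, got {rrna_rpkm_sum}")
    return gene_rpkm / rrna_rpkm_sum * total_16s


def available_ribosomes(
    total_16s: float = DEFAULT_TOTAL_16S,
    busy_fraction: float = DEFAULT_BUSY_FRACTION,
) -> float:
    """Ribosomes free for initiation: (1 - busy_fraction) * total pool."""
    if not 0.0 <= busy_fraction < 1.0:
        raise ValueError(f"busy fraction must be in [0, 1), got {busy_fraction}")
    # subtraction form: exact for the canonical 0.80 * 57,000 case
    return total_16s - busy_fraction * total_16s


def default_srna_copies(m_T: float, ratio: float = DEFAULT_SRNA_RATIO) -> float:
    """Assumed sRNA copies: ratio * target mRNA copies (default 2/3)."""
    if ratio < 0:
        raise ValueError(f"sRNA/mRNA ratio must be >= 0, got {ratio}")
    if m_T < 0:
        raise ValueError(f"mRNA copies must be >= 0, got {m_T}")
    return ratio * m_T


@dataclass(frozen=True)
class ConcentrationSet:
    """Copy numbers entering the equilibrium system for one gene."""

    m_T: float
    s_T: float
    r_T: float
    n: float = DEFAULT_OCCUPANCY

    def __post_init__(self) -> None:
        if min(self.m_T, self.s_T, self.r_T) < 0:
            raise ValueError("copy numbers must be >= 0")
        if self.n < 1:
            raise ValueError(f"occupancy n must be >= 1, got {self.n}")


@dataclass
class ExpressionTable:
    """Per-gene expression with RPKM and 16S-anchored copy numbers."""

    data: pd.DataFrame  # columns: gene_id, length_nt, count, rpkm, copies_per_cell
    total_mapped_reads: float
    rrna_rpkm_sum: float
    scale_total_16s: float

    def copies(self, gene_id: str) -> float:
        row = self.data.loc[self.data["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(f"gene {gene_id!r} not in expression table")
        return float(row["copies_per_cell"].iloc[0])

    def __contains__(self, gene_id: str) -> bool:
        return bool((self.data["gene_id"] == gene_id).any())


def load_counts(path: str | Path) -> pd.DataFrame:
    """Read a counts TSV with columns gene_id, length_nt, count."""
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = {"gene_id", "length_nt", "count"}
    if not expected <= set(df.columns):
        raise ValueError(f"counts table needs columns {sorted(expected)}, got {list(df.columns)}")
    return df


def build_expression_table(
    counts: pd.DataFrame,
    rrna_ids: Sequence[str],
    total_16s: float = DEFAULT_TOTAL_16S,
    total_mapped: float | None = None,
) -> ExpressionTable:
    """Normalize counts to RPKM and 16S-anchored copies per cell.

    ``rrna_ids`` name the 16S rRNA rows whose summed RPKM anchors the
    scale.  ``total_mapped`` defaults to the column sum of ``count``
    (appropriate when the table covers all mapped reads).
    """
    df = counts.copy()
    if total_mapped is None:
        total_mapped = float(df["count"].sum())
    df["rpkm"] = [
        rpkm(c, l, total_mapped) for c, l in zip(df["count"], df["length_nt"])
    ]
    rrna_mask = df["gene_id"].isin(set(rrna_ids))
    if not rrna_mask.any():
        raise ValueError(f"none of the 16S ids {list(rrna_ids)} found in the counts table")
    rrna_sum = float(df.loc[rrna_mask, "rpkm"].sum())
    df["copies_per_cell"] = [copies_from_rpkm(x, rrna_sum, total_16s) for x in df["rpkm"]]
    return ExpressionTable(
        data=df,
        total_mapped_reads=total_mapped,
        rrna_rpkm_sum=rrna_sum,
        scale_total_16s=total_16s,
    )


def concentrations_for(
    gene_id: str,
    table: ExpressionTable,
    ratio: float = DEFAULT_SRNA_RATIO,
    srna_id: str | None = None,
    n: float = DEFAULT_OCCUPANCY,
    busy_fraction: float = DEFAULT_BUSY_FRACTION,
) -> ConcentrationSet:
    """Assemble the concentration defaults for one screened gene.

    s_T is the measured sRNA copy number when ``srna_id`` is given and
    present in the table, else ratio * m_T.  Zero-expression genes keep
    m_T = 0; the screening layer skips them since alpha is undefined.
    """
    m_T = table.copies(gene_id)
    if srna_id is not None and srna_id in table:
        s_T = table.copies(srna_id)
    else:
        s_T = default_srna_copies(m_T, ratio)
    r_T = available_ribosomes(table.scale_total_16s, busy_fraction)
    return ConcentrationSet(m_T=m_T, s_T=s_T, r_T=r_T, n=n)
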