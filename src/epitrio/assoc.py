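"""Basic allelic chi-square association test and p-value filter.

Reimplements the classic single-locus allelic test used for dimension
reduction ahead of multi-locus modeling: per SNP, a 2x2 case/control by
allele count table, Pearson chi-square without continuity correction,
1 degree of freedom.  Missing genotypes are dropped per SNP (pairwise
deletion); a monomorphic SNP scores chi2 = 0, p = 1.  The filter keeps
SNPs with p strictly below alpha (default 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .plinkio import CaseControlLabels, GenotypeMatrix

__all__ = ["AssocResult", "allelic_test", "allelic_test_all", "filter_by_p", "write_assoc_tsv"]


@dataclass
class AssocResult:
    """One SNP's allelic test: 2x2 allele counts, chi-square and p.

    ``allele_counts`` rows are (case, control), columns (allele1, allele2);
    entries sum to twice the number of non-missing individuals.
    """

    snp_id: str
    allele_counts: np.ndarray
    chi2: float
    p_value: float


def _pearson_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square without continuity correction; df = 1.

    Returns (0.0, 1.0) when a margin is zero (monomorphic or empty class).
    """
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    total = table.sum()
    if total == 0 or (rows == 0).any() or (cols == 0).any():
        return 0.0, 1.0
    expected = np.outer(rows, cols) / total
    stat = float(((table - expected) ** 2 / expected).sum())
    return stat, float(chi2.sf(stat, df=1))


def allelic_test(
    g: GenotypeMatrix, labels: CaseControlLabels, snp_id: str
) -> AssocResult:
    """Allelic case-control test for one SNP.

    Allele-1 count per class is the sum of genotype codes over non-missing
    individuals of that class; allele-2 count is the complement to two
    chromosomes per individual.
    """
    col = g.column(snp_id)
    ok = col >= 0
    status = labels.status
    counts = np.zeros((2, 2), dtype=np.int64)
    for row, cls in ((0, 1), (1, 0)):  # row 0 = cases, row 1 = controls
        sel = ok & (status == cls)
        n = int(sel.sum())
        if n == 0:
            raise ValueError(
                f"{snp_id}: all genotypes missing in "
                f"{'cases' if cls == 1 else 'controls'}"
            )
        a1 = int(col[sel].sum())
        counts[row] = (a1, 2 * n - a1)
    stat, p = _pearson_2x2(counts)
    return AssocResult(snp_id, counts, stat, p)


def allelic_test_all(
    g: GenotypeMatrix, labels: CaseControlLabels
) -> list[AssocResult]:
    """Allelic test for every SNP in the matrix (vectorized counting)."""
    labels.require_both_classes()
    values = g.values
    ok = values >= 0
    case = labels.status == 1
    codes = np.where(ok, values, 0).astype(np.int64)
    a1_case = codes[case].sum(axis=0)
    a1_ctrl = codes[~case].sum(axis=0)
    n_case = ok[case].sum(axis=0)
    n_ctrl = ok[~case].sum(axis=0)
    if (n_case == 0).any() or (n_ctrl == 0).any():
        bad = g.snp_meta["snp_id"][(n_case == 0) | (n_ctrl == 0)].iloc[0]
        raise ValueError(f"{bad}: all genotypes missing in one class")
    out = []
    for j, snp_id in enumerate(g.snp_meta["snp_id"]):
        counts = np.array(
            [
                [a1_case[j], 2 * n_case[j] - a1_case[j]],
                [a1_ctrl[j], 2 * n_ctrl[j] - a1_ctrl[j]],
            ],
            dtype=np.int64,
        )
        stat, p = _pearson_2x2(counts)
        out.append(AssocResult(snp_id, counts, stat, p))
    return out


def filter_by_p(results: list[AssocResult], alpha: float = 0.01) -> list[str]:
    """SNP ids with p strictly below alpha, in ascending-p order."""
    if not results:
        raise ValueError("no association results to filter")
    kept = [r for r in results if r.p_value < alpha]
    kept.sort(key=lambda r: (r.p_value, r.snp_id))
    return [r.snp_id for r in kept]


def write_assoc_tsv(
    results: list[AssocResult], g: GenotypeMatrix, path: str | Path
) -> None:
    """Per-SNP TSV mirroring the classic .assoc column semantics."""
    chrom = dict(zip(g.snp_meta["snp_id"], g.snp_meta["chrom"]))
    df = pd.DataFrame(
        {
            "SNP": [r.snp_id for r in results],
            "CHR": [chrom.get(r.snp_id, "NA") for r in results],
            "C_A1_CASE": [r.allele_counts[0, 0] for r in results],
            "C_A2_CASE": [r.allele_counts[0, 1] for r in results],
            "C_A1_CTRL": [r.allele_counts[1, 0] for r in results],
            "C_A2_CTRL": [r.allele_counts[1, 1] for r in results],
            "CHISQ": [r.chi2 for r in results],
            "P": [r.p_value for r in results],
        }
    )
    df.to_csv(path, sep="\t", index=False)
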