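"""PLINK 1 binary genotype I/O.

Reads and writes the classic .bed/.bim/.fam trio (SNP-major, magic bytes
``0x6C 0x1B 0x01``) and exposes an in-memory :class:`GenotypeMatrix` of
0/1/2 minor-allele-count codes plus :class:`CaseControlLabels`.

Genotype codes count copies of the BIM A1 allele (PLINK additive coding):
``2`` = homozygous A1, ``1`` = heterozygous, ``0`` = homozygous A2,
:data:`MISSING` (= -1) = no call.  Two-bit BED encoding, least-significant
pair first within each byte: ``00`` hom A1, ``01`` missing, ``10`` het,
``11`` hom A2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "CaseControlLabels",
    "PlinkFormatError",
    "read_plink",
    "write_plink",
    "subset_snps",
]

logger = logging.getLogger(__name__)

MISSING: int = -1

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# two-bit value -> genotype code (index = bit pair)
_BITS_TO_CODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
# genotype code -> two-bit value; row index = code + 1 so MISSING maps too
_CODE_TO_BITS = np.array([1, 3, 2, 0], dtype=np.uint8)  # [-1, 0, 1, 2]


class PlinkFormatError(ValueError):
    """Malformed PLINK binary input (bad magic bytes, size mismatch...)."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs table of additive genotype codes.

    Parameters
    ----------
    values
        ``(n_individuals, n_snps)`` int8 array with entries in
        ``{0, 1, 2, MISSING}``.
    snp_meta
        DataFrame with columns ``chrom, snp_id, pos, allele1, allele2``
        (one row per SNP column, in column order).
    individual_ids
        Unique identifier per row.
    """

    values: np.ndarray
    snp_meta: pd.DataFrame
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (individuals x SNPs)")
        n_ind, n_snp = self.values.shape
        if len(self.snp_meta) != n_snp:
            raise ValueError(
                f"snp_meta has {len(self.snp_meta)} rows for {n_snp} SNP columns"
            )
        if len(self.individual_ids) != n_ind:
            raise ValueError("individual_ids length != number of rows")
        ids = self.snp_meta["snp_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate SNP ids")
        if len(set(self.individual_ids)) != n_ind:
            raise ValueError("duplicate individual ids")
        bad = ~np.isin(self.values, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be 0/1/2 or MISSING")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_meta["snp_id"])

    def column(self, snp_id: str) -> np.ndarray:
        """Genotype codes of one SNP."""
        idx = self._index_of(snp_id)
        return self.values[:, idx]

    def _index_of(self, snp_id: str) -> int:
        ids = self.snp_meta["snp_id"].to_numpy()
        hits = np.flatnonzero(ids == snp_id)
        if hits.size == 0:
            raise KeyError(f"unknown SNP id: {snp_id!r}")
        return int(hits[0])

    def to_tsv(self, path: str | Path) -> None:
        """Debug export: individuals x SNPs table of codes."""
        df = pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.snp_ids
        )
        df.to_csv(path, sep="\t", index_label="IID")


@dataclass
class CaseControlLabels:
    """Binary disease status per individual: 0 = control, 1 = case."""

    status: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        if not np.isin(self.status, [0, 1]).all():
            raise ValueError("status values must be 0 (control) or 1 (case)")

    @property
    def n_cases(self) -> int:
        return int((self.status == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())

    def require_both_classes(self) -> None:
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError("need at least one case and one control")


def _decode_bed_bytes(raw: np.ndarray, n_individuals: int, n_snps: int) -> np.ndarray:
    """SNP-major payload bytes -> (n_individuals, n_snps) int8 codes."""
    bytes_per_snp = (n_individuals + 3) // 4
    raw = raw.reshape(n_snps, bytes_per_snp)
    # expand each byte into its four 2-bit fields, LSB pair first
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    pairs = (raw[:, :, None] >> shifts) & 0b11
    codes = _BITS_TO_CODE[pairs.reshape(n_snps, -1)[:, :n_individuals]]
    return np.ascontiguousarray(codes.T)


def _encode_bed_bytes(values: np.ndarray) -> bytes:
    """(n_individuals, n_snps) codes -> SNP-major payload bytes."""
    n_ind, n_snps = values.shape
    bytes_per_snp = (n_ind + 3) // 4
    padded = np.zeros((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n_ind] = _CODE_TO_BITS[values.T.astype(np.int16) + 1]
    padded[:, n_ind:] = 0  # pad bits encode hom A2 (=0 code), PLINK convention
    pairs = padded.reshape(n_snps, bytes_per_snp, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    out = (pairs << shifts).sum(axis=2, dtype=np.uint16).astype(np.uint8)
    return out.tobytes()


def read_plink(
    bed_path: str | Path,
    bim_path: str | Path | None = None,
    fam_path: str | Path | None = None,
) -> tuple[GenotypeMatrix, CaseControlLabels]:
    """Load a PLINK 1 fileset into memory.

    ``bed_path`` may be a bare prefix; missing ``bim_path``/``fam_path``
    default to the prefix with the usual extensions.  FAM phenotypes use
    the PLINK convention 1 = control, 2 = case; individuals with -9/0
    (missing) phenotype are dropped with a logged count, anything else
    raises.

    Returns
    -------
    (GenotypeMatrix, CaseControlLabels)
    """
    bed_path = Path(bed_path)
    if bed_path.suffix != ".bed":
        prefix = bed_path
        bed_path = prefix.with_suffix(".bed")
    else:
        prefix = bed_path.with_suffix("")
    bim_path = Path(bim_path) if bim_path else prefix.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else prefix.with_suffix(".fam")

    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "allele1", "allele2"],
        dtype={"chrom": str, "snp_id": str, "allele1": str, "allele2": str},
    ) if bim_path.stat().st_size else pd.DataFrame(
        columns=["chrom", "snp_id", "cm", "pos", "allele1", "allele2"]
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )

    n_ind, n_snps = len(fam), len(bim)
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:3].tobytes() != _MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes {raw[:3].tobytes()!r}")
    payload = raw[3:]
    expected = n_snps * ((n_ind + 3) // 4)
    if payload.size != expected:
        raise PlinkFormatError(
            f"{bed_path}: expected {expected} payload bytes, found {payload.size}"
        )
    values = (
        _decode_bed_bytes(payload, n_ind, n_snps)
        if n_snps
        else np.zeros((n_ind, 0), dtype=np.int8)
    )

    pheno = fam["phenotype"].to_numpy()
    known = np.isin(pheno, [1, 2])
    missing_pheno = np.isin(pheno, [-9, 0])
    if not (known | missing_pheno).all():
        bad = sorted(set(pheno[~(known | missing_pheno)]))
        raise ValueError(f"unsupported FAM phenotype codes: {bad}")
    if missing_pheno.any():
        n_drop = int(missing_pheno.sum())
        logger.warning("dropping %d individuals with missing phenotype", n_drop)
        warnings.warn(
            f"dropped {n_drop} individuals with missing phenotype", stacklevel=2
        )
        values = values[known]
        fam = fam.loc[known].reset_index(drop=True)
        pheno = pheno[known]

    meta = bim[["chrom", "snp_id", "pos", "allele1", "allele2"]].reset_index(drop=True)
    g = GenotypeMatrix(values, meta, list(fam["iid"]))
    labels = CaseControlLabels((pheno == 2).astype(np.int8))
    return g, labels


def write_plink(
    g: GenotypeMatrix, labels: CaseControlLabels, prefix: str | Path
) -> tuple[Path, Path, Path]:
    """Write a PLINK 1 .bed/.bim/.fam trio; returns the three paths.

    Inverse of :func:`read_plink`: a round trip preserves genotype codes
    and labels bit-exactly.
    """
    prefix = Path(prefix)
    if len(labels.status) != g.n_individuals:
        raise ValueError("labels length != number of individuals")
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    with open(bed, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(_encode_bed_bytes(g.values))
    bim_df = g.snp_meta.copy()
    bim_df.insert(2, "cm", 0)
    bim_df.to_csv(bim, sep="\t", header=False, index=False)
    fam_df = pd.DataFrame(
        {
            "fid": g.individual_ids,
            "iid": g.individual_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "phenotype": np.where(labels.status == 1, 2, 1),
        }
    )
    fam_df.to_csv(fam, sep="\t", header=False, index=False)
    return bed, bim, fam


def subset_snps(g: GenotypeMatrix, snp_ids: list[str]) -> GenotypeMatrix:
    """Column subset in the requested order, metadata carried along."""
    index = {s: i for i, s in enumerate(g.snp_meta["snp_id"])}
    try:
        cols = [index[s] for s in snp_ids]
    except KeyError as exc:
        raise KeyError(f"unknown SNP id: {exc.args[0]!r}") from None
    values = (
        g.values[:, cols]
        if cols
        else np.zeros((g.n_individuals, 0), dtype=np.int8)
    )
    meta = g.snp_meta.iloc[cols].reset_index(drop=True)
    return GenotypeMatrix(values, meta, list(g.individual_ids))
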