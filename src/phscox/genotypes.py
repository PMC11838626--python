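"""Batched, memory-bounded access to biallelic genotype matrices.

The genotype matrix is the design matrix of the penalized Cox model: n
individuals by p variants, entries counting copies of the first (A1)
allele, with missing calls. At biobank scale (10^5-10^6 variants) the
matrix does not fit in memory as float64, so :class:`GenotypeStore`
exposes column batches decoded on demand from a PLINK 1 BED file (or an
in-memory byte matrix for simulated data).

QC filtering (missing rate <= 10%, MAF >= 0.001), per-variant mean
imputation and train-split standardization live here so that every
downstream consumer sees the same standardized columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeStore",
    "StandardizationStats",
    "read_bed",
    "write_bed",
    "qc_filter",
    "impute_and_standardize",
    "iter_batches",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK 1.9, variant-major

# 2-bit code -> dosage of the A1 allele; 01 is the missing code.
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}

# byte -> 4 dosages lookup, built once
_BYTE_TABLE = np.zeros((256, 4), dtype=np.int8)
for _b in range(256):
    for _k in range(4):
        _BYTE_TABLE[_b, _k] = _CODE_TO_DOSAGE[(_b >> (2 * _k)) & 0b11]


class GenotypeStore:
    """Column-accessible biallelic dosage matrix with per-variant metadata.

    Entries are counts of the A1 allele in {0, 1, 2} with -1 encoding a
    missing call in the packed int8 backing. Reads return float64 with
    NaN for missing. Identical reads always return identical values.

    Parameters
    ----------
    variants : pandas.DataFrame
        One row per variant with at least column ``id``; ``chrom``,
        ``pos``, ``a1``, ``a2`` are filled with defaults when absent.
        ``maf`` and ``missing_rate`` are populated by
        :meth:`compute_metadata` (full-cohort frequencies, computed
        before any train/test split as in standard array QC).
    """

    def __init__(
        self,
        backing: "np.ndarray | str | Path",
        n_individuals: int,
        variants: pd.DataFrame,
        sample_ids: Sequence | None = None,
        batch_size: int = 1000,
    ):
        self.n_individuals = int(n_individuals)
        self.n_variants = len(variants)
        self.variants = variants.reset_index(drop=True)
        for col, default in (("chrom", "1"), ("a1", "A"), ("a2", "B")):
            if col not in self.variants:
                self.variants[col] = default
        if "pos" not in self.variants:
            self.variants["pos"] = np.arange(1, self.n_variants + 1)
        if sample_ids is None:
            sample_ids = [f"iid_{i}" for i in range(self.n_individuals)]
        self.sample_ids = np.asarray(sample_ids)
        if len(self.sample_ids) != self.n_individuals:
            raise ValueError("sample_ids length does not match n_individuals")
        self.batch_size = int(batch_size)
        if isinstance(backing, (str, Path)):
            self._path = Path(backing)
            self._mat = None
        else:
            mat = np.asarray(backing)
            if mat.shape != (self.n_individuals, self.n_variants):
                raise ValueError(
                    f"backing shape {mat.shape} does not match "
                    f"(n_individuals={self.n_individuals}, n_variants={self.n_variants})"
                )
            self._path = None
            self._mat = np.ascontiguousarray(mat, dtype=np.int8)

    # ------------------------------------------------------------------
    # constructors / IO
    # ------------------------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        genotypes: np.ndarray,
        variant_ids: Sequence | None = None,
        sample_ids: Sequence | None = None,
        batch_size: int = 1000,
    ) -> "GenotypeStore":
        """Wrap an (n, p) dosage matrix; NaN or -1 mark missing calls."""
        g = np.asarray(genotypes)
        if np.issubdtype(g.dtype, np.floating):
            gi = np.where(np.isnan(g), -1, g).astype(np.int8)
        else:
            gi = g.astype(np.int8)
        bad = ~np.isin(gi, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype entries must be in {0,1,2} or missing")
        n, p = gi.shape
        if variant_ids is None:
            variant_ids = [f"var_{j}" for j in range(p)]
        variants = pd.DataFrame({"id": list(variant_ids)})
        store = cls(gi, n, variants, sample_ids=sample_ids, batch_size=batch_size)
        store.compute_metadata()
        return store

    @classmethod
    def from_bed(cls, prefix: "str | Path", batch_size: int = 1000) -> "GenotypeStore":
        """Open ``prefix``.bed/.bim/.fam (PLINK 1, variant-major)."""
        prefix = Path(prefix)
        bim = pd.read_csv(
            prefix.with_suffix(".bim"),
            sep="\t",
            header=None,
            names=["chrom", "id", "cm", "pos", "a1", "a2"],
            dtype={"chrom": str, "id": str, "a1": str, "a2": str},
        )
        fam = pd.read_csv(
            prefix.with_suffix(".fam"),
            sep=r"\s+",
            header=None,
            names=["fid", "iid", "father", "mother", "sex", "pheno"],
            dtype={"iid": str},
        )
        with open(prefix.with_suffix(".bed"), "rb") as fh:
            magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(f"{prefix}.bed is not a variant-major PLINK 1 BED file")
        variants = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
        store = cls(
            prefix.with_suffix(".bed"),
            len(fam),
            variants,
            sample_ids=fam["iid"].to_numpy(),
            batch_size=batch_size,
        )
        store.compute_metadata()
        return store

    def write_bed(self, prefix: "str | Path") -> None:
        """Write the matrix as ``prefix``.bed/.bim/.fam."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        n = self.n_individuals
        with open(prefix.with_suffix(".bed"), "wb") as fh:
            fh.write(_BED_MAGIC)
            for start in range(0, self.n_variants, self.batch_size):
                idx = np.arange(start, min(start + self.batch_size, self.n_variants))
                block = self._raw_columns(idx)  # (n, k) int8
                fh.write(_encode_columns(block, n).tobytes())
        bim = pd.DataFrame(
            {
                "chrom": self.variants["chrom"],
                "id": self.variants["id"],
                "cm": 0,
                "pos": self.variants["pos"],
                "a1": self.variants["a1"],
                "a2": self.variants["a2"],
            }
        )
        bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
        fam = pd.DataFrame(
            {
                "fid": self.sample_ids,
                "iid": self.sample_ids,
                "father": 0,
                "mother": 0,
                "sex": 0,
                "pheno": -9,
            }
        )
        fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)

    # ------------------------------------------------------------------
    # reads
    # ------------------------------------------------------------------
    def _raw_columns(self, variant_indices: np.ndarray) -> np.ndarray:
        """(n, k) int8 dosages, -1 = missing."""
        variant_indices = np.asarray(variant_indices, dtype=np.int64)
        if variant_indices.size and (
            variant_indices.min() < 0 or variant_indices.max() >= self.n_variants
        ):
            raise IndexError("variant index out of range")
        if self._mat is not None:
            return self._mat[:, variant_indices]
        bpf = (self.n_individuals + 3) // 4  # bytes per variant
        out = np.empty((self.n_individuals, variant_indices.size), dtype=np.int8)
        with open(self._path, "rb") as fh:
            # group contiguous runs to avoid per-column seeks
            k = 0
            for run_start, run_len in _contiguous_runs(variant_indices):
                fh.seek(3 + run_start * bpf)
                raw = np.frombuffer(fh.read(run_len * bpf), dtype=np.uint8)
                decoded = _BYTE_TABLE[raw.reshape(run_len, bpf)].reshape(run_len, -1)
                out[:, k : k + run_len] = decoded[:, : self.n_individuals].T
                k += run_len
        return out

    def dosages(
        self,
        variant_indices: Sequence | None = None,
        row_indices: Sequence | None = None,
    ) -> np.ndarray:
        """Float64 dosage block with NaN for missing calls."""
        if variant_indices is None:
            variant_indices = np.arange(self.n_variants)
        block = self._raw_columns(np.asarray(variant_indices)).astype(np.float64)
        block[block < 0] = np.nan
        if row_indices is not None:
            row_indices = np.asarray(row_indices, dtype=np.int64)
            if row_indices.size and (
                row_indices.min() < 0 or row_indices.max() >= self.n_individuals
            ):
                raise IndexError("row index out of range")
            block = block[row_indices]
        return block

    def compute_metadata(self) -> pd.DataFrame:
        """Populate per-variant ``maf`` and ``missing_rate`` (full cohort)."""
        mafs = np.empty(self.n_variants)
        miss = np.empty(self.n_variants)
        for start in range(0, self.n_variants, self.batch_size):
            idx = np.arange(start, min(start + self.batch_size, self.n_variants))
            block = self._raw_columns(idx).astype(np.float64)
            m = block < 0
            block[m] = np.nan
            miss[idx] = m.mean(axis=0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-missing column
                freq = np.nanmean(block, axis=0) / 2.0
            freq = np.where(np.isnan(freq), 0.0, freq)
            mafs[idx] = np.minimum(freq, 1.0 - freq)
        self.variants["maf"] = mafs
        self.variants["missing_rate"] = miss
        return self.variants


def _contiguous_runs(indices: np.ndarray) -> Iterator[tuple[int, int]]:
    if indices.size == 0:
        return
    start = prev = int(indices[0])
    for j in indices[1:]:
        j = int(j)
        if j == prev + 1:
            prev = j
            continue
        yield start, prev - start + 1
        start = prev = j
    yield start, prev - start + 1


def _encode_columns(block: np.ndarray, n: int) -> np.ndarray:
    """Pack an (n, k) int8 dosage block into PLINK 2-bit bytes, (k, bpf)."""
    k = block.shape[1]
    bpf = (n + 3) // 4
    codes = np.empty((k, bpf * 4), dtype=np.uint8)
    col_codes = np.array(
        [_DOSAGE_TO_CODE[2], _DOSAGE_TO_CODE[-1], _DOSAGE_TO_CODE[1], _DOSAGE_TO_CODE[0]],
        dtype=np.uint8,
    )
    # map dosage values {2,-1,1,0} -> 2-bit codes via the shared lookup
    lut = np.zeros(256, dtype=np.uint8)
    lut[np.array([2, -1, 1, 0], dtype=np.int8).view(np.uint8)] = col_codes
    codes[:, :n] = lut[block.T.astype(np.int8).view(np.uint8)]
    codes[:, n:] = _DOSAGE_TO_CODE[0]  # padding codes are hom A2 per convention
    shifted = codes.reshape(k, bpf, 4) << np.array([0, 2, 4, 6], dtype=np.uint8)
    return shifted.sum(axis=2, dtype=np.uint8)


def read_bed(prefix: "str | Path", batch_size: int = 1000) -> GenotypeStore:
    """Convenience alias for :meth:`GenotypeStore.from_bed`."""
    return GenotypeStore.from_bed(prefix, batch_size=batch_size)


def write_bed(store: GenotypeStore, prefix: "str | Path") -> None:
    """Convenience alias for :meth:`GenotypeStore.write_bed`."""
    store.write_bed(prefix)


# ----------------------------------------------------------------------
# QC + standardization
# ----------------------------------------------------------------------
def qc_filter(
    store: GenotypeStore,
    max_missing: float = 0.10,
    min_maf: float = 0.001,
) -> np.ndarray:
    """Indices of variants passing missing-rate and MAF thresholds.

    A variant is kept iff missing_rate <= ``max_missing`` and
    MAF >= ``min_maf``; input order is preserved. This mirrors standard
    array preprocessing: frequencies are full-cohort, computed before
    any split.
    """
    if "maf" not in store.variants or "missing_rate" not in store.variants:
        store.compute_metadata()
    maf = store.variants["maf"].to_numpy()
    miss = store.variants["missing_rate"].to_numpy()
    kept = np.flatnonzero((miss <= max_missing) & (maf >= min_maf))
    if kept.size == 0:
        raise ValueError("QC filter removed every variant")
    return kept


@dataclass
class StandardizationStats:
    """Train-split imputation means and scale factors.

    Means and standard deviations are computed on the training rows only
    (after mean imputation), so that held-out and replication cohorts are
    scored on the training scale and no information leaks across the
    split. Variants monomorphic in the training split (sd == 0) are
    dropped.
    """

    variant_indices: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    dropped: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self):
        if not (len(self.variant_indices) == len(self.mean) == len(self.sd)):
            raise ValueError("inconsistent standardization stats lengths")
        if np.any(self.sd <= 0):
            raise ValueError("sd must be > 0 for every retained variant")


def impute_and_standardize(
    store: GenotypeStore,
    variant_indices: Sequence,
    train_rows: Sequence,
) -> StandardizationStats:
    """Compute train-split mean-imputation and scaling statistics.

    Missing entries are replaced by the per-variant mean of the observed
    training calls; the reported mean/sd are those of the imputed
    training column (population sd, ddof=0). Variants with zero training
    variance are dropped with a warning.
    """
    variant_indices = np.asarray(variant_indices, dtype=np.int64)
    train_rows = np.asarray(train_rows, dtype=np.int64)
    means = np.empty(variant_indices.size)
    sds = np.empty(variant_indices.size)
    bs = store.batch_size
    for start in range(0, variant_indices.size, bs):
        sel = variant_indices[start : start + bs]
        block = store.dosages(sel, train_rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.nanmean(block, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        filled = np.where(np.isnan(block), mu, block)
        means[start : start + sel.size] = filled.mean(axis=0)
        sds[start : start + sel.size] = filled.std(axis=0)
    keep = sds > 0
    dropped = variant_indices[~keep]
    if dropped.size:
        warnings.warn(
            f"dropping {dropped.size} variant(s) monomorphic in the training split"
        )
    return StandardizationStats(
        variant_indices=variant_indices[keep],
        mean=means[keep],
        sd=sds[keep],
        dropped=dropped,
    )


def standardized_block(
    store: GenotypeStore,
    stats: StandardizationStats,
    cols: np.ndarray,
    row_indices: Sequence,
) -> np.ndarray:
    """Standardized columns ``cols`` (positions into stats.variant_indices)."""
    cols = np.asarray(cols, dtype=np.int64)
    block = store.dosages(stats.variant_indices[cols], row_indices)
    mu = stats.mean[cols]
    block = np.where(np.isnan(block), mu, block)
    return (block - mu) / stats.sd[cols]


def iter_batches(
    store: GenotypeStore,
    stats: StandardizationStats,
    row_indices: Sequence,
    batch_size: int | None = None,
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (column positions, standardized block) in column batches.

    Concatenating the blocks reproduces the full standardized submatrix;
    peak memory is bounded by ``len(row_indices) * batch_size`` values.
    """
    bs = batch_size or store.batch_size
    if bs < 1:
        raise ValueError("batch_size must be >= 1")
    p = len(stats.variant_indices)
    for start in range(0, p, bs):
        cols = np.arange(start, min(start + bs, p))
        yield cols, standardized_block(store, stats, cols, row_indices)
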