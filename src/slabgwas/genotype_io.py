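"""PLINK binary genotype I/O, dosage standardization and covariate residualization.

Genotypes are stored as allele-1 dosages in {0, 1, 2} with ``MISSING`` (-9)
as the missing sentinel, decoded from / encoded to the PLINK 1 bed format
(magic ``6C 1B``, SNP-major mode ``01``, two bits per call).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.int8(-9)

_BED_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = b"\x01"

# PLINK 1 two-bit code -> allele-1 dosage: 00 hom A1 (2), 01 missing,
# 10 het (1), 11 hom A2 (0).
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11, int(MISSING): 0b01}


def _byte_decode_table() -> np.ndarray:
    """256 x 4 lookup: one packed byte -> four dosages (LSB pair first)."""
    table = np.empty((256, 4), dtype=np.int8)
    for b in range(256):
        for k in range(4):
            table[b, k] = _CODE_TO_DOSAGE[(b >> (2 * k)) & 0b11]
    return table


_DECODE_TABLE = _byte_decode_table()


class BedFormatError(ValueError):
    """Raised when a .bed payload violates the PLINK 1 binary layout."""


@dataclass
class VariantRecord:
    """One biallelic variant: bim metadata plus the observed MAF.

    ``maf`` is min(f, 1-f) of the allele-1 frequency computed on
    non-missing calls; ``position`` is 1-based base pairs.
    """

    chromosome: str
    identifier: str
    position: int
    allele1: str
    allele2: str
    maf: float = np.nan
    cm: float = 0.0

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"variant {self.identifier}: position must be positive")


@dataclass
class GenotypeMatrix:
    """N x M allele-count dosage matrix with sample and variant metadata.

    ``dosages`` is int8, entries in {0, 1, 2, MISSING}; ``chromosome_index``
    maps each chromosome label to the column indices it owns and partitions
    the columns exactly.
    """

    samples: list[tuple[str, str]]
    variants: list[VariantRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n, m = self.dosages.shape
        if n != len(self.samples):
            raise ValueError("sample count does not match dosage rows")
        if m != len(self.variants):
            raise ValueError("variant count does not match dosage columns")
        valid = np.isin(self.dosages, [0, 1, 2, MISSING])
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or the missing sentinel")
        self._refresh_maf()

    def _refresh_maf(self) -> None:
        for j, v in enumerate(self.variants):
            col = self.dosages[:, j]
            obs = col[col != MISSING]
            if obs.size == 0:
                v.maf = np.nan
            else:
                f = float(obs.mean()) / 2.0
                v.maf = min(f, 1.0 - f)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def chromosome_index(self) -> dict[str, np.ndarray]:
        idx: dict[str, list[int]] = {}
        for j, v in enumerate(self.variants):
            idx.setdefault(v.chromosome, []).append(j)
        return {c: np.asarray(js, dtype=np.intp) for c, js in idx.items()}

    @property
    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for v in self.variants:
            if v.chromosome not in seen:
                seen.append(v.chromosome)
        return seen

    def mafs(self) -> np.ndarray:
        return np.array([v.maf for v in self.variants])

    def subset_variants(self, cols: np.ndarray) -> "GenotypeMatrix":
        cols = np.asarray(cols)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[j] for j in cols],
            dosages=self.dosages[:, cols].copy(),
        )

    def subset_samples(self, rows: np.ndarray) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in rows],
            variants=list(self.variants),
            dosages=self.dosages[rows, :].copy(),
        )


@dataclass
class AdjustedMatrix:
    """Standardized (and optionally covariate-residualized) dosage matrix.

    ``values`` holds the retained columns only; ``retained`` maps them back
    to the source variant indices.  ``adjustment_basis`` is the covariate
    matrix (with intercept) projected out of every column; ``scale`` the
    per-column divisor and ``center`` the per-column mean used.
    """

    values: np.ndarray
    adjustment_basis: np.ndarray
    scale: np.ndarray
    center: np.ndarray
    retained: np.ndarray
    excluded: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.intp))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# bed/bim/fam reading and writing
# ---------------------------------------------------------------------------


def read_fam(fam_path) -> list[tuple[str, str]]:
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    return list(zip(fam[0], fam[1]))


def read_bim(bim_path) -> list[VariantRecord]:
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] != 6:
        raise BedFormatError(f"bim file must have 6 columns, got {bim.shape[1]}")
    recs = [
        VariantRecord(
            chromosome=row[0],
            identifier=row[1],
            cm=float(row[2]),
            position=int(row[3]),
            allele1=row[4],
            allele2=row[5],
        )
        for row in bim.itertuples(index=False)
    ]
    ids = [r.identifier for r in recs]
    if len(set(ids)) != len(ids):
        warnings.warn("duplicate variant identifiers in bim; retained as-is")
    return recs


def read_bed(bed_path, bim_path=None, fam_path=None) -> GenotypeMatrix:
    """Read a PLINK 1 SNP-major bed/bim/fam fileset into a GenotypeMatrix.

    ``bim_path``/``fam_path`` default to the bed path with swapped suffixes.
    """
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")

    samples = read_fam(fam_path)
    variants = read_bim(bim_path)
    n, m = len(samples), len(variants)

    raw = bed_path.read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise BedFormatError(f"{bed_path}: bad magic bytes {raw[:2]!r}")
    if raw[2:3] != _SNP_MAJOR:
        raise BedFormatError(
            f"{bed_path}: mode byte {raw[2:3]!r} is not SNP-major (0x01)"
        )
    bytes_per_variant = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_variant * m:
        raise BedFormatError(
            f"{bed_path}: expected {bytes_per_variant * m} payload bytes, "
            f"got {payload.size}"
        )
    decoded = _DECODE_TABLE[payload.reshape(m, bytes_per_variant)]
    dosages = decoded.reshape(m, -1)[:, :n].T.copy()
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def write_bed(G: GenotypeMatrix, prefix) -> dict[str, Path]:
    """Write ``G`` as PLINK bed/bim/fam at ``prefix``; round trips exactly."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = G.n_samples, G.n_variants

    codes = np.zeros_like(G.dosages, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[G.dosages == dosage] = code

    bytes_per_variant = (n + 3) // 4
    # trailing slots in the last byte are zero bits, as PLINK writes them;
    # readers ignore them because the sample count bounds the slice
    padded = np.zeros((m, bytes_per_variant * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )

    bed_path = prefix.with_suffix(".bed")
    bed_path.write_bytes(_BED_MAGIC + _SNP_MAJOR + packed.tobytes())

    bim_path = prefix.with_suffix(".bim")
    with open(bim_path, "w") as fh:
        for v in G.variants:
            fh.write(
                f"{v.chromosome}\t{v.identifier}\t{v.cm:g}\t{v.position}\t"
                f"{v.allele1}\t{v.allele2}\n"
            )
    fam_path = prefix.with_suffix(".fam")
    with open(fam_path, "w") as fh:
        for fid, iid in G.samples:
            fh.write(f"{fid}\t{iid}\t0\t0\t0\t-9\n")
    return {"bed": bed_path, "bim": bim_path, "fam": fam_path}


# ---------------------------------------------------------------------------
# Standardization and covariate adjustment
# ---------------------------------------------------------------------------


def standardize(
    G: GenotypeMatrix,
    mode: str = "empirical",
    covariates: np.ndarray | None = None,
    dtype=np.float64,
) -> AdjustedMatrix:
    """Mean-impute, center and scale dosages; optionally residualize covariates.

    mode "empirical" divides by the observed (population) SD of the imputed
    column; mode "binomial" divides by sqrt(2 f (1-f)) with f the allele-1
    frequency.  Zero-variance (or all-missing) columns are excluded from the
    output and listed in ``excluded``.  If ``covariates`` is given, an
    intercept is appended and the covariate span is projected out of every
    retained column.
    """
    if G.n_variants == 0:
        raise ValueError("empty genotype matrix")
    if mode not in ("empirical", "binomial"):
        raise ValueError(f"unknown standardization mode {mode!r}")

    X = G.dosages.astype(dtype)
    miss = G.dosages == MISSING
    n_obs = (~miss).sum(axis=0).astype(dtype)
    all_missing = n_obs == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        col_mean = np.where(
            all_missing, 0.0, np.where(miss, 0, X).sum(axis=0) / np.maximum(n_obs, 1)
        )
    X = np.where(miss, col_mean, X)

    center = X.mean(axis=0)
    Xc = X - center
    var = (Xc**2).mean(axis=0)
    if mode == "empirical":
        scale = np.sqrt(var)
    else:
        f = col_mean / 2.0
        scale = np.sqrt(2.0 * f * (1.0 - f))

    keep = (var > 0) & (scale > 0) & ~all_missing
    excluded = np.flatnonzero(~keep)
    if excluded.size:
        warnings.warn(
            f"{excluded.size} zero-variance or all-missing column(s) excluded"
        )
    retained = np.flatnonzero(keep)
    values = Xc[:, retained] / scale[retained]

    basis = np.ones((G.n_samples, 1), dtype=dtype)
    if covariates is not None:
        C = np.asarray(covariates, dtype=dtype)
        if C.ndim == 1:
            C = C[:, None]
        basis = np.column_stack([basis, C])
        values = residualize_covariates(values, C)

    return AdjustedMatrix(
        values=values,
        adjustment_basis=basis,
        scale=scale[retained],
        center=center[retained],
        retained=retained,
        excluded=excluded,
    )


def residualize_covariates(Y: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    """Project the covariate span (plus intercept) out of the columns of Y.

    Returns Y - C*(C'C)^-1 C'Y with an intercept column always included.
    Raises on rank-deficient covariates, naming the collinear columns.
    """
    Y = np.asarray(Y, dtype=np.float64)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    n = Y.shape[0]
    ones = np.ones((n, 1))
    if C is None:
        Cfull = ones
    else:
        C = np.asarray(C, dtype=np.float64)
        if C.ndim == 1:
            C = C[:, None]
        Cfull = np.column_stack([ones, C])
    q, r = np.linalg.qr(Cfull)
    diag = np.abs(np.diag(r))
    bad = np.flatnonzero(diag < 1e-10 * max(diag.max(), 1.0))
    if bad.size:
        raise ValueError(
            "covariate matrix is rank deficient; collinear columns "
            f"(0 = intercept): {bad.tolist()}"
        )
    resid = Y - q @ (q.T @ Y)
    return resid[:, 0] if squeeze else resid


# ---------------------------------------------------------------------------
# Phenotype / covariate / weight tables
# ---------------------------------------------------------------------------


def read_table(path) -> pd.DataFrame:
    """Read a whitespace-delimited FID/IID-keyed table with NA for missing."""
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"], dtype={0: str, 1: str})
    df.columns = ["FID", "IID"] + list(df.columns[2:])
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def align_samples(
    G: GenotypeMatrix, *tables: pd.DataFrame
) -> tuple[np.ndarray, list[pd.DataFrame]]:
    """Inner-join genotype samples with tables on (FID, IID).

    Returns row indices into ``G`` and each table reindexed to that order.
    Unmatched samples are dropped with a logged count.
    """
    keys = pd.MultiIndex.from_tuples(G.samples, names=["FID", "IID"])
    keep = pd.Series(True, index=keys)
    for t in tables:
        tkeys = pd.MultiIndex.from_frame(t[["FID", "IID"]])
        keep &= keys.isin(tkeys)
    rows = np.flatnonzero(keep.to_numpy())
    dropped = len(keys) - rows.size
    if dropped:
        logger.info("align_samples: dropped %d unmatched genotype samples", dropped)
    kept_keys = keys[rows]
    out = []
    for t in tables:
        ti = t.set_index(["FID", "IID"]).loc[kept_keys]
        out.append(ti.reset_index())
    return rows, out
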