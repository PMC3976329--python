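"""On-disk formats and validated in-memory containers for the pipeline.

Everything downstream (association, meta-analysis, the bivariate combined
test, GREML) operates on the domain types defined here: validated per-SNP
summary statistics, genotype dosage panels, phenotype/covariate tables and
text-triplet GRMs.  Readers drop records that violate the type invariants
and report counts through the module logger; every writer/reader pair is an
identity on valid data to the stated tolerance.

Conventions
-----------
* positions are 1-based; windows elsewhere in the package are inclusive on
  both ends;
* alleles are upper-cased on read and never strand-flipped silently —
  palindromic (A/T, C/G) SNPs are flagged so the alignment step can resolve
  or drop them;
* missing values are written as ``NA``; ``NA``, ``NaN`` and the empty string
  are accepted on read.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "EmptyInputError",
    "SnpRecord",
    "SummaryStats",
    "GenotypePanel",
    "PhenotypeTable",
    "read_summary_stats",
    "write_summary_stats",
    "read_genotypes",
    "write_genotype_matrix",
    "read_phenotypes",
    "write_phenotypes",
    "read_grm",
    "write_grm",
]

IUPAC_BASES = set("ACGTURYSWKMBDHVN")
_PALINDROMIC = ({"A", "T"}, {"C", "G"})

#: canonical on-disk column order for summary statistics
SUMMARY_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N", "Z"]
#: internal (DataFrame) column names, same order
_INTERNAL = ["snp", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n", "z"]
_MANDATORY = ["SNP", "CHR", "POS", "EA", "OA", "BETA", "SE"]
_NA_VALUES = ["NA", "NaN", ""]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class EmptyInputError(FormatError):
    """A file contains no usable content at all."""


def is_palindromic(ea: str, oa: str) -> bool:
    """True for strand-ambiguous allele pairs (A/T or C/G)."""
    return {ea, oa} in _PALINDROMIC


@dataclasses.dataclass(frozen=True)
class SnpRecord:
    """Identity of one SNP: id, 1-based position and allele pair."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float = math.nan

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise FormatError(f"{self.snp_id}: effect and other allele identical")
        if self.pos < 1:
            raise FormatError(f"{self.snp_id}: position must be >= 1")

    @property
    def palindromic(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SummaryStats:
    """Validated per-SNP association results for one trait.

    ``table`` has columns ``snp, chrom, pos, ea, oa, eaf, beta, se, p, n, z``
    with unique SNP ids, ``z == beta/se`` and ``p`` consistent with ``|z|``
    (mismatches beyond 1e-6 relative are logged, not fatal, to tolerate
    rounding in published statistics and t- vs normal-reference p-values).
    """

    table: pd.DataFrame
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:  # frame-wise identity, used in tests
        if not isinstance(other, SummaryStats):
            return NotImplemented
        return self.table.reset_index(drop=True).equals(other.table.reset_index(drop=True))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SummaryStats":
        """Validate an internal-format frame, dropping invalid rows."""
        df = frame.copy()
        for col in _INTERNAL:
            if col not in df.columns:
                df[col] = np.nan
        df = df[_INTERNAL]
        df["snp"] = df["snp"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["ea"] = df["ea"].astype(str).str.upper()
        df["oa"] = df["oa"].astype(str).str.upper()
        for col in ("eaf", "beta", "se", "p", "z"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
        df["n"] = pd.to_numeric(df["n"], errors="coerce")

        # derive z / p when absent
        with np.errstate(divide="ignore", invalid="ignore"):
            z_implied = df["beta"].to_numpy() / df["se"].to_numpy()
        z = df["z"].to_numpy(dtype=float)
        fill = np.isnan(z)
        z[fill] = z_implied[fill]
        df["z"] = z
        p = df["p"].to_numpy(dtype=float)
        fillp = np.isnan(p)
        p[fillp] = np.clip(2.0 * sps.norm.sf(np.abs(z[fillp])),
                           np.nextafter(0.0, 1.0), 1.0)
        df["p"] = p

        ok = np.ones(len(df), dtype=bool)
        ok &= df["se"].to_numpy() > 0
        ok &= np.isfinite(df["beta"].to_numpy())
        ok &= (df["p"].to_numpy() > 0) & (df["p"].to_numpy() <= 1)
        pos = df["pos"].to_numpy()
        ok &= np.isfinite(pos) & (pos >= 1)
        eaf = df["eaf"].to_numpy()
        ok &= np.isnan(eaf) | ((eaf >= 0) & (eaf <= 1))
        ok &= df["ea"].ne(df["oa"]).to_numpy()
        ok &= df["ea"].isin(IUPAC_BASES).to_numpy() & df["oa"].isin(IUPAC_BASES).to_numpy()
        nvals = df["n"].to_numpy()
        ok &= np.isnan(nvals) | (nvals > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            zref = df["beta"].to_numpy() / df["se"].to_numpy()
            rel = np.abs(df["z"].to_numpy() - zref) / np.maximum(1.0, np.abs(zref))
        ok &= ~(rel > 1e-10)
        ok &= ~df["snp"].duplicated(keep="first").to_numpy()

        n_dropped = int((~ok).sum())
        if n_dropped:
            logger.info("SummaryStats validation dropped %d invalid rows", n_dropped)
        df = df.loc[ok].reset_index(drop=True)
        df["pos"] = df["pos"].astype(np.int64)

        # p / |z| consistency is advisory only (published stats are rounded,
        # GWAS p-values may come from a t reference)
        with np.errstate(over="ignore"):
            p_norm = 2.0 * sps.norm.sf(np.abs(df["z"].to_numpy()))
        mism = np.abs(df["p"].to_numpy() - p_norm) > 1e-6 * np.maximum(p_norm, 1e-300)
        if mism.any():
            logger.warning(
                "%d/%d rows have p inconsistent with |z| under the two-sided "
                "normal beyond 1e-6 relative", int(mism.sum()), len(df),
            )
        return cls(df, n_dropped=n_dropped)

    def records(self) -> Iterable[SnpRecord]:
        for row in self.table.itertuples(index=False):
            yield SnpRecord(row.snp, row.chrom, int(row.pos), row.ea, row.oa, row.eaf)


def _default_column_map() -> dict:
    return {c: i for c, i in zip(SUMMARY_COLUMNS, _INTERNAL)}


def read_summary_stats(path, column_map: Mapping[str, str] | None = None) -> SummaryStats:
    """Read a tab-delimited summary-statistics file.

    ``column_map`` maps file header names to canonical names (``SNP``, ``CHR``,
    ``POS``, ``EA``, ``OA``, ``EAF``, ``BETA``, ``SE``, ``P``, ``N``, ``Z``);
    by default the canonical names themselves (case-insensitive) are expected.
    Rows violating the :class:`SummaryStats` invariants are dropped and
    counted; a missing mandatory column raises :class:`FormatError`.
    """
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, na_values=_NA_VALUES,
                          keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty summary-statistics file") from exc
    # column_map is canonical name -> file header name; invert to rename
    lookup = {v: k.upper() for k, v in (column_map or {}).items()}
    rename = {col: lookup.get(col, col.upper()) for col in raw.columns}
    raw = raw.rename(columns=rename)
    for col in _MANDATORY:
        if col not in raw.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    canon_to_internal = _default_column_map()
    frame = pd.DataFrame({canon_to_internal[c]: raw[c] for c in SUMMARY_COLUMNS
                          if c in raw.columns})
    return SummaryStats.from_frame(frame)


def _chrom_key(chrom: pd.Series) -> pd.Series:
    """Numeric-aware chromosome sort key (1..22 before X-style labels)."""
    num = pd.to_numeric(chrom, errors="coerce")
    return num.fillna(10_000).astype(float)


def write_summary_stats(stats: SummaryStats, path) -> None:
    """Write summary statistics sorted by (chrom, pos) with fixed formatting."""
    df = stats.table.copy()
    df = df.sort_values(by=["pos", "snp"], kind="mergesort")
    df = df.iloc[np.argsort(_chrom_key(df["chrom"]).to_numpy(), kind="stable")]
    out = pd.DataFrame()
    for canon, internal in zip(SUMMARY_COLUMNS, _INTERNAL):
        out[canon] = df[internal].to_numpy()
    fmt = "%.16g"
    for col in ("EAF", "BETA", "SE", "P", "Z"):
        out[col] = [("NA" if not np.isfinite(v) else fmt % v) for v in out[col]]
    out["N"] = [("NA" if not np.isfinite(v) else "%d" % round(v)) for v in
                pd.to_numeric(out["N"], errors="coerce")]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GenotypePanel:
    """Dosage matrix (n_samples x n_snps, effect-allele counts in [0, 2])."""

    sample_ids: list[str]
    snps: list[SnpRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snps)):
            raise FormatError(
                f"dosage matrix shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def eaf(self) -> np.ndarray:
        """Per-SNP effect-allele frequency (mean dosage / 2, missing ignored)."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.eaf()
        return np.minimum(f, 1.0 - f)

    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]


def _read_vcf(path) -> GenotypePanel:
    from cyvcf2 import VCF  # deferred: htslib import is comparatively heavy

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib reports its own diagnostics
        raise FormatError(f"{path}: cannot parse VCF ({exc})") from exc
    samples = list(vcf.samples)
    snps: list[SnpRecord] = []
    columns: list[np.ndarray] = []
    n_multi = 0
    try:
        for var in vcf:
            if len(var.ALT) != 1:
                n_multi += 1
                continue
            ds = None
            try:
                ds = var.format("DS")
            except KeyError:
                ds = None
            if ds is not None:
                dose = np.asarray(ds, dtype=float).reshape(len(samples), -1)[:, 0]
            else:
                gts = np.asarray(var.genotypes, dtype=int)
                a = gts[:, :2]
                dose = np.where((a < 0).any(axis=1), np.nan,
                                (a > 0).sum(axis=1).astype(float))
            snps.append(SnpRecord(var.ID or f"{var.CHROM}:{var.POS}",
                                  str(var.CHROM), int(var.POS),
                                  str(var.ALT[0]).upper(), str(var.REF).upper()))
            columns.append(dose)
    except Exception as exc:
        raise FormatError(f"{path}: malformed VCF record ({exc})") from exc
    if n_multi:
        logger.warning("%s: skipped %d multi-allelic sites", path, n_multi)
    if not snps:
        raise EmptyInputError(f"{path}: no usable biallelic variants")
    dosages = np.column_stack(columns)
    return GenotypePanel(samples, snps, dosages)


def _read_matrix(path) -> GenotypePanel:
    meta: dict[str, SnpRecord] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##SNP\t"):
                _, sid, chrom, pos, ea, oa = line.split("\t")
                meta[sid] = SnpRecord(sid, chrom, int(pos), ea.upper(), oa.upper())
            elif header is None:
                header = line.split("\t")
            else:
                fields = line.split("\t")
                if len(fields) != len(header):
                    raise FormatError(f"{path}:{lineno}: expected "
                                      f"{len(header)} fields, got {len(fields)}")
                rows.append(fields)
    if header is None:
        raise EmptyInputError(f"{path}: empty genotype matrix")
    snp_ids = header[1:]
    sample_ids = [r[0] for r in rows]
    dosages = np.array([[math.nan if v in _NA_VALUES else float(v) for v in r[1:]]
                        for r in rows], dtype=float).reshape(len(rows), len(snp_ids))
    snps = [meta.get(s, SnpRecord(s, "0", i + 1, "A", "C"))
            for i, s in enumerate(snp_ids)]
    return GenotypePanel(sample_ids, snps, dosages)


def read_genotypes(path, format: str = "auto") -> GenotypePanel:
    """Read a genotype panel from a VCF (GT/DS) or a plain dosage matrix.

    For VCF, the effect allele is ALT; DS is preferred over GT when both are
    present; multi-allelic sites are skipped with a warning.
    """
    if format == "auto":
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "matrix"
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotype_matrix(panel: GenotypePanel, path) -> None:
    """Write a panel as a tab-delimited matrix with ##SNP metadata lines."""
    with open(path, "w") as fh:
        for s in panel.snps:
            fh.write(f"##SNP\t{s.snp_id}\t{s.chrom}\t{s.pos}\t"
                     f"{s.effect_allele}\t{s.other_allele}\n")
        fh.write("IID\t" + "\t".join(panel.snp_ids()) + "\n")
        for i, sid in enumerate(panel.sample_ids):
            vals = ("NA" if not np.isfinite(v) else "%.16g" % v
                    for v in panel.dosages[i])
            fh.write(sid + "\t" + "\t".join(vals) + "\n")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PhenotypeTable:
    """Per-sample trait values (missing allowed) and covariates.

    ``frame`` is indexed by unique sample id; ``traits`` and ``covariates``
    name its columns.  Rows with every trait missing are dropped on
    construction.  ``meta`` carries generator provenance (e.g. the fraction
    of values excluded by inclusion windows).
    """

    frame: pd.DataFrame
    traits: tuple[str, ...]
    covariates: tuple[str, ...] = ()
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame.index.duplicated().any():
            raise FormatError("duplicate sample ids in phenotype table")
        keep = self.frame[list(self.traits)].notna().any(axis=1)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropped %d samples with all traits missing", n_drop)
            self.frame = self.frame.loc[keep]


def read_phenotypes(path, traits: Sequence[str],
                    covariates: Sequence[str] = ()) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    if "IID" not in df.columns:
        raise FormatError(f"{path}: missing mandatory column 'IID'")
    for col in list(traits) + list(covariates):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.set_index(df["IID"].astype(str)).drop(columns=["IID"])
    return PhenotypeTable(df, tuple(traits), tuple(covariates))


def write_phenotypes(table: PhenotypeTable, path) -> None:
    out = table.frame.copy()
    out.insert(0, "IID", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


# ---------------------------------------------------------------------------
# GRM text-triplet dialect (GCTA-compatible)
# ---------------------------------------------------------------------------

def write_grm(grm, path_prefix) -> None:
    """Write a GRM as text triplets (i, j, n_snps, value; 1-based lower
    triangle including the diagonal) plus a ``.grm.id`` file."""
    prefix = str(path_prefix)
    ids = list(grm.ids)
    a = np.asarray(grm.matrix, dtype=float)
    with open(prefix + ".grm.txt", "w") as fh:
        for i in range(len(ids)):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.n_snps}\t{'%.12g' % a[i, j]}\n")
    with open(prefix + ".grm.id", "w") as fh:
        for sid in ids:
            fh.write(f"{sid}\n")


def read_grm(path_prefix):
    """Read a text-triplet GRM; validates triplet count and id uniqueness."""
    from .greml_rg import GRM  # local import: GRM lives with the REML code

    prefix = str(path_prefix)
    ids = [line.strip() for line in open(prefix + ".grm.id") if line.strip()]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{prefix}.grm.id: duplicate sample ids")
    n = len(ids)
    a = np.full((n, n), np.nan)
    n_snps = None
    count = 0
    with open(prefix + ".grm.txt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                i_s, j_s, m_s, v_s = line.split()
                i, j, m, v = int(i_s), int(j_s), int(m_s), float(v_s)
            except ValueError as exc:
                raise FormatError(f"{prefix}.grm.txt:{lineno}: bad triplet") from exc
            if not (1 <= j <= i <= n):
                raise FormatError(f"{prefix}.grm.txt:{lineno}: index out of range")
            a[i - 1, j - 1] = v
            a[j - 1, i - 1] = v
            n_snps = m
            count += 1
    if count != n * (n + 1) // 2:
        raise FormatError(
            f"{prefix}.grm.txt: expected {n * (n + 1) // 2} triplets, got {count}"
        )
    return GRM(ids=ids, matrix=a, n_snps=int(n_snps))


def read_config(path) -> dict[str, str]:
    """Flat ``key = value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}: expected 'key = value', got {line!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            out[key] = val
    return out
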