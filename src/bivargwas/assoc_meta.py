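"""Univariate association, genomic control and fixed-effects meta-analysis.

Produces the two per-trait summary-statistic streams the bivariate combined
test consumes: additive-model OLS per SNP on individual-level data, genomic
control (GC) estimation/adjustment of each stream, and inverse-variance
fixed-effects meta-analysis across studies with allele alignment.

GC convention: the inflation factor is lambda = median(z^2) / 0.4549364 (the
median of a 1-df chi-square); statistics are deflated only when lambda > 1.
By default GC is applied per study before meta-analysis and once more to the
meta-analysed stream ("double GC"), each application individually
toggleable.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import GenotypePanel, PhenotypeTable, SummaryStats, is_palindromic

logger = logging.getLogger(__name__)

__all__ = [
    "StudyResult",
    "MetaResult",
    "run_gwas",
    "genomic_control",
    "meta_fixed_effects",
    "align_orientation",
    "CHI2_1_MEDIAN",
    "PALINDROME_EAF_MARGIN",
]

#: median of the 1-df chi-square distribution (GC denominator)
CHI2_1_MEDIAN = 0.4549364
#: |eaf - 0.5| must exceed this on both sides to frequency-align a
#: palindromic SNP; closer to 0.5 the orientation is ambiguous -> excluded
PALINDROME_EAF_MARGIN = 0.08

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclasses.dataclass
class StudyResult:
    """One study's summary statistics plus its GC inflation factor."""

    study_id: str
    stats: SummaryStats
    lambda_gc: float = 1.0

    def __post_init__(self) -> None:
        if not self.lambda_gc > 0:
            raise ValueError("lambda_gc must be positive")


@dataclasses.dataclass
class MetaResult:
    """Combined summary statistics with per-SNP study counts and Cochran's Q."""

    stats: SummaryStats
    n_studies: pd.Series       # per SNP
    q_stat: pd.Series          # Cochran's Q per SNP
    q_df: pd.Series            # its degrees of freedom (k - 1)
    n_excluded: int = 0        # records dropped for irreconcilable alleles


def run_gwas(panel: GenotypePanel, phenotypes: PhenotypeTable, trait: str,
             covariates: Sequence[str] = ()) -> SummaryStats:
    """Per-SNP additive-model OLS of ``trait`` on dosage plus covariates.

    Implemented by residualizing trait and dosages on the covariate design
    (Frisch-Waugh), which is exact OLS for the dosage coefficient.  Two-sided
    p-values use the t reference with n - q - 1 degrees of freedom.  Samples
    with a missing trait value are dropped; SNPs monomorphic in the analyzed
    subset get missing statistics and are counted.
    """
    if trait not in phenotypes.traits:
        raise ValueError(f"unknown trait {trait!r}")
    common = [i for i, sid in enumerate(panel.sample_ids)
              if sid in phenotypes.frame.index]
    frame = phenotypes.frame.loc[[panel.sample_ids[i] for i in common]]
    y_all = frame[trait].to_numpy(dtype=float)
    keep = np.isfinite(y_all)
    for cov in covariates:
        keep &= np.isfinite(frame[cov].to_numpy(dtype=float))
    n = int(keep.sum())
    if n < 10:
        raise ValueError(f"only {n} non-missing phenotype rows (need >= 10)")
    y = y_all[keep]
    G = panel.dosages[np.asarray(common)[keep], :]

    W = np.column_stack([np.ones(n)] +
                        [frame[c].to_numpy(dtype=float)[keep] for c in covariates])
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("covariate design is rank deficient")
    Q, _ = np.linalg.qr(W)
    yr = y - Q @ (Q.T @ y)
    Gr = G - Q @ (Q.T @ G)

    sxx = np.einsum("ij,ij->j", Gr, Gr)
    syy = float(yr @ yr)
    sxy = yr @ Gr
    df = n - W.shape[1] - 1
    poly = sxx > 1e-10 * n  # residual dosage variance left after projection
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("run_gwas(%s): %d SNPs monomorphic/collinear in subset",
                    trait, n_mono)
    beta = np.full(panel.n_snps, np.nan)
    se = np.full(panel.n_snps, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta[poly] = sxy[poly] / sxx[poly]
        rss = syy - beta[poly] ** 2 * sxx[poly]
        sigma2 = np.maximum(rss, 0.0) / df
        se[poly] = np.sqrt(sigma2 / sxx[poly])
        # noiseless fits give rss = 0; keep SE positive so z stays finite
        se = np.maximum(se, np.abs(beta) * 1e-15 + 1e-300)
        tstat = beta / se
    p = 2.0 * sps.t.sf(np.abs(tstat), df)
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)

    eaf = G.mean(axis=0) / 2.0
    tab = pd.DataFrame({
        "snp": panel.snp_ids(),
        "chrom": [s.chrom for s in panel.snps],
        "pos": [s.pos for s in panel.snps],
        "ea": [s.effect_allele for s in panel.snps],
        "oa": [s.other_allele for s in panel.snps],
        "eaf": eaf, "beta": beta, "se": se, "p": p,
        "n": float(n), "z": tstat,
    })
    return SummaryStats.from_frame(tab)


def genomic_control(stats: SummaryStats) -> tuple[float, SummaryStats]:
    """Estimate the GC inflation factor and deflate the statistics.

    lambda = median(z^2) / 0.4549364.  When lambda > 1 every z is divided by
    sqrt(lambda) (equivalently the SE is inflated) and p is recomputed from
    the two-sided normal; when lambda <= 1 the statistics are returned
    unchanged (no deflation rule) but lambda is still reported.
    """
    z = stats.table["z"].to_numpy(dtype=float)
    z = z[np.isfinite(z)]
    if len(z) < 100:
        raise ValueError(f"genomic control needs >= 100 SNPs, got {len(z)}")
    lam = float(np.median(z ** 2) / CHI2_1_MEDIAN)
    if lam <= 1.0:
        return lam, stats
    adj = stats.table.copy()
    scale = np.sqrt(lam)
    adj["z"] = adj["z"] / scale
    adj["se"] = adj["se"] * scale
    adj["p"] = np.clip(2.0 * sps.norm.sf(np.abs(adj["z"].to_numpy())),
                       np.nextafter(0.0, 1.0), 1.0)
    return lam, SummaryStats(adj, n_dropped=stats.n_dropped)


def align_orientation(ref_ea, ref_oa, ea, oa, eaf=None, ref_eaf=None,
                      margin: float = PALINDROME_EAF_MARGIN):
    """Sign of a record's effect relative to a reference effect allele.

    Returns +1 (same orientation), -1 (effect/other swapped: flip beta/z
    sign and eaf) or None when the alleles are irreconcilable.  Palindromic
    pairs are oriented by effect-allele frequency when both frequencies are
    at least ``margin`` away from 0.5, otherwise excluded; non-palindromic
    mismatches are retried under strand complement (logged by callers).
    """
    pair, ref_pair = (ea, oa), (ref_ea, ref_oa)
    if is_palindromic(ea, oa):
        if {ea, oa} != {ref_ea, ref_oa}:
            return None
        if eaf is None or ref_eaf is None or np.isnan(eaf) or np.isnan(ref_eaf):
            return None
        if abs(eaf - 0.5) <= margin or abs(ref_eaf - 0.5) <= margin:
            return None
        return 1 if (eaf - 0.5) * (ref_eaf - 0.5) > 0 else -1
    if pair == ref_pair:
        return 1
    if pair == (ref_oa, ref_ea):
        return -1
    comp = (_COMPLEMENT.get(ea), _COMPLEMENT.get(oa))
    if comp == ref_pair:
        return 1
    if comp == (ref_oa, ref_ea):
        return -1
    return None


def _oriented(ref: pd.DataFrame, study: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Merge a study onto the reference alleles; returns oriented rows and
    the count excluded for irreconcilable alleles."""
    merged = study.merge(ref, on="snp", suffixes=("", "_ref"))
    signs = np.array([
        align_orientation(r.ea_ref, r.oa_ref, r.ea, r.oa, r.eaf, r.eaf_ref)
        for r in merged.itertuples(index=False)
    ], dtype=object)
    bad = np.array([s is None for s in signs])
    n_excluded = int(bad.sum())
    merged = merged.loc[~bad].copy()
    sgn = signs[~bad].astype(float)
    merged["beta"] *= sgn
    merged["z"] *= sgn
    merged["eaf"] = np.where(sgn < 0, 1.0 - merged["eaf"], merged["eaf"])
    return merged, n_excluded


def meta_fixed_effects(studies: Sequence[StudyResult | SummaryStats]) -> MetaResult:
    """Inverse-variance fixed-effects meta-analysis over allele-aligned studies.

    Weights are 1/SE^2; combined beta = sum(w b)/sum(w), SE = 1/sqrt(sum w),
    two-sided normal p.  Alleles are aligned to the first study reporting
    each SNP; records whose alleles cannot be reconciled by swapping (or by
    unambiguous strand complement) are excluded and counted.  Cochran's Q is
    reported per SNP but never filtered on.
    """
    tables = [(s.stats if isinstance(s, StudyResult) else s).table for s in studies]
    if not tables:
        raise ValueError("no studies supplied")
    ref = None
    for tab in tables:
        cur = tab[["snp", "chrom", "pos", "ea", "oa", "eaf"]]
        ref = cur if ref is None else pd.concat(
            [ref, cur.loc[~cur["snp"].isin(ref["snp"])]])
    ref = ref.rename(columns={"chrom": "chrom_ref", "pos": "pos_ref",
                              "ea": "ea_ref", "oa": "oa_ref", "eaf": "eaf_ref"})

    order = ref["snp"].tolist()
    idx = {s: i for i, s in enumerate(order)}
    nsnp = len(order)
    sw = np.zeros(nsnp); swb = np.zeros(nsnp); swb2 = np.zeros(nsnp)
    k = np.zeros(nsnp); ntot = np.zeros(nsnp)
    sum_eaf = np.zeros(nsnp); k_eaf = np.zeros(nsnp)
    n_excluded = 0
    for tab in tables:
        merged, nexc = _oriented(ref, tab)
        n_excluded += nexc
        rows = merged["snp"].map(idx).to_numpy()
        w = 1.0 / merged["se"].to_numpy() ** 2
        b = merged["beta"].to_numpy()
        np.add.at(sw, rows, w)
        np.add.at(swb, rows, w * b)
        np.add.at(swb2, rows, w * b * b)
        np.add.at(k, rows, 1.0)
        np.add.at(ntot, rows, np.nan_to_num(merged["n"].to_numpy()))
        eaf_vals = merged["eaf"].to_numpy(dtype=float)
        has_eaf = np.isfinite(eaf_vals)
        np.add.at(sum_eaf, rows[has_eaf], eaf_vals[has_eaf])
        np.add.at(k_eaf, rows[has_eaf], 1.0)
    if n_excluded:
        logger.info("meta_fixed_effects: excluded %d records with "
                    "irreconcilable alleles", n_excluded)
    present = k > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = swb / sw
        se = 1.0 / np.sqrt(sw)
        z = beta / se
        q = swb2 - swb ** 2 / sw
    p = np.clip(2.0 * sps.norm.sf(np.abs(z)), np.nextafter(0.0, 1.0), 1.0)
    out = pd.DataFrame({
        "snp": order,
        "chrom": ref["chrom_ref"].to_numpy(),
        "pos": ref["pos_ref"].to_numpy(),
        "ea": ref["ea_ref"].to_numpy(),
        "oa": ref["oa_ref"].to_numpy(),
        "eaf": np.where(k_eaf > 0, sum_eaf / np.maximum(k_eaf, 1), np.nan),
        "beta": beta, "se": se, "p": p, "n": ntot, "z": z,
    }).loc[present]
    stats = SummaryStats.from_frame(out)
    snp_index = stats.table["snp"]
    kept = stats.table["snp"].map(idx).to_numpy()
    return MetaResult(
        stats=stats,
        n_studies=pd.Series(k[kept].astype(int), index=snp_index.to_numpy()),
        q_stat=pd.Series(np.maximum(q[kept], 0.0), index=snp_index.to_numpy()),
        q_df=pd.Series(np.maximum(k[kept] - 1, 0).astype(int),
                       index=snp_index.to_numpy()),
        n_excluded=n_excluded,
    )
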