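"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator produces independent Hardy-Weinberg genotype panels and a
bivariate quantitative phenotype pair — a menarche-like trait (years, mean
13, SD 1.5, included when recalled between 9 and 17) and a menopause-like
trait (years, mean 51, SD 4, included between 40 and 60) — with a polygenic
architecture of specified per-trait heritabilities and genetic correlation,
partially overlapping trait measurement, and optional planted pleiotropic or
trait-specific SNP effects.  A direct simulator of correlated per-SNP
Z-statistic pairs supports fast calibration studies of the combined test
without individual-level data.

Defaults mirror the study population the pipeline emulates: h2 = 0.5 for
both traits, genetic correlation 0.138, and roughly a third of the cohort
measured for both traits.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .io_formats import GenotypePanel, PhenotypeTable, SnpRecord
from .lifespan import EffectClass, classify_signs

logger = logging.getLogger(__name__)

__all__ = [
    "ArchitectureSpec",
    "TraitWindow",
    "MENARCHE_WINDOW",
    "MENOPAUSE_WINDOW",
    "simulate_genotypes",
    "simulate_bivariate_phenotypes",
    "simulate_null_zscores",
    "classify_planted_effect",
]


@dataclasses.dataclass(frozen=True)
class TraitWindow:
    """Inclusion window for a trait, inclusive on both ends."""

    trait: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.trait}: window lower bound must be < upper")

    def contains(self, values: np.ndarray) -> np.ndarray:
        return (values >= self.lower) & (values <= self.upper)


MENARCHE_WINDOW = TraitWindow("menarche", 9.0, 17.0)
MENOPAUSE_WINDOW = TraitWindow("menopause", 40.0, 60.0)

#: affine map from the standardized liability to reported trait units
TRAIT_SCALES = {"menarche": (13.0, 1.5), "menopause": (51.0, 4.0)}


@dataclasses.dataclass(frozen=True)
class ArchitectureSpec:
    """Generative architecture for a two-trait cohort.

    planted_effects are (snp index, beta_trait1, beta_trait2) on the
    standardized-genotype / standardized-liability scale; a planted beta b
    contributes a per-SNP association Z of about b * sqrt(n_observed).
    """

    n_samples: int = 4000
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2: tuple[float, float] = (0.5, 0.5)
    r_g: float = 0.138
    r_e: float = 0.1
    overlap_fraction: float = 0.36
    planted_effects: tuple[tuple[int, float, float], ...] = ()
    seed: int = 0
    ld_blocks: tuple[int, float] | None = None  # (block size, dosage correlation)
    snp_spacing_bp: int = 500_000

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_snps < 1:
            raise ValueError("n_samples and n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for h in self.h2:
            if not 0 <= h <= 1:
                raise ValueError("h2 must lie in [0, 1]")
        if abs(self.r_g) > 1 or abs(self.r_e) > 1:
            raise ValueError("|r_g| and |r_e| must be <= 1 (PSD covariance)")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must lie in [0, 1]")


def _chrom_pos(i: int, spacing: int) -> tuple[str, int]:
    """Lay SNPs over 22 autosomes in contiguous blocks."""
    per_chrom = 10_000  # ample; position resets per chromosome
    chrom = 1 + (i // per_chrom) % 22
    return str(chrom), 1 + (i % per_chrom) * spacing


def simulate_genotypes(spec: ArchitectureSpec,
                       rng: np.random.Generator | None = None) -> GenotypePanel:
    """Draw an independent-SNP dosage panel, Binomial(2, p) per SNP.

    Per-SNP allele frequencies are uniform on ``spec.maf_range``; the effect
    allele is the counted allele.  With ``spec.ld_blocks = (size, rho)`` the
    panel is generated in blocks whose non-lead SNPs copy each lead gamete
    with retention probability rho, giving dosage correlation rho with the
    block lead — used only by the LD-proxy machinery.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n, m = spec.n_samples, spec.n_snps
    p = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m)
    if spec.ld_blocks is None:
        dosages = rng.binomial(2, p[None, :], size=(n, m)).astype(float)
    else:
        size, rho = spec.ld_blocks
        if not (0 <= rho <= 1):
            raise ValueError("LD block correlation must lie in [0, 1]")
        gam = np.empty((n, m, 2), dtype=np.int8)
        for j in range(m):
            lead = j - (j % size)
            if j == lead:
                gam[:, j] = rng.random((n, 2)) < p[j]
            else:
                p[j] = p[lead]
                keep = rng.random((n, 2)) < rho
                fresh = rng.random((n, 2)) < p[lead]
                gam[:, j] = np.where(keep, gam[:, lead], fresh)
        dosages = gam.sum(axis=2).astype(float)
    sample_ids = [f"S{i:06d}" for i in range(n)]
    snps = []
    for i in range(m):
        chrom, pos = _chrom_pos(i, spec.snp_spacing_bp)
        snps.append(SnpRecord(f"snp{i:06d}", chrom, pos, "A", "G", eaf=p[i]))
    return GenotypePanel(sample_ids, snps, dosages)


def standardize_dosages(dosages: np.ndarray) -> np.ndarray:
    """Center at 2p-hat and scale by sqrt(2 p-hat (1-p-hat)) per SNP.

    Matches the GRM standardization, so effects planted on this scale are
    the ones the variance-component machinery sees.  Monomorphic columns
    standardize to all-zero.
    """
    p = dosages.mean(axis=0) / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    with np.errstate(invalid="ignore", divide="ignore"):
        xs = (dosages - 2.0 * p) / sd
    xs[:, sd == 0] = 0.0
    return xs


def _mvn(rng: np.random.Generator, cov: np.ndarray, size: int) -> np.ndarray:
    """Sample MVN(0, cov) tolerating singular covariance (eigen route)."""
    w, v = np.linalg.eigh(np.asarray(cov, dtype=float))
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError("covariance matrix is not positive semi-definite")
    w = np.clip(w, 0.0, None)
    return rng.standard_normal((size, len(w))) @ (v * np.sqrt(w)).T


def _overlap_masks(n: int, overlap_fraction: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Observation masks for the two traits: one shared subcohort of size
    overlap_fraction * n, remainder split evenly into trait-exclusive halves."""
    n_both = int(round(overlap_fraction * n))
    idx = rng.permutation(n)
    both = idx[:n_both]
    rest = idx[n_both:]
    half = len(rest) // 2
    obs1 = np.zeros(n, dtype=bool)
    obs2 = np.zeros(n, dtype=bool)
    obs1[both] = True
    obs2[both] = True
    obs1[rest[:half + len(rest) % 2]] = True
    obs2[rest[half + len(rest) % 2:]] = True
    return obs1, obs2


def simulate_bivariate_phenotypes(
    panel: GenotypePanel,
    spec: ArchitectureSpec,
    windows: Sequence[TraitWindow] = (MENARCHE_WINDOW, MENOPAUSE_WINDOW),
    rng: np.random.Generator | None = None,
) -> PhenotypeTable:
    """Generate the two trait vectors for a panel under ``spec``.

    Per-SNP effect pairs are drawn zero-mean bivariate normal with
    covariance (h2_k, r_g)/m on the standardized-genotype scale and the
    realized genetic values are rescaled so each trait's genetic variance is
    exactly h2_k; residual pairs carry variance 1 - h2_k and correlation
    r_e.  Planted effects are added afterwards on the same scale.  The
    liabilities are affine-mapped to trait units, trait values outside their
    inclusion windows are set missing (inclusion filters of the emulated
    cohorts), and each trait is observed only on its overlap-design subset.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    if panel.n_samples != spec.n_samples or panel.n_snps != spec.n_snps:
        raise ValueError("panel dimensions do not match the architecture spec")
    n, m = panel.n_samples, panel.n_snps
    h1, h2_ = spec.h2
    xs = standardize_dosages(panel.dosages)

    cov_b = np.array([
        [h1, spec.r_g * np.sqrt(h1 * h2_)],
        [spec.r_g * np.sqrt(h1 * h2_), h2_],
    ]) / m
    b = _mvn(rng, cov_b, m)
    g = xs @ b
    for k, hk in enumerate((h1, h2_)):
        sd = g[:, k].std()
        if hk > 0 and sd > 0:
            g[:, k] *= np.sqrt(hk) / sd
        else:
            g[:, k] = 0.0
    cov_e = np.array([
        [1 - h1, spec.r_e * np.sqrt((1 - h1) * (1 - h2_))],
        [spec.r_e * np.sqrt((1 - h1) * (1 - h2_)), 1 - h2_],
    ])
    y = g + _mvn(rng, cov_e, n)

    for idx, b1, b2 in spec.planted_effects:
        if xs[:, idx].std() == 0:
            raise ValueError(f"planted effect on monomorphic SNP index {idx}")
        y[:, 0] += b1 * xs[:, idx]
        y[:, 1] += b2 * xs[:, idx]

    frame = {}
    excluded = {}
    obs1, obs2 = _overlap_masks(n, spec.overlap_fraction, rng)
    for k, (window, obs) in enumerate(zip(windows, (obs1, obs2))):
        mu, sd = TRAIT_SCALES.get(window.trait, (0.0, 1.0))
        vals = mu + sd * y[:, k]
        inside = window.contains(vals)
        excluded[window.trait] = float((~inside & obs).sum() / max(obs.sum(), 1))
        vals = np.where(inside & obs, vals, np.nan)
        frame[window.trait] = vals
    logger.info("window exclusion fractions: %s", excluded)

    birth_year = rng.integers(1930, 1961, size=n).astype(float)
    df = _phenotype_frame(panel.sample_ids, frame, birth_year)
    traits = tuple(w.trait for w in windows)
    return PhenotypeTable(df, traits, covariates=("birth_year",),
                          meta={"excluded_fraction": excluded,
                                "n_both": int((obs1 & obs2).sum())})


def _phenotype_frame(sample_ids, trait_cols, birth_year):
    import pandas as pd

    df = pd.DataFrame(trait_cols, index=pd.Index(sample_ids, name="IID"))
    df["birth_year"] = birth_year
    return df


def simulate_null_zscores(n_snps: int, sigma: np.ndarray,
                          seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw i.i.d. per-SNP Z-statistic K-tuples from MVN(0, sigma).

    This is the statistic-level null the perturbation calibration assumes:
    correlated Z pairs whose covariance comes from sample overlap and
    phenotypic correlation, with no true association.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("sigma must be a square matrix")
    return _mvn(rng, sigma, n_snps)


def classify_planted_effect(beta1: float, beta2: float) -> EffectClass:
    """Lifespan class of a planted (menarche, menopause) effect pair."""
    return classify_signs(beta1, beta2)
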