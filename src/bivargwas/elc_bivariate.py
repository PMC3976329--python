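"""Empirical-weighted linear-combined (eLC) test for correlated Z statistics.

The statistic fuses K aligned signed per-SNP statistics T_k (here K = 2:
menarche and menopause meta-analysis Z scores) into

    S_eLC(T, c) = sum_k max(|T_k|, c) * |T_k|,        c >= 0.

At c = 0 this is the sum of squares of the T_k; for large c it approaches an
equal-weight linear combination of the |T_k|, so c interpolates between a
quadratic and a linear pooling of evidence.  The weighting constant is
chosen adaptively: the reported statistic is the minimum, over a fixed c
grid, of the rank-based p-value of S_eLC(T, c) under the null — and the same
minimisation is replicated inside every null draw, so the selection cost is
paid in the null and the type-I error is preserved by construction.

The null is calibrated by perturbation: draws from MVN(0, Sigma), where
Sigma is the K x K covariance of the observed Z statistics estimated from
the genome-wide sample covariance (nonzero off-diagonals arise from sample
overlap and phenotypic correlation between the traits).  Rank-based
p-values resolve down to about 10/B; beyond that a generalized-Pareto tail
fitted to the extreme null draws extrapolates, with a recorded floor below
which no p-value is reported.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_C_GRID",
    "TestStatVector",
    "CovarianceEstimate",
    "ElcResult",
    "NullCalibration",
    "align_and_pair",
    "estimate_sigma",
    "elc_statistic",
    "perturbation_null",
    "elc_pvalue",
    "elc_pvalues",
    "bivariate_significance",
]

#: adaptive weighting-constant grid
DEFAULT_C_GRID = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0)
#: number of extreme null draws used for the generalized-Pareto tail fit
GPD_TAIL_COUNT = 250
#: empirical rank p-values are trusted down to this many exceedances
MIN_EMPIRICAL_EXCEEDANCES = 10


@dataclasses.dataclass(frozen=True)
class TestStatVector:
    """K aligned signed statistics for one SNP (shared effect allele)."""

    snp_id: str
    t: tuple[float, ...]

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.t)):
            raise ValueError(f"{self.snp_id}: non-finite test statistic")


@dataclasses.dataclass
class CovarianceEstimate:
    """Genome-wide estimate of the K x K null covariance of the statistics."""

    sigma: np.ndarray
    n_snps_used: int
    trimming: str = "none"

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        if not np.allclose(s, s.T):
            raise ValueError("sigma must be symmetric")
        if np.any(np.diag(s) <= 0):
            raise ValueError("sigma diagonal entries must be positive")
        self.sigma = s


@dataclasses.dataclass
class ElcResult:
    """Adaptive eLC outcome for one SNP."""

    snp_id: str
    s_elc: float
    c_selected: float
    p: float
    tail_method: str  # {"empirical", "gpd", "floor"}


@dataclasses.dataclass
class NullCalibration:
    """Perturbation null for the adaptive minimum-p eLC statistic.

    Holds, for each c in the grid, the sorted null S_eLC values together
    with a generalized-Pareto fit to their upper tail (on the S scale, so
    observed statistics beyond the Monte-Carlo support still resolve), the
    sorted per-draw minimized rank p-values, and the effective number of
    tests ``m_eff`` relating the minimized p to its tail probability,
    P(minp <= x) ~ m_eff * x for small x.  ``p_floor`` is the smallest
    p-value the calibration will report.
    """

    c_grid: np.ndarray
    B: int
    sigma: np.ndarray
    sorted_stats: np.ndarray      # (B, n_c), each column ascending
    sorted_minp: np.ndarray       # (B,) ascending
    seed: int | None
    gpd_threshold: np.ndarray | None = None   # per-c S value at the tail cut
    gpd_shape: np.ndarray | None = None
    gpd_scale: np.ndarray | None = None
    gpd_n_exceed: np.ndarray | None = None
    m_eff: float = 1.0
    p_floor: float = 1e-12
    warnings: tuple[str, ...] = ()

    @property
    def n_c(self) -> int:
        return len(self.c_grid)

    def summary(self) -> dict:
        """JSON-serialisable description (distributions omitted)."""
        return {
            "c_grid": list(map(float, self.c_grid)),
            "B": int(self.B),
            "sigma": np.asarray(self.sigma).tolist(),
            "seed": self.seed,
            "gpd": None if self.gpd_threshold is None else {
                "threshold_s": np.asarray(self.gpd_threshold).tolist(),
                "shape": np.asarray(self.gpd_shape).tolist(),
                "scale": np.asarray(self.gpd_scale).tolist(),
                "n_exceed": np.asarray(self.gpd_n_exceed).tolist(),
            },
            "m_eff": float(self.m_eff),
            "p_floor": float(self.p_floor),
            "warnings": list(self.warnings),
        }

    def save_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _check_psd(sigma: np.ndarray) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    w = np.linalg.eigvalsh(sigma)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError("sigma is not positive semi-definite")
    return sigma


def align_and_pair(stats1, stats2) -> tuple[pd.DataFrame, dict]:
    """Pair the two traits' statistics on shared SNPs, aligned in sign.

    Trait 2's z is sign-flipped when its effect allele is trait 1's other
    allele; palindromic SNPs follow the frequency rule (excluded when
    ambiguous); SNPs absent from either trait or with irreconcilable allele
    sets are omitted.  Returns (pairs, counts) where pairs has columns
    ``snp, chrom, pos, t1, t2, p1, p2`` and counts reports every exclusion.
    """
    from .assoc_meta import align_orientation

    t1 = stats1.table
    t2 = stats2.table
    merged = t1.merge(t2, on="snp", suffixes=("_1", "_2"))
    counts = {
        "only_trait1": len(t1) - len(merged),
        "only_trait2": len(t2) - len(merged),
        "incompatible_alleles": 0,
        "paired": 0,
    }
    signs = np.empty(len(merged))
    keep = np.ones(len(merged), dtype=bool)
    for i, r in enumerate(merged.itertuples(index=False)):
        s = align_orientation(r.ea_1, r.oa_1, r.ea_2, r.oa_2, r.eaf_2, r.eaf_1)
        if s is None:
            keep[i] = False
        else:
            signs[i] = s
    counts["incompatible_alleles"] = int((~keep).sum())
    merged = merged.loc[keep]
    pairs = pd.DataFrame({
        "snp": merged["snp"].to_numpy(),
        "chrom": merged["chrom_1"].to_numpy(),
        "pos": merged["pos_1"].to_numpy(),
        "t1": merged["z_1"].to_numpy(),
        "t2": merged["z_2"].to_numpy() * signs[keep],
        "p1": merged["p_1"].to_numpy(),
        "p2": merged["p_2"].to_numpy(),
    })
    counts["paired"] = len(pairs)
    if counts["incompatible_alleles"] or counts["only_trait1"] or counts["only_trait2"]:
        logger.info("align_and_pair: %s", counts)
    return pairs, counts


def estimate_sigma(pairs: pd.DataFrame | np.ndarray,
                   trim_z: float | None = None) -> CovarianceEstimate:
    """Sample covariance of the paired statistics over the genome.

    By default every SNP contributes (the genome-wide sample covariance of
    the Z statistics); with ``trim_z`` set, SNPs with max |T_k| >= trim_z
    are excluded to guard against strong true signal inflating the null
    covariance.  The result is projected to the nearest PSD matrix if
    numerically indefinite.
    """
    if isinstance(pairs, pd.DataFrame):
        t = pairs[["t1", "t2"]].to_numpy(dtype=float)
    else:
        t = np.asarray(pairs, dtype=float)
    t = t[np.isfinite(t).all(axis=1)]
    trimming = "none"
    if trim_z is not None:
        t = t[np.abs(t).max(axis=1) < trim_z]
        trimming = f"max|T| < {trim_z}"
    if len(t) < 1000:
        raise ValueError(f"estimate_sigma needs >= 1000 pairs, got {len(t)}")
    sigma = np.cov(t, rowvar=False)
    w, v = np.linalg.eigh(sigma)
    if w.min() < 0:
        sigma = (v * np.clip(w, 0.0, None)) @ v.T
        sigma = (sigma + sigma.T) / 2.0
    return CovarianceEstimate(sigma=sigma, n_snps_used=len(t), trimming=trimming)


def elc_statistic(t, c: float):
    """S_eLC(T, c) = sum_k max(|T_k|, c) * |T_k|, vectorised over rows.

    ``t`` is a length-K vector or an (n, K) array; a scalar or length-n
    array is returned accordingly.  c = 0 reduces to the sum of squares.
    """
    if c < 0:
        raise ValueError("c must be non-negative")
    at = np.abs(np.asarray(t, dtype=float))
    return (np.maximum(at, c) * at).sum(axis=-1)


def _rank_p_columns(sorted_stats: np.ndarray, s: np.ndarray, B: int) -> np.ndarray:
    """Per-c rank p-values (1 + #{null >= s}) / (B + 1) for rows of s."""
    n_c = sorted_stats.shape[1]
    p = np.empty((len(s), n_c))
    for j in range(n_c):
        cnt_ge = B - np.searchsorted(sorted_stats[:, j], s[:, j], side="left")
        p[:, j] = (1.0 + cnt_ge) / (B + 1.0)
    return p


def perturbation_null(sigma, c_grid: Sequence[float] = DEFAULT_C_GRID,
                      B: int = 100_000, seed: int | None = 0,
                      p_floor: float = 1e-12) -> NullCalibration:
    """Build the perturbation null for the adaptive minimum-p eLC statistic.

    Draws B vectors from MVN(0, sigma); for every draw computes, over the c
    grid, the rank-based p of its S_eLC against the same draws' per-c
    distribution and takes the minimum over c (the adaptive statistic).  The
    sorted minimized p-values are stored, and a generalized-Pareto tail is
    fitted to the most extreme draws (on -log p) for extrapolation beyond
    the empirical support.
    """
    sigma = _check_psd(sigma)
    if B < 1_000:
        raise ValueError("B must be at least 1000")
    warnings: list[str] = []
    if B < 10_000:
        warnings.append("B < 1e4: p-values below 1e-3 are not resolvable")
    c_grid = np.asarray(sorted(set(float(c) for c in c_grid)))
    if np.any(c_grid < 0):
        raise ValueError("c grid values must be non-negative")
    rng = np.random.default_rng(seed)
    w, v = np.linalg.eigh(sigma)
    draws = rng.standard_normal((B, sigma.shape[0])) @ \
        (v * np.sqrt(np.clip(w, 0.0, None))).T
    stats = np.column_stack([elc_statistic(draws, c) for c in c_grid])
    sorted_stats = np.sort(stats, axis=0)
    p_per_c = _rank_p_columns(sorted_stats, stats, B)
    # the null draws rank against themselves: use #{>= s}/B so each draw's
    # own exceedance count is >= 1 and p lies on {1/B, ..., 1}
    p_per_c = (p_per_c * (B + 1.0) - 1.0) / B
    minp = p_per_c.min(axis=1)
    sorted_minp = np.sort(minp)

    # per-c GPD tails on the statistic scale: these let an observed S far
    # beyond the Monte-Carlo support still map to a (continuous) per-c p
    n_tail = min(GPD_TAIL_COUNT, B // 10)
    gpd_threshold = gpd_shape = gpd_scale = gpd_n_exceed = None
    if n_tail >= 100:
        gpd_threshold = np.empty(len(c_grid))
        gpd_shape = np.empty(len(c_grid))
        gpd_scale = np.empty(len(c_grid))
        gpd_n_exceed = np.empty(len(c_grid), dtype=int)
        for j in range(len(c_grid)):
            u = sorted_stats[B - n_tail - 1, j]
            excess = sorted_stats[B - n_tail:, j] - u
            excess = excess[excess > 0]
            shape, _, scale = sps.genpareto.fit(excess, floc=0.0)
            gpd_threshold[j] = u
            gpd_shape[j] = shape
            gpd_scale[j] = scale
            gpd_n_exceed[j] = len(excess)
    else:
        warnings.append("B too small for a tail fit; empirical only")
    # effective number of tests: slope of the null minp CDF near zero,
    # estimated at the 100th order statistic
    k0 = min(100, B - 1)
    m_eff = k0 / (B * sorted_minp[k0 - 1]) if sorted_minp[k0 - 1] > 0 else 1.0
    m_eff = float(np.clip(m_eff, 1.0, len(c_grid)))
    if warnings:
        logger.warning("perturbation_null: %s", "; ".join(warnings))
    return NullCalibration(
        c_grid=c_grid, B=B, sigma=sigma, sorted_stats=sorted_stats,
        sorted_minp=sorted_minp, seed=seed, gpd_threshold=gpd_threshold,
        gpd_shape=gpd_shape, gpd_scale=gpd_scale, gpd_n_exceed=gpd_n_exceed,
        m_eff=m_eff, p_floor=p_floor, warnings=tuple(warnings),
    )


def elc_pvalues(t: np.ndarray, calibration: NullCalibration,
                snp_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Adaptive eLC p-values for an (n, K) array of statistic vectors.

    For each row, the observed minimized rank p over the c grid is compared
    with the calibration's null minimized p-values; beyond the empirical
    support the generalized-Pareto tail extrapolates, never below the
    calibration's recorded floor.  Returns a frame with columns
    ``snp, s_elc, c_selected, p, tail_method``.
    """
    t = np.atleast_2d(np.asarray(t, dtype=float))
    if t.shape[1] != calibration.sigma.shape[0]:
        raise ValueError("statistic dimension does not match the calibration")
    B = calibration.B
    stats_obs = np.column_stack([elc_statistic(t, c) for c in calibration.c_grid])
    p_per_c = _rank_p_columns(calibration.sorted_stats, stats_obs, B)
    # beyond each c's Monte-Carlo support, extrapolate with that c's GPD
    # tail so extreme statistics keep resolving
    if calibration.gpd_threshold is not None:
        for j in range(calibration.n_c):
            beyond = (stats_obs[:, j] > calibration.gpd_threshold[j]) & \
                (p_per_c[:, j] * (B + 1.0) - 1.0 < MIN_EMPIRICAL_EXCEEDANCES)
            if np.any(beyond):
                x = stats_obs[beyond, j] - calibration.gpd_threshold[j]
                sf = sps.genpareto.sf(x, calibration.gpd_shape[j], loc=0.0,
                                      scale=calibration.gpd_scale[j])
                p_per_c[beyond, j] = np.maximum(
                    calibration.gpd_n_exceed[j] / B * sf, 1e-300)
    jstar = np.argmin(p_per_c, axis=1)
    minp_obs = p_per_c[np.arange(len(t)), jstar]

    cnt_le = np.searchsorted(calibration.sorted_minp, minp_obs, side="right")
    p = (1.0 + cnt_le) / (B + 1.0)
    method = np.full(len(t), "empirical", dtype=object)

    floor = calibration.p_floor
    if B < 10_000:
        floor = max(floor, 1e-3)  # empirical resolution limit
    # deep tail: P(minp <= x) ~ m_eff * x once x is below the empirical
    # resolution of the null minimized p-values
    deep = cnt_le < MIN_EMPIRICAL_EXCEEDANCES
    if np.any(deep):
        p[deep] = calibration.m_eff * minp_obs[deep]
        method[deep] = "gpd"
    at_floor = p <= floor
    p = np.clip(p, floor, 1.0)
    method[at_floor] = "floor"

    s_sel = stats_obs[np.arange(len(t)), jstar]
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(len(t))]
    return pd.DataFrame({
        "snp": list(snp_ids),
        "s_elc": s_sel,
        "c_selected": calibration.c_grid[jstar],
        "p": p,
        "tail_method": method,
    })


def elc_pvalue(t: Sequence[float] | TestStatVector,
               calibration: NullCalibration) -> ElcResult:
    """Adaptive eLC p-value for a single statistic vector."""
    if isinstance(t, TestStatVector):
        snp_id, vec = t.snp_id, np.asarray(t.t)
    else:
        snp_id, vec = "snp0", np.asarray(t, dtype=float)
    row = elc_pvalues(vec[None, :], calibration, snp_ids=[snp_id]).iloc[0]
    return ElcResult(snp_id=row["snp"], s_elc=float(row["s_elc"]),
                     c_selected=float(row["c_selected"]), p=float(row["p"]),
                     tail_method=str(row["tail_method"]))


def bivariate_significance(results: pd.DataFrame,
                           p_gws: float = 5e-8,
                           p_suggestive: float = 1e-7) -> pd.DataFrame:
    """Apply the bivariate significance rules to scored SNPs.

    ``results`` needs columns ``p`` (bivariate), ``p1`` and ``p2``.  A SNP is
    genome-wide significant when p < 5e-8 — except when one of the
    individual trait p-values is lower than the bivariate p-value, in which
    case the signal is taken as driven by that single trait and not flagged
    as pleiotropic.  The same exception applies at the suggestive threshold
    (p < 1e-7).  SNPs with a missing univariate p are skipped and counted.
    """
    out = results.copy()
    p = out["p"].to_numpy(dtype=float)
    p1 = out["p1"].to_numpy(dtype=float)
    p2 = out["p2"].to_numpy(dtype=float)
    ok = np.isfinite(p1) & np.isfinite(p2) & np.isfinite(p)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.info("bivariate_significance: skipped %d SNPs with missing "
                    "univariate p", n_skipped)
    puni = np.minimum(p1, p2)
    exception = ok & (puni < p)
    gws = ok & (p < p_gws) & ~exception
    sugg = ok & (p < p_suggestive) & ~exception & ~gws
    flag = np.full(len(out), "none", dtype=object)
    flag[sugg] = "suggestive"
    flag[gws] = "genome_wide"
    flag[~ok] = "skipped"
    driver = np.full(len(out), "", dtype=object)
    blocked = exception & (p < p_suggestive)
    driver[blocked] = np.where(p1[blocked] <= p2[blocked], "trait1", "trait2")
    out["significance"] = flag
    out["exception_driver"] = driver
    return out
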