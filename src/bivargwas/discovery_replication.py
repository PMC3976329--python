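"""Staged discovery / replication workflow around the bivariate scan.

Selects suggestive bivariate hits and thins them to independent leads,
searches the genotype panel for LD proxies more strongly associated with
either univariate trait, combines discovery and replication summary
statistics by fixed-effects meta-analysis, counts effect-direction
consistency between stages with an exact sign test, classifies the joint
effect directions into reproductive-lifespan classes, and writes the study
report tables.  ``run_synthetic_pipeline`` chains everything end to end on
generated cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import assoc_meta, elc_bivariate, synthetic_cohorts
from .io_formats import GenotypePanel, SummaryStats, write_summary_stats
from .lifespan import EffectClass, UnclassifiableEffectError, classify_signs

logger = logging.getLogger(__name__)

__all__ = [
    "HitRecord",
    "select_hits",
    "find_ld_proxies",
    "combine_stages",
    "direction_consistency",
    "classify_effect",
    "render_report",
    "run_synthetic_pipeline",
    "PipelineResult",
]

DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_R2_MIN = 0.8


@dataclasses.dataclass
class StageStats:
    """One trait's (beta, se, p, n) in one stage, on the shared effect allele."""

    beta: float
    se: float
    p: float
    n: float


@dataclasses.dataclass
class HitRecord:
    """A discovery lead with its replication outcome and lifespan class."""

    snp_id: str
    chrom: str
    pos: int
    p_bivariate: float
    discovery: dict      # trait -> StageStats
    replication: dict    # trait -> StageStats (may be absent per trait)
    combined: dict       # trait -> StageStats
    proxies: list = dataclasses.field(default_factory=list)  # (snp, r2, trait)
    effect_class: EffectClass | None = None
    flags: tuple[str, ...] = ()


def select_hits(elc_results: pd.DataFrame, threshold: float = 1e-7,
                window_bp: int = DEFAULT_WINDOW_BP) -> pd.DataFrame:
    """SNPs below the bivariate threshold, thinned to independent leads.

    Greedy lowest-p-first: the best remaining SNP becomes a lead and every
    other selected SNP on the same chromosome within ``window_bp`` (inclusive)
    of it is suppressed.
    """
    need = {"snp", "chrom", "pos", "p"}
    if not need.issubset(elc_results.columns):
        raise ValueError(f"elc_results must have columns {sorted(need)}")
    cand = elc_results.loc[elc_results["p"] < threshold].sort_values(
        ["p", "snp"], kind="mergesort")
    leads = []
    for row in cand.itertuples(index=False):
        if any(lead.chrom == row.chrom and abs(int(lead.pos) - int(row.pos))
               <= window_bp for lead in leads):
            continue
        leads.append(row)
    return pd.DataFrame(leads, columns=cand.columns)


def find_ld_proxies(panel: GenotypePanel, lead: str,
                    window_bp: int = DEFAULT_WINDOW_BP,
                    r2_min: float = DEFAULT_R2_MIN) -> list[tuple[str, float]]:
    """SNPs within +/- window_bp of the lead with dosage r^2 > r2_min.

    r^2 is the squared Pearson correlation of dosage columns; the lead
    itself is excluded; results are sorted by descending r^2.
    """
    ids = panel.snp_ids()
    try:
        j = ids.index(lead)
    except ValueError:
        raise ValueError(f"lead SNP {lead!r} not in panel") from None
    lead_rec = panel.snps[j]
    x = panel.dosages[:, j]
    if x.std() == 0:
        raise ValueError(f"lead SNP {lead!r} is monomorphic")
    out = []
    for i, rec in enumerate(panel.snps):
        if i == j or rec.chrom != lead_rec.chrom:
            continue
        if abs(rec.pos - lead_rec.pos) > window_bp:
            continue
        y = panel.dosages[:, i]
        if y.std() == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        if r * r > r2_min:
            out.append((rec.snp_id, float(r * r)))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def combine_stages(discovery: SummaryStats,
                   replication: SummaryStats) -> tuple[SummaryStats, list[str]]:
    """Fixed-effects inverse-variance combination of the two stages.

    Delegates to :func:`assoc_meta.meta_fixed_effects`; SNPs absent from the
    replication stage pass through as discovery-only and are flagged.
    """
    meta = assoc_meta.meta_fixed_effects([discovery, replication])
    single = meta.n_studies[meta.n_studies < 2].index.tolist()
    return meta.stats, single


def direction_consistency(hits: Sequence[HitRecord] | pd.DataFrame,
                          trait: str) -> tuple[int, int, float]:
    """Sign agreement of discovery vs replication betas for one trait.

    Returns (n_consistent, n_total, p) with p the two-sided exact binomial
    test of the consistent count against 0.5.  SNPs with a zero or missing
    beta in either stage are excluded from the count.
    """
    if isinstance(hits, pd.DataFrame):
        disc = hits["beta_discovery"].to_numpy(dtype=float)
        repl = hits["beta_replication"].to_numpy(dtype=float)
    else:
        disc, repl = [], []
        for h in hits:
            d = h.discovery.get(trait)
            r = h.replication.get(trait)
            disc.append(d.beta if d else np.nan)
            repl.append(r.beta if r else np.nan)
        disc, repl = np.asarray(disc), np.asarray(repl)
    ok = np.isfinite(disc) & np.isfinite(repl) & (disc != 0) & (repl != 0)
    n_total = int(ok.sum())
    n_excl = len(disc) - n_total
    if n_excl:
        logger.info("direction_consistency(%s): excluded %d SNPs with zero "
                    "or missing betas", trait, n_excl)
    if n_total == 0:
        return 0, 0, float("nan")
    n_cons = int((np.sign(disc[ok]) == np.sign(repl[ok])).sum())
    p = float(sps.binomtest(n_cons, n_total, 0.5).pvalue)
    return n_cons, n_total, p


def classify_effect(hit: HitRecord,
                    menarche_trait: str = "menarche",
                    menopause_trait: str = "menopause") -> EffectClass:
    """Lifespan class from the combined-stage betas (shared effect allele)."""
    b1 = hit.combined.get(menarche_trait)
    b2 = hit.combined.get(menopause_trait)
    if b1 is None or b2 is None:
        raise UnclassifiableEffectError(f"{hit.snp_id}: missing combined betas")
    return classify_signs(b1.beta, b2.beta)


def render_report(hits: Sequence[HitRecord], calibration, outdir,
                  config: dict | None = None,
                  consistency: dict | None = None) -> dict[str, Path]:
    """Write deterministic report tables: a lead-SNP table (bivariate p and
    lifespan class), a per-trait staged-results table, the calibration
    summary and a config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    lead_rows = []
    staged_rows = []
    for h in sorted(hits, key=lambda h: (h.p_bivariate, h.snp_id)):
        lead_rows.append({
            "snp": h.snp_id, "chrom": h.chrom, "pos": h.pos,
            "p_bivariate": "%.6g" % h.p_bivariate,
            "effect_class": h.effect_class.value if h.effect_class else "NA",
            "flags": ";".join(h.flags) if h.flags else "",
        })
        for trait in sorted(set(h.discovery) | set(h.combined)):
            row = {"snp": h.snp_id, "trait": trait}
            for stage_name, stage in (("discovery", h.discovery),
                                      ("replication", h.replication),
                                      ("combined", h.combined)):
                s = stage.get(trait)
                for field in ("beta", "se", "p", "n"):
                    row[f"{stage_name}_{field}"] = (
                        "NA" if s is None else "%.6g" % getattr(s, field))
            staged_rows.append(row)
    lead_cols = ["snp", "chrom", "pos", "p_bivariate", "effect_class", "flags"]
    paths["leads"] = outdir / "leads.tsv"
    pd.DataFrame(lead_rows, columns=lead_cols).to_csv(
        paths["leads"], sep="\t", index=False)
    staged_cols = (["snp", "trait"] +
                   [f"{s}_{f}" for s in ("discovery", "replication", "combined")
                    for f in ("beta", "se", "p", "n")])
    paths["staged"] = outdir / "staged_results.tsv"
    pd.DataFrame(staged_rows, columns=staged_cols).to_csv(
        paths["staged"], sep="\t", index=False)
    paths["calibration"] = outdir / "calibration.json"
    payload = calibration.summary() if calibration is not None else {}
    if consistency:
        payload["direction_consistency"] = consistency
    payload["config"] = config or {}
    with open(paths["calibration"], "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# End-to-end synthetic pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineResult:
    hits: list
    scored: pd.DataFrame          # per-SNP bivariate results with flags
    calibration: object
    truth: pd.DataFrame           # planted effects and their classes
    counts: dict
    summary_stats: dict           # (stage, trait) -> SummaryStats


def _stage_stats(stats: SummaryStats, snp: str) -> StageStats | None:
    rows = stats.table.loc[stats.table["snp"] == snp]
    if rows.empty:
        return None
    r = rows.iloc[0]
    return StageStats(float(r["beta"]), float(r["se"]), float(r["p"]),
                      float(r["n"]))


def run_synthetic_pipeline(
    arch: synthetic_cohorts.ArchitectureSpec,
    replication_n: int = 2000,
    b_calibration: int = 100_000,
    p_suggestive: float = 1e-7,
    p_gws: float = 5e-8,
    r2_min: float = DEFAULT_R2_MIN,
    window_bp: int = DEFAULT_WINDOW_BP,
    trim_z: float | None = None,
    outdir=None,
) -> PipelineResult:
    """Generate discovery and replication cohorts under ``arch`` and run the
    whole workflow: per-trait GWAS with GC, Z pairing, covariance
    estimation, perturbation calibration, adaptive eLC scan, significance
    rules, lead selection, staged combination and lifespan classification.

    The replication cohort shares the architecture (including planted
    effects) but is an independent sample of ``replication_n`` women.
    """
    disc_spec = arch
    repl_spec = dataclasses.replace(arch, n_samples=replication_n,
                                    seed=arch.seed + 7001)
    stats: dict[tuple[str, str], SummaryStats] = {}
    lambdas: dict[tuple[str, str], float] = {}
    panels = {}
    for stage, spec in (("discovery", disc_spec), ("replication", repl_spec)):
        panel = synthetic_cohorts.simulate_genotypes(spec)
        phen = synthetic_cohorts.simulate_bivariate_phenotypes(panel, spec)
        panels[stage] = panel
        for trait in phen.traits:
            covs = ("birth_year",) if trait == "menarche" else ()
            raw = assoc_meta.run_gwas(panel, phen, trait, covariates=covs)
            lam, adj = assoc_meta.genomic_control(raw)
            stats[(stage, trait)] = adj
            lambdas[(stage, trait)] = lam

    pairs, pair_counts = elc_bivariate.align_and_pair(
        stats[("discovery", "menarche")], stats[("discovery", "menopause")])
    sigma = elc_bivariate.estimate_sigma(pairs, trim_z=trim_z)
    calibration = elc_bivariate.perturbation_null(
        sigma.sigma, B=b_calibration, seed=arch.seed + 9001)
    scored = elc_bivariate.elc_pvalues(
        pairs[["t1", "t2"]].to_numpy(), calibration,
        snp_ids=pairs["snp"].tolist())
    scored = scored.merge(pairs[["snp", "chrom", "pos", "p1", "p2"]], on="snp")
    scored = elc_bivariate.bivariate_significance(scored, p_gws=p_gws,
                                                  p_suggestive=p_suggestive)

    leads = select_hits(scored, threshold=p_suggestive, window_bp=window_bp)
    hits: list[HitRecord] = []
    for lead in leads.itertuples(index=False):
        discovery, replication, combined = {}, {}, {}
        flags = []
        for trait in ("menarche", "menopause"):
            d = stats[("discovery", trait)]
            r = stats[("replication", trait)]
            comb, missing = combine_stages(d, r)
            discovery[trait] = _stage_stats(d, lead.snp)
            replication[trait] = _stage_stats(r, lead.snp)
            cs = _stage_stats(comb, lead.snp)
            combined[trait] = cs
            if lead.snp in missing:
                flags.append(f"no_replication_{trait}")
        try:
            proxies = [(s, r2, "both")
                       for s, r2 in find_ld_proxies(panels["discovery"],
                                                    lead.snp, window_bp, r2_min)]
        except ValueError:
            proxies = []
        hit = HitRecord(
            snp_id=lead.snp, chrom=str(lead.chrom), pos=int(lead.pos),
            p_bivariate=float(lead.p), discovery=discovery,
            replication=replication, combined=combined, proxies=proxies,
            flags=tuple(flags),
        )
        try:
            hit.effect_class = classify_effect(hit)
        except UnclassifiableEffectError:
            hit.flags = hit.flags + ("unclassifiable",)
        hits.append(hit)

    truth_rows = []
    for idx, b1, b2 in arch.planted_effects:
        truth_rows.append({
            "snp": f"snp{idx:06d}", "beta1": b1, "beta2": b2,
            "class": synthetic_cohorts.classify_planted_effect(b1, b2).value,
        })
    truth = pd.DataFrame(truth_rows, columns=["snp", "beta1", "beta2", "class"])

    consistency = {}
    if hits:
        for trait in ("menarche", "menopause"):
            n_cons, n_tot, p_sign = direction_consistency(hits, trait)
            consistency[trait] = {"consistent": n_cons, "total": n_tot,
                                  "p_sign_test": p_sign}
    counts = {
        "lambda_gc": {f"{k[0]}:{k[1]}": v for k, v in lambdas.items()},
        "pairing": pair_counts,
        "n_leads": len(hits),
        "n_genome_wide": int((scored["significance"] == "genome_wide").sum()),
        "n_suggestive": int((scored["significance"] == "suggestive").sum()),
    }
    if outdir is not None:
        paths = render_report(hits, calibration, outdir,
                              config={"p_suggestive": p_suggestive,
                                      "p_gws": p_gws, "r2_min": r2_min,
                                      "window_bp": window_bp,
                                      "B": b_calibration, "seed": arch.seed},
                              consistency=consistency)
        truth.to_csv(Path(outdir) / "truth.tsv", sep="\t", index=False)
        for (stage, trait), s in stats.items():
            write_summary_stats(s, Path(outdir) / f"{stage}_{trait}.tsv")
        counts["report_paths"] = {k: str(v) for k, v in paths.items()}
    counts["direction_consistency"] = consistency
    return PipelineResult(hits=hits, scored=scored, calibration=calibration,
                          truth=truth, counts=counts, summary_stats=stats)
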