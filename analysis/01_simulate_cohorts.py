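"""Generate the synthetic cohorts every later step analyses.

Writes the discovery phenotypes and the truth table of planted effects
under results/cohorts/.  Genotype panels are regenerated deterministically
from the shared seed by every later script (writing a multi-megabyte
dosage matrix buys nothing), but the round-trip formats are exercised on a
small subsample here so the on-disk dialects stay covered.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

from bivargwas import io_formats as io  # noqa: E402
from bivargwas import synthetic_cohorts as sc  # noqa: E402


def main() -> None:
    out = common.outdir("cohorts")
    spec = common.DISCOVERY_SPEC
    panel = sc.simulate_genotypes(spec)
    phen = sc.simulate_bivariate_phenotypes(panel, spec)

    sample = io.GenotypePanel(panel.sample_ids[:50], panel.snps[:40],
                              panel.dosages[:50, :40])
    io.write_genotype_matrix(sample, out / "discovery_genotypes_head.tsv")
    io.write_phenotypes(phen, out / "discovery_phenotypes.tsv")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("snp\tbeta1\tbeta2\tclass\n")
        for idx, b1, b2 in spec.planted_effects:
            cls = sc.classify_planted_effect(b1, b2).value
            fh.write(f"snp{idx:06d}\t{b1:.6g}\t{b2:.6g}\t{cls}\n")

    n_men = int(phen.frame["menarche"].notna().sum())
    n_pau = int(phen.frame["menopause"].notna().sum())
    print(f"discovery cohort: {spec.n_samples} women, {spec.n_snps} SNPs")
    print(f"  menarche observed for {n_men}, menopause for {n_pau}, "
          f"both for {phen.meta['n_both']}")
    print(f"  window exclusions: {phen.meta['excluded_fraction']}")
    print(f"  planted effects: {len(spec.planted_effects)} "
          f"(see {out / 'truth.tsv'})")


if __name__ == "__main__":
    main()
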