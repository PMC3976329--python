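import logging

import numpy as np
import pytest

from bivargwas import greml_rg, synthetic_cohorts as sc

# validation chatter (e.g. t- vs normal-reference p mismatch counts) is
# expected on synthetic GWAS output; keep test output readable
logging.getLogger("bivargwas.io_formats").setLevel(logging.ERROR)

#: wide inclusion windows that exclude nobody — used when a test needs the
#: full-overlap design to stay fully observed
WIDE_WINDOWS = (sc.TraitWindow("menarche", 0.0, 100.0),
                sc.TraitWindow("menopause", 0.0, 200.0))


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-sample, 400-SNP cohort with phenotypes, reused across tests."""
    spec = sc.ArchitectureSpec(n_samples=300, n_snps=400, seed=101)
    panel = sc.simulate_genotypes(spec)
    phen = sc.simulate_bivariate_phenotypes(panel, spec)
    return spec, panel, phen


@pytest.fixture(scope="session")
def overlap_cohort():
    """Full-overlap cohort with wide windows: both traits on every sample."""
    spec = sc.ArchitectureSpec(n_samples=400, n_snps=600, h2=(0.5, 0.5),
                               r_g=0.5, r_e=0.1, overlap_fraction=1.0,
                               seed=202)
    panel = sc.simulate_genotypes(spec)
    phen = sc.simulate_bivariate_phenotypes(panel, spec, windows=WIDE_WINDOWS)
    grm = greml_rg.compute_grm(panel, maf_min=0.01)
    return spec, panel, phen, grm
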