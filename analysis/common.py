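"""Shared settings for the numbered analysis drivers.

One place defines the synthetic study conditions so every script sees the
same cohorts: a discovery cohort, an independent replication cohort, and a
single large cohort used for the genetic-correlation analysis (emulating
the one big study with individual-level data).  Two pleiotropic variants
are planted at suggestive scale — one shifting the reproductive window
right, one lengthening it.
"""

from pathlib import Path

import numpy as np

from bivargwas import synthetic_cohorts as sc

RESULTS = Path(__file__).resolve().parent.parent / "results"

SEED = 20140101
N_DISCOVERY = 4000
N_REPLICATION = 2000
N_SNPS = 2000
B_CALIBRATION = 100_000

# planted per-trait mean Z of ~7 in the discovery cohort (observed fraction
# per trait ~0.68 of the cohort under the overlap design)
_B = 7.0 / np.sqrt(N_DISCOVERY * 0.68)
PLANTED = ((300, _B, _B),          # right shift
           (1300, -_B, _B))        # lifespan increase

DISCOVERY_SPEC = sc.ArchitectureSpec(
    n_samples=N_DISCOVERY, n_snps=N_SNPS, planted_effects=PLANTED, seed=SEED)

# cohort for the GREML analysis: full overlap so every woman has both traits
GREML_SPEC = sc.ArchitectureSpec(
    n_samples=2000, n_snps=2000, h2=(0.5, 0.5), r_g=0.138, r_e=0.1,
    overlap_fraction=1.0, seed=SEED + 5)


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
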