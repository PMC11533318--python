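import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from toxgwas import SimulationConfig, simulate_survival
from toxgwas.quantgen import fit_full_model, fit_reduced_model

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def recovery_fits() -> pd.DataFrame:
    """Variance-component fits on 20 replicate simulations of the panel
    design: 204 lines x 2 sexes x 4 replicates, latent Gaussian phenotypes
    with generating components (1.0, 0.70, 0.373).

    Shared across recovery/acceptance tests so the 20 REML fits run once.
    """
    rows = []
    for seed in range(1, 21):
        cfg = SimulationConfig(
            n_lines=204, n_variants=0, seed=seed, phenotype_mode="gaussian"
        )
        surv, _ = simulate_survival(cfg)
        vc = fit_full_model(surv, method="reml")
        s2lf, s2ef = fit_reduced_model(surv[surv["sex"] == "F"], method="reml")
        s2lm, s2em = fit_reduced_model(surv[surv["sex"] == "M"], method="reml")
        tot = vc.sigma2_line + vc.sigma2_line_sex + vc.sigma2_resid
        rows.append(
            {
                "seed": seed,
                "s2_line": vc.sigma2_line,
                "s2_line_sex": vc.sigma2_line_sex,
                "s2_resid": vc.sigma2_resid,
                "s2_line_F": s2lf,
                "s2_resid_F": s2ef,
                "s2_line_M": s2lm,
                "s2_resid_M": s2em,
                "H2": (vc.sigma2_line + vc.sigma2_line_sex) / tot,
                "r_GS": vc.sigma2_line / np.sqrt(s2lf * s2lm),
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture()
def small_genotypes():
    """Deterministic 50-line x 200-variant panel with 2% missingness."""
    from toxgwas import simulate_genotypes

    cfg = SimulationConfig(n_lines=50, n_variants=200, seed=123, missing_rate=0.02)
    return simulate_genotypes(cfg)
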