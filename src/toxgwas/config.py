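"""Configuration objects for the simulator and the end-to-end pipeline."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


EFFECT_MODES = ("sex_specific_F", "sex_specific_M", "antagonistic", "concordant")


@dataclass(frozen=True)
class PlantedVariant:
    """A variant with a known effect planted into the simulated cohort.

    Effects are on the latent survival scale and apply to lines homozygous
    for the minor allele (genotype code 2); non-carriers get no shift.
    ``mode`` must be consistent with the two signed effects:

    * ``sex_specific_F``: effect_male == 0, effect_female != 0 (and vice versa)
    * ``antagonistic``: both nonzero with opposite signs
    * ``concordant``: both nonzero with the same sign
    """

    variant_index: int
    effect_female: float
    effect_male: float
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in EFFECT_MODES:
            raise ConfigError(f"unknown effect mode {self.mode!r}")
        ef, em = self.effect_female, self.effect_male
        ok = {
            "sex_specific_F": ef != 0 and em == 0,
            "sex_specific_M": em != 0 and ef == 0,
            "antagonistic": ef * em < 0,
            "concordant": ef * em > 0,
        }[self.mode]
        if not ok:
            raise ConfigError(
                f"effects (F={ef}, M={em}) inconsistent with mode {self.mode!r}"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for a synthetic inbred-line toxicology cohort.

    Defaults reproduce the study design the pipeline targets: 204 inbred
    lines scored in both sexes with four replicate vials of 15-20 flies,
    and latent variance components sigma^2_L = 1.0, sigma^2_LxS = 0.70,
    sigma^2_eps = 0.373 (ratios that give broad-sense heritability 0.82 and,
    with equal per-sex line variances, a cross-sex genetic correlation of
    1.0/1.7 ~ 0.588).  ``phenotype_mode="gaussian"`` emits the latent
    replicate values directly; ``"binomial"`` maps them to survival
    probabilities through the configured link and draws binomial counts
    (use proportion-scale variances there).
    """

    n_lines: int = 204
    n_variants: int = 5000
    maf_min: float = 0.015
    maf_max: float = 0.5
    missing_rate: float = 0.02
    mu: float = 0.5
    var_line: float = 1.0
    var_line_sex: float = 0.70
    var_resid: float = 0.373
    sex_effect: float = 0.2
    planted_effects: tuple[PlantedVariant, ...] = ()
    n_replicates: int = 4
    flies_min: int = 15
    flies_max: int = 20
    wolbachia_prevalence: float = 0.5
    n_inversions: int = 5
    inversion_effect: float = 0.0
    phenotype_mode: str = "gaussian"
    link: str = "identity"
    dose_female: float = 30.0
    dose_male: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ConfigError("n_lines must be >= 2")
        if self.n_variants < 0:
            raise ConfigError("n_variants must be >= 0")
        if not (0.0 < self.maf_min <= self.maf_max <= 0.5):
            raise ConfigError("require 0 < maf_min <= maf_max <= 0.5")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        for name in ("var_line", "var_line_sex", "var_resid"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        if not (1 <= self.flies_min <= self.flies_max):
            raise ConfigError("require 1 <= flies_min <= flies_max")
        if not (0.0 <= self.wolbachia_prevalence <= 1.0):
            raise ConfigError("wolbachia_prevalence must be in [0, 1]")
        if self.phenotype_mode not in ("gaussian", "binomial"):
            raise ConfigError("phenotype_mode must be 'gaussian' or 'binomial'")
        if self.link not in ("identity", "logistic"):
            raise ConfigError("link must be 'identity' or 'logistic'")
        for pv in self.planted_effects:
            if not (0 <= pv.variant_index < max(self.n_variants, 1)):
                raise ConfigError(
                    f"planted variant index {pv.variant_index} out of range"
                )

    def to_dict(self) -> dict:
        return asdict(self)


# Thresholds every stage shares; values are the analysis constants of the
# study design and can be overridden per run.
@dataclass
class PipelineConfig:
    outdir: str = "toxgwas_out"
    suggestive_p: float = 1e-5
    bonferroni_alpha: float = 0.05
    screen_p: float = 0.1
    min_maf: float = 0.015
    max_missing: float = 0.1
    window: int = 5000
    min_links: int = 2
    n_perm: int = 10000
    diopt_min: int = 3
    diopt_strong: int = 7
    infection_reads: int = 7000
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        import json

        payload = self.to_dict()
        payload.pop("outdir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
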