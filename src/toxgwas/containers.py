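"""Shared in-memory containers for the inbred-line toxicology pipeline.

The central object is :class:`GenotypeMatrix`: a lines × variants matrix of
homozygous genotypes coded 0 / 2 (copies of the minor-at-simulation or ALT
allele), with ``nan`` marking missing calls.  Inbred panels such as the DGRP
are (near-)fully homozygous, so a single number per line suffices and the
0/2 coding makes per-variant regression coefficients per-allele additive
effects (half the difference between the two homozygous classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "vtype"]


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes for a panel of inbred lines.

    Parameters
    ----------
    calls
        ``(n_lines, n_variants)`` float array with entries in {0.0, 2.0, nan}.
    line_ids
        Line identifiers, one per row.
    variants
        Variant metadata with columns ``variant_id, chrom, pos, ref, alt,
        vtype`` (``pos`` 1-based; ``vtype`` in {"SNP", "insertion",
        "deletion"}).
    """

    calls: np.ndarray
    line_ids: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D lines x variants array")
        if self.calls.shape[0] != len(self.line_ids):
            raise ValueError("line_ids length does not match calls rows")
        if self.calls.shape[1] != len(self.variants):
            raise ValueError("variants table does not match calls columns")
        valid = np.isnan(self.calls) | (self.calls == 0.0) | (self.calls == 2.0)
        if not valid.all():
            raise ValueError("genotype calls must be 0, 2 or missing (nan)")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variants table lacks columns: {missing}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def alt_freq(self) -> np.ndarray:
        """Frequency of the allele coded 2, among non-missing lines."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.calls, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant (non-missing lines only)."""
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.calls).mean(axis=0)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            calls=self.calls[:, idx],
            line_ids=list(self.line_ids),
            variants=self.variants.iloc[idx].reset_index(drop=True),
        )

    def subset_lines(self, keep: Sequence[str]) -> "GenotypeMatrix":
        index = {l: i for i, l in enumerate(self.line_ids)}
        rows = [index[l] for l in keep]
        return GenotypeMatrix(
            calls=self.calls[rows, :],
            line_ids=list(keep),
            variants=self.variants.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Variants x lines matrix as a DataFrame (for TSV round-trips)."""
        return pd.DataFrame(
            self.calls.T, index=self.variants["variant_id"], columns=self.line_ids
        )


@dataclass
class VarianceComponents:
    """REML / method-of-moments variance components of the line x sex model.

    ``sigma2_line`` is the among-line variance (sigma^2_L), ``sigma2_line_sex``
    the line-by-sex interaction variance (sigma^2_LxS) and ``sigma2_resid``
    the residual.  Per-sex fields hold the reduced one-way model estimates.
    Negative solutions are clamped to zero with ``clamped`` recording which.
    """

    sigma2_line: float
    sigma2_line_sex: float
    sigma2_resid: float
    sigma2_line_F: float | None = None
    sigma2_resid_F: float | None = None
    sigma2_line_M: float | None = None
    sigma2_resid_M: float | None = None
    estimation_method: str = "REML"
    clamped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("sigma2_line", "sigma2_line_sex", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative (clamp before storing)")


@dataclass
class QuantGenSummary:
    """Headline quantitative-genetic statistics for a panel screen."""

    H2_pooled: float
    H2_female: float | None
    H2_male: float | None
    r_GS: float | None
    r_GS_se: float | None
    sex_effect_p: float | None
    interaction_to_line_ratio: float | None
    components: VarianceComponents | None = None
    flags: tuple[str, ...] = ()


@dataclass
class ConnectivityTest:
    """Monte Carlo permutation test of network connectivity.

    ``p_value = n_exceed / n_permutations`` with exceedance strict (null
    connectivity > observed); when no permutation exceeds the observed value
    the displayed string follows the ``P < 1/N`` convention.
    """

    observed_connectivity: float
    null_values: np.ndarray
    n_permutations: int
    n_exceed: int
    p_value: float

    @property
    def p_display(self) -> str:
        if self.n_exceed == 0:
            return f"< {1.0 / self.n_permutations:g}"
        return f"{self.p_value:g}"


@dataclass
class SyntheticCohort:
    """Bundle of simulated inputs plus the generating truth record."""

    genotypes: GenotypeMatrix | None
    survival: pd.DataFrame
    covariates: pd.DataFrame | None
    truth: dict = field(default_factory=dict)
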