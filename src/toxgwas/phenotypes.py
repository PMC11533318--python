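"""Pooled survival phenotypes and dose-finding summaries.

Replicate vials of 15-20 same-sex flies are scored for 24-hour survival;
per line x sex (x dose) the replicates are pooled by summing counts, giving
a proportion ``p = sum(survived) / sum(exposed)`` with binomial standard
error ``sqrt(p (1 - p) / N)`` where ``N`` is the total number of flies.
Count-weighted pooling (rather than averaging replicate proportions) is the
default because the SE formula is defined in terms of total N.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_COLS = ["line_id", "sex", "dose"]


def pool_survival(table: pd.DataFrame, weighted: bool = True) -> pd.DataFrame:
    """Pool replicate survival counts per line x sex x dose.

    Parameters
    ----------
    table
        Long-format replicate table with columns ``line_id, sex, dose,
        replicate, n_exposed, n_survived``.
    weighted
        Count-weighted pooling (default).  ``False`` averages replicate
        proportions instead; ``N`` and the SE formula are unchanged.

    Returns
    -------
    DataFrame with columns ``line_id, sex, dose, p, N, se``.
    """
    required = set(GROUP_COLS + ["n_exposed", "n_survived"])
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"survival table lacks columns: {sorted(missing)}")
    if (table["n_survived"] > table["n_exposed"]).any():
        raise ValueError("n_survived exceeds n_exposed in some replicate")
    if (table["n_survived"] < 0).any() or (table["n_exposed"] < 0).any():
        raise ValueError("negative counts")

    out = []
    for key, grp in table.groupby(GROUP_COLS, sort=True):
        n_tot = int(grp["n_exposed"].sum())
        if n_tot == 0:
            warnings.warn(f"group {key} has zero exposed flies; skipped")
            continue
        if weighted:
            p = float(grp["n_survived"].sum()) / n_tot
        else:
            props = grp["n_survived"] / grp["n_exposed"]
            p = float(props.mean())
        se = float(np.sqrt(p * (1.0 - p) / n_tot))
        out.append((*key, p, n_tot, se))
    return pd.DataFrame(out, columns=GROUP_COLS + ["p", "N", "se"])


def estimate_ld50(dose_response: list[tuple[float, float]]) -> float:
    """Dose at which interpolated survival crosses 0.5.

    Monotone linear interpolation between the bracketing doses; refuses to
    extrapolate outside the tested range.
    """
    if len(dose_response) < 2:
        raise ValueError("need at least two doses")
    pts = sorted(dose_response)
    doses = np.array([d for d, _ in pts], dtype=float)
    surv = np.array([p for _, p in pts], dtype=float)
    if np.allclose(surv, surv[0]):
        raise ValueError("survival constant across doses; LD50 undefined")
    for i in range(len(pts) - 1):
        p1, p2 = surv[i], surv[i + 1]
        if (p1 - 0.5) == 0.0:
            return float(doses[i])
        if (p1 - 0.5) * (p2 - 0.5) <= 0.0:
            if p1 == p2:
                continue
            frac = (p1 - 0.5) / (p1 - p2)
            return float(doses[i] + frac * (doses[i + 1] - doses[i]))
    if surv[-1] == 0.5:
        return float(doses[-1])
    raise ValueError("LD50 outside tested range")


def discriminating_dose(
    lines_by_dose: dict[float, list[float]],
    band: float = 0.2,
    target: float = 0.5,
) -> float:
    """Dose that maximizes among-line variance of survival.

    Candidate doses are restricted to those with mean survival within
    ``target +/- band`` (the assay aims for ~50% survival so genetic
    variation is maximally expressed); ties on variance break toward the
    mean closest to the target.  If no dose lies in the band the global
    variance argmax is returned with a warning.
    """
    if len(lines_by_dose) < 2:
        raise ValueError("need at least two doses")
    stats = {}
    for dose, ps in lines_by_dose.items():
        ps = np.asarray(ps, dtype=float)
        if ps.size < 2:
            raise ValueError(f"dose {dose} has fewer than two lines")
        stats[dose] = (float(np.var(ps, ddof=1)), float(np.mean(ps)))

    in_band = {d: s for d, s in stats.items() if abs(s[1] - target) <= band}
    pool = in_band
    if not pool:
        warnings.warn(
            f"no dose with mean survival within {target}+/-{band}; "
            "returning global variance argmax"
        )
        pool = stats
    # maximize variance; ties (to relative 1e-9) break toward the mean
    # nearest the target
    vmax = max(v for v, _ in pool.values())
    tied = {d: s for d, s in pool.items() if s[0] >= vmax - 1e-9 * max(vmax, 1e-300)}
    best = min(tied.items(), key=lambda kv: abs(kv[1][1] - target))
    return best[0]
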