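"""Posterior summaries: variance ratios, systematic-effect contrasts,
dam-age response curve and genetic trends.

All quantities are computed per saved Gibbs sample and then summarized
(posterior mean and SD), the standard Bayesian practice; ratio summaries
are therefore not the plug-in ratios of averaged components.  The total
phenotypic variance used for the ratios is

    sigma2_P = sigma2_u + sigma2_m + sigma2_c + sigma2_e

i.e. the sum of variance shares, excluding the direct-maternal covariance
(including it can push shares outside [0, 1]); ``include_covariance=True``
adds it for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gibbs_core import Chain

__all__ = [
    "variance_ratios",
    "summarize_chain",
    "ContrastResult",
    "contrast_probability",
    "age_response_curve",
    "genetic_trend",
]


def _var_frame(chain) -> pd.DataFrame:
    return chain.var_samples if hasattr(chain, "var_samples") else chain


def variance_ratios(chain, include_covariance: bool = False) -> pd.DataFrame:
    """Per-sample h2, m2, c2 and the direct-maternal genetic correlation r_g.

    r_g is NaN for samples where either genetic variance is absent (e.g.
    the Calf model).  Raises on zero total variance.
    """
    v = _var_frame(chain)
    total = v["sigma2_u"] + v["sigma2_m"] + v["sigma2_c"] + v["sigma2_e"]
    if include_covariance:
        total = total + v["sigma_um"]
    if (total <= 0).any():
        raise ValueError("zero total phenotypic variance in at least one sample")
    out = pd.DataFrame(
        {
            "h2": v["sigma2_u"] / total,
            "m2": v["sigma2_m"] / total,
            "c2": v["sigma2_c"] / total,
        }
    )
    denom = np.sqrt(v["sigma2_u"] * v["sigma2_m"])
    with np.errstate(invalid="ignore", divide="ignore"):
        rg = np.where(denom > 0, v["sigma_um"] / denom, np.nan)
    out["r_g"] = rg
    return out


def summarize_chain(chain: Chain, include_covariance: bool = False) -> dict:
    """Posterior mean and SD of every variance component, ratio and (when
    stored) location effect.  SDs are posterior standard deviations."""
    v = _var_frame(chain)
    if len(v) == 0:
        raise ValueError("empty chain")
    ratios = variance_ratios(chain, include_covariance)
    summary = {
        "variance_components": pd.DataFrame(
            {"mean": v.mean(), "sd": v.std(ddof=1)}
        ),
        "ratios": pd.DataFrame({"mean": ratios.mean(), "sd": ratios.std(ddof=1)}),
        "n_samples": len(v),
    }
    if isinstance(chain, Chain) and chain.effect_samples is not None:
        nf = chain.bundle.n_fixed
        eff = chain.effect_samples[:, :nf]
        summary["systematic_effects"] = pd.DataFrame(
            {"mean": eff.mean(axis=0), "sd": eff.std(axis=0, ddof=1)},
            index=chain.effect_names[:nf],
        )
    return summary


def _factor_of(level: str) -> str | None:
    if ":" in level:
        return level.split(":", 1)[0]
    return None


def _fixed_cols_of_factor(chain: Chain, factor: str) -> list[int]:
    nf = chain.bundle.n_fixed
    return [
        j for j in range(nf) if chain.effect_names[j].startswith(factor + ":")
    ]


def _baseline_samples(chain: Chain, exclude_factor: str | None) -> np.ndarray:
    """Per-sample population-average systematic predictor, with the named
    factor's average contribution removed (so a level effect can be added
    back on top)."""
    nf = chain.bundle.n_fixed
    xbar = chain.bundle.X.mean(axis=0)
    b = chain.effect_samples[:, :nf]
    base = b @ xbar
    if exclude_factor is not None:
        cols = _fixed_cols_of_factor(chain, exclude_factor)
        if cols:
            base = base - b[:, cols] @ xbar[cols]
    return base


def _to_survival(chain: Chain, predictor: np.ndarray) -> np.ndarray:
    if chain.spec.scale == "threshold":
        return norm.cdf(predictor)
    # observed-scale linear model on a 0/1 trait: the predictor is the
    # survival probability; clip for reporting only
    return np.clip(predictor, 0.0, 1.0)


@dataclass
class ContrastResult:
    level_a: str
    level_b: str | None
    p_greater: float
    p_greater_equal: float
    mean_difference: float
    survival_a: float | None
    survival_b: float | None
    samples: np.ndarray


def contrast_probability(
    chain: Chain, level_a: str, level_b: str | None = None
) -> ContrastResult:
    """P(effect of level_a - effect of level_b > 0) over saved samples,
    with level-wise survival estimates on the observed scale.

    Reference (absorbed) levels are valid arguments and contribute 0.
    """
    ca = chain.effect(level_a)
    cb = chain.effect(level_b) if level_b is not None else np.zeros_like(ca)
    diff = ca - cb
    p_gt = float(np.mean(diff > 0))
    p_ge = float(np.mean(diff >= 0))
    surv_a = surv_b = None
    fac = _factor_of(level_a)
    if fac in ("year", "parity", "litter"):
        base = _baseline_samples(chain, fac)
        surv_a = float(np.mean(_to_survival(chain, base + ca)))
        if level_b is not None:
            surv_b = float(np.mean(_to_survival(chain, base + cb)))
    return ContrastResult(
        level_a=level_a,
        level_b=level_b,
        p_greater=p_gt,
        p_greater_equal=p_ge,
        mean_difference=float(diff.mean()),
        survival_a=surv_a,
        survival_b=surv_b,
        samples=diff,
    )


def age_response_curve(
    chain: Chain, age_grid: np.ndarray, ci: float = 0.90
) -> tuple[pd.DataFrame, dict]:
    """Predicted survival across dam age (days) with a credible band, plus
    the per-sample optimum age x* = x_mean - b_lin / (2 b_quad).

    The vertex is flagged unreliable when the posterior mass of a
    non-negative quadratic coefficient exceeds one half (the curve then has
    no interior maximum in most samples); it is still reported.
    """
    b_lin = chain.effect("age_lin")
    b_quad = chain.effect("age_quad")
    xbar = chain.bundle.coding.age_mean
    base = _baseline_samples(chain, None)
    # remove the average age contribution, then add the grid's own
    a = chain.bundle.records["dam_age_days"].to_numpy(dtype=float) - xbar
    base = base - b_lin * a.mean() - b_quad * (a * a).mean()

    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []
    for x in np.asarray(age_grid, dtype=float):
        dx = x - xbar
        pred = base + b_lin * dx + b_quad * dx * dx
        s = _to_survival(chain, pred)
        rows.append(
            {
                "age_days": x,
                "survival_mean": float(np.mean(s)),
                "survival_lo": float(np.quantile(s, lo_q)),
                "survival_hi": float(np.quantile(s, hi_q)),
            }
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        vertex = xbar - b_lin / (2.0 * b_quad)
    p_quad_nonneg = float(np.mean(b_quad >= 0))
    finite = vertex[np.isfinite(vertex)]
    vertex_info = {
        "vertex_mean_days": float(np.mean(finite)) if finite.size else np.nan,
        "vertex_median_days": float(np.median(finite)) if finite.size else np.nan,
        "p_quadratic_nonnegative": p_quad_nonneg,
        "reliable": p_quad_nonneg <= 0.5,
    }
    return pd.DataFrame(rows), vertex_info


def genetic_trend(chain: Chain, ped=None, which: str = "u") -> pd.DataFrame:
    """Cohort means of breeding values by birth year.

    For every saved sample the additive genetic values (direct ``u`` or
    maternal ``m``) are averaged within birth-year cohorts; the table
    reports the posterior mean of each cohort mean, the probability that it
    exceeds zero (strict inequality), and the cohort size.
    """
    ped = ped if ped is not None else chain.bundle.ped
    if which not in ("u", "m"):
        raise ValueError("which must be 'u' or 'm'")
    samples, names = chain.block_samples(which + ":")
    if samples.shape[1] == 0:
        raise ValueError(f"no {which!r} effects in this chain")
    pos = ped.positions([n.split(":", 1)[1] for n in names])
    years = ped.birth_year[pos]
    rows = []
    for year in sorted({int(y) for y in years if y >= 0}):
        members = np.nonzero(years == year)[0]
        if members.size == 0:
            continue
        cohort = samples[:, members].mean(axis=1)
        rows.append(
            {
                "birth_year": year,
                "mean_ebv": float(cohort.mean()),
                "sd_ebv": float(cohort.std(ddof=1)),
                "p_greater_zero": float(np.mean(cohort > 0)),
                "n": int(members.size),
            }
        )
    if not rows:
        raise ValueError("no cohorts with known birth years")
    return pd.DataFrame(rows)
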