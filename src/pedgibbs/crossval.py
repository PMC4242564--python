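"""Predictive-ability cross-validation for model selection.

The selection criterion is prediction, not fit: half of the records of the
last five birth years (the reference population) are removed at random,
the model is refit on the remainder, the removed records are predicted
from the posterior-mean solutions, and the Pearson correlation r between
the withheld records and their predictions is computed.  The procedure is
repeated over replicates (default 20) and r averaged; replicate split
seeds are shared across models so comparisons are paired.

Withheld calves stay in the pedigree, so their breeding values are still
propagated through the relationship structure by the sampler — prediction
for an unphenotyped calf rests on its relatives' records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .design import ModelSpec, build_design
from .gibbs_core import Chain, GibbsConfig, run_gibbs
from .pedigree import (
    Pedigree,
    compute_delta_f,
    compute_equivalent_generations,
    compute_inbreeding,
)
from .posterior_inference import variance_ratios

__all__ = [
    "CVResult",
    "make_cv_split",
    "predict_records",
    "run_crossval",
    "compare_models",
]


@dataclass
class CVResult:
    """Per-replicate predictive correlations for one model variant."""

    label: str
    r: np.ndarray  # NaN where undefined (constant truth or prediction)
    split_seeds: list[int]
    test_sizes: list[int]
    data_digest: str = ""
    ratio_means: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def mean_r(self) -> float:
        if np.all(np.isnan(self.r)):
            return float("nan")
        return float(np.nanmean(self.r))

    @property
    def n_valid(self) -> int:
        return int(np.sum(~np.isnan(self.r)))


def make_cv_split(
    tab: pd.DataFrame, seed: int, n_years: int = 5, fraction: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """(train_idx, test_idx) for one replicate.

    The reference population is every record whose calving year falls in
    the ``n_years`` most recent calendar years containing at least one
    record; ``floor(fraction * size)`` of them are withheld uniformly
    without replacement.
    """
    years = sorted(tab["calving_year"].unique())
    if len(years) < n_years:
        raise ValueError(
            f"need records in at least {n_years} distinct years, have {len(years)}"
        )
    recent = set(years[-n_years:])
    ref = np.nonzero(tab["calving_year"].isin(recent).to_numpy())[0]
    if ref.size < 2:
        raise ValueError("reference population has fewer than 2 records")
    n_test = int(np.floor(fraction * ref.size))
    rng = np.random.default_rng(seed)
    test = np.sort(rng.choice(ref, size=n_test, replace=False))
    mask = np.ones(len(tab), dtype=bool)
    mask[test] = False
    return np.nonzero(mask)[0], test


def predict_records(chain: Chain, test_tab: pd.DataFrame) -> np.ndarray:
    """Posterior-mean linear predictor for held-out records.

    Continuous models predict on the observed (not rounded) scale,
    threshold models on the liability scale.  Year levels unseen in
    training are mapped to the nearest pooled training level; dams without
    a training permanent-environment level contribute their prior mean 0.
    """
    bundle = chain.bundle
    ped = bundle.ped
    coding = bundle.coding
    F_rec = dF_rec = None
    if coding.inbreeding_mode in ("II", "III"):
        F = compute_inbreeding(ped)
        pos = ped.positions(test_tab["calf_id"])
        if coding.inbreeding_mode == "II":
            F_rec = F[pos]
        else:
            t = compute_equivalent_generations(ped)
            dF_rec = compute_delta_f(F, t)[pos]
    X = coding.encode(test_tab, F=F_rec, dF=dF_rec)
    means = chain.posterior_mean_effects()
    nf = bundle.n_fixed
    pred = X @ means.to_numpy()[:nf]

    if "calf_additive" in bundle.spec.random_blocks:
        u = means[[f"u:{i}" for i in ped.ids]].to_numpy()
        pred = pred + u[ped.positions(test_tab["calf_id"])]
    if bundle.m_idx is not None:
        m = means[[f"m:{i}" for i in ped.ids]].to_numpy()
        pred = pred + m[ped.positions(test_tab["dam_id"])]
    if bundle.w_idx is not None:
        c = means[[f"c:{d}" for d in bundle.dam_levels]]
        extra = np.array(
            [float(c.get(f"c:{d}", 0.0)) for d in test_tab["dam_id"]]
        )
        pred = pred + extra
    return pred


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def run_crossval(
    spec: ModelSpec,
    tab: pd.DataFrame,
    ped: Pedigree,
    a_inv: sparse.csr_matrix,
    cfg: GibbsConfig | None = None,
    n_reps: int = 20,
    base_seed: int = 0,
    n_years: int = 5,
    fraction: float = 0.5,
    F: np.ndarray | None = None,
    dF: np.ndarray | None = None,
) -> CVResult:
    """Full cross-validation of one model variant.

    Replicate k uses split seed ``base_seed + k`` (so every model variant
    run with the same ``base_seed`` sees identical test sets) and an
    independent chain seed.  Replicates whose correlation is undefined
    (constant withheld outcomes or predictions) are recorded as NaN and
    excluded from the mean, with a warning.
    """
    cfg = cfg or GibbsConfig(chain_length=100_000, burn_in=10_000, thin=10)
    rs = np.full(n_reps, np.nan)
    seeds, sizes, ratio_rows = [], [], []
    digest = ""
    for k in range(n_reps):
        split_seed = base_seed + k
        train_idx, test_idx = make_cv_split(tab, split_seed, n_years, fraction)
        train = tab.iloc[train_idx]
        test = tab.iloc[test_idx]
        bundle = build_design(train, ped, spec, F=F, dF=dF)
        chain_cfg = GibbsConfig(
            chain_length=cfg.chain_length,
            burn_in=cfg.burn_in,
            thin=cfg.thin,
            seed=(base_seed * 1_000 + 7 * k + 1) % (2**31 - 1),
            prior_df=cfg.prior_df,
            prior_scale=cfg.prior_scale,
            store_location_effects=True,
            residual_check_every=cfg.residual_check_every,
        )
        chain = run_gibbs(bundle, a_inv, spec, chain_cfg)
        digest = chain.data_digest
        pred = predict_records(chain, test)
        truth = test["survival"].to_numpy(dtype=float)
        r = _pearson(truth, pred)
        if np.isnan(r):
            warnings.warn(
                f"replicate {k}: correlation undefined (constant outcomes or "
                "predictions); excluded from the mean"
            )
        rs[k] = r
        seeds.append(split_seed)
        sizes.append(len(test_idx))
        ratio_rows.append(variance_ratios(chain).mean())
    return CVResult(
        label=spec.label,
        r=rs,
        split_seeds=seeds,
        test_sizes=sizes,
        data_digest=digest,
        ratio_means=pd.DataFrame(ratio_rows).reset_index(drop=True),
    )


def compare_models(results: list[CVResult]) -> pd.DataFrame:
    """Ranking table over model variants (best predictive r first).

    Requires identical replicate split seeds across models so per-replicate
    differences are paired; ties are broken by label for stability.
    """
    if not results:
        raise ValueError("no results to compare")
    ref = results[0]
    for res in results[1:]:
        if res.split_seeds != ref.split_seeds:
            raise ValueError(
                f"replicate seeds differ between {ref.label!r} and {res.label!r}; "
                "paired comparison broken"
            )
    rows = []
    best = max(results, key=lambda r: (np.nan_to_num(r.mean_r, nan=-2.0)))
    for res in results:
        row = {
            "model": res.label,
            "mean_r": res.mean_r,
            "n_valid_replicates": res.n_valid,
        }
        if res.ratio_means is not None:
            for col in ("h2", "m2", "c2", "r_g"):
                row[col] = float(res.ratio_means[col].mean())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            diff = res.r - best.r
            row["mean_r_minus_best"] = float(np.nanmean(diff)) if res is not best else 0.0
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        ["mean_r", "model"], ascending=[False, True]
    )
    return out.reset_index(drop=True)
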