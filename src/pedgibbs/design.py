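"""Design structures for calf-survival animal models.

Turns a phenotype table (one row per calf record) into the response vector,
the systematic-effect design matrix X and the random-effect incidence maps
needed by the Gibbs sampler, for any of the fittable model variants:

* **Calf**: direct additive genetic effect of the calf only.
* **Calf-dam**: adds the maternal genetic effect (dam's genes acting as
  environment on the calf), sampled jointly with the direct effect.
* **Calf-permanent**: adds instead the maternal permanent environmental
  effect (one iid level per dam with records).
* **Calf-dam-permanent**: both maternal effects.

Systematic effects follow the standard survival analysis of captive
ungulates: calving year (sparse years pooled), dam parity, dam age in days
as centered linear + quadratic covariates, and a 6-level litter-composition
factor F, M, F(F), F(M), M(F), M(M) (single calf's sex, or twin's sex with
the cotwin's sex in parentheses).  Inbreeding enters optionally as
covariates: mode "I" none, mode "II" F linear + quadratic, mode "III"
the individual increase in inbreeding dF linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "LITTER_CODES",
    "ModelSpec",
    "FixedCoding",
    "DesignBundle",
    "load_phenotypes",
    "validate_phenotypes",
    "pool_years",
    "code_systematic_effects",
    "build_random_design",
    "build_design",
]

LITTER_CODES = ("F", "M", "F(F)", "F(M)", "M(F)", "M(M)")
PARITY_LEVELS = ("primiparous", "multiparous")

PHENOTYPE_COLUMNS = (
    "calf_id",
    "dam_id",
    "sire_id",
    "survival",
    "calving_year",
    "parity",
    "dam_age_days",
    "litter_code",
)

_MAIN_VARIANTS = {
    "calf": ("calf_additive",),
    "calf-dam": ("calf_additive", "maternal_genetic"),
    "calf-permanent": ("calf_additive", "maternal_permanent"),
    "calf-dam-permanent": (
        "calf_additive",
        "maternal_genetic",
        "maternal_permanent",
    ),
}

_KNOWN_BLOCKS = (
    "calf_additive",
    "maternal_genetic",
    "maternal_permanent",
    "paternal_genetic",
)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model variant.

    Parameters
    ----------
    scale : {"continuous", "threshold"}
        Observed-scale linear model, or probit liability model for the
        binary outcome (residual variance fixed at 1, threshold at 0).
    random_blocks : tuple of str
        Subset of {"calf_additive", "maternal_genetic",
        "maternal_permanent", "paternal_genetic"}.
    correlated_genetic : bool
        Sample a joint covariance between the direct and maternal genetic
        blocks (the usual direct-maternal animal model) when both present.
    inbreeding_mode : {"I", "II", "III"}
        Inbreeding covariates in X: none / F + F^2 / dF.
    center_covariates : bool
        Center continuous covariates at their sample mean.
    min_year_records : int
        Pool calving-year levels until each has at least this many records.
    """

    scale: str = "continuous"
    random_blocks: tuple[str, ...] = ("calf_additive",)
    correlated_genetic: bool = True
    inbreeding_mode: str = "I"
    center_covariates: bool = True
    min_year_records: int = 5

    def __post_init__(self):
        if self.scale not in ("continuous", "threshold"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.inbreeding_mode not in ("I", "II", "III"):
            raise ValueError(f"unknown inbreeding mode {self.inbreeding_mode!r}")
        for b in self.random_blocks:
            if b not in _KNOWN_BLOCKS:
                raise ValueError(f"unknown random block {b!r}")
        # every named variant includes the calf additive block; an empty
        # tuple (pure systematic-effects model) is allowed for calibration
        # and testing
        if self.random_blocks and "calf_additive" not in self.random_blocks:
            raise ValueError("all fittable variants include the calf additive block")

    @classmethod
    def variant(cls, name: str, scale: str = "continuous", **kw) -> "ModelSpec":
        """One of the four named model variants: calf, calf-dam,
        calf-permanent, calf-dam-permanent."""
        key = name.lower().replace("_", "-")
        if key not in _MAIN_VARIANTS:
            raise ValueError(
                f"unknown model variant {name!r}; choose from {sorted(_MAIN_VARIANTS)}"
            )
        return cls(scale=scale, random_blocks=_MAIN_VARIANTS[key], **kw)

    @property
    def label(self) -> str:
        blocks = set(self.random_blocks)
        for name, b in _MAIN_VARIANTS.items():
            if blocks == set(b):
                return f"{name} ({self.scale})"
        return f"custom{sorted(blocks)} ({self.scale})"

    @property
    def has_maternal_genetic(self) -> bool:
        return "maternal_genetic" in self.random_blocks

    @property
    def has_maternal_permanent(self) -> bool:
        return "maternal_permanent" in self.random_blocks

    @property
    def has_paternal(self) -> bool:
        return "paternal_genetic" in self.random_blocks

    def with_scale(self, scale: str) -> "ModelSpec":
        return replace(self, scale=scale)


def load_phenotypes(path, sep: str = ",") -> pd.DataFrame:
    """Read a calf-record CSV and validate it (see :func:`validate_phenotypes`)."""
    df = pd.read_csv(path, sep=sep, dtype={"calf_id": str, "dam_id": str, "sire_id": str})
    return validate_phenotypes(df)


def validate_phenotypes(df: pd.DataFrame, binary: bool = True) -> pd.DataFrame:
    """Check column presence, admissible categorical values and positivity.

    ``binary=False`` admits a continuous response column (used when the
    generative model is the Gaussian reading of the animal model); the
    threshold model always requires 0/1.
    """
    missing = {"calf_id", "dam_id", "survival", "calving_year", "parity",
               "dam_age_days", "litter_code"} - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing column(s) {sorted(missing)}")
    df = df.copy()
    if "sire_id" not in df.columns:
        df["sire_id"] = ""
    df["sire_id"] = df["sire_id"].fillna("")
    if binary:
        bad = ~df["survival"].isin([0, 1])
        if bad.any():
            raise ValueError(
                f"survival must be 0/1; offending calf_id(s) {df.loc[bad, 'calf_id'].tolist()[:5]}"
            )
    bad = ~df["litter_code"].isin(LITTER_CODES)
    if bad.any():
        raise ValueError(
            f"unknown litter_code(s) {sorted(df.loc[bad, 'litter_code'].unique().tolist())}"
        )
    bad = ~df["parity"].isin(PARITY_LEVELS)
    if bad.any():
        raise ValueError(
            f"parity must be in {PARITY_LEVELS}; got {sorted(df.loc[bad, 'parity'].unique().tolist())}"
        )
    bad = ~(df["dam_age_days"] > 0)
    if bad.any():
        raise ValueError(
            f"nonpositive dam_age_days for calf_id(s) {df.loc[bad, 'calf_id'].tolist()[:5]}"
        )
    return df


def pool_years(years: pd.Series, min_records: int) -> dict[int, str]:
    """Greedy ascending pooling of calving years into levels of >= min_records.

    Mirrors how sparse terminal years are merged in studbook analyses;
    returns a map year -> level label ("1999" or "2011-2012").
    """
    counts = years.value_counts().sort_index()
    groups: list[list[int]] = []
    cur: list[int] = []
    cur_n = 0
    for y, c in counts.items():
        cur.append(int(y))
        cur_n += int(c)
        if cur_n >= min_records:
            groups.append(cur)
            cur, cur_n = [], 0
    if cur:
        if groups:
            groups[-1].extend(cur)
        else:
            groups.append(cur)

    def label(g):
        return str(g[0]) if len(g) == 1 else f"{g[0]}-{g[-1]}"

    mapping = {}
    for g in groups:
        for y in range(g[0], g[-1] + 1):  # swallow recordless interior years too
            mapping[y] = label(g)
    return mapping


@dataclass
class FixedCoding:
    """Fitted systematic-effect coding, reusable to encode held-out records.

    Reference-level (first level absorbed) coding for categorical factors,
    so sampled effects are contrasts against the reference level; continuous
    covariates centered at the training means.
    """

    year_map: dict[int, str]
    year_levels: list[str]  # first is the reference
    litter_levels: list[str]
    parity_levels: list[str]
    age_mean: float
    inbreeding_mode: str
    f_mean: float = 0.0
    df_mean: float = 0.0
    colnames: list[str] = field(default_factory=list)
    keep: np.ndarray | None = None  # mask dropping degenerate covariate columns

    def _year_level(self, y: int) -> str:
        if y in self.year_map:
            return self.year_map[y]
        # unseen year: nearest group by midpoint, earlier group on ties
        def mid(lvl):
            parts = lvl.split("-")
            return (int(parts[0]) + int(parts[-1])) / 2.0

        return min(self.year_levels, key=lambda lvl: (abs(mid(lvl) - y), mid(lvl)))

    def encode(
        self,
        tab: pd.DataFrame,
        F: np.ndarray | None = None,
        dF: np.ndarray | None = None,
    ) -> np.ndarray:
        """Design rows for the given records (F/dF are per-record, mode-dependent)."""
        n = len(tab)
        cols: list[np.ndarray] = [np.ones(n)]
        for lvl in self.year_levels[1:]:
            lv = tab["calving_year"].map(self._year_level).to_numpy()
            cols.append((lv == lvl).astype(float))
        for lvl in self.parity_levels[1:]:
            cols.append((tab["parity"].to_numpy() == lvl).astype(float))
        for lvl in self.litter_levels[1:]:
            cols.append((tab["litter_code"].to_numpy() == lvl).astype(float))
        a = tab["dam_age_days"].to_numpy(dtype=float) - self.age_mean
        cols.append(a)
        cols.append(a * a)
        if self.inbreeding_mode == "II":
            if F is None:
                raise ValueError("inbreeding mode II needs per-record F")
            f = np.asarray(F, dtype=float) - self.f_mean
            cols.append(f)
            cols.append(f * f)
        elif self.inbreeding_mode == "III":
            if dF is None:
                raise ValueError("inbreeding mode III needs per-record dF")
            cols.append(np.asarray(dF, dtype=float) - self.df_mean)
        X = np.column_stack(cols)
        if self.keep is not None:
            X = X[:, self.keep]
        return X


@dataclass
class DesignBundle:
    """Everything the sampler needs for one model variant on one data set."""

    y: np.ndarray  # response (0/1)
    X: np.ndarray  # n x p_fixed systematic design
    coding: FixedCoding
    spec: ModelSpec
    z_idx: np.ndarray  # record -> calf position in pedigree
    m_idx: np.ndarray | None  # record -> dam position (maternal genetic)
    w_idx: np.ndarray | None  # record -> dam-with-records level
    p_idx: np.ndarray | None  # record -> sire position (paternal genetic)
    dam_levels: list[str]  # ids of dams with >= 1 record (W columns)
    ped: Pedigree
    records: pd.DataFrame

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def fixed_names(self) -> list[str]:
        return self.coding.colnames


def code_systematic_effects(
    tab: pd.DataFrame,
    spec: ModelSpec,
    F_record: np.ndarray | None = None,
    dF_record: np.ndarray | None = None,
) -> tuple[np.ndarray, FixedCoding]:
    """Fit the systematic coding on `tab` and return (X, coding)."""
    year_map = pool_years(tab["calving_year"], spec.min_year_records)
    year_levels = sorted(set(year_map.values()), key=lambda s: int(s.split("-")[0]))
    litter_levels = [l for l in LITTER_CODES if (tab["litter_code"] == l).any()]
    parity_levels = [l for l in PARITY_LEVELS if (tab["parity"] == l).any()]
    age_mean = (
        float(tab["dam_age_days"].mean()) if spec.center_covariates else 0.0
    )
    f_mean = df_mean = 0.0
    if spec.center_covariates:
        if spec.inbreeding_mode == "II" and F_record is not None:
            f_mean = float(np.mean(F_record))
        if spec.inbreeding_mode == "III" and dF_record is not None:
            df_mean = float(np.mean(dF_record))
    coding = FixedCoding(
        year_map=year_map,
        year_levels=year_levels,
        litter_levels=litter_levels,
        parity_levels=parity_levels,
        age_mean=age_mean,
        inbreeding_mode=spec.inbreeding_mode,
        f_mean=f_mean,
        df_mean=df_mean,
    )
    names = ["intercept"]
    names += [f"year:{l}" for l in year_levels[1:]]
    names += [f"parity:{l}" for l in parity_levels[1:]]
    names += [f"litter:{l}" for l in litter_levels[1:]]
    names += ["age_lin", "age_quad"]
    if spec.inbreeding_mode == "II":
        names += ["F_lin", "F_quad"]
    elif spec.inbreeding_mode == "III":
        names += ["dF_lin"]
    X = coding.encode(tab, F=F_record, dF=dF_record)
    assert X.shape[1] == len(names)
    # constant covariates vanish under centering (or are identically 0,
    # e.g. dF when nobody is inbred); they carry no information beyond the
    # intercept and are dropped, keeping X full rank
    keep = (X != 0.0).any(axis=0)
    keep[0] = True
    if not keep.all():
        coding.keep = keep
        X = X[:, keep]
        names = [nm for nm, k in zip(names, keep) if k]
    coding.colnames = names
    return X, coding


def build_random_design(
    tab: pd.DataFrame, ped: Pedigree, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None, np.ndarray | None, list[str]]:
    """Record -> level index maps for the Z / M / W / P incidence structures."""
    try:
        z_idx = ped.positions(tab["calf_id"])
    except KeyError as e:
        raise ValueError(f"calf {e.args[0]!r} absent from pedigree") from None

    m_idx = w_idx = p_idx = None
    dam_levels: list[str] = []
    needs_dam = spec.has_maternal_genetic or spec.has_maternal_permanent
    if needs_dam:
        unknown = [d for d in tab["dam_id"] if d not in ped.index]
        if unknown:
            raise ValueError(
                f"maternal models need the dam in the pedigree; missing {sorted(set(unknown))[:5]}"
            )
    if spec.has_maternal_genetic:
        m_idx = ped.positions(tab["dam_id"])
    if spec.has_maternal_permanent:
        dam_levels = list(dict.fromkeys(tab["dam_id"]))
        level = {d: k for k, d in enumerate(dam_levels)}
        w_idx = np.array([level[d] for d in tab["dam_id"]], dtype=np.int64)
    if spec.has_paternal:
        missing = [s for s in tab["sire_id"] if s == "" or s not in ped.index]
        if missing:
            raise ValueError("paternal block needs every record's sire in the pedigree")
        p_idx = ped.positions(tab["sire_id"])
    return z_idx, m_idx, w_idx, p_idx, dam_levels


def build_design(
    tab: pd.DataFrame,
    ped: Pedigree,
    spec: ModelSpec,
    F: np.ndarray | None = None,
    dF: np.ndarray | None = None,
) -> DesignBundle:
    """Assemble the full design bundle for one model variant.

    ``F``/``dF`` are per-pedigree-member inbreeding quantities (as from
    :func:`pedgibbs.pedigree.inbreeding_table`), only needed for inbreeding
    modes II/III; records pick up the value of their calf.
    """
    tab = validate_phenotypes(tab, binary=(spec.scale == "threshold"))
    F_rec = dF_rec = None
    if spec.inbreeding_mode in ("II", "III"):
        try:
            z_tmp = ped.positions(tab["calf_id"])
        except KeyError as e:
            raise ValueError(f"calf {e.args[0]!r} absent from pedigree") from None
        if spec.inbreeding_mode == "II":
            if F is None:
                raise ValueError("inbreeding mode II requires F per pedigree member")
            F_rec = np.asarray(F)[z_tmp]
        else:
            if dF is None:
                raise ValueError("inbreeding mode III requires dF per pedigree member")
            dF_rec = np.asarray(dF)[z_tmp]
    X, coding = code_systematic_effects(tab, spec, F_rec, dF_rec)
    z_idx, m_idx, w_idx, p_idx, dam_levels = build_random_design(tab, ped, spec)
    y = tab["survival"].to_numpy(dtype=float)
    return DesignBundle(
        y=y,
        X=X,
        coding=coding,
        spec=spec,
        z_idx=z_idx,
        m_idx=m_idx,
        w_idx=w_idx,
        p_idx=p_idx,
        dam_levels=dam_levels,
        ped=ped,
        records=tab.reset_index(drop=True),
    )
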