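"""Pedigree handling and pedigree-derived quantities.

A studbook pedigree is the substrate for everything downstream: the
inbreeding coefficient ``F`` of each individual, the equivalent complete
generations ``t`` (a pedigree-depth measure), the individual increase in
inbreeding ``dF``, the numerator relationship matrix ``A`` and its sparse
inverse, which the Gibbs sampler uses to impose the additive-genetic
covariance structure.

Conventions
-----------
Individuals are identified by opaque strings.  Unknown parents are treated
as unrelated, non-inbred phantom founders.  Internally a pedigree is stored
topologically ordered (every parent precedes its offspring) with dense
integer indices assigned in that order.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Pedigree",
    "PedigreeError",
    "load_pedigree",
    "compute_inbreeding",
    "inbreeding_of_individual",
    "compute_equivalent_generations",
    "compute_delta_f",
    "inbreeding_table",
    "build_a_matrix",
    "build_a_inverse",
]

UNKNOWN = -1
_A_MATRIX_SIZE_GUARD = 4000


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicate ids, ...)."""


@dataclass
class Pedigree:
    """A validated, topologically ordered pedigree.

    Attributes
    ----------
    ids : list of str
        Individual identifiers in topological order (parents first).
    sire, dam : ndarray of int
        Position of each individual's sire/dam in ``ids``; ``-1`` if unknown.
    sex : ndarray of str
        ``"M"``, ``"F"`` or ``"U"`` (unknown).
    birth_year : ndarray of int
        Birth year; ``-1`` if unknown.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    birth_year: np.ndarray
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {iid: k for k, iid in enumerate(self.ids)}
        if len(self.index) != len(self.ids):
            dupes = pd.Series(self.ids).value_counts()
            raise PedigreeError(
                f"duplicate ids: {sorted(dupes[dupes > 1].index.tolist())}"
            )
        for k in range(self.n):
            for p in (self.sire[k], self.dam[k]):
                if p != UNKNOWN and p >= k:
                    raise PedigreeError(
                        f"pedigree not topologically ordered at {self.ids[k]!r}"
                    )

    @property
    def n(self) -> int:
        return len(self.ids)

    def positions(self, ids) -> np.ndarray:
        """Dense positions of the given ids; KeyError on unknown id."""
        return np.array([self.index[i] for i in ids], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        def name(p):
            return self.ids[p] if p != UNKNOWN else ""

        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [name(p) for p in self.sire],
                "dam": [name(p) for p in self.dam],
                "sex": self.sex,
                "birth_year": self.birth_year,
            }
        )


def _toposort(ids, sire_of, dam_of):
    """Kahn's algorithm; raises on cycles with the offending ids."""
    children: dict[str, list[str]] = {i: [] for i in ids}
    indeg = {i: 0 for i in ids}
    for i in ids:
        for p in (sire_of[i], dam_of[i]):
            if p is not None:
                children[p].append(i)
                indeg[i] += 1
    # heap keeps the order deterministic (input order among ready nodes)
    pos = {iid: k for k, iid in enumerate(ids)}
    ready = [pos[i] for i in ids if indeg[i] == 0]
    heapq.heapify(ready)
    out = []
    while ready:
        i = ids[heapq.heappop(ready)]
        out.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, pos[c])
    if len(out) < len(ids):
        cyc = sorted(i for i in ids if indeg[i] > 0)
        raise PedigreeError(f"cycle detected: individual(s) {cyc} are their own ancestors")
    return out


def from_records(records, strict_sex: bool = True) -> Pedigree:
    """Build a Pedigree from an iterable of (id, sire, dam, sex, birth_year).

    ``sire``/``dam`` of ``None`` mean unknown.  Parents that never appear as
    individuals are augmented as phantom founders (sex inferred from the
    role, birth year unknown).
    """
    recs = list(records)
    ids = [r[0] for r in recs]
    seen = set()
    for i in ids:
        if i in seen:
            raise PedigreeError(f"duplicate ids: ['{i}']")
        seen.add(i)

    sire_of = {r[0]: r[1] for r in recs}
    dam_of = {r[0]: r[2] for r in recs}
    sex_of = {r[0]: (r[3] or "U") for r in recs}
    year_of = {r[0]: (r[4] if r[4] is not None else UNKNOWN) for r in recs}

    all_sires = {p for p in sire_of.values() if p is not None}
    all_dams = {p for p in dam_of.values() if p is not None}
    both = all_sires & all_dams
    if strict_sex and both:
        raise PedigreeError(
            f"parent sex inconsistency: id(s) {sorted(both)} used as both sire and dam"
        )
    for p in sorted(all_sires | all_dams):
        if p not in seen:  # phantom founder
            ids.append(p)
            seen.add(p)
            sire_of[p] = dam_of[p] = None
            sex_of[p] = "M" if p in all_sires else "F"
            year_of[p] = UNKNOWN
    if strict_sex:
        bad = sorted(
            p for p in all_sires if sex_of.get(p, "U") == "F"
        ) + sorted(p for p in all_dams if sex_of.get(p, "U") == "M")
        if bad:
            raise PedigreeError(f"parent sex inconsistency for id(s) {bad}")

    order = _toposort(ids, sire_of, dam_of)
    index = {iid: k for k, iid in enumerate(order)}
    sire = np.array(
        [index[sire_of[i]] if sire_of[i] is not None else UNKNOWN for i in order],
        dtype=np.int64,
    )
    dam = np.array(
        [index[dam_of[i]] if dam_of[i] is not None else UNKNOWN for i in order],
        dtype=np.int64,
    )
    sex = np.array([sex_of[i] for i in order], dtype="U1")
    year = np.array([year_of[i] for i in order], dtype=np.int64)
    return Pedigree(order, sire, dam, sex, year)


def load_pedigree(path, unknown_code: str = "0", sep: str = ",") -> Pedigree:
    """Read a studbook-style pedigree CSV with columns id,sire,dam,sex,birth_year.

    ``unknown_code`` (default ``"0"``) and empty fields both denote an
    unknown parent / unknown birth year.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree file {path} missing column(s) {sorted(missing)}")

    def parent(v):
        v = v.strip()
        return None if v in ("", unknown_code) else v

    def year(v):
        v = str(v).strip()
        if v in ("", unknown_code):
            return None
        return int(float(v))

    def sex(v):
        v = str(v).strip().upper()
        return v if v in ("M", "F") else "U"

    recs = []
    for _, row in df.iterrows():
        recs.append(
            (
                row["id"].strip(),
                parent(row["sire"]),
                parent(row["dam"]),
                sex(row["sex"]) if "sex" in df.columns else "U",
                year(row["birth_year"]) if "birth_year" in df.columns else None,
            )
        )
    return from_records(recs)


def _mendelian_d(k: int, sire: np.ndarray, dam: np.ndarray, F: np.ndarray) -> float:
    """Variance of the Mendelian sampling term (the 'D' of the decomposition
    A = T D T'), with the standard unknown-parent adjustments."""
    s, d = sire[k], dam[k]
    if s != UNKNOWN and d != UNKNOWN:
        return 0.5 - 0.25 * (F[s] + F[d])
    if s != UNKNOWN:
        return 0.75 - 0.25 * F[s]
    if d != UNKNOWN:
        return 0.75 - 0.25 * F[d]
    return 1.0


def compute_inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F by the Meuwissen & Luo algorithm.

    F_i is the probability that individual i carries two alleles identical
    by descent; equivalently ``A_ii - 1`` from the tabular method.  For each
    individual the algorithm walks its ancestor set once, accumulating the
    squared path coefficients L weighted by the Mendelian sampling variances
    D of the ancestors, so the whole pedigree costs O(sum of ancestor-set
    sizes) instead of O(n^2) dense work.
    """
    n = ped.n
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    for i in range(n):
        F[i] = inbreeding_of_individual(i, sire, dam, F)
    return F


def inbreeding_of_individual(i, sire, dam, F) -> float:
    """F of individual i given parent arrays and the F of all earlier
    individuals (the per-individual step of the Meuwissen & Luo walk).

    Also usable incrementally while a pedigree is being grown, since it only
    consults entries of ``F`` for ancestors of i.
    """
    s, d = sire[i], dam[i]
    if s == UNKNOWN or d == UNKNOWN:
        return 0.0
    # A_ii of i itself = sum over ancestors j (incl. i) of L_ij^2 D_j.
    # Pop ancestors in decreasing topological index so every path
    # contribution to j is accumulated before j itself is popped.
    coeff: dict[int, float] = {i: 1.0}
    heap = [-i]
    aii = 0.0
    while heap:
        j = -heapq.heappop(heap)
        c = coeff.pop(j, 0.0)
        if c == 0.0:
            continue
        aii += c * c * _mendelian_d(j, sire, dam, F)
        for p in (sire[j], dam[j]):
            if p != UNKNOWN:
                if p not in coeff:
                    coeff[p] = 0.0
                    heapq.heappush(heap, -p)
                coeff[p] += 0.5 * c
    return aii - 1.0


def compute_equivalent_generations(ped: Pedigree) -> np.ndarray:
    """Equivalent complete generations t: sum over known ancestors of (1/2)^g.

    Computed by the recursion t_i = sum over known parents p of (1 + t_p)/2;
    founders get 0.
    """
    t = np.zeros(ped.n)
    for i in range(ped.n):
        acc = 0.0
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN:
                acc += 0.5 * (1.0 + t[p])
        t[i] = acc
    return t


def compute_delta_f(F: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Individual increase in inbreeding: dF = 1 - (1 - F)^(1/(t - 1)).

    dF is the constant per-generation rate that would accumulate F over the
    individual's own pedigree depth t.  For t <= 1 (founders and
    near-founders, which cannot have accumulated inbreeding) dF is 0.
    """
    F = np.asarray(F, dtype=float)
    t = np.asarray(t, dtype=float)
    if F.shape != t.shape:
        raise ValueError("F and t must be on the same id set")
    if np.any((F < 0) | (F > 1)):
        raise ValueError("F outside [0, 1]")
    dF = np.zeros_like(F)
    mask = (t > 1.0) & (F > 0.0)
    dF[mask] = 1.0 - np.power(1.0 - F[mask], 1.0 / (t[mask] - 1.0))
    return dF


def inbreeding_table(ped: Pedigree) -> pd.DataFrame:
    """Per-individual F, t and dF as a DataFrame indexed like the pedigree."""
    F = compute_inbreeding(ped)
    t = compute_equivalent_generations(ped)
    return pd.DataFrame(
        {"id": ped.ids, "F": F, "t": t, "delta_F": compute_delta_f(F, t)}
    )


def build_a_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    Intended as a small-scale oracle (diagonal 1 + F_i); guarded against
    accidental use on large pedigrees, where the sparse inverse route
    (:func:`build_a_inverse`) should be used instead.
    """
    n = ped.n
    if n > _A_MATRIX_SIZE_GUARD:
        raise ValueError(
            f"pedigree of {n} exceeds the dense-A guard ({_A_MATRIX_SIZE_GUARD}); "
            "use build_a_inverse for the sampler"
        )
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        if d != UNKNOWN:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        aii = 1.0
        if s != UNKNOWN and d != UNKNOWN:
            aii += 0.5 * A[s, d]
        A[i, i] = aii
    return A


def build_a_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sparse.csr_matrix:
    """Sparse inverse of the numerator relationship matrix.

    Uses the classical rules accounting for inbreeding: each individual
    contributes 1/D_k (the inverse Mendelian sampling variance, which needs
    the parents' F) to a 3x3 pattern over (individual, sire, dam).
    """
    if F is None:
        F = compute_inbreeding(ped)
    F = np.asarray(F, dtype=float)
    if F.shape[0] != ped.n:
        raise ValueError("F entries missing: length does not match pedigree size")
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for k in range(ped.n):
        alpha = 1.0 / _mendelian_d(k, ped.sire, ped.dam, F)
        s, d = ped.sire[k], ped.dam[k]
        add(k, k, alpha)
        for p in (s, d):
            if p != UNKNOWN:
                add(p, k, -alpha / 2.0)
                add(k, p, -alpha / 2.0)
                add(p, p, alpha / 4.0)
        if s != UNKNOWN and d != UNKNOWN:
            add(s, d, alpha / 4.0)
            add(d, s, alpha / 4.0)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(ped.n, ped.n))
    return Ainv.tocsr()
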