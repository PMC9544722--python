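"""Pedigree containers, validation, pruning, summaries and relatedness.

The central object is :class:`Pedigree`, a topologically sorted table of
(individual, dam, sire, cohort) records.  Unknown parents are treated as
unrelated, non-inbred base-population founders, which is the standard
assumption for immigrants into an open study population.

Relatedness machinery:

* inbreeding coefficients ``F`` by the Meuwissen & Luo style traversal of the
  Cholesky (gene-flow) representation ``A = L D L'``,
* the sparse inverse of the numerator relationship matrix ``A`` assembled by
  Henderson's rules with inbreeding, without ever forming dense ``A``,
* dense ``A`` by the recursive tabular method, only on request (it is
  quadratic in memory and only needed for small pedigrees / validation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

__all__ = [
    "Pedigree",
    "PedigreeSummary",
    "RelatednessStructure",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "prune_to_phenotyped",
    "summarize",
    "additive_relationship",
    "inbreeding",
]

#: parent-field values interpreted as "unknown parent" by default
DEFAULT_MISSING = ("", "NA", "na", "NaN", "nan", "0", "*", ".")

_ID_ALIASES = ("id", "individual", "individual_id", "animal")
_DAM_ALIASES = ("dam", "dam_id", "mother", "mum")
_SIRE_ALIASES = ("sire", "sire_id", "father", "dad")
_COHORT_ALIASES = ("cohort", "hatch_year", "birth_year", "year_born")


class PedigreeError(ValueError):
    """Raised for structural problems in a pedigree (duplicates, cycles...)."""


# ---------------------------------------------------------------------------
# Pedigree container
# ---------------------------------------------------------------------------


class Pedigree:
    """Topologically sorted pedigree.

    Parameters
    ----------
    ids
        Individual identifiers (opaque strings; coerced with ``str``).
    dam, sire
        Parent identifiers aligned with *ids*; ``None`` for unknown.
    cohort
        Optional hatch year per individual (``nan`` = unknown).

    Notes
    -----
    On construction the records are validated (unique ids, parents present,
    acyclic) and re-ordered so that parents always precede offspring.  Parent
    references to absent individuals raise; use :func:`read_pedigree` for the
    forgiving file-reading path that auto-inserts phantom founders.
    """

    def __init__(
        self,
        ids: Sequence,
        dam: Sequence,
        sire: Sequence,
        cohort: Sequence | None = None,
    ) -> None:
        ids = [str(i) for i in ids]
        n = len(ids)
        if len(set(ids)) != n:
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise PedigreeError(f"duplicate individual id: {i!r}")
                seen.add(i)
        index = {i: k for k, i in enumerate(ids)}

        def _pidx(p) -> int:
            if p is None or (isinstance(p, float) and np.isnan(p)) or p == "":
                return -1
            p = str(p)
            if p not in index:
                raise PedigreeError(f"parent {p!r} has no record of its own")
            return index[p]

        dam_idx = np.array([_pidx(p) for p in dam], dtype=np.int64)
        sire_idx = np.array([_pidx(p) for p in sire], dtype=np.int64)
        if cohort is None:
            coh = np.full(n, np.nan)
        else:
            coh = np.asarray(
                [np.nan if c is None else float(c) for c in cohort], dtype=float
            )

        order = _toposort(dam_idx, sire_idx, ids)
        rank = np.empty(n, dtype=np.int64)
        rank[order] = np.arange(n)
        remap = np.concatenate([rank, [-1]])  # remap[-1] stays -1

        self.ids: np.ndarray = np.array(ids, dtype=object)[order]
        self.dam: np.ndarray = remap[dam_idx][order]
        self.sire: np.ndarray = remap[sire_idx][order]
        self.cohort: np.ndarray = coh[order]
        self._index = {i: k for k, i in enumerate(self.ids)}
        self._check_cohorts()

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, item) -> bool:
        return str(item) in self._index

    def index_of(self, individual) -> int:
        """Position of *individual* in topological order."""
        return self._index[str(individual)]

    def indices_of(self, individuals: Iterable) -> np.ndarray:
        return np.array([self._index[str(i)] for i in individuals], dtype=np.int64)

    @property
    def is_founder(self) -> np.ndarray:
        """Boolean mask: neither parent known."""
        return (self.dam < 0) & (self.sire < 0)

    @property
    def n_founders(self) -> int:
        return int(self.is_founder.sum())

    def depths(self) -> np.ndarray:
        """Generation depth per individual (founders = 1, longest chain)."""
        d = np.ones(len(self), dtype=np.int64)
        for i in range(len(self)):
            for p in (self.dam[i], self.sire[i]):
                if p >= 0:
                    d[i] = max(d[i], d[p] + 1)
        return d

    def to_frame(self) -> pd.DataFrame:
        """Records as a DataFrame (id, dam, sire, cohort; NA = unknown)."""
        def _name(idx: int):
            return self.ids[idx] if idx >= 0 else None

        return pd.DataFrame(
            {
                "id": self.ids,
                "dam": [_name(i) for i in self.dam],
                "sire": [_name(i) for i in self.sire],
                "cohort": self.cohort,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        cohort = frame["cohort"] if "cohort" in frame else None
        return cls(frame["id"], frame["dam"], frame["sire"], cohort)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return (
            np.array_equal(self.ids, other.ids)
            and np.array_equal(self.dam, other.dam)
            and np.array_equal(self.sire, other.sire)
            and np.array_equal(self.cohort, other.cohort, equal_nan=True)
        )

    # -- internals ---------------------------------------------------------

    def _check_cohorts(self) -> None:
        bad = []
        for i in range(len(self)):
            if np.isnan(self.cohort[i]):
                continue
            for p in (self.dam[i], self.sire[i]):
                if p >= 0 and not np.isnan(self.cohort[p]):
                    if self.cohort[i] < self.cohort[p]:
                        bad.append(self.ids[i])
        if bad:
            warnings.warn(
                f"{len(bad)} individual(s) hatched before a parent "
                f"(first: {bad[0]!r}); check cohort assignments",
                stacklevel=3,
            )


def _toposort(dam: np.ndarray, sire: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    """Kahn's algorithm; raises PedigreeError listing one cycle on failure."""
    n = len(dam)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (dam[i], sire[i]):
            if p >= 0:
                children[p].append(i)
                indeg[i] += 1
    queue = [i for i in range(n) if indeg[i] == 0]
    order = []
    while queue:
        nxt: list[int] = []
        for u in queue:
            order.append(u)
            for c in children[u]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    nxt.append(c)
        queue = nxt
    if len(order) < n:
        remaining = [i for i in range(n) if indeg[i] > 0]
        cycle = _find_cycle(dam, sire, remaining[0])
        path = " -> ".join(ids[i] for i in cycle)
        raise PedigreeError(f"pedigree contains a cycle: {path}")
    return np.array(order, dtype=np.int64)


def _find_cycle(dam: np.ndarray, sire: np.ndarray, start: int) -> list[int]:
    seen: dict[int, int] = {}
    path = []
    u = start
    while u not in seen:
        seen[u] = len(path)
        path.append(u)
        u = dam[u] if dam[u] >= 0 else sire[u]  # any parent edge inside the cycle
    return path[seen[u] :] + [u]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_pedigree(
    path,
    missing: Sequence[str] = DEFAULT_MISSING,
    sep: str | None = None,
) -> Pedigree:
    """Read a delimited pedigree file into a :class:`Pedigree`.

    The file needs a header naming id/dam/sire columns (common aliases are
    recognised, e.g. ``animal``/``mother``/``father``); a cohort/hatch-year
    column is optional.  Parent fields matching one of *missing* are treated
    as unknown.  A parent referenced but lacking its own record is inserted
    as a founder, with a warning — this is the common shorthand in field
    pedigrees where e.g. a marked immigrant appears only as a parent.
    """
    df = pd.read_csv(
        path, sep=sep, engine="python" if sep is None else "c", dtype=str,
        keep_default_na=False,
    )
    cols = {c.lower().strip(): c for c in df.columns}

    def _pick(aliases, what, required=True):
        for a in aliases:
            if a in cols:
                return cols[a]
        if required:
            raise PedigreeError(
                f"no {what} column found (looked for {', '.join(aliases)})"
            )
        return None

    id_c = _pick(_ID_ALIASES, "individual-id")
    dam_c = _pick(_DAM_ALIASES, "dam")
    sire_c = _pick(_SIRE_ALIASES, "sire")
    coh_c = _pick(_COHORT_ALIASES, "cohort", required=False)

    miss = set(missing)

    def _clean(v: str):
        v = v.strip()
        return None if v in miss else v

    ids = [v.strip() for v in df[id_c]]
    dam = [_clean(v) for v in df[dam_c]]
    sire = [_clean(v) for v in df[sire_c]]
    cohort = None
    if coh_c is not None:
        cohort = [
            None if _clean(v) is None else float(v) for v in df[coh_c]
        ]

    known = set(ids)
    phantoms = []
    for p in list(dam) + list(sire):
        if p is not None and p not in known:
            known.add(p)
            phantoms.append(p)
    if phantoms:
        warnings.warn(
            f"{len(phantoms)} parent id(s) had no record and were added as "
            f"founders (first: {phantoms[0]!r})",
            stacklevel=2,
        )
        ids = ids + phantoms
        dam = dam + [None] * len(phantoms)
        sire = sire + [None] * len(phantoms)
        if cohort is not None:
            cohort = cohort + [None] * len(phantoms)
    return Pedigree(ids, dam, sire, cohort)


def write_pedigree(ped: Pedigree, path, sep: str = "\t") -> None:
    """Write the pedigree as delimited text (unknown parent = ``NA``)."""
    df = ped.to_frame()
    df["dam"] = df["dam"].fillna("NA")
    df["sire"] = df["sire"].fillna("NA")
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------


def prune_to_phenotyped(ped: Pedigree, phenotyped_ids: Iterable) -> Pedigree:
    """Restrict *ped* to phenotyped individuals and their ancestors.

    This is the standard pruning for animal-model analyses: individuals that
    are neither phenotyped nor ancestral to a phenotyped individual carry no
    information about the additive genetic variance and are dropped.
    Idempotent.  Raises on an empty phenotyped set or on ids absent from the
    pedigree.
    """
    pheno = {str(i) for i in phenotyped_ids}
    if not pheno:
        raise PedigreeError("phenotyped id set is empty")
    unknown = pheno - set(ped.ids)
    if unknown:
        raise PedigreeError(
            f"{len(unknown)} phenotyped id(s) not in pedigree "
            f"(first: {sorted(unknown)[0]!r})"
        )
    keep = np.zeros(len(ped), dtype=bool)
    stack = [ped.index_of(i) for i in pheno]
    while stack:
        u = stack.pop()
        if keep[u]:
            continue
        keep[u] = True
        for p in (ped.dam[u], ped.sire[u]):
            if p >= 0 and not keep[p]:
                stack.append(p)
    idx = np.flatnonzero(keep)
    sub = {int(i): k for k, i in enumerate(idx)}

    def _name(p: int):
        return ped.ids[p] if p >= 0 else None

    return Pedigree(
        ped.ids[idx],
        [_name(ped.dam[i]) for i in idx],
        [_name(ped.sire[i]) for i in idx],
        ped.cohort[idx],
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PedigreeSummary:
    """Headline structure counts of a pedigree.

    Sibling quantities are counts of unordered *pairs*; paternal/maternal
    half-sib pair counts include full-sib pairs (so ``n_fullsib_pairs`` is a
    lower bound for both).  ``max_depth`` is the longest parent chain, with
    founders at depth 1.
    """

    n_records: int
    max_depth: int
    n_paternities: int
    n_maternities: int
    n_fullsib_pairs: int
    n_paternal_halfsib_pairs_incl_full: int
    n_maternal_halfsib_pairs_incl_full: int

    def __post_init__(self):
        assert self.n_fullsib_pairs <= self.n_paternal_halfsib_pairs_incl_full
        assert self.n_fullsib_pairs <= self.n_maternal_halfsib_pairs_incl_full


def _pair_count(groups: pd.Series) -> int:
    k = groups.to_numpy(dtype=np.int64)
    return int((k * (k - 1) // 2).sum())


def summarize(ped: Pedigree) -> PedigreeSummary:
    """Compute :class:`PedigreeSummary` counts for *ped*."""
    dam, sire = ped.dam, ped.sire
    has_d, has_s = dam >= 0, sire >= 0
    df = pd.DataFrame({"dam": dam, "sire": sire})
    full = _pair_count(df[has_d & has_s].groupby(["dam", "sire"]).size())
    pat = _pair_count(df[has_s].groupby("sire").size())
    mat = _pair_count(df[has_d].groupby("dam").size())
    return PedigreeSummary(
        n_records=len(ped),
        max_depth=int(ped.depths().max()) if len(ped) else 0,
        n_paternities=int(has_s.sum()),
        n_maternities=int(has_d.sum()),
        n_fullsib_pairs=full,
        n_paternal_halfsib_pairs_incl_full=pat,
        n_maternal_halfsib_pairs_incl_full=mat,
    )


# ---------------------------------------------------------------------------
# Relatedness
# ---------------------------------------------------------------------------


@dataclass
class RelatednessStructure:
    """Additive relatedness derived from a pedigree.

    Attributes
    ----------
    F
        Inbreeding coefficient per individual (pedigree order).
    A_inv
        Sparse inverse of the numerator relationship matrix ``A`` (CSR).
    A
        Dense ``A`` if it was requested, else ``None``; see :meth:`dense_A`.
    mendelian_variance
        ``d_i`` such that the Mendelian sampling deviation of individual *i*
        has variance ``d_i * V_A`` (1 for founders, ``0.5 - 0.25 (F_s+F_d)``
        with both parents known, ``0.75 - 0.25 F_p`` with one).
    """

    F: np.ndarray
    A_inv: sparse.csr_matrix
    mendelian_variance: np.ndarray
    A: np.ndarray | None = None
    _ped: "Pedigree" = field(default=None, repr=False)

    def dense_A(self) -> np.ndarray:
        """Dense numerator relationship matrix (computed on first call)."""
        if self.A is None:
            self.A = _tabular_A(self._ped.dam, self._ped.sire)
        return self.A


@njit(cache=True)
def _inbreeding_ml(dam, sire):  # pragma: no cover - exercised via wrapper
    """Meuwissen & Luo style F: A_ii = sum_j L_ij^2 D_j over ancestors j."""
    n = dam.shape[0]
    F = np.zeros(n)
    D = np.zeros(n)
    w = np.zeros(n)
    touched = np.empty(n, dtype=np.int64)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0:
            D[i] = 0.75 - 0.25 * F[s]
        elif d >= 0:
            D[i] = 0.75 - 0.25 * F[d]
        else:
            D[i] = 1.0
            continue  # founder: F stays 0
        # accumulate a_ii by walking ancestors in decreasing topological index
        ntouch = 0
        w[i] = 1.0
        touched[ntouch] = i
        ntouch += 1
        aii = 0.0
        for k in range(i, -1, -1):
            if w[k] == 0.0:
                continue
            wk = w[k]
            aii += wk * wk * D[k]
            for p in (sire[k], dam[k]):
                if p >= 0:
                    if w[p] == 0.0:
                        touched[ntouch] = p
                        ntouch += 1
                    w[p] += 0.5 * wk
        F[i] = aii - 1.0
        for t in range(ntouch):
            w[touched[t]] = 0.0
    return F, D


@njit(cache=True)
def _tabular_A(dam, sire):  # pragma: no cover - exercised via wrapper
    """Dense A by the recursive tabular method (pedigree in topo order)."""
    n = dam.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = a
            A[j, i] = a
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
    return A


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients in pedigree order (founders = 0)."""
    F, _ = _inbreeding_ml(ped.dam, ped.sire)
    return F


def additive_relationship(ped: Pedigree, dense: bool = False) -> RelatednessStructure:
    """Build the additive relatedness structure for *ped*.

    ``A_inv`` is assembled sparsely by Henderson's rules with inbreeding,
    i.e. without forming dense ``A``.  Pass ``dense=True`` (or call
    :meth:`RelatednessStructure.dense_A` later) to also obtain dense ``A``
    from the tabular method; only sensible for modest pedigrees.
    """
    n = len(ped)
    F, D = _inbreeding_ml(ped.dam, ped.sire)
    if np.any(D <= 0):
        raise PedigreeError(
            "non-positive Mendelian sampling variance encountered; "
            "the pedigree is corrupt (impossible inbreeding values)"
        )
    rows, cols, vals = _ainv_entries(ped.dam, ped.sire, D)
    A_inv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    A = _tabular_A(ped.dam, ped.sire) if dense else None
    return RelatednessStructure(
        F=F, A_inv=A_inv, mendelian_variance=D, A=A, _ped=ped
    )


@njit(cache=True)
def _ainv_entries(dam, sire, D):  # pragma: no cover - exercised via wrapper
    n = dam.shape[0]
    # worst case 9 entries per individual
    rows = np.empty(9 * n, dtype=np.int64)
    cols = np.empty(9 * n, dtype=np.int64)
    vals = np.empty(9 * n)
    k = 0
    for i in range(n):
        alpha = 1.0 / D[i]
        s, d = sire[i], dam[i]
        rows[k], cols[k], vals[k] = i, i, alpha
        k += 1
        for p in (s, d):
            if p >= 0:
                rows[k], cols[k], vals[k] = i, p, -0.5 * alpha
                k += 1
                rows[k], cols[k], vals[k] = p, i, -0.5 * alpha
                k += 1
                rows[k], cols[k], vals[k] = p, p, 0.25 * alpha
                k += 1
        if s >= 0 and d >= 0:
            rows[k], cols[k], vals[k] = s, d, 0.25 * alpha
            k += 1
            rows[k], cols[k], vals[k] = d, s, 0.25 * alpha
            k += 1
    return rows[:k], cols[:k], vals[:k]
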