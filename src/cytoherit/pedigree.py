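"""Pedigree parsing, recursive kinship coefficients and relatedness matrices.

The kinship coefficient Phi(i, j) is the probability that one allele drawn
at random from individual i and one from j are identical by descent.  All
variance-component models in this package use the relatedness matrix 2*Phi
as the covariance structure of the additive genetic effect.

Founders are assumed unrelated and non-inbred.  Monozygotic (MZ) twins,
marked by a shared ``mz_group`` label, are treated as genetically identical:
Phi between co-twins equals self-kinship, and kinship of any individual with
a twin is automatically equal for both co-twins because they share parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "KinshipMatrix",
    "PedigreeError",
    "load_pedigree",
    "write_pedigree",
    "kinship_coefficient",
    "kinship_matrix",
    "classify_relationship",
]

PEDIGREE_COLUMNS = ["family_id", "individual_id", "father_id", "mother_id", "sex"]
OPTIONAL_COLUMNS = ["age", "mz_group"]

#: tolerance below which the relatedness matrix must be positive semi-definite
PSD_TOL = 1e-8


class PedigreeError(ValueError):
    """Malformed pedigree: bad reference, cycle, or duplicate id."""


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: int = 0  # 1 = male, 2 = female, 0 = unknown
    age: float | None = None
    mz_group: str | None = None

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """A set of families with validated parent links.

    Individuals are stored in topological order (founders first), so a
    single forward pass can propagate any quantity down the generations.
    """

    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {ind.individual_id: ind for ind in self.individuals}
        self._validate()
        self._depth = self._compute_depths()
        # sort topologically: parents always precede children
        self.individuals.sort(key=lambda ind: (self._depth[ind.individual_id], ind.individual_id))

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def __getitem__(self, individual_id: str) -> Individual:
        try:
            return self._by_id[individual_id]
        except KeyError:
            raise KeyError(f"unknown individual id: {individual_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return [ind.individual_id for ind in self.individuals]

    @property
    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    @property
    def families(self) -> dict[str, list[Individual]]:
        fams: dict[str, list[Individual]] = {}
        for ind in self.individuals:
            fams.setdefault(ind.family_id, []).append(ind)
        return fams

    def depth(self, individual_id: str) -> int:
        return self._depth[individual_id]

    def _validate(self) -> None:
        if len(self._by_id) != len(self.individuals):
            seen: set[str] = set()
            for ind in self.individuals:
                if ind.individual_id in seen:
                    raise PedigreeError(
                        f"duplicated individual_id {ind.individual_id!r}"
                    )
                seen.add(ind.individual_id)
        for ind in self.individuals:
            for parent in (ind.father_id, ind.mother_id):
                if parent is None:
                    continue
                if parent not in self._by_id:
                    raise PedigreeError(
                        f"{ind.individual_id!r} references missing parent {parent!r}"
                    )
                if self._by_id[parent].family_id != ind.family_id:
                    raise PedigreeError(
                        f"parent {parent!r} of {ind.individual_id!r} is in a "
                        "different family"
                    )

    def _compute_depths(self) -> dict[str, int]:
        """Generation depth via DFS; detects ancestry cycles."""
        depth: dict[str, int] = {}
        visiting: set[str] = set()

        def visit(iid: str) -> int:
            if iid in depth:
                return depth[iid]
            if iid in visiting:
                raise PedigreeError(f"ancestry cycle involving {iid!r}")
            visiting.add(iid)
            ind = self._by_id[iid]
            parents = [p for p in (ind.father_id, ind.mother_id) if p is not None]
            d = 0 if not parents else 1 + max(visit(p) for p in parents)
            visiting.discard(iid)
            depth[iid] = d
            return d

        for ind in self.individuals:
            visit(ind.individual_id)
        return depth


@dataclass
class KinshipMatrix:
    """Ordered ids with the kinship matrix Phi and relatedness 2*Phi."""

    ids: list[str]
    phi: np.ndarray

    @property
    def relatedness(self) -> np.ndarray:
        return 2.0 * self.phi

    def index_of(self, individual_id: str) -> int:
        return self.ids.index(individual_id)


# ---------------------------------------------------------------------------
# file I/O


def _parse_missing(value) -> str | None:
    if pd.isna(value):
        return None
    s = str(value).strip()
    return None if s in ("", "0") else s


_SEX_CODES = {"1": 1, "2": 2, "M": 1, "F": 2, "m": 1, "f": 2, "0": 0, "": 0}


def load_pedigree(path) -> Pedigree:
    """Read a tab-delimited pedigree file.

    Columns: family_id, individual_id, father_id, mother_id, sex and the
    optional age and mz_group.  "0" or an empty field denotes a missing
    parent / unknown value.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PEDIGREE_COLUMNS if c not in df.columns]
    if missing:
        raise PedigreeError(f"pedigree file missing columns: {missing}")
    individuals = []
    for _, row in df.iterrows():
        sex_raw = "" if pd.isna(row["sex"]) else str(row["sex"]).strip()
        if sex_raw not in _SEX_CODES:
            raise PedigreeError(f"unrecognized sex code {sex_raw!r}")
        age = None
        if "age" in df.columns and not pd.isna(row.get("age")):
            age = float(row["age"])
        mz = _parse_missing(row["mz_group"]) if "mz_group" in df.columns else None
        individuals.append(
            Individual(
                individual_id=str(row["individual_id"]).strip(),
                family_id=str(row["family_id"]).strip(),
                father_id=_parse_missing(row["father_id"]),
                mother_id=_parse_missing(row["mother_id"]),
                sex=_SEX_CODES[sex_raw],
                age=age,
                mz_group=mz,
            )
        )
    return Pedigree(individuals)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write the same tab-delimited dialect that :func:`load_pedigree` reads."""
    rows = []
    for ind in ped.individuals:
        rows.append(
            {
                "family_id": ind.family_id,
                "individual_id": ind.individual_id,
                "father_id": ind.father_id or "0",
                "mother_id": ind.mother_id or "0",
                "sex": ind.sex,
                "age": "" if ind.age is None else ind.age,
                "mz_group": ind.mz_group or "0",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# kinship


class _KinshipCalculator:
    """Memoized recursive kinship over one pedigree."""

    def __init__(self, ped: Pedigree):
        self.ped = ped
        self._cache: dict[tuple[str, str], float] = {}

    def phi(self, i: str, j: str) -> float:
        if i not in self.ped or j not in self.ped:
            missing = i if i not in self.ped else j
            raise KeyError(f"unknown individual id: {missing!r}")
        return self._phi(i, j)

    def _phi(self, i: str, j: str) -> float:
        key = (i, j) if i <= j else (j, i)
        if key in self._cache:
            return self._cache[key]
        a, b = self.ped[i], self.ped[j]
        if i == j:
            val = self._self_phi(a)
        elif a.mz_group is not None and a.mz_group == b.mz_group:
            # MZ co-twins are genetically identical
            val = self._self_phi(a)
        elif a.family_id != b.family_id:
            val = 0.0
        else:
            # expand the later-generation individual
            if self.ped.depth(i) < self.ped.depth(j):
                a, b, i, j = b, a, j, i
            if a.is_founder:
                val = 0.0
            else:
                val = 0.5 * (
                    (self._phi(a.father_id, j) if a.father_id else 0.0)
                    + (self._phi(a.mother_id, j) if a.mother_id else 0.0)
                )
        self._cache[key] = val
        return val

    def _self_phi(self, ind: Individual) -> float:
        if ind.father_id and ind.mother_id:
            return 0.5 * (1.0 + self._phi(ind.father_id, ind.mother_id))
        return 0.5


def kinship_coefficient(ped: Pedigree, i: str, j: str) -> float:
    """Kinship coefficient Phi(i, j) by the standard recursion."""
    return _KinshipCalculator(ped).phi(i, j)


def kinship_matrix(ped: Pedigree, ids: Sequence[str] | None = None) -> KinshipMatrix:
    """Kinship matrix over ``ids`` (default: every pedigree member).

    Ancestors absent from ``ids`` still contribute through the recursion.
    The relatedness matrix 2*Phi must be positive semi-definite to within
    ``PSD_TOL``; a violation indicates a corrupted pedigree and is an error.
    """
    if ids is None:
        ids = ped.ids
    ids = list(ids)
    if not ids:
        raise ValueError("ids must be non-empty")
    calc = _KinshipCalculator(ped)
    n = len(ids)
    phi = np.empty((n, n))
    for r in range(n):
        for c in range(r, n):
            phi[r, c] = phi[c, r] = calc.phi(ids[r], ids[c])
    rel = 2.0 * phi
    min_eig = float(np.linalg.eigvalsh(rel).min())
    if min_eig < -PSD_TOL:
        raise PedigreeError(
            f"relatedness matrix is not PSD (min eigenvalue {min_eig:.3g})"
        )
    return KinshipMatrix(ids=ids, phi=phi)


_PHI_BANDS = [
    (0.25, "first-degree"),
    (0.125, "second-degree"),
    (0.0625, "third-degree"),
    (0.0, "unrelated"),
]


def classify_relationship(ped: Pedigree, i: str, j: str, *, tol: float = 1e-9) -> str:
    """Label a pair by its kinship band.

    Returns one of {self, mz, first-degree, second-degree, third-degree,
    unrelated, other}; nonstandard coefficients (e.g. from inbred loops)
    map to "other".
    """
    if i == j:
        return "self"
    phi = kinship_coefficient(ped, i, j)
    if phi >= 0.5 - tol:
        return "mz"
    for band, label in _PHI_BANDS:
        if abs(phi - band) <= tol:
            return label
    return "other"
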