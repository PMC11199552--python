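"""Nuclear-family cohort data model and genetic/family-environment design matrices.

The cohort is a collection of nuclear families (father, mother, children),
each family tied to a single geographic location.  Phenotype and covariate
vectors are aligned to a canonical within-family ordering: father, mother,
then children sorted by birth year.  Genetic relatedness is modeled only
within families (expected additive relationship: parent-child and full-sib
pairs 0.5, spouses 0); families are genetically unrelated to each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

ROLES = ("father", "mother", "child")

_ROLE_SORT = {"father": 0, "mother": 1, "child": 2}


class PedigreeError(ValueError):
    """Structural error in a family or cohort definition."""


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    role: str
    sex: str
    birth_year: int
    months_enrolled: int
    location_id: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PedigreeError(
                f"unknown role {self.role!r} for individual {self.individual_id!r};"
                f" expected one of {ROLES}"
            )


@dataclass
class Family:
    """A nuclear family in canonical member order (father, mother, children).

    At most one father and one mother; children are treated as biological
    children of both present parents.  Single-parent and children-only
    families are permitted (relationship rules extend unchanged).
    """

    family_id: str
    members: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise PedigreeError(f"family {self.family_id!r} has no members")
        for m in self.members:
            if m.family_id != self.family_id:
                raise PedigreeError(
                    f"individual {m.individual_id!r} has family_id {m.family_id!r},"
                    f" expected {self.family_id!r}"
                )
        n_father = sum(1 for m in self.members if m.role == "father")
        n_mother = sum(1 for m in self.members if m.role == "mother")
        if n_father > 1 or n_mother > 1:
            raise PedigreeError(
                f"family {self.family_id!r} has {n_father} fathers / {n_mother} mothers"
            )
        locs = {m.location_id for m in self.members}
        if len(locs) > 1:
            raise PedigreeError(
                f"family {self.family_id!r} spans multiple locations {sorted(locs)}"
            )
        # canonical ordering: father, mother, children by birth year (id tie-break)
        self.members = sorted(
            self.members,
            key=lambda m: (_ROLE_SORT[m.role], m.birth_year, m.individual_id),
        )

    @property
    def parents(self) -> list[Individual]:
        return [m for m in self.members if m.role != "child"]

    @property
    def children(self) -> list[Individual]:
        return [m for m in self.members if m.role == "child"]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def location_id(self) -> str:
        return self.members[0].location_id

    @property
    def signature(self) -> tuple[int, int]:
        """(number of parents, number of children) — determines all
        within-family covariance patterns under canonical ordering."""
        return (len(self.parents), len(self.children))


class Cohort:
    """Ordered collection of families with flat index arrays.

    Individuals appear in family order and, within a family, in canonical
    order; all phenotype/covariate vectors must follow this ordering.
    """

    def __init__(self, families: Sequence[Family]):
        if not families:
            raise PedigreeError("cohort has no families")
        self.families: list[Family] = list(families)
        seen: set[str] = set()
        fam_ids = set()
        for fam in self.families:
            if fam.family_id in fam_ids:
                raise PedigreeError(f"duplicate family_id {fam.family_id!r}")
            fam_ids.add(fam.family_id)
            for m in fam.members:
                if m.individual_id in seen:
                    raise PedigreeError(f"duplicate individual_id {m.individual_id!r}")
                seen.add(m.individual_id)
        self.n_individuals: int = sum(f.size for f in self.families)
        self.n_families: int = len(self.families)
        # flat arrays in cohort order
        self.individual_ids = np.array(
            [m.individual_id for f in self.families for m in f.members]
        )
        self.family_index = np.repeat(
            np.arange(self.n_families), [f.size for f in self.families]
        )
        self.roles = np.array([m.role for f in self.families for m in f.members])
        self.sex = np.array([m.sex for f in self.families for m in f.members])
        self.birth_year = np.array(
            [m.birth_year for f in self.families for m in f.members], dtype=int
        )
        self.months_enrolled = np.array(
            [m.months_enrolled for f in self.families for m in f.members], dtype=int
        )
        self.location_ids = np.array(
            [m.location_id for f in self.families for m in f.members]
        )
        self.family_location = np.array([f.location_id for f in self.families])

    @property
    def N(self) -> int:
        return self.n_individuals

    def location_indicator(self, locations: Sequence[str]) -> sparse.csr_matrix:
        """N x L indicator Z_s mapping individuals to locations (given order)."""
        loc_index = {loc: i for i, loc in enumerate(locations)}
        try:
            cols = np.array([loc_index[l] for l in self.location_ids])
        except KeyError as exc:
            raise PedigreeError(f"cohort location {exc.args[0]!r} not in graph") from exc
        N, L = self.n_individuals, len(locations)
        return sparse.csr_matrix(
            (np.ones(N), (np.arange(N), cols)), shape=(N, L)
        )

    def family_location_index(self, locations: Sequence[str]) -> np.ndarray:
        loc_index = {loc: i for i, loc in enumerate(locations)}
        try:
            return np.array([loc_index[l] for l in self.family_location])
        except KeyError as exc:
            raise PedigreeError(f"cohort location {exc.args[0]!r} not in graph") from exc

    def iter_members(self) -> Iterable[Individual]:
        for fam in self.families:
            yield from fam.members


def kinship_matrix(family: Family) -> np.ndarray:
    """Expected additive relationship matrix of a nuclear family.

    Under canonical ordering: diagonal 1, spouse pairs 0, all parent-child
    and full-sibling pairs 0.5.  For a quad family this is

        [[1, 0, .5, .5],
         [0, 1, .5, .5],
         [.5, .5, 1, .5],
         [.5, .5, .5, 1]]
    """
    return kinship_from_signature(*family.signature)


def kinship_from_signature(n_parents: int, n_children: int) -> np.ndarray:
    k = n_parents + n_children
    if k == 0:
        raise PedigreeError("empty family")
    G = np.full((k, k), 0.5)
    G[:n_parents, :n_parents] = 0.0
    np.fill_diagonal(G, 1.0)
    return G


def family_env_blocks(n_parents: int, n_children: int) -> tuple[np.ndarray, np.ndarray]:
    """Within-family contribution patterns Z_par,f Z_par,f^T and
    Z_child,f Z_child,f^T for one family (canonical order)."""
    k = n_parents + n_children
    P_par = np.eye(k)
    P_par[:n_parents, :n_parents] = 1.0  # both parents share one effect
    P_child = np.eye(k)
    P_child[n_parents:, n_parents:] = 1.0  # all children share one effect
    return P_par, P_child


def family_env_design(cohort: Cohort) -> tuple[sparse.csr_matrix, sparse.csr_matrix]:
    """Sparse 0/1 design matrices (Z_par, Z_child) for the within-family
    environmental random effects.

    In Z_par both parents of a family load on one shared column and each
    child gets its own column; in Z_child all children share one column and
    each parent gets its own.  Every row has exactly one 1.
    """
    rows_par, cols_par = [], []
    rows_child, cols_child = [], []
    next_par = 0
    next_child = 0
    row = 0
    for fam in cohort.families:
        n_p, n_c = fam.signature
        # parent-environment columns: one shared (if parents), one per child
        shared_par = next_par if n_p > 0 else None
        next_par += (1 if n_p > 0 else 0)
        child_par_cols = list(range(next_par, next_par + n_c))
        next_par += n_c
        # child-environment columns: one per parent, one shared (if children)
        par_child_cols = list(range(next_child, next_child + n_p))
        next_child += n_p
        shared_child = next_child if n_c > 0 else None
        next_child += (1 if n_c > 0 else 0)
        for j, m in enumerate(fam.members):
            if m.role != "child":
                rows_par.append(row)
                cols_par.append(shared_par)
                rows_child.append(row)
                cols_child.append(par_child_cols[j])
            else:
                rows_par.append(row)
                cols_par.append(child_par_cols[j - n_p])
                rows_child.append(row)
                cols_child.append(shared_child)
            row += 1
    N = cohort.n_individuals
    Z_par = sparse.csr_matrix(
        (np.ones(N), (rows_par, cols_par)), shape=(N, next_par)
    )
    Z_child = sparse.csr_matrix(
        (np.ones(N), (rows_child, cols_child)), shape=(N, next_child)
    )
    return Z_par, Z_child


def genetic_covariance(cohort: Cohort) -> sparse.csr_matrix:
    """Block-diagonal expected relationship matrix over the whole cohort."""
    blocks = [kinship_matrix(f) for f in cohort.families]
    return sparse.block_diag(blocks, format="csr")
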