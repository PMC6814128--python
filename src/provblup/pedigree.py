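"""Pedigrees with contemporary genetic groups.

A pedigree is a list of :class:`PedigreeRecord`.  Unknown parents are the
empty string (``UNKNOWN``); a record may carry a provenance label naming the
geographic population its founders were collected from.  Under a
:class:`GroupScheme` every unknown parent slot is replaced by a *phantom
genetic group*: either the provenance group of the individual (scheme
``gc2`` on both sides, ``gc1`` on the maternal side) or a single pollen
group shared by all provenances (``gc1`` paternal side).  Groups stand in
for the mean of the unknown ancestors of a defined origin; they are
statistical devices, not genetic individuals, so they contribute no
Mendelian-sampling variance and never acquire inbreeding.

The module builds the average numerator relationship matrix ``A`` by the
tabular method (dense, used as an oracle and for moderate problems) and the
sparse inverse of the group-augmented relationship structure in the
phantom-parent (Quaas/Westell) tradition: each individual contributes the
outer product of its Mendelian-residual coefficients — ``1`` on itself,
``-1/2`` on each filled parent slot, group slots included — scaled by the
inverse Mendelian-sampling variance of the *real* pedigree.  Group
equations receive no own-founder contribution, so group effects act as
unpenalised (fixed-like) effects absorbed into breeding values.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = ""

#: input encodings of an unknown parent / missing provenance
_MISSING_TOKENS = {"", "0", "na", "nan", "none", "unknown"}


class PedigreeError(ValueError):
    """Invalid pedigree content (duplicates, cycles, bad parentage)."""


class PedigreeFormatError(PedigreeError):
    """Malformed pedigree file (missing columns and the like)."""


class GroupAssignmentError(PedigreeError):
    """A founder cannot be assigned to a genetic group."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual with its dam, sire and provenance of origin."""

    individual: str
    dam: str = UNKNOWN
    sire: str = UNKNOWN
    provenance: str = ""

    def __post_init__(self):
        if self.individual in _MISSING_TOKENS:
            raise PedigreeError("individual identifier is missing/empty")
        if self.individual in (self.dam, self.sire):
            raise PedigreeError(f"individual {self.individual!r} listed as its own parent")


@dataclass(frozen=True)
class GroupScheme:
    """Assignment of unknown-parent slots to contemporary genetic groups.

    mode ``"none"`` leaves unknown parents unknown; ``"gc2"`` sends both
    unknown slots of an individual from provenance ``p`` to that
    provenance's group; ``"gc1"`` sends unknown dams to the provenance
    group and every unknown sire to a single phantom pollen group shared
    across provenances.
    """

    mode: str = "none"
    provenance_groups: dict = field(default_factory=dict)
    pollen_group: str | None = None

    def __post_init__(self):
        if self.mode not in ("none", "gc1", "gc2"):
            raise ValueError(f"unknown group scheme mode {self.mode!r}")
        if self.mode == "gc1":
            if not self.pollen_group:
                raise ValueError("gc1 requires a pollen group")
            if self.pollen_group in set(self.provenance_groups.values()):
                raise ValueError("the pollen group must be distinct from all provenance groups")
        if self.mode == "gc2" and self.pollen_group is not None:
            raise ValueError("gc2 does not use a pollen group")

    @classmethod
    def for_provenances(cls, provenances, mode: str) -> "GroupScheme":
        """Build a scheme with one group per provenance (plus a pollen group for gc1)."""
        provs = sorted({p for p in provenances if p})
        if mode == "none":
            return cls(mode="none")
        groups = {p: f"GRP_{p}" for p in provs}
        pollen = "GRP_POLLEN" if mode == "gc1" else None
        return cls(mode=mode, provenance_groups=groups, pollen_group=pollen)

    @property
    def group_ids(self) -> list:
        ids = sorted(set(self.provenance_groups.values()))
        if self.pollen_group:
            ids.append(self.pollen_group)
        return ids


@dataclass
class AugmentedPedigree:
    """Sorted pedigree whose unknown slots point at genetic-group rows.

    ``groups`` occupy the first index block, followed by individuals in
    topological order.  ``inbreeding`` holds F per individual (groups carry
    none).  ``log_det_A`` is ``log|A|`` of the real-individual relationship
    matrix (groups treated as unknown founders), accumulated from the
    Mendelian-sampling variances during construction.
    """

    groups: list
    records: list  # PedigreeRecord with group ids allowed in parent slots
    scheme: GroupScheme
    inbreeding: np.ndarray

    def __post_init__(self):
        self._group_index = {g: k for k, g in enumerate(self.groups)}
        self._ind_index = {r.individual: k for k, r in enumerate(self.records)}

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_individuals(self) -> int:
        return len(self.records)

    @property
    def individuals(self) -> list:
        return [r.individual for r in self.records]

    def index_of(self, individual: str) -> int:
        """Index of a real individual within the individual block."""
        return self._ind_index[individual]

    def equation_index(self, identifier: str) -> int:
        """Index in the (groups + individuals) equation ordering."""
        if identifier in self._group_index:
            return self._group_index[identifier]
        return self.n_groups + self._ind_index[identifier]

    def is_group(self, identifier: str) -> bool:
        return identifier in self._group_index

    def parent_indices(self, k: int) -> tuple:
        """Equation indices of the two parent slots of individual ``k`` (-1 if unknown)."""
        rec = self.records[k]
        out = []
        for slot in (rec.dam, rec.sire):
            if slot == UNKNOWN:
                out.append(-1)
            else:
                out.append(self.equation_index(slot))
        return tuple(out)


def _clean(token) -> str:
    if token is None:
        return UNKNOWN
    s = str(token).strip()
    return UNKNOWN if s.lower() in _MISSING_TOKENS else s


def read_pedigree(path) -> list:
    """Read a delimited pedigree file into records.

    The file must have a header with columns ``individual,dam,sire,provenance``
    (comma- or tab-delimited; an optional ``role`` column from
    :func:`write_pedigree` round-trips).  Unknown parents are encoded as the
    empty string or ``"0"``.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if sample.split("\n", 1)[0].count("\t") else ","
        reader = csv.DictReader(fh, delimiter=delim)
        cols = [c.strip().lower() for c in (reader.fieldnames or [])]
        required = {"individual", "dam", "sire", "provenance"}
        if not required.issubset(cols):
            raise PedigreeFormatError(
                f"pedigree file needs columns {sorted(required)}, found {cols}"
            )
        records = []
        seen = set()
        for row in reader:
            row = {k.strip().lower(): v for k, v in row.items() if k}
            ind = _clean(row.get("individual"))
            if not ind:
                continue
            if ind in seen:
                raise PedigreeError(f"duplicate individual {ind!r} in pedigree file")
            seen.add(ind)
            records.append(
                PedigreeRecord(
                    individual=ind,
                    dam=_clean(row.get("dam")),
                    sire=_clean(row.get("sire")),
                    provenance=_clean(row.get("provenance")),
                )
            )
    return records


def write_pedigree(aug: AugmentedPedigree, path) -> None:
    """Write an augmented pedigree with a ``role`` column (group / individual)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["individual", "dam", "sire", "provenance", "role"])
        for g in aug.groups:
            w.writerow([g, "", "", "", "group"])
        for rec in aug.records:
            w.writerow([rec.individual, rec.dam, rec.sire, rec.provenance, "individual"])


def sort_and_validate(records) -> list:
    """Topologically sort records so parents precede offspring.

    Parents referenced but never declared are inserted as founders with no
    provenance.  Duplicate individuals and parentage cycles raise
    :class:`PedigreeError`; the cycle error names one individual on the
    cycle.  Already-sorted input comes back in the same order.
    """
    by_id = {}
    for rec in records:
        if rec.individual in by_id:
            raise PedigreeError(f"duplicate individual {rec.individual!r}")
        by_id[rec.individual] = rec

    order_hint = {rec.individual: k for k, rec in enumerate(records)}
    implicit = []
    for rec in records:
        for parent in (rec.dam, rec.sire):
            if parent != UNKNOWN and parent not in by_id:
                founder = PedigreeRecord(individual=parent)
                by_id[parent] = founder
                implicit.append(parent)
    # undeclared parents sort ahead of everything, in first-reference order
    for k, ind in enumerate(implicit):
        order_hint[ind] = -len(implicit) + k

    children = {i: [] for i in by_id}
    n_parents = {}
    for ind, rec in by_id.items():
        parents = [p for p in (rec.dam, rec.sire) if p != UNKNOWN]
        n_parents[ind] = len(parents)
        for p in parents:
            children[p].append(ind)

    import heapq

    ready = [(order_hint[i], i) for i, np_ in n_parents.items() if np_ == 0]
    heapq.heapify(ready)
    out = []
    while ready:
        _, ind = heapq.heappop(ready)
        out.append(by_id[ind])
        for child in children[ind]:
            n_parents[child] -= 1
            if n_parents[child] == 0:
                heapq.heappush(ready, (order_hint[child], child))
    if len(out) != len(by_id):
        stuck = sorted(set(by_id) - {r.individual for r in out})[0]
        raise PedigreeError(f"parentage cycle detected involving {stuck!r}")
    return out


def augment_with_groups(records, scheme: GroupScheme, ungrouped: str = "error") -> AugmentedPedigree:
    """Replace unknown parent slots by genetic-group identifiers.

    ``gc2``: both unknown slots of an individual from provenance ``p`` point
    to ``provenance_groups[p]``.  ``gc1``: unknown dams point to the
    provenance group, unknown sires to the pollen group.  ``mode="none"``
    passes the pedigree through unchanged (still sorted, with inbreeding).

    ``ungrouped`` controls individuals with unknown parents but no
    provenance label under an active scheme: ``"error"`` (default) raises
    :class:`GroupAssignmentError`; ``"founder"`` leaves their slots unknown
    (the convention used for control lots, which are handled by a fixed
    term instead).
    """
    recs = sort_and_validate(records)
    groups = list(scheme.group_ids) if scheme.mode != "none" else []
    gset = set(groups)
    for rec in recs:
        if rec.individual in gset:
            raise PedigreeError(
                f"group id {rec.individual!r} collides with an individual id"
            )

    if scheme.mode != "none":
        out = []
        for rec in recs:
            dam, sire = rec.dam, rec.sire
            if UNKNOWN in (dam, sire):
                if rec.provenance:
                    try:
                        prov_grp = scheme.provenance_groups[rec.provenance]
                    except KeyError:
                        raise GroupAssignmentError(
                            f"provenance {rec.provenance!r} of {rec.individual!r} "
                            "has no genetic group"
                        ) from None
                    if dam == UNKNOWN:
                        dam = prov_grp
                    if sire == UNKNOWN:
                        sire = scheme.pollen_group if scheme.mode == "gc1" else prov_grp
                elif ungrouped == "error":
                    raise GroupAssignmentError(
                        f"founder {rec.individual!r} has no provenance label; "
                        "cannot assign genetic groups"
                    )
            out.append(replace(rec, dam=dam, sire=sire))
        recs = out

    aug = AugmentedPedigree(groups=groups, records=recs, scheme=scheme, inbreeding=np.zeros(len(recs)))
    aug.inbreeding = compute_inbreeding(aug)
    return aug


def compute_inbreeding(aug: AugmentedPedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen–Luo recursion.

    Groups act as unrelated, non-inbred founders: any individual with a
    group (or unknown) parent slot is non-inbred unless both slots are real
    related individuals.
    """
    n = aug.n_individuals
    g = aug.n_groups
    # parent index within the individual block; -1 for unknown or group
    dam = np.full(n, -1, dtype=np.int64)
    sire = np.full(n, -1, dtype=np.int64)
    for k in range(n):
        di, si = aug.parent_indices(k)
        dam[k] = di - g if di >= g else -1
        sire[k] = si - g if si >= g else -1
        if dam[k] == sire[k] and dam[k] >= 0:
            raise PedigreeError(
                f"selfing (dam = sire = {aug.records[k].dam!r}) is not supported"
            )

    import heapq

    # F_i via a virtual progeny v of (dam_i, sire_i):
    # 1 + F_i = a_vv = sum_j L_v(j)^2 D_j over v and its ancestors, where
    # L_v are gene-flow coefficients and D_j Mendelian-sampling variances
    # (Meuwissen & Luo 1992).
    F = np.zeros(n)
    D = np.ones(n)  # filled in pedigree order; parents precede offspring
    for i in range(n):
        for p in (dam[i], sire[i]):
            if p >= 0:
                D[i] -= 0.25 * (1.0 + F[p])
        if dam[i] < 0 or sire[i] < 0:
            continue
        acc = 0.5 - 0.25 * (F[dam[i]] + F[sire[i]])  # D_v, L_v(v) = 1
        w = {dam[i]: 0.5, sire[i]: 0.5}
        heap = [-dam[i], -sire[i]]
        heapq.heapify(heap)
        while heap:
            j = -heapq.heappop(heap)
            if j not in w:
                continue
            lw = w.pop(j)
            acc += lw * lw * D[j]
            for p in (dam[j], sire[j]):
                if p >= 0:
                    if p not in w:
                        w[p] = 0.0
                        heapq.heappush(heap, -p)
                    w[p] += 0.5 * lw
        F[i] = max(acc - 1.0, 0.0)
    return F


def _mendelian_variance(aug: AugmentedPedigree, k: int) -> float:
    """Mendelian-sampling variance d_i of individual ``k``.

    Counts real parents only: group (and unknown) slots contribute no
    variance reduction, so d_i is that of the base pedigree with unknown
    parents as founders.
    """
    g = aug.n_groups
    F = aug.inbreeding
    d = 1.0
    for pi in aug.parent_indices(k):
        if pi >= g:
            d -= 0.25 * (1.0 + F[pi - g])
    return d


def log_det_A(aug: AugmentedPedigree) -> float:
    """log-determinant of the real-individual A (groups as unknown founders)."""
    return float(sum(np.log(_mendelian_variance(aug, k)) for k in range(aug.n_individuals)))


def build_A_tabular(aug: AugmentedPedigree) -> pd.DataFrame:
    """Average numerator relationship matrix by the recursive tabular method.

    Returned over real individuals only; group parents are treated as
    unknown founders, so the result is the classical A of the base
    pedigree.  Dense — intended for oracles and small problems.
    """
    n = aug.n_individuals
    g = aug.n_groups
    A = np.zeros((n, n))
    parents = []
    for k in range(n):
        di, si = aug.parent_indices(k)
        parents.append((di - g if di >= g else -1, si - g if si >= g else -1))
    for i in range(n):
        d, s = parents[i]
        if d >= 0 and s >= 0:
            A[i, i] = 1.0 + 0.5 * A[d, s]
        else:
            A[i, i] = 1.0
        for j in range(i):
            a = 0.0
            if d >= 0:
                a += 0.5 * A[j, d]
            if s >= 0:
                a += 0.5 * A[j, s]
            A[i, j] = A[j, i] = a
    ids = aug.individuals
    return pd.DataFrame(A, index=ids, columns=ids)


def build_Ainv_with_groups(aug: AugmentedPedigree, include_groups: bool = True) -> sp.csr_matrix:
    """Sparse inverse relationship structure over (groups + individuals).

    Quaas-style phantom-parent assembly: for each individual the outer
    product of its Mendelian-residual coefficients — ``1`` on itself and
    ``-1/2`` on every filled parent slot (real individual or group) —
    scaled by ``delta_i = 1/d_i``.  The Mendelian-sampling variance ``d_i``
    counts *real* parents only (``d_i = 1 - 0.25 (1+F) per real parent``):
    a genetic group carries the mean of the unknown ancestors but none of
    their variance, so pointing a slot at a group does not reduce ``d_i``.
    Group equations receive no own-founder term.

    The resulting matrix equals ``[[Q' A^{-1} Q, -Q' A^{-1}], [-A^{-1} Q,
    A^{-1}]]`` with ``A`` the real-individual relationship matrix (unknown
    parents as founders) and ``Q`` the group-fraction matrix, which is what
    makes the group-augmented mixed-model equations an exact rewriting of
    the model with explicit group covariates.  With
    ``include_groups=False`` (or a group-free pedigree) it is the ordinary
    Henderson A-inverse with inbreeding.
    """
    g = aug.n_groups if include_groups else 0
    n = aug.n_individuals
    rows, cols, vals = [], [], []
    for k in range(n):
        pis = []
        for pi in aug.parent_indices(k):
            if pi < 0:
                continue
            if pi < aug.n_groups and not include_groups:
                continue
            pis.append(pi if include_groups else pi - aug.n_groups)
        delta = 1.0 / _mendelian_variance(aug, k)
        idx = [g + k] + pis
        coef = [1.0] + [-0.5] * len(pis)
        for a, ca in zip(idx, coef):
            for b, cb in zip(idx, coef):
                rows.append(a)
                cols.append(b)
                vals.append(delta * ca * cb)
    return sp.csr_matrix((vals, (rows, cols)), shape=(g + n, g + n))


def build_group_fractions(aug: AugmentedPedigree) -> pd.DataFrame:
    """Expected ancestry fraction of each individual tracing to each group.

    ``row(i) = 0.5 row(dam) + 0.5 row(sire)``, a group's row being its unit
    vector and an unknown slot contributing nothing.  With an active scheme
    every row of a group-assigned individual sums to one; individuals kept
    out of group assignment (controls) have all-zero rows.
    """
    g = aug.n_groups
    n = aug.n_individuals
    Q = np.zeros((n, g))
    for k in range(n):
        for pi in aug.parent_indices(k):
            if pi < 0:
                continue
            if pi < g:
                Q[k, pi] += 0.5
            else:
                Q[k] += 0.5 * Q[pi - g]
    return pd.DataFrame(Q, index=aug.individuals, columns=list(aug.groups))
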