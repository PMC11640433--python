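"""Dyadic association rates: the simple ratio index (SRI).

For an unordered pair (a, b) over the sampling periods of a GBI:

    SRI = x / (x + ya + yb + yab)

where x counts periods in which a and b were observed associated (same
observed party), ya / yb count periods with only a / only b identified,
and yab counts periods with both identified but in different parties.
Periods in which neither was identified (yNull) are assumed
uninformative and dropped from the denominator.  Under single-focal
sampling every period holds one party, so yab is structurally zero.

A pair never identified in any period has an empty denominator; its
index is defined as 0 (no evidence of association) and flagged.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .observation import GroupByIndividualMatrix, ValidationError


@dataclasses.dataclass(frozen=True)
class DyadCounts:
    """Per-period classification counts for one unordered dyad."""

    a: str
    b: str
    x: int
    ya: int
    yb: int
    yab: int
    y_null: int = 0

    def __post_init__(self) -> None:
        if min(self.x, self.ya, self.yb, self.yab, self.y_null) < 0:
            raise ValidationError(f"dyad ({self.a}, {self.b}): negative counts")

    @property
    def denominator(self) -> int:
        return self.x + self.ya + self.yb + self.yab

    def swapped(self) -> "DyadCounts":
        return DyadCounts(self.b, self.a, self.x, self.yb, self.ya, self.yab, self.y_null)


class AssociationMatrix:
    """Symmetric matrix of SRI values over a roster; diagonal masked as 0."""

    def __init__(
        self,
        values: np.ndarray,
        ids: Sequence[str],
        species: dict[str, str] | None = None,
        never_identified: Sequence[tuple[str, str]] = (),
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (len(ids), len(ids)):
            raise ValidationError("association matrix shape does not match ids")
        if not np.allclose(values, values.T, atol=0):
            raise ValidationError("association matrix must be exactly symmetric")
        if values.size and (values.min() < 0 or values.max() > 1):
            raise ValidationError("SRI values must lie in [0, 1]")
        self.values = values
        self.ids = list(ids)
        self.species = species
        self.never_identified = list(never_identified)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, float_format="%.17g")

    def dyads(self) -> list[tuple[str, str, float]]:
        """All unordered dyads with their SRI, in id order."""
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                out.append((self.ids[i], self.ids[j], self.values[i, j]))
        return out


def sri(counts: DyadCounts) -> float:
    """Evaluate the simple ratio index for one dyad; 0 if never identified."""
    if counts.denominator == 0:
        return 0.0
    return counts.x / counts.denominator


def dyad_counts(gbi: GroupByIndividualMatrix) -> dict[tuple[str, str], DyadCounts]:
    """Classify every period for every unordered dyad.

    ``associated`` means both individuals belong to the same observed
    party of the period; with the default one-party-per-row GBI this is
    simply "both identified in the row".
    """
    if gbi.n_periods < 1:
        raise ValidationError("dyad counts need at least one period")
    ids = gbi.ids
    n = gbi.n_individuals
    if gbi.row_parties is None:
        m = gbi.matrix.astype(np.int64)
        x = m.T @ m                      # co-identified == co-associated
        ident = m.sum(axis=0)            # periods identified, per individual
        counts = {}
        for i in range(n):
            for j in range(i + 1, n):
                xij = int(x[i, j])
                counts[(ids[i], ids[j])] = DyadCounts(
                    ids[i], ids[j],
                    x=xij,
                    ya=int(ident[i]) - xij,
                    yb=int(ident[j]) - xij,
                    yab=0,
                    y_null=gbi.n_periods - int(ident[i]) - int(ident[j]) + xij,
                )
        return counts
    return _dyad_counts_with_parties(gbi)


def _dyad_counts_with_parties(
    gbi: GroupByIndividualMatrix,
) -> dict[tuple[str, str], DyadCounts]:
    ids = gbi.ids
    n = gbi.n_individuals
    x = np.zeros((n, n), dtype=np.int64)
    yab = np.zeros((n, n), dtype=np.int64)
    ident = np.zeros(n, dtype=np.int64)
    col = {ident_: k for k, ident_ in enumerate(ids)}
    for row, parties in zip(gbi.matrix, gbi.row_parties):
        present = np.flatnonzero(row)
        ident[present] += 1
        party_of = {}
        for p_idx, party in enumerate(parties):
            for member in party:
                party_of[col[member]] = p_idx
        for ai in range(len(present)):
            for bi in range(ai + 1, len(present)):
                i, j = present[ai], present[bi]
                if party_of.get(i) == party_of.get(j):
                    x[i, j] += 1
                else:
                    yab[i, j] += 1
    counts = {}
    for i in range(n):
        for j in range(i + 1, n):
            xij, yabij = int(x[i, j]), int(yab[i, j])
            both = xij + yabij
            counts[(ids[i], ids[j])] = DyadCounts(
                ids[i], ids[j],
                x=xij,
                ya=int(ident[i]) - both,
                yb=int(ident[j]) - both,
                yab=yabij,
                y_null=gbi.n_periods - int(ident[i]) - int(ident[j]) + both,
            )
    return counts


def association_matrix(
    gbi: GroupByIndividualMatrix, warn_never_identified: bool = False
) -> AssociationMatrix:
    """Apply the SRI to every unordered pair of a GBI."""
    ids = gbi.ids
    n = gbi.n_individuals
    never: list[tuple[str, str]] = []
    values = np.zeros((n, n), dtype=float)
    if gbi.row_parties is None:
        m = gbi.matrix.astype(np.int64)
        x = (m.T @ m).astype(float)
        ident = m.sum(axis=0).astype(float)
        denom = ident[:, None] + ident[None, :] - x
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(denom > 0, x / np.where(denom > 0, denom, 1.0), 0.0)
        np.fill_diagonal(values, 0.0)
        if (denom == 0).any():
            ii, jj = np.nonzero(np.triu(denom == 0, k=1))
            never = [(ids[i], ids[j]) for i, j in zip(ii, jj)]
    else:
        counts = dyad_counts(gbi)
        for (a, b), c in counts.items():
            i, j = ids.index(a), ids.index(b)
            values[i, j] = values[j, i] = sri(c)
            if c.denominator == 0:
                never.append((a, b))
    if never and warn_never_identified:
        warnings.warn(f"{len(never)} dyads never identified; SRI set to 0")
    species = gbi.species_of() if gbi.roster is not None else None
    return AssociationMatrix(values, ids, species=species, never_identified=never)


DyadFilter = Callable[[str, str], bool]


def within_species(sa: str, sb: str) -> bool:
    return sa == sb


def mixed_species(sa: str, sb: str) -> bool:
    return sa != sb


def mean_association_rate(
    matrix: AssociationMatrix,
    dyad_filter: DyadFilter | None = None,
    species: dict[str, str] | None = None,
) -> tuple[float, float]:
    """Mean and sample SD of SRI over (optionally filtered) unordered dyads.

    Zero-valued dyads are included; the SD uses the n-1 denominator
    (0 for a single dyad).  Filtering requires a species mapping, taken
    from the matrix when it carries one.
    """
    species = species or matrix.species
    selected = []
    for a, b, value in matrix.dyads():
        if dyad_filter is not None:
            if species is None:
                raise ValidationError("dyad filtering needs a species mapping")
            if not dyad_filter(species[a], species[b]):
                continue
        selected.append(value)
    if not selected:
        raise ValidationError("no dyads selected for the mean association rate")
    arr = np.asarray(selected, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd
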