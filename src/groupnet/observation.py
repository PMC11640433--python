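"""Reading and validating observation data.

Focal point-sampling data arrive as two CSV tables: a roster of
individuals (id, species, sex, group, optional age) and a log of
instantaneous point samples.  Two point-sample dialects are accepted:

* **long** (canonical): one row per (period, individual) with a ``role``
  column that is ``focal`` or ``neighbor``;
* **wide**: one row per period with columns ``period_id``, ``focal_id``
  and ``neighbor_ids`` (``;``-delimited, empty for a solitary focal).

Each point sample becomes one sampling period.  Under the gambit of the
group, the focal and every recorded neighbor are treated as one
associating party, giving one row of the group-by-individual (GBI)
matrix.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not have the expected layout (columns, dialect)."""


class ValidationError(ValueError):
    """Contents are well-formed but violate a data invariant."""


@dataclasses.dataclass(frozen=True)
class IndividualRecord:
    """One individual in a study roster."""

    id: str
    species: str
    sex: str
    group: str
    age: float | None = None

    def __post_init__(self) -> None:
        if not self.species or not self.group:
            raise ValidationError(
                f"individual {self.id!r}: species and group labels must be non-empty"
            )


@dataclasses.dataclass(frozen=True)
class PointSample:
    """One instantaneous point sample: a focal and its proximity neighbors.

    An empty neighbor set records a solitary focal.
    """

    period_id: str
    focal_id: str
    neighbor_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.focal_id in self.neighbor_ids:
            raise ValidationError(
                f"period {self.period_id!r}: focal {self.focal_id!r} "
                "listed among its own neighbors"
            )

    @property
    def party(self) -> frozenset[str]:
        """All individuals observed together in this period (focal included)."""
        return self.neighbor_ids | {self.focal_id}


class GroupByIndividualMatrix:
    """Binary periods x individuals occurrence matrix.

    Row order follows first appearance of each period in the input;
    column order follows the roster.  Entry (p, i) is 1 when individual
    *i* was part of the observed party of period *p*.  An optional
    per-row partition of the identified individuals into distinct
    observed parties supports multi-party periods; by default every row
    is a single party (single-focal sampling).
    """

    def __init__(
        self,
        matrix: np.ndarray,
        period_ids: Sequence[str],
        ids: Sequence[str],
        roster: Sequence[IndividualRecord] | None = None,
        row_parties: Sequence[Sequence[frozenset[str]]] | None = None,
    ) -> None:
        matrix = np.asarray(matrix, dtype=np.int8)
        if matrix.ndim != 2:
            raise ValidationError("GBI matrix must be 2-D")
        if matrix.shape != (len(period_ids), len(ids)):
            raise ValidationError("GBI matrix shape does not match labels")
        if matrix.size and not np.isin(matrix, (0, 1)).all():
            raise ValidationError("GBI entries must be 0/1")
        if matrix.size and (matrix.sum(axis=1) == 0).any():
            raise ValidationError("every GBI row must contain at least one individual")
        self.matrix = matrix
        self.period_ids = list(period_ids)
        self.ids = list(ids)
        self.roster = list(roster) if roster is not None else None
        self.row_parties = list(row_parties) if row_parties is not None else None

    @property
    def n_periods(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[1]

    def row_sums(self) -> np.ndarray:
        """Observed party size per period."""
        return self.matrix.sum(axis=1)

    def column_sums(self) -> np.ndarray:
        """Number of periods each individual was identified in."""
        return self.matrix.sum(axis=0)

    def species_of(self) -> dict[str, str]:
        if self.roster is None:
            raise ValidationError("GBI carries no roster")
        return {r.id: r.species for r in self.roster}

    def copy(self) -> "GroupByIndividualMatrix":
        return GroupByIndividualMatrix(
            self.matrix.copy(), self.period_ids, self.ids, self.roster, self.row_parties
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.period_ids, columns=self.ids)


def _clean(value: object) -> str:
    return str(value).strip()


def read_roster(path: str | Path) -> list[IndividualRecord]:
    """Read a roster CSV with columns id, species, sex, group[, age]."""
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    required = {"id", "species", "sex", "group"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"roster {path}: missing columns {sorted(missing)}")
    records = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        ident = _clean(row["id"])
        if ident in seen:
            raise ValidationError(f"roster {path}: duplicate id {ident!r}")
        seen.add(ident)
        age = None
        if "age" in df.columns and pd.notna(row["age"]) and _clean(row["age"]):
            age = float(row["age"])
        records.append(
            IndividualRecord(
                id=ident,
                species=_clean(row["species"]),
                sex=_clean(row["sex"]),
                group=_clean(row["group"]),
                age=age,
            )
        )
    return records


def write_roster(roster: Sequence[IndividualRecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in roster]).to_csv(path, index=False)


def _check_known(ids: Iterable[str], known: set[str], path: object) -> None:
    unknown = sorted(set(ids) - known)
    if unknown:
        raise ValidationError(f"{path}: ids not in roster: {unknown}")


def read_point_samples(
    path: str | Path, roster: Sequence[IndividualRecord]
) -> list[PointSample]:
    """Read point samples in either the long or the wide CSV dialect.

    Solitary focals (no neighbor rows / empty neighbor list) are kept as
    singleton parties.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True, keep_default_na=False)
    known = {r.id for r in roster}
    cols = set(df.columns)
    if {"period_id", "individual_id", "role"} <= cols:
        return _parse_long(df, known, path)
    if {"period_id", "focal_id", "neighbor_ids"} <= cols:
        return _parse_wide(df, known, path)
    raise FormatError(
        f"{path}: expected columns (period_id, individual_id, role) or "
        "(period_id, focal_id, neighbor_ids)"
    )


def _parse_long(df: pd.DataFrame, known: set[str], path: object) -> list[PointSample]:
    samples: list[PointSample] = []
    order: list[str] = []
    by_period: dict[str, dict[str, set[str] | str | None]] = {}
    seen_rows: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        period = _clean(row["period_id"])
        ident = _clean(row["individual_id"])
        role = _clean(row["role"]).lower()
        _check_known([ident], known, path)
        if (period, ident) in seen_rows:
            raise ValidationError(f"{path}: duplicated row for ({period!r}, {ident!r})")
        seen_rows.add((period, ident))
        if period not in by_period:
            by_period[period] = {"focal": None, "neighbors": set()}
            order.append(period)
        entry = by_period[period]
        if role == "focal":
            if entry["focal"] is not None:
                raise ValidationError(f"{path}: period {period!r} has two focal rows")
            entry["focal"] = ident
        elif role == "neighbor":
            entry["neighbors"].add(ident)  # type: ignore[union-attr]
        else:
            raise FormatError(f"{path}: unknown role {role!r} in period {period!r}")
    for period in order:
        entry = by_period[period]
        if entry["focal"] is None:
            raise ValidationError(f"{path}: period {period!r} has no focal row")
        samples.append(
            PointSample(period, entry["focal"], frozenset(entry["neighbors"]))  # type: ignore[arg-type]
        )
    return samples


def _parse_wide(df: pd.DataFrame, known: set[str], path: object) -> list[PointSample]:
    samples = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        period = _clean(row["period_id"])
        if period in seen:
            raise ValidationError(f"{path}: duplicated period row {period!r}")
        seen.add(period)
        focal = _clean(row["focal_id"])
        raw = _clean(row["neighbor_ids"])
        neighbors = frozenset(n.strip() for n in raw.split(";") if n.strip())
        _check_known([focal, *neighbors], known, path)
        samples.append(PointSample(period, focal, neighbors))
    return samples


def write_point_samples(
    samples: Sequence[PointSample], path: str | Path, dialect: str = "long"
) -> None:
    """Write samples in the long (canonical) or wide CSV dialect."""
    if dialect == "long":
        rows = []
        for s in samples:
            rows.append({"period_id": s.period_id, "individual_id": s.focal_id, "role": "focal"})
            for n in sorted(s.neighbor_ids):
                rows.append({"period_id": s.period_id, "individual_id": n, "role": "neighbor"})
        pd.DataFrame(rows, columns=["period_id", "individual_id", "role"]).to_csv(
            path, index=False
        )
    elif dialect == "wide":
        rows = [
            {
                "period_id": s.period_id,
                "focal_id": s.focal_id,
                "neighbor_ids": ";".join(sorted(s.neighbor_ids)),
            }
            for s in samples
        ]
        pd.DataFrame(rows, columns=["period_id", "focal_id", "neighbor_ids"]).to_csv(
            path, index=False
        )
    else:
        raise FormatError(f"unknown point-sample dialect {dialect!r}")


def build_gbi(
    samples: Sequence[PointSample], roster: Sequence[IndividualRecord]
) -> GroupByIndividualMatrix:
    """Build the group-by-individual matrix, one row per point sample.

    The focal and its neighbors form one associating party (gambit of
    the group).  Columns follow roster order; rows follow input order.
    """
    if not samples:
        raise ValidationError("cannot build a GBI from zero samples")
    ids = [r.id for r in roster]
    col = {ident: j for j, ident in enumerate(ids)}
    _check_known(
        (i for s in samples for i in s.party), set(col), "point samples"
    )
    matrix = np.zeros((len(samples), len(ids)), dtype=np.int8)
    for i, s in enumerate(samples):
        for ident in s.party:
            matrix[i, col[ident]] = 1
    return GroupByIndividualMatrix(
        matrix, [s.period_id for s in samples], ids, roster=roster
    )


# ---------------------------------------------------------------------------
# network serialization

_FORMATS = ("edgelist", "graphml", "adjacency")
_NODE_ATTRS = ("species", "sex", "group")


def _nodes_sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".nodes.csv")


def write_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write an annotated weighted network.

    ``edgelist`` and ``adjacency`` are CSV formats with a ``*.nodes.csv``
    sidecar carrying node attributes (species, sex, group) so that the
    matching reader round-trips losslessly; ``graphml`` is self-contained.
    """
    if net.number_of_nodes() < 1:
        raise ValidationError("cannot write an empty network")
    path = Path(path)
    if format == "graphml":
        clean = net.copy()
        for _, data in clean.nodes(data=True):
            for key in [k for k, v in data.items() if v is None]:
                del data[key]
        nx.write_graphml(clean, path)
    elif format == "edgelist":
        rows = [
            {"source": u, "target": v, "weight": repr(float(d["weight"]))}
            for u, v, d in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(path, index=False)
        _write_node_table(net, _nodes_sidecar(path))
    elif format == "adjacency":
        ids = list(net.nodes)
        mat = nx.to_numpy_array(net, nodelist=ids, weight="weight")
        pd.DataFrame(mat, index=ids, columns=ids).to_csv(path, float_format="%.17g")
        _write_node_table(net, _nodes_sidecar(path))
    else:
        raise FormatError(f"unsupported network format {format!r}; use one of {_FORMATS}")


def _write_node_table(net: nx.Graph, path: Path) -> None:
    rows = []
    for node, data in net.nodes(data=True):
        row = {"id": node}
        row.update({k: data.get(k) for k in _NODE_ATTRS if data.get(k) is not None})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    if format == "graphml":
        net = nx.read_graphml(path)
        return nx.relabel_nodes(net, {n: str(n) for n in net.nodes})
    if format == "edgelist":
        net = nx.Graph()
        _read_node_table(net, _nodes_sidecar(path))
        edges = pd.read_csv(path, dtype={"source": str, "target": str})
        for _, row in edges.iterrows():
            net.add_edge(row["source"], row["target"], weight=float(row["weight"]))
        return net
    if format == "adjacency":
        mat = pd.read_csv(path, index_col=0)
        mat.index = mat.index.astype(str)
        net = nx.Graph()
        _read_node_table(net, _nodes_sidecar(path))
        values = mat.to_numpy()
        ids = list(mat.index)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if values[i, j] > 0:
                    net.add_edge(ids[i], ids[j], weight=float(values[i, j]))
        return net
    raise FormatError(f"unsupported network format {format!r}; use one of {_FORMATS}")


def _read_node_table(net: nx.Graph, path: Path) -> None:
    if not path.exists():
        warnings.warn(f"node table {path} missing; node attributes lost")
        return
    nodes = pd.read_csv(path, dtype=str)
    for _, row in nodes.iterrows():
        attrs = {k: row[k] for k in _NODE_ATTRS if k in nodes.columns and pd.notna(row[k])}
        net.add_node(row["id"], **attrs)


def solitary_count(samples: Sequence[PointSample]) -> int:
    """Number of point samples in which the focal had no neighbors."""
    return sum(1 for s in samples if not s.neighbor_ids)


def roster_by_group(
    roster: Sequence[IndividualRecord],
) -> Mapping[str, list[IndividualRecord]]:
    groups: dict[str, list[IndividualRecord]] = {}
    for rec in roster:
        groups.setdefault(rec.group, []).append(rec)
    return groups
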