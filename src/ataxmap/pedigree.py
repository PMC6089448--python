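"""Pedigree container with structural validation.

Unknown parents are encoded as ``None`` in memory and "0" on disk.
Unknown-parent animals are treated as unrelated, non-inbred founders.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .errors import PedigreeStructureError

UNKNOWN = None


@dataclass(frozen=True)
class PedigreeEntry:
    animal_id: str
    sire_id: str | None
    dam_id: str | None
    sex: str  # "M" or "F"
    birth_cohort: int

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise PedigreeStructureError(
                f"animal {self.animal_id}: sex must be 'M' or 'F', got {self.sex!r}"
            )


class Pedigree:
    """An ordered, validated collection of :class:`PedigreeEntry`.

    Validation enforces: acyclicity, sire recorded as male and dam as
    female whenever the parent itself appears in the pedigree, and no
    self-parenting.
    """

    def __init__(self, entries: list[PedigreeEntry]):
        self.entries = list(entries)
        self.by_id = {e.animal_id: e for e in self.entries}
        if len(self.by_id) != len(self.entries):
            raise PedigreeStructureError("duplicate animal ids in pedigree")
        self._validate()
        self._topo: list[str] | None = None

    def _validate(self) -> None:
        for e in self.entries:
            for pid in (e.sire_id, e.dam_id):
                if pid == e.animal_id:
                    raise PedigreeStructureError(f"animal {e.animal_id} is its own parent")
            sire = self.by_id.get(e.sire_id) if e.sire_id else None
            dam = self.by_id.get(e.dam_id) if e.dam_id else None
            if sire is not None and sire.sex != "M":
                raise PedigreeStructureError(
                    f"sire {sire.animal_id} of {e.animal_id} is not recorded as male"
                )
            if dam is not None and dam.sex != "F":
                raise PedigreeStructureError(
                    f"dam {dam.animal_id} of {e.animal_id} is not recorded as female"
                )
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise PedigreeStructureError(
                f"pedigree contains a cycle involving animal {cycle[0][0]!r}"
            )

    def graph(self) -> nx.DiGraph:
        """Parent -> offspring DAG over animals present in the pedigree."""
        g = nx.DiGraph()
        g.add_nodes_from(self.by_id)
        for e in self.entries:
            for pid in (e.sire_id, e.dam_id):
                if pid is not None and pid in self.by_id:
                    g.add_edge(pid, e.animal_id)
        return g

    def topological_order(self) -> list[str]:
        """Animal ids with every parent preceding its offspring."""
        if self._topo is None:
            order = list(nx.topological_sort(self.graph()))
            # stable: keep original ordering among incomparable animals
            rank = {a: i for i, a in enumerate(self.ids())}
            depth: dict[str, int] = {}
            for a in order:
                e = self.by_id[a]
                d = 0
                for pid in (e.sire_id, e.dam_id):
                    if pid in self.by_id:
                        d = max(d, depth[pid] + 1)
                depth[a] = d
            self._topo = sorted(self.by_id, key=lambda a: (depth[a], rank[a]))
        return self._topo

    def ids(self) -> list[str]:
        return [e.animal_id for e in self.entries]

    def founders(self) -> list[str]:
        return [
            e.animal_id
            for e in self.entries
            if (e.sire_id is None or e.sire_id not in self.by_id)
            and (e.dam_id is None or e.dam_id not in self.by_id)
        ]

    def parents(self, animal_id: str) -> tuple[str | None, str | None]:
        e = self.by_id[animal_id]
        sire = e.sire_id if e.sire_id in self.by_id else None
        dam = e.dam_id if e.dam_id in self.by_id else None
        return sire, dam

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)
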