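"""Signed directed network model: typed nodes plus (source, target, type) edges.

An edge carries a sign code: ``"P"`` for phosphorylation, ``"D"`` for
dephosphorylation.  Node roles are ``"kinase"``, ``"phosphatase"`` or
``"other"``; only enzymes (kinases and phosphatases) may be edge sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ValidationError

logger = logging.getLogger(__name__)

EDGE_TYPES = frozenset({"P", "D"})
ENZYME_ROLES = frozenset({"kinase", "phosphatase"})
ROLES = ENZYME_ROLES | {"other"}


@dataclass(frozen=True, order=True)
class Edge:
    """A signed directed interaction."""

    source: str
    target: str
    itype: str

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValidationError("edge endpoints must be non-empty identifiers")
        if self.itype not in EDGE_TYPES:
            raise ValidationError(
                f"interaction type must be one of {sorted(EDGE_TYPES)}, got {self.itype!r}"
            )


@dataclass(frozen=True)
class DirectedNetwork:
    """Immutable signed directed network with node roles.

    Parameters
    ----------
    roles
        Mapping from node identifier to role.  Nodes that appear only in
        edges default to role ``"other"``.
    edges
        Unique (source, target, itype) triples.  Duplicates are dropped
        with a warning; an edge whose source has role ``"other"`` raises
        :class:`ValidationError`.
    """

    roles: Mapping[str, str]
    edges: frozenset[Edge] = field(default_factory=frozenset)

    @classmethod
    def build(
        cls,
        edges: Iterable[Edge | tuple[str, str, str]],
        roles: Mapping[str, str] | None = None,
    ) -> "DirectedNetwork":
        roles = dict(roles or {})
        for node, role in roles.items():
            if role not in ROLES:
                raise ValidationError(f"unknown role {role!r} for node {node!r}")
        uniq: set[Edge] = set()
        n_dup = 0
        for e in edges:
            edge = e if isinstance(e, Edge) else Edge(*e)
            if edge in uniq:
                n_dup += 1
            else:
                uniq.add(edge)
        if n_dup:
            logger.warning("dropped %d duplicate edge triple(s)", n_dup)
        for edge in uniq:
            roles.setdefault(edge.source, "other")
            roles.setdefault(edge.target, "other")
        for edge in sorted(uniq):
            if roles[edge.source] not in ENZYME_ROLES:
                raise ValidationError(
                    f"edge source {edge.source!r} has role {roles[edge.source]!r} "
                    f"(edge {edge.source}->{edge.target}:{edge.itype}); "
                    "sources must be kinases or phosphatases"
                )
        return cls(roles=roles, edges=frozenset(uniq))

    # -- basic views -------------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.roles)

    @property
    def enzymes(self) -> frozenset[str]:
        return frozenset(n for n, r in self.roles.items() if r in ENZYME_ROLES)

    @property
    def kinases(self) -> frozenset[str]:
        return frozenset(n for n, r in self.roles.items() if r == "kinase")

    @property
    def phosphatases(self) -> frozenset[str]:
        return frozenset(n for n, r in self.roles.items() if r == "phosphatase")

    @property
    def n_nodes(self) -> int:
        return len(self.roles)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges)

    def replace_edges(self, edges: Iterable[Edge]) -> "DirectedNetwork":
        """New network with the same roles and a different edge set."""
        return DirectedNetwork.build(edges, roles=self.roles)
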