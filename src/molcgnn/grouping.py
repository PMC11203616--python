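"""Atom-species grouping for heterogeneous molecular graphs.

Molecular datasets contain dozens of element species, most of them rare.
To keep the number of node types (and the length of the species one-hot)
manageable, elements are partitioned into eight groups: the five common
organic elements get singleton groups, and the remaining species are pooled
by their periodic-table class (metals, metalloids, halogens), so that
elements sharing a group have similar chemical behaviour.

The shipped table covers the heavy atoms occurring in common molecular
property-prediction benchmarks.  Hydrogen and the noble gases have no group
(benchmark molecular graphs are heavy-atom graphs) and raise
:class:`UnsupportedElementError`.  The table is stored as package data and a
custom table can be loaded with :meth:`ElementGrouping.from_json`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

__all__ = [
    "GROUP_NAMES",
    "ElementGrouping",
    "UnsupportedElementError",
    "default_grouping",
    "element_to_group",
]

#: Canonical group order; indices are 1-based throughout.
GROUP_NAMES = (
    "Metals",
    "Metalloids",
    "Halogens",
    "Carbon",
    "Nitrogen",
    "Oxygen",
    "Phosphorus",
    "Sulfur",
)

N_GROUPS = len(GROUP_NAMES)


class UnsupportedElementError(KeyError):
    """Raised for an element symbol absent from the grouping table."""

    def __init__(self, symbol: str, extra: str = ""):
        self.symbol = symbol
        msg = f"unsupported element symbol {symbol!r}{extra}"
        super().__init__(msg)
        self.message = msg

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.message


@dataclass(frozen=True)
class ElementGrouping:
    """A partition of element symbols into 8 ordered named groups.

    Attributes
    ----------
    group_names:
        The 8 group names, in canonical order (group index = position + 1).
    element_to_group:
        Map from element symbol to 1-based group index.
    """

    group_names: tuple[str, ...]
    element_to_group: Mapping[str, int] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.group_names) != N_GROUPS:
            raise ValueError(
                f"expected exactly {N_GROUPS} groups, got {len(self.group_names)}"
            )
        for sym, idx in self.element_to_group.items():
            if not 1 <= idx <= N_GROUPS:
                raise ValueError(
                    f"element {sym!r} maps to group {idx}, outside 1..{N_GROUPS}"
                )

    def group_of(self, symbol: str) -> int:
        """Return the 1-based group index of ``symbol``."""
        try:
            return self.element_to_group[symbol]
        except KeyError:
            raise UnsupportedElementError(symbol) from None

    def members(self, group_index: int) -> tuple[str, ...]:
        """All element symbols mapped to the given 1-based group index."""
        return tuple(
            s for s, g in self.element_to_group.items() if g == group_index
        )

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ElementGrouping":
        names = tuple(payload["group_names"])
        table: dict[str, int] = {}
        for gi, name in enumerate(names, start=1):
            for sym in payload["groups"][name]:
                if sym in table:
                    raise ValueError(f"element {sym!r} assigned to two groups")
                table[sym] = gi
        return cls(group_names=names, element_to_group=table)

    @classmethod
    def from_json(cls, path) -> "ElementGrouping":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_grouping() -> ElementGrouping:
    """The grouping table shipped with the package."""
    payload = json.loads(
        resources.files("molcgnn.data").joinpath("element_groups.json").read_text()
    )
    return ElementGrouping.from_dict(payload)


_DEFAULT = default_grouping()


def element_to_group(symbol: str, grouping: ElementGrouping | None = None) -> int:
    """Map an element symbol to its 1-based group index (1..8).

    Raises :class:`UnsupportedElementError` for symbols absent from the
    table (e.g. ``H`` or noble gases, which do not occur as nodes in
    heavy-atom molecular graphs).
    """
    return (grouping or _DEFAULT).group_of(symbol)
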