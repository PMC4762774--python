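"""Element data used by the descriptor construction.

Each element carries its main-group valence-electron count ``z`` (used by
the branching degree v = z - h + 1) and its Pauling electronegativity
(used by the group/equilibrium electronegativity recursion).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Element:
    """A chemical element with the two attributes the descriptors need."""

    symbol: str
    z: int
    chi_pauling: float

    def __post_init__(self) -> None:
        if self.z < 1:
            raise ValueError(f"valence electron count must be >= 1, got {self.z}")
        if self.chi_pauling <= 0:
            raise ValueError(f"Pauling electronegativity must be > 0, got {self.chi_pauling}")


# Pauling electronegativities: H/C/N/I as used in the worked group examples
# of the construction; O and Br from the standard Pauling scale.
_DEFAULT: dict[str, Element] = {
    "H": Element("H", 1, 2.20),
    "C": Element("C", 4, 2.55),
    "N": Element("N", 5, 3.04),
    "O": Element("O", 6, 3.44),
    "Br": Element("Br", 7, 2.96),
    "I": Element("I", 7, 2.66),
}


class ElementTable:
    """Lookup table for elements; Pauling values can be overridden.

    Parameters
    ----------
    en_overrides
        Mapping of element symbol to Pauling electronegativity, replacing
        the default value (the valence-electron count is fixed per element).
    """

    def __init__(self, en_overrides: dict[str, float] | None = None):
        self._table = dict(_DEFAULT)
        for sym, chi in (en_overrides or {}).items():
            if sym not in self._table:
                raise KeyError(f"unsupported element {sym!r}")
            base = self._table[sym]
            self._table[sym] = Element(sym, base.z, float(chi))

    def __getitem__(self, symbol: str) -> Element:
        try:
            return self._table[symbol]
        except KeyError:
            raise KeyError(f"unsupported element {symbol!r}") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._table

    def symbols(self) -> list[str]:
        return list(self._table)


DEFAULT_ELEMENTS = ElementTable()
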