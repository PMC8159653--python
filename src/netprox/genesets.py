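"""Named gene sets with provenance tags.

These hold the pipeline's symbol collections: the differential-expression
intersection (G_D), the coexpression-module set (G_W), the disease union
(G_HCC), the PPI core hubs (G_P), the key set G_K = (G_D ∩ G_W) ∪ G_P, and
the ingredient-target/disease intersection (G_YH).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .graph_core import normalize_symbol


@dataclass(frozen=True)
class GeneSet:
    """A named, case-normalized, deduplicated set of gene symbols."""

    name: str
    members: frozenset[str] = field(default_factory=frozenset)
    provenance: str = "custom"

    @classmethod
    def from_symbols(
        cls, name: str, symbols: Iterable[str], provenance: str = "custom"
    ) -> "GeneSet":
        return cls(name, frozenset(normalize_symbol(s) for s in symbols), provenance)

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None,
                  provenance: str = "custom") -> "GeneSet":
        """Read a plain-text gene list, one symbol per line."""
        path = Path(path)
        symbols = [
            ln.strip() for ln in path.read_text().splitlines() if ln.strip()
        ]
        return cls.from_symbols(name or path.stem, symbols, provenance)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("".join(f"{s}\n" for s in sorted(self.members)))

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(sorted(self.members))

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.members

    def intersect(self, other: "GeneSet", name: str | None = None,
                  provenance: str = "custom") -> "GeneSet":
        return GeneSet(name or f"{self.name}&{other.name}",
                       self.members & other.members, provenance)

    def union(self, other: "GeneSet", name: str | None = None,
              provenance: str = "custom") -> "GeneSet":
        return GeneSet(name or f"{self.name}|{other.name}",
                       self.members | other.members, provenance)
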