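"""miRNA->target gene-set libraries (GMT) and the enrichment universe.

The enrichment background ("universe") is the union of all unique valid
gene symbols measured across the processed cohorts.  Regulons (per-miRNA
validated target sets) are intersected with that universe *before* testing
so regulon sizes count only background-measurable genes, minimizing
platform-coverage bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import GMTParseError, UniverseError
from .symbol_curation import is_valid_symbol
from .toptable_io import DETable

logger = logging.getLogger(__name__)


@dataclass
class TargetLibrary:
    """Map of miRNA id -> validated target symbols."""

    regulons: dict[str, frozenset[str]] = field(default_factory=dict)
    source: str = ""

    def __len__(self) -> int:
        return len(self.regulons)

    def sizes(self) -> dict[str, int]:
        return {m: len(r) for m, r in self.regulons.items()}


@dataclass(frozen=True)
class Universe:
    """Background gene set defining N in the hypergeometric model."""

    symbols: frozenset[str]

    @property
    def n(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


def read_gmt(path: str | Path) -> TargetLibrary:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Member symbols are uppercased and deduplicated.  Duplicate set names are
    merged by union with a warning.  Lines with fewer than three fields
    raise :class:`GMTParseError` with the line number.
    """
    path = Path(path)
    regulons: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0].strip()
            members = {m.strip().upper() for m in fields[2:] if m.strip()}
            if name in regulons:
                logger.warning("duplicate GMT set %r merged by union", name)
                regulons[name] |= members
            else:
                regulons[name] = members
    return TargetLibrary(
        regulons={m: frozenset(s) for m, s in regulons.items()},
        source=str(path),
    )


def write_gmt(lib: TargetLibrary, path: str | Path, description: str = "NA") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in sorted(lib.regulons):
            members = "\t".join(sorted(lib.regulons[name]))
            fh.write(f"{name}\t{description}\t{members}\n")
    return path


def build_universe(tables: Iterable[DETable]) -> Universe:
    """Union of valid gene symbols across curated cohort tables."""
    symbols: set[str] = set()
    for t in tables:
        symbols |= {s for s in t.symbols if is_valid_symbol(s)}
    if not symbols:
        raise UniverseError("no valid symbols across input tables")
    return Universe(symbols=frozenset(symbols))


def universe_from_symbols(symbols: Iterable[str]) -> Universe:
    syms = frozenset(str(s).strip().upper() for s in symbols
                     if is_valid_symbol(s))
    if not syms:
        raise UniverseError("no valid symbols supplied")
    return Universe(symbols=syms)


def restrict_library(lib: TargetLibrary, universe: Universe) -> TargetLibrary:
    """Intersect every regulon with the universe; drop emptied regulons."""
    restricted: dict[str, frozenset[str]] = {}
    n_dropped = 0
    for mirna, regulon in lib.regulons.items():
        inter = regulon & universe.symbols
        if inter:
            restricted[mirna] = inter
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("restriction dropped %d regulon(s) with no universe overlap",
                    n_dropped)
    if not restricted:
        raise UniverseError(
            "every regulon is empty after universe restriction "
            "(library/universe mismatch?)"
        )
    return TargetLibrary(regulons=restricted, source=lib.source)


def write_universe(universe: Universe, path: str | Path) -> Path:
    """One symbol per line, sorted."""
    path = Path(path)
    path.write_text("\n".join(sorted(universe.symbols)) + "\n")
    return path
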