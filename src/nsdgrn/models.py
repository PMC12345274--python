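"""Core domain types shared across pipeline stages.

Coordinates are 0-based half-open throughout the package. GFF3 input
(1-based inclusive) is converted on read; BED input passes through
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional


class NsdgrnError(ValueError):
    """Base class for user-facing pipeline errors."""


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene.

    ``translation_start`` is the 0-based position of the first coding base
    (the A of the start codon), the anchor for promoter windows. For minus
    strand genes this lies at the high-coordinate end of the CDS.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    translation_start: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise NsdgrnError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.start < self.end:
            raise NsdgrnError(
                f"gene {self.gene_id!r}: start must be < end ({self.start}, {self.end})"
            )
        if not (self.start <= self.translation_start < self.end):
            raise NsdgrnError(
                f"gene {self.gene_id!r}: translation_start {self.translation_start} "
                f"outside gene body [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class Peak:
    """A ChIP peak interval with a summit position.

    The summit is either the called summit (narrowPeak offset column) or
    the interval midpoint (floor) when no summit was reported.
    """

    chrom: str
    start: int
    end: int
    summit: int
    name: str = "."
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise NsdgrnError(
                f"peak {self.name!r}: start must be < end ({self.start}, {self.end})"
            )
        if not (self.start <= self.summit < self.end):
            raise NsdgrnError(
                f"peak {self.name!r}: summit {self.summit} outside [{self.start}, {self.end})"
            )


def percent_of_universe(count: int, universe_size: int) -> float:
    """Percentage of a gene universe, rounded to one decimal.

    This is the convention used for 'percent of annotated genes bound'
    style reporting (e.g. 502 of 10,988 genes -> 4.6).
    """
    if universe_size <= 0:
        raise NsdgrnError("universe size must be positive")
    return round(100.0 * count / universe_size, 1)


@dataclass(frozen=True)
class TargetClassification:
    """The four regulator-relative gene sets.

    * putative_direct -- promoter bound by the regulator (ChIP)
    * degs            -- differentially expressed in the deletion mutant
    * direct          -- bound AND differentially expressed
    * indirect        -- differentially expressed but not bound
    * associated      -- bound OR differentially expressed
    """

    putative_direct: FrozenSet[str]
    degs: FrozenSet[str]
    universe: FrozenSet[str]
    direct: FrozenSet[str] = field(init=False)
    indirect: FrozenSet[str] = field(init=False)
    associated: FrozenSet[str] = field(init=False)

    def __post_init__(self) -> None:
        for label, s in (("putative_direct", self.putative_direct), ("degs", self.degs)):
            extra = s - self.universe
            if extra:
                shown = ", ".join(sorted(extra)[:10])
                raise NsdgrnError(
                    f"{label} contains {len(extra)} genes outside the universe: {shown}"
                )
        object.__setattr__(self, "direct", self.putative_direct & self.degs)
        object.__setattr__(self, "indirect", self.degs - self.putative_direct)
        object.__setattr__(self, "associated", self.putative_direct | self.degs)

    def summary(self) -> dict:
        """Set sizes plus percent-of-universe for the bound set."""
        return {
            "n_universe": len(self.universe),
            "n_putative_direct": len(self.putative_direct),
            "n_degs": len(self.degs),
            "n_direct": len(self.direct),
            "n_indirect": len(self.indirect),
            "n_associated": len(self.associated),
            "pct_putative_direct": percent_of_universe(
                len(self.putative_direct), len(self.universe)
            ),
            "pct_associated": percent_of_universe(
                len(self.associated), len(self.universe)
            ),
        }


def as_frozenset(items: Iterable[str]) -> FrozenSet[str]:
    return items if isinstance(items, frozenset) else frozenset(items)
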