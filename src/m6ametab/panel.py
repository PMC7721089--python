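"""Curated panel of m6A regulator genes.

The m6A machinery is conventionally split into three roles: *writers*
(the methyltransferase complex that deposits N6-methyladenosine),
*erasers* (demethylases that remove it) and *readers* (proteins that
recognise the modified site and change the fate of the transcript).
The default panel is the 23-gene literature-curated set used for
expression-based subtyping of hepatocellular carcinoma; the clustering
panel drops the three IGF2BP readers, which are frequently absent or
unreliably quantified across RNA-seq cohorts, leaving 20 genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Role",
    "RegulatorPanel",
    "default_panel",
    "clustering_panel",
    "restrict_to_matrix",
    "WRITERS",
    "ERASERS",
    "READERS",
]


class Role(str, Enum):
    WRITER = "writer"
    ERASER = "eraser"
    READER = "reader"


WRITERS = (
    "METTL3",
    "METTL14",
    "RBM15",
    "RBM15B",
    "WTAP",
    "KIAA1429",
    "CBLL1",
    "ZC3H13",
)
ERASERS = ("ALKBH5", "FTO")
READERS = (
    "YTHDC1",
    "YTHDC2",
    "YTHDF1",
    "YTHDF2",
    "YTHDF3",
    "IGF2BP1",
    "IGF2BP2",
    "IGF2BP3",
    "HNRNPA2B1",
    "HNRNPC",
    "FMR1",
    "LRPPRC",
    "ELAVL1",
)

_IGF2BP_FAMILY = ("IGF2BP1", "IGF2BP2", "IGF2BP3")


@dataclass(frozen=True)
class RegulatorPanel:
    """An ordered list of (gene symbol, role) pairs.

    Symbols are unique, non-empty and stored uppercase; matching against
    expression matrices is exact after uppercasing (no alias resolution,
    e.g. KIAA1429 is not mapped to VIRMA — rename upstream if needed).
    """

    entries: tuple[tuple[str, Role], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        cleaned = []
        for symbol, role in self.entries:
            if not symbol or not symbol.strip():
                raise ValueError("empty gene symbol in regulator panel")
            sym = symbol.strip().upper()
            if sym in seen:
                raise ValueError(f"duplicate gene symbol in panel: {sym}")
            seen.add(sym)
            cleaned.append((sym, Role(role)))
        object.__setattr__(self, "entries", tuple(cleaned))

    @property
    def genes(self) -> list[str]:
        return [sym for sym, _ in self.entries]

    @property
    def roles(self) -> dict[str, Role]:
        return dict(self.entries)

    def genes_with_role(self, role: Role | str) -> list[str]:
        role = Role(role)
        return [sym for sym, r in self.entries if r is role]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol.strip().upper() in {s for s, _ in self.entries}

    def to_tsv(self, path: str | Path) -> None:
        """Write the panel as two-column TSV (gene_symbol, role)."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write("gene_symbol\trole\n")
            for sym, role in self.entries:
                fh.write(f"{sym}\t{role.value}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegulatorPanel":
        path = Path(path)
        entries: list[tuple[str, Role]] = []
        with path.open() as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["gene_symbol", "role"]:
                raise ValueError(
                    f"{path}: expected header 'gene_symbol\\trole', got {header!r}"
                )
            for line in fh:
                if not line.strip():
                    continue
                sym, role = line.rstrip("\n").split("\t")[:2]
                entries.append((sym, Role(role)))
        return cls(tuple(entries))


def default_panel() -> RegulatorPanel:
    """The 23-gene m6A regulator panel: 8 writers, 2 erasers, 13 readers."""
    entries = (
        [(g, Role.WRITER) for g in WRITERS]
        + [(g, Role.ERASER) for g in ERASERS]
        + [(g, Role.READER) for g in READERS]
    )
    return RegulatorPanel(tuple(entries))


def clustering_panel(panel: RegulatorPanel | None = None) -> RegulatorPanel:
    """Drop the IGF2BP reader family, yielding the 20-gene clustering panel.

    Order of the remaining entries is preserved. If the panel already
    lacks the IGF2BPs the call is a no-op with a warning.
    """
    if panel is None:
        panel = default_panel()
    present = [g for g in _IGF2BP_FAMILY if g in panel]
    if not present:
        warnings.warn(
            "panel contains no IGF2BP genes; clustering_panel is a no-op",
            UserWarning,
            stacklevel=2,
        )
        return panel
    kept = tuple(
        (sym, role) for sym, role in panel.entries if sym not in _IGF2BP_FAMILY
    )
    return RegulatorPanel(kept)


def restrict_to_matrix(
    panel: RegulatorPanel, expr: "ExpressionMatrix"
) -> tuple[RegulatorPanel, list[str]]:
    """Keep panel genes present in the expression matrix.

    Returns the sub-panel and the list of missing symbols (each absence
    is logged). Raises ``ValueError`` if no panel gene is measured.
    """
    available = set(expr.genes)
    kept = tuple((s, r) for s, r in panel.entries if s in available)
    missing = [s for s, _ in panel.entries if s not in available]
    for sym in missing:
        logger.warning("panel gene %s not found in expression matrix", sym)
    if not kept:
        raise ValueError(
            "no panel gene present in the expression matrix; cannot proceed"
        )
    return RegulatorPanel(kept), missing
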