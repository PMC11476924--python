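"""Chemokine family registry.

The human chemokine system comprises 39 ligands in four subfamilies (CXC, CC,
CX3C, XC, defined by the spacing of the conserved N-terminal cysteines) and 22
receptors (conventional G-protein-coupled receptors plus the four atypical
ACKR scavengers).  This module ships that roster as a versioned data table and
exposes lookups used throughout the pipeline:

* subfamily and ligand/receptor role per gene,
* the ELR+ subset (CXCL1, 2, 3, 5, 6, 7/PPBP, 8) that signals through
  CXCR1/CXCR2,
* receptor → ligand pairing,
* the human → mouse ortholog map used for cross-species comparisons.

Several human chemokines (CXCL8 most prominently) have no mouse ortholog;
those genes are simply absent from the homolog map rather than mapped to a
placeholder.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

from .errors import UnknownGeneError

FAMILIES = ("CXC", "CC", "CX3C", "XC")

#: ELR-motif-positive CXC chemokines (CXCL7 is stored under its HGNC symbol PPBP).
ELR_POSITIVE = frozenset({"CXCL1", "CXCL2", "CXCL3", "CXCL5", "CXCL6", "PPBP", "CXCL8"})

#: Receptor → ligand pairing (partial; conventional, well-established pairs).
RECEPTOR_LIGAND_MAP: Mapping[str, frozenset[str]] = {
    "CXCR1": ELR_POSITIVE,
    "CXCR2": ELR_POSITIVE,
    "CXCR3": frozenset({"CXCL9", "CXCL10", "CXCL11"}),
    "CXCR4": frozenset({"CXCL12"}),
    "CXCR5": frozenset({"CXCL13"}),
    "CXCR6": frozenset({"CXCL16"}),
    "CCR1": frozenset(
        {"CCL3", "CCL5", "CCL7", "CCL8", "CCL13", "CCL14", "CCL15", "CCL16", "CCL23"}
    ),
    "CCR2": frozenset({"CCL2", "CCL7", "CCL8", "CCL13"}),
    "CCR3": frozenset({"CCL5", "CCL7", "CCL11", "CCL13", "CCL24", "CCL26"}),
    "CCR4": frozenset({"CCL22"}),
    "CCR5": frozenset({"CCL3", "CCL4", "CCL5"}),
    "CCR6": frozenset({"CCL20"}),
    "CCR7": frozenset({"CCL19", "CCL21"}),
    "CCR9": frozenset({"CCL25"}),
    "CCR10": frozenset({"CCL28"}),
    "XCR1": frozenset({"XCL1", "XCL2"}),
    "CX3CR1": frozenset({"CX3CL1"}),
    "ACKR3": frozenset({"CXCL11", "CXCL12"}),
}

_PREFIX_FAMILY = (
    ("CX3C", "CX3C"),
    ("CXC", "CXC"),
    ("CC", "CC"),
    ("XC", "XC"),
)


def infer_family(symbol: str) -> Optional[str]:
    """Derive the subfamily from a symbol prefix; None if the symbol is opaque
    (e.g. PF4, PPBP, ACKR*), in which case an alias may still be informative."""
    for prefix, family in _PREFIX_FAMILY:
        if symbol.startswith((prefix + "L", prefix + "R")):
            return family
    return None


@dataclass(frozen=True)
class GeneRecord:
    """One chemokine ligand or receptor."""

    symbol: str
    family: str
    role: str  # "ligand" or "receptor"
    elr_positive: bool = False
    aliases: tuple[str, ...] = ()
    mouse_homolog: Optional[str] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown subfamily {self.family!r} for {self.symbol}")
        if self.role not in ("ligand", "receptor"):
            raise ValueError(f"unknown role {self.role!r} for {self.symbol}")
        if self.elr_positive and self.role != "ligand":
            raise ValueError(f"ELR flag is only meaningful for ligands ({self.symbol})")


class GeneRegistry:
    """Ordered collection of chemokine ligand and receptor records.

    Construction is self-validating: the roster must hold exactly 39 ligands
    and 22 receptors, prefix-derivable subfamilies must be consistent, the
    ELR+ flag must mark exactly the seven ELR-motif chemokines, and the mouse
    homolog map must be injective.  Lookup is alias-aware and
    case-insensitive (so ``CXCL7`` resolves to the PPBP record).
    """

    def __init__(self, records: Iterable[GeneRecord], *, validate: bool = True):
        self.records: tuple[GeneRecord, ...] = tuple(records)
        self.ligands = tuple(r for r in self.records if r.role == "ligand")
        self.receptors = tuple(r for r in self.records if r.role == "receptor")
        self._index: dict[str, GeneRecord] = {}
        for rec in self.records:
            for name in (rec.symbol, *rec.aliases):
                self._index[name.upper()] = rec
        self.receptor_ligand_map = {
            r.symbol: RECEPTOR_LIGAND_MAP[r.symbol]
            for r in self.receptors
            if r.symbol in RECEPTOR_LIGAND_MAP
        }
        if validate:
            self._validate()

    # -- construction -----------------------------------------------------

    def _validate(self) -> None:
        if len(self.ligands) != 39:
            raise ValueError(f"expected 39 ligands, got {len(self.ligands)}")
        if len(self.receptors) != 22:
            raise ValueError(f"expected 22 receptors, got {len(self.receptors)}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.symbol in seen:
                raise ValueError(f"duplicate symbol {rec.symbol}")
            seen.add(rec.symbol)
            derived = infer_family(rec.symbol) or next(
                filter(None, (infer_family(a) for a in rec.aliases)), None
            )
            if derived is not None and derived != rec.family:
                raise ValueError(
                    f"{rec.symbol}: declared family {rec.family} != derived {derived}"
                )
        flagged = {r.symbol for r in self.ligands if r.elr_positive}
        if flagged != set(ELR_POSITIVE):
            raise ValueError(f"ELR+ set mismatch: {sorted(flagged)}")
        homologs = [r.mouse_homolog for r in self.records if r.mouse_homolog]
        if len(homologs) != len(set(homologs)):
            raise ValueError("mouse homolog map is not injective")

    # -- queries ----------------------------------------------------------

    def lookup(self, symbol: str) -> GeneRecord:
        try:
            return self._index[symbol.strip().upper()]
        except KeyError:
            raise UnknownGeneError(symbol) from None

    def __contains__(self, symbol: str) -> bool:
        return symbol.strip().upper() in self._index

    def resolve(self, symbol: str) -> str:
        """Canonical HGNC-style symbol for a symbol or alias."""
        return self.lookup(symbol).symbol

    def ligand_symbols(self) -> tuple[str, ...]:
        return tuple(r.symbol for r in self.ligands)

    def receptor_symbols(self) -> tuple[str, ...]:
        return tuple(r.symbol for r in self.receptors)

    def all_symbols(self) -> tuple[str, ...]:
        return tuple(r.symbol for r in self.records)

    def panel(self, which: str = "both") -> tuple[str, ...]:
        """Gene panel selection: ``ligands``, ``receptors`` or ``both``."""
        if which == "ligands":
            return self.ligand_symbols()
        if which == "receptors":
            return self.receptor_symbols()
        if which == "both":
            return self.all_symbols()
        raise ValueError(f"unknown panel {which!r}")

    @property
    def homolog_map(self) -> dict[str, str]:
        return {r.symbol: r.mouse_homolog for r in self.records if r.mouse_homolog}

    @property
    def mouse_to_human(self) -> dict[str, str]:
        return {m: h for h, m in self.homolog_map.items()}


def build_default_registry() -> GeneRegistry:
    """Load the bundled chemokine roster (39 ligands + 22 receptors)."""
    path = resources.files("chemoatlas.data") / "chemokine_registry.tsv"
    records = []
    with path.open("r", encoding="utf-8") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            records.append(
                GeneRecord(
                    symbol=row["symbol"],
                    family=row["family"],
                    role=row["role"],
                    elr_positive=row["elr_positive"].strip().lower() == "true",
                    aliases=tuple(a for a in (row["aliases"] or "").split(",") if a),
                    mouse_homolog=(row["mouse_homolog"] or "").strip() or None,
                )
            )
    return GeneRegistry(records)


def map_to_mouse(
    registry: GeneRegistry, symbols: Sequence[str]
) -> tuple[dict[str, str], list[str]]:
    """Map human symbols to their mouse orthologs.

    Returns ``(mapping, unmapped)`` where *mapping* preserves the input order
    and contains only symbols with a defined ortholog, and *unmapped* lists
    (canonical) symbols without one.  Unknown symbols raise
    :class:`UnknownGeneError` naming the offender.
    """
    mapping: dict[str, str] = {}
    unmapped: list[str] = []
    for symbol in symbols:
        record = registry.lookup(symbol)  # raises UnknownGeneError
        if record.mouse_homolog is None:
            unmapped.append(record.symbol)
        else:
            mapping[record.symbol] = record.mouse_homolog
    return mapping, unmapped
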