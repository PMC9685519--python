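"""Actionable-gene panel: the in-silico gene list the screen is restricted to.

The default panel ships with the package and contains the 59 medically
actionable genes of the ACMG secondary-findings v2.0 recommendation, each
with a mode of inheritance (AD, AR, XL, or SD for the semidominant
hypercholesterolemia genes) and a disease domain used for cohort-level
composition summaries. Alternative panels (e.g. the later 73-gene update)
can be supplied as a TSV with the same three columns.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .errors import ConfigError
from .model import PanelGene

_DEFAULT_RESOURCE = "acmg_sf_v2_panel.tsv"


class Panel:
    """An ordered, symbol-unique collection of actionable genes."""

    def __init__(self, genes: Iterable[PanelGene]):
        self._genes: list[PanelGene] = list(genes)
        self._by_symbol: dict[str, PanelGene] = {}
        for gene in self._genes:
            if gene.symbol in self._by_symbol:
                raise ConfigError(f"duplicate gene symbol {gene.symbol!r} in panel")
            self._by_symbol[gene.symbol] = gene
        if not self._genes:
            raise ConfigError("panel must contain at least one gene")

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[PanelGene]:
        return iter(self._genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def get(self, symbol: str) -> Optional[PanelGene]:
        return self._by_symbol.get(symbol)

    def moi(self, symbol: str) -> str:
        gene = self._by_symbol.get(symbol)
        if gene is None:
            raise ConfigError(f"gene {symbol!r} is not on the panel")
        return gene.moi

    def domain(self, symbol: str) -> str:
        gene = self._by_symbol.get(symbol)
        if gene is None:
            raise ConfigError(f"gene {symbol!r} is not on the panel")
        return gene.domain

    @property
    def symbols(self) -> list[str]:
        return [g.symbol for g in self._genes]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Panel":
        genes = []
        with open(path, newline="") as handle:
            reader = csv.DictReader(handle, delimiter="\t")
            required = {"symbol", "moi", "domain"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise ConfigError(
                    f"panel file {path} must have columns {sorted(required)}, "
                    f"got {reader.fieldnames}"
                )
            for row in reader:
                genes.append(PanelGene(row["symbol"], row["moi"], row["domain"]))
        return cls(genes)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(["symbol", "moi", "domain"])
            for gene in self._genes:
                writer.writerow([gene.symbol, gene.moi, gene.domain])


def default_panel() -> Panel:
    """The 59-gene actionable panel shipped with the package."""
    source = resources.files("sfscreen.data").joinpath(_DEFAULT_RESOURCE)
    with resources.as_file(source) as path:
        panel = Panel.from_tsv(path)
    if len(panel) != 59:
        raise ConfigError(f"default panel must have 59 genes, found {len(panel)}")
    return panel
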