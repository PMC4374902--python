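"""CTRA indicator gene sets.

The conserved transcriptional response to adversity (CTRA) is scored as a
signed composite over a fixed panel of leukocyte transcripts: pro-inflammatory
genes enter with contrast sign +1, type I interferon and antibody-synthesis
genes with sign -1 (their expression is sign-inverted before averaging, so a
higher composite always means a more "adverse" profile).

The full discovery panel has 53 genes (19 pro-inflammatory, 31 interferon,
3 antibody).  Dropping ``IL6`` — unavailable in the confirmation-study arrays —
yields the 52-gene confirmation panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

_EXPECTED_COMPOSITION = {"proinflammatory": 19, "interferon": 31, "antibody": 3}
N_MARKERS = 8


@dataclass(frozen=True)
class CtraGeneSet:
    """Named genes with +1/-1 contrast signs and category tags."""

    symbols: tuple[str, ...]
    signs: tuple[int, ...]
    categories: tuple[str, ...]
    name: str = "ctra"

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("gene set is empty")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("duplicate gene symbols in gene set")
        if not (len(self.symbols) == len(self.signs) == len(self.categories)):
            raise ValueError("symbols, signs and categories must align")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("contrast signs must be +1 or -1")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    @property
    def sign_map(self) -> dict[str, int]:
        return dict(zip(self.symbols, self.signs))

    @property
    def n_negative(self) -> int:
        return sum(1 for s in self.signs if s == -1)

    def counts_by_category(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.categories:
            out[c] = out.get(c, 0) + 1
        return out

    def exclude(self, symbols: Iterable[str]) -> "CtraGeneSet":
        """Drop genes by symbol (e.g. ``IL6`` for the confirmation panel)."""
        drop = set(symbols)
        unknown = drop - set(self.symbols)
        if unknown:
            raise KeyError(f"cannot exclude genes not in set: {sorted(unknown)}")
        keep = [i for i, s in enumerate(self.symbols) if s not in drop]
        if not keep:
            raise ValueError("excluding all genes leaves an empty set")
        return CtraGeneSet(
            symbols=tuple(self.symbols[i] for i in keep),
            signs=tuple(self.signs[i] for i in keep),
            categories=tuple(self.categories[i] for i in keep),
            name=self.name,
        )


def _default_config() -> Mapping:
    with resources.files("ctra_wellbeing.data").joinpath("ctra_genes.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_gene_set(
    path: str | Path | None = None,
    exclude: Sequence[str] = (),
    validate_composition: bool | None = None,
) -> CtraGeneSet:
    """Load a CTRA gene set from a YAML config (default: the shipped 53-gene panel).

    Parameters
    ----------
    path
        YAML file with a ``genes:`` list of ``{symbol, sign, category}`` entries.
        ``None`` loads the package default.
    exclude
        Symbols to drop after loading (applied after composition validation).
    validate_composition
        Check the 19/31/3 category counts.  Defaults to ``True`` for the shipped
        default panel and ``False`` for user-supplied files.
    """
    if path is None:
        cfg = _default_config()
        if validate_composition is None:
            validate_composition = True
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if validate_composition is None:
            validate_composition = False
    entries = cfg["genes"]
    gs = CtraGeneSet(
        symbols=tuple(e["symbol"] for e in entries),
        signs=tuple(int(e["sign"]) for e in entries),
        categories=tuple(e["category"] for e in entries),
    )
    if validate_composition:
        counts = gs.counts_by_category()
        if counts != _EXPECTED_COMPOSITION:
            raise ValueError(
                f"gene-set composition {counts} != expected {_EXPECTED_COMPOSITION}"
            )
    if exclude:
        gs = gs.exclude(exclude)
    return gs


def default_marker_transcripts(path: str | Path | None = None) -> tuple[str, ...]:
    """The 8 leukocyte-subset marker transcripts used as covariates."""
    cfg = _default_config() if path is None else yaml.safe_load(open(path))
    markers = tuple(cfg["markers"])
    if len(markers) != N_MARKERS:
        raise ValueError(f"expected {N_MARKERS} marker transcripts, got {len(markers)}")
    return markers
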