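"""Combinatorial sgRNA library model.

A dual-sgRNA (CombiGEM-style) library delivers every ordered pair of guides
from a catalog of ``n_genes × n_sgrna_per_gene`` targeting sgRNAs plus a set
of non-targeting controls.  A catalog of S guides induces S² ordered sgRNA
pairs; collapsing guides to gene labels (with "control" as one pseudo-gene)
induces C(G, 2) + G unordered gene pairs including self-pairs, where
G = n_genes + 1.  For the 76-gene × 3-guide + 5-control design that is
233² = 54,289 sgRNA pairs and 3003 gene pairs.
"""

from __future__ import annotations

import itertools
import math
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

#: Reserved gene label carried by non-targeting control sgRNAs.
CONTROL = "Control"

_SPACER_RE = re.compile(r"^[ACGT]+$")


class PairClass(Enum):
    """Mutually exclusive classification of a gene-label pair."""

    DOUBLE_TARGET = "double_target"
    SINGLE_PLUS_CONTROL = "single_plus_control"
    CONTROL_CONTROL = "control_control"
    SAME_GENE = "same_gene"


@dataclass(frozen=True)
class SgRNA:
    """A single guide, identified by its spacer sequence.

    ``gene`` is the target gene symbol, or :data:`CONTROL` for non-targeting
    controls.  ``cassette_slot`` records positional restrictions; the default
    library places every guide in both cassette positions.
    """

    id: str
    spacer: str
    gene: str
    cassette_slot: str = "both"

    def __post_init__(self) -> None:
        if not _SPACER_RE.match(self.spacer):
            raise InputError(
                f"sgRNA {self.id!r}: spacer contains characters other than A/C/G/T"
            )
        if self.cassette_slot not in ("both", "first", "second"):
            raise InputError(f"sgRNA {self.id!r}: invalid cassette_slot")

    @property
    def is_control(self) -> bool:
        return self.gene == CONTROL


@dataclass
class LibraryDesign:
    """The sgRNA catalog and the pair universes it induces."""

    sgrnas: list[SgRNA]
    n_sgrna_per_gene: int = field(init=False)
    genes: list[str] = field(init=False)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sgrnas]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate sgRNA ids: {dupes[:5]}")
        self.genes = sorted({s.gene for s in self.sgrnas if not s.is_control})
        counts = {g: 0 for g in self.genes}
        for s in self.sgrnas:
            if not s.is_control:
                counts[s.gene] += 1
        per_gene = sorted(set(counts.values()))
        self.n_sgrna_per_gene = per_gene[-1] if per_gene else 0
        if len(per_gene) > 1:
            uneven = {g: c for g, c in counts.items() if c != self.n_sgrna_per_gene}
            warnings.warn(
                f"uneven sgRNA counts per gene (expected {self.n_sgrna_per_gene}): "
                f"{dict(itertools.islice(uneven.items(), 5))}",
                stacklevel=2,
            )
        self._by_id = {s.id: s for s in self.sgrnas}
        self._by_spacer: dict[str, str] = {}
        for s in self.sgrnas:
            if s.spacer in self._by_spacer:
                raise InputError(f"duplicate spacer {s.spacer!r}")
            self._by_spacer[s.spacer] = s.id

    # -- lookups -----------------------------------------------------------

    @property
    def control_sgrnas(self) -> list[SgRNA]:
        return [s for s in self.sgrnas if s.is_control]

    @property
    def spacer_to_id(self) -> dict[str, str]:
        return self._by_spacer

    def sgrna(self, sgrna_id: str) -> SgRNA:
        try:
            return self._by_id[sgrna_id]
        except KeyError:
            raise InputError(f"unknown sgRNA id {sgrna_id!r}") from None

    def gene_of(self, sgrna_id: str) -> str:
        return self.sgrna(sgrna_id).gene

    @property
    def gene_labels(self) -> list[str]:
        """All gene labels, sorted; the control pseudo-gene only if controls exist."""
        if self.control_sgrnas:
            return sorted(self.genes + [CONTROL])
        return list(self.genes)

    def __len__(self) -> int:
        return len(self.sgrnas)


def load_library(path: str | Path, *, strict: bool = False) -> LibraryDesign:
    """Read a library table (TSV/CSV with header id, spacer, gene, is_control).

    ``is_control`` accepts 1/0, true/false, yes/no.  Control rows are assigned
    the reserved :data:`CONTROL` label regardless of their gene column.  With
    ``strict=True`` an uneven guides-per-gene count raises instead of warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"library table not found: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"id", "spacer", "gene", "is_control"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"library table missing columns: {sorted(missing)}")
    truthy = {"1", "true", "yes", "t", "y"}
    sgrnas = []
    for row in df.itertuples(index=False):
        is_ctrl = str(row.is_control).strip().lower() in truthy
        gene = CONTROL if is_ctrl else str(row.gene).strip()
        sgrnas.append(SgRNA(id=str(row.id).strip(), spacer=str(row.spacer).strip().upper(), gene=gene))
    if strict:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            return LibraryDesign(sgrnas)
    return LibraryDesign(sgrnas)


def write_library(design: LibraryDesign, path: str | Path) -> None:
    """Write a design back to a tab-delimited library table."""
    df = pd.DataFrame(
        {
            "id": [s.id for s in design.sgrnas],
            "spacer": [s.spacer for s in design.sgrnas],
            "gene": ["" if s.is_control else s.gene for s in design.sgrnas],
            "is_control": [int(s.is_control) for s in design.sgrnas],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def enumerate_sgrna_pairs(design: LibraryDesign) -> list[tuple[str, str]]:
    """All ordered sgRNA-id pairs (a, b), including a == b; count = S²."""
    ids = [s.id for s in design.sgrnas]
    return list(itertools.product(ids, ids))


def enumerate_gene_pairs(design: LibraryDesign) -> list[tuple[str, str]]:
    """All unordered gene-label pairs including self-pairs.

    The control label counts as one pseudo-gene, so a design with N genes
    yields C(N+1, 2) + (N+1) pairs.  Keys are sorted 2-tuples.
    """
    labels = design.gene_labels
    return list(itertools.combinations_with_replacement(labels, 2))


def gene_pair_key(a_gene: str, b_gene: str) -> tuple[str, str]:
    """Canonical (sorted) key for an unordered gene pair."""
    return (a_gene, b_gene) if a_gene <= b_gene else (b_gene, a_gene)


def sgrna_pair_key(a_id: str, b_id: str) -> tuple[str, str]:
    """Canonical (sorted) key for an unordered sgRNA pair."""
    return (a_id, b_id) if a_id <= b_id else (b_id, a_id)


def classify_pair(a_gene: str, b_gene: str, design: LibraryDesign | None = None) -> PairClass:
    """Classify a gene-label pair; symmetric in its arguments."""
    if design is not None:
        known = set(design.gene_labels)
        for g in (a_gene, b_gene):
            if g not in known:
                raise InputError(f"unknown gene label {g!r}")
    if a_gene == CONTROL and b_gene == CONTROL:
        return PairClass.CONTROL_CONTROL
    if a_gene == CONTROL or b_gene == CONTROL:
        return PairClass.SINGLE_PLUS_CONTROL
    if a_gene == b_gene:
        return PairClass.SAME_GENE
    return PairClass.DOUBLE_TARGET


def n_gene_pairs(n_genes: int) -> int:
    """Closed form for the gene-pair universe: C(G,2)+G with G = n_genes+1."""
    g = n_genes + 1
    return math.comb(g, 2) + g


def expected_coverage(cells: float, moi: float, library_size: int) -> int:
    """Expected cells per construct at transduction, rounded half-up.

    For 1e8 cells at MOI 0.3 over 54,289 constructs this is 553.
    """
    if cells < 0 or moi < 0:
        raise InputError("cells and moi must be non-negative")
    if library_size <= 0:
        raise InputError("library_size must be positive")
    return int(np.floor(cells * moi / library_size + 0.5))
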