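"""Ordered sgRNA-pair extraction from paired-end amplicon reads.

Each read pair carries two 20-nt spacers directly (no barcodes): spacer 1
sits on the forward read immediately after a fixed anchor sequence, spacer 2
on the reverse read after its own anchor (the reverse read is reverse-
complemented first by default).  Anchors tolerate a small mismatch budget;
spacers must match the library exactly — Brunello spacers are well separated,
so a sequencing error in the spacer simply drops the read rather than
miscalling it.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import InputError
from .library import LibraryDesign, enumerate_sgrna_pairs, gene_pair_key

# 3' ends of the custom paired-end sequencing primers; override per dataset.
DEFAULT_FWD_ANCHOR = "GCTCTCAAAC"
DEFAULT_REV_ANCHOR = "GAATTCGTGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AnchorConfig:
    """Amplicon layout: anchors flanking the two spacers.

    ``rev_read_orientation`` says how the reverse read relates to the
    cassette: ``reverse_complement`` (default) means the read is reverse-
    complemented before searching for ``rev_anchor``.
    """

    fwd_anchor: str = DEFAULT_FWD_ANCHOR
    rev_anchor: str = DEFAULT_REV_ANCHOR
    spacer_len: int = 20
    max_mismatches: int = 1
    rev_read_orientation: str = "reverse_complement"

    def __post_init__(self) -> None:
        if not self.fwd_anchor or not self.rev_anchor:
            raise InputError("anchors must be non-empty")
        if self.spacer_len <= 0:
            raise InputError("spacer_len must be positive")
        if self.max_mismatches < 0:
            raise InputError("max_mismatches must be >= 0")
        if self.rev_read_orientation not in ("as_sequenced", "reverse_complement"):
            raise InputError("invalid rev_read_orientation")


class ParseResult(NamedTuple):
    """Outcome of parsing one read pair: a matched pair or a typed miss."""

    status: str  # "ok" | "anchor_not_found" | "spacer_unknown"
    pair: tuple[str, str] | None


def find_anchor(seq: str, anchor: str, max_mismatches: int, spacer_len: int) -> int:
    """Leftmost offset where ``anchor`` matches within the mismatch budget.

    Only offsets leaving room for a full spacer downstream are considered.
    Returns -1 when no offset qualifies.
    """
    la = len(anchor)
    last = len(seq) - la - spacer_len
    if last < 0:
        return -1
    if max_mismatches == 0:
        pos = seq.find(anchor)
        return pos if 0 <= pos <= last else -1
    # exact hit short-circuits the mismatch scan
    pos = seq.find(anchor)
    if 0 <= pos <= last:
        exact = pos
    else:
        exact = -1
    for off in range(last + 1):
        if off == exact:
            return off
        mism = 0
        for i in range(la):
            if seq[off + i] != anchor[i]:
                mism += 1
                if mism > max_mismatches:
                    break
        if mism <= max_mismatches:
            return off
    return -1


def parse_read_pair(
    fwd_seq: str,
    rev_seq: str,
    cfg: AnchorConfig,
    design: LibraryDesign,
) -> ParseResult:
    """Extract the ordered (slot-1, slot-2) sgRNA pair from one read pair."""
    fwd_seq = fwd_seq.upper()
    rev_seq = rev_seq.upper()
    if cfg.rev_read_orientation == "reverse_complement":
        rev_seq = reverse_complement(rev_seq)
    lookup = design.spacer_to_id

    pos1 = find_anchor(fwd_seq, cfg.fwd_anchor, cfg.max_mismatches, cfg.spacer_len)
    if pos1 < 0:
        return ParseResult("anchor_not_found", None)
    pos2 = find_anchor(rev_seq, cfg.rev_anchor, cfg.max_mismatches, cfg.spacer_len)
    if pos2 < 0:
        return ParseResult("anchor_not_found", None)

    s1 = fwd_seq[pos1 + len(cfg.fwd_anchor) : pos1 + len(cfg.fwd_anchor) + cfg.spacer_len]
    s2 = rev_seq[pos2 + len(cfg.rev_anchor) : pos2 + len(cfg.rev_anchor) + cfg.spacer_len]
    id1 = lookup.get(s1)
    id2 = lookup.get(s2)
    if id1 is None or id2 is None:
        return ParseResult("spacer_unknown", None)
    return ParseResult("ok", (id1, id2))


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTQ file not found: {path}")
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _fastq_pairs(fastq_fwd, fastq_rev) -> Iterator[tuple[str, str]]:
    with _open_maybe_gzip(fastq_fwd) as fh1, _open_maybe_gzip(fastq_rev) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for rec1, rec2 in itertools.zip_longest(it1, it2):
            if rec1 is None or rec2 is None:
                raise InputError(
                    "desynchronized mates: forward and reverse FASTQ differ in length"
                )
            yield rec1[1], rec2[1]


def pair_index(design: LibraryDesign) -> pd.MultiIndex:
    """MultiIndex over the full ordered sgRNA-pair universe."""
    return pd.MultiIndex.from_tuples(
        enumerate_sgrna_pairs(design), names=["sgrna_1", "sgrna_2"]
    )


def count_pairs(
    fastq_fwd: str | Path,
    fastq_rev: str | Path,
    cfg: AnchorConfig,
    design: LibraryDesign,
) -> tuple[pd.Series, dict[str, int]]:
    """Stream one sample's read pairs into a count column.

    Returns the counts over the full ordered-pair universe (zeros included)
    and per-sample miss statistics.  Files are streamed record by record.
    """
    counts: dict[tuple[str, str], int] = {}
    stats = {"total_reads": 0, "matched": 0, "anchor_not_found": 0, "spacer_unknown": 0}
    for fwd, rev in _fastq_pairs(fastq_fwd, fastq_rev):
        stats["total_reads"] += 1
        res = parse_read_pair(fwd, rev, cfg, design)
        if res.status == "ok":
            stats["matched"] += 1
            counts[res.pair] = counts.get(res.pair, 0) + 1
        else:
            stats[res.status] += 1
    idx = pair_index(design)
    col = pd.Series(0, index=idx, dtype=np.int64)
    if counts:
        got = pd.Series(counts)
        got.index = pd.MultiIndex.from_tuples(got.index, names=idx.names)
        col = col.add(got, fill_value=0).reindex(idx).astype(np.int64)
    return col, stats


@dataclass
class PairCountMatrix:
    """Ordered sgRNA-pair × sample count table with sample metadata.

    ``counts`` is indexed by (sgrna_1, sgrna_2) over the full pair universe;
    ``samples`` is indexed by sample id with columns ``timepoint`` (D0/D20)
    and ``replicate`` (int).  ``unmatched`` holds per-sample miss stats.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    unmatched: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise InputError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise InputError(f"samples metadata missing for: {sorted(missing)}")
        bad_tp = set(self.samples["timepoint"]) - {"D0", "D20"}
        if bad_tp:
            raise InputError(f"unknown timepoints: {sorted(bad_tp)}")

    def column(self, sample: str) -> pd.Series:
        if sample not in self.counts.columns:
            raise InputError(f"sample {sample!r} not in count matrix")
        return self.counts[sample]


def rpm_normalize(counts: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Reads per million matched reads, per column; columns sum to 1e6."""
    if isinstance(counts, pd.Series):
        total = counts.sum()
        if total <= 0:
            raise InputError("zero-depth column cannot be RPM-normalized")
        return counts * (1e6 / total)
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise InputError(f"zero-depth columns: {list(zero.index)}")
    return counts * (1e6 / totals)


@dataclass
class RepresentationQC:
    """Library representation: gene pairs covered by enough sgRNA pairs.

    ``per_gene_pair`` counts, for every unordered gene pair, the ordered
    sgRNA pairs (orientations distinct) whose log10 RPM meets the threshold.
    """

    per_gene_pair: pd.Series
    min_sgrna_pairs: int
    threshold_log10_rpm: float
    n_pass: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_pass / self.n_total if self.n_total else 0.0

    def summary(self) -> str:
        return (
            f"{self.n_pass}/{self.n_total} gene pairs "
            f"({100 * self.fraction:.1f}%) represented by >= {self.min_sgrna_pairs} "
            f"sgRNA pairs at log10 RPM >= {self.threshold_log10_rpm}"
        )


def representation_qc(
    counts: PairCountMatrix | pd.Series,
    design: LibraryDesign,
    *,
    sample: str | None = None,
    min_sgrna_pairs: int = 6,
    log10_rpm_threshold: float = 0.5,
) -> RepresentationQC:
    """Fraction of gene pairs represented by enough well-covered sgRNA pairs.

    Defaults mirror the screen QC convention: at least six ordered sgRNA
    pairs per gene pair at log10 RPM >= 0.5 in the baseline (D0) sample.
    """
    if isinstance(counts, PairCountMatrix):
        if sample is None:
            d0 = counts.samples.index[counts.samples["timepoint"] == "D0"]
            if len(d0) == 0:
                raise InputError("no D0 sample for representation QC")
            col = counts.counts[list(d0)].sum(axis=1)
        else:
            col = counts.column(sample)
    else:
        col = counts

    total = col.sum()
    genes = np.array([design.gene_of(i) for i in col.index.get_level_values(0)])
    genes2 = np.array([design.gene_of(i) for i in col.index.get_level_values(1)])
    keys = [gene_pair_key(a, b) for a, b in zip(genes, genes2)]
    if total > 0:
        rpm = col.to_numpy() * (1e6 / total)
        with np.errstate(divide="ignore"):
            passing = np.log10(rpm, out=np.full(len(rpm), -np.inf), where=rpm > 0)
        ok = passing >= log10_rpm_threshold
    else:
        ok = np.zeros(len(col), dtype=bool)
    per = (
        pd.Series(ok.astype(int), index=pd.MultiIndex.from_tuples(keys, names=["gene_a", "gene_b"]))
        .groupby(level=[0, 1])
        .sum()
        .sort_index()
    )
    n_pass = int((per >= min_sgrna_pairs).sum())
    return RepresentationQC(
        per_gene_pair=per,
        min_sgrna_pairs=min_sgrna_pairs,
        threshold_log10_rpm=log10_rpm_threshold,
        n_pass=n_pass,
        n_total=len(per),
    )
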