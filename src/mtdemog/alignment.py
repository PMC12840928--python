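"""Reading, validating and summarising protein-coding mtDNA alignments.

The alignments handled here are short, ungapped, equal-length fragments of a
protein-coding mitochondrial gene (e.g. a Cytochrome b fragment) from a set of
haploid samples.  All site and window coordinates are 1-based and inclusive,
relative to the start of the analysed fragment.

IUPAC ambiguity codes and ``N`` are treated as missing data for site
classification and distance computations (pairwise deletion).  Haplotype
collapsing is strict by default: two sequences share a haplotype only if they
are literally identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("mtdemog")

#: unambiguous nucleotide states
BASES = ("A", "C", "G", "T")
_BASE_SET = frozenset(BASES)


def is_missing(char: str) -> bool:
    """True for any character treated as missing data (N, IUPAC ambiguity, gap)."""
    return char not in _BASE_SET


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned haploid sequence with optional sample metadata."""

    id: str
    sequence: str
    region: str | None = None
    source: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence for {self.id!r} is empty")


@dataclass(frozen=True)
class Alignment:
    """An equal-length, ungapped multiple sequence alignment.

    ``window`` records 1-based inclusive coordinates of this alignment
    relative to the original fragment when it was produced by
    :func:`trim_window`.
    """

    records: tuple[SequenceRecord, ...]
    window: tuple[int, int] | None = None

    def __post_init__(self):
        if not self.records:
            raise ValueError("alignment has no records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            bad = [r.id for r in self.records
                   if len(r.sequence) != len(self.records[0].sequence)]
            raise ValueError(
                f"unequal sequence lengths in alignment; offending ids: {bad}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dups}")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def matrix(self) -> np.ndarray:
        """Character matrix of shape (n, L), dtype '<U1'."""
        return np.array([list(r.sequence) for r in self.records])

    def column(self, pos: int) -> list[str]:
        """Site column at 1-based position ``pos``."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside 1..{self.length}")
        return [r.sequence[pos - 1] for r in self.records]

    def subset(self, ids: list[str]) -> "Alignment":
        wanted = set(ids)
        recs = tuple(r for r in self.records if r.id in wanted)
        missing = wanted - {r.id for r in recs}
        if missing:
            raise KeyError(f"ids not in alignment: {sorted(missing)}")
        return Alignment(recs, window=self.window)

    def drop(self, ids: list[str]) -> "Alignment":
        unwanted = set(ids)
        return Alignment(tuple(r for r in self.records if r.id not in unwanted),
                         window=self.window)


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct sequences, their counts, and the sample ids carrying them."""

    haplotypes: tuple[tuple[str, str, int, tuple[str, ...]], ...]
    # each entry: (label, sequence, count, member ids)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def counts(self) -> list[int]:
        return [h[2] for h in self.haplotypes]

    @property
    def n(self) -> int:
        return sum(self.counts)

    def label_of(self, sample_id: str) -> str:
        for label, _seq, _c, members in self.haplotypes:
            if sample_id in members:
                return label
        raise KeyError(sample_id)

    def expand(self) -> list[str]:
        """Multiset of member sequences (one per original record)."""
        out = []
        for _label, seq, count, _members in self.haplotypes:
            out.extend([seq] * count)
        return out


@dataclass(frozen=True)
class SiteClassification:
    """Per-site polymorphism categories and their totals."""

    categories: tuple[str, ...]  # 'monomorphic' | 'singleton' | 'parsimony-informative'
    segregating_positions: tuple[int, ...]  # 1-based

    @property
    def S(self) -> int:
        return len(self.segregating_positions)

    @property
    def n_singletons(self) -> int:
        return sum(1 for c in self.categories if c == "singleton")

    @property
    def n_parsimony_informative(self) -> int:
        return sum(1 for c in self.categories if c == "parsimony-informative")


@dataclass
class QCReport:
    """Report-only QC of a protein-coding alignment (gaps, internal stops)."""

    passed: bool
    gap_positions: dict[str, list[int]] = field(default_factory=dict)
    internal_stops: dict[str, list[int]] = field(default_factory=dict)  # 1-based codon index

    def to_json(self) -> str:
        return json.dumps({
            "passed": self.passed,
            "gap_positions": self.gap_positions,
            "internal_stops": self.internal_stops,
        }, indent=2)

    def to_text(self) -> str:
        lines = [f"QC {'PASS' if self.passed else 'FAIL'}"]
        for sid, pos in self.gap_positions.items():
            lines.append(f"  {sid}: gap characters at positions {pos}")
        for sid, codons in self.internal_stops.items():
            lines.append(f"  {sid}: internal stop codon(s) at codon index {codons}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path, metadata_path: str | Path | None = None) -> Alignment:
    """Read an aligned multi-FASTA file, optionally joining a metadata TSV.

    The metadata TSV must have a header line ``id<TAB>region<TAB>source``.
    Rows whose id does not occur in the FASTA are logged as a warning and
    ignored.  Sequences are upper-cased.
    """
    path = Path(path)
    seqs = list(SeqIO.parse(str(path), "fasta"))
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    meta: dict[str, tuple[str | None, str | None]] = {}
    if metadata_path is not None:
        meta = _read_metadata(Path(metadata_path))
    records = []
    for rec in seqs:
        region, source = meta.get(rec.id, (None, None))
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(),
                                      region=region, source=source))
    aln = Alignment(tuple(records))
    unmatched = set(meta) - set(aln.ids)
    if unmatched:
        logger.warning("metadata rows with no matching FASTA record: %s",
                       sorted(unmatched))
    return aln


def _read_metadata(path: Path) -> dict[str, tuple[str | None, str | None]]:
    meta = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:1] != ["id"]:
            raise ValueError(f"metadata TSV must start with an 'id' column, got {header}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            row = dict(zip(header, parts))
            meta[row["id"]] = (row.get("region") or None, row.get("source") or None)
    return meta


def write_fasta(aln: Alignment, path: str | Path, width: int = 70) -> None:
    """Write an alignment as wrapped multi-FASTA (deterministic byte output)."""
    with open(path, "w") as fh:
        for rec in aln.records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def write_metadata(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tregion\tsource\n")
        for rec in aln.records:
            fh.write(f"{rec.id}\t{rec.region or ''}\t{rec.source or ''}\n")


# ---------------------------------------------------------------------------
# QC and windowing


def qc_coding(aln: Alignment, frame_offset: int = 0) -> QCReport:
    """Scan for gap characters and internal stop codons (vertebrate mito code).

    ``frame_offset`` is the number of leading bases before the first complete
    codon.  A terminal partial codon is ignored.  Report-only: never raises on
    a failing alignment.
    """
    gaps: dict[str, list[int]] = {}
    stops: dict[str, list[int]] = {}
    for rec in aln.records:
        gap_pos = [i + 1 for i, ch in enumerate(rec.sequence) if ch == "-"]
        if gap_pos:
            gaps[rec.id] = gap_pos
        coding = rec.sequence[frame_offset:]
        n_codons = len(coding) // 3
        stop_idx = []
        for c in range(n_codons):
            codon = coding[3 * c:3 * c + 3]
            if any(is_missing(ch) for ch in codon):
                continue
            # vertebrate mitochondrial code, NCBI table 2; a stop is internal
            # unless it is the very last complete codon with nothing after it
            if str(Seq(codon).translate(table=2)) == "*":
                is_terminal = (c == n_codons - 1) and (len(coding) % 3 == 0)
                if not is_terminal:
                    stop_idx.append(c + 1)
        if stop_idx:
            stops[rec.id] = stop_idx
    return QCReport(passed=not gaps and not stops,
                    gap_positions=gaps, internal_stops=stops)


def trim_window(aln: Alignment, start: int, end: int) -> Alignment:
    """Restrict the alignment to 1-based inclusive positions [start, end]."""
    if not (1 <= start <= end <= aln.length):
        raise ValueError(
            f"window ({start}, {end}) out of range for alignment of length {aln.length}")
    offset = aln.window[0] - 1 if aln.window else 0
    records = tuple(replace(r, sequence=r.sequence[start - 1:end])
                    for r in aln.records)
    return Alignment(records, window=(offset + start, offset + end))


# ---------------------------------------------------------------------------
# Haplotypes and site classification


def collapse_haplotypes(aln: Alignment, strict: bool = True) -> HaplotypeTable:
    """Group identical sequences into haplotypes labelled H1..Hk by first occurrence.

    With ``strict=False``, two sequences that differ only at positions where at
    least one of them is missing are merged (the earlier sequence's haplotype
    absorbs the later one).
    """
    entries: list[list] = []  # [label, sequence, members]
    for rec in aln.records:
        hit = None
        for entry in entries:
            if rec.sequence == entry[1]:
                hit = entry
                break
            if not strict and _compatible_modulo_missing(rec.sequence, entry[1]):
                hit = entry
                break
        if hit is None:
            entries.append([f"H{len(entries) + 1}", rec.sequence, [rec.id]])
        else:
            hit[2].append(rec.id)
    return HaplotypeTable(tuple(
        (label, seq, len(members), tuple(members)) for label, seq, members in entries))


def _compatible_modulo_missing(a: str, b: str) -> bool:
    return all(x == y or is_missing(x) or is_missing(y) for x, y in zip(a, b))


def classify_sites(aln: Alignment) -> SiteClassification:
    """Classify each site as monomorphic, singleton, or parsimony-informative.

    A site is segregating when it shows >= 2 distinct non-missing states;
    parsimony-informative when >= 2 states each occur >= 2 times; otherwise
    (segregating but not informative) it is a singleton site.
    """
    cats = []
    seg_pos = []
    for pos in range(1, aln.length + 1):
        col = [c for c in aln.column(pos) if not is_missing(c)]
        counts = sorted((col.count(b) for b in set(col)), reverse=True)
        if len(counts) < 2:
            cats.append("monomorphic")
            continue
        seg_pos.append(pos)
        if sum(1 for c in counts if c >= 2) >= 2:
            cats.append("parsimony-informative")
        else:
            cats.append("singleton")
    return SiteClassification(tuple(cats), tuple(seg_pos))
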