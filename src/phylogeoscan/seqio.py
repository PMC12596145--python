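"""Sequence I/O and alignment.

FASTA reading/writing goes through Biopython; pairwise alignment is
Needleman-Wunsch / Smith-Waterman (affine gaps) via ``Bio.Align.PairwiseAligner``.
A multiple alignment is assembled from pairwise alignments as a reference-guided
star alignment with "once a gap, always a gap" propagation — a deliberately
simple, deterministic construction that is *not* equivalent to progressive MSA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "SequenceRecord",
    "Alignment",
    "ScoringScheme",
    "read_fasta",
    "write_fasta",
    "pairwise_align",
    "build_msa",
]

IUPAC_CHARS = frozenset("ACGTN-")

#: Alphabet known to the aligner. ``N`` scores as a mismatch against everything,
#: including another ``N`` (conservative: never inflates similarity). ``-`` is
#: included so the string metrics can score gapped window rows as ordinary
#: characters; raw input sequences normally contain no gaps.
_ALPHABET = "ACGTN-"


class FastaError(ValueError):
    """Malformed or invalid FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A labeled nucleotide sequence over {A, C, G, T, N, -}.

    Residues are upper-cased on construction; lower-case input is accepted.
    """

    label: str
    residues: str

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("sequence label must be nonempty")
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError(f"sequence {self.label!r} has no residues")
        bad = set(self.residues) - IUPAC_CHARS
        if bad:
            raise FastaError(
                f"sequence {self.label!r} contains non-IUPAC character(s): "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class Alignment:
    """An ordered set of equal-length gapped sequences with unique labels."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain at least one record")
        labels = [r.label for r in self.records]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate labels in alignment: {dupes}")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths in alignment: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.records == other.records

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)

    def slice_columns(self, start: int, end: int) -> "Alignment":
        if not (0 <= start < end <= self.length):
            raise IndexError(f"invalid column slice [{start}, {end}) for length {self.length}")
        return Alignment(
            [SequenceRecord(r.label, r.residues[start:end]) for r in self.records]
        )

    def take_columns(self, cols: list[int]) -> "Alignment":
        return Alignment(
            [
                SequenceRecord(r.label, "".join(r.residues[j] for j in cols))
                for r in self.records
            ]
        )


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring: match/mismatch and affine gap penalties.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``; both penalties
    are non-positive. ``mode`` selects global (Needleman-Wunsch) or local
    (Smith-Waterman) alignment.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5
    mode: str = "global"

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be non-positive")
        if self.mode not in ("global", "local"):
            raise ValueError(f"unknown alignment mode {self.mode!r}")


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into an ordered list of records.

    The label is the header text up to the first whitespace. Duplicate labels,
    empty files and non-IUPAC residues are errors.
    """
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except FileNotFoundError:
        raise
    if not parsed:
        raise FastaError(f"no FASTA records found in {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in parsed:
        if rec.id in seen:
            raise FastaError(f"duplicate label {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            records.append(SequenceRecord(rec.id, str(rec.seq)))
        except FastaError as exc:
            raise FastaError(f"{exc} (near line {_find_line(path, rec.id)} of {path})") from None
    return records


def _find_line(path, label: str) -> int:
    """1-based line number of the header for *label* (error reporting only)."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[:1] == [label]:
                return i
    return 0


def write_fasta(alignment_or_records, path, width: int = 60) -> None:
    """Write records to FASTA, wrapping sequence lines at *width* columns.

    Labels are written verbatim; a label containing whitespace will be
    truncated at that whitespace when re-read (FASTA header semantics).
    """
    records = getattr(alignment_or_records, "records", alignment_or_records)
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.label}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Pairwise alignment (Needleman-Wunsch / Smith-Waterman, affine gaps)
# ---------------------------------------------------------------------------


def _substitution_matrix(scheme: ScoringScheme):
    m = substitution_matrices.Array(_ALPHABET, dims=2)
    for x in _ALPHABET:
        for y in _ALPHABET:
            same = x == y and x != "N"  # N mismatches everything, incl. N
            m[x, y] = scheme.match if same else scheme.mismatch
    return m


def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = scheme.mode
    aligner.substitution_matrix = _substitution_matrix(scheme)
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


def alignment_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Optimal alignment score of two raw strings under *scheme*."""
    if scheme.mode == "global" and (not a or not b):
        raise ValueError("cannot align empty sequences")
    if not a or not b:
        return 0.0
    return float(_aligner(scheme).score(a, b))


def pairwise_align(
    a: SequenceRecord, b: SequenceRecord, scheme: ScoringScheme | None = None
) -> tuple[str, str, float]:
    """Optimally align two sequences; returns (gapped_a, gapped_b, score).

    Global mode returns a full-length aligned pair whose de-gapped rows equal
    the inputs; local mode returns the maximum-scoring local segment pair.
    Among co-optimal alignments the first one reported by the DP traceback is
    returned, which is deterministic.
    """
    scheme = scheme or ScoringScheme()
    if not a.residues or not b.residues:
        raise ValueError("cannot align empty sequences")
    aln = _aligner(scheme).align(a.residues, b.residues)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return ga, gb, float(aln.score)


# ---------------------------------------------------------------------------
# Star MSA: align everything to a reference, propagate reference gaps
# ---------------------------------------------------------------------------


def _reference_index(records: list[SequenceRecord], reference: str) -> int:
    if reference != "auto":
        for i, rec in enumerate(records):
            if rec.label == reference:
                return i
        raise ValueError(f"reference label {reference!r} not among input records")
    # longest sequence; ties broken by input order
    best = 0
    for i, rec in enumerate(records):
        if len(rec) > len(records[best]):
            best = i
    return best


def _gap_profile(ref_gapped: str, ref_len: int) -> list[int]:
    """Number of gap columns inserted before each reference residue (and at end)."""
    gaps = [0] * (ref_len + 1)
    pos = 0
    for ch in ref_gapped:
        if ch == "-":
            gaps[pos] += 1
        else:
            pos += 1
    return gaps


def build_msa(
    records: list[SequenceRecord],
    scheme: ScoringScheme | None = None,
    reference: str = "auto",
) -> Alignment:
    """Reference-guided star alignment.

    Each sequence is globally aligned to the reference (default: the longest
    input, ties to the first); gap columns any pairwise alignment inserts into
    the reference are merged ("once a gap, always a gap") and propagated to all
    rows, so every row ends up the same length.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 sequences to build an alignment")
    scheme = scheme or ScoringScheme()
    if scheme.mode != "global":
        scheme = ScoringScheme(
            scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend, "global"
        )
    records = [SequenceRecord(r.label, r.ungapped()) for r in records]
    ref_i = _reference_index(records, reference)
    ref = records[ref_i]
    L = len(ref)

    pairs: dict[int, tuple[str, str]] = {}
    master = [0] * (L + 1)
    for i, rec in enumerate(records):
        if i == ref_i:
            continue
        ga, gb, _ = pairwise_align(ref, rec, scheme)
        pairs[i] = (ga, gb)
        for p, g in enumerate(_gap_profile(ga, L)):
            master[p] = max(master[p], g)

    rows: list[SequenceRecord] = []
    for i, rec in enumerate(records):
        if i == ref_i:
            out: list[str] = []
            for p in range(L + 1):
                out.append("-" * master[p])
                if p < L:
                    out.append(ref.residues[p])
            rows.append(SequenceRecord(rec.label, "".join(out)))
            continue
        ga, gb = pairs[i]
        own = _gap_profile(ga, L)
        out = []
        k = 0  # cursor into the pairwise columns
        for p in range(L + 1):
            chunk = gb[k : k + own[p]]  # row chars in columns inserted before ref residue p
            k += own[p]
            out.append(chunk + "-" * (master[p] - own[p]))
            if p < L:
                out.append(gb[k])
                k += 1
        rows.append(SequenceRecord(rec.label, "".join(out)))

    # restore input order invariantly (rows were built in input order already)
    return Alignment(rows)
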