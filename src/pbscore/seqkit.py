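"""Sequence-level analysis of the phycobilisome-core subunits.

Translation of the apc gene CDSs, global alignment of subunit pairs
(alpha vs alphaII, beta vs beta18, alpha vs the PB domain of the
core-membrane linker), percent identity, conserved-cysteine mapping,
PB-loop insertion detection, hydroxylated-residue composition, a
PROSITE-subset motif scanner, and primer statistics.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from pathlib import Path
from typing import Iterable, NamedTuple

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord
from Bio.SeqUtils import MeltingTemp, gc_fraction

from . import config

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZ*")
NUCLEOTIDE_ALPHABET = set("ACGTUNRYSWKMBDHV")

GAP = "-"


class SequenceError(ValueError):
    pass


@dataclasses.dataclass
class SequenceRecord:
    """A named nucleotide or protein sequence (1-based residue numbering)."""

    id: str
    kind: str                      # "nucleotide" | "protein"
    residues: str
    annotations: list[tuple[int, str]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if self.kind not in ("nucleotide", "protein"):
            raise SequenceError(f"unknown kind {self.kind!r}")
        if not self.residues:
            raise SequenceError("empty sequence")
        alpha = (NUCLEOTIDE_ALPHABET if self.kind == "nucleotide"
                 else PROTEIN_ALPHABET)
        bad = set(self.residues) - alpha
        if bad:
            raise SequenceError(f"{self.id}: invalid {self.kind} "
                                f"letters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclasses.dataclass
class PairwiseAlignment:
    """Two gapped rows of equal length plus scoring metadata."""

    id_a: str
    id_b: str
    row_a: str
    row_b: str
    score: float
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise SequenceError("alignment rows differ in length")
        if any(a == GAP and b == GAP
               for a, b in zip(self.row_a, self.row_b)):
            raise SequenceError("gap/gap column in alignment")

    @property
    def seq_a(self) -> str:
        return self.row_a.replace(GAP, "")

    @property
    def seq_b(self) -> str:
        return self.row_b.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.row_a)


class MotifHit(NamedTuple):
    pattern_id: str
    start: int     # 1-based inclusive
    end: int       # 1-based inclusive
    matched: str


@dataclasses.dataclass
class PrimerStats:
    length: int
    gc_fraction: float
    tm_wallace: float
    tm_nn: float


# ---------------------------------------------------------------------------
# Translation

_STANDARD_BASES = set("ACGT")


def translate_cds(nt: SequenceRecord, frame: int = 1) -> SequenceRecord:
    """Translate a coding sequence with the standard genetic code.

    Translation stops at the first stop codon; a trailing partial codon is
    dropped.  Codons containing non-ACGT letters become 'X' with a warning.
    """
    if nt.kind != "nucleotide":
        raise SequenceError("translate_cds needs a nucleotide record")
    if frame not in (1, 2, 3):
        raise SequenceError("frame must be 1, 2 or 3")
    s = nt.residues.replace("U", "T")[frame - 1:]
    if len(s) < 3:
        raise SequenceError("fewer than one codon after frame offset")
    aas = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i:i + 3]
        if set(codon) - _STANDARD_BASES:
            warnings.warn(f"ambiguous codon {codon} at nt {i + 1} "
                          "translated as X")
            aas.append("X")
            continue
        aa = str(Seq(codon).translate())
        if aa == "*":
            break
        aas.append(aa)
    if not aas:
        raise SequenceError("translation is empty (leading stop codon)")
    return SequenceRecord(f"{nt.id}_translated", "protein", "".join(aas))


def reverse_complement(nt: SequenceRecord) -> SequenceRecord:
    return SequenceRecord(nt.id, "nucleotide",
                          str(Seq(nt.residues).reverse_complement()))


# ---------------------------------------------------------------------------
# Global alignment

def _aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load(matrix)
    al.open_gap_score = -abs(gap_open)
    al.extend_gap_score = -abs(gap_extend)
    return al


def global_align(a: SequenceRecord, b: SequenceRecord,
                 matrix: str = config.ALIGN_MATRIX,
                 gap_open: float = config.GAP_OPEN,
                 gap_extend: float = config.GAP_EXTEND) -> PairwiseAlignment:
    """Optimal global alignment (Needleman-Wunsch, affine gaps).

    The first optimal alignment in Biopython's deterministic traceback
    order is returned, so repeated calls are reproducible.
    """
    if a.kind != "protein" or b.kind != "protein":
        raise SequenceError("global_align expects protein records")
    al = _aligner(matrix, gap_open, gap_extend)
    result = al.align(a.residues, b.residues)
    best = result[0]
    return PairwiseAlignment(a.id, b.id, str(best[0]), str(best[1]),
                             float(best.score),
                             {"matrix": matrix, "gap_open": gap_open,
                              "gap_extend": gap_extend})


def percent_identity(aln: PairwiseAlignment) -> float:
    """100 x identical columns / columns where both rows are non-gap."""
    pairs = [(x, y) for x, y in zip(aln.row_a, aln.row_b)
             if x != GAP and y != GAP]
    if not pairs:
        return 0.0
    ident = sum(1 for x, y in pairs if x == y)
    return 100.0 * ident / len(pairs)


class MappedPosition(NamedTuple):
    pos_b: int | None      # 1-based position in sequence b, or None at a gap
    residue_b: str | None


def map_aligned_position(aln: PairwiseAlignment, pos_a: int) -> MappedPosition:
    """Map a 1-based position of sequence a to its alignment partner in b."""
    if not 1 <= pos_a <= len(aln.seq_a):
        raise SequenceError(f"position {pos_a} outside sequence a")
    ia = ib = 0
    for x, y in zip(aln.row_a, aln.row_b):
        if x != GAP:
            ia += 1
        if y != GAP:
            ib += 1
        if x != GAP and ia == pos_a:
            if y == GAP:
                return MappedPosition(None, None)
            return MappedPosition(ib, y)
    raise AssertionError("unreachable")


def detect_insertions(aln: PairwiseAlignment,
                      min_len: int = 1) -> list[tuple[str, int, int]]:
    """Maximal gap blocks per row with length >= min_len.

    Returns (row, start, length) triples, row in {"a", "b"}; *start* is the
    1-based alignment column of the first gap.  A gap block in row "a" is an
    insertion of sequence b relative to a.  Sorted by column.
    """
    out = []
    for row_name, row in (("a", aln.row_a), ("b", aln.row_b)):
        for m in re.finditer(rf"{GAP}+", row):
            if m.end() - m.start() >= min_len:
                out.append((row_name, m.start() + 1, m.end() - m.start()))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def residue_composition(seq: SequenceRecord, region: tuple[int, int],
                        residues: Iterable[str]) -> dict[str, int]:
    """Exact counts of the requested one-letter codes in the inclusive region."""
    start, end = region
    if start > end:
        raise SequenceError(f"inverted region {region}")
    if start < 1 or end > len(seq):
        raise SequenceError(f"region {region} outside sequence")
    sub = seq.residues[start - 1:end]
    return {r: sub.count(r) for r in residues}


# ---------------------------------------------------------------------------
# PROSITE-subset motif scanner
#
# Grammar subset: elements separated by '-'; an element is a residue letter,
# 'x' (any), '[..]' (allowed set) or '{..}' (excluded set), optionally
# followed by an (n) repeat.  Matching slides over every start position, so
# overlapping hits are reported.

_ELEMENT_RE = re.compile(
    r"^(?:(?P<letter>[A-Za-z])|\[(?P<inc>[A-Za-z]+)\]|\{(?P<exc>[A-Za-z]+)\})"
    r"(?:\((?P<rep>\d+)\))?$")


class PrositePatternError(ValueError):
    pass


def _compile_prosite(pattern: str) -> list[frozenset[str] | None]:
    """Compile to one matcher per position: a residue set, or None for 'any'."""
    positions: list[frozenset[str] | None] = []
    for token in pattern.strip().rstrip(".").split("-"):
        m = _ELEMENT_RE.match(token)
        if not m:
            raise PrositePatternError(f"malformed PROSITE token {token!r} "
                                      f"in pattern {pattern!r}")
        rep = int(m.group("rep") or 1)
        if m.group("letter"):
            letter = m.group("letter").upper()
            matcher = None if letter == "X" else frozenset(letter)
        elif m.group("inc"):
            matcher = frozenset(m.group("inc").upper())
        else:
            excluded = set(m.group("exc").upper())
            matcher = frozenset(set("ACDEFGHIKLMNPQRSTVWY") - excluded)
        positions.extend([matcher] * rep)
    if not positions:
        raise PrositePatternError(f"empty pattern {pattern!r}")
    return positions


def prosite_scan(seq: SequenceRecord,
                 patterns: dict[str, str] | None = None) -> list[MotifHit]:
    """Scan for PROSITE-style motifs; overlapping matches are all reported.

    Default patterns are the PKC and CK2 phosphosite consensus motifs.
    Hits are ordered by pattern id, then start position.
    """
    if patterns is None:
        patterns = config.PHOSPHOSITE_PATTERNS
    s = seq.residues
    hits: list[MotifHit] = []
    for pid in sorted(patterns):
        matchers = _compile_prosite(patterns[pid])
        w = len(matchers)
        for start in range(len(s) - w + 1):
            window = s[start:start + w]
            if all(m is None or c in m for m, c in zip(matchers, window)):
                hits.append(MotifHit(pid, start + 1, start + w, window))
    return hits


# ---------------------------------------------------------------------------
# Primers

def primer_stats(primer: SequenceRecord) -> PrimerStats:
    """Length, GC fraction, Wallace Tm and nearest-neighbor Tm of a primer.

    Tm_NN uses the Allawi & SantaLucia (1997) table at Biopython's standard
    conditions (50 mM Na+, 25 nM each strand).
    """
    if primer.kind != "nucleotide":
        raise SequenceError("primer must be a nucleotide record")
    s = primer.residues
    if set(s) - _STANDARD_BASES:
        raise SequenceError(f"primer contains non-ACGT letters: "
                            f"{sorted(set(s) - _STANDARD_BASES)}")
    return PrimerStats(
        length=len(s),
        gc_fraction=gc_fraction(s),
        tm_wallace=float(MeltingTemp.Tm_Wallace(s)),
        tm_nn=float(MeltingTemp.Tm_NN(s)),
    )


# ---------------------------------------------------------------------------
# FASTA I/O

def read_fasta(path: str | Path, kind: str) -> list[SequenceRecord]:
    recs = [SequenceRecord(r.id, kind, str(r.seq))
            for r in SeqIO.parse(str(path), "fasta")]
    if not recs:
        raise SequenceError(f"no FASTA records in {path}")
    return recs


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [_BioRecord(Seq(r.residues), id=r.id, description="")
           for r in records]
    SeqIO.write(bio, str(path), "fasta")


def alignment_summary(aln: PairwiseAlignment) -> dict:
    """Tab-friendly summary: ids, score, identity %, gap columns."""
    gaps = sum(1 for x, y in zip(aln.row_a, aln.row_b)
               if x == GAP or y == GAP)
    return {"id_a": aln.id_a, "id_b": aln.id_b, "score": aln.score,
            "identity_pct": percent_identity(aln), "gap_columns": gaps,
            "columns": len(aln)}
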