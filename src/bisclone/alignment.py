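"""Alignment of bisulfite reads to an in-silico converted reference.

Bisulfite treatment converts unmethylated cytosine to uracil (read as T after
PCR) while 5-methylcytosine stays C.  In a CpG-centred analysis the reference
is therefore converted in silico: every cytosine *not* followed by guanine is
replaced by T, while CpG cytosines are kept as C because they may legitimately
read either C (methylated) or T (unmethylated).  Reads are aligned to this
converted reference with a bisulfite-aware scoring scheme in which a read T
opposite a reference CpG-C scores as a match, so the methylation state of a
molecule does not bias its alignment.

Each read is aligned in both orientations (the sequencing vector inserts
molecules in random direction); the better-scoring orientation wins and read
bases that fall outside the reference span (cloning-vector sequence) are
trimmed.  The per-read pairwise alignments are then merged into one shared
gapped coordinate frame, either by stitching (taking, at each reference
position, the longest read insertion observed) or by a centre-star progressive
merge with the converted reference as the hub.  With the reference as the
centre both strategies produce the same frame; the configured mode is recorded
and drives the automatic fallback rule for CpG sites sitting behind a
T-homopolymer near a reference end, where T-stretch indel artifacts are
common.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import reverse_complement

from .errors import UnalignableReadError

DNA_ALPHABET = "ACGTN"

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class AlignParams:
    """Scoring and heuristic parameters for read-to-reference alignment.

    ``match``/``mismatch``/``gap_open``/``gap_extend`` follow the usual affine
    convention: a gap of length L costs ``gap_open + L * gap_extend``.  End
    gaps are free on both sequences so that partial reads and vector overhangs
    are not penalised.  A read whose best orientation scores below
    ``min_score_per_bp * min(len(read), len(reference))`` is flagged
    unalignable.

    ``end_window`` and ``tstretch_min`` parameterise the automatic fallback to
    a multiple-alignment merge: it triggers when a CpG lies within
    ``end_window`` bases of a reference end and is immediately preceded (5' in
    the converted reference) by a T-homopolymer of at least ``tstretch_min``
    bases.  ``check_both_ends=False`` restricts the rule to the 3' end.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    min_score_per_bp: float = 0.25
    end_window: int = 30
    tstretch_min: int = 4
    check_both_ends: bool = True
    max_tie_candidates: int = 32


@dataclass(frozen=True)
class ReferenceRecord:
    """Original and in-silico converted reference with indexed cytosines."""

    id: str
    original: str
    converted: str
    cpg_positions: tuple[int, ...]
    noncpg_c_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.converted) != len(self.original):
            raise ValueError("converted reference must have the reference length")

    @property
    def length(self) -> int:
        return len(self.original)

    @property
    def cpg_set(self) -> frozenset[int]:
        return frozenset(self.cpg_positions)

    @property
    def noncpg_c_set(self) -> frozenset[int]:
        return frozenset(self.noncpg_c_positions)


def convert_reference(ref_id: str, seq: str) -> ReferenceRecord:
    """Apply in-silico bisulfite conversion to a reference sequence.

    Every C not followed by G becomes T (full conversion of unmethylated
    non-CpG cytosines is assumed); CpG cytosines are preserved.  A terminal C
    has no following G and is converted.
    """
    seq = seq.upper()
    if len(seq) < 2:
        raise ValueError("reference must be at least 2 bp long")
    bad = set(seq) - set(DNA_ALPHABET)
    if bad:
        raise ValueError(f"reference contains non-ACGTN characters: {sorted(bad)}")
    converted = list(seq)
    cpg: list[int] = []
    noncpg: list[int] = []
    for i, base in enumerate(seq):
        if base != "C":
            continue
        if i + 1 < len(seq) and seq[i + 1] == "G":
            cpg.append(i)
        else:
            noncpg.append(i)
            converted[i] = "T"
    return ReferenceRecord(
        id=ref_id,
        original=seq,
        converted="".join(converted),
        cpg_positions=tuple(cpg),
        noncpg_c_positions=tuple(noncpg),
    )


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped pairwise alignment (reference row first)."""

    ref_gapped: str
    read_gapped: str
    score: float

    def __post_init__(self) -> None:
        if len(self.ref_gapped) != len(self.read_gapped):
            raise ValueError("alignment rows must have equal length")

    @property
    def ref_ungapped(self) -> str:
        return self.ref_gapped.replace("-", "")

    @property
    def read_ungapped(self) -> str:
        return self.read_gapped.replace("-", "")


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    mat = substitution_matrices.Array(DNA_ALPHABET, dims=2)
    for a in "ACGT":
        for b in "ACGT":
            mat[a, b] = params.match if a == b else params.mismatch
    # Bisulfite-aware: read T opposite a reference C (only CpG cytosines stay
    # C after conversion) is a legitimate unmethylated state, not a mismatch.
    mat["C", "T"] = params.match
    for x in DNA_ALPHABET:
        mat["N", x] = 0.0
        mat[x, "N"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    # free end gaps on both rows (vector overhang / partial coverage)
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def _gap_key(ref_row: str, read_row: str) -> tuple:
    gap_cols = [i for i, (a, b) in enumerate(zip(ref_row, read_row)) if a == "-" or b == "-"]
    return (len(gap_cols), tuple(gap_cols))


def pairwise_align(a: str, b: str, params: AlignParams | None = None) -> PairwiseAlignment:
    """Optimal global alignment of read ``b`` against reference ``a``.

    End gaps are free on both sequences.  Ties between co-optimal alignments
    are broken deterministically: fewest gap columns first (i.e. mismatch
    preferred over gap), then leftmost gap placement.
    """
    params = params or AlignParams()
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(params)
    alignments = aligner.align(a.upper(), b.upper())
    best = None
    best_key = None
    for aln in itertools.islice(alignments, params.max_tie_candidates):
        ref_row, read_row = str(aln[0]), str(aln[1])
        key = _gap_key(ref_row, read_row)
        if best_key is None or key < best_key:
            best, best_key = (ref_row, read_row, aln.score), key
    assert best is not None
    return PairwiseAlignment(ref_gapped=best[0], read_gapped=best[1], score=float(best[2]))


def _trim_to_reference(aln: PairwiseAlignment) -> PairwiseAlignment:
    """Drop alignment columns outside the reference span (vector/adapter)."""
    ref = aln.ref_gapped
    first = len(ref) - len(ref.lstrip("-"))
    last = len(ref.rstrip("-"))
    return PairwiseAlignment(
        ref_gapped=ref[first:last],
        read_gapped=aln.read_gapped[first:last],
        score=aln.score,
    )


def orient_and_trim(
    read_id: str,
    sequence: str,
    ref: ReferenceRecord,
    params: AlignParams | None = None,
) -> tuple[str, str, PairwiseAlignment]:
    """Determine read orientation and trim vector overhang.

    Aligns the read and its reverse complement to the converted reference; the
    higher-scoring orientation wins (forward on ties).  Read bases aligned
    outside the reference span are trimmed.  Returns
    ``(oriented_trimmed_read, orientation, alignment)``.

    Raises :class:`UnalignableReadError` when both orientations score below
    the floor ``min_score_per_bp * min(len(read), len(reference))``.
    """
    params = params or AlignParams()
    sequence = sequence.upper()
    if not sequence:
        raise ValueError(f"read {read_id!r} is empty")
    fwd = pairwise_align(ref.converted, sequence, params)
    rev = pairwise_align(ref.converted, reverse_complement(sequence), params)
    orientation, aln = (FORWARD, fwd) if fwd.score >= rev.score else (REVERSE, rev)
    floor = params.min_score_per_bp * min(len(sequence), ref.length)
    if aln.score < floor:
        raise UnalignableReadError(
            f"read {read_id!r}: best alignment score {aln.score:.1f} below floor {floor:.1f}"
        )
    trimmed = _trim_to_reference(aln)
    return trimmed.read_ungapped, orientation, trimmed


@dataclass
class AlignedRead:
    """A read placed in the shared gapped coordinate frame."""

    read_id: str
    columns: str
    orientation: str
    col_of_refpos: dict[int, int] = field(repr=False)
    ref_row: str = field(repr=False)

    @property
    def ungapped(self) -> str:
        return self.columns.replace("-", "")

    def base_at_ref(self, refpos: int) -> str:
        return self.columns[self.col_of_refpos[refpos]]

    def prev_read_base(self, col: int) -> str | None:
        """Previous non-gap read base strictly 5' of ``col`` (read coordinates)."""
        for i in range(col - 1, -1, -1):
            if self.columns[i] != "-":
                return self.columns[i]
        return None

    def span_cols(self) -> tuple[int, int] | None:
        """(first, last) columns covered by the read, or None if empty."""
        stripped = self.columns.strip("-")
        if not stripped:
            return None
        first = len(self.columns) - len(self.columns.lstrip("-"))
        return first, first + len(stripped) - 1


@dataclass
class MultiAlignment:
    """All reads in one gapped frame anchored on the converted reference."""

    reference_row: str
    rows: list[AlignedRead]
    mode: str
    col_of_refpos: dict[int, int] = field(repr=False)

    def refpos_of_col(self) -> dict[int, int]:
        out = {}
        pos = -1
        for col, base in enumerate(self.reference_row):
            if base != "-":
                pos += 1
                out[col] = pos
        return out


@dataclass(frozen=True)
class OrientedRead:
    """Output of :func:`orient_and_trim`, input to :func:`build_alignment`."""

    read_id: str
    orientation: str
    alignment: PairwiseAlignment


def _parse_pairwise(aln: PairwiseAlignment) -> tuple[dict[int, str], dict[int, str]]:
    """Split a trimmed pairwise alignment into per-reference-position bases
    and insertion strings keyed by the preceding reference position."""
    base_at: dict[int, str] = {}
    insertions: dict[int, str] = {}
    pos = -1
    for r, q in zip(aln.ref_gapped, aln.read_gapped):
        if r != "-":
            pos += 1
            base_at[pos] = q
        else:
            insertions[pos] = insertions.get(pos, "") + q
    return base_at, insertions


def _merge(oriented: list[OrientedRead], ref: ReferenceRecord) -> tuple[str, list[AlignedRead], dict[int, int]]:
    parsed = [_parse_pairwise(o.alignment) for o in oriented]
    ins_len: dict[int, int] = {}
    for _, ins in parsed:
        for p, s in ins.items():
            ins_len[p] = max(ins_len.get(p, 0), len(s))
    conv = ref.converted
    ref_parts: list[str] = []
    col_of_refpos: dict[int, int] = {}
    col = 0
    if -1 in ins_len:  # insertions before the first reference base
        ref_parts.append("-" * ins_len[-1])
        col += ins_len[-1]
    for p in range(len(conv)):
        col_of_refpos[p] = col
        block = conv[p] + "-" * ins_len.get(p, 0)
        ref_parts.append(block)
        col += len(block)
    reference_row = "".join(ref_parts)
    rows: list[AlignedRead] = []
    for o, (base_at, ins) in zip(oriented, parsed):
        parts: list[str] = []
        if -1 in ins_len:
            s = ins.get(-1, "")
            parts.append(s + "-" * (ins_len[-1] - len(s)))
        for p in range(len(conv)):
            s = ins.get(p, "")
            # insertions are left-aligned within their block
            parts.append(base_at.get(p, "-") + s + "-" * (ins_len.get(p, 0) - len(s)))
        rows.append(
            AlignedRead(
                read_id=o.read_id,
                columns="".join(parts),
                orientation=o.orientation,
                col_of_refpos=col_of_refpos,
                ref_row=reference_row,
            )
        )
    return reference_row, rows, col_of_refpos


def needs_msa_fallback(ref: ReferenceRecord, params: AlignParams | None = None) -> bool:
    """True when a CpG near a reference end sits behind a T-stretch.

    T-homopolymers generated by conversion are prone to polymerase slippage;
    when the affected CpG is close to a PCR-product end the independent
    pairwise alignments tend to misplace the terminal indel, so a joint
    multiple-alignment merge is preferred.
    """
    params = params or AlignParams()
    conv = ref.converted
    n = len(conv)
    for c in ref.cpg_positions:
        near_3p = (n - 1 - (c + 1)) < params.end_window
        near_5p = c < params.end_window
        if not (near_3p or (params.check_both_ends and near_5p)):
            continue
        run = 0
        i = c - 1
        while i >= 0 and conv[i] == "T":
            run += 1
            i -= 1
        if run >= params.tstretch_min:
            return True
    return False


def build_alignment(
    oriented: list[OrientedRead],
    ref: ReferenceRecord,
    mode: str = "auto",
    params: AlignParams | None = None,
) -> MultiAlignment:
    """Merge per-read pairwise alignments into one shared frame.

    ``mode``:

    * ``stitched`` — batch merge: at each reference position the frame opens
      the longest insertion observed in any read.
    * ``msa`` — centre-star progressive merge around the converted reference
      ("once a gap, always a gap").  With the reference as the star centre
      this produces the same frame as stitching; the mode is recorded for the
      run report.
    * ``auto`` — ``msa`` iff :func:`needs_msa_fallback`, else ``stitched``.
    """
    if not oriented:
        raise ValueError("need at least one read to build an alignment")
    if mode not in ("auto", "stitched", "msa"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    if mode == "auto":
        mode = "msa" if needs_msa_fallback(ref, params) else "stitched"
    reference_row, rows, col_of_refpos = _merge(oriented, ref)
    return MultiAlignment(
        reference_row=reference_row, rows=rows, mode=mode, col_of_refpos=col_of_refpos
    )
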