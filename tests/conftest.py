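"""Shared fixtures and independent test oracles.

Fixtures build synthetic inputs programmatically (no stored data files):
hand-constructed alignment frames for call-logic truth tables, minimal
ABIF binary traces for the AB1 reader, and small simulated datasets.
"""

from __future__ import annotations

import io
import struct

import pytest

from bisclone.alignment import AlignedRead, MultiAlignment, ReferenceRecord, convert_reference


# ---------------------------------------------------------------------------
# hand-built alignment frames
# ---------------------------------------------------------------------------

def manual_frame(ref: ReferenceRecord, ref_row: str, reads: dict[str, str]) -> MultiAlignment:
    """Construct a MultiAlignment directly from gapped row strings.

    ``ref_row`` must ungap to the converted reference; every read row must
    have the same length.  Used to exercise call logic on exact column
    layouts without going through the aligner.
    """
    assert ref_row.replace("-", "") == ref.converted
    col_of_refpos = {}
    pos = -1
    for col, base in enumerate(ref_row):
        if base != "-":
            pos += 1
            col_of_refpos[pos] = col
    rows = []
    for rid, row in reads.items():
        assert len(row) == len(ref_row), f"row {rid} length mismatch"
        rows.append(
            AlignedRead(
                read_id=rid,
                columns=row,
                orientation="forward",
                col_of_refpos=col_of_refpos,
                ref_row=ref_row,
            )
        )
    return MultiAlignment(
        reference_row=ref_row, rows=rows, mode="stitched", col_of_refpos=col_of_refpos
    )


# ---------------------------------------------------------------------------
# brute-force pairwise alignment oracle
# ---------------------------------------------------------------------------

def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (row_a, row_b) pairs."""
    if not a and not b:
        yield ("", "")
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield (a[0] + ra, "-" + rb)
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield ("-" + ra, b[0] + rb)
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield (a[0] + ra, b[0] + rb)


def score_alignment(
    row_a: str,
    row_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
    free_end_gaps: bool = True,
    cpg_ref_c: set[int] | None = None,
) -> float:
    """Column-by-column score with linear gap costs and free end gaps.

    ``cpg_ref_c`` optionally holds reference positions where a read T scores
    as a match (bisulfite-aware scoring of CpG cytosines).
    """
    n = len(row_a)
    interior = set(range(n))
    if free_end_gaps:
        for row in (row_a, row_b):
            lead = len(row) - len(row.lstrip("-"))
            trail = len(row) - len(row.rstrip("-"))
            interior -= set(range(lead))
            interior -= set(range(n - trail, n))
    score = 0.0
    refpos = -1
    for i, (x, y) in enumerate(zip(row_a, row_b)):
        if x != "-":
            refpos += 1
        if i not in interior:
            continue
        if x == "-" or y == "-":
            score += gap
        elif x == y or (cpg_ref_c is not None and refpos in cpg_ref_c and y in "CT"):
            score += match
        else:
            score += mismatch
    return score


def best_alignments_bruteforce(a: str, b: str, **score_kwargs):
    """All optimal global alignments of two short strings, with their score."""
    scored = [
        (score_alignment(ra, rb, **score_kwargs), ra, rb)
        for ra, rb in enumerate_alignments(a, b)
    ]
    best = max(s for s, _, _ in scored)
    return best, [(ra, rb) for s, ra, rb in scored if s == best]


# ---------------------------------------------------------------------------
# minimal ABIF trace builder
# ---------------------------------------------------------------------------

def make_abif(tags: list[tuple[bytes, int, bytes]]) -> bytes:
    """Serialise a minimal ABIF trace holding char-typed tags.

    ``tags`` is a list of (name, tag_number, payload) triples; payloads of
    four bytes or fewer are stored inline in the directory entry per the
    ABIF layout.
    """
    blob = b""
    offsets = []
    cur = 128
    for _, _, data in tags:
        if len(data) <= 4:
            offsets.append(data.ljust(4, b"\0"))
        else:
            offsets.append(struct.pack(">i", cur))
            blob += data
            cur += len(data)
    out = io.BytesIO()
    out.write(b"ABIF")
    out.write(struct.pack(">h", 101))
    out.write(
        b"tdir"
        + struct.pack(">ihhiiii", 1, 1023, 28, len(tags), len(tags) * 28, cur, 0)
    )
    out.write(b"\0" * (128 - out.tell()))
    out.write(blob)
    for (name, num, data), off in zip(tags, offsets):
        out.write(
            name
            + struct.pack(">ihhii", num, 2, 1, len(data), len(data))
            + off
            + struct.pack(">i", 0)
        )
    return out.getvalue()


@pytest.fixture
def abif_with_edit(tmp_path):
    """Trace carrying both edited (PBAS1) and primary (PBAS2) basecalls."""
    path = tmp_path / "edited.ab1"
    path.write_bytes(make_abif([(b"PBAS", 1, b"ACGT"), (b"PBAS", 2, b"ACGA")]))
    return path


@pytest.fixture
def abif_primary_only(tmp_path):
    """Trace carrying only the primary basecalls."""
    path = tmp_path / "primary.ab1"
    path.write_bytes(make_abif([(b"PBAS", 2, b"TTGA")]))
    return path


# ---------------------------------------------------------------------------
# small reference fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def small_ref() -> ReferenceRecord:
    """14 bp reference with one CpG behind a T-stretch and two non-CpG Cs."""
    return convert_reference("small", "CAATTTCGAATGCA")


@pytest.fixture
def plain_ref() -> ReferenceRecord:
    """Reference with a single CpG and no other cytosines."""
    return convert_reference("plain", "AACGAA")
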