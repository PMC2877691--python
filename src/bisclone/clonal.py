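"""Detection and removal of clonal PCR duplicates.

PCR over-amplification of a single bisulfite-converted template yields
several identical subclones that would bias methylation statistics.  Each
read is reduced to its cytosine pattern — the methylation state at every CpG
site plus the conversion state (converted T vs. unconverted artifact C) at
every non-CpG cytosine — and patterns are compared pairwise.  Positions where
a read has an unresolved basecall (N) are ignored during comparison, since N
marks poor sequencing quality, not a different molecule.

Two molecules with identical patterns may nevertheless be independent
templates that genuinely share a methylation pattern — common in highly
methylated or fully unmethylated regions.  A shared *conversion artifact* at
the same non-CpG position, in contrast, is strong evidence of clonal origin
because incomplete conversion strikes random positions.  Hence two modes:

* ``strict``  — keep one representative per identical-pattern group.
* ``suggested`` — remove a group member only if it shares at least one
  conversion artifact position with the representative; identical patterns
  confined to CpG sites are all kept.
* ``off`` — keep everything.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import AlignedRead, ReferenceRecord

CONVERTED = "c"
ARTIFACT = "a"
OTHER = "."

KEPT_UNIQUE = "unique_pattern"
KEPT_REPRESENTATIVE = "kept_representative"
REMOVED_CLONAL = "removed_clonal"
KEPT_CPG_ONLY = "kept_cpg_only_match"

MODES = ("suggested", "strict", "off")


@dataclass(frozen=True)
class CytosinePattern:
    """Per-cytosine symbol vector used for duplicate detection.

    ``positions`` covers every reference cytosine (CpG and non-CpG) in
    ascending order.  CpG positions carry the methylation call (M/U/X);
    non-CpG cytosines carry 'c' (converted, read T), 'a' (conversion
    artifact, read C) or '.' (anything else).  ``n_mask`` holds positions
    where the read base is N.
    """

    read_id: str
    positions: tuple[int, ...]
    symbols: str
    n_mask: frozenset[int]

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.symbols):
            raise ValueError("one symbol per cytosine position required")

    def symbol_at(self, pos: int) -> str:
        return self.symbols[self.positions.index(pos)]


@dataclass(frozen=True)
class ClonalDecision:
    read_id: str
    kept: bool
    group_id: int | None
    reason: str


def cytosine_pattern(
    row: AlignedRead, ref: ReferenceRecord, calls: dict[int, str] | list[str]
) -> CytosinePattern:
    """Build the cytosine pattern of one read from its calls and alignment.

    ``calls`` maps CpG position -> call, or is a list parallel to
    ``ref.cpg_positions``.
    """
    if not isinstance(calls, dict):
        calls = dict(zip(ref.cpg_positions, calls))
    positions = tuple(sorted(ref.cpg_positions + ref.noncpg_c_positions))
    cpg = ref.cpg_set
    symbols = []
    n_mask = set()
    for pos in positions:
        base = row.base_at_ref(pos)
        if base == "N":
            n_mask.add(pos)
        if pos in cpg:
            symbols.append(calls[pos])
        else:
            if base == "T":
                symbols.append(CONVERTED)
            elif base == "C":
                symbols.append(ARTIFACT)
            else:
                symbols.append(OTHER)
    return CytosinePattern(
        read_id=row.read_id,
        positions=positions,
        symbols="".join(symbols),
        n_mask=frozenset(n_mask),
    )


def patterns_match(p: CytosinePattern, q: CytosinePattern) -> bool:
    """True iff the symbols agree everywhere outside either read's N-mask."""
    if p.positions != q.positions:
        raise ValueError("patterns were built over different references")
    masked = p.n_mask | q.n_mask
    return all(
        a == b
        for pos, a, b in zip(p.positions, p.symbols, q.symbols)
        if pos not in masked
    )


def _shares_artifact(p: CytosinePattern, q: CytosinePattern) -> bool:
    masked = p.n_mask | q.n_mask
    return any(
        a == ARTIFACT and b == ARTIFACT
        for pos, a, b in zip(p.positions, p.symbols, q.symbols)
        if pos not in masked
    )


def _group(patterns: list[CytosinePattern]) -> list[list[int]]:
    """Transitive closure of pairwise matches (union-find).

    N-wildcard matching is not transitive, so groups are the connected
    components of the match graph; the earliest read of each component is its
    representative.
    """
    n = len(patterns)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if patterns_match(patterns[i], patterns[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [groups[r] for r in sorted(groups)]


def classify_clonal(patterns: list[CytosinePattern], mode: str = "suggested") -> list[ClonalDecision]:
    """Decide, per read, whether it is kept or removed as a PCR duplicate.

    The representative of each group is the earliest read in input order and
    is always kept; every duplicate group keeps at least one member.
    Decisions are returned in input order.
    """
    if mode not in MODES:
        raise ValueError(f"unknown clonal mode {mode!r}")
    if mode == "off":
        return [ClonalDecision(p.read_id, True, None, KEPT_UNIQUE) for p in patterns]
    decisions: dict[int, ClonalDecision] = {}
    for group in _group(patterns):
        rep = group[0]
        if len(group) == 1:
            decisions[rep] = ClonalDecision(patterns[rep].read_id, True, None, KEPT_UNIQUE)
            continue
        gid = rep
        decisions[rep] = ClonalDecision(patterns[rep].read_id, True, gid, KEPT_REPRESENTATIVE)
        for i in group[1:]:
            if mode == "strict":
                decisions[i] = ClonalDecision(patterns[i].read_id, False, gid, REMOVED_CLONAL)
            else:  # suggested
                if _shares_artifact(patterns[rep], patterns[i]):
                    decisions[i] = ClonalDecision(patterns[i].read_id, False, gid, REMOVED_CLONAL)
                else:
                    decisions[i] = ClonalDecision(patterns[i].read_id, True, gid, KEPT_CPG_ONLY)
    return [decisions[i] for i in range(len(patterns))]


def apply_overrides(
    decisions: list[ClonalDecision],
    keep_ids: set[str] | None = None,
    drop_ids: set[str] | None = None,
) -> list[ClonalDecision]:
    """User-supplied include/exclude lists override automatic decisions."""
    keep_ids = keep_ids or set()
    drop_ids = drop_ids or set()
    out = []
    for d in decisions:
        if d.read_id in drop_ids:
            out.append(ClonalDecision(d.read_id, False, d.group_id, "user_excluded"))
        elif d.read_id in keep_ids:
            out.append(ClonalDecision(d.read_id, True, d.group_id, "user_included"))
        else:
            out.append(d)
    return out
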