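"""CpG methylation calling and summary statistics.

A CpG site is called per read by first verifying that the read carries a
guanine in the column aligned to the reference CpG's G.  Only then is the
read's previous non-gap base in 5' direction (read coordinates, skipping
alignment gaps) interpreted: C means methylated, T unmethylated, anything
else — A, G, N, a gap, or no preceding base — gives "unknown".  Checking the
G first avoids annotating mutated or miscalled sites (TA, TT, TN, CN...) as
methylation states, and taking the previous *read* base rather than the base
in the reference-C column makes the call robust to thymine insertions or
deletions produced by polymerase slippage in T-stretches.

Per-site averages are only reported when at least ``min_site_n`` (default 5)
reads are informative at the site, which avoids propagating weak data points.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import AlignedRead, MultiAlignment, ReferenceRecord

METHYLATED = "M"
UNMETHYLATED = "U"
UNKNOWN = "X"


def find_cpg_sites(ref: ReferenceRecord) -> list[int]:
    """0-based positions i with original[i:i+2] == 'CG'."""
    seq = ref.original
    sites = [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]
    assert tuple(sites) == ref.cpg_positions
    return sites


def call_cpg(row: AlignedRead, site: int, ref: ReferenceRecord) -> str:
    """Methylation call for one read at one reference CpG position."""
    if site not in ref.cpg_set:
        raise ValueError(f"position {site} is not a CpG cytosine in the reference")
    g_col = row.col_of_refpos[site + 1]
    if row.columns[g_col] != "G":
        return UNKNOWN
    prev = row.prev_read_base(g_col)
    if prev == "C":
        return METHYLATED
    if prev == "T":
        return UNMETHYLATED
    return UNKNOWN


@dataclass
class CallMatrix:
    """Clone x CpG-site grid of calls ('M'/'U'/'X')."""

    site_positions: list[int]
    clone_ids: list[str]
    calls: list[list[str]]

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.clone_ids):
            raise ValueError("one call row per clone required")
        for row in self.calls:
            if len(row) != len(self.site_positions):
                raise ValueError("one call per site required")

    def row(self, clone_id: str) -> list[str]:
        return self.calls[self.clone_ids.index(clone_id)]

    def column(self, site_index: int) -> list[str]:
        return [row[site_index] for row in self.calls]

    def subset(self, clone_ids: list[str]) -> "CallMatrix":
        index = {cid: i for i, cid in enumerate(self.clone_ids)}
        return CallMatrix(
            site_positions=list(self.site_positions),
            clone_ids=list(clone_ids),
            calls=[list(self.calls[index[cid]]) for cid in clone_ids],
        )


def call_all(aln: MultiAlignment, ref: ReferenceRecord) -> CallMatrix:
    sites = list(ref.cpg_positions)
    calls = [[call_cpg(row, s, ref) for s in sites] for row in aln.rows]
    return CallMatrix(
        site_positions=sites,
        clone_ids=[row.read_id for row in aln.rows],
        calls=calls,
    )


def per_clone_mean(row: list[str]) -> float | None:
    """Percent methylation over a clone's informative sites (None if none)."""
    m = row.count(METHYLATED)
    u = row.count(UNMETHYLATED)
    if m + u == 0:
        return None
    return 100.0 * m / (m + u)


@dataclass
class SummaryStats:
    per_site: dict[int, tuple[int, int, float | None]]  # pos -> (n_informative, n_meth, pct|None)
    per_clone: dict[str, float | None]
    overall_pct: float | None
    informative_pct: float | None
    n_methylated: int
    n_unmethylated: int
    n_unknown: int
    per_site_informative_counts: dict[int, int]


def summarize(matrix: CallMatrix, min_site_n: int = 5) -> SummaryStats:
    """Overall, per-site and per-clone methylation statistics.

    Per-site percentages are suppressed (None) at sites with fewer than
    ``min_site_n`` informative reads.  "Informative" counts only M and U
    calls; unknowns carry no methylation information.
    """
    n_m = n_u = n_x = 0
    per_site: dict[int, tuple[int, int, float | None]] = {}
    informative_counts: dict[int, int] = {}
    for j, pos in enumerate(matrix.site_positions):
        col = matrix.column(j)
        m = col.count(METHYLATED)
        u = col.count(UNMETHYLATED)
        n_m += m
        n_u += u
        n_x += col.count(UNKNOWN)
        informative_counts[pos] = m + u
        pct = 100.0 * m / (m + u) if (m + u) >= min_site_n and (m + u) > 0 else None
        per_site[pos] = (m + u, m, pct)
    per_clone = {cid: per_clone_mean(matrix.row(cid)) for cid in matrix.clone_ids}
    total = n_m + n_u + n_x
    overall = 100.0 * n_m / (n_m + n_u) if (n_m + n_u) else None
    informative = 100.0 * (n_m + n_u) / total if total else None
    return SummaryStats(
        per_site=per_site,
        per_clone=per_clone,
        overall_pct=overall,
        informative_pct=informative,
        n_methylated=n_m,
        n_unmethylated=n_u,
        n_unknown=n_x,
        per_site_informative_counts=informative_counts,
    )


def sort_by_methylation(matrix: CallMatrix, enabled: bool = True) -> CallMatrix:
    """Order clones by descending per-clone methylation (stable on ties).

    Clones without any informative site sort last; with ``enabled=False`` the
    input order is preserved.
    """
    if not enabled:
        return matrix
    keyed = []
    for i, cid in enumerate(matrix.clone_ids):
        mean = per_clone_mean(matrix.calls[i])
        keyed.append((0 if mean is not None else 1, -(mean or 0.0), i, cid))
    keyed.sort()
    return matrix.subset([k[3] for k in keyed])
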