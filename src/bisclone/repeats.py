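"""Consensus-based methylation analysis of repetitive elements.

Repeat families (e.g. Alu) occur in thousands of diverged genomic copies, so
an amplified molecule cannot be compared against a defined genomic reference;
reads are aligned to the family consensus instead.  Two complications follow:
an observed TG at a consensus CpG cannot be distinguished from a CpG that is
genomically mutated to TG, and reads may carry CpG sites absent from the
consensus.

Two strategies are provided:

1. *Methylated-CpG extraction*: every read position showing C immediately
   followed (next non-gap read base) by G is recorded as a methylated CpG,
   flagged by whether its column aligns to a consensus CpG cytosine.
   Per-read counts, per-100-bp rates and count distributions summarise the
   data without assuming a per-site reference.

2. *Mutation-corrected overall methylation* (after Yang et al. 2004): at
   consensus CpG positions, the CG -> CA count estimates the CG -> TG
   mutation rate of the sequenced strand (a CA arises from a CG -> TG
   exchange on the opposite strand, and strand mutation rates are assumed
   symmetric).  The unmethylated tally is corrected by subtracting the
   estimated mutated fraction from the TG count before computing
   ``100 * CG / (CG + TG_corrected)``.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

from .alignment import AlignedRead, MultiAlignment, ReferenceRecord


@dataclass(frozen=True)
class RepeatReadResult:
    read_id: str
    meth_positions: tuple[tuple[int, bool], ...]  # (alignment column, is_consensus_cpg)
    aligned_span: int  # aligned read bases

    @property
    def meth_count(self) -> int:
        return len(self.meth_positions)

    @property
    def per100bp(self) -> float:
        if self.aligned_span == 0:
            return 0.0
        return 100.0 * self.meth_count / self.aligned_span


@dataclass(frozen=True)
class DinucleotideTally:
    """Dinucleotide counts over all reads x consensus CpG positions."""

    n_CG: int = 0
    n_TG: int = 0
    n_CA: int = 0
    n_TA: int = 0
    n_other: int = 0


def extract_methylated_cpgs(row: AlignedRead, consensus: ReferenceRecord) -> RepeatReadResult:
    """Find every methylated CpG a read shows, at consensus or novel positions.

    Adjacency is evaluated in read space (C followed by the next non-gap read
    base G), so CpGs inserted relative to the consensus are counted.
    """
    cols = [(i, b) for i, b in enumerate(row.columns) if b != "-"]
    refpos_by_col = {col: p for p, col in row.col_of_refpos.items()}
    cpg = consensus.cpg_set
    hits: list[tuple[int, bool]] = []
    for (col, base), (_, nxt) in zip(cols, cols[1:]):
        if base == "C" and nxt == "G":
            hits.append((col, refpos_by_col.get(col) in cpg))
    return RepeatReadResult(
        read_id=row.read_id,
        meth_positions=tuple(hits),
        aligned_span=len(cols),
    )


def repeat_summaries(
    results: list[RepeatReadResult],
) -> tuple[dict[int, int], list[float], float, list[str]]:
    """Count histogram, per-100bp rates, their mean, and count-sorted order.

    Reads are sorted by methylated-CpG count (descending, stable on ties).
    """
    if not results:
        raise ValueError("no repeat read results to summarise")
    histogram = dict(sorted(Counter(r.meth_count for r in results).items()))
    per100 = [r.per100bp for r in results]
    mean = sum(per100) / len(per100)
    order = [
        r.read_id
        for _, _, r in sorted((-r.meth_count, i, r) for i, r in enumerate(results))
    ]
    return histogram, per100, mean, order


def tally_consensus_dinucleotides(
    aln: MultiAlignment, consensus: ReferenceRecord
) -> DinucleotideTally:
    """Tally the (5'-of-G base, G-column base) pair at every consensus CpG.

    The first member of the pair follows the same 5'-of-G convention as
    unique-mode calling, so T-stretch indels do not shift it.  Pairs
    containing an N, a gap, or any base combination other than CG/TG/CA/TA go
    to ``n_other``.
    """
    counts = Counter()
    for row in aln.rows:
        for site in consensus.cpg_positions:
            g_col = row.col_of_refpos[site + 1]
            b2 = row.columns[g_col]
            b1 = row.prev_read_base(g_col)
            pair = (b1 or "-") + b2
            if pair in ("CG", "TG", "CA", "TA"):
                counts[pair] += 1
            else:
                counts["other"] += 1
    return DinucleotideTally(
        n_CG=counts["CG"],
        n_TG=counts["TG"],
        n_CA=counts["CA"],
        n_TA=counts["TA"],
        n_other=counts["other"],
    )


def naive_overall_methylation(t: DinucleotideTally) -> float:
    """Uncorrected percent methylation, 100 * CG / (CG + TG)."""
    if t.n_CG + t.n_TG == 0:
        raise ValueError("no CG or TG observations at consensus CpG positions")
    return 100.0 * t.n_CG / (t.n_CG + t.n_TG)


def yang_overall_methylation(t: DinucleotideTally) -> float:
    """Mutation-corrected percent methylation at consensus CpG positions.

    The TG tally is reduced by the CA count (the opposite-strand mutation
    estimate); the corrected unmethylated count is clamped at zero with a
    warning if CA exceeds TG.  With no CA observations this reduces to the
    naive ``CG / (CG + TG)``.
    """
    if t.n_CG + t.n_TG == 0:
        raise ValueError("no CG or TG observations at consensus CpG positions")
    u = t.n_TG - t.n_CA
    if u < 0:
        warnings.warn(
            f"CA count ({t.n_CA}) exceeds TG count ({t.n_TG}); "
            "unmethylated tally clamped at 0",
            stacklevel=2,
        )
        u = 0
    if t.n_CG == 0 and u == 0:
        return 0.0
    return 100.0 * t.n_CG / (t.n_CG + u)
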