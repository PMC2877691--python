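"""End-to-end analysis pipelines for unique loci and repeat consensus runs.

``analyze_unique`` / ``analyze_repeat`` operate on in-memory objects and
return a result dataclass; ``run_unique`` / ``run_repeat`` add file input
and output around them.  Stages for a unique locus: orientation and vector
trimming -> shared alignment frame -> quality filtering -> CpG calling ->
clonal duplicate filtering -> summary statistics -> optional sorting by
per-clone methylation.  Repeat runs replace per-site calling with
methylated-CpG extraction and the mutation-corrected overall estimator, and
skip clonal filtering (diverged repeat copies make identical patterns
uninformative as duplicate evidence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .alignment import (
    AlignParams,
    MultiAlignment,
    OrientedRead,
    ReferenceRecord,
    build_alignment,
    convert_reference,
    orient_and_trim,
)
from .clonal import ClonalDecision, apply_overrides, classify_clonal, cytosine_pattern
from .errors import UnalignableReadError
from .io_formats import (
    ReadSet,
    read_reads,
    read_reference,
    write_outputs,
    write_repeat_outputs,
)
from .methylation import CallMatrix, SummaryStats, call_all, sort_by_methylation, summarize
from .quality import FilterConfig, FilterDecision, QualityMetrics, filter_alignment
from .repeats import (
    DinucleotideTally,
    RepeatReadResult,
    extract_methylated_cpgs,
    naive_overall_methylation,
    repeat_summaries,
    tally_consensus_dinucleotides,
    yang_overall_methylation,
)

EXIT_OK = 0
EXIT_NO_SURVIVORS = 3


@dataclass
class AnalysisResult:
    reference: ReferenceRecord
    alignment_mode: str
    alignment: MultiAlignment | None
    matrix: CallMatrix
    summary: SummaryStats
    metrics: dict[str, QualityMetrics]
    filter_decisions: dict[str, FilterDecision]
    clonal_decisions: list[ClonalDecision]
    unalignable: dict[str, str]
    artifact_positions: dict[str, list[int]] = field(default_factory=dict)
    input_order: list[str] = field(default_factory=list)
    n_input: int = 0

    @property
    def kept_ids(self) -> list[str]:
        return list(self.matrix.clone_ids)

    @property
    def exit_status(self) -> int:
        return EXIT_OK if self.kept_ids else EXIT_NO_SURVIVORS


def _orient_all(
    reads: ReadSet, ref: ReferenceRecord, params: AlignParams
) -> tuple[list[OrientedRead], dict[str, str]]:
    oriented: list[OrientedRead] = []
    unalignable: dict[str, str] = {}
    for read in reads:
        try:
            _, orientation, aln = orient_and_trim(read.read_id, read.sequence, ref, params)
        except UnalignableReadError as exc:
            unalignable[read.read_id] = str(exc)
            continue
        oriented.append(OrientedRead(read.read_id, orientation, aln))
    return oriented, unalignable


def _observed_artifacts(aln: MultiAlignment, ref: ReferenceRecord) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for row in aln.rows:
        out[row.read_id] = [
            p for p in ref.noncpg_c_positions if row.base_at_ref(p) == "C"
        ]
    return out


def analyze_unique(
    ref_id: str,
    ref_seq: str,
    reads: ReadSet,
    filter_cfg: FilterConfig | None = None,
    align_params: AlignParams | None = None,
    align_mode: str = "auto",
    sort: bool = True,
    min_site_n: int = 5,
    keep_ids: set[str] | None = None,
    drop_ids: set[str] | None = None,
) -> AnalysisResult:
    """Run the unique-locus pipeline on in-memory inputs."""
    cfg = filter_cfg or FilterConfig.unique_defaults()
    params = align_params or AlignParams()
    ref = convert_reference(ref_id, ref_seq)
    input_order = reads.ids()

    oriented, unalignable = _orient_all(reads, ref, params)
    sites = list(ref.cpg_positions)
    empty = CallMatrix(site_positions=sites, clone_ids=[], calls=[])

    def _empty(metrics=None, decisions=None, clonal=None, mode="none", aln=None):
        return AnalysisResult(
            reference=ref,
            alignment_mode=mode,
            alignment=aln,
            matrix=empty,
            summary=summarize(empty, min_site_n),
            metrics=metrics or {},
            filter_decisions=decisions or {},
            clonal_decisions=clonal or [],
            unalignable=unalignable,
            input_order=input_order,
            n_input=len(reads),
        )

    if not oriented:
        return _empty()

    aln = build_alignment(oriented, ref, mode=align_mode, params=params)
    metrics, decisions = filter_alignment(aln, ref, cfg)
    survivors = [o for o in oriented if decisions[o.read_id].passed]
    if not survivors:
        return _empty(metrics, decisions, mode=aln.mode)

    # rebuild the frame with quality-passing reads only
    aln = build_alignment(survivors, ref, mode=aln.mode, params=params)
    matrix = call_all(aln, ref)
    patterns = [
        cytosine_pattern(row, ref, matrix.row(row.read_id)) for row in aln.rows
    ]
    clonal_decisions = classify_clonal(patterns, mode=cfg.clonal_mode)
    clonal_decisions = apply_overrides(clonal_decisions, keep_ids, drop_ids)
    kept = [d.read_id for d in clonal_decisions if d.kept]
    if not kept:
        return _empty(metrics, decisions, clonal_decisions, mode=aln.mode)

    final_oriented = [o for o in survivors if o.read_id in set(kept)]
    final_aln = build_alignment(final_oriented, ref, mode=aln.mode, params=params)
    final_matrix = call_all(final_aln, ref)
    final_matrix = sort_by_methylation(final_matrix, enabled=sort)
    summary = summarize(final_matrix, min_site_n=min_site_n)
    return AnalysisResult(
        reference=ref,
        alignment_mode=final_aln.mode,
        alignment=final_aln,
        matrix=final_matrix,
        summary=summary,
        metrics=metrics,
        filter_decisions=decisions,
        clonal_decisions=clonal_decisions,
        unalignable=unalignable,
        artifact_positions=_observed_artifacts(final_aln, ref),
        input_order=input_order,
        n_input=len(reads),
    )


def run_unique(
    ref_path: str | Path,
    reads_path: str | Path,
    outdir: str | Path | None = None,
    ab1: bool = False,
    **kwargs,
) -> AnalysisResult:
    """File-based unique-locus run; writes all artifacts when ``outdir`` given."""
    ref_id, ref_seq = read_reference(ref_path)
    reads = read_reads(reads_path, ab1=ab1)
    result = analyze_unique(ref_id, ref_seq, reads, **kwargs)
    if outdir is not None:
        write_outputs(result, outdir)
    return result


@dataclass
class RepeatAnalysisResult:
    consensus: ReferenceRecord
    alignment: MultiAlignment | None
    per_read: list[RepeatReadResult]
    histogram: dict[int, int]
    per100bp_values: list[float]
    mean_per100bp: float
    sorted_order: list[str]
    tally: DinucleotideTally
    yang_pct: float | None
    naive_pct: float | None
    metrics: dict[str, QualityMetrics]
    filter_decisions: dict[str, FilterDecision]
    unalignable: dict[str, str]
    input_order: list[str] = field(default_factory=list)
    n_input: int = 0

    @property
    def exit_status(self) -> int:
        return EXIT_OK if self.per_read else EXIT_NO_SURVIVORS


def analyze_repeat(
    consensus_id: str,
    consensus_seq: str,
    reads: ReadSet,
    filter_cfg: FilterConfig | None = None,
    align_params: AlignParams | None = None,
) -> RepeatAnalysisResult:
    """Run the repeat-consensus pipeline on in-memory inputs.

    Alignment always uses the stitched strategy (the consensus is the hub of
    all pairwise comparisons); the MSA fallback rule targets unique PCR
    products.
    """
    cfg = filter_cfg or FilterConfig.repeat_defaults()
    params = align_params or AlignParams()
    ref = convert_reference(consensus_id, consensus_seq)
    input_order = reads.ids()
    oriented, unalignable = _orient_all(reads, ref, params)

    def _empty(metrics=None, decisions=None, aln=None):
        return RepeatAnalysisResult(
            consensus=ref,
            alignment=aln,
            per_read=[],
            histogram={},
            per100bp_values=[],
            mean_per100bp=0.0,
            sorted_order=[],
            tally=DinucleotideTally(),
            yang_pct=None,
            naive_pct=None,
            metrics=metrics or {},
            filter_decisions=decisions or {},
            unalignable=unalignable,
            input_order=input_order,
            n_input=len(reads),
        )

    if not oriented:
        return _empty()
    aln = build_alignment(oriented, ref, mode="stitched", params=params)
    metrics, decisions = filter_alignment(aln, ref, cfg)
    survivors = [o for o in oriented if decisions[o.read_id].passed]
    if not survivors:
        return _empty(metrics, decisions)
    aln = build_alignment(survivors, ref, mode="stitched", params=params)
    per_read = [extract_methylated_cpgs(row, ref) for row in aln.rows]
    histogram, per100, mean_per100, order = repeat_summaries(per_read)
    tally = tally_consensus_dinucleotides(aln, ref)
    if tally.n_CG + tally.n_TG > 0:
        yang = yang_overall_methylation(tally)
        naive = naive_overall_methylation(tally)
    else:
        yang = naive = None
    return RepeatAnalysisResult(
        consensus=ref,
        alignment=aln,
        per_read=per_read,
        histogram=histogram,
        per100bp_values=per100,
        mean_per100bp=mean_per100,
        sorted_order=order,
        tally=tally,
        yang_pct=yang,
        naive_pct=naive,
        metrics=metrics,
        filter_decisions=decisions,
        unalignable=unalignable,
        input_order=input_order,
        n_input=len(reads),
    )


def run_repeat(
    consensus_path: str | Path,
    reads_path: str | Path,
    outdir: str | Path | None = None,
    ab1: bool = False,
    **kwargs,
) -> RepeatAnalysisResult:
    """File-based repeat-consensus run; writes artifacts when ``outdir`` given."""
    cons_id, cons_seq = read_reference(consensus_path)
    reads = read_reads(reads_path, ab1=ab1)
    result = analyze_repeat(cons_id, cons_seq, reads, **kwargs)
    if outdir is not None:
        write_repeat_outputs(result, outdir)
    return result
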