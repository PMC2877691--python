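"""Per-read quality metrics and threshold filtering.

Four properties of an aligned read are assessed against the reference:
identity, bisulfite conversion rate (fraction of non-CpG reference cytosines
read as T — a proxy for treatment completeness), gap content, and unresolved
basecalls (N) at reference cytosine positions.  Two filtering modes exist:

* ``unique`` (single-copy genomic locus): identity >= 90 %, conversion
  >= 95 %, gaps <= 20 % by default.
* ``repeat`` (consensus-based repeat analysis): identity >= 70 %, gaps
  <= 20 %, and a read is excluded when it carries 3 or more unconverted
  cytosines per 100 bp of aligned reference span.

Thresholds are inclusive for passing except the repeat unconverted rule,
which excludes at the stated count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .alignment import AlignedRead, MultiAlignment, ReferenceRecord

#: numeric slack so that exact-boundary metrics compare as intended
EPS = 1e-9

UNIQUE = "unique"
REPEAT = "repeat"


@dataclass(frozen=True)
class QualityMetrics:
    identity: float
    conversion_rate: float | None
    unconverted_per_100bp: float
    gap_fraction: float
    n_at_cytosine: int
    aligned_span: int


@dataclass(frozen=True)
class FilterConfig:
    """Quality thresholds; percentages on the 0-100 scale.

    ``max_unconverted_per_100bp`` is the repeat-mode exclusion bound: a read
    with that many or more unconverted cytosines per 100 aligned bp fails.
    ``max_n_at_cytosine`` has no published default; 3 is this package's
    default and is configurable.
    """

    mode: str = UNIQUE
    min_identity: float = 90.0
    min_conversion: float = 95.0
    max_unconverted_per_100bp: float = 3.0
    max_gap_fraction: float = 20.0
    max_n_at_cytosine: int = 3
    clonal_mode: str = "suggested"

    @classmethod
    def unique_defaults(cls, **overrides) -> "FilterConfig":
        return replace(cls(mode=UNIQUE, min_identity=90.0, min_conversion=95.0), **overrides)

    @classmethod
    def repeat_defaults(cls, **overrides) -> "FilterConfig":
        return replace(
            cls(mode=REPEAT, min_identity=70.0, max_unconverted_per_100bp=3.0), **overrides
        )


@dataclass(frozen=True)
class FilterDecision:
    read_id: str
    passed: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be equivalent to an empty reason list")


def compute_metrics(row: AlignedRead, ref: ReferenceRecord) -> QualityMetrics:
    """Compute quality metrics for one aligned read.

    Columns where both the read and the reference row are gaps (padding
    introduced by other reads' insertions) are ignored, so metrics are
    identical whether computed in the shared frame or on the read's own
    pairwise alignment.  Within the identity computation a read C *or* T
    opposite a reference CpG cytosine counts as a match, and columns with an N
    in either row are excluded.
    """
    span = row.span_cols()
    if span is None:
        return QualityMetrics(0.0, None, 0.0, 0.0, 0, 0)
    first, last = span
    refpos_by_col = {col: p for p, col in row.col_of_refpos.items()}
    cpg = ref.cpg_set
    noncpg = ref.noncpg_c_set

    span_cols = 0
    gap_cols = 0
    ident_num = 0
    ident_den = 0
    conv_t = 0
    conv_c = 0
    n_at_c = 0
    aligned_span = 0

    for col in range(first, last + 1):
        r = row.ref_row[col]
        b = row.columns[col]
        if r == "-" and b == "-":
            continue
        span_cols += 1
        if r == "-" or b == "-":
            gap_cols += 1
        refpos = refpos_by_col.get(col)
        if refpos is not None:
            aligned_span += 1
        if r != "-" and b != "-":
            if b != "N" and r != "N":
                ident_den += 1
                if b == r or (refpos in cpg and b in "CT"):
                    ident_num += 1
        if refpos is not None:
            if refpos in noncpg:
                if b == "T":
                    conv_t += 1
                elif b == "C":
                    conv_c += 1
            if b == "N" and (refpos in noncpg or refpos in cpg):
                n_at_c += 1

    identity = ident_num / ident_den if ident_den else 0.0
    denom = conv_t + conv_c
    conversion = conv_t / denom if denom else None
    per100 = 100.0 * conv_c / aligned_span if aligned_span else 0.0
    gap_fraction = gap_cols / span_cols if span_cols else 0.0
    return QualityMetrics(
        identity=identity,
        conversion_rate=conversion,
        unconverted_per_100bp=per100,
        gap_fraction=gap_fraction,
        n_at_cytosine=n_at_c,
        aligned_span=aligned_span,
    )


def apply_filters(read_id: str, metrics: QualityMetrics, cfg: FilterConfig) -> FilterDecision:
    """Apply mode-specific thresholds; every failed criterion is listed."""
    reasons: list[str] = []
    if metrics.identity * 100.0 < cfg.min_identity - EPS:
        reasons.append("identity")
    if cfg.mode == UNIQUE:
        if metrics.conversion_rate is not None and (
            metrics.conversion_rate * 100.0 < cfg.min_conversion - EPS
        ):
            reasons.append("conversion")
    elif cfg.mode == REPEAT:
        if metrics.unconverted_per_100bp >= cfg.max_unconverted_per_100bp - EPS:
            reasons.append("conversion")
    else:
        raise ValueError(f"unknown filter mode {cfg.mode!r}")
    if metrics.gap_fraction * 100.0 > cfg.max_gap_fraction + EPS:
        reasons.append("gaps")
    if metrics.n_at_cytosine > cfg.max_n_at_cytosine:
        reasons.append("n_sites")
    return FilterDecision(read_id=read_id, passed=not reasons, reasons=tuple(reasons))


def filter_alignment(
    aln: MultiAlignment, ref: ReferenceRecord, cfg: FilterConfig
) -> tuple[dict[str, QualityMetrics], dict[str, FilterDecision]]:
    """Metrics and decisions for every row of a multi-alignment."""
    metrics = {row.read_id: compute_metrics(row, ref) for row in aln.rows}
    decisions = {rid: apply_filters(rid, m, cfg) for rid, m in metrics.items()}
    return metrics, decisions
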