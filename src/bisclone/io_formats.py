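"""Reading references and reads; writing result tables and alignments.

Reads can arrive as one multi-FASTA file, as a directory of per-clone files,
or as a ZIP archive of per-clone files.  Per-clone files may be FASTA, plain
text holding the extracted sequence, or (optionally) AB1/ABIF trace files
from which the basecalls are extracted — preferring the user-edited basecall
record over the primary one, so manual corrections made in a trace editor
are honoured.

All outputs are plain text (TSV with tab delimiter, '.' decimal point and
"NA" for suppressed values; JSON with sorted keys) and byte-identical across
repeated runs on identical inputs.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .errors import FormatError, InputError

DNA_ALPHABET = set("ACGTN")

FASTA_EXTENSIONS = {".fa", ".fasta", ".fna", ".fas"}
AB1_EXTENSIONS = {".ab1", ".abi"}


@dataclass(frozen=True)
class RawRead:
    """One experimental sequence (a subclone) prior to alignment."""

    read_id: str
    sequence: str
    source: str = "fasta"  # fasta | text | ab1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"read {self.read_id!r} has an empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"read {self.read_id!r} contains non-ACGTN characters: {sorted(bad)}"
            )


@dataclass
class ReadSet:
    """Ordered collection of reads; input order is preserved because it is
    the deterministic tie-break for downstream decisions."""

    reads: list[RawRead]
    origin: str = ""

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def ids(self) -> list[str]:
        return [r.read_id for r in self.reads]


def _clean_sequence(raw: str, label: str) -> str:
    seq = "".join(raw.split()).upper()
    if not seq:
        raise InputError(f"{label}: empty sequence")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise FormatError(f"{label}: invalid sequence characters {sorted(bad)}")
    return seq


def read_reference(path: str | Path) -> tuple[str, str]:
    """Read a single-record FASTA reference; IUPAC codes other than N are
    rejected so downstream conversion logic stays well-defined."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise FormatError(
            f"{path}: reference FASTA must contain exactly one record, found {len(records)}"
        )
    rec = records[0]
    seq = _clean_sequence(str(rec.seq), str(path))
    return rec.id, seq


def extract_basecalls_ab1(source: str | Path | io.BytesIO, read_id: str | None = None) -> RawRead:
    """Extract the basecall string from an AB1/ABIF trace.

    Prefers the user-edited basecall record (PBAS tag number 1) when present,
    falling back to the primary basecalls (PBAS 2).
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        with open(path, "rb") as fh:
            magic = fh.read(4)
        if magic != b"ABIF":
            raise FormatError(f"{path}: not an ABIF trace file")
        handle = str(path)
        rid = read_id or path.stem
    else:
        source.seek(0)
        if source.read(4) != b"ABIF":
            raise FormatError("not an ABIF trace file")
        source.seek(0)
        handle = source
        rid = read_id or "ab1_read"
    try:
        rec = SeqIO.read(handle, "abi")
    except Exception as exc:  # biopython raises assorted errors on bad traces
        raise FormatError(f"failed to parse ABIF trace: {exc}") from exc
    raw = rec.annotations.get("abif_raw", {})
    basecalls = raw.get("PBAS1") or raw.get("PBAS2")
    if not basecalls:
        raise FormatError("ABIF trace lacks basecall (PBAS) records")
    if isinstance(basecalls, bytes):
        basecalls = basecalls.decode("ascii")
    return RawRead(read_id=rid, sequence=_clean_sequence(basecalls, rid), source="ab1")


def _read_from_bytes(name: str, data: bytes, ab1: bool) -> RawRead:
    stem = Path(name).stem
    suffix = Path(name).suffix.lower()
    if data[:4] == b"ABIF" or suffix in AB1_EXTENSIONS:
        if not ab1:
            raise FormatError(
                f"{name}: AB1 trace input requires trace support to be enabled"
            )
        return extract_basecalls_ab1(io.BytesIO(data), read_id=stem)
    try:
        text = data.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise FormatError(f"{name}: not a text or ABIF file") from exc
    if not text.strip():
        raise InputError(f"{name}: file is empty")
    if text.lstrip().startswith(">"):
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
        if len(records) != 1:
            raise FormatError(
                f"{name}: per-clone FASTA must contain exactly one record, found {len(records)}"
            )
        return RawRead(
            read_id=stem, sequence=_clean_sequence(str(records[0].seq), name), source="fasta"
        )
    return RawRead(read_id=stem, sequence=_clean_sequence(text, name), source="text")


def _check_duplicates(reads: list[RawRead], origin: str) -> None:
    seen: dict[str, int] = {}
    for r in reads:
        seen[r.read_id] = seen.get(r.read_id, 0) + 1
    dups = sorted(rid for rid, n in seen.items() if n > 1)
    if dups:
        raise InputError(f"{origin}: duplicate read ids: {dups}")


def read_reads(path: str | Path, ab1: bool = False) -> ReadSet:
    """Load experimental reads from a multi-FASTA file, directory, or ZIP.

    Per-file inputs take the file stem as read id and are processed in
    lexicographic name order; multi-FASTA records keep file order with ids
    taken from the header up to the first whitespace.
    """
    path = Path(path)
    reads: list[RawRead] = []
    if path.is_dir():
        names = sorted(p.name for p in path.iterdir() if p.is_file())
        if not names:
            raise InputError(f"{path}: directory contains no files")
        for name in names:
            reads.append(_read_from_bytes(name, (path / name).read_bytes(), ab1))
    elif zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            names = sorted(n for n in zf.namelist() if not n.endswith("/"))
            if not names:
                raise InputError(f"{path}: archive contains no files")
            for name in names:
                reads.append(_read_from_bytes(name, zf.read(name), ab1))
    elif path.is_file():
        text = path.read_text()
        if not text.lstrip().startswith(">"):
            raise FormatError(f"{path}: expected multi-FASTA, a directory, or a ZIP archive")
        for rec in SeqIO.parse(io.StringIO(text), "fasta"):
            reads.append(
                RawRead(
                    read_id=rec.id,
                    sequence=_clean_sequence(str(rec.seq), rec.id),
                    source="fasta",
                )
            )
        if not reads:
            raise InputError(f"{path}: no FASTA records found")
    else:
        raise InputError(f"{path}: no such file or directory")
    _check_duplicates(reads, str(path))
    return ReadSet(reads=reads, origin=str(path))


# ---------------------------------------------------------------------------
# output writing
# ---------------------------------------------------------------------------

def fmt_pct(x: float | None, digits: int = 2) -> str:
    return "NA" if x is None else f"{x:.{digits}f}"


def write_fasta(path: Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_tsv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_outputs(result, outdir: str | Path) -> dict[str, str]:
    """Write all unique-mode result artifacts; returns the manifest.

    The manifest maps artifact classes (alignment, annotated alignment, call
    matrix, per-site and per-clone summaries, run summary, filter and clonal
    logs) to file names.  Output is byte-identical across repeated runs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = {
        "alignment": "alignment.fasta",
        "annotated_alignment": "alignment_annotated.txt",
        "call_matrix": "call_matrix.tsv",
        "per_site_summary": "per_site.tsv",
        "per_clone_summary": "per_clone.tsv",
        "run_summary": "summary.json",
        "filter_log": "filter_log.tsv",
        "clonal_report": "clonal_report.tsv",
    }

    matrix = result.matrix
    summary = result.summary
    order = list(matrix.clone_ids)

    # 1) gapped alignment + plain-text annotation
    aln_records = []
    row_by_id = {}
    if result.alignment is not None:
        aln_records.append((result.reference.id, result.alignment.reference_row))
        row_by_id = {r.read_id: r for r in result.alignment.rows}
        for rid in order:
            if rid in row_by_id:
                aln_records.append((rid, row_by_id[rid].columns))
    write_fasta(outdir / manifest["alignment"], aln_records)

    with open(outdir / manifest["annotated_alignment"], "w") as fh:
        fh.write(f"# reference: {result.reference.id}\n")
        fh.write(
            "# CpG positions (1-based): "
            + ",".join(str(p + 1) for p in matrix.site_positions)
            + "\n"
        )
        fh.write("# per-clone calls: M=methylated U=unmethylated X=unknown\n")
        for rid in order:
            calls = "".join(matrix.row(rid))
            arts = result.artifact_positions.get(rid, [])
            art_s = ",".join(str(p + 1) for p in arts) if arts else "-"
            fh.write(f"{rid}\t{calls}\tartifacts:{art_s}\n")

    # 2) call matrix
    header = ["clone_id"] + [f"pos_{p + 1}" for p in matrix.site_positions]
    rows = [[rid] + list(matrix.row(rid)) for rid in order]
    write_tsv(outdir / manifest["call_matrix"], header, rows)

    # 3) per-site summary
    rows = []
    for pos in matrix.site_positions:
        n_inf, n_meth, pct = summary.per_site[pos]
        rows.append([str(pos + 1), str(n_inf), str(n_meth), fmt_pct(pct)])
    write_tsv(
        outdir / manifest["per_site_summary"],
        ["position", "n_informative", "n_methylated", "pct_methylated"],
        rows,
    )

    # 4) per-clone summary
    rows = []
    for rid in order:
        row = matrix.row(rid)
        m = row.count("M")
        u = row.count("U")
        rows.append([rid, str(m + u), str(m), fmt_pct(summary.per_clone[rid])])
    write_tsv(
        outdir / manifest["per_clone_summary"],
        ["clone_id", "n_informative", "n_methylated", "pct_methylated"],
        rows,
    )

    # 5) run summary JSON
    write_json(
        outdir / manifest["run_summary"],
        {
            "reference_id": result.reference.id,
            "reference_length": result.reference.length,
            "n_cpg_sites": len(matrix.site_positions),
            "alignment_mode": result.alignment_mode,
            "n_reads_input": result.n_input,
            "n_reads_unalignable": len(result.unalignable),
            "n_reads_failed_quality": sum(
                1 for d in result.filter_decisions.values() if not d.passed
            ),
            "n_reads_removed_clonal": sum(
                1 for d in result.clonal_decisions if not d.kept
            ),
            "n_clones_analyzed": len(order),
            "n_calls_methylated": summary.n_methylated,
            "n_calls_unmethylated": summary.n_unmethylated,
            "n_calls_unknown": summary.n_unknown,
            "overall_methylation_pct": summary.overall_pct,
            "informative_pct": summary.informative_pct,
        },
    )

    # 6) filter log
    rows = []
    for rid in result.input_order:
        if rid in result.unalignable:
            rows.append([rid, "NA", "NA", "NA", "NA", "NA", "fail", "unalignable"])
            continue
        m = result.metrics[rid]
        d = result.filter_decisions[rid]
        rows.append(
            [
                rid,
                f"{m.identity * 100:.2f}",
                fmt_pct(None if m.conversion_rate is None else m.conversion_rate * 100),
                f"{m.gap_fraction * 100:.2f}",
                str(m.n_at_cytosine),
                str(m.aligned_span),
                "pass" if d.passed else "fail",
                ";".join(d.reasons) if d.reasons else "-",
            ]
        )
    write_tsv(
        outdir / manifest["filter_log"],
        [
            "read_id", "identity_pct", "conversion_pct", "gap_pct",
            "n_at_cytosine", "aligned_span", "status", "reasons",
        ],
        rows,
    )

    # clonal report
    rows = [
        [
            d.read_id,
            "-" if d.group_id is None else f"G{d.group_id}",
            "yes" if d.kept else "no",
            d.reason,
        ]
        for d in result.clonal_decisions
    ]
    write_tsv(
        outdir / manifest["clonal_report"],
        ["read_id", "group_id", "kept", "reason"],
        rows,
    )
    return manifest


def write_repeat_outputs(result, outdir: str | Path) -> dict[str, str]:
    """Write repeat-mode artifacts (per-read table, histogram, estimator)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "alignment": "alignment.fasta",
        "per_read": "per_read.tsv",
        "histogram": "histogram.tsv",
        "estimator": "estimator.json",
        "filter_log": "filter_log.tsv",
    }
    aln_records = []
    if result.alignment is not None:
        aln_records.append((result.consensus.id, result.alignment.reference_row))
        by_id = {r.read_id: r for r in result.alignment.rows}
        for rid in result.sorted_order:
            aln_records.append((rid, by_id[rid].columns))
    write_fasta(outdir / manifest["alignment"], aln_records)

    by_id = {r.read_id: r for r in result.per_read}
    rows = []
    for rid in result.sorted_order:
        r = by_id[rid]
        pos_s = ";".join(
            f"{col + 1}{'*' if is_cons else ''}" for col, is_cons in r.meth_positions
        )
        rows.append(
            [rid, str(r.meth_count), f"{r.per100bp:.2f}", str(r.aligned_span), pos_s or "-"]
        )
    write_tsv(
        outdir / manifest["per_read"],
        ["read_id", "n_methylated_cpg", "meth_cpg_per_100bp", "aligned_span",
         "positions(*=consensus)"],
        rows,
    )
    write_tsv(
        outdir / manifest["histogram"],
        ["n_methylated_cpg", "n_reads"],
        [[str(k), str(v)] for k, v in sorted(result.histogram.items())],
    )
    write_json(
        outdir / manifest["estimator"],
        {
            "n_CG": result.tally.n_CG,
            "n_TG": result.tally.n_TG,
            "n_CA": result.tally.n_CA,
            "n_TA": result.tally.n_TA,
            "n_other": result.tally.n_other,
            "naive_methylation_pct": result.naive_pct,
            "corrected_methylation_pct": result.yang_pct,
            "mean_meth_cpg_per_100bp": result.mean_per100bp,
            "n_reads_analyzed": len(result.per_read),
        },
    )
    rows = []
    for rid in result.input_order:
        if rid in result.unalignable:
            rows.append([rid, "NA", "NA", "NA", "NA", "fail", "unalignable"])
            continue
        m = result.metrics[rid]
        d = result.filter_decisions[rid]
        rows.append(
            [
                rid,
                f"{m.identity * 100:.2f}",
                f"{m.unconverted_per_100bp:.2f}",
                f"{m.gap_fraction * 100:.2f}",
                str(m.n_at_cytosine),
                "pass" if d.passed else "fail",
                ";".join(d.reasons) if d.reasons else "-",
            ]
        )
    write_tsv(
        outdir / manifest["filter_log"],
        ["read_id", "identity_pct", "unconverted_per_100bp", "gap_pct",
         "n_at_cytosine", "status", "reasons"],
        rows,
    )
    return manifest
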