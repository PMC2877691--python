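"""Synthetic bisulfite-clone datasets with known ground truth.

The generator emulates the data model of a subcloning bisulfite experiment:
a genomic region with a chosen number of CpG sites is drawn, each subclone
samples a methylation state per CpG, and the molecule is bisulfite-converted
(methylated C kept, unmethylated CpG C -> T, non-CpG C -> T except for
conversion failures that leave an artifact C).  Sequencing-level noise is
then applied per read: thymine insertions/deletions at T-homopolymers
(polymerase slippage), random substitutions, unresolved basecalls (N),
cloning-vector flanks, and random read orientation.  Clonal PCR duplicates
copy an earlier clone's *converted molecule* — sharing its methylation
pattern and conversion artifacts — while sequencing noise stays independent.

For repeat-mode test beds, consensus CpG sites additionally mutate CG -> TG
per strand: a sequenced-strand mutation reads TG regardless of methylation,
while an opposite-strand mutation turns the G into A so the site reads CA
(methylated) or TA (unmethylated).

Every stochastic draw is governed by a single integer seed and recorded in a
truth manifest, so planted parameters can be recovered and compared with
pipeline output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .alignment import FORWARD, REVERSE, convert_reference
from .io_formats import RawRead

BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults model a typical subcloning experiment: a ~400 bp amplicon with
    20 CpG sites, 50 sequenced clones, moderate methylation (30 %), a 2 %
    bisulfite conversion-failure rate, low sequencing error and N rates, a
    20 bp vector flank on each side and random insert orientation.
    ``mutation_rate`` (per consensus CpG, per strand) is only meaningful for
    repeat-mode datasets and is off by default.
    """

    seed: int = 0
    ref_length: int = 400
    n_cpg: int = 20
    n_clones: int = 50
    per_site_p: float | Sequence[float] = 0.3
    conv_failure: float = 0.02
    seq_error: float = 0.001
    tstretch_indel: float = 0.05
    clonal_fraction: float = 0.0
    vector_flank: int = 20
    revcomp_fraction: float = 0.5
    n_rate: float = 0.001
    mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        probs = {
            "conv_failure": self.conv_failure,
            "seq_error": self.seq_error,
            "tstretch_indel": self.tstretch_indel,
            "clonal_fraction": self.clonal_fraction,
            "revcomp_fraction": self.revcomp_fraction,
            "n_rate": self.n_rate,
            "mutation_rate": self.mutation_rate,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_cpg < 1:
            raise ValueError("n_cpg must be >= 1")

    def site_probs(self) -> np.ndarray:
        p = np.broadcast_to(np.asarray(self.per_site_p, dtype=float), (self.n_cpg,))
        if ((p < 0) | (p > 1)).any():
            raise ValueError("per_site_p entries must be probabilities")
        return p


@dataclass
class TruthManifest:
    """Ground truth of one simulated dataset."""

    reference: str
    cpg_positions: list[int]
    clone_ids: list[str]
    methylation: dict[str, list[bool]]
    duplicate_of: dict[str, str]
    artifact_positions: dict[str, list[int]]
    mutations: dict[str, dict[str, list[int]]]
    orientation: dict[str, str]
    molecules: dict[str, str] = field(repr=False, default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


def _rand_seq(rng: np.random.Generator, length: int) -> list[str]:
    """Random DNA without any CG dinucleotide (CpGs are planted explicitly)."""
    seq: list[str] = []
    for _ in range(length):
        choices = BASES if not seq or seq[-1] != "C" else "ACT"
        seq.append(choices[int(rng.integers(len(choices)))])
    return seq


def simulate_reference(cfg: SimConfig) -> tuple[str, str]:
    """Random reference with exactly ``n_cpg`` CpG sites.

    When T-stretch indels are enabled a 5-T homopolymer is planted so the
    slippage noise model always has a substrate.  Deterministic given the
    seed.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.ref_length < 4 * cfg.n_cpg:
        raise ValueError(
            f"ref_length {cfg.ref_length} too small for {cfg.n_cpg} CpGs "
            f"(need >= {4 * cfg.n_cpg})"
        )
    seq = _rand_seq(rng, cfg.ref_length)
    # plant CpGs in jittered evenly-spaced slots; spacing >= 3 avoids overlap
    stride = cfg.ref_length // cfg.n_cpg
    cpg_pos = []
    for i in range(cfg.n_cpg):
        jitter = int(rng.integers(0, max(1, stride - 3)))
        p = min(i * stride + jitter, cfg.ref_length - 2)
        cpg_pos.append(p)
        seq[p] = "C"
        seq[p + 1] = "G"
    if cfg.tstretch_indel > 0:
        blocked = {q for p in cpg_pos for q in range(p - 1, p + 3)}
        for start in range(cfg.ref_length - 5):
            window = range(start, start + 5)
            if not blocked.intersection(window):
                for q in window:
                    seq[q] = "T"
                break
    out = "".join(seq)
    n_found = sum(
        1 for i in range(len(out) - 1) if out[i] == "C" and out[i + 1] == "G"
    )
    assert n_found == cfg.n_cpg, "CpG planting produced an unexpected count"
    return "simref", out


def _convert_molecule(
    original: str,
    cpg_positions: Sequence[int],
    noncpg_c_positions: Sequence[int],
    meth: Sequence[bool],
    artifacts: set[int],
    same_strand_mut: set[int],
    opp_strand_mut: set[int],
) -> str:
    """Apply mutation and bisulfite-conversion rules to one template."""
    seq = list(original)
    for k, pos in enumerate(cpg_positions):
        if k in same_strand_mut:
            seq[pos] = "T"
        elif not meth[k]:
            seq[pos] = "T"
        if k in opp_strand_mut:
            seq[pos + 1] = "A"
    for pos in noncpg_c_positions:
        if pos not in artifacts:
            seq[pos] = "T"
    return "".join(seq)


def bisulfite_convert(
    original: str, meth: Sequence[bool], artifacts: Sequence[int] = ()
) -> str:
    """Convert a reference-like sequence given per-CpG methylation states.

    Convenience wrapper used to construct deterministic scenario datasets:
    methylated CpG cytosines stay C, unmethylated ones read T, and non-CpG
    cytosines convert to T except at the listed artifact positions.
    """
    ref = convert_reference("tmp", original)
    if len(meth) != len(ref.cpg_positions):
        raise ValueError("one methylation state per CpG site required")
    return _convert_molecule(
        original, ref.cpg_positions, ref.noncpg_c_positions, list(meth),
        set(artifacts), set(), set(),
    )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _apply_tstretch_indels(seq: str, rng: np.random.Generator, prob: float) -> str:
    if prob <= 0:
        return seq
    runs = []
    i = 0
    while i < len(seq):
        if seq[i] == "T":
            j = i
            while j < len(seq) and seq[j] == "T":
                j += 1
            if j - i >= 4:
                runs.append(i)
            i = j
        else:
            i += 1
    out = seq
    for start in reversed(runs):  # back-to-front so indices stay valid
        if rng.random() < prob:
            if rng.random() < 0.5:
                out = out[:start] + "T" + out[start:]
            else:
                out = out[:start] + out[start + 1 :]
    return out


def simulate_reads(
    reference: str, cfg: SimConfig
) -> tuple[list[RawRead], TruthManifest]:
    """Emit reads for ``cfg.n_clones`` subclones of ``reference``.

    The read order is the clone order; read ids are ``clone_000``... .
    All randomness comes from ``cfg.seed`` (reads and reference draw from
    independent streams so the same reference can host different read sets).
    """
    rng = np.random.default_rng((cfg.seed, 1))
    ref = convert_reference("sim", reference)
    p = cfg.site_probs()
    manifest = TruthManifest(
        reference=reference,
        cpg_positions=list(ref.cpg_positions),
        clone_ids=[],
        methylation={},
        duplicate_of={},
        artifact_positions={},
        mutations={},
        orientation={},
    )
    reads: list[RawRead] = []
    molecules: list[str] = []
    for i in range(cfg.n_clones):
        rid = f"clone_{i:03d}"
        manifest.clone_ids.append(rid)
        if i > 0 and rng.random() < cfg.clonal_fraction:
            j = int(rng.integers(0, i))
            src = manifest.clone_ids[j]
            molecule = molecules[j]
            manifest.duplicate_of[rid] = src
            manifest.methylation[rid] = list(manifest.methylation[src])
            manifest.artifact_positions[rid] = list(manifest.artifact_positions[src])
            manifest.mutations[rid] = {
                k: list(v) for k, v in manifest.mutations[src].items()
            }
        else:
            meth = [bool(b) for b in rng.random(cfg.n_cpg) < p]
            artifacts = {
                pos for pos in ref.noncpg_c_positions if rng.random() < cfg.conv_failure
            }
            s_mut = set()
            o_mut = set()
            if cfg.mutation_rate > 0:
                for k in range(cfg.n_cpg):
                    if rng.random() < cfg.mutation_rate:
                        s_mut.add(k)
                    if rng.random() < cfg.mutation_rate:
                        o_mut.add(k)
            molecule = _convert_molecule(
                reference, ref.cpg_positions, ref.noncpg_c_positions,
                meth, artifacts, s_mut, o_mut,
            )
            manifest.methylation[rid] = meth
            manifest.artifact_positions[rid] = sorted(artifacts)
            manifest.mutations[rid] = {
                "same_strand": sorted(s_mut),
                "opposite_strand": sorted(o_mut),
            }
        molecules.append(molecule)
        manifest.molecules[rid] = molecule

        # per-read sequencing noise (independent for duplicates)
        read = _apply_tstretch_indels(molecule, rng, cfg.tstretch_indel)
        chars = list(read)
        for k in range(len(chars)):
            if rng.random() < cfg.seq_error:
                alts = [b for b in BASES if b != chars[k]]
                chars[k] = alts[int(rng.integers(3))]
            if rng.random() < cfg.n_rate:
                chars[k] = "N"
        read = "".join(chars)
        if cfg.vector_flank > 0:
            pre = "".join(BASES[int(b)] for b in rng.integers(4, size=cfg.vector_flank))
            suf = "".join(BASES[int(b)] for b in rng.integers(4, size=cfg.vector_flank))
            read = pre + read + suf
        if rng.random() < cfg.revcomp_fraction:
            read = _revcomp(read)
            manifest.orientation[rid] = REVERSE
        else:
            manifest.orientation[rid] = FORWARD
        reads.append(RawRead(read_id=rid, sequence=read, source="fasta"))
    return reads, manifest
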