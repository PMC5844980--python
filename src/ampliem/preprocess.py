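"""Read preprocessing: pair merging, quality filtering, dereplication.

The preprocessing chain mirrors the order in which amplicon reads are
prepared for clustering: merge paired-end mates, keep only reads whose
every 50-base moving window has mean Phred >= 32, collapse identical
sequences into :class:`DereplicatedSequence` records with per-sample
counts, and drop sequences seen fewer than twice.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class QualityRead:
    """A read with per-base Phred scores (Sanger scale, 0..60)."""

    id: str
    bases: str
    quals: np.ndarray

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int64)
        if len(self.quals) != len(self.bases):
            raise ValueError(f"read {self.id}: quals/bases length mismatch")
        if len(self.quals) and (self.quals.min() < 0 or self.quals.max() > 60):
            raise ValueError(f"read {self.id}: Phred scores outside [0, 60]")


@dataclass
class DereplicatedSequence:
    """A unique sequence with its total abundance and per-sample counts."""

    sequence: str
    abundance: int
    per_sample_counts: dict[str, int]
    id: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            self.id = sequence_id(self.sequence)
        if self.abundance != sum(self.per_sample_counts.values()):
            raise ValueError("abundance must equal the sum of per-sample counts")
        if self.abundance < 1:
            raise ValueError("abundance must be >= 1")


def sequence_id(sequence: str) -> str:
    """Stable hash-derived identifier for a dereplicated sequence."""
    return "sq" + hashlib.sha1(sequence.encode("ascii")).hexdigest()[:12]


def normalize_sequence(seq: str) -> str:
    """Upper-case and U->T so dereplication is strict string equality."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fastq(path) -> list[QualityRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            QualityRead(
                id=rec.id,
                bases=str(rec.seq),
                quals=np.asarray(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def write_fastq(reads: Iterable[QualityRead], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.quals]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def merge_pairs(
    fwd: QualityRead,
    rev: QualityRead,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.25,
) -> QualityRead | None:
    """Merge a forward/reverse mate pair by best ungapped overlap scan.

    The reverse mate is reverse-complemented, every overlap length from
    the maximum possible down to ``min_overlap`` is scored, and the
    overlap with the most matching bases (ties -> longer overlap) is
    chosen.  At overlap disagreements the base with the higher Phred
    score wins (ties -> forward base).  Returns ``None`` (a reject value,
    not an exception) when no acceptable overlap exists.
    """
    if not fwd.bases or not rev.bases:
        raise ValueError("both mates must be non-empty")
    rc = reverse_complement(rev.bases)
    rq = rev.quals[::-1]
    f, q_f = fwd.bases, fwd.quals
    best = None  # (n_matches, overlap_len, n_mismatches)
    max_ov = min(len(f), len(rc))
    for ov in range(max_ov, min_overlap - 1, -1):
        fa = f[len(f) - ov :]
        ra = rc[:ov]
        n_match = sum(1 for x, y in zip(fa, ra) if x == y)
        n_mis = ov - n_match
        if best is None or n_match > best[0]:
            best = (n_match, ov, n_mis)
    if best is None:
        return None
    n_match, ov, n_mis = best
    if n_mis / ov > max_mismatch_frac:
        return None
    mid_b = []
    mid_q = []
    off_f = len(f) - ov
    for k in range(ov):
        bf, qf = f[off_f + k], q_f[off_f + k]
        br, qr = rc[k], rq[k]
        if bf == br:
            mid_b.append(bf)
            mid_q.append(max(qf, qr))
        elif qr > qf:
            mid_b.append(br)
            mid_q.append(qr)
        else:
            mid_b.append(bf)
            mid_q.append(qf)
    bases = f[:off_f] + "".join(mid_b) + rc[ov:]
    quals = np.concatenate([q_f[:off_f], np.asarray(mid_q), rq[ov:]])
    return QualityRead(id=fwd.id, bases=bases, quals=quals)


def quality_filter(
    read: QualityRead, window: int = 50, min_mean_q: float = 32.0
) -> bool:
    """True iff every length-``window`` contiguous window has mean Phred
    >= ``min_mean_q``.  Reads shorter than the window are judged on their
    whole length; empty reads fail with a warning."""
    if window < 1:
        raise ValueError("window must be >= 1")
    q = read.quals
    n = len(q)
    if n == 0:
        warnings.warn(f"empty read {read.id} fails quality filter")
        return False
    if n < window:
        return float(q.mean()) >= min_mean_q
    c = np.concatenate([[0], np.cumsum(q)])
    window_sums = c[window:] - c[:-window]
    return bool(window_sums.min() >= min_mean_q * window)


def dereplicate(
    reads_by_sample: Mapping[str, Iterable[QualityRead | str]],
) -> list[DereplicatedSequence]:
    """Collapse identical sequences across samples.

    Accepts plain strings or :class:`QualityRead` values per sample.
    Sequences are normalised (upper case, U->T) before comparison.  The
    result is sorted by descending abundance, then sequence, so output is
    deterministic; total abundance equals the number of input reads.
    """
    counts: dict[str, dict[str, int]] = {}
    for sample, reads in reads_by_sample.items():
        for r in reads:
            seq = normalize_sequence(r if isinstance(r, str) else r.bases)
            per = counts.setdefault(seq, {})
            per[sample] = per.get(sample, 0) + 1
    out = [
        DereplicatedSequence(
            sequence=seq,
            abundance=sum(per.values()),
            per_sample_counts=dict(sorted(per.items())),
        )
        for seq, per in counts.items()
    ]
    out.sort(key=lambda s: (-s.abundance, s.sequence))
    return out


def abundance_filter(
    seqs: Sequence[DereplicatedSequence], min_abundance: int = 2
) -> list[DereplicatedSequence]:
    """Keep sequences with abundance >= ``min_abundance`` (default 2,
    i.e. discard singletons)."""
    kept = [s for s in seqs if s.abundance >= min_abundance]
    removed = len(seqs) - len(kept)
    if removed:
        log.info("abundance_filter removed %d of %d sequences", removed, len(seqs))
    if not kept and seqs:
        warnings.warn("abundance filter removed every sequence")
    return kept


def preprocess_reads(
    reads_by_sample: Mapping[str, Iterable[QualityRead]],
    window: int = 50,
    min_mean_q: float = 32.0,
    min_abundance: int = 2,
) -> list[DereplicatedSequence]:
    """Quality-filter, dereplicate and abundance-filter per-sample reads."""
    filtered = {
        sample: [r for r in reads if quality_filter(r, window, min_mean_q)]
        for sample, reads in reads_by_sample.items()
    }
    n_in = sum(len(list(v)) for v in filtered.values())
    log.info("quality filter retained %d reads", n_in)
    return abundance_filter(dereplicate(filtered), min_abundance)


def write_dereplicated_fasta(seqs: Sequence[DereplicatedSequence], path) -> None:
    """Write dereplicated sequences with UPARSE-style ``;size=N`` headers."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id};size={s.abundance}\n{s.sequence}\n")
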