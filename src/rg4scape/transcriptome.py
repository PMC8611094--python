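"""Transcript-space coordinate system, annotation and interval arithmetic.

Every stage of the package works on intervals in *transcript coordinates*:
0-based, half-open ``[start, end)`` positions on the sense strand of a
single transcript.  Transcripts are partitioned into three features —
5'UTR, CDS, 3'UTR — whose lengths are given per transcript in a TSV
annotation.  Reads are intervals too (5' end + fixed length, iCLIP
convention); the 5' end is the crosslink-proxy position consumed by
binning and pileups.

BED6 is the interchange format: the chrom column carries the transcript
id and the strand is always ``+`` (RNA is single-stranded).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

FEATURES = ("utr5", "cds", "utr3")


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Feature segmentation of one transcript.

    The transcript is laid out as ``[0, utr5_len) [utr5_len, utr5_len+cds_len)
    [utr5_len+cds_len, total)`` for 5'UTR, CDS and 3'UTR respectively.
    ``gene_sets`` carries arbitrary labels (e.g. ``"RP-like"`` for
    ribosomal-protein-like transcripts) used by gene-set tests.
    """

    transcript_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    gene_sets: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name in ("utr5_len", "cds_len", "utr3_len"):
            if getattr(self, name) < 0:
                raise ValueError(
                    f"{self.transcript_id}: negative {name}={getattr(self, name)}"
                )
        if self.length == 0:
            raise ValueError(f"{self.transcript_id}: zero total length")

    @property
    def length(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    def feature_interval(self, feature: str) -> "Interval":
        """The span of one feature as an Interval (may be empty -> ValueError)."""
        bounds = {
            "utr5": (0, self.utr5_len),
            "cds": (self.utr5_len, self.utr5_len + self.cds_len),
            "utr3": (self.utr5_len + self.cds_len, self.length),
        }
        if feature not in bounds:
            raise ValueError(f"unknown feature {feature!r}")
        s, e = bounds[feature]
        if s == e:
            raise ValueError(f"{self.transcript_id}: empty feature {feature}")
        return Interval(self.transcript_id, s, e)


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open interval [start, end) on a transcript's sense strand."""

    transcript_id: str
    start: int
    end: int
    name: str = field(default=".", compare=False)
    score: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.transcript_id}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "Interval") -> int:
        if self.transcript_id != other.transcript_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class ReadSet:
    """Aligned reads of one library replicate, as transcript-space intervals.

    The library size (number of reads) is the CPM normalisation basis.
    """

    library_id: str
    replicate: int
    condition: str
    reads: List[Interval]

    @property
    def size(self) -> int:
        return len(self.reads)

    def starts_by_transcript(self) -> Dict[str, np.ndarray]:
        """Read 5' end positions grouped per transcript (sorted ascending)."""
        out: Dict[str, list] = {}
        for r in self.reads:
            out.setdefault(r.transcript_id, []).append(r.start)
        return {t: np.sort(np.asarray(v, dtype=np.int64)) for t, v in out.items()}

    def intervals_by_transcript(self) -> Dict[str, np.ndarray]:
        """(n, 2) start/end arrays per transcript, sorted by start."""
        out: Dict[str, list] = {}
        for r in self.reads:
            out.setdefault(r.transcript_id, []).append((r.start, r.end))
        return {
            t: np.asarray(sorted(v), dtype=np.int64).reshape(-1, 2)
            for t, v in out.items()
        }


class AnnotationError(ValueError):
    """Raised for malformed annotation input, naming the offending row."""


def load_annotation(path) -> Dict[str, TranscriptAnnotation]:
    """Read a TSV annotation into a dict keyed by transcript_id.

    Required columns: ``transcript_id, utr5_len, cds_len, utr3_len,
    gene_sets`` (semicolon-delimited label list, empty cell allowed).
    Duplicate transcript ids, negative lengths and zero total length are
    errors naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["transcript_id", "utr5_len", "cds_len", "utr3_len", "gene_sets"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AnnotationError(f"missing column(s): {', '.join(missing)}")
    out: Dict[str, TranscriptAnnotation] = {}
    for i, row in df.iterrows():
        tid = row["transcript_id"]
        if tid in out:
            raise AnnotationError(f"row {i + 1}: duplicate transcript_id {tid!r}")
        try:
            lengths = [int(row[c]) for c in ("utr5_len", "cds_len", "utr3_len")]
        except ValueError as exc:
            raise AnnotationError(f"row {i + 1} ({tid}): non-integer length") from exc
        labels = frozenset(s for s in row["gene_sets"].split(";") if s)
        try:
            out[tid] = TranscriptAnnotation(tid, *lengths, gene_sets=labels)
        except ValueError as exc:
            raise AnnotationError(f"row {i + 1}: {exc}") from exc
    return out


def write_annotation(annotations: Mapping[str, TranscriptAnnotation], path) -> None:
    rows = [
        {
            "transcript_id": a.transcript_id,
            "utr5_len": a.utr5_len,
            "cds_len": a.cds_len,
            "utr3_len": a.utr3_len,
            "gene_sets": ";".join(sorted(a.gene_sets)),
        }
        for a in annotations.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def feature_of(annotation: TranscriptAnnotation, position: int) -> str:
    """Feature label (utr5/cds/utr3) hosting a 0-based position."""
    if not (0 <= position < annotation.length):
        raise ValueError(
            f"position {position} outside {annotation.transcript_id} "
            f"[0,{annotation.length})"
        )
    if position < annotation.utr5_len:
        return "utr5"
    if position < annotation.utr5_len + annotation.cds_len:
        return "cds"
    return "utr3"


def overlap_pairs(
    a: Sequence[Interval], b: Sequence[Interval], min_bp: int = 1
) -> List[Tuple[int, int]]:
    """Index pairs (i, j) where a[i] and b[j] share >= min_bp on one transcript.

    Output is sorted by a-index then b-index.  Sweep over per-transcript
    sorted b-intervals keeps this near-linear for typical peak/motif sets.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    b_by_t: Dict[str, list] = {}
    for j, iv in enumerate(b):
        b_by_t.setdefault(iv.transcript_id, []).append((iv.start, iv.end, j))
    for lst in b_by_t.values():
        lst.sort()
    pairs: List[Tuple[int, int]] = []
    for i, iv in enumerate(a):
        cand = b_by_t.get(iv.transcript_id)
        if not cand:
            continue
        hits = []
        for bs, be, j in cand:
            if bs >= iv.end:  # sorted by start: nothing later can overlap
                # long b-intervals starting before iv may still overlap, so
                # only break on start >= a.end
                break
            if min(iv.end, be) - max(iv.start, bs) >= min_bp:
                hits.append(j)
        pairs.extend((i, j) for j in sorted(hits))
    return pairs


def merge_intervals(x: Iterable[Interval], gap: int = 0) -> List[Interval]:
    """Merge per-transcript intervals whose separation is <= gap.

    Touching half-open intervals (separation 0) always merge.  Output is
    sorted by (transcript, start) and non-overlapping.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    by_t: Dict[str, list] = {}
    for iv in x:
        by_t.setdefault(iv.transcript_id, []).append((iv.start, iv.end))
    out: List[Interval] = []
    for t in sorted(by_t):
        spans = sorted(by_t[t])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s - cur_e <= gap:
                cur_e = max(cur_e, e)
            else:
                out.append(Interval(t, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(Interval(t, cur_s, cur_e))
    return out


def coverage_arrays(
    intervals: Iterable[Interval], annotations: Mapping[str, TranscriptAnnotation]
) -> Dict[str, np.ndarray]:
    """Per-base overlap depth per transcript (integer arrays)."""
    cov = {t: np.zeros(a.length, dtype=np.int64) for t, a in annotations.items()}
    for iv in intervals:
        arr = cov.get(iv.transcript_id)
        if arr is None:
            raise KeyError(f"unknown transcript {iv.transcript_id!r}")
        if iv.end > arr.size:
            raise ValueError(
                f"interval {iv.transcript_id}:{iv.start}-{iv.end} exceeds "
                f"transcript length {arr.size}"
            )
        arr[iv.start] += 1
        # diff-array trick; cumsum applied below
        if iv.end < arr.size:
            arr[iv.end] -= 1
    # The loop stored deltas; convert to depth.
    return {t: np.cumsum(arr) for t, arr in cov.items()}


def cpm_coverage(
    reads: ReadSet, annotations: Mapping[str, TranscriptAnnotation]
) -> Dict[str, np.ndarray]:
    """Per-base read coverage in counts-per-million (CPM).

    CPM at a base = (# reads overlapping the base) * 1e6 / library size.
    """
    if reads.size == 0:
        raise ValueError(f"empty ReadSet {reads.library_id!r}")
    depth = coverage_arrays(reads.reads, annotations)
    scale = 1e6 / reads.size
    return {t: arr * scale for t, arr in depth.items()}


def depth_footprint(
    depth: Mapping[str, np.ndarray], min_depth: int
) -> List[Interval]:
    """Maximal intervals where per-base depth >= min_depth."""
    out: List[Interval] = []
    for t in sorted(depth):
        mask = depth[t] >= min_depth
        if not mask.any():
            continue
        padded = np.concatenate([[False], mask, [False]])
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for s, e in edges.reshape(-1, 2):
            out.append(Interval(t, int(s), int(e)))
    return out


class BedError(ValueError):
    """Malformed BED input, naming the line."""


def write_bed(path, intervals: Iterable[Interval]) -> None:
    """Write intervals as BED6 (chrom = transcript_id, strand fixed '+')."""
    buf = io.StringIO()
    for iv in intervals:
        score = iv.score
        score_str = repr(score) if isinstance(score, float) else str(score)
        buf.write(
            f"{iv.transcript_id}\t{iv.start}\t{iv.end}\t{iv.name}\t{score_str}\t+\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_bed(path) -> List[Interval]:
    """Read a BED6 file written by :func:`write_bed` (round-trip identity)."""
    out: List[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedError(f"line {lineno}: expected 6 fields, got {len(fields)}")
            tid, start, end, name, score, strand = fields[:6]
            try:
                s, e = int(start), int(end)
                sc = float(score)
            except ValueError as exc:
                raise BedError(f"line {lineno}: non-numeric coordinate/score") from exc
            if strand != "+":
                raise BedError(f"line {lineno}: strand must be '+' (transcript space)")
            if not (0 <= s < e):
                raise BedError(f"line {lineno}: invalid span [{s},{e})")
            if sc == int(sc) and "." not in score and "e" not in score.lower():
                sc = int(sc)
            out.append(Interval(tid, s, e, name=name, score=sc))
    return out
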