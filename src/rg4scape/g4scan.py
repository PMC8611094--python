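"""Putative RNA G-quadruplex (G4) motif scanning.

Two motif classes are scanned, named for the number of stacked guanine
tetrads the matched sequence can support:

* three-tetrad: ``G{3,}(N{1,7}G{3,}){3}`` — four tracts of >=3 guanines
  separated by loops of 1-7 nucleotides (the classic quadparser consensus);
* two-tetrad: ``G{2,}(N{1,9}G{2,}){3}`` — four tracts of >=2 guanines with
  loops of 1-9 nt, reported only where the span is not contained in a
  three-tetrad match (the classes are exclusive).

Matching is leftmost with greedy tract extension and non-overlapping
continuation from each match end, so motif counts are deterministic.
Loop caps are parameters: the two-tetrad class in particular has no single
agreed definition, and downstream counts depend on it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence

from rg4scape.transcriptome import Interval, TranscriptAnnotation, feature_of

_VALID = re.compile(r"^[ACGU]*$")


@dataclass(frozen=True)
class G4Motif:
    """A scanned G4 motif occurrence on one transcript."""

    interval: Interval
    tetrad_class: str  # "two" | "three"
    sequence: str
    n_tracts: int
    feature: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tetrad_class not in ("two", "three"):
            raise ValueError(f"unknown tetrad class {self.tetrad_class!r}")
        if len(self.sequence) != self.interval.length:
            raise ValueError("sequence length != interval length")


def _normalise(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACGU"))
        raise ValueError(f"invalid character(s) in sequence: {bad}")
    return seq


def _tract_pattern(min_g: int, max_loop: int) -> re.Pattern:
    return re.compile(
        rf"G{{{min_g},}}(?:[ACGU]{{1,{max_loop}}}G{{{min_g},}}){{3}}"
    )


def _scan(
    seq: str,
    transcript_id: str,
    min_g: int,
    max_loop: int,
    tetrad_class: str,
) -> List[G4Motif]:
    rna = _normalise(seq)
    pat = _tract_pattern(min_g, max_loop)
    out: List[G4Motif] = []
    pos = 0
    while True:
        m = pat.search(rna, pos)
        if m is None:
            break
        s, e = m.span()
        sub = rna[s:e]
        n_tracts = len(re.findall(rf"G{{{min_g},}}", sub))
        out.append(
            G4Motif(
                interval=Interval(
                    transcript_id, s, e, name=tetrad_class, score=n_tracts
                ),
                tetrad_class=tetrad_class,
                sequence=sub,
                n_tracts=n_tracts,
            )
        )
        pos = e  # non-overlapping continuation
    return out


def scan_three_tetrad(
    seq: str, transcript_id: str = ".", max_loop: int = 7
) -> List[G4Motif]:
    """Scan for three-tetrad G4 motifs (>=3 G per tract, loops 1..max_loop)."""
    return _scan(seq, transcript_id, 3, max_loop, "three")


def scan_two_tetrad(
    seq: str,
    transcript_id: str = ".",
    max_loop: int = 9,
    three_tetrad_max_loop: int = 7,
) -> List[G4Motif]:
    """Scan for two-tetrad G4 motifs, excluding spans inside three-tetrad hits.

    A two-tetrad match fully contained in any three-tetrad match is dropped:
    such a region is reported once, under the stronger class.
    """
    three = scan_three_tetrad(seq, transcript_id, max_loop=three_tetrad_max_loop)
    spans = [(m.interval.start, m.interval.end) for m in three]
    hits = _scan(seq, transcript_id, 2, max_loop, "two")
    return [
        m
        for m in hits
        if not any(
            s <= m.interval.start and m.interval.end <= e for s, e in spans
        )
    ]


def scan_sequences(
    sequences: Mapping[str, str],
    classes: Sequence[str] = ("two", "three"),
    two_max_loop: int = 9,
    three_max_loop: int = 7,
) -> List[G4Motif]:
    """Scan a {transcript_id: sequence} map for the requested motif classes."""
    out: List[G4Motif] = []
    for tid in sorted(sequences):
        seq = sequences[tid]
        if "three" in classes:
            out.extend(scan_three_tetrad(seq, tid, max_loop=three_max_loop))
        if "two" in classes:
            out.extend(
                scan_two_tetrad(
                    seq,
                    tid,
                    max_loop=two_max_loop,
                    three_tetrad_max_loop=three_max_loop,
                )
            )
    return out


def annotate_motifs(
    motifs: Sequence[G4Motif],
    annotations: Mapping[str, TranscriptAnnotation],
) -> List[G4Motif]:
    """Label each motif with the feature hosting its midpoint.

    Motifs straddling a feature boundary take the midpoint's label
    (half-open rule: a midpoint exactly at utr5_len is CDS).
    """
    out = []
    for m in motifs:
        ann = annotations.get(m.interval.transcript_id)
        if ann is None:
            raise KeyError(f"unknown transcript {m.interval.transcript_id!r}")
        out.append(replace(m, feature=feature_of(ann, m.interval.midpoint)))
    return out


def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into {id: sequence} (file order preserved)."""
    from Bio import SeqIO

    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(path, sequences: Mapping[str, str], width: int = 70) -> None:
    """Write {id: sequence} as wrapped FASTA (deterministic bytes)."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
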