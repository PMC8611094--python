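"""Synthetic transcriptome and sequencing libraries with exported ground truth.

Generates a toy transcriptome whose statistical structure mirrors a
transcriptome-wide RNA G4 study: transcripts partitioned into
5'UTR/CDS/3'UTR with planted two- and three-tetrad G4 motifs (a subset
flagged "folded"), a ribosomal-protein-like ("RP-like") transcript class
whose 5'UTR starts with a pyrimidine tract followed by a guaranteed G4;
CLIP-style protein libraries whose reads cluster at bound motifs with a
protein-specific positional offset (3'-skewed, 5'-skewed or centred);
structure-antibody (BG4) pulldown libraries enriched only at folded
motifs, a matched negative-control antibody (A9) enriched only at planted
"sticky" decoy regions, and input libraries following transcript
abundance; and polysome/total count matrices with a planted translational
effect on the RP-like set under the treated condition.

Every random choice flows from one master seed through named substreams
(one per library/replicate, derived by fixed hashing), so identical
config + seed gives bit-identical outputs and adding a library never
perturbs the others.  The emitted TruthTable is the recovery oracle for
every downstream stage.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from rg4scape.g4scan import scan_three_tetrad, scan_two_tetrad
from rg4scape.te import TECounts
from rg4scape.transcriptome import (
    Interval,
    ReadSet,
    TranscriptAnnotation,
    feature_of,
)

BASES = np.array(list("ACGU"))
SANITISE_FLANK = 12  # nt each side of a planted motif kept free of G runs
MOTIF_MIN_GAP = 30  # nt between planted motifs


def _stream(seed: int, label: str) -> np.random.Generator:
    """Independent RNG stream derived from the master seed by fixed hashing."""
    return np.random.default_rng([seed, zlib.crc32(label.encode()) & 0x7FFFFFFF])


@dataclass(frozen=True)
class ProteinProfile:
    """Binding geometry of one simulated G4-interacting protein."""

    enrichment: float  # fold over local background at bound sites
    offset_mean: float  # mean read-5' offset from the motif midpoint (nt)
    offset_sd: float
    bound_fraction: float = 0.8  # probability a motif is a bound site

    def __post_init__(self) -> None:
        if self.enrichment < 1:
            raise ValueError("enrichment factor must be >= 1")
        if not 0 <= self.bound_fraction <= 1:
            raise ValueError("bound_fraction must be in [0, 1]")


def _default_profiles() -> Dict[str, ProteinProfile]:
    # geometries mirroring a 3'-tail helicase, a 5'-overhang helicase and a
    # protein binding across the G-rich stretch
    return {
        "helicase_3p": ProteinProfile(10.0, +15.0, 8.0),
        "helicase_5p": ProteinProfile(10.0, -15.0, 8.0),
        "centred": ProteinProfile(10.0, 0.0, 8.0),
    }


def _default_plant_rates() -> Dict[Tuple[str, str], float]:
    # probability of planting one motif per (feature, tetrad class);
    # 5'UTR-heavy, matching the observed feature preference of folded G4s
    return {
        ("utr5", "three"): 0.40,
        ("utr5", "two"): 0.30,
        ("cds", "three"): 0.15,
        ("cds", "two"): 0.20,
        ("utr3", "three"): 0.15,
        ("utr3", "two"): 0.20,
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment."""

    n_transcripts: int = 300
    utr5_range: Tuple[int, int] = (60, 160)
    cds_range: Tuple[int, int] = (300, 900)
    utr3_range: Tuple[int, int] = (150, 450)
    gc_content: float = 0.45
    plant_rates: Dict[Tuple[str, str], float] = field(
        default_factory=_default_plant_rates
    )
    folded_fraction: float = 0.6
    protein_profiles: Dict[str, ProteinProfile] = field(
        default_factory=_default_profiles
    )
    replicates: int = 3
    reads_per_library: int = 100_000
    read_length: int = 30
    bg4_enrichment: float = 4.0
    bg4_abundance_sigma: float = 0.25
    n_sticky_decoys: int = 10
    decoy_length: int = 40
    te_effect_log2: float = -0.5
    nb_dispersion: float = 0.01
    polysome_depth: int = 3_000_000
    te_dispersion: float = 5e-4
    rp_set_size: int = 60
    rp_label: str = "RP-like"
    abundance_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (
            ("gc_content", self.gc_content),
            ("folded_fraction", self.folded_fraction),
        ):
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for rate in self.plant_rates.values():
            if not 0 <= rate <= 1:
                raise ValueError("plant rates must be in [0, 1]")
        if self.bg4_enrichment < 1:
            raise ValueError("bg4_enrichment must be >= 1")
        if self.reads_per_library < 1000:
            raise ValueError("reads_per_library must be >= 1000")
        if self.rp_set_size > self.n_transcripts:
            raise ValueError("rp_set_size exceeds n_transcripts")
        # longest plantable motif (4 tracts + 3 loops) must fit each feature
        max_motif = 4 * 3 + 3 * 7
        for feat, rng_ in (
            ("utr5", self.utr5_range),
            ("cds", self.cds_range),
            ("utr3", self.utr3_range),
        ):
            if any(self.plant_rates.get((feat, c), 0) > 0 for c in ("two", "three")):
                if rng_[0] < max_motif + 2 * SANITISE_FLANK:
                    raise ValueError(
                        f"{feat} minimum length {rng_[0]} cannot hold a planted "
                        f"motif plus flanks ({max_motif + 2 * SANITISE_FLANK} nt)"
                    )


@dataclass
class TruthMotif:
    interval: Interval
    tetrad_class: str
    folded: bool
    feature: str


@dataclass
class TruthTable:
    """Planted ground truth, emitted before any analysis stage runs."""

    motifs: List[TruthMotif]
    protein_sites: Dict[str, List[int]]  # motif indices per protein
    bg4_regions: List[Interval]  # truth BG4-enriched regions
    decoys: List[Interval]
    te_logfc: Dict[str, float]
    gene_sets: Dict[str, Set[str]]
    abundance: Dict[str, float]
    bg4_abundance: Dict[str, float]


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=n, p=p)]


def _motif_sequence(
    rng: np.random.Generator, tetrad_class: str
) -> str:
    """A motif drawn from the class grammar: G tracts joined by G-free loops."""
    if tetrad_class == "three":
        g, max_loop = 3, 7
    else:
        g, max_loop = 2, 9
    loops = [
        "".join(rng.choice(list("ACU"), size=rng.integers(1, max_loop + 1)))
        for _ in range(3)
    ]
    tract = "G" * g
    return tract + "".join(loop + tract for loop in loops)


def _sanitise_flanks(seq: np.ndarray, spans: Sequence[Tuple[int, int]]) -> None:
    """Strip G from the flanks of planted motifs so scans recover exact spans."""
    for s, e in spans:
        for lo, hi in ((max(0, s - SANITISE_FLANK), s), (e, min(len(seq), e + SANITISE_FLANK))):
            region = seq[lo:hi]
            region[region == "G"] = "A"
            seq[lo:hi] = region


def _verify_transcript(
    seq: str, planted: Sequence[TruthMotif]
) -> bool:
    """Planted spans recovered exactly; no stray three-tetrad hits nearby."""
    three = {(m.interval.start, m.interval.end) for m in scan_three_tetrad(seq)}
    two = {(m.interval.start, m.interval.end) for m in scan_two_tetrad(seq)}
    truth3 = {
        (m.interval.start, m.interval.end)
        for m in planted
        if m.tetrad_class == "three"
    }
    truth2 = {
        (m.interval.start, m.interval.end) for m in planted if m.tetrad_class == "two"
    }
    if not truth3 <= three or not truth2 <= two:
        return False
    for s, e in three - truth3:
        for m in planted:
            if s < m.interval.end + 20 and e > m.interval.start - 20:
                return False
    return True


def generate_transcriptome(
    config: SimulationConfig,
) -> Tuple[Dict[str, str], Dict[str, TranscriptAnnotation], TruthTable]:
    """Build sequences, annotation and truth for the synthetic transcriptome.

    RP-like transcripts (the first ``rp_set_size``) start with an
    8-nt pyrimidine tract followed by a guaranteed three-tetrad 5'UTR G4.
    Background sequence is resampled until planted spans scan back exactly
    and no unplanted three-tetrad match falls within 20 nt of a truth span.
    """
    rng = _stream(config.seed, "transcriptome")
    sequences: Dict[str, str] = {}
    annotations: Dict[str, TranscriptAnnotation] = {}
    motifs: List[TruthMotif] = []

    width = len(str(config.n_transcripts))
    for i in range(config.n_transcripts):
        tid = f"T{i + 1:0{width}d}"
        is_rp = i < config.rp_set_size
        u5 = int(rng.integers(*config.utr5_range, endpoint=True))
        cds = int(rng.integers(*config.cds_range, endpoint=True))
        u3 = int(rng.integers(*config.utr3_range, endpoint=True))
        labels = frozenset({config.rp_label}) if is_rp else frozenset()
        ann = TranscriptAnnotation(tid, u5, cds, u3, gene_sets=labels)
        annotations[tid] = ann
        length = ann.length

        # choose motif spans first, sequences second
        planted: List[Tuple[int, str, str]] = []  # (start, class, motif seq)
        occupied: List[Tuple[int, int]] = []

        def try_plant(feat: str, cls: str, fixed_start: Optional[int] = None) -> bool:
            mseq = _motif_sequence(rng, cls)
            fi = ann.feature_interval(feat)
            lo = max(fi.start, SANITISE_FLANK)
            hi = min(fi.end, length - SANITISE_FLANK) - len(mseq)
            if hi < lo:
                return False
            for _ in range(20):
                s = fixed_start if fixed_start is not None else int(
                    rng.integers(lo, hi + 1)
                )
                e = s + len(mseq)
                if all(
                    s - MOTIF_MIN_GAP >= oe or e + MOTIF_MIN_GAP <= os
                    for os, oe in occupied
                ):
                    planted.append((s, cls, mseq))
                    occupied.append((s, e))
                    return True
                if fixed_start is not None:
                    return False
            return False

        if is_rp:
            # pyrimidine tract at [0,8) then a 5'UTR G4 at a fixed offset
            if not try_plant("utr5", "three", fixed_start=SANITISE_FLANK):
                raise RuntimeError(f"{tid}: cannot place RP-like 5'UTR motif")
        for (feat, cls), rate in config.plant_rates.items():
            if is_rp and feat == "utr5" and cls == "three":
                continue  # already guaranteed
            if rate > 0 and rng.random() < rate:
                try_plant(feat, cls)

        t_motifs = [
            TruthMotif(
                interval=Interval(tid, s, s + len(mseq), name=cls),
                tetrad_class=cls,
                folded=bool(rng.random() < config.folded_fraction),
                feature=feature_of(ann, (2 * s + len(mseq)) // 2),
            )
            for s, cls, mseq in sorted(planted)
        ]

        for attempt in range(50):
            seq = _random_bases(rng, length, config.gc_content)
            if is_rp:
                seq[:8] = np.array(list("CUCCUUCC"))
            for s, cls, mseq in planted:
                seq[s : s + len(mseq)] = np.array(list(mseq))
            _sanitise_flanks(seq, occupied)
            text = "".join(seq)
            if _verify_transcript(text, t_motifs):
                break
        else:
            raise RuntimeError(f"{tid}: background resampling failed 50 times")
        sequences[tid] = text
        motifs.extend(t_motifs)

    # abundances: log-normal, mean-normalised
    tids = sorted(annotations)
    a_rng = _stream(config.seed, "abundance")
    raw = np.exp(a_rng.normal(0.0, config.abundance_sigma, size=len(tids)))
    abundance = dict(zip(tids, raw / raw.mean()))
    raw_bg4 = np.exp(a_rng.normal(0.0, config.bg4_abundance_sigma, size=len(tids)))
    bg4_abundance = dict(zip(tids, raw_bg4 / raw_bg4.mean()))

    # per-protein bound sites
    site_rng = _stream(config.seed, "bound-sites")
    protein_sites: Dict[str, List[int]] = {}
    for protein in config.protein_profiles:
        prof = config.protein_profiles[protein]
        protein_sites[protein] = [
            i for i in range(len(motifs)) if site_rng.random() < prof.bound_fraction
        ]

    # sticky decoys: regions away from any motif, enriched by both antibodies
    decoy_rng = _stream(config.seed, "decoys")
    decoys: List[Interval] = []
    guard = 0
    while len(decoys) < config.n_sticky_decoys and guard < 10_000:
        guard += 1
        tid = tids[int(decoy_rng.integers(len(tids)))]
        L = annotations[tid].length
        if L <= config.decoy_length:
            continue
        s = int(decoy_rng.integers(0, L - config.decoy_length))
        cand = Interval(tid, s, s + config.decoy_length, name="decoy")
        near = any(
            m.interval.transcript_id == tid
            and cand.start < m.interval.end + 50
            and cand.end > m.interval.start - 50
            for m in motifs
        ) or any(cand.overlap(d) > 0 for d in decoys)
        if not near:
            decoys.append(cand)

    rp_ids = {t for t in tids if config.rp_label in annotations[t].gene_sets}
    truth = TruthTable(
        motifs=motifs,
        protein_sites=protein_sites,
        bg4_regions=[m.interval for m in motifs if m.folded],
        decoys=decoys,
        te_logfc={
            t: (config.te_effect_log2 if t in rp_ids else 0.0) for t in tids
        },
        gene_sets={config.rp_label: rp_ids},
        abundance=abundance,
        bg4_abundance=bg4_abundance,
    )
    return sequences, annotations, truth


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean, phi) with variance mean + phi mean^2 (phi -> 0 is Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + np.maximum(mean, 1e-12)))


def _background_reads(
    rng: np.random.Generator,
    n: int,
    tids: List[str],
    annotations: Mapping[str, TranscriptAnnotation],
    weights: np.ndarray,
    read_length: int,
) -> List[Interval]:
    counts = rng.multinomial(n, weights / weights.sum())
    reads: List[Interval] = []
    for tid, c in zip(tids, counts):
        if c == 0:
            continue
        L = annotations[tid].length
        hi = max(1, L - read_length + 1)
        starts = rng.integers(0, hi, size=c)
        reads.extend(
            Interval(tid, int(s), int(min(s + read_length, L))) for s in starts
        )
    return reads


def simulate_protein_reads(
    config: SimulationConfig,
    truth: TruthTable,
    annotations: Mapping[str, TranscriptAnnotation],
    protein: str,
    replicate: int,
) -> ReadSet:
    """One CLIP-style library: abundance-weighted background plus bound-site
    reads offset from motif midpoints by the protein's binding geometry.

    Per-site read counts are NB with mean = local background in a
    read-length window x (enrichment - 1), so enrichment factor 1 leaves
    pure background.  The sampled per-site counts are attached to the
    returned ReadSet as ``site_counts`` (motif index -> count).
    """
    if protein not in config.protein_profiles:
        raise KeyError(f"unknown protein {protein!r}")
    prof = config.protein_profiles[protein]
    rng = _stream(config.seed, f"iclae/{protein}/{replicate}")
    tids = sorted(annotations)
    lengths = np.array([annotations[t].length for t in tids], dtype=float)
    ab = np.array([truth.abundance[t] for t in tids])
    weights = ab * lengths
    p_t = dict(zip(tids, weights / weights.sum()))

    N = config.reads_per_library
    site_reads: List[Interval] = []
    site_counts: Dict[int, int] = {}
    for idx in truth.protein_sites[protein]:
        m = truth.motifs[idx]
        tid = m.interval.transcript_id
        L = annotations[tid].length
        rate = N * p_t[tid] / L  # background reads per nt
        lam = rate * config.read_length * (prof.enrichment - 1.0)
        c = int(_nb_draw(rng, np.array([lam]), config.nb_dispersion)[0])
        site_counts[idx] = c
        if c == 0:
            continue
        anchor = m.interval.midpoint
        offsets = np.rint(rng.normal(prof.offset_mean, prof.offset_sd, size=c))
        starts = np.clip(anchor + offsets, 0, max(0, L - config.read_length))
        site_reads.extend(
            Interval(tid, int(s), int(min(s + config.read_length, L)))
            for s in starts
        )
    n_bg = N - len(site_reads)
    if n_bg < 0:
        raise ValueError(
            "bound-site reads exceed library size; lower enrichment or raise "
            "reads_per_library"
        )
    reads = site_reads + _background_reads(
        rng, n_bg, tids, annotations, weights, config.read_length
    )
    rs = ReadSet(
        library_id=f"{protein}_rep{replicate}",
        replicate=replicate,
        condition=protein,
        reads=reads,
    )
    rs.site_counts = site_counts  # type: ignore[attr-defined]
    return rs


def _enriched_library(
    config: SimulationConfig,
    annotations: Mapping[str, TranscriptAnnotation],
    abundance: Mapping[str, float],
    enriched_regions: Sequence[Interval],
    enrichment: float,
    rng: np.random.Generator,
    library_id: str,
    replicate: int,
    condition: str,
) -> ReadSet:
    """Background library plus (enrichment-1)-fold extra reads over regions."""
    tids = sorted(annotations)
    lengths = np.array([annotations[t].length for t in tids], dtype=float)
    ab = np.array([abundance[t] for t in tids])
    weights = ab * lengths
    p_t = dict(zip(tids, weights / weights.sum()))
    N = config.reads_per_library
    rl = config.read_length

    extra: List[Interval] = []
    for region in enriched_regions:
        tid = region.transcript_id
        L = annotations[tid].length
        rate = N * p_t[tid] / L
        window = region.length + rl - 1  # starts whose read overlaps the region
        lam = rate * window * (enrichment - 1.0)
        c = int(_nb_draw(rng, np.array([lam]), config.nb_dispersion)[0])
        if c == 0:
            continue
        lo = max(0, region.start - rl + 1)
        hi = min(region.end - 1, max(0, L - rl))
        starts = rng.integers(lo, hi + 1, size=c)
        extra.extend(Interval(tid, int(s), int(min(s + rl, L))) for s in starts)
    n_bg = N - len(extra)
    if n_bg < 0:
        raise ValueError("enriched reads exceed library size")
    reads = extra + _background_reads(rng, n_bg, tids, annotations, weights, rl)
    return ReadSet(
        library_id=library_id, replicate=replicate, condition=condition, reads=reads
    )


def simulate_bg4_experiment(
    config: SimulationConfig,
    truth: TruthTable,
    annotations: Mapping[str, TranscriptAnnotation],
) -> Dict[str, List[ReadSet]]:
    """BG4/A9/input uvRIP libraries (``replicates`` each).

    BG4 IPs are enriched ``bg4_enrichment``-fold over input only at
    folded-flagged motifs; both antibodies are additionally enriched at
    the sticky decoy regions; inputs follow abundance alone.
    """
    out: Dict[str, List[ReadSet]] = {"BG4": [], "A9": [], "input": []}
    ab = truth.bg4_abundance
    for rep in range(1, config.replicates + 1):
        rng_in = _stream(config.seed, f"uvrip/input/{rep}")
        out["input"].append(
            _enriched_library(
                config, annotations, ab, [], 1.0, rng_in, f"input_rep{rep}", rep,
                "input",
            )
        )
        rng_bg4 = _stream(config.seed, f"uvrip/BG4/{rep}")
        out["BG4"].append(
            _enriched_library(
                config,
                annotations,
                ab,
                list(truth.bg4_regions) + list(truth.decoys),
                config.bg4_enrichment,
                rng_bg4,
                f"BG4_rep{rep}",
                rep,
                "BG4",
            )
        )
        rng_a9 = _stream(config.seed, f"uvrip/A9/{rep}")
        out["A9"].append(
            _enriched_library(
                config,
                annotations,
                ab,
                list(truth.decoys),
                config.bg4_enrichment,
                rng_a9,
                f"A9_rep{rep}",
                rep,
                "A9",
            )
        )
    return out


def simulate_polysome_counts(
    config: SimulationConfig,
    truth: TruthTable,
    annotations: Mapping[str, TranscriptAnnotation],
) -> TECounts:
    """Polysome/total NB count matrices for control vs treated conditions.

    Total-RNA means are identical between conditions (the design isolates
    translation from abundance changes); treated polysome means of
    transcripts with planted effects are scaled by 2^(true logFC TE).
    """
    tids = sorted(annotations)
    lengths = np.array([annotations[t].length for t in tids], dtype=float)
    ab = np.array([truth.abundance[t] for t in tids])
    weights = ab * lengths
    base_mean = config.polysome_depth * weights / weights.sum()
    effect = np.array([2.0 ** truth.te_logfc[t] for t in tids])

    counts: Dict[Tuple[str, str, int], pd.Series] = {}
    for fraction in ("polysome", "total"):
        for condition in ("control", "treated"):
            for rep in range(1, config.replicates + 1):
                mean = base_mean.copy()
                if fraction == "polysome" and condition == "treated":
                    mean = mean * effect
                rng = _stream(
                    config.seed, f"polysome/{fraction}/{condition}/{rep}"
                )
                counts[(fraction, condition, rep)] = pd.Series(
                    _nb_draw(rng, mean, config.te_dispersion),
                    index=pd.Index(tids, name="transcript_id"),
                    dtype=np.int64,
                )
    # nominal sequencing depth as the CPM basis: every library is sequenced
    # to the same depth, so composition shifts do not masquerade as TE
    sizes = {k: config.polysome_depth for k in counts}
    return TECounts(counts=counts, library_sizes=sizes)


def plant_feature_biased_intervals(
    annotations: Mapping[str, TranscriptAnnotation],
    n: int,
    width: int,
    feature: str = "utr5",
    bias: float = 8.0,
    seed: int = 0,
) -> List[Interval]:
    """Query intervals with a ``bias``-fold per-base preference for a feature.

    Mixture placement: with probability theta an interval lands fully inside
    a random feature segment (picked proportional to segment length), else
    uniformly within a transcript.  theta = f (bias - 1) / (1 - f) with f
    the feature's base fraction, so the in-feature placement density is
    ~bias-fold the uniform one (an error if the bias is infeasible).
    """
    rng = np.random.default_rng([seed, zlib.crc32(b"biased-intervals")])
    tids = sorted(annotations)
    segs = []
    for t in tids:
        try:
            seg = annotations[t].feature_interval(feature)
        except ValueError:
            continue
        if seg.length >= width:
            segs.append(seg)
    if not segs:
        raise ValueError(f"no {feature} segment can hold width {width}")
    seg_len = np.array([s.length for s in segs], dtype=float)
    total = sum(annotations[t].length for t in tids)
    f = seg_len.sum() / total
    theta = f * (bias - 1.0) / (1.0 - f)
    if theta > 1:
        raise ValueError(
            f"bias {bias} infeasible: feature fraction {f:.3f} allows at most "
            f"{1 / f:.1f}-fold"
        )
    t_len = np.array([annotations[t].length for t in tids], dtype=float)
    out: List[Interval] = []
    for _ in range(n):
        if rng.random() < theta:
            seg = segs[int(rng.choice(len(segs), p=seg_len / seg_len.sum()))]
            s = int(rng.integers(seg.start, seg.end - width + 1))
            out.append(Interval(seg.transcript_id, s, s + width))
        else:
            j = int(rng.choice(len(tids), p=t_len / t_len.sum()))
            tid = tids[j]
            s = int(rng.integers(0, annotations[tid].length - width + 1))
            out.append(Interval(tid, s, s + width))
    return out


# ---------------------------------------------------------------------------
# truth serialisation

def emit_truth(truth: TruthTable, directory) -> None:
    """Serialise the TruthTable as BED6 + TSV (lossless round trip)."""
    from pathlib import Path

    from rg4scape.transcriptome import write_bed

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_bed(
        d / "truth_motifs.bed",
        [
            Interval(
                m.interval.transcript_id,
                m.interval.start,
                m.interval.end,
                name=f"{m.tetrad_class}|{int(m.folded)}|{m.feature}",
                score=0,
            )
            for m in truth.motifs
        ],
    )
    write_bed(d / "truth_bg4_regions.bed", truth.bg4_regions)
    write_bed(d / "truth_decoys.bed", truth.decoys)
    pd.DataFrame(
        [
            {"protein": p, "motif_index": i}
            for p in sorted(truth.protein_sites)
            for i in truth.protein_sites[p]
        ]
    ).to_csv(d / "truth_protein_sites.tsv", sep="\t", index=False)
    rows = [
        {
            "transcript_id": t,
            "te_logfc": repr(float(truth.te_logfc[t])),
            "abundance": repr(float(truth.abundance[t])),
            "bg4_abundance": repr(float(truth.bg4_abundance[t])),
            "gene_sets": ";".join(
                sorted(g for g, mem in truth.gene_sets.items() if t in mem)
            ),
        }
        for t in sorted(truth.te_logfc)
    ]
    pd.DataFrame(rows).to_csv(d / "truth_transcripts.tsv", sep="\t", index=False)


def load_truth(directory) -> TruthTable:
    """Read back a TruthTable written by :func:`emit_truth`."""
    from pathlib import Path

    from rg4scape.transcriptome import read_bed

    d = Path(directory)
    motifs = []
    for iv in read_bed(d / "truth_motifs.bed"):
        cls, folded, feature = iv.name.split("|")
        motifs.append(
            TruthMotif(
                interval=Interval(iv.transcript_id, iv.start, iv.end, name=cls),
                tetrad_class=cls,
                folded=bool(int(folded)),
                feature=feature,
            )
        )
    sites_df = pd.read_csv(d / "truth_protein_sites.tsv", sep="\t")
    protein_sites: Dict[str, List[int]] = {}
    for _, row in sites_df.iterrows():
        protein_sites.setdefault(row["protein"], []).append(int(row["motif_index"]))
    tdf = pd.read_csv(
        d / "truth_transcripts.tsv", sep="\t", dtype=str, keep_default_na=False
    )
    te_logfc, abundance, bg4_ab = {}, {}, {}
    gene_sets: Dict[str, Set[str]] = {}
    for _, row in tdf.iterrows():
        t = row["transcript_id"]
        te_logfc[t] = float(row["te_logfc"])
        abundance[t] = float(row["abundance"])
        bg4_ab[t] = float(row["bg4_abundance"])
        for label in row["gene_sets"].split(";"):
            if label:
                gene_sets.setdefault(label, set()).add(t)
    return TruthTable(
        motifs=motifs,
        protein_sites=protein_sites,
        bg4_regions=read_bed(d / "truth_bg4_regions.bed"),
        decoys=read_bed(d / "truth_decoys.bed"),
        te_logfc=te_logfc,
        gene_sets=gene_sets,
        abundance=abundance,
        bg4_abundance=bg4_ab,
    )
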