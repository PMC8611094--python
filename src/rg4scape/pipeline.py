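"""End-to-end pipeline: configuration, orchestration, manifest and resume.

One YAML config drives every stage in dependency order::

    simulate -> scan -> callpeaks -> consensus -> bg4diff -> enrich
             -> positional -> te -> gsea

Stages read their inputs from, and write their outputs to, the run
directory, so each stage is individually re-runnable from persisted
intermediates.  A manifest records the SHA-256 of every output file;
re-running with ``resume=True`` skips stages whose outputs still match the
manifest and re-executes any stage whose files are missing or corrupted.
With a fixed seed the whole run is bit-reproducible (manifest equality).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Callable, Dict, List

import numpy as np
import pandas as pd
import yaml

from rg4scape import bg4diff as bg4mod
from rg4scape import enrich as enrichmod
from rg4scape import g4scan, peakcall, positional, te
from rg4scape import synthetic_data as synth
from rg4scape.transcriptome import (
    Interval,
    ReadSet,
    load_annotation,
    read_bed,
    write_annotation,
    write_bed,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = (
    "simulate",
    "scan",
    "callpeaks",
    "consensus",
    "bg4diff",
    "enrich",
    "positional",
    "te",
    "gsea",
)


def default_config() -> dict:
    """The shipped pipeline configuration (small, minutes-scale run)."""
    return {
        "seed": 11,
        "stages": {s: True for s in STAGE_ORDER},
        "simulate": {
            "n_transcripts": 120,
            "rp_set_size": 24,
            "reads_per_library": 20_000,
            "replicates": 3,
        },
        "callpeaks": {"bin_size": 30, "p_cutoff": 1e-4, "merge_gap_bins": 1},
        "consensus": {"min_replicates": 2},
        "bg4diff": {"candidate_cpm": None, "lfc_min": 0.8, "fdr_max": 0.05},
        "enrich": {"n_perm": 500, "statistic": "bp", "fdr_floor": 0.01},
        "positional": {"w": 100, "min_reads": 5},
        "te": {"pseudocount": 0.5, "min_cpm": 1.0, "fdr": 0.1},
        "gsea": {"n_perm": 500, "weight": 1.0},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def validate_config(cfg: dict) -> List[str]:
    """All cross-field rules, errors aggregated (empty list = valid)."""
    errors: List[str] = []
    if "seed" not in cfg or not isinstance(cfg["seed"], int):
        errors.append("seed: an integer master seed is mandatory")
    sim = cfg.get("simulate", {})
    reps = sim.get("replicates", 3)
    minrep = cfg.get("consensus", {}).get("min_replicates", 2)
    if minrep > reps:
        errors.append(
            f"consensus.min_replicates={minrep} exceeds simulate.replicates={reps}"
        )
    if minrep < 1:
        errors.append("consensus.min_replicates must be >= 1")
    pc = cfg.get("callpeaks", {}).get("p_cutoff", 1e-4)
    if not 0 < pc < 1:
        errors.append(f"callpeaks.p_cutoff={pc} outside (0, 1)")
    en = cfg.get("enrich", {})
    floor = en.get("fdr_floor", 0.01)
    n_perm = en.get("n_perm", 500)
    if floor <= 0 or floor >= 1:
        errors.append(f"enrich.fdr_floor={floor} outside (0, 1)")
    elif n_perm < 1.0 / floor:
        errors.append(
            f"enrich.n_perm={n_perm} cannot support empirical FDR floor "
            f"{floor} (need n_perm >= {int(np.ceil(1.0 / floor))})"
        )
    bd = cfg.get("bg4diff", {})
    if not 0 < bd.get("fdr_max", 0.05) < 1:
        errors.append("bg4diff.fdr_max outside (0, 1)")
    if bd.get("lfc_min", 0.8) < 0:
        errors.append("bg4diff.lfc_min must be non-negative")
    tecfg = cfg.get("te", {})
    if not 0 < tecfg.get("fdr", 0.1) < 1:
        errors.append("te.fdr outside (0, 1)")
    if cfg.get("positional", {}).get("w", 100) < 1:
        errors.append("positional.w must be >= 1")
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sim_config(cfg: dict) -> synth.SimulationConfig:
    return synth.SimulationConfig(seed=cfg["seed"], **cfg.get("simulate", {}))


def _read_readset(path: Path, library_id: str, replicate: int, condition: str) -> ReadSet:
    return ReadSet(
        library_id=library_id,
        replicate=replicate,
        condition=condition,
        reads=read_bed(path),
    )


def _proteins(cfg: dict) -> List[str]:
    return sorted(_sim_config(cfg).protein_profiles)


# ---------------------------------------------------------------------------
# stages: each reads inputs from disk and returns the files it wrote


def stage_simulate(cfg: dict, out: Path) -> List[Path]:
    sc = _sim_config(cfg)
    sequences, annotations, truth = synth.generate_transcriptome(sc)
    files: List[Path] = []
    g4scan.write_fasta(out / "transcripts.fasta", sequences)
    files.append(out / "transcripts.fasta")
    write_annotation(annotations, out / "annotation.tsv")
    files.append(out / "annotation.tsv")
    synth.emit_truth(truth, out / "truth")
    files += sorted((out / "truth").iterdir())
    (out / "reads").mkdir(exist_ok=True)
    for protein in sorted(sc.protein_profiles):
        for rep in range(1, sc.replicates + 1):
            rs = synth.simulate_protein_reads(sc, truth, annotations, protein, rep)
            p = out / "reads" / f"iclae_{protein}_rep{rep}.bed"
            write_bed(p, rs.reads)
            files.append(p)
    uvrip = synth.simulate_bg4_experiment(sc, truth, annotations)
    for role in ("BG4", "A9", "input"):
        for rs in uvrip[role]:
            p = out / "reads" / f"uvrip_{role}_rep{rs.replicate}.bed"
            write_bed(p, rs.reads)
            files.append(p)
    counts = synth.simulate_polysome_counts(sc, truth, annotations)
    wide = pd.DataFrame(
        {f"{f}:{c}:{r}": s for (f, c, r), s in counts.counts.items()}
    )
    wide.index.name = "transcript_id"
    p = out / "polysome_counts.tsv"
    wide.to_csv(p, sep="\t")
    files.append(p)
    return files


def stage_scan(cfg: dict, out: Path) -> List[Path]:
    sequences = g4scan.read_fasta(out / "transcripts.fasta")
    annotations = load_annotation(out / "annotation.tsv")
    files = []
    for cls in ("three", "two"):
        motifs = g4scan.annotate_motifs(
            g4scan.scan_sequences(sequences, classes=(cls,)), annotations
        )
        ivs = [
            Interval(
                m.interval.transcript_id,
                m.interval.start,
                m.interval.end,
                name=f"{m.tetrad_class}|{m.feature}",
                score=m.n_tracts,
            )
            for m in motifs
        ]
        p = out / f"motifs_{cls}.bed"
        write_bed(p, ivs)
        files.append(p)
    return files


def _iclae_readsets(cfg: dict, out: Path) -> Dict[str, List[ReadSet]]:
    sc = _sim_config(cfg)
    sets: Dict[str, List[ReadSet]] = {}
    for protein in _proteins(cfg):
        sets[protein] = [
            _read_readset(
                out / "reads" / f"iclae_{protein}_rep{rep}.bed",
                f"{protein}_rep{rep}",
                rep,
                protein,
            )
            for rep in range(1, sc.replicates + 1)
        ]
    return sets


def stage_callpeaks(cfg: dict, out: Path) -> List[Path]:
    pc = cfg.get("callpeaks", {})
    (out / "peaks").mkdir(exist_ok=True)
    files = []
    for protein, readsets in _iclae_readsets(cfg, out).items():
        for rs in readsets:
            counts = peakcall.bin_read_starts(rs, bin_size=pc.get("bin_size", 30))
            fit = peakcall.fit_background(counts)
            peaks = peakcall.call_peaks(
                counts,
                fit,
                p_cutoff=pc.get("p_cutoff", 1e-4),
                merge_gap_bins=pc.get("merge_gap_bins", 1),
            )
            p = out / "peaks" / f"{protein}_rep{rs.replicate}.peaks.bed"
            write_bed(p, [pk.interval for pk in peaks])
            files.append(p)
    return files


def stage_consensus(cfg: dict, out: Path) -> List[Path]:
    sc = _sim_config(cfg)
    minrep = cfg.get("consensus", {}).get("min_replicates", 2)
    (out / "consensus").mkdir(exist_ok=True)
    files = []
    for protein in _proteins(cfg):
        rep_sets = []
        for rep in range(1, sc.replicates + 1):
            ivs = read_bed(out / "peaks" / f"{protein}_rep{rep}.peaks.bed")
            rep_sets.append(
                [peakcall.Peak(interval=iv, min_p=1.0, total_count=0) for iv in ivs]
            )
        cons = peakcall.consensus_peaks(rep_sets, min_replicates=minrep)
        p = out / "consensus" / f"{protein}.bed"
        write_bed(p, [c.interval for c in cons])
        files.append(p)
    return files


def _uvrip_readsets(cfg: dict, out: Path) -> Dict[str, List[ReadSet]]:
    sc = _sim_config(cfg)
    return {
        role: [
            _read_readset(
                out / "reads" / f"uvrip_{role}_rep{rep}.bed",
                f"{role}_rep{rep}",
                rep,
                role,
            )
            for rep in range(1, sc.replicates + 1)
        ]
        for role in ("BG4", "A9", "input")
    }


def auto_candidate_cpm(cfg: dict, annotations) -> float:
    """Candidate threshold ~1.9x the mean per-base coverage in CPM.

    Mean coverage CPM equals 1e6 * read_length / workspace_length for any
    library size, so the threshold sits above abundance-driven background
    but below the enriched islands (which exceed it by the enrichment fold).
    """
    sc = _sim_config(cfg)
    total = sum(a.length for a in annotations.values())
    return 1.9 * 1e6 * sc.read_length / total


def stage_bg4diff(cfg: dict, out: Path) -> List[Path]:
    bd = cfg.get("bg4diff", {})
    annotations = load_annotation(out / "annotation.tsv")
    sets = _uvrip_readsets(cfg, out)
    cpm_thr = bd.get("candidate_cpm")
    if cpm_thr is None:
        cpm_thr = auto_candidate_cpm(cfg, annotations)
    regions = bg4mod.candidate_regions(
        sets["BG4"] + sets["A9"], annotations, cpm_threshold=cpm_thr
    )
    readsets = sets["BG4"] + sets["A9"] + sets["input"]
    roles = [(rs.condition, rs.replicate) for rs in readsets]
    matrix = bg4mod.count_region_reads(regions, readsets, roles)
    bg4_res = bg4mod.run_exact_tests(matrix, ("BG4", "input"))
    a9_res = bg4mod.run_exact_tests(matrix, ("A9", "input"))
    called = bg4mod.call_structure_peaks(
        bg4_res,
        a9_res,
        lfc_min=bd.get("lfc_min", 0.8),
        fdr_max=bd.get("fdr_max", 0.05),
    )
    (out / "bg4").mkdir(exist_ok=True)
    files = []
    p = out / "bg4" / "structure_peaks.bed"
    write_bed(p, called)
    files.append(p)
    tab = pd.concat(
        [bg4mod.results_frame(bg4_res), bg4mod.results_frame(a9_res)]
    )
    p = out / "bg4" / "differential.tsv"
    tab.to_csv(p, sep="\t", index=False)
    files.append(p)
    return files


def stage_enrich(cfg: dict, out: Path) -> List[Path]:
    en = cfg.get("enrich", {})
    annotations = load_annotation(out / "annotation.tsv")
    panel = dict(enrichmod.feature_panel(annotations))
    panel["motifs_three"] = read_bed(out / "motifs_three.bed")
    panel["motifs_two"] = read_bed(out / "motifs_two.bed")
    rows = []
    for protein in _proteins(cfg):
        query = read_bed(out / "consensus" / f"{protein}.bed")
        if not query:
            continue
        results = enrichmod.enrichment_panel(
            query,
            panel,
            annotations,
            n_perm=en.get("n_perm", 500),
            statistic=en.get("statistic", "bp"),
            seed=cfg["seed"] + 1000,
            query_name=protein,
        )
        rows.append(enrichmod.results_frame(results))
    (out / "enrich").mkdir(exist_ok=True)
    p = out / "enrich" / "enrichment.tsv"
    pd.concat(rows).to_csv(p, sep="\t", index=False)
    return [p]


def stage_positional(cfg: dict, out: Path) -> List[Path]:
    po = cfg.get("positional", {})
    sc = _sim_config(cfg)
    anchors = read_bed(out / "motifs_three.bed")
    (out / "positional").mkdir(exist_ok=True)
    files = []
    summary = []
    skews: Dict[str, positional.SkewResult] = {}
    for protein in _proteins(cfg):
        pooled_reads = []
        for rep in range(1, sc.replicates + 1):
            pooled_reads += read_bed(
                out / "reads" / f"iclae_{protein}_rep{rep}.bed"
            )
        rs = ReadSet(
            library_id=f"{protein}_pooled",
            replicate=0,
            condition=protein,
            reads=pooled_reads,
        )
        prof = positional.pileup_profile(rs, anchors, w=po.get("w", 100))
        p = out / "positional" / f"profile_{protein}.tsv"
        positional.profile_frame(prof).to_csv(p, sep="\t", index=False)
        files.append(p)
        sk = positional.skew_statistic(
            rs, anchors, w=po.get("w", 100), min_reads=po.get("min_reads", 5)
        )
        skews[protein] = sk
        summary.append(
            {"protein": protein, "median_skew": sk.median, "n_sites": sk.n_sites}
        )
    names = sorted(skews)
    comps = [
        {
            "protein_a": a,
            "protein_b": b,
            "p": positional.compare_skew(skews[a], skews[b]),
        }
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    ]
    p = out / "positional" / "skew_summary.tsv"
    pd.DataFrame(summary).to_csv(p, sep="\t", index=False)
    files.append(p)
    p = out / "positional" / "skew_comparisons.tsv"
    pd.DataFrame(comps).to_csv(p, sep="\t", index=False)
    files.append(p)
    return files


def load_te_counts(path) -> te.TECounts:
    wide = pd.read_csv(path, sep="\t", index_col="transcript_id")
    counts = {}
    for col in wide.columns:
        fraction, condition, rep = col.split(":")
        counts[(fraction, condition, int(rep))] = wide[col].astype(np.int64)
    return te.TECounts(counts=counts)


def stage_te(cfg: dict, out: Path) -> List[Path]:
    tc = cfg.get("te", {})
    counts = load_te_counts(out / "polysome_counts.tsv")
    results = te.differential_te(
        counts,
        pseudocount=tc.get("pseudocount", 0.5),
        min_cpm=tc.get("min_cpm", 1.0),
    )
    (out / "te").mkdir(exist_ok=True)
    p = out / "te" / "te_results.tsv"
    te.results_frame(results).to_csv(p, sep="\t", index=False)
    return [p]


def stage_gsea(cfg: dict, out: Path) -> List[Path]:
    gs = cfg.get("gsea", {})
    sc = _sim_config(cfg)
    tab = pd.read_csv(out / "te" / "te_results.tsv", sep="\t")
    logfc = dict(zip(tab["transcript_id"], tab["logfc_te"]))
    annotations = load_annotation(out / "annotation.tsv")
    members = {
        t for t, a in annotations.items() if sc.rp_label in a.gene_sets
    } & set(logfc)
    res = te.gene_set_running_score(
        logfc,
        members,
        set_name=sc.rp_label,
        weight=gs.get("weight", 1.0),
        n_perm=gs.get("n_perm", 500),
        seed=cfg["seed"] + 2000,
    )
    sig = {t for t, row in tab.set_index("transcript_id").iterrows() if row["fdr"] < cfg.get("te", {}).get("fdr", 0.1)}
    hyper_p = te.hypergeometric_test(sig, members, set(logfc))
    p = out / "te" / "gene_set.json"
    with open(p, "w") as fh:
        json.dump(
            {
                "set": res.set_name,
                "es": res.es,
                "nes": res.nes,
                "p": res.p,
                "n_permutations": res.n_permutations,
                "hypergeometric_p": hyper_p,
                "n_significant": len(sig),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return [p]


STAGES: Dict[str, Callable[[dict, Path], List[Path]]] = {
    "simulate": stage_simulate,
    "scan": stage_scan,
    "callpeaks": stage_callpeaks,
    "consensus": stage_consensus,
    "bg4diff": stage_bg4diff,
    "enrich": stage_enrich,
    "positional": stage_positional,
    "te": stage_te,
    "gsea": stage_gsea,
}


def run_pipeline(cfg: dict, outdir, resume: bool = False) -> dict:
    """Execute enabled stages in order; return (and write) the manifest.

    With ``resume=True``, a stage whose recorded output files all exist
    with matching checksums is skipped; any missing or corrupted file
    triggers re-execution of that stage.
    """
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_bytes = json.dumps(cfg, sort_keys=True, default=str).encode()
    cfg_hash = hashlib.sha256(cfg_bytes).hexdigest()

    old = None
    manifest_path = out / "manifest.json"
    if resume and manifest_path.exists():
        with open(manifest_path) as fh:
            old = json.load(fh)
        if old.get("config") != cfg_hash:
            logger.info("config changed; resume disabled for this run")
            old = None

    manifest: dict = {"config": cfg_hash, "files": {}, "stage_files": {}}
    enabled = cfg.get("stages", {})
    for stage in STAGE_ORDER:
        if not enabled.get(stage, True):
            logger.info("stage %s disabled", stage)
            continue
        if old is not None and stage in old.get("stage_files", {}):
            rels = old["stage_files"][stage]
            ok = all(
                (out / rel).exists()
                and _sha256(out / rel) == old["files"].get(rel)
                for rel in rels
            )
            if ok:
                logger.info("stage %s up to date; skipping", stage)
                manifest["stage_files"][stage] = rels
                for rel in rels:
                    manifest["files"][rel] = old["files"][rel]
                continue
            logger.info("stage %s outputs missing or corrupted; re-running", stage)
        t0 = time.monotonic()
        files = STAGES[stage](cfg, out)
        dt = time.monotonic() - t0
        logger.info("stage %s finished in %.1fs (%d files)", stage, dt, len(files))
        rels = sorted(str(p.relative_to(out)) for p in files)
        manifest["stage_files"][stage] = rels
        for rel in rels:
            manifest["files"][rel] = _sha256(out / rel)
    manifest["files"] = dict(sorted(manifest["files"].items()))
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
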