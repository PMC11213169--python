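"""Stage orchestration: scan -> annotate -> junction -> de novo -> stats.

`run_all` drives the full analysis from a config (paths + parameters),
writes one TSV per stage plus a JSON stats summary and a run manifest
(parameter values, input checksums, seed), and is deterministic given the
manifest.  `demo` builds a miniature synthetic cohort and prints a
human-readable report.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import pandas as pd
import yaml

from . import __version__
from . import annotate as ann
from . import denovo as dn
from . import io as rio
from . import junctions as jx
from . import simulate as sim
from . import stats as st
from .models import DeletionAnnotation, PatientRecord

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters of one analysis run.

    Defaults mirror the analysis conventions used throughout the package:
    50 bp flanks, scan threshold p < 1e-4, 1000 bp Ig/TCR buffer, decay grid
    5..200 bp, 7-mer de novo search, 10,000 bootstrap replicates.
    """

    genome: str = ""
    deletions: str = ""
    deletions_format: str = "auto"
    regions: str = ""
    metadata: str = ""
    pwm_file: str = ""  # MEME file with 'heptamer' and 'nonamer'; empty = defaults
    outdir: str = "ragdel_out"
    flank: int = 50
    decay_flank: int = 200
    threshold: float = 1e-4
    buffer: int = 1000
    decay_grid: Sequence[int] = field(default_factory=lambda: list(range(5, 201, 5)))
    k: int = 7
    bootstrap_B: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_motifs(cfg: PipelineConfig):
    if cfg.pwm_file:
        motifs = rio.read_meme_motifs(cfg.pwm_file)
        missing = {"heptamer", "nonamer"} - set(motifs)
        if missing:
            raise ValueError(f"{cfg.pwm_file}: missing motifs {sorted(missing)}")
        return motifs["heptamer"], motifs["nonamer"]
    from .pwm import default_heptamer, default_nonamer

    return default_heptamer(), default_nonamer()


def run_all(cfg: PipelineConfig) -> Dict[str, Path]:
    """Run every stage in order and write all output tables + manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("genome", "deletions", "regions", "metadata"):
        p = getattr(cfg, name)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"config.{name}: missing input file {p!r}")
    if cfg.pwm_file and not Path(cfg.pwm_file).exists():
        raise FileNotFoundError(f"config.pwm_file: missing input file {cfg.pwm_file!r}")

    genome = rio.load_genome(cfg.genome)
    regions = rio.read_regions(cfg.regions)
    patients = rio.read_patients(cfg.metadata)
    read_stats = rio.ReadStats()
    deletions = rio.read_deletions(cfg.deletions, cfg.deletions_format, stats=read_stats)
    hep, non = load_motifs(cfg)
    logger.info("inputs: %d deletions / %d patients / %d regions",
                len(deletions), len(patients), len(regions))

    paths: Dict[str, Path] = {}

    # stage 1+2: junction normalisation, scan & annotate (classification flank)
    junctions = jx.resolve_all(deletions, genome, renormalize=True)
    scanner = ann.build_scanner(hep, non, cfg.threshold)
    annotations = ann.annotate_deletions(
        deletions, genome, regions, scanner, flank=cfg.flank, buffer=cfg.buffer
    )
    for a in annotations:
        a.junction = junctions[a.deletion.del_id]
    paths["annotations"] = outdir / "annotations.tsv"
    ann.annotations_to_frame(annotations).to_csv(paths["annotations"], sep="\t", index=False)

    # stage 3: junction table + NTN by class
    paths["junctions"] = outdir / "junctions.tsv"
    jx.junctions_to_frame(annotations).to_csv(paths["junctions"], sep="\t", index=False)
    paths["ntn_by_class"] = outdir / "ntn_by_class.tsv"
    off_target = [a for a in annotations if a.target_status == "off_target"]
    jx.ntn_by_class(off_target).to_csv(paths["ntn_by_class"], sep="\t", index=False)

    # stage 4: motif decay over the wide flank
    wide = ann.annotate_deletions(
        deletions, genome, regions, scanner, flank=cfg.decay_flank, buffer=cfg.buffer
    )
    decay = ann.decay_profile(
        [a for a in wide if a.target_status == "off_target"],
        cfg.decay_grid, motifs=("rss_full_12", "rss_full_23"),
    )
    paths["decay"] = outdir / "decay_profile.tsv"
    decay.to_csv(paths["decay"], sep="\t", index=False)

    # stage 5: de novo k-mer discovery on off-target flanks
    flanks = collect_flank_sequences(
        [a.deletion for a in annotations if a.target_status == "off_target"],
        genome, cfg.flank,
    )
    enrich = dn.discover_kmers(flanks, k=cfg.k, seed=cfg.seed)
    paths["denovo"] = outdir / "denovo_kmers.tsv"
    pd.DataFrame([dataclasses.asdict(e) for e in enrich]).to_csv(
        paths["denovo"], sep="\t", index=False
    )

    # stage 6: cohort statistics
    stats = compute_cohort_stats(annotations, patients, seed=cfg.seed, B=cfg.bootstrap_B)
    stats["inputs"] = {
        "n_deletions": len(deletions),
        "n_vaf_excluded": read_stats.n_vaf_excluded,
        "top_kmer": enrich[0].kmer if enrich else None,
        "top_kmer_target_freq": enrich[0].target_freq if enrich else None,
    }
    paths["stats"] = outdir / "stats.json"
    with open(paths["stats"], "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)

    # manifest
    manifest = {
        "version": __version__,
        "python": sys.version.split()[0],
        "parameters": {
            k: (list(v) if isinstance(v, (list, tuple)) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "input_checksums": {
            name: _sha256(Path(getattr(cfg, name)))
            for name in ("genome", "deletions", "regions", "metadata")
        },
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    paths["manifest"] = outdir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths


def collect_flank_sequences(
    deletions, genome, flank: int, repeat_mask: bool = True
) -> List[str]:
    """Breakpoint flank windows (2*flank nt, junction-centred) for de novo
    discovery.  Soft-masked (lowercase) reference bases become N before any
    other processing, so they contribute no k-mers; right-breakpoint windows
    are then reverse-complemented so the interior direction is uniform."""
    from .pwm import revcomp

    out = []
    for d in deletions:
        left, right = ann.extract_flanks(d, genome, flank)
        lseq, rseq = dn.masked_sequences([left.seq, right.seq], repeat_mask)
        if lseq:
            out.append(lseq)
        if rseq:
            out.append(revcomp(rseq))
    return out


def compute_cohort_stats(
    annotations: Sequence[DeletionAnnotation],
    patients: Sequence[PatientRecord],
    seed: int = 0,
    B: int = 10_000,
) -> dict:
    """Group contrasts the cohort analysis reports (all seeds recorded)."""
    summaries = st.patient_summaries(annotations, patients)
    high = summaries[summaries.exposure_group == "high"]
    low = summaries[summaries.exposure_group == "low"]

    out: dict = {"seed": seed, "bootstrap_B": B}

    # per-deletion off-target contrasts
    for key, indicator, test in [
        ("rag_mediated", "rag_mediated", "chi2"),
        ("full_both", "full:both", "fisher"),
        ("heptamer_any", "heptamer:any", "chi2"),
        ("heptamer_both", "heptamer:both", "fisher"),
        ("nonamer_any", "nonamer:any", "chi2"),
    ]:
        t = st.cohort_contingency(annotations, patients, indicator, "off_target")
        entry = {
            "table": [[t.a, t.b], [t.c, t.d]],
            "prop_high": t.prop_high if t.a + t.b else None,
            "prop_low": t.prop_low if t.c + t.d else None,
        }
        try:
            if test == "chi2":
                stat, p = st.chi_square_test(t)
                entry.update(statistic=stat, p=p, test="chi-square")
            else:
                entry.update(p=st.fisher_exact_test(t), test="fisher")
            orr = st.odds_ratio(t)
            entry.update(odds_ratio=orr.odds_ratio,
                         or_ci=[orr.ci_low, orr.ci_high])
        except ValueError as exc:
            entry.update(error=str(exc))
        # bootstrap CIs of the per-group proportions (resampling deletions)
        group_of = {p.patient_id: p.exposure_group for p in patients}
        for grp, sub in (("high", (t.a, t.b)), ("low", (t.c, t.d))):
            n_yes, n_no = sub
            if n_yes + n_no:
                outc = [True] * n_yes + [False] * n_no
                entry[f"ci_{grp}"] = list(
                    st.bootstrap_proportion_ci(outc, B=B, seed=seed)
                )
        out[key] = entry

    # per-patient count comparisons (Wilcoxon) and age associations
    out["wilcoxon_n_deletions_p"] = st.wilcoxon_group_test(
        high.n_deletions, low.n_deletions
    )
    out["wilcoxon_n_rag_p"] = st.wilcoxon_group_test(high.n_rag, low.n_rag)
    slope, p = st.age_association(summaries.n_deletions, summaries.age_at_dx)
    out["age_vs_n_deletions"] = {"slope": slope, "p": p}
    ok = summaries.prop_off_target_rag.notna()
    if ok.sum() >= 3:
        slope, p = st.age_association(
            summaries.prop_off_target_rag[ok], summaries.age_at_dx[ok]
        )
        out["age_vs_prop_rag"] = {"slope": slope, "p": p}

    # multilevel models (off-target deletions)
    for outcome in ("rag_mediated", "full_both"):
        try:
            fit = st.multilevel_rag_model(annotations, patients, outcome)
            out[f"multilevel_{outcome}"] = {
                "or": fit.fixed_effect_or,
                "ci": [fit.ci_low, fit.ci_high],
                "random_intercept_var": fit.random_intercept_var,
                "converged": fit.converged,
                "separated": fit.separated,
            }
        except ValueError as exc:
            out[f"multilevel_{outcome}"] = {"error": str(exc)}
    return out


def demo(seed: int = 1, out=None) -> dict:
    """Miniature end-to-end run (5 patients/group, small genome); prints a
    report and returns the stats dict."""
    cfg = sim.SyntheticConfig(
        n_high=5, n_low=5, n_chroms=2, chrom_length=400_000,
        locus_length=10_000, del_len_max=50_000, ontarget_len_max=20_000,
        seed=seed,
    )
    out = out if out is not None else sys.stdout
    cohort = sim.simulate_cohort(cfg)
    scanner = ann.build_scanner()
    jx.resolve_all(cohort.deletions, cohort.genome)
    annotations = ann.annotate_deletions(
        cohort.deletions, cohort.genome, cohort.regions, scanner
    )
    jx.attach_junctions(annotations, cohort.genome)
    stats = compute_cohort_stats(annotations, cohort.patients, seed=seed, B=2_000)
    rm = stats["rag_mediated"]
    print(f"ragdel demo (seed={seed})", file=out)
    print(f"  patients: {len(cohort.patients)}  deletions: {len(cohort.deletions)}", file=out)
    off = [a for a in annotations if a.target_status == "off_target"]
    print(f"  off-target deletions: {len(off)}", file=out)
    if rm.get("prop_high") is not None and rm.get("prop_low") is not None:
        print(
            f"  off-target RAG-mediated: high {rm['prop_high']:.1%} "
            f"vs low {rm['prop_low']:.1%} (chi-square p = {rm.get('p', float('nan')):.3g})",
            file=out,
        )
    ml = stats.get("multilevel_rag_mediated", {})
    if "or" in ml:
        print(
            f"  multilevel OR (high vs low): {ml['or']:.2f} "
            f"[{ml['ci'][0]:.2f}, {ml['ci'][1]:.2f}]",
            file=out,
        )
    ntn = jx.ntn_by_class(annotations)
    for _, r in ntn.iterrows():
        if r.n_resolved:
            print(
                f"  NTN | {r.rag_group}: {r.prop_ntn:.1%} "
                f"({r.n_ntn}/{r.n_resolved} resolved junctions)",
                file=out,
            )
    return stats
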