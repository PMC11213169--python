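"""Seeded synthetic cohort generator.

Builds a random background genome (A/T 0.3, C/G 0.2, matching the scan
background), six labelled Ig/TCR loci, a two-group patient cohort, and a
deletion callset with the statistical structure the analysis assumes:

* 18 high- / 17 low-exposure patients; per-patient deletion counts drawn
  from a negative binomial with a higher mean in the high-exposure group
  (group totals land near the ~220 vs ~91 off-target deletions of a real
  childhood-ALL cohort of this size);
* ~45% of deletions touch an Ig/TCR locus;
* group-specific off-target RAG-mediated fractions (defaults 0.41 / 0.21);
* RSS instances sampled from the PWMs and written into the genome interior
  to each designated breakpoint, in excision-circle orientation, at
  geometrically decaying offsets (truncated so the planted motif stays
  inside the scanned flank and remains recoverable);
* non-templated junction insertions with class-specific probabilities
  (full RSS at both breakpoints 0.92, at one 0.79, non-RAG 0.65), written
  in canonical (maximally stripped) form.

Every planted attribute is emitted in a truth table so end-to-end recovery
can be checked.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import DeletionCall, GenomicInterval, PatientRecord
from .pwm import (
    ALPHABET,
    DEFAULT_BACKGROUND,
    Pwm,
    default_heptamer,
    default_nonamer,
    revcomp,
)
from . import io as rio

logger = logging.getLogger(__name__)

LOCUS_LABELS = ("IgH", "IgK", "IgL", "TRB", "TRA_TRD", "TRG")


@dataclass
class SyntheticConfig:
    """Study conditions of the emulated cohort (defaults are the analysis
    defaults throughout; see docs/methods.md for provenance of each)."""

    n_high: int = 18
    n_low: int = 17
    # negative-binomial deletion counts per patient (group totals ~400/170,
    # of which ~55% off-target -> ~220/~95)
    mean_deletions_high: float = 22.0
    mean_deletions_low: float = 10.0
    deletions_dispersion: float = 8.0
    min_deletions: int = 3
    p_ontarget: float = 0.45
    p_rag_high: float = 0.41
    p_rag_low: float = 0.21
    p_rag_ontarget: float = 0.93
    p_full_both_given_rag: float = 0.23
    interior_offset_mean: float = 15.0  # geometric, bp from the junction
    p_spacer_23: float = 0.3
    p_ntn_by_class: Dict[str, float] = field(
        default_factory=lambda: {"full_both": 0.92, "full_one": 0.79, "none": 0.65}
    )
    ntn_length_mean: float = 4.0  # geometric, >= 1
    p_unresolved_junction: float = 0.05
    consensus_planting: bool = False  # plant exact consensus instead of PWM draws
    # genome
    n_chroms: int = 4
    chrom_length: int = 1_500_000
    locus_length: int = 25_000
    background: np.ndarray = field(default_factory=lambda: DEFAULT_BACKGROUND.copy())
    # deletion geometry
    del_len_min: int = 1_000
    del_len_max: int = 1_000_000
    ontarget_len_max: int = 100_000
    buffer: int = 1_000  # off-target = both breakpoints > buffer from loci
    flank: int = 50  # planted motifs stay recoverable within this flank
    seed: Optional[int] = None

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError("SyntheticConfig.seed is mandatory")
        return int(self.seed)


@dataclass
class SyntheticCohort:
    genome: Dict[str, str]
    regions: List[GenomicInterval]
    patients: List[PatientRecord]
    deletions: List[DeletionCall]
    truth: pd.DataFrame
    config: SyntheticConfig


def generate_genome(cfg: SyntheticConfig) -> Tuple[Dict[str, str], List[GenomicInterval]]:
    """Background-composition genome plus six non-overlapping Ig/TCR loci."""
    seed = cfg.require_seed()
    rng = np.random.default_rng([seed, 0])
    if cfg.locus_length * 2 > cfg.chrom_length:
        raise ValueError("loci exceed chromosome length")
    bases = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    genome: Dict[str, str] = {}
    for i in range(cfg.n_chroms):
        arr = rng.choice(bases, size=cfg.chrom_length, p=cfg.background)
        genome[f"chr{i + 1}"] = arr.tobytes().decode("ascii")
    regions: List[GenomicInterval] = []
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in genome}
    margin = 2 * cfg.buffer + 2_000
    for j, label in enumerate(LOCUS_LABELS):
        chrom = f"chr{j % cfg.n_chroms + 1}"
        for _ in range(200):
            start = int(rng.integers(margin, cfg.chrom_length - cfg.locus_length - margin))
            end = start + cfg.locus_length
            if all(e + margin <= start or end + margin <= s for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                regions.append(GenomicInterval(chrom, start, end, label))
                break
        else:
            raise ValueError(f"could not place locus {label}: genome too small")
    regions.sort(key=lambda iv: (iv.chrom, iv.start))
    return genome, regions


def _sample_motif(pwm: Pwm, rng: np.random.Generator, consensus: bool) -> str:
    if consensus:
        return pwm.consensus()
    return "".join(
        ALPHABET[rng.choice(4, p=row / row.sum())] for row in pwm.probs
    )


def _truncated_geometric(rng: np.random.Generator, mean: float, cap: int) -> int:
    """Geometric (support 1,2,...) conditioned on <= cap."""
    p = 1.0 / max(mean, 1.0)
    for _ in range(1000):
        v = int(rng.geometric(p))
        if v <= cap:
            return v
    return cap


class _Planter:
    """Writes RSS instances into a mutable genome, tracking footprints so two
    planted motifs never overlap."""

    def __init__(self, genome: Dict[str, str], cfg: SyntheticConfig, rng: np.random.Generator):
        from .pwm import ScoreTable, compose_full_rss

        self.cfg = cfg
        self.rng = rng
        self.buf = {c: bytearray(s, "ascii") for c, s in genome.items()}
        self.footprints: Dict[str, List[Tuple[int, int]]] = {c: [] for c in genome}
        self.hep = default_heptamer(cfg.background)
        self.non = default_nonamer(cfg.background)
        # planted sites emulate RSSs actually used by RAG, i.e. functional
        # sites: instances are PWM-sampled but conditioned on passing the
        # scanner's P < 1e-4 threshold for their spacer variant
        self._tables = {
            sp: ScoreTable(compose_full_rss(self.hep, self.non, sp))
            for sp in (12, 23)
        }
        self._thresholds = {sp: t.threshold_int(1e-4) for sp, t in self._tables.items()}

    def _free(self, chrom: str, start: int, end: int) -> bool:
        return all(e <= start or end <= s for s, e in self.footprints[chrom])

    def rss_sequence(self) -> Tuple[str, int]:
        spacer_len = 23 if self.rng.random() < self.cfg.p_spacer_23 else 12
        bases = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
        spacer = self.rng.choice(bases, size=spacer_len, p=self.cfg.background).tobytes().decode()
        table, thr = self._tables[spacer_len], self._thresholds[spacer_len]
        for _ in range(200):
            hep = _sample_motif(self.hep, self.rng, self.cfg.consensus_planting)
            non = _sample_motif(self.non, self.rng, self.cfg.consensus_planting)
            seq = hep + spacer + non
            if table.int_score(seq) >= thr:
                return seq, spacer_len
        # unreachable in practice (consensus always passes)
        return self.hep.consensus() + spacer + self.non.consensus(), spacer_len

    def plant(self, chrom: str, bp: int, side: str) -> Optional[Tuple[int, int]]:
        """Plant one full RSS interior to a breakpoint in excision-circle
        orientation.  Returns (offset, spacer_len) or None if no free slot."""
        seq, spacer_len = self.rss_sequence()
        L = len(seq)
        cap = max(1, self.cfg.flank - L + 1)
        for _ in range(20):
            off = _truncated_geometric(self.rng, self.cfg.interior_offset_mean, cap)
            if side == "left":
                start = bp + off - 1  # interior position `off` = index bp+off-1
                text = seq
            else:
                start = bp - off - L + 1  # motif's junction-proximal base at bp-off
                text = revcomp(seq)
            end = start + L
            if start < 0 or end > len(self.buf[chrom]):
                continue
            if self._free(chrom, start, end):
                self.buf[chrom][start:end] = text.encode("ascii")
                self.footprints[chrom].append((start, end))
                return off, spacer_len
        return None

    def sequences(self) -> Dict[str, str]:
        return {c: b.decode("ascii") for c, b in self.buf.items()}


def generate_cohort(
    cfg: SyntheticConfig,
    genome: Dict[str, str],
    regions: Sequence[GenomicInterval],
) -> SyntheticCohort:
    """Draw the patient cohort and deletion callset, planting motifs and
    junction inserts into a copy of the genome."""
    seed = cfg.require_seed()
    rng = np.random.default_rng([seed, 1])
    patients = _draw_patients(cfg, rng)
    planter = _Planter(genome, cfg, rng)
    bases = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    chroms = list(genome)
    deletions: List[DeletionCall] = []
    truth_rows: List[dict] = []
    # registries keeping scan windows clear of other breakpoints' planted
    # motifs: off-target deletions are re-scanned with 200 bp decay flanks,
    # so they get a wider exclusion radius than on-target ones (50 bp flanks)
    bp_on: Dict[str, List[int]] = {c: [] for c in chroms}
    bp_off: Dict[str, List[int]] = {c: [] for c in chroms}

    k = cfg.deletions_dispersion
    for p in patients:
        mean = cfg.mean_deletions_high if p.exposure_group == "high" else cfg.mean_deletions_low
        n_del = max(cfg.min_deletions, int(rng.negative_binomial(k, k / (k + mean))))
        for j in range(n_del):
            del_id = f"{p.patient_id}_d{j + 1}"
            ontarget = rng.random() < cfg.p_ontarget
            d, row = _draw_deletion(cfg, rng, planter, regions, chroms, genome,
                                    bp_on, bp_off, p, del_id, ontarget)
            deletions.append(d)
            truth_rows.append(row)

    final = planter.sequences()
    # junction inserts need the final planted genome (canonical NTN form)
    for d, row in zip(deletions, truth_rows):
        _assign_junction(cfg, rng, final, d, row)
    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(
        genome=final, regions=list(regions), patients=patients,
        deletions=deletions, truth=truth, config=cfg,
    )


def _draw_patients(cfg: SyntheticConfig, rng: np.random.Generator) -> List[PatientRecord]:
    patients = []
    for i in range(cfg.n_high + cfg.n_low):
        group = "high" if i < cfg.n_high else "low"
        patients.append(
            PatientRecord(
                patient_id=f"P{i + 1:02d}",
                exposure_group=group,
                age_at_dx=float(np.round(rng.uniform(1.0, 14.0), 1)),
            )
        )
    return patients


def _draw_deletion(cfg, rng, planter, regions, chroms, genome, bp_on, bp_off,
                   patient, del_id, ontarget) -> Tuple[DeletionCall, dict]:
    region_idx_margin = cfg.buffer + 2 * cfg.flank
    # clearance radii: widest scan flank (200 bp decay scan for off-target,
    # cfg.flank for on-target) + planted-motif reach (~90 bp from its bp)
    spacing_off = 300
    spacing_on = 3 * cfg.flank

    def clear(chrom, *bps) -> bool:
        """Distinct rearrangement events use distinct RSS sites: no
        breakpoint may see another breakpoint's planted motif in its
        scan window."""
        radius_on = spacing_on if ontarget else spacing_off
        for bp in bps:
            if any(abs(bp - q) < spacing_off for q in bp_off[chrom]):
                return False
            if any(abs(bp - q) < radius_on for q in bp_on[chrom]):
                return False
        return True

    for _ in range(200):
        if ontarget:
            locus = regions[rng.integers(len(regions))]
            left = int(rng.integers(locus.start, locus.end))
            length = int(np.exp(rng.uniform(np.log(cfg.del_len_min), np.log(cfg.ontarget_len_max))))
            right = left + length
            chrom = locus.chrom
            if right + cfg.flank >= len(genome[chrom]):
                continue
            if not clear(chrom, left, right):
                continue
            is_rag = rng.random() < cfg.p_rag_ontarget
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            n = len(genome[chrom])
            max_len = min(cfg.del_len_max, n // 2)
            length = int(np.exp(rng.uniform(np.log(cfg.del_len_min), np.log(max_len))))
            left = int(rng.integers(cfg.flank + 1, n - length - cfg.flank - 1))
            right = left + length
            # both breakpoints must be off-locus by > buffer
            near = any(
                iv.chrom == chrom
                and (iv.start - region_idx_margin < bp < iv.end + region_idx_margin)
                for iv in regions for bp in (left, right)
            )
            if near:
                continue
            if not clear(chrom, left, right):
                continue
            group_p = cfg.p_rag_high if patient.exposure_group == "high" else cfg.p_rag_low
            is_rag = rng.random() < group_p

        rag_class = "none"
        off_l = off_r = None
        spacer_l = spacer_r = None
        if is_rag:
            both = rng.random() < cfg.p_full_both_given_rag
            sides = ("left", "right") if both else (("left",) if rng.random() < 0.5 else ("right",))
            planted = {}
            for side in sides:
                bp = left if side == "left" else right
                res = planter.plant(chrom, bp, side)
                if res is not None:
                    planted[side] = res
            if len(planted) == 2:
                rag_class = "full_both"
            elif len(planted) == 1:
                rag_class = "full_one"
            else:
                continue  # no free slot; redraw the whole deletion
            off_l, spacer_l = planted.get("left", (None, None))
            off_r, spacer_r = planted.get("right", (None, None))
        (bp_on if ontarget else bp_off)[chrom].extend((left, right))
        d = DeletionCall(
            patient_id=patient.patient_id, chrom=chrom, left_bp=left,
            right_bp=right, vaf=float(np.round(rng.uniform(0.15, 0.6), 3)),
            del_id=del_id,
        )
        row = {
            "del_id": del_id, "patient_id": patient.patient_id,
            "exposure_group": patient.exposure_group,
            "chrom": chrom, "left_bp": left, "right_bp": right,
            "target_truth": "ig_tcr" if ontarget else "off_target",
            "rag_truth": rag_class,
            "rag_mediated_truth": rag_class in ("full_both", "full_one"),
            "offset_left": off_l, "offset_right": off_r,
            "spacer_left": spacer_l, "spacer_right": spacer_r,
        }
        return d, row
    raise ValueError(
        f"could not place deletion {del_id} after 200 attempts "
        f"(genome too small or loci too dense)"
    )


def _assign_junction(cfg, rng, genome, d: DeletionCall, row: dict) -> None:
    """Draw the junction insert: NTN with class-specific probability, written
    in canonical form (first/last NTN base never templated)."""
    if rng.random() < cfg.p_unresolved_junction:
        d.junction_insert = None
        row.update(ntn_truth=None, ntn_len_truth=None, junction_resolved=False)
        return
    cls = row["rag_truth"]
    p_ntn = cfg.p_ntn_by_class.get(cls, cfg.p_ntn_by_class["none"])
    has_ntn = rng.random() < p_ntn
    if not has_ntn:
        d.junction_insert = ""
        row.update(ntn_truth=False, ntn_len_truth=0, junction_resolved=True)
        return
    length = max(1, int(rng.geometric(1.0 / cfg.ntn_length_mean)))
    bases = list("ACGT")
    probs = np.asarray(cfg.background)
    seq = [bases[rng.choice(4, p=probs)] for _ in range(length)]
    # canonical form: the junction must not be reducible by template stripping
    first_tpl = genome[d.chrom][d.left_bp]
    last_tpl = genome[d.chrom][d.right_bp - 1]
    if length == 1:
        # a single base must avoid both templated neighbours
        cand = [b for b in bases if b != first_tpl and b != last_tpl]
        seq = [cand[int(rng.integers(len(cand)))]]
    else:
        while seq[0] == first_tpl:
            seq[0] = bases[rng.choice(4, p=probs)]
        while seq[-1] == last_tpl:
            seq[-1] = bases[rng.choice(4, p=probs)]
    d.junction_insert = "".join(seq)
    row.update(ntn_truth=True, ntn_len_truth=length, junction_resolved=True)


def simulate_cohort(cfg: SyntheticConfig) -> SyntheticCohort:
    """Genome + cohort in one call (the usual entry point)."""
    genome, regions = generate_genome(cfg)
    return generate_cohort(cfg, genome, regions)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Dict[str, Path]:
    """Write FASTA/BED/VCF/TSV representations of a synthetic cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "regions": outdir / "ig_tcr_loci.bed",
        "deletions_vcf": outdir / "deletions.vcf",
        "deletions_tsv": outdir / "deletions.tsv",
        "patients": outdir / "patients.tsv",
        "truth": outdir / "truth.tsv",
    }
    rio.write_fasta(cohort.genome, paths["genome"])
    rio.write_regions_bed(cohort.regions, paths["regions"])
    rio.write_deletions_vcf(
        cohort.deletions, paths["deletions_vcf"],
        {c: len(s) for c, s in cohort.genome.items()},
    )
    rio.write_deletions_tsv(cohort.deletions, paths["deletions_tsv"])
    rio.write_patients_tsv(cohort.patients, paths["patients"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def simulate_mixed_logit_outcomes(
    n_high: int = 18,
    n_low: int = 17,
    mean_obs: float = 9.0,
    intercept: float = -1.3,
    odds_ratio: float = 2.5,
    intercept_sd: float = 0.5,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-deletion outcomes drawn directly from the random-intercept
    logistic model (for parameter-recovery checks of the estimator)."""
    rng = np.random.default_rng(seed)
    y, x, cl = [], [], []
    for i in range(n_high + n_low):
        grp = 1 if i < n_high else 0
        u = rng.normal(0.0, intercept_sd)
        n_i = max(2, int(rng.poisson(mean_obs)))
        eta = intercept + np.log(odds_ratio) * grp + u
        p = 1.0 / (1.0 + np.exp(-eta))
        y.extend(rng.random(n_i) < p)
        x.extend([grp] * n_i)
        cl.extend([f"P{i:02d}"] * n_i)
    return np.asarray(y, int), np.asarray(x, int), np.asarray(cl)
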