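"""Readers and writers for the pipeline's external formats.

Deletion callsets come in as VCF (SVTYPE=DEL with END), BEDPE or TSV; locus
annotations as BED; motifs as MEME-minimal probability matrices; patient
metadata and all result tables as TSV.  Everything is normalised to 0-based
half-open coordinates on the way in.

VCF convention used here: POS is taken as the first deleted base (1-based)
and END as the last, so the deleted segment is ``[POS-1, END)`` 0-based.
Callers that emit a padding base at POS should be converted upstream or read
via TSV/BEDPE.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import DeletionCall, GenomicInterval, PatientRecord
from .pwm import Pwm

logger = logging.getLogger(__name__)

VAF_MIN = 0.10  # callset inclusion threshold (exclusive)

DELETION_TSV_COLUMNS = [
    "del_id", "patient_id", "chrom", "left_bp", "right_bp", "vaf",
    "junction_insert",
]


# junction inserts distinguish "absent" (junction unresolved, written ".")
# from "resolved with no inserted bases" (written "-")
def _insert_encode(ins: Optional[str]) -> str:
    if ins is None:
        return "."
    return ins if ins else "-"


def _insert_decode(raw) -> Optional[str]:
    if raw is None or raw == ".":
        return None
    s = str(raw)
    return "" if s == "-" else s


@dataclass
class ReadStats:
    """Bookkeeping for a callset read: kept/excluded record counts."""

    n_read: int = 0
    n_kept: int = 0
    n_vaf_excluded: int = 0


# ---------------------------------------------------------------------------
# deletion callsets


def read_deletions(
    path: str | Path,
    format: str = "auto",
    vaf_min: float = VAF_MIN,
    default_patient: str = "",
    stats: Optional[ReadStats] = None,
) -> List[DeletionCall]:
    """Read a deletion callset; records with VAF <= ``vaf_min`` are dropped.

    ``format`` is one of vcf / bedpe / tsv / auto (by extension).  Exclusions
    are counted in ``stats`` (if given) and logged.
    """
    path = Path(path)
    if format == "auto":
        suffix = path.suffix.lower()
        format = {".vcf": "vcf", ".bedpe": "bedpe"}.get(suffix, "tsv")
    if format == "vcf":
        calls = _read_vcf(path, vaf_min, default_patient, stats)
    elif format == "bedpe":
        calls = _read_bedpe(path, vaf_min, default_patient, stats)
    elif format == "tsv":
        calls = _read_tsv(path, vaf_min, stats)
    else:
        raise ValueError(f"unknown deletion format {format!r}")
    return calls


def _keep(vaf: Optional[float], vaf_min: float) -> bool:
    return vaf is None or vaf > vaf_min


def _validate_vcf_ends(path) -> None:
    """htslib clamps END < POS with only a warning; fail loudly instead."""
    import re

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: malformed VCF record")
            m = re.search(r"(?:^|;)END=(-?\d+)", fields[7])
            if m and int(m.group(1)) < int(fields[1]):
                raise ValueError(
                    f"{path}:{lineno}: END={m.group(1)} < POS={fields[1]}"
                )


def _read_vcf(path, vaf_min, default_patient, stats) -> List[DeletionCall]:
    stats = stats if stats is not None else ReadStats()
    _validate_vcf_ends(path)
    calls: List[DeletionCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        declared = set(vcf.header.info)

        def info(rec, key, default=None):
            return rec.info.get(key, default) if key in declared else default

        for i, rec in enumerate(vcf.fetch() if vcf.index else vcf):
            if info(rec, "SVTYPE") != "DEL":
                continue
            stats.n_read += 1
            end = rec.stop  # pysam: 0-based exclusive end from END
            left = rec.pos - 1  # first deleted base, 0-based
            if end < rec.pos:
                raise ValueError(
                    f"{path}: record {rec.id or i + 1} at {rec.chrom}:{rec.pos}: "
                    f"END {end} < POS {rec.pos}"
                )
            vaf = info(rec, "VAF")
            if isinstance(vaf, tuple):
                vaf = vaf[0]
            if not _keep(vaf, vaf_min):
                stats.n_vaf_excluded += 1
                continue
            insert = info(rec, "INSSEQ")
            patient = info(rec, "PID", default_patient)
            calls.append(
                DeletionCall(
                    patient_id=str(patient),
                    chrom=rec.chrom,
                    left_bp=left,
                    right_bp=end,
                    vaf=float(vaf) if vaf is not None else None,
                    junction_insert=_insert_decode(insert),
                    del_id=rec.id or f"del{i + 1}",
                )
            )
            stats.n_kept += 1
    _log_exclusions(path, stats)
    return calls


def _read_bedpe(path, vaf_min, default_patient, stats) -> List[DeletionCall]:
    """BEDPE: deletion spans [start1, end2); optional cols 11/12 = patient, vaf."""
    stats = stats if stats is not None else ReadStats()
    calls: List[DeletionCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: BEDPE needs >= 6 columns")
            try:
                c1, s1, _e1, c2, _s2, e2 = parts[0], int(parts[1]), int(parts[2]), parts[3], int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BEDPE record") from exc
            if c1 != c2:
                raise ValueError(f"{path}:{lineno}: inter-chromosomal record is not a deletion")
            stats.n_read += 1
            name = parts[6] if len(parts) > 6 else f"del{lineno}"
            patient = parts[10] if len(parts) > 10 else default_patient
            vaf = float(parts[11]) if len(parts) > 11 else None
            if not _keep(vaf, vaf_min):
                stats.n_vaf_excluded += 1
                continue
            calls.append(
                DeletionCall(patient_id=patient, chrom=c1, left_bp=s1,
                             right_bp=e2, vaf=vaf, del_id=name)
            )
            stats.n_kept += 1
    _log_exclusions(path, stats)
    return calls


def _read_tsv(path, vaf_min, stats) -> List[DeletionCall]:
    stats = stats if stats is not None else ReadStats()
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "chrom": str})
    missing = {"patient_id", "chrom", "left_bp", "right_bp"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    calls: List[DeletionCall] = []
    for i, row in enumerate(df.itertuples(index=False), 2):  # 2 = header + 1
        stats.n_read += 1
        vaf = getattr(row, "vaf", None)
        vaf = None if vaf is None or pd.isna(vaf) else float(vaf)
        if not _keep(vaf, vaf_min):
            stats.n_vaf_excluded += 1
            continue
        ins = getattr(row, "junction_insert", None)
        ins = None if ins is None or (isinstance(ins, float) and pd.isna(ins)) else _insert_decode(ins)
        try:
            calls.append(
                DeletionCall(
                    patient_id=str(row.patient_id), chrom=str(row.chrom),
                    left_bp=int(row.left_bp), right_bp=int(row.right_bp),
                    vaf=vaf, junction_insert=ins,
                    del_id=str(getattr(row, "del_id", "") or f"del{i - 1}"),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
        stats.n_kept += 1
    _log_exclusions(path, stats)
    return calls


def _log_exclusions(path, stats: ReadStats) -> None:
    if stats.n_vaf_excluded:
        logger.info(
            "%s: excluded %d/%d records with VAF <= %.2f",
            path, stats.n_vaf_excluded, stats.n_read, VAF_MIN,
        )


def write_deletions_tsv(calls: Sequence[DeletionCall], path: str | Path) -> None:
    rows = [
        {
            "del_id": c.del_id, "patient_id": c.patient_id, "chrom": c.chrom,
            "left_bp": c.left_bp, "right_bp": c.right_bp,
            "vaf": c.vaf if c.vaf is not None else np.nan,
            "junction_insert": _insert_encode(c.junction_insert),
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=DELETION_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def write_deletions_vcf(
    calls: Sequence[DeletionCall],
    path: str | Path,
    contig_lengths: Dict[str, int],
) -> None:
    """Write deletions as symbolic <DEL> records (POS = first deleted base)."""
    header = pysam.VariantHeader()
    header.add_line('##ALT=<ID=DEL,Description="Deletion">')
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="Last deleted base (1-based)">')
    header.add_line('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">')
    header.add_line('##INFO=<ID=PID,Number=1,Type=String,Description="Patient id">')
    header.add_line('##INFO=<ID=INSSEQ,Number=1,Type=String,Description="Junction insert sequence">')
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.chrom, c.left_bp)):
            rec = out.new_record(
                contig=c.chrom, start=c.left_bp, stop=c.right_bp,
                alleles=("N", "<DEL>"), id=c.del_id or None,
            )
            rec.info["SVTYPE"] = "DEL"
            if c.vaf is not None:
                rec.info["VAF"] = c.vaf
            if c.patient_id:
                rec.info["PID"] = c.patient_id
            if c.junction_insert is not None:
                rec.info["INSSEQ"] = _insert_encode(c.junction_insert)
            out.write(rec)


# ---------------------------------------------------------------------------
# regions / BED


def read_regions(path: str | Path, merge: bool = True) -> List[GenomicInterval]:
    """Read a BED3+ file; overlapping intervals are merged per chromosome."""
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            label = parts[3] if len(parts) > 3 else ""
            intervals.append(GenomicInterval(chrom, start, end, label))
    return merge_intervals(intervals) if merge else intervals


def merge_intervals(intervals: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    """Sort per chromosome and merge overlapping (not merely abutting-label) runs."""
    out: List[GenomicInterval] = []
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur = ivs[0]
        labels = [cur.label] if cur.label else []
        cur_start, cur_end = cur.start, cur.end
        for iv in ivs[1:]:
            if iv.start < cur_end:  # strict overlap
                cur_end = max(cur_end, iv.end)
                if iv.label and iv.label not in labels:
                    labels.append(iv.label)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end, ",".join(labels)))
                cur_start, cur_end = iv.start, iv.end
                labels = [iv.label] if iv.label else []
        out.append(GenomicInterval(chrom, cur_start, cur_end, ",".join(labels)))
    return out


def write_regions_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


# ---------------------------------------------------------------------------
# patients


def read_patients(path: str | Path) -> List[PatientRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    missing = {"patient_id", "exposure_group", "age_at_dx"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        PatientRecord(
            patient_id=str(r.patient_id),
            exposure_group=str(r.exposure_group),
            age_at_dx=float(r.age_at_dx),
            immunophenotype=str(getattr(r, "immunophenotype", "")) or None,
        )
        for r in df.itertuples(index=False)
    ]


def write_patients_tsv(patients: Sequence[PatientRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id, "exposure_group": p.exposure_group,
                "age_at_dx": p.age_at_dx,
                "immunophenotype": p.immunophenotype or ".",
            }
            for p in patients
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MEME-minimal motif files
#
# Bio.motifs' "minimal" reader stores rounded pseudo-counts, which distorts
# probability columns; the reader below keeps the printed probabilities exact.


def read_meme_motifs(path: str | Path, pseudocount: float = 0.01) -> Dict[str, Pwm]:
    """Parse a MEME-minimal file into named Pwm objects.

    ``pseudocount`` is added to every cell before per-row renormalisation so
    zero probabilities never occur (log-odds stay finite).
    """
    background = None
    motifs: Dict[str, Pwm] = {}
    name, rows = None, []

    def flush():
        nonlocal name, rows
        if name is not None:
            if not rows:
                raise ValueError(f"{path}: motif {name!r} has width 0")
            mat = np.asarray(rows, dtype=float)
            if (mat.sum(axis=1) == 0).any():
                raise ValueError(f"{path}: motif {name!r} has an all-zero row")
            mat = mat + pseudocount
            mat = mat / mat.sum(axis=1, keepdims=True)
            motifs[name] = Pwm(name, mat, background)
        name, rows = None, []

    with open(path) as fh:
        lines = iter(fh)
        for line in lines:
            s = line.strip()
            if s.startswith("Background letter frequencies"):
                vals = next(lines).split()
                background = np.array(
                    [float(dict(zip(vals[::2], vals[1::2]))[b]) for b in "ACGT"]
                )
            elif s.startswith("MOTIF"):
                flush()
                name = s.split()[1]
            elif s.startswith("letter-probability matrix"):
                continue
            elif name is not None and s and s[0] in "0123456789.":
                vals = [float(x) for x in s.split()]
                if len(vals) != 4:
                    raise ValueError(f"{path}: motif {name!r}: need 4 values per row")
                if any(v < 0 for v in vals):
                    raise ValueError(f"{path}: motif {name!r}: negative weight")
                rows.append(vals)
    flush()
    return motifs


def read_pwm(path: str | Path, name: Optional[str] = None, pseudocount: float = 0.01) -> Pwm:
    """Read one motif from a MEME file (the named one, or the first)."""
    motifs = read_meme_motifs(path, pseudocount)
    if not motifs:
        raise ValueError(f"{path}: no motifs found")
    if name is None:
        return next(iter(motifs.values()))
    if name not in motifs:
        raise ValueError(f"{path}: no motif named {name!r} (have {sorted(motifs)})")
    return motifs[name]


def write_meme_motifs(motifs: Sequence[Pwm], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifs[0].background if motifs else [0.25] * 4
        fh.write("Background letter frequencies\n")
        fh.write("A {0:.6g} C {1:.6g} G {2:.6g} T {3:.6g}\n\n".format(*bg))
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in m.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: Dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def load_genome(path: str | Path) -> Dict[str, str]:
    """Load a FASTA into memory as plain uppercase-preserving strings.

    Synthetic genomes here are a few Mb, so in-memory strings are simpler and
    faster than indexed access; lowercase (soft-masked) bases are preserved.
    """
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end], clamped to the contig; works for dicts
    of strings and for pyfaidx.Fasta objects."""
    seq = genome[chrom]
    n = len(seq)
    start, end = max(0, start), min(n, end)
    if start >= end:
        return ""
    piece = seq[start:end]
    return piece if isinstance(piece, str) else str(piece)
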