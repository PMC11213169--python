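"""Per-deletion breakpoint annotation.

For every deletion this module decides (i) whether it touches an Ig/TCR
locus (on-target) or lies fully outside them (off-target, the candidate
pool for illegitimate RAG recombination), (ii) which RSS evidence class it
falls in based on motif scans of the breakpoint flanks, (iii) whether
interior heptamers sit in the excision-circle orientation, and (iv) how the
proportion of motif-positive deletions decays with distance from the
breakpoint.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import DeletionAnnotation, DeletionCall, GenomicInterval, MotifHit
from .pwm import (
    MotifScanner,
    Pwm,
    best_hit,
    compose_full_rss,
    default_heptamer,
    default_nonamer,
)
from . import io as rio

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 50
DEFAULT_BUFFER = 1000
DEFAULT_THRESHOLD = 1e-4


@dataclass
class Flank:
    """One breakpoint flank window, junction-relative.

    ``seq[breakpoint_offset:]`` is interior when ``interior_sign == +1``,
    ``seq[:breakpoint_offset]`` when ``-1``.  ``truncated`` marks windows
    clipped by a contig end, ``clipped`` marks interior extents shortened to
    the deletion midpoint (short deletions), so one motif instance cannot be
    counted for both breakpoints.
    """

    seq: str
    breakpoint_offset: int
    interior_sign: int
    truncated: bool = False
    clipped: bool = False


class RegionIndex:
    """Sorted per-chromosome interval lookup with a symmetric buffer."""

    def __init__(self, regions: Sequence[GenomicInterval], buffer: int = DEFAULT_BUFFER):
        self.buffer = buffer
        self.regions = list(regions)
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        by_chrom: Dict[str, List[GenomicInterval]] = {}
        for iv in rio.merge_intervals(regions):
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            self._starts[chrom] = np.array([iv.start - buffer for iv in ivs])
            self._ends[chrom] = np.array([iv.end + buffer for iv in ivs])

    def contains(self, chrom: str, pos: int) -> bool:
        """True iff pos lies within <= buffer bp of any region on chrom."""
        if chrom not in self._starts:
            return False
        i = np.searchsorted(self._starts[chrom], pos, side="right") - 1
        return i >= 0 and pos < self._ends[chrom][i]

    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(self._starts)


def classify_target_status(
    d: DeletionCall,
    regions: RegionIndex | Sequence[GenomicInterval],
    buffer: int = DEFAULT_BUFFER,
) -> str:
    """"ig_tcr" if either breakpoint lies within ``buffer`` bp (inclusive) of
    an Ig/TCR locus, else "off_target"."""
    idx = regions if isinstance(regions, RegionIndex) else RegionIndex(regions, buffer)
    if d.chrom not in idx.chroms:
        logger.debug("chromosome %s absent from region set; off_target", d.chrom)
        return "off_target"
    if idx.contains(d.chrom, d.left_bp) or idx.contains(d.chrom, d.right_bp):
        return "ig_tcr"
    return "off_target"


def extract_flanks(
    d: DeletionCall,
    genome,
    flank: int = DEFAULT_FLANK,
    clip_interior: bool = True,
) -> Tuple[Flank, Flank]:
    """Windows of up to 2*flank bp centred on each breakpoint.

    Interior extents of deletions shorter than 2*flank are clipped at the
    segment midpoint (left side gets the ceil half) so the two windows never
    share interior bases.
    """
    length = d.length
    overlap = length < 2 * flank
    if clip_interior:
        mid = d.left_bp + (length + 1) // 2
        left_int = min(d.left_bp + flank, mid)
        right_int = max(d.right_bp - flank, mid)
    else:
        left_int = min(d.left_bp + flank, d.right_bp)
        right_int = max(d.right_bp - flank, d.left_bp)
    n = len(genome[d.chrom])

    lstart = max(0, d.left_bp - flank)
    lseq = rio.fetch(genome, d.chrom, lstart, left_int)
    left = Flank(
        seq=lseq,
        breakpoint_offset=d.left_bp - lstart,
        interior_sign=1,
        truncated=lstart > d.left_bp - flank or d.left_bp - flank < 0,
        clipped=clip_interior and overlap,
    )

    rend = min(n, d.right_bp + flank)
    rseq = rio.fetch(genome, d.chrom, right_int, rend)
    right = Flank(
        seq=rseq,
        breakpoint_offset=d.right_bp - right_int,
        interior_sign=-1,
        truncated=d.right_bp + flank > n,
        clipped=clip_interior and overlap,
    )
    return left, right


def build_scanner(
    heptamer: Optional[Pwm] = None,
    nonamer: Optional[Pwm] = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> MotifScanner:
    """Scanner over heptamer, nonamer and both full-RSS spacer variants."""
    hep = heptamer if heptamer is not None else default_heptamer()
    non = nonamer if nonamer is not None else default_nonamer()
    motifs = [
        hep,
        non,
        compose_full_rss(hep, non, 12),
        compose_full_rss(hep, non, 23),
    ]
    return MotifScanner(motifs, threshold=threshold)


def classify_rag(
    d: DeletionCall,
    left_hits: Sequence[MotifHit],
    right_hits: Sequence[MotifHit],
) -> str:
    """Strongest RSS evidence class for one deletion.

    A full RSS (either spacer variant) at both breakpoints -> full_both; at
    exactly one -> full_one; otherwise heptamer-only, then nonamer-only,
    then none.  full_both/full_one constitute "putatively RAG-mediated".
    """
    def has_full(hits: Sequence[MotifHit]) -> bool:
        return any(h.motif_name.startswith("rss_full") for h in hits)

    full_l, full_r = has_full(left_hits), has_full(right_hits)
    if full_l and full_r:
        return "full_both"
    if full_l or full_r:
        return "full_one"
    all_hits = list(left_hits) + list(right_hits)
    if any(h.motif_name == "heptamer" for h in all_hits):
        return "heptamer_only"
    if any(h.motif_name == "nonamer" for h in all_hits):
        return "nonamer_only"
    return "none"


def check_orientation(hit: MotifHit, side: str) -> Optional[bool]:
    """Excision-circle orientation test for an interior heptamer.

    Deleted RSSs leave the genome as an excision circle whose heptamers face
    the retained junction with their 5'-CAC end: at the left breakpoint a
    correctly oriented interior heptamer matches the + strand, at the right
    breakpoint the - strand.  Exterior hits have no defined orientation
    (returns None).
    """
    if hit.start_offset <= 0:
        return None
    if side == "left":
        return hit.strand == "+"
    if side == "right":
        return hit.strand == "-"
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def annotate_deletions(
    deletions: Sequence[DeletionCall],
    genome,
    regions: Sequence[GenomicInterval] | RegionIndex,
    scanner: Optional[MotifScanner] = None,
    flank: int = DEFAULT_FLANK,
    buffer: int = DEFAULT_BUFFER,
) -> List[DeletionAnnotation]:
    """Scan and classify every deletion.

    Hits are collapsed to the best match per motif per side before
    classification, so hit multiplicity never changes a class.
    """
    scanner = scanner if scanner is not None else build_scanner()
    idx = regions if isinstance(regions, RegionIndex) else RegionIndex(regions, buffer)
    out: List[DeletionAnnotation] = []
    for d in deletions:
        left, right = extract_flanks(d, genome, flank)
        lh = scanner.scan(left.seq, left.breakpoint_offset, left.interior_sign)
        rh = scanner.scan(right.seq, right.breakpoint_offset, right.interior_sign)
        lh = collapse_hits(lh)
        rh = collapse_hits(rh)
        target = classify_target_status(d, idx)
        rag = classify_rag(d, lh, rh)
        ori_l = _orientation_flag(lh, "left")
        ori_r = _orientation_flag(rh, "right")
        out.append(
            DeletionAnnotation(
                deletion=d, target_status=target, rag_class=rag,
                left_hits=lh, right_hits=rh,
                orientation_ok_left=ori_l, orientation_ok_right=ori_r,
            )
        )
    return out


def collapse_hits(hits: Sequence[MotifHit]) -> List[MotifHit]:
    """One best hit per motif name (lowest p, then |offset|, interior first)."""
    names = []
    for h in hits:
        if h.motif_name not in names:
            names.append(h.motif_name)
    return [best_hit(hits, n) for n in names]


def _orientation_flag(hits: Sequence[MotifHit], side: str) -> Optional[bool]:
    """Orientation of the best interior heptamer evidence on one side.

    Prefers the heptamer itself; falls back to the heptamer part of a full
    RSS (same strand logic).  None when no interior hit exists.
    """
    interior = [h for h in hits if h.start_offset > 0]
    hep = [h for h in interior if h.motif_name == "heptamer"]
    if not hep:
        hep = [h for h in interior if h.motif_name.startswith("rss_full")]
    if not hep:
        return None
    return check_orientation(best_hit(hep), side)


def decay_profile(
    annotations: Sequence[DeletionAnnotation],
    distances: Iterable[int] = range(5, 201, 5),
    motifs: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Proportion of deletions with >= 1 hit within each signed distance band.

    For a grid distance d, the interior proportion counts deletions with any
    selected hit at 0 < offset <= d (either breakpoint), the exterior one at
    -d <= offset < 0.  Both curves are monotone non-decreasing in d.
    """
    distances = list(distances)
    rows = []
    n = len(annotations)
    if n == 0:
        return pd.DataFrame(columns=["distance", "interior", "exterior"])
    offsets: List[List[int]] = []
    for a in annotations:
        offs = [
            h.start_offset
            for h in list(a.left_hits) + list(a.right_hits)
            if motifs is None or h.motif_name in motifs
        ]
        offsets.append(offs)
    for d in distances:
        n_int = sum(1 for offs in offsets if any(0 < o <= d for o in offs))
        n_ext = sum(1 for offs in offsets if any(-d <= o < 0 for o in offs))
        rows.append({"distance": d, "interior": n_int / n, "exterior": n_ext / n})
    return pd.DataFrame(rows)


def annotations_to_frame(annotations: Sequence[DeletionAnnotation]) -> pd.DataFrame:
    """Flatten annotations into the per-deletion result table."""
    rows = []
    for a in annotations:
        d = a.deletion
        row = {
            "del_id": d.del_id,
            "patient_id": d.patient_id,
            "chrom": d.chrom,
            "left_bp": d.left_bp,
            "right_bp": d.right_bp,
            "length": d.length,
            "target_status": a.target_status,
            "rag_class": a.rag_class,
            "rag_mediated": a.rag_mediated,
            "full_any": a.has_motif("full"),
            "full_both": a.has_motif("full", "both"),
            "heptamer_any": a.has_motif("heptamer"),
            "heptamer_both": a.has_motif("heptamer", "both"),
            "nonamer_any": a.has_motif("nonamer"),
            "nonamer_both": a.has_motif("nonamer", "both"),
            "orientation_ok_left": a.orientation_ok_left,
            "orientation_ok_right": a.orientation_ok_right,
        }
        if a.junction is not None:
            row.update(
                junction_status=a.junction.status,
                ntn_len=a.junction.ntn_len,
                ntn_seq=a.junction.ntn_seq or ".",
                mh_len=a.junction.mh_len,
            )
        rows.append(row)
    return pd.DataFrame(rows)
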