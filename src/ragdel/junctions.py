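"""Deletion junction classification: NTN, microhomology, or blunt.

Non-templated nucleotides (NTN) at a deletion junction — bases matching
neither flank's reference continuation — are a hallmark of RAG cleavage
followed by NHEJ repair with TdT activity.  Junctions without an insert are
classified by the longest exact sequence shared by both breakpoint flanks
(microhomology, assignable to either side) or as blunt joins.

Templated bases in a reported insert are stripped maximally against the
deleted sequence on both sides and the breakpoints re-normalised
accordingly, so caller-dependent junction shifts cannot move motif offsets.
"""
from __future__ import annotations

import logging
from typing import List, Optional, Sequence

import pandas as pd

from .models import DeletionAnnotation, DeletionCall, JunctionResult
from . import io as rio

logger = logging.getLogger(__name__)

MAX_MICROHOMOLOGY = 25  # bp; far above biological expectation

_VALID = set("ACGTN")


def resolve_junction(
    d: DeletionCall,
    genome,
    max_mh: int = MAX_MICROHOMOLOGY,
    renormalize: bool = True,
) -> JunctionResult:
    """Classify one junction; may left-align ``d``'s breakpoints in place.

    With an observed insert, the longest prefix matching the reference
    continuation past the left breakpoint and the longest suffix matching
    the reference preceding the right breakpoint are stripped (templated
    bases); what remains is NTN.  Stripped bases shift the breakpoints
    (logged), keeping the junction representation canonical.  An empty
    insert is resolved by exact-shared-suffix microhomology, else blunt.
    ``junction_insert is None`` -> unresolved.
    """
    ins = d.junction_insert
    if ins is None:
        return JunctionResult(status="unresolved")
    ins = ins.upper()
    if set(ins) - _VALID:
        raise ValueError(
            f"deletion {d.del_id or '?'}: junction insert contains "
            f"non-ACGTN characters: {ins!r}"
        )

    left_bp, right_bp = d.left_bp, d.right_bp
    if ins:
        # templated prefix from the deleted sequence past the left breakpoint
        avail = min(len(ins), right_bp - left_bp - 1)
        ref_fwd = rio.fetch(genome, d.chrom, left_bp, left_bp + avail)
        p = _common_prefix(ins, ref_fwd)
        rest = ins[p:]
        # templated suffix from the deleted sequence before the right breakpoint
        avail = min(len(rest), right_bp - (left_bp + p) - 1)
        ref_rev = rio.fetch(genome, d.chrom, right_bp - avail, right_bp)
        s = _common_suffix(rest, ref_rev)
        ntn = rest[: len(rest) - s] if s else rest
        if renormalize and (p or s):
            logger.debug(
                "deletion %s: stripped %d templated prefix / %d suffix bases; "
                "breakpoints re-normalised", d.del_id or "?", p, s,
            )
            d.left_bp = left_bp + p
            d.right_bp = right_bp - s
            d.junction_insert = ntn if ntn else ""
        if ntn:
            return JunctionResult(status="ntn", ntn_seq=ntn, ntn_len=len(ntn))
        left_bp, right_bp = left_bp + p, right_bp - s

    # no (remaining) inserted bases: microhomology or blunt
    mh = microhomology_length(genome, d.chrom, left_bp, right_bp, max_mh)
    if mh:
        return JunctionResult(status="microhomology", mh_len=mh)
    return JunctionResult(status="blunt")


def microhomology_length(
    genome, chrom: str, left_bp: int, right_bp: int, max_mh: int = MAX_MICROHOMOLOGY
) -> int:
    """Longest m with the m bases ending at left_bp equal to those ending at
    right_bp (shared junction sequence assignable to either side)."""
    cap = min(max_mh, left_bp, right_bp - left_bp)
    m = 0
    left = rio.fetch(genome, chrom, left_bp - cap, left_bp)
    right = rio.fetch(genome, chrom, right_bp - cap, right_bp)
    while m < cap and left[cap - 1 - m] == right[cap - 1 - m]:
        m += 1
    return m


def _common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _common_suffix(a: str, b: str) -> int:
    return _common_prefix(a[::-1], b[::-1])


def resolve_all(
    deletions: Sequence[DeletionCall], genome, renormalize: bool = True
) -> dict:
    """Resolve every junction (breakpoints re-normalised in place first, so
    motif annotation downstream sees canonical coordinates).  Returns a
    mapping del_id -> JunctionResult."""
    return {d.del_id: resolve_junction(d, genome, renormalize=renormalize) for d in deletions}


def attach_junctions(
    annotations: Sequence[DeletionAnnotation], genome
) -> List[DeletionAnnotation]:
    """Resolve and attach a JunctionResult to every annotation (in place).

    Breakpoints are not re-normalised here — use :func:`resolve_all` before
    annotation when canonicalisation is wanted."""
    for a in annotations:
        a.junction = resolve_junction(a.deletion, genome, renormalize=False)
    return list(annotations)


def ntn_by_class(annotations: Sequence[DeletionAnnotation]) -> pd.DataFrame:
    """NTN proportion by RAG evidence group over resolved junctions.

    Groups: full RSS at both breakpoints, at one breakpoint, and everything
    else (non-RAG).  Proportions use resolved junctions as the denominator;
    total counts are reported alongside.
    """
    groups = {"full_both": "full_both", "full_one": "full_one"}
    rows = []
    for group in ("full_both", "full_one", "other"):
        members = [
            a for a in annotations
            if groups.get(a.rag_class, "other") == group
        ]
        resolved = [
            a for a in members
            if a.junction is not None and a.junction.status != "unresolved"
        ]
        n_ntn = sum(1 for a in resolved if a.junction.status == "ntn")
        rows.append(
            {
                "rag_group": group,
                "n_total": len(members),
                "n_resolved": len(resolved),
                "n_ntn": n_ntn,
                "prop_ntn": n_ntn / len(resolved) if resolved else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def junctions_to_frame(annotations: Sequence[DeletionAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        j = a.junction or JunctionResult(status="unresolved")
        rows.append(
            {
                "del_id": a.deletion.del_id,
                "patient_id": a.deletion.patient_id,
                "status": j.status,
                "ntn_len": j.ntn_len,
                "ntn_seq": j.ntn_seq or ".",
                "mh_len": j.mh_len,
            }
        )
    return pd.DataFrame(rows)
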