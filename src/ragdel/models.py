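"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open everywhere inside the package.  A
deletion's removed segment is ``[left_bp, right_bp)``; file readers convert
from the 1-based conventions of VCF/BED on the way in.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence


@dataclass(frozen=True)
class GenomicInterval:
    """A labelled half-open interval on a chromosome (e.g. an Ig/TCR locus)."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class DeletionCall:
    """One somatic deletion call in one patient.

    The deleted segment is ``[left_bp, right_bp)`` (0-based half-open).
    ``junction_insert`` is the tumour-observed sequence between the retained
    left and right flanks, when the caller reports it; ``None`` means the
    junction could not be resolved from the callset.
    """

    patient_id: str
    chrom: str
    left_bp: int
    right_bp: int
    vaf: Optional[float] = None
    junction_insert: Optional[str] = None
    del_id: str = ""

    def __post_init__(self) -> None:
        if self.right_bp - self.left_bp < 1:
            raise ValueError(
                f"deletion {self.del_id or '?'}: right_bp must exceed left_bp "
                f"({self.left_bp} >= {self.right_bp})"
            )

    @property
    def length(self) -> int:
        return self.right_bp - self.left_bp


@dataclass(frozen=True)
class PatientRecord:
    """Cohort metadata for one patient."""

    patient_id: str
    exposure_group: str  # "high" or "low"
    age_at_dx: float
    immunophenotype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.exposure_group not in ("high", "low"):
            raise ValueError(
                f"exposure_group must be 'high' or 'low', got "
                f"{self.exposure_group!r}"
            )


@dataclass(frozen=True)
class MotifHit:
    """One motif match near a breakpoint.

    ``start_offset`` is the signed distance (bp) from the breakpoint to the
    match base nearest the junction: positive offsets are interior to the
    deletion (inside the removed segment), negative exterior.  The first
    interior base is +1, the first exterior base is -1.
    """

    motif_name: str
    strand: str  # "+" or "-"
    start_offset: int
    score: float  # log-odds, bits
    pvalue: float


@dataclass
class JunctionResult:
    """Classification of one deletion junction.

    ``ntn`` — non-templated nucleotides remain after stripping bases that
    match either reference flank continuation; ``microhomology`` — the two
    flanks share a suffix assignable to either side; ``blunt`` — neither;
    ``unresolved`` — no junction sequence was available.
    """

    status: str  # ntn | microhomology | blunt | unresolved
    ntn_seq: str = ""
    ntn_len: int = 0
    mh_len: int = 0


# RAG evidence classes, strongest first.  "full_both"/"full_one" constitute
# "putatively RAG-mediated"; heptamer/nonamer-only are weaker evidence.
RAG_CLASSES = ("full_both", "full_one", "heptamer_only", "nonamer_only", "none")


@dataclass
class DeletionAnnotation:
    """Per-deletion result of the breakpoint motif analysis."""

    deletion: DeletionCall
    target_status: str  # "ig_tcr" | "off_target"
    rag_class: str
    left_hits: Sequence[MotifHit] = field(default_factory=list)
    right_hits: Sequence[MotifHit] = field(default_factory=list)
    orientation_ok_left: Optional[bool] = None
    orientation_ok_right: Optional[bool] = None
    junction: Optional[JunctionResult] = None

    @property
    def rag_mediated(self) -> bool:
        """True when a full RSS was found within the flank of >= 1 breakpoint."""
        return self.rag_class in ("full_both", "full_one")

    def has_motif(self, kind: str, side: str = "any") -> bool:
        """Indicator for per-motif tabulations independent of rag_class.

        kind: "full", "heptamer" or "nonamer"; side: "any", "both", "left",
        "right".
        """

        def present(hits: Sequence[MotifHit]) -> bool:
            if kind == "full":
                return any(h.motif_name.startswith("rss_full") for h in hits)
            return any(h.motif_name == kind for h in hits)

        left, right = present(self.left_hits), present(self.right_hits)
        if side == "left":
            return left
        if side == "right":
            return right
        if side == "both":
            return left and right
        return left or right
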