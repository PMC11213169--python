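"""Position-weight-matrix scoring of recombination signal sequences (RSS).

The scanner mirrors FIMO's model: a window of width *w* gets the log-odds
score

    s(x) = sum_i log2( p_i(x_i) / b(x_i) )

under a 0-order background *b* (default A/T 0.3, C/G 0.2), and the match
p-value is the exact probability that a background-drawn window scores at
least *s*.  The exact null distribution is computed by dynamic programming
over per-position score contributions discretised to a fixed granularity
(default 1e-3 bits); p-value lookups use the same discretised scores, so
the table agrees with brute-force enumeration bin for bin.

A full RSS matrix is the heptamer followed by an uninformative 12- or 23-nt
spacer (columns equal to the background) and the nonamer, so the spacer
contributes exactly zero to every score.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .models import MotifHit

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
#: Background of the study genome: A/T 0.3 each, C/G 0.2 each.
DEFAULT_BACKGROUND = np.array([0.3, 0.2, 0.2, 0.3])

#: RSS consensus sequences (heptamer abuts the coding segment via its CAC end).
HEPTAMER_CONSENSUS = "CACAGTG"
NONAMER_CONSENSUS = "ACAAAAACC"

DEFAULT_GRANULARITY = 1e-3  # bits per discretisation bin


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8: A=0 C=1 G=2 T=3, anything else 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def revcomp(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass
class Pwm:
    """Probability matrix over ACGT with an attached background model."""

    name: str
    probs: np.ndarray  # shape (width, 4), rows sum to 1
    background: np.ndarray = None  # shape (4,)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.background is None:
            self.background = DEFAULT_BACKGROUND.copy()
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] == 0:
            raise ValueError(f"PWM {self.name!r}: need a (width, 4) matrix")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name!r}: columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """(width, 5) log2(p/b) matrix; column 4 (N) contributes 0."""
        lo = np.log2(self.probs / self.background)
        return np.hstack([lo, np.zeros((self.width, 1))])

    def reverse_complement(self) -> "Pwm":
        """PWM matching the motif on the opposite strand of the scanned text."""
        return Pwm(self.name, self.probs[::-1, ::-1].copy(), self.background)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))


def consensus_pwm(
    name: str,
    consensus: str,
    consensus_weight: float = 0.8,
    background: Optional[np.ndarray] = None,
) -> Pwm:
    """Build a PWM placing `consensus_weight` on each consensus base.

    The remaining mass is split evenly over the three other bases.  This is
    the package's default stand-in for experimentally derived RSS matrices
    (which are configurable via MEME files).
    """
    w = len(consensus)
    probs = np.full((w, 4), (1.0 - consensus_weight) / 3.0)
    for i, base in enumerate(consensus.upper()):
        probs[i, _BASE_INDEX[base]] = consensus_weight
    return Pwm(name, probs, background)


def default_heptamer(background: Optional[np.ndarray] = None) -> Pwm:
    return consensus_pwm("heptamer", HEPTAMER_CONSENSUS, 0.8, background)


def default_nonamer(background: Optional[np.ndarray] = None) -> Pwm:
    return consensus_pwm("nonamer", NONAMER_CONSENSUS, 0.8, background)


def score_window(pwm: Pwm, window: str) -> float:
    """Log-odds score (bits) of a single window of length ``pwm.width``."""
    if len(window) != pwm.width:
        raise ValueError(
            f"window length {len(window)} != PWM width {pwm.width}"
        )
    idx = encode(window)
    return float(pwm.log_odds()[np.arange(pwm.width), idx].sum())


def compose_full_rss(heptamer: Pwm, nonamer: Pwm, spacer_len: int) -> Pwm:
    """Concatenate heptamer + uninformative spacer + nonamer.

    Physiological RSSs carry a 12- or 23-nt spacer between heptamer and
    nonamer; the spacer is unconstrained, so its columns equal the
    background and contribute zero log-odds.
    """
    if spacer_len not in (12, 23):
        raise ValueError(f"spacer_len must be 12 or 23, got {spacer_len}")
    if heptamer.width != 7:
        raise ValueError("heptamer PWM must have width 7")
    if nonamer.width != 9:
        raise ValueError("nonamer PWM must have width 9")
    bg = heptamer.background
    spacer = np.tile(bg, (spacer_len, 1))
    probs = np.vstack([heptamer.probs, spacer, nonamer.probs])
    return Pwm(f"rss_full_{spacer_len}", probs, bg)


class ScoreTable:
    """Exact p-value table for one PWM orientation under its background.

    Per-position log-odds contributions are discretised to integer multiples
    of ``granularity``; the distribution of the discretised window score
    under the background is built by repeated convolution.  ``pvalue`` of a
    window is the tail mass at the window's own discretised score, hence
    identical to brute-force enumeration using the same discretisation.
    """

    def __init__(self, pwm: Pwm, granularity: float = DEFAULT_GRANULARITY):
        if granularity <= 0:
            raise ValueError("granularity must be positive")
        self.granularity = granularity
        self.pwm = pwm
        lo = pwm.log_odds()  # (w, 5)
        self.int_matrix = np.rint(lo / granularity).astype(np.int64)
        K = self.int_matrix[:, :4]
        lo_min = int(K.min(axis=1).sum())
        lo_max = int(K.max(axis=1).sum())
        span = lo_max - lo_min + 1
        bg = pwm.background
        # point mass at score 0; array index of int score s is s - lo_min
        dist = np.zeros(span)
        dist[-lo_min] = 1.0
        cur_min = cur_max = 0  # running support of the partial sum
        for i in range(pwm.width):
            new = np.zeros(span)
            for b in range(4):
                k = int(K[i, b])
                src = dist[cur_min - lo_min : cur_max - lo_min + 1]
                new[cur_min + k - lo_min : cur_max + k - lo_min + 1] += bg[b] * src
            kmin, kmax = int(K[i].min()), int(K[i].max())
            cur_min += kmin
            cur_max += kmax
            dist = new
        # tail[j] = P(int score >= lo_min + j)
        self.lo_min = lo_min
        self.tail = np.minimum(dist[::-1].cumsum()[::-1], 1.0)

    def int_score(self, window: str) -> int:
        idx = encode(window)
        return int(self.int_matrix[np.arange(self.pwm.width), idx].sum())

    def pvalue_of_int(self, s: np.ndarray | int) -> np.ndarray | float:
        """Tail probability P(background window's discretised score >= s)."""
        j = np.clip(np.asarray(s) - self.lo_min, 0, len(self.tail) - 1)
        out = self.tail[j]
        out = np.where(np.asarray(s) - self.lo_min < 0, 1.0, out)
        out = np.where(np.asarray(s) - self.lo_min >= len(self.tail), 0.0, out)
        if np.ndim(s) == 0:
            return float(out)
        return out

    def pvalue(self, score_bits: float) -> float:
        """p-value of a continuous score, rounded to the table's granularity."""
        return float(self.pvalue_of_int(int(round(score_bits / self.granularity))))

    def threshold_int(self, alpha: float) -> int:
        """Smallest discretised score with tail probability < alpha."""
        idx = np.searchsorted(-self.tail, -alpha, side="right")
        return self.lo_min + int(idx)


def score_pvalue_table(pwm: Pwm, granularity: float = DEFAULT_GRANULARITY) -> ScoreTable:
    return ScoreTable(pwm, granularity)


class MotifScanner:
    """Compiled scanner for a set of motifs (both strands, shared threshold).

    Tables for the reverse strand are built from the reverse-complemented
    matrix, so asymmetric backgrounds are handled correctly.
    """

    def __init__(
        self,
        motifs: Sequence[Pwm],
        threshold: float = 1e-4,
        granularity: float = DEFAULT_GRANULARITY,
    ):
        self.threshold = threshold
        self.motifs = list(motifs)
        self._compiled: List[Tuple[str, int, ScoreTable, ScoreTable]] = []
        for m in self.motifs:
            fwd = ScoreTable(m, granularity)
            rev = ScoreTable(m.reverse_complement(), granularity)
            self._compiled.append((m.name, m.width, fwd, rev))

    def scan(
        self,
        seq: str,
        breakpoint_offset: int,
        interior_sign: int = 1,
    ) -> List[MotifHit]:
        """All sub-threshold matches in ``seq``, breakpoint-relative offsets.

        ``breakpoint_offset`` is the index in ``seq`` where the junction
        falls: with ``interior_sign=+1`` bases ``seq[breakpoint_offset:]``
        are interior to the deletion, with ``-1`` bases
        ``seq[:breakpoint_offset]`` are.  Offsets follow the MotifHit
        convention (first interior base +1, first exterior base -1; the
        offset of a hit is taken at its base nearest the junction, interior
        preferred on ties).
        """
        idx = encode(seq)
        n = len(idx)
        hits: List[MotifHit] = []
        for name, w, fwd, rev in self._compiled:
            if n < w:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(idx, w)
            pos = np.arange(n - w + 1)
            for strand, table in (("+", fwd), ("-", rev)):
                ints = table.int_matrix[np.arange(w), windows].sum(axis=1)
                pv = table.pvalue_of_int(ints)
                keep = pv < self.threshold
                if not keep.any():
                    continue
                lo_cont = table.pwm.log_odds()  # (w, 5) continuous bits
                for p0, pval in zip(pos[keep], pv[keep]):
                    score = float(
                        lo_cont[np.arange(w), windows[p0]].sum()
                    )
                    off = _signed_offset(
                        int(p0), w, breakpoint_offset, interior_sign
                    )
                    hits.append(
                        MotifHit(
                            motif_name=name,
                            strand=strand,
                            start_offset=off,
                            score=score,
                            pvalue=float(pval),
                        )
                    )
        hits.sort(key=lambda h: (h.pvalue, abs(h.start_offset), -h.start_offset))
        return hits


def _signed_offset(start: int, width: int, bp_offset: int, interior_sign: int) -> int:
    """Breakpoint-relative signed coordinate of a match's nearest-junction base.

    Sequence index j maps to +((j - bp_offset) + 1) interior / (j - bp_offset)
    exterior when interior extends rightward, mirrored otherwise.  A match
    straddling the junction gets +1 (interior preferred).
    """
    lo, hi = start, start + width - 1  # inclusive index range of the match

    def coord(j: int) -> int:
        if interior_sign >= 0:
            return j - bp_offset + 1 if j >= bp_offset else j - bp_offset
        return bp_offset - j if j < bp_offset else -(j - bp_offset + 1)

    cs = (coord(lo), coord(hi))
    if min(cs) < 0 < max(cs):
        return 1
    # all one sign: pick the end nearest the junction
    return min(cs, key=abs)


def scan_flank(
    seq: str,
    motifs: Sequence[Pwm],
    threshold: float = 1e-4,
    breakpoint_offset: int = 0,
    interior_sign: int = 1,
    granularity: float = DEFAULT_GRANULARITY,
) -> List[MotifHit]:
    """One-shot scan of a flank sequence (see :meth:`MotifScanner.scan`)."""
    return MotifScanner(motifs, threshold, granularity).scan(
        seq, breakpoint_offset, interior_sign
    )


def best_hit(hits: Iterable[MotifHit], motif_name: Optional[str] = None) -> Optional[MotifHit]:
    """Collapse overlapping hits of one motif to the single best match.

    Order: lowest p-value, then smallest |offset|, then interior preferred.
    """
    cand = [
        h for h in hits if motif_name is None or h.motif_name == motif_name
    ]
    if not cand:
        return None
    return min(cand, key=lambda h: (h.pvalue, abs(h.start_offset), -h.start_offset))
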