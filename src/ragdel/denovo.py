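"""Agnostic k-mer enrichment at breakpoint flanks.

A deliberately simple de-novo motif search: ZOOPS presence counting of every
canonical k-mer (a k-mer and its reverse complement are one entry) in the
target flanks versus a dinucleotide-shuffled background, with a one-sided
binomial enrichment test.  No PWM refinement is attempted — recovering the
RSS heptamer as the top-ranked 7-mer is the point.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
from scipy import stats as sps

from .pwm import revcomp

K_MIN, K_MAX = 5, 12
BACKGROUND_MULTIPLIER = 10


@dataclass
class KmerEnrichment:
    kmer: str  # canonical form (lexicographically smaller of kmer/revcomp)
    target_count: int
    target_freq: float
    background_count: int
    background_freq: float
    log_p: float  # log10 of the one-sided enrichment p-value
    rank: int = 0


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def masked_sequences(flanks: Sequence[str], repeat_mask: bool = True) -> List[str]:
    """Replace soft-masked (lowercase) bases by N so they contribute no k-mers."""
    if not repeat_mask:
        return [s.upper() for s in flanks]
    return [
        "".join("N" if c.islower() else c for c in s).upper() for s in flanks
    ]


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (Altschul–Erickson).

    A random Eulerian path through the dinucleotide multigraph with the same
    start and end letters as the input; local composition is preserved, any
    longer-range motif structure is destroyed.
    """
    if len(seq) < 3:
        return seq
    letters = sorted(set(seq))
    if len(letters) == 1:
        return seq
    edges: Dict[str, List[str]] = {c: [] for c in letters}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    # pick a random last-edge arborescence toward `last` (Altschul–Erickson)
    while True:
        last_edge = {}
        for c in letters:
            if c != last and edges[c]:
                last_edge[c] = edges[c][rng.integers(len(edges[c]))]
        # check connectivity: every vertex must reach `last` via last-edges
        ok = True
        for c in last_edge:
            seen = {c}
            cur = c
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    out = []
    pools = {}
    for c in letters:
        pool = list(edges[c])
        if c in last_edge:
            pool.remove(last_edge[c])
        rng.shuffle(pool)
        if c in last_edge:
            pool.append(last_edge[c])
        pools[c] = pool[::-1]  # pop() from the front order
    cur = seq[0]
    out.append(cur)
    while pools.get(cur):
        cur = pools[cur].pop()
        out.append(cur)
    return "".join(out)


def shuffled_background(
    targets: Sequence[str],
    rng: np.random.Generator,
    multiplier: int = BACKGROUND_MULTIPLIER,
) -> List[str]:
    """Dinucleotide-shuffled copies of the targets, ``multiplier`` per target.

    Each target is shuffled in its canonical orientation (lexicographically
    smaller of sequence/revcomp), so reverse-complementing the input changes
    nothing — presence counting is strand-symmetric anyway."""
    oriented = [canonical(t.upper()) for t in targets]
    return [
        dinucleotide_shuffle(t, rng) for _ in range(multiplier) for t in oriented
    ]


def _present_kmers(seq: str, k: int) -> Set[str]:
    seq = seq.upper()
    out: Set[str] = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        out.add(canonical(w))
    return out


def n_canonical_kmers(k: int) -> int:
    """Number of canonical k-mers: reverse-complement pairs plus palindromes."""
    pal = 4 ** (k // 2) if k % 2 == 0 else 0
    return (4**k + pal) // 2


def discover_kmers(
    targets: Sequence[str],
    background: Optional[Sequence[str]] = None,
    k: int = 7,
    seed: int = 0,
    background_multiplier: int = BACKGROUND_MULTIPLIER,
    method: str = "hypergeometric",
) -> List[KmerEnrichment]:
    """Rank canonical k-mers by one-sided enrichment p-value.

    ZOOPS counting: each sequence contributes at most once per k-mer,
    scanning both strands.  If no background is given, a seeded
    dinucleotide-shuffled background of ``background_multiplier`` x the
    target set is built.

    ``method`` "hypergeometric" (default) is the exact conditional test of
    target presence count given total presence count — calibrated even
    though the background frequency is itself estimated.  "binomial" treats
    the (Laplace-smoothed) background presence frequency as known; it is
    slightly anti-conservative near Bonferroni thresholds and kept for
    comparison only.
    """
    if not (K_MIN <= k <= K_MAX):
        raise ValueError(f"k must be in {K_MIN}..{K_MAX}, got {k}")
    if any(len(t) < k for t in targets):
        raise ValueError("k exceeds the length of the shortest target sequence")
    rng = np.random.default_rng(seed)
    if background is None:
        background = shuffled_background(targets, rng, background_multiplier)
    if not background:
        raise ValueError("background must be non-empty")

    t_counts: Dict[str, int] = {}
    for seq in targets:
        for kmer in _present_kmers(seq, k):
            t_counts[kmer] = t_counts.get(kmer, 0) + 1
    b_counts: Dict[str, int] = {}
    for seq in background:
        for kmer in _present_kmers(seq, k):
            b_counts[kmer] = b_counts.get(kmer, 0) + 1

    n_t, n_b = len(targets), len(background)
    kmers = sorted(t_counts)
    ct = np.array([t_counts[km] for km in kmers])
    cb = np.array([b_counts.get(km, 0) for km in kmers])
    if method == "hypergeometric":
        # P(X >= ct) for X ~ Hypergeom(N = n_t + n_b, K = ct + cb, n = n_t);
        # evaluate once per distinct (ct, ct+cb) pair — they repeat heavily
        pairs = np.stack([ct, ct + cb])
        uniq, inv = np.unique(pairs, axis=1, return_inverse=True)
        uniq_logp = sps.hypergeom.logsf(uniq[0] - 1, n_t + n_b, uniq[1], n_t)
        log_p = uniq_logp[inv] / np.log(10.0)
    elif method == "binomial":
        p0 = (cb + 1.0) / (n_b + 2.0)
        log_p = sps.binom.logsf(ct - 1, n_t, p0) / np.log(10.0)
    else:
        raise ValueError(f"unknown method {method!r}")

    entries = [
        KmerEnrichment(
            kmer=km, target_count=int(c), target_freq=c / n_t,
            background_count=int(b), background_freq=b / n_b,
            log_p=float(lp),
        )
        for km, c, b, lp in zip(kmers, ct, cb, log_p)
    ]
    entries.sort(key=lambda e: (e.log_p, -e.target_freq, e.kmer))
    for i, e in enumerate(entries, 1):
        e.rank = i
    return entries


def bonferroni_significant(
    entries: Sequence[KmerEnrichment], k: int, alpha: float = 0.05
) -> List[KmerEnrichment]:
    """Entries significant after Bonferroni over all possible canonical k-mers."""
    cut = np.log10(alpha / n_canonical_kmers(k))
    return [e for e in entries if e.log_p < cut]
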