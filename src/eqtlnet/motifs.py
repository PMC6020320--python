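"""PSSM construction, promoter scanning, and exact score p-values.

A position frequency matrix (counts per base per position) becomes a
position-specific scoring matrix by pseudocount-smoothed column
normalization and log2 odds against a background composition. Windows are
scored by summing per-position log-odds (bits); the p-value of a score is
P(score(W) >= s) for a random window W drawn from the background, obtained
by convolving the per-position score distributions.

The convolution tracks *exact* achievable score sums (merged at 1e-9 bits)
while the state count stays tractable, so for typical motif lengths the
p-values match full 4^L enumeration; very long motifs fall back to a fixed
1e-3-bit discretization grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Pssm", "pfm_to_pssm", "score_window", "exact_score_pvalue",
           "scan_promoters", "target_hit_fraction"]

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = 4

UNIFORM_BACKGROUND = np.full(4, 0.25)

# states kept exactly before switching to the discretization grid (4^11)
_MAX_EXACT_STATES = 4_194_304
_GRID_BITS = 1e-3


@dataclass
class Pssm:
    """Probabilities and log2-odds scores for one motif.

    ``probs`` and ``log_odds`` are 4 x L (rows A, C, G, T); scoring appends a
    fifth all-zero row so an N base contributes the background expectation.
    """

    probs: np.ndarray
    log_odds: np.ndarray
    background: np.ndarray
    pseudocount: float
    _dist: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    def reverse_complement(self) -> "Pssm":
        return Pssm(
            probs=self.probs[::-1, ::-1].copy(),
            log_odds=self.log_odds[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
        )

    def score_distribution(self):
        """Sorted achievable scores and their background probabilities.

        Cached on the instance; see the module docstring for the exact /
        gridded convolution strategy.
        """
        if self._dist is None:
            self._dist = _convolve_distribution(self.log_odds, self.background)
        return self._dist

    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())


def pfm_to_pssm(
    counts: np.ndarray,
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
) -> Pssm:
    """Counts -> probabilities -> log2-odds scoring matrix.

    probs[b, j] = (counts[b, j] + pseudocount) / (colsum_j + 4 * pseudocount).
    With pseudocount 0 an all-zero column is an error; with pseudocount > 0
    every log-odds entry is finite.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("PFM counts must be a 4 x L matrix (A, C, G, T rows)")
    if (counts < 0).any():
        raise ValueError("PFM counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    colsum = counts.sum(axis=0)
    if pseudocount == 0 and (colsum == 0).any():
        raise ValueError("all-zero PFM column requires a positive pseudocount")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be a 4-vector summing to 1")
    probs = (counts + pseudocount) / (colsum + 4.0 * pseudocount)
    with np.errstate(divide="ignore"):
        log_odds = np.log2(probs / bg[:, None])
    return Pssm(probs=probs, log_odds=log_odds, background=bg, pseudocount=float(pseudocount))


def encode(seq: str) -> np.ndarray:
    """Sequence -> integer codes (A0 C1 G2 T3, N/other 4)."""
    return np.fromiter((_BASE_INDEX.get(c, 4) for c in seq.upper()), dtype=np.intp, count=len(seq))


def _scoring_rows(pssm: Pssm) -> np.ndarray:
    """log-odds with an appended zero row for N."""
    return np.vstack([pssm.log_odds, np.zeros((1, pssm.length))])


def score_window(pssm: Pssm, window: str) -> float:
    """Sum of per-position log-odds over an L-mer; N scores 0 (background)."""
    if len(window) != pssm.length:
        raise ValueError(f"window length {len(window)} != motif length {pssm.length}")
    rows = _scoring_rows(pssm)
    codes = encode(window)
    return float(rows[codes, np.arange(pssm.length)].sum())


_NEG_SENTINEL = -1e6  # stands in for -inf per-position scores (zero probability)


def _convolve_distribution(log_odds: np.ndarray, background: np.ndarray):
    L = log_odds.shape[1]
    log_odds = np.where(np.isneginf(log_odds), _NEG_SENTINEL, log_odds)
    scores = np.array([0.0])
    probs = np.array([1.0])
    grid = False
    for j in range(L):
        col = log_odds[:, j]
        new_scores = (scores[:, None] + col[None, :]).ravel()
        new_probs = (probs[:, None] * background[None, :]).ravel()
        if grid or len(new_scores) > _MAX_EXACT_STATES:
            if not grid:
                log.info("PSSM length %d: switching to %g-bit grid p-values", L, _GRID_BITS)
                grid = True
            keys = np.round(new_scores / _GRID_BITS).astype(np.int64)
        else:
            keys = np.round(new_scores / 1e-9).astype(np.int64)
        order = np.argsort(keys, kind="stable")
        keys, new_scores, new_probs = keys[order], new_scores[order], new_probs[order]
        uniq, idx = np.unique(keys, return_index=True)
        sums = np.add.reduceat(new_probs, idx)
        reps = np.add.reduceat(new_scores * new_probs, idx)
        scores = reps / sums  # probability-weighted representative score per bin
        probs = sums
    order = np.argsort(scores)
    return scores[order], probs[order]


def score_pvalues(pssm: Pssm, scores_query) -> np.ndarray:
    """Vectorized P(score(W) >= s) lookups against the cached distribution."""
    scores, probs = pssm.score_distribution()
    tail = np.concatenate([np.cumsum(probs[::-1])[::-1], [0.0]])
    q = np.where(np.isneginf(scores_query), -np.inf, np.asarray(scores_query, dtype=float))
    # tolerance guards float-associativity differences between the DP sums
    # and a directly scored window
    idx = np.searchsorted(scores, q - 1e-7, side="left")
    return np.minimum(tail[idx], 1.0)


def exact_score_pvalue(pssm: Pssm, score: float) -> float:
    """P(score(W) >= s) for a background-distributed random window W."""
    if np.isnan(score) or score == np.inf:
        raise ValueError("score must be finite (or -inf for an impossible window)")
    if np.isneginf(score):
        return 1.0
    return float(score_pvalues(pssm, np.array([score]))[0])


def extract_promoters(
    genome: dict[str, str],
    gene_table,
    length: int = 1500,
) -> dict[str, str]:
    """Strand-aware upstream promoter sequences from a reference genome.

    For a + gene the promoter is the ``length`` bp ending just before the
    annotated start; for a - gene it is the reverse complement of the
    ``length`` bp starting just after the annotated end. Windows are clipped
    at contig boundaries (clipped promoters are shorter than ``length``).
    """
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    out: dict[str, str] = {}
    for row in gene_table.itertuples(index=False):
        if row.chromosome not in genome:
            raise ValueError(f"gene {row.gene_id} on unknown contig {row.chromosome!r}")
        contig = genome[row.chromosome]
        if row.strand == "-":
            start0 = int(row.end)  # 0-based: first base after the gene span
            seq = contig[start0 : start0 + length]
            seq = seq.translate(comp)[::-1]
        else:
            end0 = int(row.start) - 1  # 0-based exclusive end of the window
            seq = contig[max(0, end0 - length) : end0]
        out[row.gene_id] = seq.upper()
    return out


def scan_promoters(
    pssm: Pssm,
    promoters: dict[str, str],
    p_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan every promoter window on both strands for significant sites.

    Returns ``(hits, gene_summary)``: per-hit rows (gene, 0-based offset,
    strand, score, exact p) with p <= threshold, and a per-gene table with
    the best hit and a has-site indicator. Promoters shorter than the motif
    are skipped with a warning.
    """
    L = pssm.length
    fwd_rows = _scoring_rows(pssm)
    rev_rows = _scoring_rows(pssm.reverse_complement())
    hit_rows = []
    summary_rows = []
    for gene, seq in promoters.items():
        if len(seq) < L:
            log.warning("promoter of %s (%d bp) shorter than motif (%d bp); skipped",
                        gene, len(seq), L)
            continue
        codes = encode(seq)
        windows = np.lib.stride_tricks.sliding_window_view(codes, L)
        pos_idx = np.arange(L)
        best = {"score": -np.inf, "offset": -1, "strand": "+", "p": 1.0}
        for strand, rows in (("+", fwd_rows), ("-", rev_rows)):
            sc = rows[windows, pos_idx].sum(axis=1)
            pvals = score_pvalues(pssm, sc)
            for off in np.flatnonzero(pvals <= p_threshold):
                hit_rows.append((gene, int(off), strand, float(sc[off]), float(pvals[off])))
            j = int(np.argmax(sc))
            if sc[j] > best["score"]:
                best = {"score": float(sc[j]), "offset": j, "strand": strand,
                        "p": float(pvals[j])}
        summary_rows.append((gene, best["offset"], best["strand"], best["score"], best["p"]))
    hits = pd.DataFrame(hit_rows, columns=["gene_id", "offset", "strand", "score", "p_value"])
    summary = pd.DataFrame(
        summary_rows, columns=["gene_id", "best_offset", "best_strand", "best_score", "best_p"]
    )
    summary["has_hit"] = summary["gene_id"].isin(set(hits["gene_id"]))
    return hits, summary


def target_hit_fraction(gene_summary: pd.DataFrame, target_genes) -> float:
    """Fraction of target-gene promoters with at least one significant site."""
    targets = list(target_genes)
    if not targets:
        raise ValueError("empty target gene list")
    sub = gene_summary.set_index("gene_id")["has_hit"].reindex(targets)
    missing = sub.isna()
    if missing.any():
        raise ValueError(f"targets missing from scan summary: {list(sub[missing].index)[:5]}")
    return float(sub.mean())
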