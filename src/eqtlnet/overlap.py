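"""Permutation test for overlap between two genomic region sets.

The observed statistic is the total basewise overlap, in Mb, between the
merged unions of the two sets. The null resamples set A: every interval is
replaced by a random interval of the same length on the same chromosome
(start uniform over valid placements), so the permutation distribution is
matched on size and chromosomal composition. The p-value uses the standard
add-one permutation estimator, p = (1 + #{perm >= obs}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import RegionSet

__all__ = [
    "merge_intervals",
    "basewise_overlap",
    "sample_matched_regions",
    "permutation_overlap_test",
    "classify_overlap",
    "classify_all_pairs",
    "OverlapTestResult",
]


@dataclass
class OverlapTestResult:
    observed_mb: float
    perm_mean_mb: float
    perm_sd_mb: float
    p_value: float
    n_perm: int
    alternative: str
    z_score: float | None = None

    def summary(self) -> str:
        z = f"{self.z_score:.3f}" if self.z_score is not None else "n/a"
        return (
            "Region overlap permutation test\n"
            "-------------------------------\n"
            f"observed overlap:   {self.observed_mb:.4f} Mb\n"
            f"permutation mean:   {self.perm_mean_mb:.4f} Mb (sd {self.perm_sd_mb:.4f})\n"
            f"z-score:            {z}\n"
            f"p-value ({self.alternative}): {self.p_value:.4g}  [{self.n_perm} permutations]"
        )


def _to_arrays(intervals: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, sub in intervals.groupby("chromosome", sort=True):
        out[str(chrom)] = (
            sub["start"].to_numpy(dtype=np.int64),
            sub["end"].to_numpy(dtype=np.int64),
        )
    return out


def _merge_arrays(starts: np.ndarray, ends: np.ndarray):
    """Union of 1-based inclusive intervals given as parallel arrays."""
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    # an interval starts a new block iff it begins after the running max end + 1
    running_end = np.maximum.accumulate(e)
    new_block = np.empty(len(s), dtype=bool)
    new_block[0] = True
    new_block[1:] = s[1:] > running_end[:-1] + 1
    block = np.cumsum(new_block) - 1
    out_s = s[new_block]
    out_e = np.maximum.reduceat(e, np.flatnonzero(new_block))
    del block
    return out_s, out_e


def _overlap_bases(a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]) -> int:
    """Intersection size of two merged (disjoint, sorted) interval lists."""
    as_, ae = a
    bs, be = b
    total = 0
    i = j = 0
    while i < len(as_) and j < len(bs):
        s = max(as_[i], bs[j])
        e = min(ae[i], be[j])
        if e >= s:
            total += int(e - s + 1)
        if ae[i] < be[j]:
            i += 1
        else:
            j += 1
    return total


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of 1-based inclusive intervals, per chromosome."""
    rows = []
    for chrom, (s, e) in _to_arrays(intervals).items():
        ms, me = _merge_arrays(s, e)
        rows.extend((chrom, int(x), int(y)) for x, y in zip(ms, me))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end"])


def basewise_overlap(set_a: RegionSet, set_b: RegionSet) -> float:
    """Mb of bases in (union of A) ∩ (union of B); merging prevents double count."""
    a = {c: _merge_arrays(*v) for c, v in _to_arrays(set_a.intervals).items()}
    b = {c: _merge_arrays(*v) for c, v in _to_arrays(set_b.intervals).items()}
    total = sum(_overlap_bases(a[c], b[c]) for c in set(a) & set(b))
    return total / 1e6


def sample_matched_regions(
    template: RegionSet, chrom_lengths: dict[str, int], rng
) -> RegionSet:
    """Random regions matching the template's lengths and chromosome counts."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    chroms = template.intervals["chromosome"].astype(str).to_numpy()
    lens = (template.intervals["end"] - template.intervals["start"] + 1).to_numpy(dtype=np.int64)
    starts = np.empty(len(chroms), dtype=np.int64)
    for i, (chrom, L) in enumerate(zip(chroms, lens)):
        if chrom not in chrom_lengths:
            raise ValueError(f"no chromosome length for {chrom!r}")
        clen = int(chrom_lengths[chrom])
        if L > clen:
            raise ValueError(f"interval of {L} bp exceeds chromosome {chrom} ({clen} bp)")
        starts[i] = rng.integers(1, clen - L + 2)  # uniform over valid placements
    return RegionSet(
        label=f"{template.label}_matched",
        intervals=pd.DataFrame(
            {"chromosome": chroms, "start": starts, "end": starts + lens - 1}
        ),
    )


def permutation_overlap_test(
    set_a: RegionSet,
    set_b: RegionSet,
    chrom_lengths: dict[str, int],
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
) -> OverlapTestResult:
    """Size- and chromosome-matched permutation test of A-vs-B overlap."""
    if n_perm < 20:
        raise ValueError("n_perm < 20 cannot resolve a useful p-value")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    rng = np.random.default_rng(seed)
    observed = basewise_overlap(set_a, set_b)

    b_merged = {c: _merge_arrays(*v) for c, v in _to_arrays(set_b.intervals).items()}
    chroms = set_a.intervals["chromosome"].astype(str).to_numpy()
    lens = (set_a.intervals["end"] - set_a.intervals["start"] + 1).to_numpy(dtype=np.int64)
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in np.unique(chroms):
        if chrom not in chrom_lengths:
            raise ValueError(f"no chromosome length for {chrom!r}")
        L = lens[chroms == chrom]
        if (L > int(chrom_lengths[chrom])).any():
            raise ValueError(f"interval exceeds chromosome {chrom}")
        by_chrom[chrom] = L

    perms = np.empty(n_perm)
    for k in range(n_perm):
        total = 0
        for chrom, L in by_chrom.items():
            clen = int(chrom_lengths[chrom])
            starts = rng.integers(1, clen - L + 2)
            if chrom in b_merged:
                ms, me = _merge_arrays(starts, starts + L - 1)
                total += _overlap_bases((ms, me), b_merged[chrom])
        perms[k] = total / 1e6
    if alternative == "greater":
        extreme = int(np.sum(perms >= observed))
    else:
        extreme = int(np.sum(perms <= observed))
    p = (1 + extreme) / (1 + n_perm)
    sd = float(perms.std(ddof=1)) if n_perm > 1 else 0.0
    z = float((observed - perms.mean()) / sd) if sd > 0 else None
    return OverlapTestResult(
        observed_mb=float(observed),
        perm_mean_mb=float(perms.mean()),
        perm_sd_mb=sd,
        p_value=float(p),
        n_perm=n_perm,
        alternative=alternative,
        z_score=z,
    )


def classify_overlap(a: tuple[int, int], b: tuple[int, int]) -> str:
    """Four-way overlap category for one overlapping interval pair.

    AinB: a contained in b (non-strict, so identical intervals are AinB);
    BinA: b strictly contained in a; AleftB / ArightB: a overhangs b's left
    or right end.
    """
    (a1, a2), (b1, b2) = a, b
    if min(a2, b2) < max(a1, b1):
        raise ValueError(f"intervals {a} and {b} do not overlap")
    if b1 <= a1 and a2 <= b2:
        return "AinB"
    if a1 <= b1 and b2 <= a2:
        return "BinA"
    return "AleftB" if a1 < b1 else "ArightB"


def classify_all_pairs(set_a: RegionSet, set_b: RegionSet) -> pd.DataFrame:
    """Category for every overlapping (a, b) pair, on the unmerged inputs."""
    rows = []
    for ra in set_a.intervals.itertuples(index=False):
        sub = set_b.intervals[set_b.intervals["chromosome"] == ra.chromosome]
        for rb in sub.itertuples(index=False):
            if min(ra.end, rb.end) >= max(ra.start, rb.start):
                rows.append(
                    (
                        ra.chromosome,
                        ra.start,
                        ra.end,
                        rb.start,
                        rb.end,
                        classify_overlap((ra.start, ra.end), (rb.start, rb.end)),
                    )
                )
    return pd.DataFrame(
        rows, columns=["chromosome", "a_start", "a_end", "b_start", "b_end", "category"]
    )
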