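"""QTL calling from association scans, co-location and interval expansion.

A QTL is a maximal run of at least ``min_run`` significant SNPs on one
chromosome in which every gap between adjacent significant SNPs is strictly
less than ``max_gap`` (default 170 kb, matching the LD decay scale of rice
diversity panels). The member SNP with the largest -log10(p) is the lead
SNP; the interval spans the outermost member positions and interval lengths
are coordinate differences (right - left), not inclusive base counts.

Two QTLs from different population scans whose intervals overlap are
co-located; the commonly-significant-SNP count is taken over the union of
the two member intervals.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class QTL:
    name: str
    population: str
    chrom: str
    member_pos: np.ndarray  # positions of member significant SNPs, sorted
    member_neg_log10_p: np.ndarray
    lead_pos: int
    lead_neg_log10_p: float

    def __post_init__(self) -> None:
        self.member_pos = np.asarray(self.member_pos, dtype=np.int64)
        self.member_neg_log10_p = np.asarray(self.member_neg_log10_p, dtype=float)
        if not (self.left <= self.lead_pos <= self.right):
            raise ValueError(f"lead SNP outside interval for {self.name}")

    @property
    def left(self) -> int:
        return int(self.member_pos[0])

    @property
    def right(self) -> int:
        return int(self.member_pos[-1])

    @property
    def length(self) -> int:
        """Interval length as a coordinate difference (right - left), bp."""
        return self.right - self.left

    @property
    def n_snps(self) -> int:
        return int(self.member_pos.size)


@dataclass
class ColocatedQTL:
    name: str
    qtl_a: QTL
    qtl_b: QTL
    overlap_left: int
    overlap_right: int
    n_common_sig_snps: int = 0

    @property
    def overlap_length(self) -> int:
        return self.overlap_right - self.overlap_left


def significant_snps(assoc: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Rows with neg_log10_p >= threshold, input order preserved."""
    scores = assoc["neg_log10_p"].to_numpy()
    keep = ~np.isnan(scores) & (scores >= threshold)
    return assoc.loc[keep].reset_index(drop=True)


def name_qtl(trait: str, population: str, chrom, ordinal: int) -> str:
    """Per-population QTL name, e.g. qTFC-Full-7-1."""
    if ordinal < 1:
        raise ValueError("ordinal must be >= 1")
    c = str(chrom).removeprefix("Chr").removeprefix("chr")
    return f"q{trait}-{population}-{c}-{ordinal}"


def merge_name(trait: str, chrom, ordinal: int) -> str:
    """Merged co-located QTL name, e.g. qTFC7-2."""
    if ordinal < 1:
        raise ValueError("ordinal must be >= 1")
    c = str(chrom).removeprefix("Chr").removeprefix("chr")
    return f"q{trait}{c}-{ordinal}"


def call_qtls(sig_snps: pd.DataFrame, min_run: int = 3,
              max_gap: int = 170_000, population: str = "Full",
              trait: str = "TFC") -> list[QTL]:
    """Greedy run extension over the significant-SNP list, per chromosome.

    A run extends while the next significant SNP on the same chromosome is
    strictly closer than ``max_gap``; maximal runs with at least ``min_run``
    members become QTLs. Lead SNP ties break to the smaller position.
    """
    qtls: list[QTL] = []
    if len(sig_snps) == 0:
        return qtls
    counters: dict[str, int] = {}
    for chrom, sub in sig_snps.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"significant SNPs unsorted on {chrom}")
        nlp = sub["neg_log10_p"].to_numpy(dtype=float)
        run_start = 0
        for i in range(1, pos.size + 1):
            at_end = i == pos.size
            if at_end or pos[i] - pos[i - 1] >= max_gap:
                run = slice(run_start, i)
                if i - run_start >= min_run:
                    rp, rs = pos[run], nlp[run]
                    # tie -> smaller position: argmax takes the first maximum
                    lead = int(np.argmax(rs))
                    counters[chrom] = counters.get(chrom, 0) + 1
                    qtls.append(QTL(
                        name=name_qtl(trait, population, chrom, counters[chrom]),
                        population=population, chrom=str(chrom),
                        member_pos=rp, member_neg_log10_p=rs,
                        lead_pos=int(rp[lead]),
                        lead_neg_log10_p=float(rs[lead])))
                run_start = i
    return qtls


def interval_overlap(a: tuple[int, int], b: tuple[int, int]
                     ) -> tuple[int, int, int] | None:
    """Overlap (left, right, length) of two intervals, or None if disjoint.

    Length is the coordinate difference right - left. Intervals that merely
    touch (max(lefts) == min(rights)) have zero-length intersection and are
    treated as disjoint: an overlap requires max(lefts) < min(rights).
    """
    (al, ar), (bl, br) = a, b
    if al > ar or bl > br:
        raise ValueError("interval left must not exceed right")
    left = max(al, bl)
    right = min(ar, br)
    if left >= right:
        return None
    return left, right, right - left


def colocate(qtls_a: list[QTL], qtls_b: list[QTL],
             sig_positions: dict[str, dict[str, set[int]]] | None = None,
             trait: str = "TFC") -> list[ColocatedQTL]:
    """All cross pairs of QTLs from two populations with overlapping intervals.

    ``sig_positions`` maps population -> chromosome -> set of significant
    positions; the commonly-significant count is the size of the two
    populations' intersection restricted to the union of the member
    intervals. Merged names are assigned per chromosome in positional order
    of the overlap.
    """
    if qtls_a and qtls_b and qtls_a[0].population == qtls_b[0].population:
        raise ValueError("co-location requires two different populations")
    hits = []
    for qa in qtls_a:
        for qb in qtls_b:
            if qa.chrom != qb.chrom:
                continue
            ov = interval_overlap((qa.left, qa.right), (qb.left, qb.right))
            if ov is None:
                continue
            left, right, _ = ov
            n_common = 0
            if sig_positions is not None:
                lo = min(qa.left, qb.left)
                hi = max(qa.right, qb.right)
                sa = sig_positions.get(qa.population, {}).get(qa.chrom, set())
                sb = sig_positions.get(qb.population, {}).get(qb.chrom, set())
                n_common = sum(lo <= p <= hi for p in sa & sb)
            hits.append((qa, qb, left, right, n_common))
    hits.sort(key=lambda h: (h[0].chrom, h[2], h[3]))
    out: list[ColocatedQTL] = []
    counters: dict[str, int] = {}
    for qa, qb, left, right, n_common in hits:
        counters[qa.chrom] = counters.get(qa.chrom, 0) + 1
        out.append(ColocatedQTL(
            name=merge_name(trait, qa.chrom, counters[qa.chrom]),
            qtl_a=qa, qtl_b=qb, overlap_left=left, overlap_right=right,
            n_common_sig_snps=n_common))
    return out


def relax_and_expand(assoc: pd.DataFrame, qtl: QTL,
                     relaxed_threshold: float,
                     original_threshold: float | None = None,
                     min_run: int = 3, max_gap: int = 170_000) -> QTL:
    """Re-call QTLs at a relaxed threshold and return the one holding the lead.

    Restricted to the original QTL's chromosome; the relaxed QTL whose
    interval contains the original lead SNP is returned (its lead may
    differ if a relaxed member scores higher, but in practice the relaxed
    set is a superset of the original members, so it does not).
    """
    if original_threshold is not None and relaxed_threshold > original_threshold:
        raise ValueError("relaxed threshold must not exceed the original")
    sub = assoc.loc[assoc["chrom"] == qtl.chrom].reset_index(drop=True)
    sig = significant_snps(sub, relaxed_threshold)
    relaxed = call_qtls(sig, min_run=min_run, max_gap=max_gap,
                        population=qtl.population,
                        trait=_trait_of(qtl.name))
    for rq in relaxed:
        if rq.left <= qtl.lead_pos <= rq.right:
            rq.name = qtl.name
            return rq
    raise ValueError(
        f"lead orphaned at relaxed threshold for {qtl.name}: no relaxed "
        f"QTL contains position {qtl.lead_pos}")


def _trait_of(name: str) -> str:
    # names look like q<TRAIT>-<Pop>-<chr>-<i>
    core = name[1:] if name.startswith("q") else name
    return core.split("-")[0]


def qtl_table(qtls: list[QTL]) -> pd.DataFrame:
    """Tabular view: name, chrom, lead, lead score, interval, member count."""
    return pd.DataFrame([{
        "name": q.name, "chrom": q.chrom, "lead_pos": q.lead_pos,
        "lead_neg_log10_p": q.lead_neg_log10_p, "left": q.left,
        "right": q.right, "length": q.length, "n_snps": q.n_snps,
        "population": q.population,
    } for q in qtls])


def colocated_table(coloc: list[ColocatedQTL]) -> pd.DataFrame:
    rows = []
    for c in coloc:
        for q in (c.qtl_a, c.qtl_b):
            rows.append({
                "merged_name": c.name, "qtl_name": q.name, "chrom": q.chrom,
                "lead_pos": q.lead_pos, "lead_neg_log10_p": q.lead_neg_log10_p,
                "left": q.left, "right": q.right,
                "overlap_length": c.overlap_length,
                "n_common_sig_snps": c.n_common_sig_snps,
            })
    return pd.DataFrame(rows)
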