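"""Top-k unions across representative approaches and block-pruned tables.

The *top-k union* is the set of SNPs ranking in the top k in at least one
representative approach; its size is the *union number* (Sigma_k). Each
union SNP carries an *extraction number* (how many approaches rank it in
their top k) and an *average position* (its mean rank across those
approaches). To isolate independent signals, union SNPs are grouped into
haplotype blocks and each block keeps its most stable member (highest
extraction number, then lowest average position).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gwasrank.genotype_io import MISSING, GenotypeMatrix


def _rank_series(r) -> pd.Series:
    return r if isinstance(r, pd.Series) else pd.Series(r)


def _common_universe(rankings: dict[str, pd.Series]) -> set[str]:
    it = iter(rankings.items())
    _, first = next(it)
    universe = set(first.index)
    for name, r in it:
        if set(r.index) != universe:
            raise ValueError(f"ranking {name!r} covers a different SNP universe")
    return universe


def top_k_union(rankings: dict[str, pd.Series], k: int) -> tuple[set[str], int]:
    """SNPs in the top k of at least one approach, and the union number."""
    if len(rankings) < 1:
        raise ValueError("need at least one ranking")
    rankings = {n: _rank_series(r) for n, r in rankings.items()}
    universe = _common_universe(rankings)
    if k > len(universe):
        raise ValueError(f"k={k} exceeds universe size {len(universe)}")
    union: set[str] = set()
    for r in rankings.values():
        union |= set(r.index[r.to_numpy() <= k])
    return union, len(union)


@dataclass
class UnionTable:
    """Per-SNP union rows: extraction number, average position, ranks.

    ``rows`` columns: marker_id, extraction_number, average_position, plus
    one rank column per approach (NaN when the SNP is outside that
    approach's top k). Sorted by decreasing extraction number, then
    increasing average position.
    """

    k: int
    approaches: list[str]
    rows: pd.DataFrame

    @property
    def union_number(self) -> int:
        return len(self.rows)

    def write_tsv(self, path: str | Path) -> None:
        """TSV where each approach column holds k + 1 - rank for SNPs in
        that approach's top k (k best, 1 worst) and 0 otherwise."""
        out = self.rows[["marker_id", "extraction_number", "average_position"]].copy()
        for a in self.approaches:
            r = self.rows[a]
            out[a] = np.where(r.notna(), self.k + 1 - r.fillna(0), 0).astype(int)
        out.to_csv(path, sep="\t", index=False)


def union_table(rankings: dict[str, pd.Series], k: int) -> UnionTable:
    """Build the top-k union table across representative approaches."""
    rankings = {n: _rank_series(r) for n, r in rankings.items()}
    union, _ = top_k_union(rankings, k)
    names = list(rankings)
    records = []
    for snp in union:
        ranks = {n: float(rankings[n].loc[snp]) for n in names}
        present = {n: v for n, v in ranks.items() if v <= k}
        rec = {"marker_id": snp,
               "extraction_number": len(present),
               "average_position": float(np.mean(list(present.values())))}
        for n in names:
            rec[n] = present.get(n, np.nan)
        records.append(rec)
    cols = ["marker_id", "extraction_number", "average_position"] + names
    rows = pd.DataFrame(records, columns=cols)
    rows = rows.sort_values(
        by=["extraction_number", "average_position", "marker_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return UnionTable(k, names, rows)


def stability_fraction(union_number: int, k: int, m: int,
                       denominator: str = "mk") -> float:
    """Union number as a percentage of complete instability.

    With ``denominator="mk"`` (default) this is 100 * Sigma_k / (m * k):
    100% when the m top-k lists are pairwise disjoint. The alternative
    ``"mk_minus_k"`` rescales so identical lists give 0%:
    100 * (Sigma_k - k) / (m*k - k).
    """
    if m < 2:
        raise ValueError("need m >= 2 approaches")
    if denominator == "mk":
        return 100.0 * union_number / (m * k)
    if denominator == "mk_minus_k":
        return 100.0 * (union_number - k) / (m * k - k)
    raise ValueError(f"unknown denominator {denominator!r}")


# ---------------------------------------------------------------------------
# Haplotype blocks
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeBlocks:
    """Non-overlapping marker blocks per chromosome (plus singletons).

    ``blocks``: list of (chromosome, start_bp, end_bp, [marker ids]).
    Every dataset marker belongs to exactly one block; markers not covered
    by a multi-marker block form their own singleton block.
    """

    blocks: list[tuple[str, int, int, list[str]]] = field(default_factory=list)

    def block_of(self) -> dict[str, int]:
        """Marker id -> block index."""
        out: dict[str, int] = {}
        for i, (_c, _s, _e, members) in enumerate(self.blocks):
            for m in members:
                if m in out:
                    raise ValueError(f"marker {m} in more than one block")
                out[m] = i
        return out

    def write_det(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("CHR\tBP1\tBP2\tKB\tNSNPS\tSNPS\n")
            for chrom, s, e, members in self.blocks:
                if len(members) < 2:
                    continue  # .det files list multi-marker blocks only
                kb = (e - s) / 1000.0
                fh.write(f"{chrom}\t{s}\t{e}\t{kb:.3f}\t{len(members)}\t"
                         f"{'|'.join(members)}\n")


def _em_haplotype_freqs(table_3x3: np.ndarray, tol: float = 1e-9,
                        max_iter: int = 1000) -> np.ndarray:
    """ML two-locus haplotype frequencies from unphased genotype counts.

    ``table_3x3[i, j]`` counts individuals with i alt alleles at locus A
    and j at locus B. Returns frequencies [f00, f01, f10, f11] (alt-allele
    indicators at A then B). The double-heterozygote class is ambiguous
    between (00,11) and (01,10) phase and is resolved by EM.
    """
    t = np.asarray(table_3x3, dtype=float)
    n_hap = 2.0 * t.sum()
    if n_hap == 0:
        raise ValueError("empty genotype table")
    # unambiguous haplotype contributions: genotype (i, j) contributes
    # haplotypes deterministically except for (1, 1)
    base = np.zeros(4)  # f00, f01, f10, f11 counts
    contrib = {
        (0, 0): [(0, 2)], (0, 1): [(0, 1), (1, 1)], (0, 2): [(1, 2)],
        (1, 0): [(0, 1), (2, 1)], (1, 2): [(1, 1), (3, 1)],
        (2, 0): [(2, 2)], (2, 1): [(2, 1), (3, 1)], (2, 2): [(3, 2)],
    }
    for (i, j), parts in contrib.items():
        for hap, mult in parts:
            base[hap] += mult * t[i, j]
    n_dh = t[1, 1]  # double heterozygotes: 00/11 or 01/10 phase
    f = np.full(4, 0.25)
    for _ in range(max_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        tot = cis + trans
        w = 0.5 if tot == 0 else cis / tot
        counts = base.copy()
        counts[0] += w * n_dh
        counts[3] += w * n_dh
        counts[1] += (1 - w) * n_dh
        counts[2] += (1 - w) * n_dh
        new = counts / n_hap
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return f


def d_prime(table_3x3: np.ndarray) -> float:
    """|D'| between two loci from EM haplotype frequency estimates."""
    f = _em_haplotype_freqs(table_3x3)
    p_a = f[2] + f[3]  # alt frequency at locus A
    p_b = f[1] + f[3]
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("|D'| undefined for a monomorphic locus")
    d = f[3] - p_a * p_b
    if d >= 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    if dmax == 0:
        raise ValueError("|D'| undefined: zero D_max")
    return float(abs(d) / dmax)


def _pair_table(calls_a: np.ndarray, calls_b: np.ndarray) -> np.ndarray:
    ok = (calls_a != MISSING) & (calls_b != MISSING)
    t = np.zeros((3, 3))
    np.add.at(t, (calls_a[ok], calls_b[ok]), 1)
    return t


def infer_blocks(gm: GenotypeMatrix, dprime_threshold: float = 0.9,
                 max_span_kb: float = 200.0) -> HaplotypeBlocks:
    """Greedy |D'|-threshold haplotype blocks.

    Adjacent markers join the current block while their |D'| against the
    block's last member is at least ``dprime_threshold`` and the block span
    stays within ``max_span_kb``. Two-locus haplotype frequencies come from
    the EM estimator; pairs with undefined |D'| never join. This is a
    deliberate simplification of confidence-interval-based block callers;
    externally computed block definitions can be loaded instead with
    :func:`load_blocks`.
    """
    blocks: list[tuple[str, int, int, list[str]]] = []
    chroms = gm.markers["chromosome"].to_numpy()
    positions = gm.markers["position_bp"].to_numpy()
    ids = gm.markers["marker_id"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        current: list[int] = []
        for j in idx:
            if not current:
                current = [j]
                continue
            last = current[-1]
            span_kb = (positions[j] - positions[current[0]]) / 1000.0
            try:
                dp = d_prime(_pair_table(gm.calls[last], gm.calls[j]))
            except ValueError:
                dp = -1.0  # undefined: below any threshold
            if dp >= dprime_threshold and span_kb <= max_span_kb:
                current.append(j)
            else:
                blocks.append((str(chrom), int(positions[current[0]]),
                               int(positions[current[-1]]),
                               [str(ids[i]) for i in current]))
                current = [j]
        if current:
            blocks.append((str(chrom), int(positions[current[0]]),
                           int(positions[current[-1]]),
                           [str(ids[i]) for i in current]))
    return HaplotypeBlocks(blocks)


def load_blocks(blocks_file: str | Path,
                gm: GenotypeMatrix | None = None) -> HaplotypeBlocks:
    """Load block definitions in the .blocks.det dialect.

    Columns: CHR BP1 BP2 KB NSNPS SNPS (SNPS pipe-delimited). Dataset
    markers not listed in any block become singleton blocks when a
    genotype matrix is supplied. Overlapping blocks on a chromosome are an
    error.
    """
    blocks: list[tuple[str, int, int, list[str]]] = []
    with open(blocks_file) as fh:
        header = fh.readline()
        if header.strip() and not header.upper().split()[:3] == ["CHR", "BP1", "BP2"]:
            raise ValueError(f"{blocks_file}:1: expected header CHR BP1 BP2 ...")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(
                    f"{blocks_file}:{lineno}: expected 6 fields, got {len(fields)}"
                )
            chrom, bp1, bp2, _kb, nsnps, snps = fields[:6]
            members = snps.split("|")
            if int(nsnps) != len(members):
                raise ValueError(
                    f"{blocks_file}:{lineno}: NSNPS={nsnps} but "
                    f"{len(members)} SNPs listed"
                )
            blocks.append((chrom, int(bp1), int(bp2), members))

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e, _m in blocks:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, spans in by_chrom.items():
        spans = sorted(spans)
        for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping blocks on chromosome {chrom}: "
                    f"[{s1}, {e1}] and starting {s2}"
                )

    if gm is not None:
        assigned = {m for _c, _s, _e, mem in blocks for m in mem}
        for row in gm.markers.itertuples(index=False):
            if row.marker_id not in assigned:
                blocks.append((str(row.chromosome), int(row.position_bp),
                               int(row.position_bp), [row.marker_id]))
    return HaplotypeBlocks(blocks)


def prune_union(table: UnionTable, blocks: HaplotypeBlocks) -> UnionTable:
    """Keep one SNP per haplotype block: the block's most stable member.

    Selection order: highest extraction number, lowest average position,
    best (smallest) single rank across approaches, then the marker with
    the smallest marker_id for full determinism.
    """
    block_of = blocks.block_of()
    missing = [m for m in table.rows["marker_id"] if m not in block_of]
    if missing:
        raise ValueError(f"union SNPs not assigned to any block: {missing}")
    rows = table.rows.copy()
    rows["_block"] = [block_of[m] for m in rows["marker_id"]]
    rank_cols = table.approaches
    rows["_best_rank"] = rows[rank_cols].min(axis=1)

    keep_idx = []
    for _block, grp in rows.groupby("_block", sort=False):
        grp = grp.sort_values(
            by=["extraction_number", "average_position", "_best_rank", "marker_id"],
            ascending=[False, True, True, True],
            kind="mergesort",
        )
        keep_idx.append(grp.index[0])
    pruned = rows.loc[sorted(keep_idx)].drop(columns=["_block", "_best_rank"])
    pruned = pruned.sort_values(
        by=["extraction_number", "average_position", "marker_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return UnionTable(table.k, list(table.approaches), pruned)


def extraction_boxplot_data(pruned: UnionTable) -> pd.DataFrame:
    """Per-approach distributions of extraction numbers in the pruned union.

    For each approach: the extraction numbers of the pruned-union SNPs that
    are in that approach's top k, with quartiles for boxplot rendering.
    Returns a tidy frame (approach, n, min, q1, median, q3, max, values).
    """
    if pruned.union_number == 0:
        raise ValueError("empty union table")
    records = []
    for a in pruned.approaches:
        vals = pruned.rows.loc[pruned.rows[a].notna(), "extraction_number"]
        vals = vals.to_numpy(dtype=float)
        if len(vals) == 0:
            records.append({"approach": a, "n": 0, "min": np.nan, "q1": np.nan,
                            "median": np.nan, "q3": np.nan, "max": np.nan,
                            "values": ""})
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        records.append({
            "approach": a, "n": len(vals), "min": vals.min(), "q1": q1,
            "median": med, "q3": q3, "max": vals.max(),
            "values": ",".join(str(int(v)) for v in sorted(vals)),
        })
    return pd.DataFrame.from_records(records)
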