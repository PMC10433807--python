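"""Genome-level strain identity.

Four complementary views of genome relatedness, each reduced to a labeled
symmetric matrix over genomes:

* SNP distances from a whole-genome alignment (snp-dists semantics: only
  unambiguous A/C/G/T mismatches count; gaps, Ns and ambiguity codes skip
  the column);
* average nucleotide identity (ANI) estimated from canonical k-mer Jaccard
  via the Mash distance formula;
* gene-content Jaccard distances from a presence/absence matrix;
* UPGMA clustering of any of the above, with deterministic tie-breaking
  and newick output.

``partition_by_dyad`` splits any matrix's off-diagonal pairs into
within-dyad vs between-dyad sets — the strain-sharing contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenomeSet
from .stats import TwoSampleResult, mann_whitney

_CODE = np.full(256, -1, dtype=np.int8)
for i, base in enumerate(b"ACGT"):
    _CODE[base] = i
    _CODE[base + 32] = i  # lowercase
_RC = np.array([3, 2, 1, 0], dtype=np.int8)


@dataclass
class PairwiseMatrix:
    """Symmetric matrix of pairwise genome statistics with dyad labels."""

    genome_ids: list[str]
    values: np.ndarray
    metric: str  # snp_count | ani | jaccard_distance
    dyad_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genome_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match genome_ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix is not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genome_ids, columns=self.genome_ids)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(
        cls, path: str | Path, metric: str, dyad_ids: dict[str, str] | None = None
    ) -> "PairwiseMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            genome_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            metric=metric,
            dyad_ids=dyad_ids or {},
        )


@dataclass
class DyadPartitionResult:
    within_values: np.ndarray
    between_values: np.ndarray
    median_within: float
    median_between: float
    test: TwoSampleResult | None


@dataclass
class TreeNode:
    """Node of a rooted ultrametric tree; leaves carry genome ids."""

    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    branch_length: float = 0.0
    height: float = 0.0  # merge height above the leaves

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out

    def newick(self) -> str:
        if self.is_leaf:
            return f"{self.name};"
        inner = ",".join(c._newick_inner() for c in self.children)
        return f"({inner});"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{_fmt(self.branch_length)}"
        inner = ",".join(c._newick_inner() for c in self.children)
        return f"({inner}):{_fmt(self.branch_length)}"

    def root_to_leaf_depths(self) -> list[float]:
        if self.is_leaf:
            return [self.branch_length]
        return [self.branch_length + d for c in self.children for d in c.root_to_leaf_depths()]


def _fmt(x: float) -> str:
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s else "0"


# ---------------------------------------------------------------------------
# SNP distances


def _encoded(genomes: GenomeSet) -> dict[str, np.ndarray]:
    return {
        gid: _CODE[np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)]
        for gid, rec in genomes.records.items()
    }


def snp_distance_matrix(alignment: GenomeSet) -> PairwiseMatrix:
    """Pairwise SNP counts over a whole-genome alignment.

    Entry (i, j) counts alignment columns where both sequences carry an
    unambiguous A/C/G/T (case-insensitive) and the bases differ; columns
    with a gap, N or ambiguity code in either sequence are skipped.
    """
    if not alignment.aligned:
        raise ValueError("snp_distance_matrix requires an aligned GenomeSet")
    ids = alignment.genome_ids
    enc = _encoded(alignment)
    n = len(ids)
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        a = enc[ids[i]]
        ok_a = a >= 0
        for j in range(i + 1, n):
            b = enc[ids[j]]
            d = int(np.count_nonzero(ok_a & (b >= 0) & (a != b)))
            out[i, j] = out[j, i] = d
    return PairwiseMatrix(
        genome_ids=ids,
        values=out,
        metric="snp_count",
        dyad_ids={gid: r.dyad_id for gid, r in alignment.records.items() if r.dyad_id},
    )


# ---------------------------------------------------------------------------
# k-mer ANI


def _canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical (strand-folded) k-mer codes as a unique int64 array.

    Each k-mer is 2-bit packed; the canonical form is the numeric minimum
    of the forward code and the code of its reverse complement. Windows
    containing non-ACGT characters are dropped.
    """
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        raise ValueError(f"sequence shorter than k={k}")
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    w = windows[valid].astype(np.int64)
    weights_f = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    fwd = w @ weights_f
    # reverse complement: complement codes, read right-to-left
    rc = (3 - w) @ weights_f[::-1]
    return np.unique(np.minimum(fwd, rc))


def _mash_hash(x: np.ndarray) -> np.ndarray:
    """Deterministic 64-bit mix (splitmix64 finalizer) for MinHash sketching."""
    z = x.astype(np.uint64)
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> np.uint64(31))


def ani_estimate(
    genome_a: str,
    genome_b: str,
    k: int = 21,
    mode: str = "exact_sets",
    sketch_size: int = 5000,
) -> tuple[float, bool]:
    """Estimate ANI between two genome sequences from k-mer Jaccard.

    The Jaccard index J of the canonical k-mer sets (exact, or a bottom-s
    MinHash sketch of the union) is converted to identity by the Mash
    formula  ANI = 1 + (1/k) ln(2J / (1 + J)),  clamped to [0, 1].

    Returns ``(ani, related)``; ``related`` is False when J = 0, in which
    case ANI is reported as 0.0 (the formula diverges).
    """
    if k % 2 == 0 or k < 3:
        raise ValueError("k must be odd and >= 3")
    if mode not in ("exact_sets", "minhash"):
        raise ValueError(f"unknown mode {mode!r}")
    ka = _canonical_kmers(genome_a, k)
    kb = _canonical_kmers(genome_b, k)
    if mode == "minhash":
        ha = np.sort(_mash_hash(ka))[:sketch_size]
        hb = np.sort(_mash_hash(kb))[:sketch_size]
        union = np.sort(np.union1d(ha, hb))[:sketch_size]
        inter = np.intersect1d(ha, hb, assume_unique=True)
        shared = np.intersect1d(union, inter, assume_unique=True).size
        j = shared / union.size
    else:
        inter = np.intersect1d(ka, kb, assume_unique=True).size
        j = inter / (ka.size + kb.size - inter)
    if j <= 0:
        return 0.0, False
    ani = 1.0 + np.log(2.0 * j / (1.0 + j)) / k
    return float(min(1.0, max(0.0, ani))), True


def ani_matrix(genomes: GenomeSet, k: int = 21, mode: str = "exact_sets",
               sketch_size: int = 5000) -> PairwiseMatrix:
    """Pairwise ANI over a genome set (diagonal = 1)."""
    ids = genomes.genome_ids
    kmers = {gid: _canonical_kmers(genomes.records[gid].sequence, k) for gid in ids}
    n = len(ids)
    out = np.ones((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            if mode == "exact_sets":
                ka, kb = kmers[ids[i]], kmers[ids[j]]
                inter = np.intersect1d(ka, kb, assume_unique=True).size
                jac = inter / (ka.size + kb.size - inter)
                if jac <= 0:
                    ani = 0.0
                else:
                    ani = float(min(1.0, max(0.0, 1.0 + np.log(2 * jac / (1 + jac)) / k)))
            else:
                ani, _ = ani_estimate(
                    genomes.records[ids[i]].sequence,
                    genomes.records[ids[j]].sequence,
                    k=k, mode=mode, sketch_size=sketch_size,
                )
            out[i, j] = out[j, i] = ani
    return PairwiseMatrix(
        genome_ids=ids,
        values=out,
        metric="ani",
        dyad_ids={gid: r.dyad_id for gid, r in genomes.records.items() if r.dyad_id},
    )


# ---------------------------------------------------------------------------
# gene content


def jaccard_gene_distance(
    gene_matrix: pd.DataFrame, dyad_ids: dict[str, str] | None = None
) -> PairwiseMatrix:
    """Jaccard distances between genome gene sets (genes x genomes booleans).

    distance(i, j) = 1 - |Gi & Gj| / |Gi | Gj|. Two empty gene sets are at
    distance 0 from each other and 1 from any non-empty set.
    """
    m = gene_matrix.to_numpy(dtype=bool)
    ids = [str(c) for c in gene_matrix.columns]
    n = len(ids)
    inter = (m.T.astype(np.int64) @ m.astype(np.int64)).astype(float)
    sizes = m.sum(axis=0).astype(float)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    both_empty = (sizes[:, None] == 0) & (sizes[None, :] == 0)
    dist[both_empty] = 0.0
    np.fill_diagonal(dist, 0.0)
    return PairwiseMatrix(
        genome_ids=ids, values=dist, metric="jaccard_distance", dyad_ids=dyad_ids or {}
    )


# ---------------------------------------------------------------------------
# UPGMA


def upgma(matrix: PairwiseMatrix) -> TreeNode:
    """UPGMA agglomeration of a distance matrix into a rooted ultrametric tree.

    Size-weighted average linkage; each merge sits at height d/2 and branch
    lengths are merge-height differences. Ties are broken deterministically
    by the lexicographically smallest member label of the candidate pair.
    """
    n = len(matrix.genome_ids)
    if n < 2:
        raise ValueError("UPGMA requires at least 2 leaves")
    d = matrix.values.astype(float).copy()
    if np.diag(d).any():
        raise ValueError("UPGMA requires a zero diagonal")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=matrix.genome_ids[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    # sort key of a cluster: lexicographically smallest member label
    keys = {i: matrix.genome_ids[i] for i in range(n)}
    active = list(range(n))
    dist = {(min(i, j), max(i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(active) > 1:
        best = min(
            ((i, j) for idx, i in enumerate(active) for j in active[idx + 1:]),
            key=lambda ij: (
                dist[(min(ij), max(ij))],
                *sorted((keys[ij[0]], keys[ij[1]])),
            ),
        )
        i, j = best
        h = dist[(min(i, j), max(i, j))] / 2.0
        left, right = sorted((nodes[i], nodes[j]), key=lambda t: min(t.leaf_names()))
        for child in (left, right):
            child.branch_length = h - child.height
        parent = TreeNode(children=[left, right], height=h)
        si, sj = sizes[i], sizes[j]
        for kk in active:
            if kk in (i, j):
                continue
            dik = dist[(min(i, kk), max(i, kk))]
            djk = dist[(min(j, kk), max(j, kk))]
            dist[(min(next_id, kk), max(next_id, kk))] = (si * dik + sj * djk) / (si + sj)
        active = [a for a in active if a not in (i, j)] + [next_id]
        nodes[next_id] = parent
        sizes[next_id] = si + sj
        keys[next_id] = min(keys[i], keys[j])
        next_id += 1
    root = nodes[active[0]]
    root.branch_length = 0.0
    return root


def is_ultrametric(tree: TreeNode, tol: float = 1e-9) -> bool:
    depths = tree.root_to_leaf_depths()
    return max(depths) - min(depths) <= tol


def dyad_cherry_fraction(tree: TreeNode, dyad_ids: dict[str, str]) -> float:
    """Fraction of multi-genome dyads whose members form a cherry (sister pair)."""
    cherries = set()

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            return
        kids = node.children
        if len(kids) == 2 and all(c.is_leaf for c in kids):
            cherries.add(frozenset(c.name for c in kids))
        for c in kids:
            walk(c)

    walk(tree)
    by_dyad: dict[str, list[str]] = {}
    for gid, dyad in dyad_ids.items():
        by_dyad.setdefault(dyad, []).append(gid)
    pairs = [frozenset(g) for g in by_dyad.values() if len(g) == 2]
    if not pairs:
        raise ValueError("no two-genome dyads to assess")
    return sum(p in cherries for p in pairs) / len(pairs)


# ---------------------------------------------------------------------------
# within/between partition and identity calls


def partition_by_dyad(matrix: PairwiseMatrix, run_test: bool = True) -> DyadPartitionResult:
    """Split off-diagonal pairs into within-dyad vs between-dyad sets.

    Every genome must carry a dyad label. The Mann-Whitney U test is run
    when both sets are non-empty (each pair treated as an independent
    observation, a deliberate simplification shared with the motivating
    analysis).
    """
    ids = matrix.genome_ids
    missing = [g for g in ids if g not in matrix.dyad_ids]
    if missing:
        raise ValueError(f"genomes without dyad labels: {missing[:5]}")
    within, between = [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            v = matrix.values[i, j]
            if matrix.dyad_ids[ids[i]] == matrix.dyad_ids[ids[j]]:
                within.append(v)
            else:
                between.append(v)
    w = np.asarray(within, dtype=float)
    b = np.asarray(between, dtype=float)
    test = None
    if run_test and len(w) and len(b):
        test = mann_whitney(w, b)
    return DyadPartitionResult(
        within_values=w,
        between_values=b,
        median_within=float(np.median(w)) if len(w) else float("nan"),
        median_between=float(np.median(b)) if len(b) else float("nan"),
        test=test,
    )


def strain_identity_call(
    matrix: PairwiseMatrix,
    origins: dict[str, str],
    ani_threshold: float = 0.999,
    snp_threshold: int = 25,
) -> dict[str, str]:
    """Per-dyad identical/nonidentical strain calls from a pairwise matrix.

    A dyad is "identical" if any maternal-infant genome pair within it
    passes the active threshold: ANI strictly greater than ``ani_threshold``
    (metric 'ani') or SNP count at most ``snp_threshold`` (metric
    'snp_count'), both boundary conventions inclusive of transmission.
    Dyads with genomes from only one side are "not_assessable".
    """
    if matrix.metric not in ("ani", "snp_count"):
        raise ValueError(f"identity calls undefined for metric {matrix.metric!r}")
    ids = matrix.genome_ids
    by_dyad: dict[str, list[str]] = {}
    for gid in ids:
        dyad = matrix.dyad_ids.get(gid)
        if dyad is None:
            raise ValueError(f"genome {gid!r} has no dyad label")
        by_dyad.setdefault(dyad, []).append(gid)
    idx = {gid: i for i, gid in enumerate(ids)}
    calls: dict[str, str] = {}
    for dyad, members in sorted(by_dyad.items()):
        mothers = [g for g in members if origins.get(g) == "maternal"]
        infants = [g for g in members if origins.get(g) == "infant"]
        if not mothers or not infants:
            calls[dyad] = "not_assessable"
            continue
        hit = False
        for m in mothers:
            for inf in infants:
                v = matrix.values[idx[m], idx[inf]]
                if matrix.metric == "ani" and v > ani_threshold:
                    hit = True
                elif matrix.metric == "snp_count" and v <= snp_threshold:
                    hit = True
        calls[dyad] = "identical" if hit else "nonidentical"
    return calls
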