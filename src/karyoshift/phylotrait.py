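"""Phylogenetic trait regression under Brownian motion, alignment filtering
statistics, and gene-tree quartet frequencies.

The regression is generalized least squares with residual covariance
proportional to the Brownian-motion matrix C, where C_ij is the shared
root-to-tip path length of tips i and j.  For a fixed tree the BM rate is
profiled analytically, so the closed form is exact:

    beta_hat  = (X' C^-1 X)^-1 X' C^-1 y
    sigma2    = (y - X beta)' C^-1 (y - X beta) / (n - p)
    SE(beta)  = sqrt(diag(sigma2 (X' C^-1 X)^-1))

with X = [1, x], p = 2, and two-sided p-values from Student's t on n - 2
degrees of freedom.  On a star tree with equal tip depths C is proportional
to the identity and the fit collapses to ordinary least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy import linalg, stats

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")


def phylo_covariance(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance of a rooted tree with branch lengths.

    Returns tip labels (tree leaf order) and C with C_ij = depth of the most
    recent common ancestor of tips i and j measured from the root (so the
    diagonal holds tip depths).
    """
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    index = {id(lf): i for i, lf in enumerate(leaves)}
    C = np.zeros((n, n))
    # each internal node's depth is the covariance of every pair of leaves
    # whose MRCA it is; filling per node covers all pairs exactly once
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._leafset = [index[id(node)]]
            C[node._leafset[0], node._leafset[0]] = node.root_distance
            continue
        depth = node.root_distance or 0.0
        children_sets = [ch._leafset for ch in node.child_nodes()]
        for a in range(len(children_sets)):
            for b in range(a + 1, len(children_sets)):
                for i in children_sets[a]:
                    for j in children_sets[b]:
                        C[i, j] = C[j, i] = depth
        node._leafset = [i for s in children_sets for i in s]
    return labels, C


@dataclass
class PglsResult:
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    t: float
    df: int
    p: float
    sigma2: float
    p_adjusted: float | None = None


def pgls_bm(
    tree: dendropy.Tree,
    y: Mapping[str, float] | Sequence[float],
    x: Mapping[str, float] | Sequence[float],
) -> PglsResult:
    """Fit trait ~ predictor by GLS under Brownian motion on ``tree``.

    ``y`` and ``x`` may be mappings keyed by tip label (matched to the tree)
    or sequences aligned to the tree's leaf order.
    """
    labels, C = phylo_covariance(tree)
    n = len(labels)
    if n < 4:
        raise ValueError("need at least 4 tips for a 2-parameter GLS fit")

    def _vec(v) -> np.ndarray:
        if isinstance(v, Mapping):
            missing = [lab for lab in labels if lab not in v]
            if missing:
                raise KeyError(f"missing trait values for tips: {missing}")
            return np.array([float(v[lab]) for lab in labels])
        arr = np.asarray(v, dtype=float)
        if arr.shape != (n,):
            raise ValueError("trait vector length does not match tree tips")
        return arr

    yv = _vec(y)
    xv = _vec(x)
    X = np.column_stack([np.ones(n), xv])
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("predictor is collinear with the intercept")
    try:
        cf = linalg.cho_factor(C)
    except linalg.LinAlgError as exc:
        raise ValueError(f"singular BM covariance (duplicate tips?): {exc}") from None
    Ci_X = linalg.cho_solve(cf, X)
    Ci_y = linalg.cho_solve(cf, yv)
    XtCiX = X.T @ Ci_X
    beta = np.linalg.solve(XtCiX, X.T @ Ci_y)
    resid = yv - X @ beta
    sigma2 = float(resid @ linalg.cho_solve(cf, resid)) / (n - 2)
    cov_beta = sigma2 * np.linalg.inv(XtCiX)
    se = np.sqrt(np.diag(cov_beta))
    t = float(beta[1] / se[1])
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return PglsResult(float(beta[0]), float(beta[1]), float(se[0]), float(se[1]),
                      t, n - 2, p, sigma2)


def bonferroni(pvals: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p × m capped at 1; m defaults to len(pvals)."""
    m = len(pvals) if m is None else m
    return [min(1.0, float(p) * m) for p in pvals]


@dataclass(frozen=True)
class AlignmentStats:
    alignment_id: str
    length: int
    pct_variable: float
    pct_parsimony_informative: float
    pct_gap_columns: float


def alignment_stats(
    sequences: Sequence[str], alignment_id: str = "aln"
) -> AlignmentStats:
    """Column statistics of an equal-length alignment.

    A column is variable when it has >= 2 distinct non-gap states, parsimony
    informative when >= 2 states each occur >= 2 times (gaps never count as
    states), and gap-containing when any sequence has a gap there.
    """
    if not sequences:
        raise ValueError("empty alignment")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("ragged alignment: sequences differ in length")
    if L == 0:
        raise ValueError("zero-length alignment")
    var = pi = gap = 0
    for col in zip(*sequences):
        states: dict[str, int] = {}
        has_gap = False
        for ch in col:
            cu = ch.upper()
            if cu in GAP_CHARS:
                has_gap = True
            else:
                states[cu] = states.get(cu, 0) + 1
        if has_gap:
            gap += 1
        if len(states) >= 2:
            var += 1
            if sum(1 for c in states.values() if c >= 2) >= 2:
                pi += 1
    return AlignmentStats(alignment_id, L, 100 * var / L, 100 * pi / L, 100 * gap / L)


def read_fasta_alignment(path) -> list[str]:
    from Bio import SeqIO
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


def filter_alignments(
    stats: Iterable[AlignmentStats],
    min_len: int = 500,
    min_var: float = 5.0,
    min_pi: float = 2.5,
    max_gap: float = 30.0,
) -> tuple[list[AlignmentStats], list[AlignmentStats]]:
    """Keep alignments longer than ``min_len`` with more than ``min_var``%
    variable and ``min_pi``% parsimony-informative columns and at most
    ``max_gap``% gap-containing columns (strict > on the first three,
    non-strict <= on gaps)."""
    kept, removed = [], []
    for s in stats:
        ok = (s.length > min_len
              and s.pct_variable > min_var
              and s.pct_parsimony_informative > min_pi
              and s.pct_gap_columns <= max_gap)
        (kept if ok else removed).append(s)
    return kept, removed


def quartet_frequencies(
    gene_trees: Sequence[dendropy.Tree],
    groups: Mapping[str, Sequence[str]],
) -> dict:
    """Relative support among gene trees for the three unrooted resolutions
    of four taxon groups.

    Each tree is restricted to the members of the four groups; a resolution
    such as AB|CD is counted when some edge bipartition separates exactly
    the A and B members from the C and D members.  Trees in which no pairing
    forms a clean bipartition (polytomies, non-monophyletic groups) count as
    unresolved and leave the denominator; trees missing a whole group are
    skipped.
    """
    names = list(groups)
    if len(names) != 4:
        raise ValueError("exactly four taxon groups required")
    pairings = [
        ((names[0], names[1]), (names[2], names[3])),
        ((names[0], names[2]), (names[1], names[3])),
        ((names[0], names[3]), (names[1], names[2])),
    ]
    counts = {pr: 0 for pr in pairings}
    unresolved = 0
    skipped = 0
    for tree in gene_trees:
        labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
        members = {g: set(t for t in groups[g]) & labels for g in names}
        if any(not members[g] for g in names):
            skipped += 1
            continue
        keep = set().union(*members.values())
        sub = tree.extract_tree_with_taxa_labels(keep)
        bipartitions: set[frozenset[str]] = set()
        for node in sub.preorder_node_iter():
            below = frozenset(lf.taxon.label for lf in node.leaf_iter())
            bipartitions.add(below)
            bipartitions.add(frozenset(keep - below))
        hit = None
        for pr in pairings:
            (g1, g2), (g3, g4) = pr
            side = frozenset(members[g1] | members[g2])
            if side in bipartitions:
                hit = pr
                break
        if hit is None:
            unresolved += 1
        else:
            counts[hit] += 1
    resolved = sum(counts.values())
    freqs = {
        f"{a}+{b}|{c}+{d}": (counts[((a, b), (c, d))] / resolved if resolved else np.nan)
        for (a, b), (c, d) in pairings
    }
    return {"frequencies": freqs, "counts": {f"{a}+{b}|{c}+{d}": counts[((a, b), (c, d))]
                                             for (a, b), (c, d) in pairings},
            "n_resolved": resolved, "n_unresolved": unresolved, "n_skipped": skipped}
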