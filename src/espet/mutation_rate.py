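"""Per-site relative mutation-rate estimation on a fixed phylogeny.

Given a rooted tree with branch lengths ``b_i`` (total ``B``) and the tip
genotypes of one site, ancestral states are reconstructed by Fitch
parsimony and branches are partitioned into those whose endpoints differ
(G1) and those that do not (G0).  Assuming the mutation count on branch
``i`` is Poisson with mean ``k b_i / B``, the likelihood of the partition
is

    L(k) = prod_{i in G1} (1 - e^{-k b_i / B}) prod_{j in G0} e^{-k b_j / B}

and the per-site expected mutation count ``k`` is estimated by solving
``d ln L / d k = 0``, which accounts for multiple mutations surfacing as a
single observable change on long branches.  ``k_hat / B`` is a relative
per-site mutation rate comparable across sites because ``B`` is shared.
Non-segregating sites are assigned a zero (negligible) rate; sites where
every branch changed have no finite maximizer and are flagged.

Strand-biased classification of C->T mutation events assumes hydrolytic
deamination of cytosine dominates C/G -> T/A changes: a C->T call sits on
the Watson strand and a G->A call is a C->T on the Crick strand; relative
to a gene's orientation each event is then a coding- or template-strand
deamination.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "TreeIndex",
    "infer_ancestral_states",
    "partition_branches",
    "estimate_k",
    "site_rates",
    "strand_classify",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = np.array(["A", "C", "G", "T"])
_BIT = np.array([1, 2, 4, 8], dtype=np.uint8)


class TreeIndex:
    """Array view of a rooted dendropy tree for vectorized traversals.

    Nodes are numbered in preorder (root first).  ``parent[j]`` is the
    preorder index of node ``j``'s parent (-1 for the root) and
    ``edge_length[j]`` the length of the branch above ``j``.
    """

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): j for j, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.parent = np.array(
            [
                index[id(nd.parent_node)] if nd.parent_node is not None else -1
                for nd in nodes
            ]
        )
        self.postorder = np.array(
            [index[id(nd)] for nd in tree.postorder_node_iter()]
        )
        self.children: list[list[int]] = [
            [index[id(ch)] for ch in nd.child_nodes()] for nd in nodes
        ]
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        lengths = []
        for nd in nodes:
            if nd.parent_node is None:
                lengths.append(0.0)
            else:
                if nd.edge.length is None or nd.edge.length <= 0:
                    raise ValueError(
                        "all branch lengths must be positive; got "
                        f"{nd.edge.length!r}"
                    )
                lengths.append(float(nd.edge.length))
        self.edge_length = np.array(lengths)
        self.tip_index = {
            nd.taxon.label: index[id(nd)]
            for nd in nodes
            if not nd.child_nodes()
        }
        self.total_length = float(self.edge_length.sum())


def _encode_genotypes(genotypes: np.ndarray) -> np.ndarray:
    if genotypes.dtype.kind in "US":
        flat = np.vectorize(_BASE_CODE.__getitem__, otypes=[np.uint8])(genotypes)
        return flat
    return genotypes.astype(np.uint8)


def infer_ancestral_states(
    tree_index: TreeIndex, tip_states: np.ndarray, tip_order: list[str]
) -> np.ndarray:
    """Fitch-parsimony states for every node, vectorized across sites.

    ``tip_states`` is (n_sites, n_tips) of base codes (0..3) or letters,
    with columns in ``tip_order``.  Downpass: a node's candidate set is
    the intersection of its children's sets when non-empty, else the
    union (multifurcations fold children in pairwise, the standard
    generalization).  Uppass: a node keeps its parent's state when that
    state is in its candidate set; otherwise ties are broken by the
    site's tip-base majority, then alphabetically.  Returns (n_nodes,
    n_sites) base codes in preorder node numbering.
    """
    codes = _encode_genotypes(np.asarray(tip_states))
    n_sites, n_tips = codes.shape
    if n_tips != len(tip_order):
        raise ValueError("tip_order does not match genotype matrix width")

    masks = np.zeros((tree_index.n_nodes, n_sites), dtype=np.uint8)
    for label, col in zip(tip_order, range(n_tips)):
        masks[tree_index.tip_index[label]] = _BIT[codes[:, col]]

    for j in tree_index.postorder:
        children = tree_index.children[j]
        if not children:
            continue
        inter = np.full(n_sites, 0x0F, dtype=np.uint8)
        union = np.zeros(n_sites, dtype=np.uint8)
        for c in children:
            inter &= masks[c]
            union |= masks[c]
        masks[j] = np.where(inter != 0, inter, union)

    # majority-then-alphabetical preference per site: score each base by
    # its tip count, breaking count ties toward the alphabetically first
    counts = np.zeros((4, n_sites), dtype=np.int64)
    for b in range(4):
        counts[b] = (codes == b).sum(axis=1)
    priority = counts * 4 + (3 - np.arange(4))[:, None]  # (4, n_sites)

    def pick(mask: np.ndarray) -> np.ndarray:
        scored = np.where(
            (mask[None, :] & _BIT[:, None]) != 0, priority, -1
        )
        return scored.argmax(axis=0).astype(np.uint8)

    states = np.zeros((tree_index.n_nodes, n_sites), dtype=np.uint8)
    for j in range(tree_index.n_nodes):  # nodes are numbered in preorder
        p = tree_index.parent[j]
        if p < 0:
            states[j] = pick(masks[j])
            continue
        parent_bit = _BIT[states[p]]
        keep = (masks[j] & parent_bit) != 0
        states[j] = np.where(keep, states[p], pick(masks[j]))
    return states


def partition_branches(
    tree_index: TreeIndex, node_states: np.ndarray
) -> np.ndarray:
    """Boolean (n_nodes, n_sites) matrix: branch above node j changed (G1).

    The root row (no branch) is always False.  ``G0`` is the complement
    over non-root rows.
    """
    changed = np.zeros_like(node_states, dtype=bool)
    for j in range(1, tree_index.n_nodes):
        changed[j] = node_states[j] != node_states[tree_index.parent[j]]
    return changed


def _stationarity(k: float, w1: np.ndarray, s0: float) -> float:
    # d ln L / d k, with w = b_i / B:
    #   sum_{G1} w e^{-k w} / (1 - e^{-k w}) - sum_{G0} w
    kw = k * w1
    # 1 - e^{-kw} via expm1 keeps the ratio finite for tiny kw
    return float((w1 * np.exp(-kw) / (-np.expm1(-kw))).sum() - s0)


def estimate_k(
    g1_lengths: np.ndarray,
    g0_lengths: np.ndarray,
    B: float | None = None,
    rtol: float = 1e-9,
) -> float:
    """ML expected mutation count from the branch partition.

    ``g1_lengths``/``g0_lengths`` are the branch lengths of the changed
    and unchanged groups.  Returns 0 when no branch changed, and NaN when
    every branch changed (the likelihood increases without bound).  The
    stationarity function is strictly decreasing in ``k``, so the root is
    bracketed by doubling and solved to relative tolerance ``rtol``.
    """
    w1 = np.asarray(g1_lengths, dtype=float)
    w0 = np.asarray(g0_lengths, dtype=float)
    if np.any(w1 <= 0) or np.any(w0 <= 0):
        raise ValueError("branch lengths must be positive")
    if B is None:
        B = w1.sum() + w0.sum()
    if B <= 0:
        raise ValueError("total branch length must be positive")
    if w1.size == 0:
        return 0.0
    if w0.size == 0:
        return float("nan")
    w1 = w1 / B
    s0 = float(w0.sum()) / B
    lo, hi = 1e-12, 1.0
    while _stationarity(hi, w1, s0) > 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - pathological scaling
            raise RuntimeError("failed to bracket the stationarity root")
    return float(
        optimize.brentq(
            _stationarity, lo, hi, args=(w1, s0), rtol=rtol, xtol=1e-12
        )
    )


def log_likelihood(
    k: float, g1_lengths: np.ndarray, g0_lengths: np.ndarray, B: float | None = None
) -> float:
    """ln L(k) for the branch-partition Poisson model (for diagnostics)."""
    w1 = np.asarray(g1_lengths, dtype=float)
    w0 = np.asarray(g0_lengths, dtype=float)
    if B is None:
        B = w1.sum() + w0.sum()
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return 0.0 if w1.size == 0 else float("-inf")
    with np.errstate(divide="ignore"):
        return float(
            np.log1p(-np.exp(-k * w1 / B)).sum() - k * w0.sum() / B
        )


def site_rates(
    tree: dendropy.Tree | TreeIndex,
    genotypes: np.ndarray,
    tip_order: list[str],
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Relative mutation rate for every site of a genotype matrix.

    Returns a frame with columns ``segregating``, ``n_changes`` (the
    parsimony change count |G1|), ``k_hat``, ``rate`` (= k_hat / B) and
    ``flagged`` (True when every branch changed and no finite estimate
    exists; such sites get NaN rates).  Optional ``sites`` supplies
    identifier columns to prepend.
    """
    ti = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    codes = _encode_genotypes(np.asarray(genotypes))
    n_sites = codes.shape[0]

    seg = (codes != codes[:, [0]]).any(axis=1)
    k_hat = np.zeros(n_sites)
    n_changes = np.zeros(n_sites, dtype=int)
    flagged = np.zeros(n_sites, dtype=bool)

    if seg.any():
        seg_idx = np.flatnonzero(seg)
        states = infer_ancestral_states(ti, codes[seg_idx], tip_order)
        changed = partition_branches(ti, states)
        b = ti.edge_length[1:]  # skip root row
        B = ti.total_length
        for s_local, s in enumerate(seg_idx):
            g1 = changed[1:, s_local]
            n_changes[s] = int(g1.sum())
            if g1.all():
                flagged[s] = True
                k_hat[s] = np.nan
            else:
                k_hat[s] = estimate_k(b[g1], b[~g1], B)

    out = pd.DataFrame(
        {
            "segregating": seg,
            "n_changes": n_changes,
            "k_hat": k_hat,
            "rate": k_hat / ti.total_length,
            "flagged": flagged,
        }
    )
    if sites is not None:
        out = pd.concat(
            [sites.reset_index(drop=True), out], axis=1
        )
    return out


@dataclass
class StrandClassification:
    """Per-gene stranded C->T deamination summary."""

    per_gene: pd.DataFrame
    n_ignored: int


def strand_classify(
    mutations: pd.DataFrame, genes: pd.DataFrame
) -> StrandClassification:
    """Assign C->T/G->A events to DNA strands and gene-relative roles.

    ``mutations`` needs columns gene_id, ref, alt (Watson-strand alleles);
    ``genes`` needs gene_id, strand ('+' for Watson-sense genes) and the
    cytosine counts of the two strands, ``n_c_watson`` and ``n_c_crick``,
    used to normalize counts into relative per-C rates.  Non-deamination
    events are ignored and counted.
    """
    for col in ("gene_id", "ref", "alt"):
        if col not in mutations.columns:
            raise ValueError(f"mutation table is missing column {col!r}")
    for col in ("gene_id", "strand", "n_c_watson", "n_c_crick"):
        if col not in genes.columns:
            raise ValueError(f"gene table is missing column {col!r}")

    ref = mutations["ref"].str.upper()
    alt = mutations["alt"].str.upper()
    is_ct = (ref == "C") & (alt == "T")
    is_ga = (ref == "G") & (alt == "A")
    usable = mutations.loc[is_ct | is_ga].copy()
    usable["dna_strand"] = np.where(
        (usable["ref"].str.upper() == "C"), "watson", "crick"
    )

    gene_info = genes.set_index("gene_id")
    rows = []
    for gene_id, grp in usable.groupby("gene_id"):
        if gene_id not in gene_info.index:
            raise KeyError(f"gene {gene_id!r} missing from annotation")
        info = gene_info.loc[gene_id]
        sense = "watson" if info["strand"] == "+" else "crick"
        coding = int((grp["dna_strand"] == sense).sum())
        template = int((grp["dna_strand"] != sense).sum())
        n_c_coding = info["n_c_watson"] if sense == "watson" else info["n_c_crick"]
        n_c_template = info["n_c_crick"] if sense == "watson" else info["n_c_watson"]
        rows.append(
            {
                "gene_id": gene_id,
                "coding_ct": coding,
                "template_ct": template,
                "coding_rate": coding / n_c_coding if n_c_coding else np.nan,
                "template_rate": template / n_c_template
                if n_c_template
                else np.nan,
            }
        )
    per_gene = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "coding_ct",
            "template_ct",
            "coding_rate",
            "template_rate",
        ],
    )
    return StrandClassification(
        per_gene=per_gene, n_ignored=int(len(mutations) - len(usable))
    )
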