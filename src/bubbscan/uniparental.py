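"""Y-chromosome haplogroup workflow: site filtering, NJ clustering, frequencies.

Male-specific sites are kept only if they are absent from females, never
heterozygous in a male (a haploid chromosome cannot be het; such calls are
mapping artifacts) and called in at least 95% of males.  Pairwise Hamming
distances (normalised by shared called sites) feed a canonical
neighbour-joining tree; haplogroups are the two sides of the deepest
bipartition (or of the outgroup edge when an outgroup is supplied), and
per-geographic-group haplogroup frequencies are tabulated from the labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants_io import MISSING


@dataclass
class YMatrix:
    """Males x sites haploid calls in {0,1} with -1 for missing."""

    calls: np.ndarray
    males: list[str]
    site_ids: list[str] = field(default_factory=list)
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape[0] != len(self.males):
            raise ValueError("calls must be males x sites")
        bad = ~np.isin(self.calls, [0, 1, MISSING])
        if np.any(bad):
            raise ValueError("haploid calls must be 0, 1 or missing after filtering")


def filter_y_sites(male_calls: np.ndarray, female_called: np.ndarray,
                   het_flags: np.ndarray | None = None, max_missing: float = 0.05,
                   males: list[str] | None = None) -> tuple[YMatrix, dict[str, int]]:
    """Apply the three male-specific site filters; report per-filter attrition.

    Parameters
    ----------
    male_calls : males x sites in {0,1,-1}, or diploid-coded {0,1,2,-1} in
        which case dosage 1 marks a heterozygous artifact call.
    female_called : per-site bool, True where any female carries a call.
    het_flags : optional per-site bool marking heterozygous sites; derived
        from dosage-1 entries when absent.
    max_missing : drop sites whose missing fraction among males exceeds this
        (default 0.05, i.e. call rate below 95%).

    The filters commute; they are applied to the full site set independently.
    """
    calls = np.asarray(male_calls)
    n_males, n_sites = calls.shape
    female_called = np.asarray(female_called, dtype=bool)
    if female_called.size != n_sites:
        raise ValueError("female_called length must match site count")
    if het_flags is None:
        # diploid-coded input: dosage 1 marks a heterozygous artifact call
        if calls.max(initial=0) > 1:
            het_flags = np.any(calls == 1, axis=0)
        else:
            het_flags = np.zeros(n_sites, dtype=bool)
    het_flags = np.asarray(het_flags, dtype=bool)
    missing_frac = np.mean(calls == MISSING, axis=0)
    drop_female = female_called
    drop_het = het_flags
    drop_missing = missing_frac > max_missing
    keep = ~(drop_female | drop_het | drop_missing)
    report = {
        "input_sites": n_sites,
        "removed_in_females": int(drop_female.sum()),
        "removed_heterozygous": int(drop_het.sum()),
        "removed_low_call_rate": int(drop_missing.sum()),
        "retained": int(keep.sum()),
    }
    if report["retained"] == 0:
        raise ValueError(f"no sites survive the Y filters: {report}")
    kept = calls[:, keep].copy()
    kept[kept == 2] = 1  # collapse diploid-coded derived calls to haploid
    if males is None:
        males = [f"male_{i}" for i in range(n_males)]
    site_ids = [f"site_{j}" for j in np.flatnonzero(keep)]
    return YMatrix(kept.astype(np.int8), list(males), site_ids), report


def hamming_matrix(y: YMatrix) -> np.ndarray:
    """Pairwise mismatch fraction over sites called in both haplotypes.

    Symmetric, zero diagonal.  A pair sharing no called site gets NaN.
    """
    calls = y.calls
    called = calls != MISSING
    n = calls.shape[0]
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        both = called[i] & called
        diff = (calls[i] != calls) & both
        shared = both.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(shared > 0, diff.sum(axis=1) / shared, np.nan)
        d[i] = row
    np.fill_diagonal(d, 0.0)
    return d


class TreeNode:
    """Minimal binary-ish tree node with branch length to its parent."""

    __slots__ = ("name", "length", "children")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 children: list["TreeNode"] | None = None):
        self.name = name
        self.length = length
        self.children = children or []

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out: list[str] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(ch._nwk() for ch in self.children)
        return f"({inner}):{self.length:.6g}"


def nj_tree(distances: np.ndarray, labels: list[str]) -> TreeNode:
    """Canonical neighbour-joining (Saitou & Nei / Studier & Keppler).

    Ties in the Q matrix break towards the lowest (i, j) index pair.
    Negative branch lengths are clamped to 0 with the length transferred to
    the sibling edge, preserving the pair's summed length.
    Returns an unrooted tree represented with a trifurcating root (or a
    single edge for 2 taxa).
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix / label mismatch")
    if np.any(np.isnan(d)):
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    nodes = [TreeNode(name=l) for l in labels]
    active = list(range(n))
    dist = d.copy()
    if n == 1:
        return nodes[0]
    if n == 2:
        a, b = nodes
        a.length = dist[0, 1] / 2
        b.length = dist[0, 1] / 2
        return TreeNode(children=[a, b])
    while len(active) > 2:
        r = len(active)
        sub = dist[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (r - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: flat argmin scans rows then columns
        fi, fj = divmod(int(np.argmin(q)), r)
        if fi > fj:
            fi, fj = fj, fi
        i, j = active[fi], active[fj]
        dij = sub[fi, fj]
        li = 0.5 * dij + (totals[fi] - totals[fj]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            lj, li = dij, 0.0
        if lj < 0:
            li, lj = dij, 0.0
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_d = 0.5 * (dist[i, active] + dist[j, active] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        k = dist.shape[0] - 1
        dist[k, active] = new_d
        dist[active, k] = new_d
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [k]
    i, j = active
    # final edge: a leaf keeps the full remaining length (path lengths are
    # preserved either way; this keeps small-tree output conventional)
    if not nodes[i].children:
        nodes[i].length, nodes[j].length = dist[i, j], 0.0
    elif not nodes[j].children:
        nodes[i].length, nodes[j].length = 0.0, dist[i, j]
    else:
        nodes[i].length, nodes[j].length = dist[i, j], 0.0
    return TreeNode(children=[nodes[i], nodes[j]])


@dataclass
class CladeAssignment:
    """Haplogroup label per male plus the tree the split came from."""

    labels: dict[str, str]
    tree: TreeNode
    split_edge_length: float


def _internal_edges(root: TreeNode) -> list[tuple[TreeNode, float, list[str]]]:
    """(node, branch length, leafset below) for every non-root internal node."""
    edges = []

    def walk(node: TreeNode) -> None:
        for ch in node.children:
            if ch.children:
                edges.append((ch, ch.length, ch.leaves()))
            walk(ch)

    walk(root)
    return edges


def assign_clades(tree: TreeNode, outgroup: str | None = None,
                  k: int = 2) -> CladeAssignment:
    """Bipartition the tree into haplogroups.

    With an outgroup, the split is at the outgroup edge and the outgroup is
    excluded from the labels.  Otherwise the longest internal edge defines
    the bipartition; on a star-like tree (no internal edge) the first
    bipartition is used with a warning.  ``k`` > 2 recursively splits the
    largest clade at its own longest internal edge.
    """
    all_leaves = tree.leaves()
    if outgroup is not None:
        if outgroup not in all_leaves:
            raise ValueError(f"outgroup {outgroup!r} not in tree")
        members = [l for l in all_leaves if l != outgroup]
        # an edge whose below-leafset contains the outgroup bipartitions the
        # ingroup via its complement
        edges = []
        for n, ln, lv in _internal_edges(tree):
            inside = ([l for l in members if l not in lv] if outgroup in lv
                      else list(lv))
            if 0 < len(inside) < len(members):
                edges.append((n, ln, inside))
    else:
        members = all_leaves
        edges = [(n, ln, lv) for n, ln, lv in _internal_edges(tree)
                 if 0 < len(lv) < len(members)]
    if edges and max(e[1] for e in edges) > 0:
        _, length, inside = max(edges, key=lambda e: e[1])
    else:
        import warnings
        warnings.warn("star-like tree: no positive-length internal edge; "
                      "using the first bipartition")
        if edges:
            _, length, inside = edges[0]
        else:
            inside = tree.children[0].leaves() if tree.children else members[:1]
            length = 0.0
        inside = [l for l in inside if l in members]
    inside_set = set(inside)
    labels = {m: ("H1" if m in inside_set else "H2") for m in members}
    if k != 2:
        raise NotImplementedError("only k=2 haplogroups are supported")
    return CladeAssignment(labels, tree, float(length))


def haplogroup_frequencies(assign: CladeAssignment,
                           group_labels: dict[str, str]) -> pd.DataFrame:
    """Per-group haplogroup counts and percentages (2-dp, summing to 100).

    ``group_labels`` maps male id -> geographic group.  Males without a group
    label fall into "ungrouped".
    """
    rows = []
    for male, hap in assign.labels.items():
        rows.append({"male": male, "haplogroup": hap,
                     "group": group_labels.get(male, "ungrouped")})
    df = pd.DataFrame(rows)
    counts = df.groupby(["group", "haplogroup"]).size().unstack(fill_value=0)
    freq = counts.div(counts.sum(axis=1), axis=0) * 100
    out = counts.join(freq.round(2), lsuffix="_n", rsuffix="_pct")
    out.columns = [f"{c}" for c in out.columns]
    return out.reset_index()
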