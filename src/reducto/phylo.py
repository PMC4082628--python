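"""Marker-gene phylogenetics: alignment, distances, neighbor joining with
bootstrap, MLST, subspecies-diagnostic sites and tree-incongruence screening.

Multiple alignment delegates to MAFFT (progressive stage, deterministic:
input is canonicalized to label order and run single-threaded), so the
induced alignment is invariant under permutations of the input.  Distance
computation (p-distance or Kimura two-parameter, pairwise deletion of gap
columns), neighbor joining, bootstrap supports, bipartition extraction and
Robinson-Foulds comparison are implemented here; trees are carried as
:class:`dendropy.Tree` objects.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from math import log, sqrt
from pathlib import Path

import dendropy
import numpy as np

from .seqio import read_fasta, write_fasta

TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass
class MultipleAlignment:
    labels: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise ValueError("labels/rows length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")
        if self.rows and len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows of unequal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]

    def identity_matrix(self) -> np.ndarray:
        """Pairwise fraction-identical over columns where neither row gaps."""
        n = len(self.rows)
        out = np.eye(n)
        arr = np.array([list(r) for r in self.rows])
        for i in range(n):
            for j in range(i + 1, n):
                ok = (arr[i] != "-") & (arr[j] != "-")
                out[i, j] = out[j, i] = (
                    float(np.mean(arr[i][ok] == arr[j][ok])) if ok.any() else 0.0)
        return out


def progressive_align(seqs: dict[str, str] | list[tuple[str, str]]) -> MultipleAlignment:
    """Progressive multiple alignment (MAFFT, FFT-NS-2, single thread).

    Sequences are passed to the aligner in sorted label order, which makes
    the result independent of the caller's input order; the output keeps
    sorted label order.
    """
    items = sorted(dict(seqs).items())
    if len(items) < 2:
        raise ValueError("progressive alignment requires >= 2 sequences")
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fasta"
        write_fasta(inp, items)
        res = subprocess.run(
            ["mafft", "--retree", "2", "--maxiterate", "0", "--thread", "1",
             "--preservecase", "--quiet", str(inp)],
            capture_output=True, text=True, check=True)
        out = Path(tmp) / "out.fasta"
        out.write_text(res.stdout)
        aligned = read_fasta(out)
    labels = [k for k, _ in items]
    return MultipleAlignment(labels, [aligned[k] for k in labels])


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _pair_distance(a: str, b: str, model: str) -> float:
    valid = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not valid:
        return float("nan")
    n = len(valid)
    if model == "p":
        return sum(x != y for x, y in valid) / n
    if model == "K2P":
        p = sum(x != y and frozenset((x, y)) in TRANSITIONS for x, y in valid) / n
        q = sum(x != y and frozenset((x, y)) not in TRANSITIONS for x, y in valid) / n
        w1 = 1 - 2 * p - q
        w2 = 1 - 2 * q
        if w1 <= 0 or w2 <= 0:
            return float("nan")  # distance undefined, flagged as missing
        return -0.5 * log(w1 * sqrt(w2))
    raise ValueError(f"unknown model {model!r}")


def distance_matrix(aln: MultipleAlignment, model: str = "p") -> np.ndarray:
    """Symmetric pairwise distance matrix with pairwise deletion of gaps."""
    n = len(aln.rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pair_distance(aln.rows[i], aln.rows[j], model)
    return d


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{max(x, 0.0):.12g}"


def nj_tree(d: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Standard neighbor joining on a symmetric distance matrix.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister edge; joins break ties deterministically on the smallest
    (lexicographic) pair of cluster labels.  Returns an unrooted tree whose
    seed node has three children (two for n = 2).
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    if n != len(labels):
        raise ValueError("labels do not match matrix size")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains missing entries")

    newicks = list(labels)     # newick fragment per active cluster
    minlab = list(labels)      # smallest leaf label per cluster, for ties
    dm = d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = dm[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = [(tuple(sorted((minlab[active[i]], minlab[active[j]]))), i, j)
                for i, j in zip(*np.where(np.isclose(q, qmin, rtol=0, atol=1e-12)))
                if i < j]
        _, i, j = min(ties)
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        merged = f"({newicks[ai]}:{_fmt(li)},{newicks[aj]}:{_fmt(lj)})"
        new_idx = dm.shape[0]
        newd = np.zeros((new_idx + 1, new_idx + 1))
        newd[:new_idx, :new_idx] = dm
        for k in active:
            if k in (ai, aj):
                continue
            v = (dm[ai, k] + dm[aj, k] - dij) / 2
            newd[new_idx, k] = newd[k, new_idx] = v
        dm = newd
        newicks.append(merged)
        minlab.append(min(minlab[ai], minlab[aj]))
        active = [k for k in active if k not in (ai, aj)] + [new_idx]

    if len(active) == 3:
        a, b, c = active
        la = (dm[a, b] + dm[a, c] - dm[b, c]) / 2
        lb = (dm[a, b] + dm[b, c] - dm[a, c]) / 2
        lc = (dm[a, c] + dm[b, c] - dm[a, b]) / 2
        newick = (f"({newicks[a]}:{_fmt(la)},{newicks[b]}:{_fmt(lb)},"
                  f"{newicks[c]}:{_fmt(lc)});")
    else:
        a, b = active
        half = dm[a, b] / 2
        newick = f"({newicks[a]}:{_fmt(half)},{newicks[b]}:{_fmt(half)});"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions and Robinson-Foulds
# ---------------------------------------------------------------------------

def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of leaf labels, each normalized
    to the side not containing the lexicographically smallest leaf."""
    taxa = leaf_labels(tree)
    ref = min(taxa)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if ref in side:
            side = taxa - side
        if 1 < len(side) < len(taxa) - 1:
            out.add(frozenset(side))
    return out


def supported_bipartitions(tree: dendropy.Tree, threshold: float) -> set[frozenset]:
    """Bipartitions whose internal-node support label meets ``threshold``;
    unlabeled edges are treated as supported."""
    taxa = leaf_labels(tree)
    ref = min(taxa)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        support = None
        if node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                support = None
        if support is not None and support < threshold:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if ref in side:
            side = taxa - side
        if 1 < len(side) < len(taxa) - 1:
            out.add(frozenset(side))
    return out


def restrict_to_leaves(tree: dendropy.Tree, labels: set[str]) -> dendropy.Tree:
    copy = tree.extract_tree()
    copy.retain_taxa_with_labels(sorted(labels))
    copy.is_rooted = False
    return copy


def rf_incongruence(t1: dendropy.Tree, t2: dendropy.Tree,
                    support_threshold: float = 70.0) -> tuple[int, int, bool]:
    """Robinson-Foulds distance on the shared leaf set.

    Returns ``(rf, n_shared_leaves, incongruent)``; the flag considers only
    bipartitions supported at ``support_threshold`` or better (unlabeled
    edges count as supported), so weakly supported conflicts do not trigger
    a horizontal-transfer signal.
    """
    shared = leaf_labels(t1) & leaf_labels(t2)
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared leaves; need >= 4")
    r1 = restrict_to_leaves(t1, shared)
    r2 = restrict_to_leaves(t2, shared)
    b1, b2 = bipartitions(r1), bipartitions(r2)
    rf = len(b1 ^ b2)
    s1, s2 = supported_bipartitions(r1, support_threshold), supported_bipartitions(r2, support_threshold)
    incongruent = len((s1 - b2) | (s2 - b1)) > 0
    return rf, len(shared), incongruent


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(aln: MultipleAlignment, n_reps: int = 1000,
                      seed: int = 0, model: str = "p") -> dendropy.Tree:
    """Neighbor-joining tree with bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; the support of
    each internal edge of the full-data tree is the percentage of replicate
    trees containing its bipartition, written to the internal node label.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(distance_matrix(aln, model), aln.labels)
    rng = np.random.default_rng(seed)
    arr = np.array([list(r) for r in aln.rows])
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(tree)}
    n_cols = aln.n_columns
    for _ in range(n_reps):
        idx = rng.integers(0, n_cols, size=n_cols)
        rep = MultipleAlignment(aln.labels, ["".join(row) for row in arr[:, idx]])
        try:
            rep_tree = nj_tree(distance_matrix(rep, model), rep.labels)
        except ValueError:  # e.g. K2P undefined on a resample
            continue
        rep_bps = bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    taxa = leaf_labels(tree)
    ref = min(taxa)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if ref in side:
            side = taxa - side
        bp = frozenset(side)
        if bp in counts:
            node.label = f"{100.0 * counts[bp] / n_reps:g}"
    return tree


# ---------------------------------------------------------------------------
# MLST
# ---------------------------------------------------------------------------

MLST_LOCI = ("fusA", "gyrB", "hsp60", "ileS", "pyrG", "recA", "recG")


@dataclass
class MlstScheme:
    loci: tuple[str, ...] = MLST_LOCI
    gene_ids: dict[str, str] | None = None  # locus -> gene id in the annotation

    def __post_init__(self):
        if len(self.loci) != 7:
            raise ValueError("an MLST scheme here has exactly 7 loci")
        if self.gene_ids is None:
            self.gene_ids = {l: l for l in self.loci}


def extract_mlst_loci(strains, scheme: MlstScheme) -> dict[str, dict[str, str]]:
    """Pull each locus sequence out of annotated strain genomes by the
    ``gene`` attribute of CDS features.  Returns locus -> strain -> seq."""
    from .seqio import extract_feature_seq
    out: dict[str, dict[str, str]] = {l: {} for l in scheme.loci}
    for strain in strains:
        by_gene = {f.attributes.get("gene"): f for f in strain.features
                   if f.ftype == "CDS"}
        for locus in scheme.loci:
            feat = by_gene.get(scheme.gene_ids[locus])
            if feat is not None:
                out[locus][strain.strain_id] = extract_feature_seq(strain.seq, feat)
    return out


def mlst_run(locus_seqs: dict[str, dict[str, str]],
             scheme: MlstScheme | None = None,
             model: str = "p") -> tuple[MultipleAlignment, dendropy.Tree]:
    """Concatenated-locus alignment and its neighbor-joining tree.

    Strains missing any locus are excluded with a warning.
    """
    scheme = scheme or MlstScheme(loci=tuple(sorted(locus_seqs)))
    strains = None
    for locus in scheme.loci:
        present = set(locus_seqs.get(locus, {}))
        strains = present if strains is None else strains & present
    all_strains = set().union(*(set(v) for v in locus_seqs.values()))
    for missing in sorted(all_strains - (strains or set())):
        warnings.warn(f"strain {missing} lacks one or more MLST loci; excluded")
    strains = sorted(strains or ())
    if len(strains) < 2:
        raise ValueError("fewer than 2 strains with all loci present")
    parts = {s: [] for s in strains}
    for locus in scheme.loci:
        aln = progressive_align({s: locus_seqs[locus][s] for s in strains})
        for s in strains:
            parts[s].append(aln.row(s))
    concat = MultipleAlignment(strains, ["".join(parts[s]) for s in strains])
    tree = nj_tree(distance_matrix(concat, model), concat.labels)
    return concat, tree


def is_monophyletic(tree: dendropy.Tree, labels: set[str]) -> bool:
    """True when ``labels`` form one side of some edge of the unrooted tree."""
    taxa = leaf_labels(tree)
    group = frozenset(labels)
    if group == taxa or len(group) <= 1:
        return True
    ref = min(taxa)
    target = frozenset(taxa - group) if ref in group else group
    if len(target) in (1, len(taxa) - 1):
        return True
    return target in bipartitions(tree)


# ---------------------------------------------------------------------------
# diagnostic sites
# ---------------------------------------------------------------------------

def diagnostic_sites(aln: MultipleAlignment, groups: dict[str, str],
                     share_groups: set[str], differ_group: str,
                     query: str | None = None) -> list[int]:
    """Alignment columns that separate ``differ_group`` from the shared state.

    A column qualifies when every member of every group in ``share_groups``
    (and the query row, if given) carries one identical nucleotide, every
    member of ``differ_group`` carries one identical nucleotide, and the two
    states differ.  Columns with a gap in any involved row are skipped.
    Returns 1-based column indices on the alignment.
    """
    share_rows = [l for l in aln.labels
                  if groups.get(l) in share_groups and l != query]
    differ_rows = [l for l in aln.labels
                   if groups.get(l) == differ_group and l != query]
    for name, rows in (("share", share_rows), ("differ", differ_rows)):
        if not rows:
            raise ValueError(f"{name} group is empty")
    involved = share_rows + ([query] if query else [])
    sites = []
    for col in range(aln.n_columns):
        states = {aln.row(l)[col] for l in involved}
        dstates = {aln.row(l)[col] for l in differ_rows}
        if "-" in states or "-" in dstates:
            continue
        if len(states) == 1 and len(dstates) == 1 and states != dstates:
            sites.append(col + 1)
    return sites
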