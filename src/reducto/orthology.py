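"""All-vs-all protein comparison, single-linkage ortholog clustering and
core-proteome partitioning.

The clustering criterion follows blastp-style practice for bacterial
pan-genome analyses: two proteins are linked when some local alignment
between them simultaneously satisfies an e-value ceiling, a minimum percent
identity over the aligned columns, and a minimum aligned span on the longer
of the two sequences.  Ortholog groups are the connected components of the
resulting similarity graph (single linkage), so one qualifying hit in either
direction suffices to merge two groups.

Only intact proteins take part: pseudogene fragments are excluded by
contract and are instead cross-referenced afterwards (:func:`fragment_rescue`)
to ask whether a clade-specific group left recognizable gene remnants in the
opposite clade — the signature of differential gene loss.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
from Bio.Align import PairwiseAligner, substitution_matrices

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

# Karlin-Altschul parameters for gapped BLOSUM62 with BLAST's default
# penalties (open 11, extend 1); used for the e-value approximation.
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass(frozen=True)
class ProteinRecord:
    strain_id: str
    protein_id: str
    sequence: str
    is_pseudo: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(f"{self.protein_id}: invalid residues {sorted(bad)}")


@dataclass
class ClusterParams:
    evalue_max: float = 1e-3
    identity_min: float = 0.78
    coverage_min: float = 0.76
    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self):
        for name in ("identity_min", "coverage_min"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        try:
            substitution_matrices.load(self.matrix_name)
        except Exception:
            raise ValueError(f"unknown substitution matrix {self.matrix_name!r}")


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    score: float
    bit_score: float
    evalue: float
    identity: float          # identical matches / aligned columns (incl. gaps)
    longest_coverage: float  # aligned span on the longer sequence / its length
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]


def _make_aligner(params: ClusterParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    # BLAST convention: a gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def karlin_altschul_evalue(score: float, m: int, n: int) -> float:
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


def bit_score(score: float) -> float:
    return (KA_LAMBDA * score - math.log(KA_K)) / math.log(2)


def local_align(a: ProteinRecord, b: ProteinRecord,
                params: ClusterParams | None = None,
                search_space: int | None = None) -> AlignmentHit:
    """Optimal local alignment of two proteins under affine gap penalties.

    Identity is computed over all aligned columns including gap columns
    (blastp convention); coverage is the aligned span on the longer sequence
    divided by its length; the e-value uses the Karlin-Altschul approximation
    with ``search_space`` as the product of query and database lengths
    (defaults to ``len(a) * len(b)``).
    """
    params = params or ClusterParams()
    aligner = _make_aligner(params)
    aln = aligner.align(a.sequence, b.sequence)[0]
    blocks_a, blocks_b = aln.aligned
    identities = 0
    columns = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        columns += ea - sa
        identities += sum(a.sequence[sa + i] == b.sequence[sb + i]
                          for i in range(ea - sa))
    # gap columns between consecutive aligned blocks
    for k in range(1, len(blocks_a)):
        columns += (blocks_a[k][0] - blocks_a[k - 1][1]) + (blocks_b[k][0] - blocks_b[k - 1][1])
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    longer_span, longer_len = ((span_a, len(a.sequence))
                               if len(a.sequence) >= len(b.sequence)
                               else (span_b, len(b.sequence)))
    mn = search_space if search_space is not None else len(a.sequence) * len(b.sequence)
    score = float(aln.score)
    return AlignmentHit(
        query_id=a.protein_id, subject_id=b.protein_id, score=score,
        bit_score=bit_score(score),
        evalue=karlin_altschul_evalue(score, 1, mn),
        identity=identities / columns if columns else 0.0,
        longest_coverage=longer_span / longer_len,
        query_interval=(int(blocks_a[0][0]), int(blocks_a[-1][1])),
        subject_interval=(int(blocks_b[0][0]), int(blocks_b[-1][1])),
    )


def hit_qualifies(hit: AlignmentHit, params: ClusterParams) -> bool:
    """Strict inequalities: e < max, identity > min, coverage > min."""
    return (hit.evalue < params.evalue_max
            and hit.identity > params.identity_min
            and hit.longest_coverage > params.coverage_min)


def _kmer_candidates(proteins: list[ProteinRecord], k: int = 5,
                     min_shared: int = 8) -> set[tuple[int, int]]:
    """Candidate pairs sharing at least ``min_shared`` k-mers.

    At the identity level that can qualify an edge (>78% over >76% of the
    longer sequence) homologous pairs share conserved k-mers in abundance,
    while unrelated pairs of a few hundred residues share none to a handful;
    the cutoff prunes the quadratic alignment stage without touching real
    edges at realistic divergence.
    """
    index: dict[str, list[int]] = defaultdict(list)
    for i, p in enumerate(proteins):
        for j in set(p.sequence[x:x + k] for x in range(len(p.sequence) - k + 1)):
            index[j].append(i)
    shared: dict[tuple[int, int], int] = defaultdict(int)
    for members in index.values():
        if len(members) < 2:
            continue
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                shared[(members[x], members[y])] += 1
    return {pair for pair, n in shared.items() if n >= min_shared}


def similarity_edges(proteomes: list[ProteinRecord],
                     params: ClusterParams | None = None,
                     exhaustive: bool = False,
                     cross_strain_only: bool = False) -> list[tuple[str, str, AlignmentHit]]:
    """Undirected qualifying edges between all protein pairs.

    ``exhaustive=True`` disables the shared-k-mer prefilter and evaluates
    every pair.  The search space for the e-value is the total residue count
    of the run times the query length, mirroring a database search.
    """
    params = params or ClusterParams()
    for p in proteomes:
        if p.is_pseudo:
            raise ValueError(
                f"{p.protein_id} is flagged as a pseudogene fragment; "
                "clustering is defined over proteins encoded by non-pseudogenes")
    ids = set()
    for p in proteomes:
        key = (p.strain_id, p.protein_id)
        if key in ids:
            raise ValueError(f"duplicate protein {key}")
        ids.add(key)
    db_residues = sum(len(p.sequence) for p in proteomes)
    if exhaustive:
        pairs = [(i, j) for i in range(len(proteomes))
                 for j in range(i + 1, len(proteomes))]
    else:
        pairs = sorted(_kmer_candidates(proteomes))
    edges = []
    for i, j in pairs:
        a, b = proteomes[i], proteomes[j]
        if a.protein_id == b.protein_id and a.strain_id == b.strain_id:
            continue
        if cross_strain_only and a.strain_id == b.strain_id:
            continue
        hit = local_align(a, b, params, search_space=len(a.sequence) * db_residues)
        if hit_qualifies(hit, params):
            edges.append((a.protein_id, b.protein_id, hit))
    return edges


@dataclass
class OrthologGroup:
    group_id: str
    members: list[tuple[str, str]]  # (strain_id, protein_id)

    @property
    def strains(self) -> set[str]:
        return {s for s, _ in self.members}


def cluster_single_linkage(proteins: list[ProteinRecord],
                           edges: list) -> list[OrthologGroup]:
    """Connected components of the similarity graph; singletons for proteins
    with no qualifying hit.  Groups are ordered lexicographically by their
    smallest member protein id, which also names them."""
    by_id = {p.protein_id: p for p in proteins}
    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    for edge in edges:
        u, v = edge[0], edge[1]
        if u not in by_id or v not in by_id:
            raise ValueError(f"edge references unknown protein: {u!r} - {v!r}")
        graph.add_edge(u, v)
    comps = sorted((sorted(c) for c in nx.connected_components(graph)),
                   key=lambda c: c[0])
    groups = []
    for idx, comp in enumerate(comps):
        members = [(by_id[pid].strain_id, pid) for pid in comp]
        groups.append(OrthologGroup(f"OG{idx + 1:05d}", members))
    return groups


@dataclass
class CorePartition:
    """Core-proteome partition of ortholog groups over two subspecies.

    ``labels[0]`` plays the role of the first subspecies: category A
    (``specific[labels[0]]``) collects groups present in every strain of it
    and absent from all strains of the other; category B
    (``partial[labels[0]]``) groups present in every strain of it but absent
    from only some (1..n-1) strains of the other.  C and D are symmetric.
    "Absent" means no intact member at all — pseudogene fragments never count
    as presence.
    """

    labels: tuple[str, str]
    overall_core: int
    core_groups: list[str]
    specific: dict[str, list[str]] = field(default_factory=dict)
    partial: dict[str, list[str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "core": self.overall_core,
            "A": len(self.specific[self.labels[0]]),
            "B": len(self.partial[self.labels[0]]),
            "C": len(self.specific[self.labels[1]]),
            "D": len(self.partial[self.labels[1]]),
        }


def partition_core(groups: list[OrthologGroup], strain_meta: dict[str, str],
                   labels: tuple[str, str] | None = None) -> CorePartition:
    """Partition ortholog groups into overall core and the four
    subspecies-specific categories."""
    found = sorted(set(strain_meta.values()))
    if len(found) != 2:
        raise ValueError(f"exactly two subspecies labels required, got {found}")
    if labels is None:
        labels = (found[0], found[1])
    elif sorted(labels) != found:
        raise ValueError(f"labels {labels} do not match metadata {found}")
    strains = {lab: {s for s, m in strain_meta.items() if m == lab} for lab in labels}
    for g in groups:
        unknown = g.strains - set(strain_meta)
        if unknown:
            raise ValueError(f"group {g.group_id} contains strains without "
                             f"metadata: {sorted(unknown)}")
    part = CorePartition(labels=labels, overall_core=0, core_groups=[],
                         specific={lab: [] for lab in labels},
                         partial={lab: [] for lab in labels})
    all_strains = strains[labels[0]] | strains[labels[1]]
    for g in groups:
        present = g.strains
        if all_strains <= present:
            part.overall_core += 1
            part.core_groups.append(g.group_id)
        for home, away in (labels, labels[::-1]):
            if strains[home] <= present:
                n_missing = len(strains[away] - present)
                if n_missing == len(strains[away]):
                    part.specific[home].append(g.group_id)
                elif 1 <= n_missing:
                    part.partial[home].append(g.group_id)
    return part


def fragment_rescue(specific_groups: list[OrthologGroup],
                    pseudo_calls: list,
                    strain_meta: dict[str, str],
                    opposite_label: str) -> tuple[int, list[str]]:
    """Count clade-specific groups with a pseudogene trace opposite.

    A group is *rescued* when at least one strain of ``opposite_label``
    carries a detected pseudogene fragment whose best-hit protein belongs to
    the group.  ``pseudo_calls`` are :class:`~reducto.pseudogenes.PseudogeneCall`
    objects (only fragment verdicts are considered) carrying the strain id
    and the best-hit protein id.
    """
    member_to_group = {}
    for g in specific_groups:
        for _, pid in g.members:
            member_to_group[pid] = g.group_id
    rescued = set()
    for call in pseudo_calls:
        if call.verdict != "pseudogene_fragment":
            continue
        if strain_meta.get(call.strain_id) != opposite_label:
            continue
        gid = member_to_group.get(call.best_hit_protein_id)
        if gid is not None:
            rescued.add(gid)
    return len(rescued), sorted(rescued)
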