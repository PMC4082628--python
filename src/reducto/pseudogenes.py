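"""Pseudogene-fragment detection by translated back-alignment.

The procedure mirrors how fragment remnants of decayed genes are recognized
in bacterial genome annotation:

1. each annotated CDS is compared, conceptually translated in all six
   frames, against a protein database (here: the union of intact proteins
   from the other strains of the run);
2. when the best-hit protein is more than ``length_tol`` (default 10%)
   longer or shorter than the CDS-encoded protein, the database protein is
   back-aligned to the genomic context of the CDS (the CDS plus
   ``context_window`` bp of flank), frame by frame on both strands;
3. high-scoring per-frame segments are chained when collinear on the
   protein and close on the genome; a frame change between adjacent chained
   segments is a frameshift, and stop codons inside aligned segments are
   internal stops;
4. the CDS is marked ``pseudogene_fragment`` when the chained alignment
   extends beyond the CDS on the genome and shows at least one frameshift
   or internal stop.

Exact local dynamic programming over the bounded region of interest is used
instead of seeded heuristics; at the scale of one CDS neighbourhood this is
both affordable and deterministic.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices

from .orthology import KA_K, KA_LAMBDA, ProteinRecord
from .seqio import Feature, revcomp
from .simulate import _CODON_TABLE

CODING_FEATURE_TYPES = ("CDS", "pseudogene")


@dataclass(frozen=True)
class CdsFeature:
    genome_id: str
    cds_id: str
    start: int  # 0-based half-open
    end: int
    strand: str

    def __post_init__(self):
        if self.end - self.start < 3:
            raise ValueError(f"{self.cds_id}: CDS shorter than 3 nt")
        if self.strand not in "+-":
            raise ValueError(f"{self.cds_id}: bad strand")

    @classmethod
    def from_feature(cls, feat: Feature) -> "CdsFeature":
        return cls(feat.seqid, feat.feature_id, feat.start, feat.end, feat.strand)

    def nt_seq(self, genome: str) -> str:
        sub = genome[self.start:self.end]
        return revcomp(sub) if self.strand == "-" else sub


@dataclass
class PseudoParams:
    length_tol: float = 0.10
    context_window: int = 3000
    chain_max_gap: int = 60
    min_segment_bits: float = 30.0
    min_novel_aa: int = 20  # novel protein coverage a segment must add

    def __post_init__(self):
        if not 0.0 < self.length_tol < 1.0:
            raise ValueError("length_tol outside (0, 1)")
        if self.context_window < 0:
            raise ValueError("context_window must be >= 0")

    @property
    def min_segment_raw(self) -> float:
        return (self.min_segment_bits * math.log(2) + math.log(KA_K)) / KA_LAMBDA


@dataclass(frozen=True)
class Segment:
    g_start: int
    g_end: int
    strand: str
    frame: int  # 0..2, offset of the reading frame within the region
    score: float
    prot_start: int
    prot_end: int


@dataclass
class TranslatedHit:
    protein_id: str
    segments: list[Segment] = field(default_factory=list)
    frameshifts: list[int] = field(default_factory=list)   # genomic positions
    internal_stops: list[int] = field(default_factory=list)  # genomic positions of stop codons

    @property
    def extent(self) -> tuple[int, int] | None:
        if not self.segments:
            return None
        return (min(s.g_start for s in self.segments),
                max(s.g_end for s in self.segments))


@dataclass(frozen=True)
class PseudogeneCall:
    strain_id: str
    cds_id: str
    verdict: str  # intact | pseudogene_fragment
    evidence: frozenset
    best_hit_protein_id: str | None
    anomaly_ratio: float | None
    frameshift_positions: tuple[int, ...] = ()
    internal_stop_positions: tuple[int, ...] = ()

    def __post_init__(self):
        if self.verdict == "pseudogene_fragment":
            if "length_anomaly" not in self.evidence or not (
                    {"frameshift", "internal_stop"} & set(self.evidence)):
                raise ValueError("fragment verdict requires length_anomaly and "
                                 "frameshift or internal_stop evidence")


_PROTEIN_ALIGNER = None


def _aligner() -> PairwiseAligner:
    global _PROTEIN_ALIGNER
    if _PROTEIN_ALIGNER is None:
        a = PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -12.0
        a.extend_gap_score = -1.0
        _PROTEIN_ALIGNER = a
    return _PROTEIN_ALIGNER


def translate_frame(nt: str, frame: int) -> str:
    """Read-through translation (stops as ``*``) of one frame."""
    out = []
    for i in range(frame, len(nt) - 2, 3):
        out.append(_CODON_TABLE[nt[i:i + 3]] if "N" not in nt[i:i + 3] else "X")
    return "".join(out)


def six_frame_translations(nt: str) -> list[tuple[str, int, str]]:
    """(strand, frame, translation) for all six frames."""
    frames = []
    for strand, seq in (("+", nt), ("-", revcomp(nt))):
        for f in range(3):
            frames.append((strand, f, translate_frame(seq, f)))
    return frames


class ProteinKmerIndex:
    """Shared-k-mer prefilter over the protein database."""

    def __init__(self, db: list[ProteinRecord], k: int = 5):
        self.db = {p.protein_id: p for p in db}
        self.k = k
        self.index: dict[str, set[str]] = defaultdict(set)
        for p in db:
            for x in range(len(p.sequence) - k + 1):
                self.index[p.sequence[x:x + k]].add(p.protein_id)

    def candidates(self, query_aa: str, min_shared: int = 3) -> list[str]:
        shared: dict[str, int] = defaultdict(int)
        for kmer in set(query_aa[x:x + self.k]
                        for x in range(len(query_aa) - self.k + 1)):
            for pid in self.index.get(kmer, ()):
                shared[pid] += 1
        return [pid for pid, n in shared.items() if n >= min_shared]


def translated_search(cds_nt: str, protein_db: list[ProteinRecord],
                      index: ProteinKmerIndex | None = None
                      ) -> tuple[str, float] | None:
    """Best (protein_id, raw score) over six frames against the database.

    Ties break deterministically by lexicographic protein id.  Returns None
    when nothing aligns above zero.
    """
    if len(cds_nt) < 3:
        raise ValueError("CDS shorter than 3 nt")
    if not protein_db:
        raise ValueError("empty protein database")
    index = index or ProteinKmerIndex(protein_db)
    aligner = _aligner()
    scored: dict[str, float] = {}
    searched_any = False
    for _, _, aa in six_frame_translations(cds_nt):
        if len(aa) < index.k:
            continue
        for pid in index.candidates(aa):
            searched_any = True
            s = float(aligner.score(aa.replace("*", "X"), index.db[pid].sequence))
            if s > scored.get(pid, -1.0):
                scored[pid] = s
    if not searched_any:
        # tiny or kmer-free queries: fall back to the full database
        for _, _, aa in six_frame_translations(cds_nt):
            if not aa:
                continue
            for p in protein_db:
                s = float(aligner.score(aa.replace("*", "X"), p.sequence))
                if s > scored.get(p.protein_id, -1.0):
                    scored[p.protein_id] = s
    if not scored:
        return None
    best = sorted(scored.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    return best[0], best[1]


def length_anomaly(cds_protein_len: int, hit_protein_len: int,
                   length_tol: float = 0.10) -> bool:
    """True iff the db protein is more than ``length_tol`` longer or shorter
    than the CDS-encoded protein (strict inequality; denominator is the CDS)."""
    if cds_protein_len < 1 or hit_protein_len < 1:
        raise ValueError("protein lengths must be >= 1")
    return abs(hit_protein_len - cds_protein_len) / cds_protein_len > length_tol


def back_align(protein: ProteinRecord, genome: str,
               roi: tuple[int, int], params: PseudoParams | None = None
               ) -> TranslatedHit:
    """Back-align a database protein to a genomic region of interest.

    Per-frame local alignments over the region are chained when collinear on
    the protein and separated by at most ``chain_max_gap`` bp on the genome;
    frame changes between adjacent chained segments are frameshifts and
    aligned stop codons are internal stops.
    """
    params = params or PseudoParams()
    s, e = roi
    if not (0 <= s < e <= len(genome)):
        raise ValueError(f"roi {roi} outside genome of length {len(genome)}")
    region = genome[s:e]
    aligner = _aligner()
    raw_segments: list[tuple[Segment, list[int]]] = []
    for strand, frame, aa in six_frame_translations(region):
        if not aa:
            continue
        aln = aligner.align(aa, protein.sequence)
        if not len(aln):
            continue
        best = aln[0]
        if float(best.score) < params.min_segment_raw:
            continue
        blocks_t, blocks_p = best.aligned
        t0, t1 = int(blocks_t[0][0]), int(blocks_t[-1][1])
        p0, p1 = int(blocks_p[0][0]), int(blocks_p[-1][1])
        if strand == "+":
            g_start, g_end = s + frame + 3 * t0, s + frame + 3 * t1
        else:
            g_start, g_end = e - frame - 3 * t1, e - frame - 3 * t0
        seg = Segment(g_start, g_end, strand, frame, float(best.score), p0, p1)
        stops = []
        for (ts, te), _ in zip(blocks_t, blocks_p):
            for i in range(ts, te):
                if aa[i] == "*":
                    if strand == "+":
                        stops.append(s + frame + 3 * i)
                    else:
                        stops.append(e - frame - 3 * (i + 1))
        raw_segments.append((seg, stops))

    # drop nested hits: a lower-scoring segment survives only when it adds
    # enough novel protein coverage (local alignments bracketing a lesion
    # overrun it by a fuzzy margin, so plain overlap is not a reason to drop)
    raw_segments.sort(key=lambda sv: (-sv[0].score, sv[0].prot_start))
    kept: list[tuple[Segment, list[int]]] = []
    for seg, stops in raw_segments:
        overlap = 0
        for kseg, _ in kept:
            overlap = max(overlap,
                          min(seg.prot_end, kseg.prot_end)
                          - max(seg.prot_start, kseg.prot_start))
        if (seg.prot_end - seg.prot_start) - overlap >= params.min_novel_aa \
                or overlap <= 0:
            kept.append((seg, stops))

    kept.sort(key=lambda sv: sv[0].prot_start)
    hit = TranslatedHit(protein_id=protein.protein_id)
    chain: list[Segment] = []
    chain_stops: list[int] = []
    for seg, stops in kept:
        if not chain:
            chain.append(seg)
            chain_stops.extend(stops)
            continue
        last = chain[-1]
        if seg.strand != last.strand:
            continue
        p_overlap = max(0, last.prot_end - seg.prot_start)
        gap = (seg.g_start - last.g_end if seg.strand == "+"
               else last.g_start - seg.g_end)
        # genomic overlap of about 3 nt per overlapping residue is expected
        # when both local alignments overrun the lesion
        if -(3 * p_overlap + params.chain_max_gap) <= gap <= params.chain_max_gap:
            if (seg.strand, seg.frame) != (last.strand, last.frame):
                boundary = ((last.g_end + seg.g_start) // 2 if seg.strand == "+"
                            else (seg.g_end + last.g_start) // 2)
                hit.frameshifts.append(boundary)
            chain.append(seg)
            chain_stops.extend(stops)
    hit.segments = chain
    hit.internal_stops = sorted(chain_stops)
    return hit


def classify(cds: CdsFeature, best_hit_protein_len: int,
             best_hit_protein_id: str, back: TranslatedHit,
             params: PseudoParams | None = None) -> PseudogeneCall:
    """Combine the three lines of evidence into a verdict.

    ``pseudogene_fragment`` requires the length anomaly, a chained
    back-alignment whose genomic extent exceeds the CDS interval, and at
    least one frameshift or internal stop.  The terminal stop codon of the
    annotated CDS counts as internal only when the alignment extends past
    the CDS 3' end, i.e. when it sits inside — not at the edge of — the
    reconstructed ancestral gene.
    """
    params = params or PseudoParams()
    cds_prot_len = (cds.end - cds.start) // 3 - 1
    ratio = abs(best_hit_protein_len - cds_prot_len) / max(cds_prot_len, 1)
    anomaly = cds_prot_len >= 1 and length_anomaly(
        cds_prot_len, best_hit_protein_len, params.length_tol)

    terminal_stop_pos = cds.end - 3 if cds.strand == "+" else cds.start
    extent = back.extent
    extends_past_3prime = False
    if extent is not None:
        if cds.strand == "+":
            extends_past_3prime = extent[1] > cds.end
        else:
            extends_past_3prime = extent[0] < cds.start
    stops = [p for p in back.internal_stops
             if p != terminal_stop_pos or extends_past_3prime]

    exceeds = (extent is not None
               and (extent[1] - extent[0]) > (cds.end - cds.start))
    evidence = set()
    if anomaly:
        evidence.add("length_anomaly")
    if back.frameshifts:
        evidence.add("frameshift")
    if stops:
        evidence.add("internal_stop")
    verdict = ("pseudogene_fragment"
               if anomaly and exceeds and ({"frameshift", "internal_stop"} & evidence)
               else "intact")
    return PseudogeneCall(
        strain_id=cds.genome_id, cds_id=cds.cds_id, verdict=verdict,
        evidence=frozenset(evidence),
        best_hit_protein_id=best_hit_protein_id, anomaly_ratio=ratio,
        frameshift_positions=tuple(back.frameshifts),
        internal_stop_positions=tuple(stops),
    )


def scan_strain(genome: str, features: list[Feature],
                protein_db: list[ProteinRecord],
                params: PseudoParams | None = None) -> list[PseudogeneCall]:
    """Run the full detection procedure over every coding-type feature of a
    strain genome against ``protein_db`` (intact proteins of other strains)."""
    params = params or PseudoParams()
    if not protein_db:
        raise ValueError("empty protein database")
    index = ProteinKmerIndex(protein_db)
    calls = []
    for feat in features:
        if feat.ftype not in CODING_FEATURE_TYPES:
            continue
        cds = CdsFeature.from_feature(feat)
        best = translated_search(cds.nt_seq(genome), protein_db, index)
        if best is None:
            calls.append(PseudogeneCall(cds.genome_id, cds.cds_id, "intact",
                                        frozenset(), None, None))
            continue
        pid, _ = best
        hit_protein = index.db[pid]
        cds_prot_len = (cds.end - cds.start) // 3 - 1
        if cds_prot_len < 1 or not length_anomaly(
                max(cds_prot_len, 1), len(hit_protein.sequence), params.length_tol):
            calls.append(PseudogeneCall(
                cds.genome_id, cds.cds_id, "intact", frozenset(), pid,
                abs(len(hit_protein.sequence) - cds_prot_len) / max(cds_prot_len, 1)))
            continue
        roi = (max(0, cds.start - params.context_window),
               min(len(genome), cds.end + params.context_window))
        back = back_align(hit_protein, genome, roi, params)
        calls.append(classify(cds, len(hit_protein.sequence), pid, back, params))
    return calls
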