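"""Synthetic strain genomes evolved from a planted ancestral pangenome.

The generator emulates the evolutionary regime of a dairy-adapted
*Lactobacillus*-like species pair: a shared ancestral gene repertoire,
lineage-specific gene loss and pseudogenization at different intensities in
two subspecies-like clades, a small horizontally acquired gene set, IS-element
insertions confined to intergenic spacers, and sequence divergence that is
low within and higher between clades.  Every event is recorded in a
machine-readable truth table so each downstream analysis stage can be scored
against planted ground truth.

Design notes
------------
* Pseudogenizing lesions are single events: one +-1 frameshift, one in-frame
  stop-codon substitution, or one 3'-truncation per gene.
* Ancestral genes carry "hidden" stop codons in both shifted reading frames
  at least every ~15 codons (cf. the ambush hypothesis), so a frameshifted
  open reading frame terminates close to the lesion and the remnant CDS is
  unambiguously shorter than its ancestral protein.
* Point substitutions are uniform and unweighted but reading-frame preserving:
  they never create or destroy an in-frame stop, never touch the start codon,
  and never destroy a hidden off-frame stop.  This keeps the planted
  intact/pseudogene status authoritative.
* Coordinates are 0-based half-open internally; GFF3 emission converts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import Feature, extract_feature_seq, read_fasta, read_gff3, revcomp, write_fasta, write_gff3

STOP_CODONS = ("TAA", "TAG", "TGA")
BASES = "ACGT"

#: codon pairs appended when a shifted reading frame has gone too long
#: without a stop; each spells TGA across the codon junction in frame +1 or
#: +2.  A GC-poor and a GC-rich variant exist per frame so the insertion can
#: steer the gene's composition toward its target.
_CASSETTES_F1 = (("TTG", "AAT"), ("CTG", "ACG"))  # xTG|Ayz -> TGA in frame +1
_CASSETTES_F2 = (("AAT", "GAT"), ("GCT", "GAC"))  # xyT|GAz -> TGA in frame +2
#: maximum codons a shifted frame may run without a stop in ancestral genes
HIDDEN_STOP_CAP = 15

_CODON_TABLE = {}


def _build_codon_table():
    # bacterial table 11 via biopython, built once
    from Bio.Seq import Seq
    for a in BASES:
        for b in BASES:
            for c in BASES:
                codon = a + b + c
                _CODON_TABLE[codon] = str(Seq(codon).translate(table=11))


_build_codon_table()


def translate(nt: str) -> str:
    """Translate a coding sequence (table 11), stopping at the first stop."""
    aas = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        aa = _CODON_TABLE[nt[i:i + 3]]
        if aa == "*":
            break
        aas.append(aa)
    return "".join(aas)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    gene_id: str
    seq: str  # coding strand, ATG..stop, multiple of 3
    pathway_id: str | None = None


@dataclass(frozen=True)
class IsElement:
    family: str
    seq: str


@dataclass
class AncestralPangenome:
    genes: list[Gene]
    intergenic_spacer_len: int = 150
    gc_target: float = 0.5

    def __post_init__(self):
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            _check_gene(g.seq, g.gene_id)

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def _check_gene(seq: str, gene_id: str) -> None:
    if len(seq) % 3 != 0:
        raise ValueError(f"{gene_id}: length not a multiple of 3")
    if not seq.startswith("ATG"):
        raise ValueError(f"{gene_id}: does not start with ATG")
    if seq[-3:] not in STOP_CODONS:
        raise ValueError(f"{gene_id}: does not end with a stop codon")
    for i in range(0, len(seq) - 3, 3):
        if seq[i:i + 3] in STOP_CODONS:
            raise ValueError(f"{gene_id}: internal stop at codon {i // 3}")


LESION_TYPES = ("frameshift", "premature_stop", "truncation")
STATUSES = ("intact", "pseudogene", "absent", "hgt")


@dataclass
class EvolutionParams:
    """Per-strain evolution model parameters.

    ``forced_fates`` overrides the random draws with explicit planted fates,
    mapping gene_id to ``(status, lesion_type-or-None)``; genes not listed
    are drawn from the ``loss_prob``/``pseudo_prob`` model.
    """

    strain_id: str = "strain"
    substitution_rate: float = 0.0
    loss_prob: float = 0.0
    pseudo_prob: float = 0.0
    pseudo_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    hgt_genes: tuple[Gene, ...] = ()
    is_library: tuple[IsElement, ...] = ()
    n_is_insertions: int = 0
    seed: int = 0
    forced_fates: dict | None = None

    def __post_init__(self):
        for name in ("substitution_rate", "loss_prob", "pseudo_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.pseudo_mix) - 1.0) > 1e-9:
            raise ValueError("pseudo_mix must sum to 1")
        if self.loss_prob + self.pseudo_prob > 1.0 + 1e-12:
            raise ValueError("loss_prob + pseudo_prob must be <= 1")
        if self.n_is_insertions and not self.is_library:
            raise ValueError("n_is_insertions > 0 but is_library is empty")


@dataclass(frozen=True)
class TruthRow:
    strain_id: str
    gene_id: str
    status: str  # intact | pseudogene | absent | hgt
    lesion_type: str | None
    lesion_offset: int | None  # nt from gene start on coding strand
    start: int | None  # genomic interval of the retained material
    end: int | None
    strand: str | None

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"bad status {self.status}")
        if (self.status == "pseudogene") != (self.lesion_type is not None):
            raise ValueError("lesion fields set iff status == pseudogene")


@dataclass
class StrainGenome:
    strain_id: str
    seq: str
    features: list[Feature]
    truth: list[TruthRow]
    proteins: dict[str, str]  # protein_id -> aa sequence (intact CDS only)


# ---------------------------------------------------------------------------
# ancestor generation
# ---------------------------------------------------------------------------

def _codon_gc_after_rejection(gc: float) -> float:
    """Realized per-base GC of a codon sampled base-wise at ``gc`` and
    rejection-sampled against the three stop codons (closed form)."""
    a, q = (1 - gc) / 2, gc / 2
    p_stop = a ** 3 + 2 * a ** 2 * q          # TAA + (TAG, TGA)
    gc_in_stops = 2 * a ** 2 * q              # TAG and TGA carry one G each
    return (3 * gc - gc_in_stops) / (3 * (1 - p_stop))


def _sampling_gc(target: float) -> float:
    """Invert the stop-rejection bias: base-sampling GC whose accepted-codon
    composition equals ``target`` (bisection; monotone in (0, 1))."""
    if target <= 0.0 or target >= 1.0:
        return target
    lo, hi = 1e-6, 1 - 1e-6
    for _ in range(60):
        mid = (lo + hi) / 2
        if _codon_gc_after_rejection(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _random_codon(rng: np.random.Generator, sampling_gc: float) -> str:
    p = np.array([(1 - sampling_gc) / 2, sampling_gc / 2,
                  sampling_gc / 2, (1 - sampling_gc) / 2])
    while True:
        codon = "".join(BASES[i] for i in rng.choice(4, size=3, p=p))
        if codon not in STOP_CODONS:
            return codon


def _gc_frac(s: str) -> float:
    return (s.count("G") + s.count("C")) / len(s) if s else 0.0


def _random_gene_seq(rng: np.random.Generator, n_nt: int, gc: float) -> str:
    """ATG + body + stop, with hidden off-frame stops every <= ~15 codons.

    Body codons are sampled at a rejection-corrected GC; hidden-stop
    cassettes pick their GC-poor or GC-rich variant according to the running
    composition, so the emitted gene tracks ``gc`` closely.
    """
    n_body = n_nt // 3 - 2
    samp_gc = _sampling_gc(gc)
    codons = ["ATG"]
    run1 = run2 = 0  # codons since last stop seen in frame +1 / +2
    while len(codons) - 1 < n_body:
        room = n_body - (len(codons) - 1)
        if (run1 >= HIDDEN_STOP_CAP or run2 >= HIDDEN_STOP_CAP) and room >= 2:
            variants = _CASSETTES_F1 if run1 >= HIDDEN_STOP_CAP else _CASSETTES_F2
            pair = variants[1] if _gc_frac("".join(codons)) < gc else variants[0]
        else:
            pair = (_random_codon(rng, samp_gc),)
        for codon in pair:
            prev = codons[-1]
            codons.append(codon)
            run1 = 0 if (prev[1] + prev[2] + codon[0]) in STOP_CODONS else run1 + 1
            run2 = 0 if (prev[2] + codon[0] + codon[1]) in STOP_CODONS else run2 + 1
    codons.append(STOP_CODONS[rng.integers(3)])
    return "".join(codons)


def generate_ancestor(
    n_genes: int,
    length_range: tuple[int, int] = (312, 960),
    gc_target: float = 0.5,
    pathway_assignments: dict[str, str] | None = None,
    seed: int = 0,
    intergenic_spacer_len: int = 150,
) -> AncestralPangenome:
    """Draw an ancestral pangenome of ``n_genes`` random protein-coding genes.

    Gene lengths are uniform over multiples of 3 in ``length_range``
    (inclusive, nucleotides including start and stop codons).
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    lo, hi = length_range
    if lo % 3 or hi % 3:
        raise ValueError(f"length_range {length_range} must be multiples of 3")
    if lo < 33 or hi < lo:
        raise ValueError("length_range must satisfy 33 <= lo <= hi")
    if not 0.0 <= gc_target <= 1.0:
        raise ValueError("gc_target outside [0, 1]")
    rng = np.random.default_rng(seed)
    pathway_assignments = pathway_assignments or {}
    width = max(4, len(str(n_genes)))
    genes = []
    for i in range(n_genes):
        gid = f"gene{i + 1:0{width}d}"
        n_nt = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
        genes.append(Gene(gid, _random_gene_seq(rng, n_nt, gc_target),
                          pathway_assignments.get(gid)))
    return AncestralPangenome(genes, intergenic_spacer_len=intergenic_spacer_len,
                              gc_target=gc_target)


# ---------------------------------------------------------------------------
# substitution model
# ---------------------------------------------------------------------------

def _substitution_safe(seq: str, pos: int, new: str) -> bool:
    """Frame-preserving check: no in-frame stop gained, no start/terminal-stop
    change, no hidden off-frame stop lost."""
    n = len(seq)
    if pos < 3 or pos >= n - 3:
        return False
    cstart = pos - pos % 3
    codon = seq[cstart:cstart + 3]
    mutated = codon[:pos - cstart] + new + codon[pos - cstart + 1:]
    if mutated in STOP_CODONS:
        return False
    for s in (pos - 2, pos - 1, pos):
        if s < 0 or s + 3 > n or s % 3 == 0:
            continue
        old_tri = seq[s:s + 3]
        if old_tri in STOP_CODONS:
            new_tri = "".join(new if s + k == pos else seq[s + k] for k in range(3))
            if new_tri not in STOP_CODONS:
                return False
    return True


def mutate_gene(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for pos in hits:
        old = chars[pos]
        new = BASES[(BASES.index(old) + int(rng.integers(1, 4))) % 4]
        if _substitution_safe("".join(chars), int(pos), new):
            chars[pos] = new
    return "".join(chars)


def mutate_genes(genes: Sequence[Gene], rate: float, seed: int) -> list[Gene]:
    rng = np.random.default_rng(seed)
    return [replace(g, seq=mutate_gene(g.seq, rate, rng)) for g in genes]


# ---------------------------------------------------------------------------
# per-strain evolution
# ---------------------------------------------------------------------------

def _apply_lesion(seq: str, lesion: str, rng: np.random.Generator):
    """Apply one lesion; return (genomic_seq, fragment_len_nt, offset_nt)."""
    n_coding = len(seq) // 3 - 1  # codons excluding the stop
    lo = max(2, math.ceil(0.3 * n_coding))
    hi = min(n_coding - 2, math.floor(0.7 * n_coding))
    c = int(rng.integers(lo, hi + 1))
    offset = 3 * c
    if lesion == "frameshift":
        if rng.integers(2):
            mutated = seq[:offset] + seq[offset + 1:]  # 1-nt deletion
        else:
            mutated = seq[:offset] + BASES[rng.integers(4)] + seq[offset:]
        frag_end = None
        for j in range(len(mutated) // 3):
            if mutated[3 * j:3 * j + 3] in STOP_CODONS:
                frag_end = 3 * (j + 1)
                break
        if frag_end is None:  # cannot happen for hidden-stop ancestors
            raise RuntimeError("frameshifted ORF did not terminate in gene")
        return mutated, frag_end, offset
    if lesion == "premature_stop":
        stop = STOP_CODONS[rng.integers(3)]
        mutated = seq[:offset] + stop + seq[offset + 3:]
        return mutated, offset + 3, offset
    if lesion == "truncation":
        stop = STOP_CODONS[rng.integers(3)]
        mutated = seq[:offset] + stop
        return mutated, len(mutated), offset
    raise ValueError(f"unknown lesion type {lesion!r}")


def evolve_strain(ancestor: AncestralPangenome, params: EvolutionParams) -> StrainGenome:
    """Evolve one strain genome from the ancestral pangenome.

    Returns the assembled genome with CDS / pseudogene / IS features and one
    truth row per ancestral or horizontally acquired gene.
    """
    rng = np.random.default_rng(params.seed)
    forced = params.forced_fates or {}

    entries = []  # (gene, status, lesion_type)
    for gene in ancestor.genes:
        if gene.gene_id in forced:
            status, lesion = forced[gene.gene_id]
        else:
            u = rng.random()
            if u < params.loss_prob:
                status, lesion = "absent", None
            elif u < params.loss_prob + params.pseudo_prob:
                status = "pseudogene"
                lesion = LESION_TYPES[int(rng.choice(3, p=np.asarray(params.pseudo_mix)))]
            else:
                status, lesion = "intact", None
        entries.append((gene, status, lesion))
    for gene in params.hgt_genes:
        entries.append((gene, "hgt", None))

    retained = [(g, s, l) for g, s, l in entries if s != "absent"]
    n_spacers = len(retained) + 1
    if params.n_is_insertions > n_spacers:
        raise ValueError(
            f"{params.n_is_insertions} IS insertions requested but only "
            f"{n_spacers} intergenic spacers available")
    is_slots = {}
    if params.n_is_insertions:
        slots = rng.choice(n_spacers, size=params.n_is_insertions, replace=False)
        for slot in sorted(int(s) for s in slots):
            elem = params.is_library[rng.integers(len(params.is_library))]
            cut = int(rng.integers(5, ancestor.intergenic_spacer_len - 5))
            is_slots[slot] = (elem, cut)

    gc = ancestor.gc_target
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    parts: list[str] = []
    cursor = 0
    features: list[Feature] = []
    truth: list[TruthRow] = []
    proteins: dict[str, str] = {}
    sid = params.strain_id

    def emit_spacer(slot: int):
        nonlocal cursor
        spacer = "".join(BASES[i] for i in rng.choice(4, size=ancestor.intergenic_spacer_len, p=p))
        if slot in is_slots:
            elem, cut = is_slots[slot]
            parts.append(spacer[:cut])
            cursor += cut
            features.append(Feature(sid, "mobile_genetic_element", cursor,
                                    cursor + len(elem.seq), "+",
                                    {"ID": f"{sid}_IS{slot:03d}", "family": elem.family}))
            parts.append(elem.seq)
            cursor += len(elem.seq)
            parts.append(spacer[cut:])
            cursor += len(spacer) - cut
        else:
            parts.append(spacer)
            cursor += len(spacer)

    for slot, (gene, status, lesion) in enumerate(retained):
        emit_spacer(slot)
        seq = gene.seq
        if status != "hgt":  # acquired genes carry no accumulated divergence
            seq = mutate_gene(seq, params.substitution_rate, rng)
        strand = "+" if rng.integers(2) else "-"
        if status == "pseudogene":
            genomic_seq, frag_len, offset = _apply_lesion(seq, lesion, rng)
        else:
            genomic_seq, frag_len, offset = seq, None, None
        start, end = cursor, cursor + len(genomic_seq)
        parts.append(genomic_seq if strand == "+" else revcomp(genomic_seq))
        cursor = end

        if status == "pseudogene":
            if strand == "+":
                fs, fe = start, start + frag_len
            else:
                fs, fe = end - frag_len, end
            features.append(Feature(sid, "pseudogene", fs, fe, strand,
                                    {"ID": f"{sid}_{gene.gene_id}", "gene": gene.gene_id}))
            truth.append(TruthRow(sid, gene.gene_id, "pseudogene", lesion,
                                  offset, start, end, strand))
        else:
            pid = f"{sid}|{gene.gene_id}"
            features.append(Feature(sid, "CDS", start, end, strand,
                                    {"ID": f"{sid}_{gene.gene_id}", "gene": gene.gene_id,
                                     "protein_id": pid}))
            proteins[pid] = translate(genomic_seq)
            truth.append(TruthRow(sid, gene.gene_id, status, None, None,
                                  start, end, strand))
    emit_spacer(len(retained))

    for gene, status, lesion in entries:
        if status == "absent":
            truth.append(TruthRow(sid, gene.gene_id, "absent", None, None,
                                  None, None, None))

    order = {g.gene_id: i for i, (g, _, _) in enumerate(entries)}
    truth.sort(key=lambda r: order[r.gene_id])
    return StrainGenome(sid, "".join(parts), features, truth, proteins)


# ---------------------------------------------------------------------------
# two-clade study design
# ---------------------------------------------------------------------------

MLST_LOCI = ("fusA", "gyrB", "hsp60", "ileS", "pyrG", "recA", "recG")


@dataclass
class CladePlan:
    """Study design for a two-clade synthetic dataset.

    Defaults emulate the contrast between a milder and a more advanced
    reductive-evolution lineage: clade-specific gene complements, partially
    lost genes, per-strain pseudogenization, an HGT island restricted to one
    clade, and an IS load that differs between clades.
    """

    clade_names: tuple[str, str] = ("lactis_like", "bulgaricus_like")
    n_per_clade: tuple[int, int] = (5, 5)
    n_core: int = 120
    n_specific: tuple[int, int] = (12, 8)   # present in all of one clade, absent from the other
    n_partial: tuple[int, int] = (10, 10)   # present in all of one clade, absent from 1..n-1 of the other
    n_rescued: tuple[int, int] = (5, 3)     # clade-specific genes pseudogenized (not lost) opposite
    pseudo_per_strain: int = 4
    lesion_cycle: tuple[str, ...] = ("frameshift", "premature_stop", "truncation")
    rescue_lesions: tuple[str, ...] = ("frameshift", "premature_stop")
    clade_divergence: float = 0.02
    strain_divergence: float = 0.01
    n_hgt: int = 4
    hgt_clade: int = 0
    hgt_strains: int = 3
    hgt_gc: float = 0.34
    is_per_strain: tuple[int, int] = (12, 4)
    gene_length_range: tuple[int, int] = (312, 960)
    gc_target: float = 0.5
    spacer_len: int = 150


@dataclass
class SyntheticDataset:
    strains: list[StrainGenome]
    meta: dict[str, str]             # strain_id -> clade label
    truth: list[TruthRow]
    ancestor: AncestralPangenome
    scheme: dict[str, str]           # MLST locus -> gene_id
    plan: CladePlan
    seed: int


def simulate_clades(plan: CladePlan | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate the full two-clade dataset with planted ground truth."""
    plan = plan or CladePlan()
    rng = np.random.default_rng(seed)
    n1, n2 = plan.n_per_clade
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 strains per clade")

    n_total = plan.n_core + sum(plan.n_specific) + sum(plan.n_partial)
    base = generate_ancestor(
        n_total, plan.gene_length_range, plan.gc_target,
        seed=int(rng.integers(2 ** 31)), intergenic_spacer_len=plan.spacer_len)

    # role-based gene ids; the first 7 core genes double as the MLST loci
    ids = list(MLST_LOCI)
    ids += [f"core{i + 1:04d}" for i in range(plan.n_core - len(MLST_LOCI))]
    for k, tag in ((0, "A"), (1, "B")):
        ids += [f"spec{tag}{i + 1:03d}" for i in range(plan.n_specific[k])]
    for k, tag in ((0, "A"), (1, "B")):
        ids += [f"part{tag}{i + 1:03d}" for i in range(plan.n_partial[k])]
    genes = [replace(g, gene_id=gid) for g, gid in zip(base.genes, ids)]
    ancestor = AncestralPangenome(genes, plan.spacer_len, plan.gc_target)

    clade_genes = [
        mutate_genes(genes, plan.clade_divergence, int(rng.integers(2 ** 31)))
        for _ in range(2)
    ]

    hgt_genes = []
    if plan.n_hgt:
        hgt_anc = generate_ancestor(plan.n_hgt, plan.gene_length_range,
                                    plan.hgt_gc, seed=int(rng.integers(2 ** 31)))
        hgt_genes = [replace(g, gene_id=f"hgt{i + 1:03d}")
                     for i, g in enumerate(hgt_anc.genes)]

    is_library = tuple(
        IsElement(f"ISRed{i + 1}",
                  "".join(BASES[j] for j in rng.choice(
                      4, size=800, p=[0.275, 0.225, 0.225, 0.275])))
        for i in range(3))

    strain_ids = [[f"{plan.clade_names[k]}{i + 1}" for i in range(plan.n_per_clade[k])]
                  for k in range(2)]
    meta = {s: plan.clade_names[k] for k in range(2) for s in strain_ids[k]}

    # planted fates, per strain
    fates: dict[str, dict] = {s: {} for s in meta}
    cycler = {s: 0 for s in meta}

    def plant_pseudo(strain: str, gid: str, lesions: tuple[str, ...]):
        fates[strain][gid] = ("pseudogene", lesions[cycler[strain] % len(lesions)])
        cycler[strain] += 1

    # clade-specific genes: intact at home, absent (or pseudogenized) opposite
    for k, tag in ((0, "A"), (1, "B")):
        other = 1 - k
        spec_ids = [f"spec{tag}{i + 1:03d}" for i in range(plan.n_specific[k])]
        rescued = spec_ids[:plan.n_rescued[k]]
        for gid in spec_ids:
            for s in strain_ids[k]:
                fates[s][gid] = ("intact", None)
            if gid in rescued:
                carriers = rng.choice(strain_ids[other],
                                      size=int(rng.integers(1, 3)), replace=False)
                for s in strain_ids[other]:
                    if s in carriers:
                        plant_pseudo(s, gid, plan.rescue_lesions)
                    else:
                        fates[s][gid] = ("absent", None)
            else:
                for s in strain_ids[other]:
                    fates[s][gid] = ("absent", None)

    # partially lost genes: absent from 1..n-1 strains of the other clade
    for k, tag in ((0, "A"), (1, "B")):
        other = 1 - k
        n_other = plan.n_per_clade[other]
        for i in range(plan.n_partial[k]):
            gid = f"part{tag}{i + 1:03d}"
            k_missing = int(rng.integers(1, n_other))
            missing = set(rng.choice(strain_ids[other], size=k_missing, replace=False))
            for s in strain_ids[k]:
                fates[s][gid] = ("intact", None)
            for s in strain_ids[other]:
                fates[s][gid] = ("absent", None) if s in missing else ("intact", None)

    # per-strain pseudogenization of core genes (disjoint; MLST loci spared)
    pool = [g.gene_id for g in genes[len(MLST_LOCI):plan.n_core]]
    rng.shuffle(pool)
    need = plan.pseudo_per_strain * (n1 + n2)
    if need > len(pool):
        raise ValueError("not enough core genes for the requested per-strain "
                         "pseudogenization plan")
    it = iter(pool)
    for s in [*strain_ids[0], *strain_ids[1]]:
        for _ in range(plan.pseudo_per_strain):
            plant_pseudo(s, next(it), plan.lesion_cycle)
    for s in meta:
        for g in genes:
            fates[s].setdefault(g.gene_id, ("intact", None))

    hgt_carriers = set(strain_ids[plan.hgt_clade][:plan.hgt_strains]) if hgt_genes else set()

    strains = []
    for k in range(2):
        source = clade_genes[k]
        for s in strain_ids[k]:
            params = EvolutionParams(
                strain_id=s,
                substitution_rate=plan.strain_divergence,
                forced_fates=fates[s],
                hgt_genes=tuple(hgt_genes) if s in hgt_carriers else (),
                is_library=is_library,
                n_is_insertions=plan.is_per_strain[k],
                seed=int(rng.integers(2 ** 31)),
            )
            strains.append(evolve_strain(
                AncestralPangenome(source, plan.spacer_len, plan.gc_target), params))

    truth = [row for strain in strains for row in strain.truth]
    # strains lacking the HGT island still owe a truth row per HGT gene
    for strain in strains:
        if strain.strain_id not in hgt_carriers:
            for g in hgt_genes:
                truth.append(TruthRow(strain.strain_id, g.gene_id, "absent",
                                      None, None, None, None, None))
    scheme = {locus: locus for locus in MLST_LOCI}
    return SyntheticDataset(strains, meta, truth, ancestor, scheme, plan, seed)


# ---------------------------------------------------------------------------
# truth-side accounting (independent of the sequence-based pipeline)
# ---------------------------------------------------------------------------

def truth_partition_counts(truth: list[TruthRow], meta: dict[str, str],
                           labels: tuple[str, str]) -> dict[str, int]:
    """Figure-2-style category counts derived purely from planted statuses.

    A gene is *present* in a strain iff its planted status is intact or hgt;
    pseudogene fragments do not count as presence.
    """
    by_gene: dict[str, dict[str, bool]] = {}
    for row in truth:
        by_gene.setdefault(row.gene_id, {})[row.strain_id] = row.status in ("intact", "hgt")
    g1 = [s for s, lab in meta.items() if lab == labels[0]]
    g2 = [s for s, lab in meta.items() if lab == labels[1]]
    counts = {"core": 0, "A": 0, "B": 0, "C": 0, "D": 0}
    for gene, pres in by_gene.items():
        in1 = sum(pres.get(s, False) for s in g1)
        in2 = sum(pres.get(s, False) for s in g2)
        if in1 == len(g1) and in2 == len(g2):
            counts["core"] += 1
        if in1 == len(g1) and in2 == 0:
            counts["A"] += 1
        if in1 == len(g1) and 1 <= len(g2) - in2 <= len(g2) - 1:
            counts["B"] += 1
        if in2 == len(g2) and in1 == 0:
            counts["C"] += 1
        if in2 == len(g2) and 1 <= len(g1) - in1 <= len(g1) - 1:
            counts["D"] += 1
    return counts


def truth_rescue_counts(truth: list[TruthRow], meta: dict[str, str],
                        labels: tuple[str, str]) -> dict[str, int]:
    """Planted fragment-rescue counts: clade-specific genes of one clade with
    a pseudogene remnant in at least one strain of the other clade."""
    by_gene: dict[str, dict[str, str]] = {}
    for row in truth:
        by_gene.setdefault(row.gene_id, {})[row.strain_id] = row.status
    out = {}
    for home, away in (labels, labels[::-1]):
        home_s = [s for s, lab in meta.items() if lab == home]
        away_s = [s for s, lab in meta.items() if lab == away]
        n = 0
        for gene, stat in by_gene.items():
            if (all(stat.get(s) in ("intact", "hgt") for s in home_s)
                    and not any(stat.get(s) in ("intact", "hgt") for s in away_s)
                    and any(stat.get(s) == "pseudogene" for s in away_s)):
                n += 1
        out[home] = n
    return out


# ---------------------------------------------------------------------------
# dataset emission / parsing
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ("strain_id", "gene_id", "status", "lesion_type",
                 "lesion_offset", "start", "end", "strand")


def emit_dataset(dataset: SyntheticDataset | list[StrainGenome], out_dir: Path,
                 meta: dict[str, str] | None = None) -> Path:
    """Write one genome FASTA, GFF3 and protein FASTA per strain plus the
    truth and metadata tables.  Round-trips through :func:`load_dataset`."""
    if isinstance(dataset, SyntheticDataset):
        strains, meta, truth = dataset.strains, dataset.meta, dataset.truth
        scheme = dataset.scheme
    else:
        strains, truth, scheme = dataset, [r for s in dataset for r in s.truth], {}
        meta = meta or {}
    if not strains:
        raise ValueError("no strains to emit")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in strains:
        write_fasta(out / f"{s.strain_id}.fna", [(s.strain_id, s.seq)])
        write_gff3(out / f"{s.strain_id}.gff3", s.features)
        write_fasta(out / f"{s.strain_id}.faa", sorted(s.proteins.items()))
    with open(out / "truth.tsv", "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r in truth:
            fh.write("\t".join("" if getattr(r, c) is None else str(getattr(r, c))
                               for c in TRUTH_COLUMNS) + "\n")
    with open(out / "meta.tsv", "w") as fh:
        fh.write("strain_id\tsubspecies\n")
        for sid, lab in sorted(meta.items()):
            fh.write(f"{sid}\t{lab}\n")
    if scheme:
        with open(out / "mlst_scheme.tsv", "w") as fh:
            fh.write("locus\tgene_id\n")
            for locus, gid in scheme.items():
                fh.write(f"{locus}\t{gid}\n")
    return out


def load_dataset(out_dir: Path):
    """Parse an emitted dataset back into strain objects, truth and metadata.

    Returns ``(strains, meta, truth, scheme)``.
    """
    out = Path(out_dir)
    meta = {}
    for line in (out / "meta.tsv").read_text().splitlines()[1:]:
        sid, lab = line.split("\t")
        meta[sid] = lab
    truth = []
    for line in (out / "truth.tsv").read_text().splitlines()[1:]:
        vals = line.split("\t")
        row = dict(zip(TRUTH_COLUMNS, [v if v != "" else None for v in vals]))
        for c in ("lesion_offset", "start", "end"):
            if row[c] is not None:
                row[c] = int(row[c])
        truth.append(TruthRow(**row))
    strains = []
    for sid in sorted(meta):
        genome = read_fasta(out / f"{sid}.fna")[sid]
        features = read_gff3(out / f"{sid}.gff3")
        proteins = read_fasta(out / f"{sid}.faa")
        strain_truth = [r for r in truth if r.strain_id == sid]
        strains.append(StrainGenome(sid, genome, features, strain_truth, proteins))
    scheme = {}
    scheme_path = out / "mlst_scheme.tsv"
    if scheme_path.exists():
        for line in scheme_path.read_text().splitlines()[1:]:
            locus, gid = line.split("\t")
            scheme[locus] = gid
    return strains, meta, truth, scheme
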