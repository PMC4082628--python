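"""Genome composition statistics and the IS-element landscape.

Covers the usual per-genome report of a bacterial comparative study:
overall GC, coding GC at third codon positions (GC3, the classic indicator
of directional mutational pressure in rapidly evolving genomes), coding
density as the union of CDS intervals, gap-aware genome-size estimation for
draft assemblies, and the distribution of IS elements along the genome
including the largest IS-free region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .seqio import Feature, extract_feature_seq

VALID_NT = set("ACGTN")


@dataclass
class GenomeAssembly:
    genome_id: str
    contigs: list[str]
    gap_estimates: list[int] | None = None
    circular: bool = False

    def __post_init__(self):
        if self.gap_estimates is not None:
            expected = max(0, len(self.contigs) - 1)
            if len(self.gap_estimates) != expected:
                raise ValueError(
                    f"{len(self.gap_estimates)} gap estimates for "
                    f"{len(self.contigs)} contigs (expected {expected})")

    @property
    def assembled_size(self) -> int:
        return sum(len(c) for c in self.contigs)


@dataclass
class IsAnnotation:
    elements: list[tuple[str, int, int, str]]  # (family, start, end, strand)

    @classmethod
    def from_features(cls, features: list[Feature]) -> "IsAnnotation":
        return cls([(f.attributes.get("family", "unknown"), f.start, f.end, f.strand)
                    for f in features if f.ftype == "mobile_genetic_element"])


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); N is excluded from the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - VALID_NT
    if bad:
        raise ValueError(f"ambiguity codes other than N are not supported: {sorted(bad)}")
    gc = seq.count("G") + seq.count("C")
    acgt = len(seq) - seq.count("N")
    if acgt == 0:
        raise ValueError("sequence contains only N")
    return gc / acgt


def gc3(genome: str, cds_features: list[Feature]) -> float:
    """G+C fraction at third codon positions over all complete codons of all
    CDS, strand-corrected; features whose length is not a multiple of 3 are
    skipped with a warning, pseudogene features are ignored."""
    thirds = []
    n_valid = 0
    for feat in cds_features:
        if feat.ftype != "CDS":
            continue
        seq = extract_feature_seq(genome, feat)
        if len(seq) % 3:
            warnings.warn(f"{feat.feature_id}: length not a multiple of 3, skipped")
            continue
        n_valid += 1
        thirds.append(seq[2::3])
    if not n_valid:
        raise ValueError("no valid CDS")
    return gc_content("".join(thirds))


def coding_density(genome_len: int, cds_features: list[Feature]) -> float:
    """Percent of the genome covered by the union of (non-pseudogene) CDS."""
    ivals = sorted((f.start, f.end) for f in cds_features if f.ftype == "CDS")
    for s, e in ivals:
        if not (0 <= s < e <= genome_len):
            raise ValueError(f"interval [{s}, {e}) outside genome")
    covered = 0
    cur_s = cur_e = None
    for s, e in ivals:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return 100.0 * covered / genome_len


def estimate_genome_size(assembly: GenomeAssembly) -> tuple[int, bool]:
    """Assembled size plus estimated inter-contig gap sizes.

    Returns ``(size, gaps_included)``; when no gap estimates are available
    the assembled size is returned with the flag set to False.
    """
    if assembly.gap_estimates is None:
        return assembly.assembled_size, False
    if any(g < 0 for g in assembly.gap_estimates):
        raise ValueError("negative gap estimate")
    return assembly.assembled_size + sum(assembly.gap_estimates), True


def _max_free_interval(bounds: list[tuple[int, int]], genome_len: int,
                       circular: bool) -> tuple[int, int]:
    """Largest element-free interval between consecutive element boundaries."""
    if not bounds:
        return (0, genome_len)
    bounds = sorted(bounds)
    best = (0, 0)
    for i in range(len(bounds) - 1):
        gap = (bounds[i][1], bounds[i + 1][0])
        if gap[1] - gap[0] > best[1] - best[0]:
            best = gap
    if circular:
        wrap_len = (genome_len - bounds[-1][1]) + bounds[0][0]
        if wrap_len > best[1] - best[0]:
            best = (bounds[-1][1], bounds[0][0] + genome_len)
    else:
        head = (0, bounds[0][0])
        tail = (bounds[-1][1], genome_len)
        for gap in (head, tail):
            if gap[1] - gap[0] > best[1] - best[0]:
                best = gap
    return best


def is_landscape(genome_len: int, is_ann: IsAnnotation, window: int = 10000,
                 circular: bool = False, midpoint_mode: bool = False):
    """Per-family counts, a sliding density track and the largest IS-free
    interval.

    The free interval is measured between element boundaries (end of one
    element to start of the next) by default; ``midpoint_mode`` measures
    between element midpoints instead.  On circular genomes the interval may
    wrap the origin, in which case its end coordinate exceeds ``genome_len``.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    counts: dict[str, int] = {}
    for fam, s, e, _ in is_ann.elements:
        if not (0 <= s < e <= genome_len):
            raise ValueError(f"IS interval [{s}, {e}) outside genome")
        counts[fam] = counts.get(fam, 0) + 1
    mids = sorted((s + e) // 2 for _, s, e, _ in is_ann.elements)
    step = max(1, window // 2)
    starts = np.arange(0, max(genome_len - window, 0) + 1, step)
    track = np.zeros(len(starts), dtype=int)
    marr = np.asarray(mids)
    for i, w0 in enumerate(starts):
        track[i] = int(np.sum((marr >= w0) & (marr < w0 + window))) if len(marr) else 0
    if midpoint_mode:
        bounds = [(m, m) for m in mids]
    else:
        bounds = [(s, e) for _, s, e, _ in is_ann.elements]
    free = _max_free_interval(bounds, genome_len, circular)
    return {
        "family_counts": counts,
        "total": len(is_ann.elements),
        "density_track": list(zip(starts.tolist(), track.tolist())),
        "largest_free_interval": free,
        "largest_free_length": free[1] - free[0],
    }


def round_half_up(x: float, digits: int = 1) -> float:
    """Presentation rounding for the report tables (half-up, not banker's)."""
    import decimal
    q = decimal.Decimal(10) ** -digits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class StatsReport:
    genome_id: str
    overall_gc_pct: float
    cds_gc_pct: float
    gc3_pct: float
    coding_density_pct: float
    assembled_size: int
    estimated_size: int
    size_includes_gaps: bool
    n_cds: int
    n_pseudogene_fragments: int
    is_counts: dict = field(default_factory=dict)
    largest_is_free_interval: tuple[int, int] = (0, 0)

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["largest_is_free_interval"] = list(self.largest_is_free_interval)
        return d


def strain_stats(genome_id: str, genome: str, features: list[Feature],
                 assembly: GenomeAssembly | None = None,
                 circular: bool = False, window: int = 10000) -> StatsReport:
    """Assemble the full composition report for one strain."""
    cds = [f for f in features if f.ftype == "CDS"]
    pseudo = [f for f in features if f.ftype == "pseudogene"]
    assembly = assembly or GenomeAssembly(genome_id, [genome], circular=circular)
    est, has_gaps = estimate_genome_size(assembly)
    cds_seq = "".join(extract_feature_seq(genome, f) for f in cds)
    landscape = is_landscape(len(genome), IsAnnotation.from_features(features),
                             window=window, circular=circular)
    return StatsReport(
        genome_id=genome_id,
        overall_gc_pct=round_half_up(100 * gc_content(genome)),
        cds_gc_pct=round_half_up(100 * gc_content(cds_seq)) if cds_seq else 0.0,
        gc3_pct=round_half_up(100 * gc3(genome, features)) if cds else 0.0,
        coding_density_pct=round_half_up(coding_density(len(genome), features)),
        assembled_size=assembly.assembled_size,
        estimated_size=est,
        size_includes_gaps=has_gaps,
        n_cds=len(cds),
        n_pseudogene_fragments=len(pseudo),
        is_counts=landscape["family_counts"],
        largest_is_free_interval=landscape["largest_free_interval"],
    )
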