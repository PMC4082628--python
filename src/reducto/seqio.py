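"""FASTA / GFF3 / TSV input-output for the pipeline's own file formats.

FASTA goes through :mod:`Bio.SeqIO`.  GFF3 emission and parsing are a thin
tab-separated reader/writer restricted to the feature set this package
produces (``CDS``, ``pseudogene``, ``mobile_genetic_element``): coordinates
are converted between the internal 0-based half-open convention and GFF3's
1-based inclusive one at this boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF_VERSION_LINE = "##gff-version 3"


@dataclass(frozen=True)
class Feature:
    """One genomic feature on a strain genome.

    ``start``/``end`` are 0-based half-open; ``strand`` is ``+`` or ``-``.
    ``attributes`` maps GFF3 column-9 keys to values (``ID`` is mandatory).
    """

    seqid: str
    ftype: str
    start: int
    end: int
    strand: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if "ID" not in self.attributes:
            raise ValueError("feature requires an ID attribute")

    @property
    def feature_id(self) -> str:
        return self.attributes["ID"]

    def __eq__(self, other):
        if not isinstance(other, Feature):
            return NotImplemented
        return (
            self.seqid == other.seqid
            and self.ftype == other.ftype
            and self.start == other.start
            and self.end == other.end
            and self.strand == other.strand
            and self.attributes == other.attributes
        )

    def __hash__(self):
        return hash((self.seqid, self.ftype, self.start, self.end, self.strand,
                     tuple(sorted(self.attributes.items()))))


def write_fasta(path: Path, records: Iterable[tuple[str, str]]) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _escape(value: str) -> str:
    return (value.replace("%", "%25").replace(";", "%3B")
            .replace("=", "%3D").replace(",", "%2C"))


def _unescape(value: str) -> str:
    return (value.replace("%2C", ",").replace("%3D", "=")
            .replace("%3B", ";").replace("%25", "%"))


def write_gff3(path: Path, features: Iterable[Feature],
               header_pragmas: Iterable[str] = ()) -> None:
    lines = [GFF_VERSION_LINE, *header_pragmas]
    for f in features:
        attrs = ";".join(f"{k}={_escape(str(v))}"
                         for k, v in f.attributes.items())
        lines.append("\t".join([
            f.seqid, "reducto", f.ftype, str(f.start + 1), str(f.end),
            ".", f.strand, ".", attrs,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: Path) -> list[Feature]:
    feats: list[Feature] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        attrs = {}
        for item in cols[8].split(";"):
            if item:
                k, _, v = item.partition("=")
                attrs[k] = _unescape(v)
        feats.append(Feature(
            seqid=cols[0], ftype=cols[2], start=int(cols[3]) - 1,
            end=int(cols[4]), strand=cols[6], attributes=attrs,
        ))
    return feats


REVCOMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(REVCOMP)[::-1]


def extract_feature_seq(genome: str, feat: Feature) -> str:
    """Spliced-out feature sequence on its coding strand."""
    sub = genome[feat.start:feat.end]
    return revcomp(sub) if feat.strand == "-" else sub
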