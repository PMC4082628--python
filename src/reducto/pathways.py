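"""Carbohydrate-pathway completeness and fermentation-phenotype prediction.

A pathway definition is an AND of gene groups, each group an OR of
alternative genes (isozymes or alternative transporters).  A strain is
predicted to ferment a substrate when every required group has at least one
*intact* gene: pseudogene fragments never satisfy a group, since a
fragmented gene is taken to be non-functional.  Comparing predictions or
observations across two subspecies yields the substrates that discriminate
them: uniformly fermented by one subspecies and by no strain of the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

GENE_STATUSES = ("present", "pseudo", "absent")


@dataclass
class GeneGroup:
    name: str
    genes: frozenset
    transporter: bool = False

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"group {self.name}: empty gene set")


@dataclass
class PathwayDef:
    substrate: str
    groups: list[GeneGroup]

    def __post_init__(self):
        if not self.groups:
            raise ValueError(f"{self.substrate}: a pathway needs >= 1 group")


class GeneStatusTable:
    """(strain, gene) -> present | pseudo | absent, defaulting to absent."""

    def __init__(self, entries: dict | None = None):
        self._d: dict[tuple[str, str], str] = {}
        for k, v in (entries or {}).items():
            self.set(k[0], k[1], v)

    def set(self, strain: str, gene: str, status: str) -> None:
        if status not in GENE_STATUSES:
            raise ValueError(f"bad status {status!r}")
        self._d[(strain, gene)] = status

    def get(self, strain: str, gene: str) -> str:
        return self._d.get((strain, gene), "absent")

    def strains(self) -> list[str]:
        return sorted({s for s, _ in self._d})


def gene_status(intact_genes: set[str], fragment_genes: set[str],
                synonyms: list[str]) -> str:
    """Status of one functional gene for one strain.

    ``present`` if any synonym names an intact CDS, ``pseudo`` if synonyms
    match only pseudogene fragments, ``absent`` otherwise.
    """
    if not synonyms:
        raise ValueError("synonym list must be non-empty")
    if any(s in intact_genes for s in synonyms):
        return "present"
    if any(s in fragment_genes for s in synonyms):
        return "pseudo"
    return "absent"


def pathway_complete(defn: PathwayDef, statuses: GeneStatusTable,
                     strain: str) -> tuple[bool, list[tuple[str, str]]]:
    """Completeness of one pathway in one strain.

    Returns ``(complete, failures)`` where each failure names the group and
    whether it failed by ``absence`` or by ``fragmentation`` (at least one
    member survives only as a pseudogene fragment).
    """
    failures = []
    for group in defn.groups:
        st = {statuses.get(strain, g) for g in group.genes}
        if "present" in st:
            continue
        failures.append((group.name,
                         "fragmentation" if "pseudo" in st else "absence"))
    return not failures, failures


@dataclass
class PhenotypeMatrix:
    strains: list[str]
    substrates: list[str]
    values: dict = field(default_factory=dict)  # (strain, substrate) -> + | - | untested

    def get(self, strain: str, substrate: str) -> str:
        return self.values.get((strain, substrate), "untested")

    def fermented_counts(self) -> dict[str, int]:
        return {s: sum(self.get(s, sub) == "+" for sub in self.substrates)
                for s in self.strains}


def predict_phenotypes(defs: list[PathwayDef], statuses: GeneStatusTable,
                       strains: list[str] | None = None) -> PhenotypeMatrix:
    """Predicted fermentation matrix: ``+`` iff the pathway is complete."""
    strains = strains if strains is not None else statuses.strains()
    mat = PhenotypeMatrix(strains=list(strains),
                          substrates=[d.substrate for d in defs])
    for d in defs:
        for s in strains:
            ok, _ = pathway_complete(d, statuses, s)
            mat.values[(s, d.substrate)] = "+" if ok else "-"
    return mat


def compare_and_discriminate(observed: PhenotypeMatrix, meta: dict[str, str],
                             predicted: PhenotypeMatrix | None = None):
    """Per-strain fermented counts, discriminating substrates and (optional)
    concordance with a predicted matrix.

    A substrate discriminates the two subspecies when every tested strain of
    one subspecies is ``+`` and every tested strain of the other is ``-``;
    untested cells are excluded, never imputed.
    """
    labels = sorted({meta[s] for s in observed.strains})
    if len(labels) != 2:
        raise ValueError(f"exactly two subspecies required, got {labels}")
    by_label = {lab: [s for s in observed.strains if meta[s] == lab]
                for lab in labels}
    discriminating = []
    for sub in observed.substrates:
        verdicts = {}
        for lab in labels:
            vals = {observed.get(s, sub) for s in by_label[lab]} - {"untested"}
            verdicts[lab] = vals
        if any(not v for v in verdicts.values()):
            continue
        if (verdicts[labels[0]] == {"+"} and verdicts[labels[1]] == {"-"}) or (
                verdicts[labels[0]] == {"-"} and verdicts[labels[1]] == {"+"}):
            discriminating.append(sub)
    result = {
        "fermented_counts": observed.fermented_counts(),
        "discriminating_substrates": discriminating,
    }
    if predicted is not None:
        agree = total = 0
        for s in observed.strains:
            for sub in observed.substrates:
                o = observed.get(s, sub)
                p = predicted.get(s, sub)
                if o == "untested" or p == "untested":
                    continue
                total += 1
                agree += o == p
        result["concordance"] = agree / total if total else float("nan")
    return result


# ---------------------------------------------------------------------------
# data loading
# ---------------------------------------------------------------------------

def load_phenotype_table(path: Path | None = None) -> tuple[PhenotypeMatrix, dict[str, str]]:
    """Load a strains x substrates +/- table (TSV with ``strain`` and
    ``subspecies`` columns).  Defaults to the packaged fermentation-profile
    table of the ten-strain study set."""
    if path is None:
        path = resources.files("reducto.data") / "fermentation_profiles.tsv"
    lines = Path(str(path)).read_text().splitlines()
    header = lines[0].split("\t")
    substrates = header[2:]
    strains, meta, values = [], {}, {}
    for line in lines[1:]:
        if not line.strip():
            continue
        cols = line.split("\t")
        strain, subspecies = cols[0], cols[1]
        strains.append(strain)
        meta[strain] = subspecies
        for sub, v in zip(substrates, cols[2:]):
            if v not in "+-" and v != "untested":
                raise ValueError(f"bad phenotype value {v!r}")
            values[(strain, sub)] = v
    return PhenotypeMatrix(strains, substrates, values), meta


def load_pathway_defs(path: Path | None = None) -> list[PathwayDef]:
    """Load pathway definitions from YAML (AND-of-ORs per substrate)."""
    if path is None:
        path = resources.files("reducto.data") / "pathway_definitions.yaml"
    doc = yaml.safe_load(Path(str(path)).read_text())
    defs = []
    for substrate, spec in doc["substrates"].items():
        groups = [GeneGroup(name=g["name"], genes=frozenset(g["genes"]),
                            transporter=bool(g.get("transporter", False)))
                  for g in spec["groups"]]
        defs.append(PathwayDef(substrate=substrate, groups=groups))
    return defs
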