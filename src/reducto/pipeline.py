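"""End-to-end orchestration: stats -> pseudogenes -> orthology -> partition
-> fragment rescue -> phylogeny -> pathway phenotypes, from one config.

Every stage writes its table under the output directory and contributes to
a consolidated JSON summary.  Runs are deterministic for a fixed config and
seed; the seed is recorded in the summary header.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import genome_stats, orthology, pathways, phylo, pseudogenes, simulate

log = logging.getLogger("reducto")


@dataclass
class RunConfig:
    dataset_dir: str | None = None     # emitted dataset to analyse; None -> simulate
    out_dir: str = "reducto_out"
    seed: int = 0
    labels: tuple[str, str] | None = None  # subspecies order for A/B vs C/D
    cluster: orthology.ClusterParams = field(default_factory=orthology.ClusterParams)
    pseudo: pseudogenes.PseudoParams = field(default_factory=pseudogenes.PseudoParams)
    is_window: int = 10000
    bootstrap_reps: int = 100
    phenotype_table: str | None = None  # None -> packaged study table
    run_phenotypes: bool = True

    def __post_init__(self):
        if self.dataset_dir is not None and not Path(self.dataset_dir).exists():
            raise ValueError(f"dataset_dir does not exist: {self.dataset_dir}")


_CLUSTER_KEYS = {f.name for f in dataclasses.fields(orthology.ClusterParams)}
_PSEUDO_KEYS = {f.name for f in dataclasses.fields(pseudogenes.PseudoParams)}
_TOP_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def validate_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are rejected and
    missing keys take the documented defaults (the clustering and pseudogene
    thresholds default to the published values: e-value 1e-3, identity 0.78,
    coverage 0.76, length tolerance 0.10)."""
    doc = {}
    if path is not None:
        text = Path(path).read_text()
        doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, val in doc.items():
        if key == "cluster":
            bad = set(val) - _CLUSTER_KEYS
            if bad:
                raise ValueError(f"cluster: unknown keys {sorted(bad)}")
            kwargs["cluster"] = orthology.ClusterParams(**val)
        elif key == "pseudo":
            bad = set(val) - _PSEUDO_KEYS
            if bad:
                raise ValueError(f"pseudo: unknown keys {sorted(bad)}")
            kwargs["pseudo"] = pseudogenes.PseudoParams(**val)
        elif key == "labels":
            kwargs["labels"] = tuple(val)
        else:
            kwargs[key] = val
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config: {exc}") from exc


def _stage(name: str):
    log.info("stage %s", name)
    return time.time()


def intact_proteins(strains) -> list[orthology.ProteinRecord]:
    records = []
    for s in strains:
        for pid, seq in sorted(s.proteins.items()):
            records.append(orthology.ProteinRecord(s.strain_id, pid, seq))
    return records


def pseudo_scan_all(strains, params) -> list[pseudogenes.PseudogeneCall]:
    """Scan every strain against the union of the other strains' intact
    proteins (the in-run stand-in for an external reference database)."""
    calls = []
    for s in strains:
        db = [orthology.ProteinRecord(o.strain_id, pid, seq)
              for o in strains if o.strain_id != s.strain_id
              for pid, seq in sorted(o.proteins.items())]
        calls.extend(pseudogenes.scan_strain(s.seq, s.features, db, params))
    return calls


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the JSON-ready summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(asctime)s %(name)s %(message)s")

    if config.dataset_dir is None:
        t = _stage("simulate")
        dataset = simulate.simulate_clades(seed=config.seed)
        simulate.emit_dataset(dataset, out / "dataset")
        strains, meta = dataset.strains, dataset.meta
        scheme = dataset.scheme
        log.info("simulate done in %.1fs", time.time() - t)
    else:
        strains, meta, _, scheme = simulate.load_dataset(config.dataset_dir)
    if not strains:
        raise RuntimeError("no strains in dataset")
    for s in strains:
        if not s.features:
            raise RuntimeError(f"stage load: strain {s.strain_id} has no features")

    summary: dict = {"seed": config.seed, "n_strains": len(strains)}

    t = _stage("stats")
    stats = [genome_stats.strain_stats(s.strain_id, s.seq, s.features,
                                       window=config.is_window)
             for s in strains]
    summary["stats"] = {r.genome_id: r.as_dict() for r in stats}
    _write_tsv(out / "stats.tsv",
               ["strain", "gc_pct", "gc3_pct", "coding_density_pct", "n_cds",
                "n_pseudogene_fragments", "n_is_elements"],
               [[r.genome_id, r.overall_gc_pct, r.gc3_pct, r.coding_density_pct,
                 r.n_cds, r.n_pseudogene_fragments, sum(r.is_counts.values())]
                for r in stats])
    log.info("stats done in %.1fs", time.time() - t)

    t = _stage("pseudogenes")
    calls = pseudo_scan_all(strains, config.pseudo)
    n_frag = sum(c.verdict == "pseudogene_fragment" for c in calls)
    summary["pseudogenes"] = {"n_scanned": len(calls), "n_fragments": n_frag}
    _write_tsv(out / "pseudogene_calls.tsv",
               ["strain", "cds_id", "verdict", "evidence", "best_hit",
                "anomaly_ratio"],
               [[c.strain_id, c.cds_id, c.verdict,
                 ",".join(sorted(c.evidence)), c.best_hit_protein_id or "",
                 "" if c.anomaly_ratio is None else f"{c.anomaly_ratio:.3f}"]
                for c in calls])
    log.info("pseudogenes done in %.1fs", time.time() - t)

    t = _stage("orthology")
    proteins = intact_proteins(strains)
    edges = orthology.similarity_edges(proteins, config.cluster)
    groups = orthology.cluster_single_linkage(proteins, edges)
    labels = config.labels or tuple(sorted(set(meta.values())))
    part = orthology.partition_core(groups, meta, labels)
    summary["orthology"] = {
        "n_proteins": len(proteins), "n_edges": len(edges),
        "n_groups": len(groups), "partition": part.counts,
    }
    _write_tsv(out / "ortholog_groups.tsv", ["group_id", "members"],
               [[g.group_id, ",".join(pid for _, pid in sorted(g.members))]
                for g in groups])
    log.info("orthology done in %.1fs", time.time() - t)

    t = _stage("fragment_rescue")
    by_id = {g.group_id: g for g in groups}
    rescue = {}
    for home, away in (labels, labels[::-1]):
        spec_groups = [by_id[gid] for gid in part.specific[home]]
        n, gids = orthology.fragment_rescue(spec_groups, calls, meta, away)
        rescue[home] = {"n_specific": len(spec_groups), "n_rescued": n,
                        "rescued_groups": gids}
    summary["fragment_rescue"] = rescue
    log.info("fragment_rescue done in %.1fs", time.time() - t)

    if scheme:
        t = _stage("phylogeny")
        mlst_scheme = phylo.MlstScheme(loci=tuple(scheme),
                                       gene_ids=dict(scheme))
        loci = phylo.extract_mlst_loci(strains, mlst_scheme)
        concat, tree = phylo.mlst_run(loci, mlst_scheme)
        tree = phylo.bootstrap_support(concat, n_reps=config.bootstrap_reps,
                                       seed=config.seed)
        newick = tree.as_string(schema="newick", suppress_rooting=True)
        (out / "mlst_tree.nwk").write_text(newick)
        summary["phylogeny"] = {
            "n_strains_in_tree": len(concat.labels),
            "alignment_columns": concat.n_columns,
            "clades_monophyletic": {
                lab: phylo.is_monophyletic(
                    tree, {s for s in concat.labels if meta[s] == lab})
                for lab in labels},
        }
        log.info("phylogeny done in %.1fs", time.time() - t)

    if config.run_phenotypes:
        t = _stage("phenotypes")
        table_path = config.phenotype_table
        observed, pheno_meta = pathways.load_phenotype_table(table_path)
        res = pathways.compare_and_discriminate(observed, pheno_meta)
        summary["phenotypes"] = {
            "fermented_counts": res["fermented_counts"],
            "discriminating_substrates": res["discriminating_substrates"],
        }
        log.info("phenotypes done in %.1fs", time.time() - t)

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
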