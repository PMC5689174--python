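"""Orchestration: simulate -> detect -> classify -> date -> census -> phylo
-> enrich as one configured, seeded, logged run.

One global seed is fanned out per stage through a stable hash of the
stage name, so toggling one stage never shifts another stage's
randomness.  All writers used here live in :mod:`retroburst.seqio`; the
GFF3 element schema is the single annotation interchange format.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import DEFAULT_SUBSTITUTION_RATE
from .census import run_census
from .classify import classify_elements, load_default_library, scan_domains
from .dating import date_elements, profile_from_rows
from .detect import DetectorParams, candidates_to_annotations, detect_elements
from .enrich import enrich_report
from .phylo import (
    align_peptides,
    bootstrap_support,
    distance_matrix,
    extract_rt_peptides,
    root_with_outgroup,
)
from .seqio import (
    read_elements_gff,
    read_fasta,
    write_elements_gff,
    write_fasta,
    write_tsv,
)
from .simulate import (
    SimulationConfig,
    gene_universe,
    make_family_template,
    insert_elements,
    simulate_annotation_tables,
    simulate_background,
    write_annotation_tables,
    write_truth_gff,
)

log = logging.getLogger("retroburst")

STAGES = ("simulate", "detect", "classify", "date", "census", "phylo", "enrich")

# stages that consume the previous stage's element annotations
_NEEDS = {
    "detect": ("simulate",),
    "classify": ("detect",),
    "date": ("classify",),
    "census": ("classify",),
    "phylo": ("census",),
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


class ConfigError(ValueError):
    pass


def derive_seed(global_seed: int, stage: str) -> int:
    """Stage-specific seed from a stable hash of the stage name."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % 2**32


@dataclass
class RunReport:
    config: dict
    stages: Dict[str, dict] = field(default_factory=dict)
    elapsed: float = 0.0

    def record(self, stage: str, n_records: int, outputs: List[str],
               warnings: Optional[List[str]] = None) -> None:
        self.stages[stage] = {
            "records": n_records,
            "outputs": outputs,
            "warnings": warnings or [],
        }

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "stages": self.stages, "elapsed_s": self.elapsed},
            indent=2,
            sort_keys=True,
        )


def _validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    stages = cfg.get("stages", {name: True for name in STAGES})
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    enabled = {name for name in STAGES if stages.get(name, False)}
    for stage, deps in _NEEDS.items():
        if stage in enabled:
            for dep in deps:
                needs_input = (
                    (stage == "detect" and "genome" not in cfg)
                    or (stage == "classify" and "elements" not in cfg)
                    or stage in ("date", "census", "phylo")
                )
                if dep not in enabled and needs_input:
                    raise ConfigError(
                        f"stage {stage!r} enabled but dependency {dep!r} is not"
                    )
    if "seed" in cfg and not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")
    return cfg


def default_config() -> dict:
    """The bundled demo configuration (full synthetic run)."""
    return {
        "seed": 1,
        "out_dir": "retroburst_out",
        "stages": {name: True for name in STAGES},
        "simulate": {
            "genome_length": 300_000,
            "gc_fraction": 0.5,
            "families": [
                {"id": "GYPSY_A", "superfamily": "Gypsy", "chromoviridae": True,
                 "ltr_len": 350, "peptide_divergence": 0.15},
                {"id": "COPIA_A", "superfamily": "Copia", "ltr_len": 300,
                 "peptide_divergence": 0.15},
            ],
            "n_insertions": 4,
            "ages": [2.0e6, 5.0e6, 8.0e6, 12.0e6],
            "rate_r": DEFAULT_SUBSTITUTION_RATE,
            "transition_fraction": 0.5,
            "truncation_fraction": 0.0,
            "solo_ltr_fraction": 0.0,
        },
        "detect": {},
        "date": {"rate_r": DEFAULT_SUBSTITUTION_RATE, "bin_my": 5.0,
                 "only_classified": False},
        "census": {"min_identity": 0.8},
        "phylo": {"bootstrap": 100, "outgroup": "__outgroup__"},
        "enrich": {
            "n_genes": 14_928,
            "n_secreted": 470,
            "planted_terms": [["GO:0030600", 6, 9]],
            "alpha": 0.05,
        },
    }


def run_pipeline(config: dict | str | Path) -> RunReport:
    """Run the enabled stages in dependency order; see `default_config`."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = _validate_config(config)
    t0 = time.time()
    report = RunReport(config=cfg)
    seed = int(cfg.get("seed", 0))
    out_dir = Path(cfg.get("out_dir", "retroburst_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", {name: True for name in STAGES})

    records: Optional[List[Tuple[str, str]]] = None
    elements = None
    hit_table = None
    families = None

    if cfg.get("genome"):
        records = read_fasta(cfg["genome"])
    if cfg.get("elements"):
        elements = read_elements_gff(cfg["elements"])

    if stages.get("simulate"):
        scfg = dict(cfg.get("simulate", {}))
        fam_specs = scfg.pop("families", default_config()["simulate"]["families"])
        sim_seed = derive_seed(seed, "simulate")
        genome = simulate_background(
            scfg.get("genome_length", 300_000), scfg.get("gc_fraction", 0.5), sim_seed
        )
        templates = [
            make_family_template(
                spec["id"],
                spec.get("superfamily", "Gypsy"),
                seed=derive_seed(sim_seed, spec["id"]),
                ltr_len=spec.get("ltr_len", 400),
                chromoviridae=spec.get("chromoviridae", False),
                peptide_divergence=spec.get("peptide_divergence", 0.0),
            )
            for spec in fam_specs
        ]
        sim = SimulationConfig(
            genome_length=scfg.get("genome_length", 300_000),
            gc_fraction=scfg.get("gc_fraction", 0.5),
            n_insertions=scfg.get("n_insertions", 4),
            ages=[float(a) for a in scfg.get("ages", [5e6])],
            rate_r=float(scfg.get("rate_r", DEFAULT_SUBSTITUTION_RATE)),
            transition_fraction=scfg.get("transition_fraction", 0.5),
            truncation_fraction=scfg.get("truncation_fraction", 0.0),
            solo_ltr_fraction=scfg.get("solo_ltr_fraction", 0.0),
            seed=sim_seed,
        )
        genome, truths = insert_elements(genome, templates, sim)
        records = genome.records
        fa = out_dir / "genome.fasta"
        gff = out_dir / "truth.gff3"
        write_fasta(fa, records)
        write_truth_gff(gff, truths)
        report.record("simulate", len(truths), [str(fa), str(gff)])
        log.info("simulate: %d insertions into %d bp", len(truths), genome.total_length)

    if stages.get("detect"):
        if records is None:
            raise PipelineError("detect", "no genome available (enable simulate or set genome:)")
        params = DetectorParams(**cfg.get("detect", {}))
        candidates = detect_elements(records, params)
        elements = candidates_to_annotations(candidates)
        gff = out_dir / "detected.gff3"
        tsv = out_dir / "detected.tsv"
        write_elements_gff(gff, elements)
        write_tsv(
            tsv,
            ["element_id", "seq_id", "start", "end", "ltr5_len", "ltr3_len",
             "identity", "tsd"],
            [
                [e.element_id, c.seq_id, c.start, c.end,
                 c.ltr5[1] - c.ltr5[0], c.ltr3[1] - c.ltr3[0],
                 f"{c.ltr_identity:.4f}", c.tsd or "."]
                for e, c in zip(elements, candidates)
            ],
        )
        report.record("detect", len(elements), [str(gff), str(tsv)])
        log.info("detect: %d candidates", len(elements))

    if stages.get("classify"):
        if records is None or elements is None:
            raise PipelineError("classify", "needs a genome and detected elements")
        elements, hit_table = classify_elements(records, elements)
        gff = out_dir / "classified.gff3"
        tsv = out_dir / "domains.tsv"
        write_elements_gff(gff, elements)
        write_tsv(
            tsv,
            ["element_id", "domain", "frame", "start", "end", "score", "identity"],
            [
                [eid, h.domain, h.frame, h.start, h.end, f"{h.score:.1f}",
                 f"{h.identity:.4f}"]
                for eid, h in hit_table
            ],
        )
        report.record("classify", len(elements), [str(gff), str(tsv)])

    if stages.get("date"):
        if records is None or elements is None:
            raise PipelineError("date", "needs a genome and classified elements")
        dcfg = cfg.get("date", {})
        to_date = elements
        if dcfg.get("only_classified"):
            to_date = [e for e in elements
                       if e.attributes.get("Superfamily", "unknown") != "unknown"]
        rows = date_elements(records, to_date,
                             rate_r=float(dcfg.get("rate_r", DEFAULT_SUBSTITUTION_RATE)))
        bin_w = float(dcfg.get("bin_my", 5.0)) * 1e6
        profile = profile_from_rows(rows, bin_width=bin_w)
        tsv = out_dir / "dating.tsv"
        ptsv = out_dir / "profile.tsv"
        write_tsv(
            tsv,
            ["element_id", "P", "Q", "usable_sites", "K", "T_years", "status"],
            [
                [r.element_id,
                 "" if r.P is None else f"{r.P:.6f}",
                 "" if r.Q is None else f"{r.Q:.6f}",
                 "" if r.usable_sites is None else r.usable_sites,
                 "" if r.K is None else f"{r.K:.6f}",
                 "" if r.T is None else f"{r.T:.1f}",
                 r.status]
                for r in rows
            ],
        )
        write_tsv(
            ptsv,
            ["bin_start_MY", "bin_end_MY", "count"],
            [
                [i * bin_w / 1e6, (i + 1) * bin_w / 1e6, c]
                for i, c in enumerate(profile.bin_counts)
            ],
        )
        report.record("date", len(rows), [str(tsv), str(ptsv)])

    if stages.get("census"):
        if records is None or elements is None:
            raise PipelineError("census", "needs a genome and classified elements")
        ccfg = cfg.get("census", {})
        families, copies, census_rows = run_census(
            records, elements,
            min_identity=float(ccfg.get("min_identity", 0.8)),
            min_mutual_coverage=float(ccfg.get("min_mutual_coverage", 0.8)),
            two_pass=bool(ccfg.get("two_pass", True)),
        )
        cons_fa = out_dir / "consensus.fasta"
        copies_gff = out_dir / "copies.gff3"
        census_tsv = out_dir / "census.tsv"
        write_fasta(cons_fa, [(f.family_id, f.consensus) for f in families])
        from .seqio import ElementAnnotation

        write_elements_gff(
            copies_gff,
            [
                ElementAnnotation(
                    element_id=f"copy_{i:04d}", seq_id=c.seq_id, start=c.start,
                    end=c.end,
                    attributes={
                        "Family": c.family_id,
                        "Identity": f"{c.identity:.4f}",
                        "ConsensusFraction": f"{c.fraction_of_consensus:.4f}",
                    },
                )
                for i, c in enumerate(copies)
            ],
        )
        write_tsv(
            census_tsv,
            ["classification", "families", "copies", "full_copies", "coverage_percent"],
            [
                [q.label, q.n_families, q.n_copies, q.n_full_copies,
                 f"{q.coverage_percent:.2f}"]
                for q in census_rows
            ],
        )
        report.record("census", len(copies), [str(cons_fa), str(copies_gff), str(census_tsv)])

    if stages.get("phylo"):
        if families is None:
            raise PipelineError("phylo", "needs census families")
        pcfg = cfg.get("phylo", {})
        phylo_seed = derive_seed(seed, "phylo")
        library = load_default_library()
        seqs = {f.family_id: f.consensus for f in families}
        outgroup_id = pcfg.get("outgroup", "__outgroup__")
        if outgroup_id == "__outgroup__":
            og = make_family_template(
                "__outgroup__", "Gypsy", seed=derive_seed(phylo_seed, "outgroup"),
                peptide_divergence=0.4,
            )
            seqs["__outgroup__"] = og.element_sequence
        hits = {taxon: scan_domains(s, library) for taxon, s in seqs.items()}
        peptides = extract_rt_peptides(seqs, hits)
        warnings = [f"no RT hit for {t}; skipped" for t in seqs if t not in peptides]
        outputs: List[str] = []
        if len(peptides) >= 3:
            aln = align_peptides(peptides)
            tree = bootstrap_support(aln, n_replicates=int(pcfg.get("bootstrap", 100)),
                                     seed=phylo_seed)
            if outgroup_id in peptides:
                tree = root_with_outgroup(tree, outgroup_id)
            nwk = out_dir / "tree.nwk"
            aln_fa = out_dir / "rt_alignment.fasta"
            dist_tsv = out_dir / "distances.tsv"
            nwk.write_text(tree.newick() + "\n")
            write_fasta(aln_fa, aln.rows)
            taxa, D = distance_matrix(aln)
            write_tsv(dist_tsv, ["taxon"] + taxa,
                      [[t] + [f"{D[i, j]:.6f}" for j in range(len(taxa))]
                       for i, t in enumerate(taxa)])
            outputs = [str(nwk), str(aln_fa), str(dist_tsv)]
        else:
            warnings.append("fewer than 3 RT peptides; tree skipped")
        report.record("phylo", len(peptides), outputs, warnings)

    if stages.get("enrich"):
        ecfg = cfg.get("enrich", {})
        enrich_seed = derive_seed(seed, "enrich")
        if "annotations" in ecfg:
            from .seqio import read_tsv

            _, rows_in = read_tsv(ecfg["annotations"], expect_header=False)
            table = [(r[0], r[1]) for r in rows_in]
            subset = {
                line.strip()
                for line in open(ecfg["subset"])
                if line.strip()
            }
            genes = None
            if "genes" in ecfg:
                genes = [line.strip() for line in open(ecfg["genes"]) if line.strip()]
        else:
            n_genes = int(ecfg.get("n_genes", 14_928))
            table, subset = simulate_annotation_tables(
                n_genes=n_genes,
                n_secreted=int(ecfg.get("n_secreted", 470)),
                planted_terms=[tuple(t) for t in ecfg.get("planted_terms", [])],
                seed=enrich_seed,
            )
            genes = gene_universe(n_genes)
            write_annotation_tables(out_dir / "annotation", table, subset, genes)
        rows = enrich_report(table, subset, alpha=float(ecfg.get("alpha", 0.05)),
                             genome_genes=genes)
        tsv = out_dir / "enrichment.tsv"
        write_tsv(
            tsv,
            ["term", "subset_count", "subset_size", "genome_count", "genome_size",
             "p_raw", "p_corrected", "significant"],
            [
                [r.term_id, r.counts.a, r.counts.subset_size, r.counts.term_total,
                 r.counts.population, f"{r.p_raw:.6g}", f"{r.p_corrected:.6g}",
                 str(r.significant).lower()]
                for r in rows
            ],
        )
        report.record("enrich", len(rows), [str(tsv)])

    report.elapsed = time.time() - t0
    (out_dir / "report.json").write_text(report.to_json() + "\n")
    return report
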