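"""End-to-end orchestration: simulate → network → classify → quantify →
profile → pan-BGC → mutation scan, with a machine-readable JSON report.

Every stochastic stage derives its randomness from the single run seed, so
re-running an identical configuration reproduces every artifact byte for
byte (timing excluded from the report's determinism contract).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genomecmp, profiles, quantify, synthetic, tags
from .network import ScoringParams, build_network, cluster_spectra, constellations, export_network
from .spectra import write_mgf
from .synthetic import MutationPlan, SimulationConfig

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    # genomics side
    n_genome_strains: int = 18
    n_core_bgc: int = 18
    n_accessory_bgc: int = 22
    n_unique_bgc: int = 2
    n_cluster_genes: int = 16
    cds_codons: int = 120
    mutations_per_strain: tuple[int, int, int] = (1, 3, 0)  # silent, non-silent, deletions

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        self.sim = dataclasses.replace(self.sim, seed=self.seed)


def _echo_config(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["outdir"] = str(cfg.outdir)
    return d


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage on synthetic inputs and write artifacts plus a report."""
    t0 = time.time()
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _echo_config(cfg), "stages": {}}
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    try:
        # --- simulate ---------------------------------------------------
        lib = synthetic.make_library(cfg.sim)
        production = synthetic.make_production(lib, cfg=cfg.sim)
        spectra = synthetic.simulate_spectra(lib, production, cfg.sim)
        for strain in production.strains:
            subset = [s for s in spectra if s.strain == strain]
            if subset:
                write_mgf(subset, out / f"{strain}.mgf")
        production.values.to_csv(out / "production.tsv", sep="\t")
        report["stages"]["simulate"] = {
            "n_compounds": len(lib.compounds),
            "n_strains": len(production.strains),
            "n_spectra": len(spectra),
        }

        # --- network ----------------------------------------------------
        nodes = cluster_spectra(spectra, cfg.scoring)
        graph = build_network(nodes, cfg.scoring)
        comps = constellations(graph)
        export_network(graph, out / "network")
        report["stages"]["network"] = {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "n_constellations": len(comps),
            "largest_constellation": len(comps[0]) if comps else 0,
        }

        # --- classify ---------------------------------------------------
        spectra_by_id = {s.id: s for s in spectra}
        calls = []
        for node in nodes:
            evidence = [tags.screen_tags(spectra_by_id[mid]) for mid in node.member_ids]
            call = tags.classify_node(node.id, evidence)
            node.group = call.group
            calls.append(call)
        tally = pd.Series([c.group for c in calls]).value_counts().sort_index()
        pd.DataFrame(
            [{"node": c.node_id, "group": c.group, "ambiguous": c.ambiguous,
              "n_evidence": len(c.evidence)} for c in calls]
        ).to_csv(out / "group_calls.tsv", sep="\t", index=False)
        report["stages"]["classify"] = {"group_tally": tally.to_dict()}

        # --- quantify ---------------------------------------------------
        eics = synthetic.simulate_eic(lib, production, cfg.sim)
        areas = pd.DataFrame(0.0, index=production.strains, columns=production.compounds)
        for strain, traces in eics.items():
            for comp, trace in zip(lib.compounds, traces):
                if trace.intensity.max() <= 0:
                    continue
                window = quantify.detect_window(trace)
                areas.loc[strain, comp.name] = quantify.integrate_peak(trace, window)
        matrix = quantify.StrainCompoundMatrix(areas, production.reference_strain)
        ra = quantify.relative_abundance(matrix)
        ra.values.to_csv(out / "relative_abundance.tsv", sep="\t")
        ra.flags.to_csv(out / "relative_abundance_flags.tsv", sep="\t")
        best = quantify.best_producer(matrix)
        best.to_csv(out / "best_producers.tsv", sep="\t")
        report["stages"]["quantify"] = {
            "reference": matrix.reference_strain,
            "n_reference_nonproducer_cells": int((ra.flags.values != "").sum()),
        }

        # --- profile ----------------------------------------------------
        presence = profiles.presence_matrix(matrix)
        stats = profiles.producing_strains(presence)
        transformed = profiles.glog_pareto(matrix.values)
        clustering = profiles.cluster_profiles(transformed)
        (out / "strain_dendrogram.nwk").write_text(
            profiles.linkage_to_newick(clustering.row_linkage, list(transformed.index)))
        (out / "compound_dendrogram.nwk").write_text(
            profiles.linkage_to_newick(clustering.col_linkage, list(transformed.columns)))
        presence.values.to_csv(out / "presence.tsv", sep="\t")
        report["stages"]["profile"] = {
            "exclusive_compounds": stats.exclusive_count,
            "per_strain_compound_counts": stats.per_strain_counts.to_dict(),
        }

        # --- pan-BGC ----------------------------------------------------
        bgc = synthetic.make_bgc_matrix(
            cfg.n_genome_strains, cfg.n_core_bgc, cfg.n_accessory_bgc,
            cfg.n_unique_bgc, seed=cfg.seed)
        bgc.to_csv(out / "bgc_matrix.tsv", sep="\t")
        pan = genomecmp.pan_bgc_stats(bgc, type_strain=bgc.index[0])
        report["stages"]["panbgc"] = {
            "union": pan.union_size,
            "core": pan.core_count,
            "non_core_fraction": round(pan.non_core_fraction, 2),
            "absent_from_type_strain": pan.absent_from_type_strain,
            "unique_families": len(pan.unique_to_one_strain),
        }

        # --- mutation scan ----------------------------------------------
        reference = synthetic.random_reference_cds(
            cfg.n_cluster_genes, cfg.cds_codons, seed=cfg.seed)
        n_sil, n_non, n_del = cfg.mutations_per_strain
        plans = {
            f"S{i + 2:02d}": MutationPlan(n_sil, n_non, n_del)
            for i in range(min(cfg.n_genome_strains - 1, 4))
        }
        mutated, _truth = synthetic.make_cds_set(reference, plans, seed=cfg.seed)
        events = []
        for strain, genes in mutated.items():
            for gene, seq in genes.items():
                aln = genomecmp.align_cds(reference[gene], seq)
                events.extend(genomecmp.classify_mutations(aln, gene=gene, strain=strain))
        summary = genomecmp.mutation_matrix(events)
        summary.per_gene_strain.to_csv(out / "mutation_matrix.tsv", sep="\t")
        report["stages"]["mutscan"] = {
            "distinct_mutations": summary.distinct_total,
            "per_strain_totals": summary.per_strain_totals.to_dict(),
            "by_kind": summary.by_kind.to_dict(),
        }
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        log.error("pipeline failed: %s", exc)
        raise

    report["elapsed_seconds"] = round(time.time() - t0, 3)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    log.info("pipeline finished in %.1f s", report["elapsed_seconds"])
    return report
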