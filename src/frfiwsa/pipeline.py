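"""End-to-end pipeline: filter -> encode -> optimize -> infer -> report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import interpret
from .data import ExpressionDataset, RunConfig, write_dataset
from .frbms import evaluate_kb, render_rules
from .frfi import f_information_ranking, filter_top_genes
from .wsa import optimize

log = logging.getLogger("frfiwsa")


@dataclasses.dataclass
class PipelineResult:
    """Paths of everything one full run writes."""

    ranking_file: Path
    filtered_file: Path
    kb_file: Path
    eval_file: Path
    interpret_file: Path
    trace_file: Path
    manifest_file: Path


def _write_ranking(ranking, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tgene_id\tF_sig\tFI\n")
        for rank, gene, sig, fi in ranking.as_rows():
            fh.write(f"{rank}\t{gene}\t{sig:.6f}\t{fi:.6f}\n")


def _write_interpret(kb, dataset, config: RunConfig, path: Path) -> None:
    stats = interpret.rule_stats(kb, dataset)
    averages = interpret.ruleset_averages(kb, dataset)
    report = interpret.cofiring_matrix(kb, dataset)
    ci, cfci, _, cfci_rule = interpret.comprehensibility(
        report, config.cfci_threshold, normalize=True)
    with open(path, "w") as fh:
        fh.write(f"#R\t{averages.n_rules}\n")
        fh.write(f"A_rl\t{averages.a_rl:.4f}\n")
        fh.write(f"A_fr\t{averages.a_fr:.4f}\n")
        fh.write(f"A_cfd\t{averages.a_cfd:.4f}\n")
        fh.write(f"CI\t{ci:.6f}\nCFCI\t{cfci:.6f}\n")
        fh.write("rule\tR_cov\tR_cov_pct\tR_acc\tR_acc_pct\tR_gud\tCFCI\n")
        for s in stats:
            if not kb.rules[s.rule_index].is_active:
                continue
            fh.write(
                f"R{s.rule_index + 1}\t{s.r_cov:.4f}\t{100 * s.r_cov:.2f}\t"
                f"{s.r_acc:.4f}\t{100 * s.r_acc:.2f}\t{s.r_gud:.4f}\t"
                f"{cfci_rule[s.rule_index]:.4f}\n"
            )


def run_pipeline(dataset: ExpressionDataset, config: RunConfig,
                 outdir: str | Path) -> PipelineResult:
    """Filter, train, evaluate and report; returns the written paths.

    Fully determined by (dataset, config): the manifest records the
    config and a hash of the input matrix so a rerun can be verified
    byte-for-byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(
        ranking_file=outdir / "ranking.tsv",
        filtered_file=outdir / "filtered.csv",
        kb_file=outdir / "kb.yaml",
        eval_file=outdir / "evaluation.txt",
        interpret_file=outdir / "interpretability.tsv",
        trace_file=outdir / "trace.tsv",
        manifest_file=outdir / "manifest.json",
    )

    log.info("phase 1: F-information filtering (%d -> %d genes)",
             dataset.n_genes, config.f_filtered)
    ranking = f_information_ranking(dataset)
    _write_ranking(ranking, result.ranking_file)
    f = min(config.f_filtered, dataset.n_genes)
    filtered = filter_top_genes(dataset, ranking, f)
    write_dataset(filtered, result.filtered_file)

    log.info("phases 2-6: swirl optimization (%d particles, %d iterations)",
             config.swarm_size, config.iterations)
    swirl = optimize(filtered, config)
    swirl.kb.save(result.kb_file)
    np.savetxt(result.trace_file, swirl.trace, fmt="%.6f",
               header="best_objective", comments="")

    log.info("phase 7: reports")
    res = evaluate_kb(swirl.kb, filtered)
    with open(result.eval_file, "w") as fh:
        fh.write(f"samples\t{res.ts}\ncorrect\t{res.cs}\n"
                 f"accuracy\t{res.accuracy:.4f}\nrules\t{res.rs}\n"
                 f"genes\t{res.gs}\nobjective\t{swirl.objective_value:.4f}\n\n")
        fh.write(render_rules(swirl.kb, filtered.gene_ids,
                              filtered.class_names) + "\n")
    _write_interpret(swirl.kb, filtered, config, result.interpret_file)

    digest = hashlib.sha256(
        np.ascontiguousarray(dataset.values).tobytes()
        + dataset.labels.tobytes()
    ).hexdigest()
    manifest = {
        "config": dataclasses.asdict(config),
        "input_sha256": digest,
        "n_genes": dataset.n_genes,
        "n_samples": dataset.n_samples,
        "n_classes": dataset.n_classes,
        "outputs": {k: str(v) for k, v in dataclasses.asdict(result).items()},
    }
    with open(result.manifest_file, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return result
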