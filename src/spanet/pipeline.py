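"""End-to-end pipeline: reconstruct -> tune -> topology -> modules -> enrich -> reporters.

``run_pipeline`` chains the stages on files, writes a report directory of TSV
tables, and is byte-deterministic for a fixed configuration seed.  Stage
errors propagate wrapped in :class:`PipelineStageError` naming the stage; the
reporter stage is skipped (with a logged notice) when the regulatory inputs
are not supplied.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx

from . import io as spio
from .config import PipelineConfig
from .enrichment import enrich_modules, unknown_function_candidates
from .mcode import McodeParams, find_modules
from .reporter import RegulatoryNetwork, gene_z_scores, score_reporters
from .spa import reconstruct
from .topology import clustering_by_degree, summarize
from .tuning import build_ensemble, tune

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _read_ppi(path: Path):
    """Sniff BioGrid TAB 2.0 vs plain two-column edge list."""
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith(("#", "!")):
                if len(line.split("\t")) >= spio.TAB2_MIN_COLUMNS:
                    return spio.read_biogrid_tab2(path, keep="physical")
                break
    return list(spio.read_network(path, format="edge_tsv").edges())


def run_pipeline(
    config: PipelineConfig,
    ppi_path,
    gaf_path,
    cores_path,
    out_dir,
    regnet_path=None,
    pvalues_path=None,
) -> Path:
    """Run every stage and write the report directory; returns its path."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def note(msg: str) -> None:
        logger.info(msg)
        log.append(msg)

    # --- reconstruction -----------------------------------------------------
    try:
        interactions = _read_ppi(Path(ppi_path))
        annotations = spio.read_gaf(gaf_path)
        cores = spio.read_id_list(cores_path)
        known = [c for c in cores if c in annotations]
        for c in cores:
            if c not in known:
                logger.warning("core %s absent from the annotation/interaction inputs; dropped", c)
                log.append(f"core {c} absent from the annotation/interaction inputs; dropped")
        cores = known
        note(f"inputs: {len(interactions)} interactions, {len(annotations)} annotated proteins, {len(cores)} cores")
        etn = reconstruct(cores, annotations, interactions)
        dropped = [c for c in cores if c not in etn]
        for c in dropped:
            note(f"core {c} dropped: no surviving physical interaction")
        note(f"reconstructed network: {etn.number_of_nodes()} nodes, {etn.number_of_edges()} edges")
        spio.write_network(etn, out_dir / "etn.tsv", format="edge_tsv")
    except Exception as exc:  # noqa: BLE001 - stage name must propagate
        raise PipelineStageError("reconstruct", exc) from exc

    # --- tuning -------------------------------------------------------------
    try:
        ensemble = build_ensemble(
            etn, R=config.n_random, seed=config.seed, swap_multiplier=config.swap_multiplier
        )
        tetn, records = tune(ensemble, alpha=config.alpha_tuning)
        note(
            f"tuning: alpha={config.alpha_tuning}, R={config.n_random}, "
            f"retained {tetn.number_of_nodes()}/{etn.number_of_nodes()} nodes, "
            f"{tetn.number_of_edges()} edges"
        )
        spio.write_network(tetn, out_dir / "tetn.tsv", format="edge_tsv")
        spio.write_tsv(
            out_dir / "tuning_table.tsv",
            ["node", "observed_evc", "mean_random_evc", "t_statistic", "p_value", "retained"],
            ((r.node, r.observed_evc, r.mean_random_evc, r.t_statistic, r.p_value, r.retained) for r in records),
        )
    except Exception as exc:
        raise PipelineStageError("tune", exc) from exc

    # --- topology -----------------------------------------------------------
    try:
        comps = sorted(nx.connected_components(tetn), key=lambda c: (-len(c), min(c)))
        giant = tetn.subgraph(comps[0]).copy() if comps else tetn
        if len(comps) > 1:
            note(f"topology computed on the largest tuned component ({len(comps[0])} nodes of {tetn.number_of_nodes()})")
        summary = summarize(giant)
        spio.write_tsv(
            out_dir / "topology.tsv",
            ["n_nodes", "n_edges", "diameter", "avg_shortest_path", "avg_clustering", "power_law_w", "power_law_r2"],
            [(
                summary.n_nodes,
                summary.n_edges,
                summary.diameter,
                summary.avg_shortest_path,
                summary.avg_clustering,
                "NA" if summary.power_law_w is None else summary.power_law_w,
                "NA" if summary.power_law_r2 is None else summary.power_law_r2,
            )],
        )
        spio.write_tsv(
            out_dir / "degree_distribution.tsv",
            ["degree", "n_nodes"],
            sorted(summary.degree_distribution.items()),
        )
        spio.write_tsv(
            out_dir / "ck_curve.tsv",
            ["degree", "mean_clustering"],
            sorted(clustering_by_degree(giant).items()),
        )
    except Exception as exc:
        raise PipelineStageError("topology", exc) from exc

    # --- modules ------------------------------------------------------------
    try:
        mcode_params = McodeParams(
            degree_threshold=config.mcode_degree_threshold,
            node_score_threshold=config.mcode_node_score_threshold,
            kcore_threshold=config.mcode_kcore,
            max_depth=config.mcode_max_depth,
            haircut=config.mcode_haircut,
            fluff=config.mcode_fluff,
        )
        modules = find_modules(tetn, mcode_params)
        note(f"module detection: {len(modules)} modules")
        spio.write_tsv(
            out_dir / "modules.tsv",
            ["rank", "score", "size", "seed_node", "members"],
            ((m.rank, m.score, m.size, m.seed_node, ",".join(sorted(m.members))) for m in modules),
        )
    except Exception as exc:
        raise PipelineStageError("modules", exc) from exc

    # --- enrichment and candidates -------------------------------------------
    try:
        reference = sorted(
            p for p in tetn.nodes() if annotations.get(p) and annotations[p].process_terms
        )
        records = enrich_modules(
            modules, annotations, reference,
            alpha=config.enrichment_alpha, min_size=config.min_module_size,
        )
        note(
            f"enrichment: {len(records)} significant (module, term) pairs at "
            f"q<{config.enrichment_alpha} over {len(reference)} reference proteins"
        )
        spio.write_tsv(
            out_dir / "enrichment.tsv",
            ["module_rank", "term", "k", "n", "K", "N", "p_value", "q_value"],
            ((r.module_rank, r.term, r.k, r.n, r.K, r.N, r.p_value, r.q_value) for r in records),
        )
        candidates = unknown_function_candidates(modules, annotations, min_size=config.min_module_size)
        note(f"candidate extraction: {len(candidates)} unknown-function module members")
        spio.write_tsv(
            out_dir / "candidates.tsv",
            ["protein", "module_rank", "reason"],
            ((c.protein, c.module_rank, c.reason) for c in candidates),
        )
    except Exception as exc:
        raise PipelineStageError("enrich", exc) from exc

    # --- reporter TFs (optional) ---------------------------------------------
    if regnet_path is not None and pvalues_path is not None:
        try:
            regnet = RegulatoryNetwork.from_edges(spio.read_regnet(regnet_path))
            pvalues = spio.read_pvalues(pvalues_path)
            z = gene_z_scores(pvalues)
            reporter_records = score_reporters(
                regnet,
                z,
                background_samples=config.reporter_background_samples,
                seed=config.seed + 1000,
                alpha=config.reporter_alpha,
            )
            n_sig = sum(r.significant for r in reporter_records)
            note(
                f"reporter stage: {n_sig}/{len(reporter_records)} TFs significant at "
                f"p<{config.reporter_alpha}"
            )
            spio.write_tsv(
                out_dir / "reporter_tfs.tsv",
                ["tf", "n_targets_scored", "raw_z", "corrected_z", "p_value", "significant"],
                (
                    (r.tf, r.n_targets_scored, r.raw_z, r.corrected_z, r.p_value, r.significant)
                    for r in reporter_records
                ),
            )
        except Exception as exc:
            raise PipelineStageError("reporter", exc) from exc
    else:
        note("reporter stage skipped: regulatory network or p-value table not supplied")

    note(f"config: seed={config.seed} alpha_tuning={config.alpha_tuning} n_random={config.n_random} "
         f"enrichment_alpha={config.enrichment_alpha} min_module_size={config.min_module_size} "
         f"reporter_alpha={config.reporter_alpha} swap_multiplier={config.swap_multiplier}")
    (out_dir / "run_log.txt").write_text("".join(f"{line}\n" for line in log))
    return out_dir
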