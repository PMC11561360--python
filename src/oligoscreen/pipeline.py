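"""End-to-end screen: signature -> connectivity -> scoring -> filtering.

`run_pipeline` is the file-based entry point behind the ``oligoscreen
run`` command: it reads DEG tables, builds the combined signed
signature, queries the compound compendium with both the broad
signature (route A) and the curated-gene signature (route B), keeps
compounds positively associated with both, scores them with the
curation table, applies blocklist and ADMET policy, and writes ranked
tables plus a JSON run report.

`run_synthetic_screen` executes the same stages in memory on generated
fixtures with planted ground truth; it is the workhorse of the
planted-recovery validation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

from oligoscreen import __version__
from oligoscreen.connectivity import find_hub_genes, query_compendium
from oligoscreen.io import (
    RunConfig,
    read_admet_table,
    read_compendium_wide,
    read_deg_table,
    write_connectivity_results,
    write_signed_set,
)
from oligoscreen.oligoscore import (
    CurationTable,
    compound_target_set,
    load_curation,
    score_compound,
)
from oligoscreen.screening import (
    CompoundDossier,
    FilterPolicy,
    admet_filter,
    apply_blocklist,
    merge_candidates,
    rank_by_score,
    select_top,
)
from oligoscreen.signatures import (
    SignedGeneSet,
    apply_expression_floor,
    filter_degs,
    refine_combined,
)
from oligoscreen.synthetic import (
    SimConfig,
    gen_admet,
    gen_compendium,
    gen_curation,
    gen_deg_tables,
    gen_signature,
    planted_ids,
)

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_FAILURE = 1
EXIT_MISSING_INPUT = 2


def curated_signed_set(table: CurationTable, name: str = "curated") -> SignedGeneSet:
    """Net-sign signature of the curation table.

    Each curated gene is tagged by the sign of the sum of its process
    scores (its net promoting/inhibiting role); genes with a zero net
    sum are dropped.  This is the route-B query signature.
    """
    net: dict[str, int] = {}
    for (gene, _), score in table.entries.items():
        net[gene] = net.get(gene, 0) + score
    entries = {g: (1 if s > 0 else -1) for g, s in net.items() if s != 0}
    return SignedGeneSet(name=name, entries=entries)


def _build_signature(config: RunConfig) -> tuple[SignedGeneSet, list[dict]]:
    per_table = []
    stage_log = []
    for path in config.deg_paths:
        table = read_deg_table(path)
        n_raw = len(table)
        if "expression" in table.frame.columns:
            table = apply_expression_floor(table, config.expr_floor)
        sig = filter_degs(
            table, fc_min=config.fc_min, p_max=config.p_max, direction="both",
            name=Path(path).stem,
        )
        per_table.append(sig)
        stage_log.append({"path": str(path), "rows": n_raw, "genes_kept": len(sig)})
    combined = refine_combined(per_table, name="combined")
    return combined, stage_log


def run_pipeline(config: RunConfig) -> tuple[int, dict]:
    """Execute the full screen from files; returns (exit code, report)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    report: dict = {
        "version": __version__,
        "params": asdict(config),
        "stages": {},
    }
    required = [*config.deg_paths, config.compendium_path, config.curation_path]
    if config.admet_path:
        required.append(config.admet_path)
    if config.gene_compendium_path:
        required.append(config.gene_compendium_path)
    for path in required:
        if not Path(path).is_file():
            logger.error("missing input file: %s", path)
            report["error"] = f"missing input file: {path}"
            return EXIT_MISSING_INPUT, report

    out.mkdir(parents=True, exist_ok=True)

    # stage 1: signature
    signature, deg_log = _build_signature(config)
    write_signed_set(signature, out / "signature.tsv")
    report["stages"]["signature"] = {"tables": deg_log, "n_genes": len(signature)}

    # stage 2: connectivity (route A broad, route B curated, optional hubs)
    compendium = read_compendium_wide(config.compendium_path)
    curation = load_curation(config.curation_path)
    curated_query = curated_signed_set(curation)
    common_kwargs = dict(
        alpha=config.alpha,
        null=config.null,
        seed=config.seed,
        min_overlap=config.min_overlap,
    )
    route_a = query_compendium(signature, compendium, **common_kwargs)
    route_b = query_compendium(curated_query, compendium, **common_kwargs)
    write_connectivity_results(route_a, out / "routeA.tsv")
    write_connectivity_results(route_b, out / "routeB.tsv")
    report["stages"]["connectivity"] = {
        "n_profiles": len(compendium),
        "routeA_correlated": sum(r.call == "correlated" for r in route_a),
        "routeB_correlated": sum(r.call == "correlated" for r in route_b),
    }
    if config.gene_compendium_path:
        gene_compendium = read_compendium_wide(config.gene_compendium_path, kind="gene")
        hubs = find_hub_genes(signature, gene_compendium, **common_kwargs)
        write_connectivity_results(hubs["correlated"], out / "hubs_correlated.tsv")
        write_connectivity_results(hubs["anticorrelated"], out / "hubs_anticorrelated.tsv")
        report["stages"]["hubs"] = {
            k: len(v) for k, v in hubs.items()
        }

    # stage 3: merge + score
    candidates = merge_candidates(route_a, route_b)
    dossiers: dict[str, CompoundDossier] = {}
    ra = {r.id: r for r in route_a}
    rb = {r.id: r for r in route_b}
    for cid in candidates:
        profile = compendium.get(cid)
        targets = compound_target_set(
            profile, curation, mode=config.targets_mode, query=signature
        )
        dossiers[cid] = CompoundDossier(
            id=cid,
            connectivity={"routeA": ra[cid], "routeB": rb[cid]},
            oligoscore=score_compound(targets, curation),
        )
    report["stages"]["merge_score"] = {"n_candidates": len(candidates)}

    # stage 4: screen
    kept = apply_blocklist(candidates, config.blocklist)
    if config.admet_path:
        admet = {r.id: r for r in read_admet_table(config.admet_path)}
        for cid in kept:
            dossiers[cid].admet = admet.get(cid)
        policy = FilterPolicy(ri_cutoff=config.ri_cutoff)
        passed, failed = admet_filter({c: dossiers[c] for c in kept}, policy)
    else:
        passed, failed = list(kept), {}
    ranked = rank_by_score(passed, dossiers)
    for i, cid in enumerate(ranked, start=1):
        dossiers[cid].rank = i
    shortlist = select_top(ranked, config.top_k)
    report["stages"]["screen"] = {
        "blocklisted": len(candidates) - len(kept),
        "admet_failed": {k: v for k, v in failed.items()},
        "n_ranked": len(ranked),
        "shortlist": shortlist,
    }

    with open(out / "ranked.tsv", "w", encoding="utf-8") as fh:
        fh.write("rank\tid\ttotal_score\n")
        for i, cid in enumerate(ranked, start=1):
            fh.write(f"{i}\t{cid}\t{dossiers[cid].total_score}\n")
    with open(out / "dossiers.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                cid: {
                    "total_score": d.total_score,
                    "process_scores": d.oligoscore.scores,
                    "rank": d.rank,
                    "fail_reasons": d.fail_reasons,
                }
                for cid, d in dossiers.items()
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return EXIT_OK, report


def write_fixtures(sim: SimConfig, out_dir: str | Path) -> dict[str, str]:
    """Generate and write every fixture file format to ``out_dir``.

    Output is byte-stable for a fixed configuration.  Returns a map of
    fixture kind -> path.
    """
    from oligoscreen.io import write_admet_table, write_compendium_wide, write_deg_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = gen_signature(sim)
    paths: dict[str, str] = {}

    write_signed_set(truth, out / "truth_signature.tsv")
    paths["truth_signature"] = str(out / "truth_signature.tsv")

    for i, table in enumerate(gen_deg_tables(sim, truth)):
        p = out / f"deg_table{i}.tsv"
        write_deg_table(table, p)
        paths[f"deg_table{i}"] = str(p)

    write_compendium_wide(gen_compendium(sim, truth, kind="compound"), out / "compendium.tsv")
    paths["compendium"] = str(out / "compendium.tsv")
    write_compendium_wide(gen_compendium(sim, truth, kind="gene"), out / "gene_compendium.tsv")
    paths["gene_compendium"] = str(out / "gene_compendium.tsv")

    ups = sorted(g for g, d in truth.entries.items() if d > 0)
    downs = sorted(g for g, d in truth.entries.items() if d < 0)
    half = sim.curation_size // 2
    curation = gen_curation(sim, promote=ups[:half], inhibit=downs[: sim.curation_size - half])
    curation.to_wide_frame().to_csv(out / "curation.csv", index=False)
    paths["curation"] = str(out / "curation.csv")

    write_admet_table(gen_admet(sim, doomed=()), out / "admet.csv")
    paths["admet"] = str(out / "admet.csv")

    with open(out / "sim_config.yaml", "w", encoding="utf-8") as fh:
        import yaml

        yaml.safe_dump(asdict(sim), fh, sort_keys=True)
    paths["sim_config"] = str(out / "sim_config.yaml")
    paths["planted"] = ",".join(planted_ids(sim))
    return paths


def run_synthetic_screen(
    sim: SimConfig,
    top_k: int | None = None,
    alpha: float = 0.05,
    null: str = "binomial",
    min_overlap: int = 5,
    fc_min: float = 1.2,
    p_max: float = 0.05,
    expr_floor: float = 0.5,
    doomed: tuple[str, ...] = (),
) -> dict:
    """Run the whole screen in memory on planted synthetic fixtures.

    Returns the shortlist, the planted ids, per-route results and the
    rebuilt signature so callers can measure recovery, ranking AUC and
    filter sensitivity/FDR directly.
    """
    truth = gen_signature(sim)
    tables = gen_deg_tables(sim, truth)
    table = apply_expression_floor(tables[0], expr_floor)
    signature = filter_degs(table, fc_min=fc_min, p_max=p_max, name="rebuilt")

    ups = sorted(g for g, d in truth.entries.items() if d > 0)
    downs = sorted(g for g, d in truth.entries.items() if d < 0)
    half = sim.curation_size // 2
    curation = gen_curation(sim, promote=ups[:half], inhibit=downs[: sim.curation_size - half])
    curated_query = curated_signed_set(curation)

    compendium = gen_compendium(sim, truth, kind="compound")
    kwargs = dict(alpha=alpha, null=null, seed=sim.seed, min_overlap=min_overlap)
    route_a = query_compendium(signature, compendium, **kwargs)
    route_b = query_compendium(curated_query, compendium, **kwargs)
    candidates = merge_candidates(route_a, route_b)

    dossiers: dict[str, CompoundDossier] = {}
    ra = {r.id: r for r in route_a}
    rb = {r.id: r for r in route_b}
    for cid in candidates:
        targets = compound_target_set(compendium.get(cid), curation, mode="all")
        dossiers[cid] = CompoundDossier(
            id=cid,
            connectivity={"routeA": ra[cid], "routeB": rb[cid]},
            oligoscore=score_compound(targets, curation),
        )
    admet = {r.id: r for r in gen_admet(sim, doomed=doomed)}
    for cid in candidates:
        dossiers[cid].admet = admet.get(cid)
    passed, failed = admet_filter(dossiers, FilterPolicy())
    ranked = rank_by_score(passed, dossiers)
    shortlist = select_top(ranked, sim.n_planted if top_k is None else top_k)
    return {
        "truth": truth,
        "signature": signature,
        "planted": planted_ids(sim),
        "route_a": route_a,
        "route_b": route_b,
        "candidates": candidates,
        "dossiers": dossiers,
        "admet_failed": failed,
        "ranked": ranked,
        "shortlist": shortlist,
    }
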