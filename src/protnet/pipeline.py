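"""Full-pipeline orchestration: config, seeding, logging and the run report.

The pipeline sequences the whole analysis: total-signal normalization, the four
pairwise differential-abundance comparisons, the differential-module PPI
network (score >= 0.15 on the high-confidence DAP tier), condition-level PPI
(score >= 0.6) and co-expression (|rho| >= 0.95) networks, centrality/hub
calling with randomized-network nulls, and term enrichment.  Inputs come
either from files or from the synthetic-study generator; every intermediate
table is written to the output directory and a manifest records versions,
seeds and thresholds, so rerunning an identical config reproduces identical
outputs.

A single global seed fans out to per-stage seeds through a fixed counter
scheme (stage k uses seed * 100 + k), so any stage can be rerun in isolation.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .enrichment import AnnotationMap, assign_functional_modules, hypergeometric_enrichment
from .networks import build_coexpression_network, filter_ppi_edges, largest_connected_component
from .nulls import null_centrality_test
from .quantify import (
    CountMatrix,
    detection_overlap,
    differential_abundance,
    normalize_total_signal,
    records_to_table,
    select_daps,
)
from .simulate import SimDesign, simulate_annotation, simulate_counts, simulate_network
from .topology import PPI_HUB_METRICS, call_hubs, centrality_table, scale_free_diagnostic

log = logging.getLogger("protnet")

STAGE_OFFSETS = {"counts": 1, "network": 2, "annotation": 3, "nulls": 4, "decoys": 5}


def stage_seed(base: int, stage: str) -> int:
    return (base * 100 + STAGE_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class Thresholds:
    score_min_modules: float = 0.15
    score_min_ppi: float = 0.6
    rho_min: float = 0.95
    rho_p_max: float = 0.01
    f_min: float = 5.0
    p_dap: float = 0.01
    p_highconf: float = 0.001
    fc_cap: float = 5.0
    hub_rule: str = "all"
    alpha_modules: float = 0.01
    alpha_profiles: float = 0.05

    def validate(self) -> None:
        for name in ("score_min_modules", "score_min_ppi", "rho_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("rho_p_max", "p_dap", "p_highconf", "alpha_modules", "alpha_profiles"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.f_min < 0 or self.fc_cap <= 0:
            raise ValueError("f_min must be >= 0 and fc_cap > 0")
        if self.hub_rule not in {"all", "any", "k_of"}:
            raise ValueError(f"unknown hub rule {self.hub_rule!r}")


@dataclass
class SimulationBlock:
    n_proteins: int = 3000
    n_network_nodes: int = 400
    n_bridges: int = 1
    attach_m: int = 2
    n_terms: int = 50
    planted_term_size: int = 60
    enrichment_fraction: float = 0.8
    n_coexpr_blocks: int = 2
    coexpr_block_size: int = 5
    effect_ln_fc: float = 2.0
    frac_dap: float = 0.05
    frac_exclusive: float = 0.02
    dispersion: float = 0.2
    baseline_mean: float = 20.0
    batch_sd: float = 0.1


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    counts: str | None = None
    design: str | None = None
    edges: str | None = None
    annotation: str | None = None
    simulation: SimulationBlock | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    null_model: str = "degree_preserving"
    null_ensemble: int = 100

    def validate(self) -> None:
        has_paths = any(p is not None for p in (self.counts, self.design, self.edges, self.annotation))
        if has_paths and self.simulation is not None:
            raise ValueError("config must give either input paths or a simulation block, not both")
        if not has_paths and self.simulation is None:
            raise ValueError("config gives neither input paths nor a simulation block")
        if has_paths:
            missing = [
                name
                for name, p in (
                    ("counts", self.counts),
                    ("design", self.design),
                    ("edges", self.edges),
                    ("annotation", self.annotation),
                )
                if p is None or not Path(p).exists()
            ]
            if missing:
                raise ValueError(f"missing input(s): {missing}")
        self.thresholds.validate()
        if self.null_ensemble < 1:
            raise ValueError("null_ensemble must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationBlock(**raw["simulation"])
        if "thresholds" in raw:
            raw["thresholds"] = Thresholds(**raw["thresholds"])
        return cls(**raw)


def _simulated_edge_table(g: nx.Graph, proteins: list[str], seed: int, n_decoys: int = 200):
    """Scored edge table whose high-confidence part is the simulated network.

    Network nodes are mapped onto protein ids; true edges get scores in
    [0.6, 1] with database/experimental evidence, decoy pairs get sub-threshold
    scores or text-mining-only evidence, so the score and evidence filters are
    both exercised.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes())
    if len(nodes) > len(proteins):
        raise ValueError("more network nodes than proteins")
    chosen = rng.choice(len(proteins), size=len(nodes), replace=False)
    mapping = {v: proteins[i] for v, i in zip(nodes, chosen)}
    rows = []
    for u, v in g.edges():
        a, b = sorted((mapping[u], mapping[v]))
        rows.append(
            {
                "protein_a": a,
                "protein_b": b,
                "combined_score": float(rng.uniform(0.6, 1.0)),
                "database": bool(rng.random() < 0.8),
                "experimental": True,
                "textmining": bool(rng.random() < 0.5),
            }
        )
    ids = [mapping[v] for v in nodes]
    for _ in range(n_decoys):
        a, b = rng.choice(ids, size=2, replace=False)
        a, b = sorted((a, b))
        low_score = rng.random() < 0.5
        rows.append(
            {
                "protein_a": a,
                "protein_b": b,
                "combined_score": float(rng.uniform(0.0, 0.59)) if low_score else float(rng.uniform(0.6, 1.0)),
                "database": False,
                "experimental": False if not low_score else bool(rng.random() < 0.5),
                "textmining": True,
            }
        )
    # decoys that duplicate a true edge must not outrank it
    table = pd.DataFrame(rows)
    return table, mapping


def _concat_tables(tables) -> pd.DataFrame:
    nonempty = [t for t in tables if not t.empty]
    if not nonempty:
        return next(iter(tables)).copy()
    return pd.concat(nonempty, ignore_index=True)


def run_full_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and return the run report (also written as JSON)."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    th = cfg.thresholds
    report: dict = {"seed": cfg.seed, "thresholds": asdict(th)}

    # ----- stage 0: inputs ------------------------------------------------
    truth = None
    if cfg.simulation is not None:
        sim = cfg.simulation
        design = SimDesign(n_proteins=sim.n_proteins, seed=stage_seed(cfg.seed, "counts"))
        matrix, truth = simulate_counts(
            design,
            baseline_mean=sim.baseline_mean,
            dispersion=sim.dispersion,
            effect_ln_fc=sim.effect_ln_fc,
            frac_dap=sim.frac_dap,
            frac_exclusive=sim.frac_exclusive,
            batch_sd=sim.batch_sd,
            n_coexpr_blocks=sim.n_coexpr_blocks,
            coexpr_block_size=sim.coexpr_block_size,
        )
        net, net_truth = simulate_network(
            sim.n_network_nodes, sim.attach_m, sim.n_bridges, seed=stage_seed(cfg.seed, "network")
        )
        edge_table, node_map = _simulated_edge_table(
            net, matrix.protein_ids, seed=stage_seed(cfg.seed, "decoys")
        )
        truth.hub_ids = {node_map[v] for v in net_truth.hub_ids}
        terms, ann_truth = simulate_annotation(
            set(matrix.protein_ids),
            n_terms=sim.n_terms,
            planted_term_size=sim.planted_term_size,
            dap_ids=set(truth.dap_ids),
            enrichment_fraction=sim.enrichment_fraction,
            seed=stage_seed(cfg.seed, "annotation"),
        )
        truth.enriched_terms = ann_truth.enriched_terms
        ann = AnnotationMap(terms, set(matrix.protein_ids))
        pio.write_count_matrix(matrix, out / "counts.tsv", out / "design.tsv")
        pio.write_edge_table(edge_table, out / "edges.tsv")
        pio.write_annotation(ann, out / "annotation.tsv")
        pio.write_truth(truth, out / "truth")
    else:
        matrix = pio.read_count_matrix(cfg.counts, cfg.design)
        edge_table = pio.read_edge_table(cfg.edges)
        ann = pio.read_annotation(cfg.annotation, universe=set(matrix.protein_ids))
    log.info("inputs: %d proteins x %d samples, %d edge rows, %d terms",
             len(matrix.protein_ids), len(matrix.sample_ids), len(edge_table), len(ann.terms))

    # ----- stage 1: normalization and differential abundance --------------
    norm = normalize_total_signal(matrix)
    conditions = norm.conditions
    pairs = [
        (conditions[0], conditions[1]),
        (conditions[0], conditions[2]),
        (conditions[2], conditions[3]),
        (conditions[1], conditions[3]),
    ] if len(conditions) == 4 else list(itertools.combinations(conditions, 2))
    all_records, dap_tables, highconf_tables = {}, {}, {}
    for pair in pairs:
        recs = differential_abundance(norm, pair)
        all_records[pair] = recs
        dap_tables[pair] = select_daps(recs, f_min=th.f_min, p_max=th.p_dap)
        highconf_tables[pair] = select_daps(recs, f_min=th.f_min, p_max=th.p_highconf)
        tag = f"{pair[0]}_vs_{pair[1]}".replace(" ", "_")
        records_to_table(recs).to_csv(out / f"differential_{tag}.tsv", sep="\t", index=False)
        log.info("comparison %s vs %s: %d tested, %d DAPs (p<=%g), %d high-confidence (p<=%g)",
                 *pair, len(recs), len(dap_tables[pair]), th.p_dap,
                 len(highconf_tables[pair]), th.p_highconf)
    dap_union = _concat_tables(dap_tables.values())
    highconf_union = _concat_tables(highconf_tables.values())
    dap_union.to_csv(out / "daps.tsv", sep="\t", index=False)
    highconf_union.to_csv(out / "daps_highconf.tsv", sep="\t", index=False)
    report["n_daps"] = int(dap_union["protein"].nunique())
    report["n_daps_highconf"] = int(highconf_union["protein"].nunique())
    report["daps_per_comparison"] = {
        f"{a} vs {b}": int(len(t)) for (a, b), t in dap_tables.items()
    }

    avspc = pd.DataFrame(
        {c: norm.counts[norm.samples_of(c)].mean(axis=1) for c in conditions}
    )
    avspc.to_csv(out / "avspc.tsv", sep="\t")

    # ----- stage 2: detection overlaps ------------------------------------
    overlap = detection_overlap(norm)
    report["detected_per_condition"] = {
        c: sum(n for key, n in overlap.regions.items() if c in key) for c in conditions
    }
    report["n_detected"] = int((matrix.counts.gt(0).any(axis=1)).sum())
    report["n_core"] = len(overlap.core)
    pd.DataFrame(
        [{"sets": "|".join(sorted(k)), "count": v} for k, v in sorted(
            overlap.regions.items(), key=lambda kv: sorted(kv[0]))]
    ).to_csv(out / "venn_regions.tsv", sep="\t", index=False)
    pd.DataFrame({"protein": sorted(overlap.core)}).to_csv(
        out / "core_proteins.tsv", sep="\t", index=False
    )

    # ----- stage 3: differential-module PPI network -----------------------
    highconf_ids = set(highconf_union["protein"])
    module_edges = edge_table[
        edge_table["protein_a"].isin(highconf_ids) & edge_table["protein_b"].isin(highconf_ids)
    ]
    module_net = (
        filter_ppi_edges(module_edges, th.score_min_modules)
        if len(module_edges)
        else nx.Graph()
    )
    pio.write_network_sif(module_net, out / "module_network.sif")
    report["module_network"] = {
        "nodes": module_net.number_of_nodes(), "edges": module_net.number_of_edges()
    }

    # ----- stage 4: condition PPI networks, topology, hubs, nulls ---------
    ppi_full = filter_ppi_edges(edge_table, th.score_min_ppi)
    ppi_reports = {}
    for cond in conditions:
        detected = set(matrix.counts.index[matrix.counts[matrix.samples_of(cond)].gt(0).any(axis=1)])
        sub = largest_connected_component(ppi_full.subgraph(detected & set(ppi_full.nodes)))
        if sub.number_of_nodes() < 3:
            ppi_reports[cond] = {"nodes": sub.number_of_nodes(), "skipped": True}
            continue
        ctab = centrality_table(sub)
        hubs = call_hubs(ctab, metrics=PPI_HUB_METRICS, rule=th.hub_rule)
        diag = scale_free_diagnostic(sub)
        null = null_centrality_test(
            sub, "mean_betweenness", M=cfg.null_ensemble,
            seed=stage_seed(cfg.seed, "nulls"), model=cfg.null_model,
        )
        tag = cond.replace(" ", "_")
        ctab.to_csv(out / f"centrality_ppi_{tag}.tsv", sep="\t")
        pio.write_network_sif(sub, out / f"ppi_{tag}.sif")
        pio.write_network_graphml(sub, out / f"ppi_{tag}.graphml")
        pd.DataFrame({"hub": sorted(map(str, hubs.hubs))}).to_csv(
            out / f"hubs_ppi_{tag}.tsv", sep="\t", index=False
        )
        ppi_reports[cond] = {
            "nodes": sub.number_of_nodes(),
            "edges": sub.number_of_edges(),
            "n_hubs": len(hubs.hubs),
            "scale_free": diag.verdict,
            "powerlaw_slope": diag.slope,
            "null_z_mean_betweenness": null.z_score,
            "null_p": null.empirical_p,
        }
        log.info("PPI %s: %d nodes, %d edges, %d hubs, %s", cond,
                 sub.number_of_nodes(), sub.number_of_edges(), len(hubs.hubs), diag.verdict)
    report["ppi"] = ppi_reports

    # ----- stage 5: co-expression networks --------------------------------
    coexpr_reports = {}
    for cond in conditions:
        g = build_coexpression_network(
            norm, cond, rho_min=th.rho_min, p_max=th.rho_p_max, core=overlap.core
        )
        ctab = centrality_table(g, include_centroid=False)
        hubs = call_hubs(ctab, metrics=("degree",), rule="all")
        tag = cond.replace(" ", "_")
        pio.write_network_edges_tsv(g, out / f"coexpr_{tag}.tsv")
        pd.DataFrame({"hub": sorted(map(str, hubs.hubs))}).to_csv(
            out / f"hubs_coexpr_{tag}.tsv", sep="\t", index=False
        )
        coexpr_reports[cond] = {
            "nodes": g.number_of_nodes(),
            "edges": g.number_of_edges(),
            "n_hubs": len(hubs.hubs),
        }
    report["coexpression"] = coexpr_reports

    # ----- stage 6: enrichment and functional modules ---------------------
    ann_detected = ann.restricted_to(
        set(matrix.counts.index[matrix.counts.gt(0).any(axis=1)])
    )
    dap_ids = set(dap_union["protein"]) & ann_detected.universe
    enr = hypergeometric_enrichment(dap_ids, ann_detected, alpha=th.alpha_modules)
    enr.to_csv(out / "enrichment_daps.tsv", sep="\t", index=False)
    modules = assign_functional_modules(dap_union, avspc, ann_detected, alpha=th.alpha_modules)
    pd.DataFrame(
        [
            {"term": mmod.term, "q": mmod.q_value, "n_members": len(mmod.members),
             "members": ",".join(mmod.members)}
            for mmod in modules
        ],
        columns=["term", "q", "n_members", "members"],
    ).to_csv(out / "functional_modules.tsv", sep="\t", index=False)
    report["n_modules"] = len(modules)

    # ----- stage 7: recovery vs planted truth -----------------------------
    if truth is not None:
        report["recovery"] = _recovery_report(
            truth, all_records, dap_tables, ppi_reports, enr, out, conditions, matrix, cfg
        )

    manifest = {
        "config": _config_dict(cfg),
        "stage_seeds": {k: stage_seed(cfg.seed, k) for k in STAGE_OFFSETS},
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    return report


def _recovery_report(truth, all_records, dap_tables, ppi_reports, enr, out, conditions, matrix, cfg):
    rec: dict = {}
    # DAP recall/precision on the planted comparison
    planted_pairs = {pair for d in truth.dap_ids.values() for pair in d}
    if planted_pairs:
        pair = next(iter(planted_pairs))
        table = dap_tables.get(pair)
        if table is None:  # planted pair may be reversed relative to tested pairs
            table = dap_tables.get((pair[1], pair[0]))
        if table is not None:
            called = set(table["protein"])
            planted = {p for p, d in truth.dap_ids.items() if pair in d}
            tp = len(called & planted)
            rec["dap_recall"] = tp / len(planted) if planted else float("nan")
            rec["dap_precision"] = tp / len(called) if called else float("nan")
    # exclusives: must carry lnFC exactly +/- cap in the comparison they enter
    ok = total = 0
    for recs in all_records.values():
        for r in recs:
            if r.protein_id in truth.exclusive_ids and truth.exclusive_ids[r.protein_id] in r.comparison:
                total += 1
                ok += abs(r.ln_fc) == cfg.thresholds.fc_cap
    rec["exclusive_rule_ok"] = (ok == total) if total else None
    # planted term rank
    if truth.enriched_terms:
        term = next(iter(truth.enriched_terms))
        ranked = list(enr["term"])
        rec["planted_term_rank"] = ranked.index(term) + 1 if term in ranked else None
    # planted bridge hubs
    if truth.hub_ids:
        called_hubs = set()
        for cond in conditions:
            path = out / f"hubs_ppi_{cond.replace(' ', '_')}.tsv"
            if path.exists():
                df = pd.read_csv(path, sep="\t")
                called_hubs |= set(df["hub"].astype(str))
        rec["hub_recall"] = len(truth.hub_ids & called_hubs) / len(truth.hub_ids)
    # co-expression block recovery: planted within-block pairs present as edges
    if truth.coexpr_blocks:
        got = want = 0
        for cond in conditions:
            path = out / f"coexpr_{cond.replace(' ', '_')}.tsv"
            edges = set()
            if path.exists():
                df = pd.read_csv(path, sep="\t")
                edges = {tuple(sorted((a, b))) for a, b in zip(df["protein_a"], df["protein_b"])}
            for block in truth.coexpr_blocks:
                members = sorted(block)
                for a, b in itertools.combinations(members, 2):
                    want += 1
                    got += tuple(sorted((a, b))) in edges
        rec["coexpr_block_edge_recall"] = got / want if want else None
    return rec


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    return d


def _versions() -> dict:
    import networkx
    import numpy
    import pandas
    import scipy

    from . import __version__

    return {
        "protnet": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "networkx": networkx.__version__,
    }
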