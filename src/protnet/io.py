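"""Readers and writers for the plain-text formats shared by all stages.

Count matrices, sample designs, scored edge tables, correlation records and
enrichment tables travel as TSV; annotations as two-column TSV or GMT;
networks as SIF ("A pp B") plus edge-table TSV and GraphML; dendrograms as
Newick.  Writers emit exactly the dialects the readers accept, so every type
round-trips.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .enrichment import AnnotationMap
from .quantify import DESIGN_COLUMNS, CountMatrix


# ---------------------------------------------------------------------------
# Count matrices and designs
# ---------------------------------------------------------------------------

def write_count_matrix(m: CountMatrix, counts_path, design_path) -> None:
    counts = m.counts.copy()
    counts.index.name = "protein"
    counts.to_csv(counts_path, sep="\t")
    design = m.design.copy()
    design.index.name = "sample"
    design.to_csv(design_path, sep="\t")


def read_count_matrix(counts_path, design_path, normalized: bool = False) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    dupes = counts.index[counts.index.duplicated()].unique()
    if len(dupes):
        lines = [i + 2 for i, pid in enumerate(counts.index) if pid in set(dupes)]
        raise ValueError(f"duplicate protein id(s) {list(dupes)} at line(s) {lines}")
    if (counts.to_numpy() < 0).any():
        bad = counts.index[(counts < 0).any(axis=1)]
        raise ValueError(f"negative counts for protein(s): {list(bad)}")
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design file missing column(s): {missing}")
    unknown = set(design.index) - set(counts.columns)
    if unknown:
        raise ValueError(f"design references unknown sample(s): {sorted(unknown)}")
    return CountMatrix(counts, design, normalized=normalized)


# ---------------------------------------------------------------------------
# Edge tables and networks
# ---------------------------------------------------------------------------

def write_edge_table(t: pd.DataFrame, path) -> None:
    t.to_csv(path, sep="\t", index=False)


def read_edge_table(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    required = ("protein_a", "protein_b", "combined_score")
    missing = [c for c in required if c not in t.columns]
    if missing:
        raise ValueError(f"edge table missing column(s): {missing}")
    bad = t.index[t["combined_score"].isna()]
    if len(bad):
        raise ValueError(f"malformed combined_score at row(s): {[i + 2 for i in bad]}")
    for col in t.columns:
        if t[col].dtype == object and set(t[col].dropna().unique()) <= {"True", "False"}:
            t[col] = t[col] == "True"
    return t


def write_network_sif(g: nx.Graph, path, relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for u, v in sorted((tuple(sorted((str(a), str(b)))) for a, b in g.edges())):
            fh.write(f"{u}\t{relation}\t{v}\n")
        for v in sorted(str(n) for n in nx.isolates(g)):
            fh.write(f"{v}\n")


def read_network_sif(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1 and parts[0]:
                g.add_node(parts[0])
            elif len(parts) >= 3:
                g.add_edge(parts[0], parts[2])
    return g


def write_network_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def write_network_edges_tsv(g: nx.Graph, path) -> None:
    rows = []
    for u, v, data in g.edges(data=True):
        a, b = sorted((str(u), str(v)))
        row = {"protein_a": a, "protein_b": b}
        row.update(data)
        rows.append(row)
    pd.DataFrame(rows).sort_values(["protein_a", "protein_b"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def read_annotation(path, universe: set | None = None) -> AnnotationMap:
    """Two-column TSV (protein, term) or GMT (term, description, members...).

    The universe defaults to the union of annotated proteins.
    """
    path = Path(path)
    terms: dict[str, set] = {}
    if path.suffix.lower() == ".gmt":
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                terms.setdefault(parts[0], set()).update(p for p in parts[2:] if p)
    else:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 2:
            raise ValueError("annotation TSV needs two columns: protein, term")
        for protein, term in zip(df[0], df[1]):
            terms.setdefault(str(term), set()).add(str(protein))
    annotated = set().union(*terms.values()) if terms else set()
    return AnnotationMap(terms, universe if universe is not None else annotated)


def write_annotation(ann: AnnotationMap, path) -> None:
    rows = [(p, t) for t, members in sorted(ann.terms.items()) for p in sorted(members)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def write_annotation_gmt(ann: AnnotationMap, path) -> None:
    with open(path, "w") as fh:
        for t, members in sorted(ann.terms.items()):
            fh.write("\t".join([t, ""] + sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# Truth tables
# ---------------------------------------------------------------------------

def write_truth(truth, directory) -> None:
    """Flat TSV per planted category, under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = [
        {"protein": p, "comparison": f"{a} vs {b}", "true_lnFC": v}
        for p, d in truth.dap_ids.items()
        for (a, b), v in d.items()
    ]
    pd.DataFrame(rows, columns=["protein", "comparison", "true_lnFC"]).to_csv(
        directory / "truth_daps.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"protein": p, "zeroed_condition": c} for p, c in truth.exclusive_ids.items()],
        columns=["protein", "zeroed_condition"],
    ).to_csv(directory / "truth_exclusives.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"block": i, "protein": p}
            for i, block in enumerate(truth.coexpr_blocks)
            for p in sorted(block)
        ],
        columns=["block", "protein"],
    ).to_csv(directory / "truth_coexpr_blocks.tsv", sep="\t", index=False)
    pd.DataFrame({"hub": sorted(truth.hub_ids)}).to_csv(
        directory / "truth_hubs.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"term": t, "fraction": f} for t, f in truth.enriched_terms.items()],
        columns=["term", "fraction"],
    ).to_csv(directory / "truth_enriched_terms.tsv", sep="\t", index=False)
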