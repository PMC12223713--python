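"""Condition-specific PPI and co-expression network construction.

PPI networks are built from a scored, evidence-flagged edge table (the column
layout of a STRING download): edges are kept when the combined confidence score
passes a threshold (0.15 for differential-module networks, 0.6 for
condition-level models) and the interaction is annotated in databases and/or
experimentally determined.  Co-expression networks connect proteins whose
abundance profiles across one condition's replicates have Spearman
|rho| >= 0.95 with p <= 0.01, computed over the core set of proteins detected
in every sample of the study.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats as st

from .quantify import CountMatrix, detection_overlap

EDGE_COLUMNS = ("protein_a", "protein_b", "combined_score")
EVIDENCE_COLUMNS = ("database", "experimental")


# ---------------------------------------------------------------------------
# PPI edge filtering
# ---------------------------------------------------------------------------

def clean_edge_table(t: pd.DataFrame) -> pd.DataFrame:
    """Drop self-edges and collapse unordered duplicates keeping the max score.

    Evidence flags of collapsed duplicates are OR-combined.
    """
    missing = [c for c in EDGE_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"edge table missing columns: {missing}")
    bad = t.index[(t["combined_score"] < 0) | (t["combined_score"] > 1)]
    if len(bad):
        raise ValueError(f"combined_score outside [0,1] at row(s): {list(bad)}")
    t = t[t["protein_a"] != t["protein_b"]].copy()
    key = [tuple(sorted(p)) for p in zip(t["protein_a"], t["protein_b"])]
    t["_key"] = key
    flag_cols = [c for c in t.columns if t[c].dtype == bool]
    agg = {"combined_score": "max", **{c: "any" for c in flag_cols}}
    out = t.groupby("_key", sort=True).agg(agg).reset_index()
    out["protein_a"] = [k[0] for k in out["_key"]]
    out["protein_b"] = [k[1] for k in out["_key"]]
    return out.drop(columns="_key")[
        ["protein_a", "protein_b", "combined_score", *flag_cols]
    ]


def filter_ppi_edges(
    t: pd.DataFrame,
    score_min: float,
    require_evidence: tuple[str, ...] = EVIDENCE_COLUMNS,
) -> nx.Graph:
    """Build a simple undirected PPI graph from a scored edge table.

    Keeps edges with combined_score >= score_min whose evidence satisfies at
    least one of the ``require_evidence`` channels (default: annotated in
    databases and/or experimentally determined).  Nodes with no surviving edge
    are dropped.
    """
    if not 0 <= score_min <= 1:
        raise ValueError("score_min must be in [0, 1]")
    t = clean_edge_table(t)
    keep = t["combined_score"] >= score_min
    if require_evidence:
        missing = [c for c in require_evidence if c not in t.columns]
        if missing:
            raise ValueError(f"evidence column(s) absent: {missing}")
        ev = np.zeros(len(t), dtype=bool)
        for c in require_evidence:
            ev |= t[c].to_numpy(dtype=bool)
        keep &= ev
    g = nx.Graph()
    for _, row in t[keep].iterrows():
        g.add_edge(row["protein_a"], row["protein_b"], score=float(row["combined_score"]))
    return g


def largest_connected_component(g: nx.Graph) -> nx.Graph:
    """The component with most nodes; ties go to the one holding the smallest id."""
    if g.number_of_nodes() == 0:
        return g.copy()
    comps = list(nx.connected_components(g))
    top = max(len(c) for c in comps)
    tied = [c for c in comps if len(c) == top]
    best = min(tied, key=lambda c: min(map(str, c)))
    return g.subgraph(best).copy()


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationRecord:
    pair: tuple[str, str]
    rho: float
    p_value: float
    n: int
    valid: bool = True  # False when a profile is constant (rho undefined)


def _spearman_p(rho: float, n: int) -> float:
    """Two-sided p from the t approximation with n-2 df; |rho| = 1 reports 0."""
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * st.t.sf(abs(t), n - 2))


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float, rng=None) -> float:
    """Permutation p for |rho| >= |rho_obs|: exhaustive for n <= 7, else Monte Carlo."""
    n = len(x)
    rx = st.rankdata(x)
    ry = st.rankdata(y)

    def rho_of(perm):
        r = np.corrcoef(rx, ry[perm])[0, 1]
        return r

    if n <= 7:
        perms = itertools.permutations(range(n))
        hits = total = 0
        for p in perms:
            total += 1
            if abs(rho_of(np.array(p))) >= abs(rho_obs) - 1e-12:
                hits += 1
        return hits / total
    rng = np.random.default_rng(rng)
    m = 20000
    hits = 1
    for _ in range(m):
        if abs(rho_of(rng.permutation(n))) >= abs(rho_obs) - 1e-12:
            hits += 1
    return hits / (m + 1)


def spearman_correlation(
    x, y, pair: tuple[str, str] = ("x", "y"), method: str = "t", seed: int | None = None
) -> CorrelationRecord:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of average ranks (ties averaged).  The
    default p uses the t approximation t = rho*sqrt((n-2)/(1-rho^2)) with
    n-2 df; ``method="permutation"`` gives an exact/Monte-Carlo permutation p
    for small n.  Constant input yields an invalid record (rho undefined),
    excluded downstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n or n < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationRecord(pair, float("nan"), 1.0, n, valid=False)
    rho = float(np.corrcoef(st.rankdata(x), st.rankdata(y))[0, 1])
    if method == "permutation":
        p = _exact_spearman_p(x, y, rho, rng=seed)
    else:
        p = _spearman_p(rho, n)
    return CorrelationRecord(pair, rho, p, n)


# ---------------------------------------------------------------------------
# Co-expression networks
# ---------------------------------------------------------------------------

def build_coexpression_network(
    m: CountMatrix,
    condition: str,
    rho_min: float = 0.95,
    p_max: float = 0.01,
    core: set | None = None,
) -> nx.Graph:
    """Per-condition Spearman co-expression network over the all-sample core set.

    Nodes are the core proteins (detected in every sample of the full study,
    or the supplied ``core``); proteins (i, j) are joined when their profiles
    across this condition's replicates have |rho| >= rho_min with p <= p_max.
    Edge weight is the signed rho.  Constant profiles never gain edges.

    At the design's n = 9 replicates the p <= 0.01 condition is implied by
    |rho| >= 0.95 (t ~ 8.05, p ~ 4e-5), so the score threshold binds.
    """
    if core is None:
        core = detection_overlap(m).core
    if not core:
        raise ValueError("core protein set is empty")
    samples = m.samples_of(condition)
    if len(samples) < 4:
        raise ValueError(f"condition {condition!r} has fewer than 4 samples")
    proteins = [p for p in m.counts.index if p in core]
    x = m.counts.loc[proteins, samples].to_numpy(dtype=float)
    n = x.shape[1]

    ranks = np.apply_along_axis(st.rankdata, 1, x)
    constant = np.ptp(x, axis=1) == 0
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    norms[norms == 0] = 1.0
    unit = centered / norms[:, None]
    rho = unit @ unit.T
    np.clip(rho, -1.0, 1.0, out=rho)

    g = nx.Graph()
    g.add_nodes_from(proteins)
    iu, ju = np.triu_indices(len(proteins), k=1)
    strong = np.abs(rho[iu, ju]) >= rho_min
    for i, j in zip(iu[strong], ju[strong]):
        if constant[i] or constant[j]:
            continue
        r = float(rho[i, j])
        if _spearman_p(r, n) <= p_max:
            g.add_edge(proteins[i], proteins[j], weight=r)
    return g
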