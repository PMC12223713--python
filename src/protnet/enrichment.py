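"""Functional-term enrichment and module grouping.

Two enrichment procedures are provided, matching the two stages of the
analysis: (1) hypergeometric over-representation with Benjamini-Hochberg FDR
control (significance q <= 0.01) for grouping differentially abundant proteins
(DAPs) into functional modules, and (2) per-replicate one-sided Fisher exact
tests with Bonferroni correction (p <= 0.05) for term profiles, which are then
compared across conditions with the same two-class F criterion used for
protein abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .quantify import scale_to_0_100, two_group_f


@dataclass
class AnnotationMap:
    """term id -> protein set, with an explicit universe.

    Every annotated protein must belong to the universe; empty terms are
    rejected.
    """

    terms: dict[str, set]
    universe: set

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("universe is empty")
        for term, members in self.terms.items():
            if not members:
                raise ValueError(f"term {term!r} is empty")
            stray = members - self.universe
            if stray:
                raise ValueError(f"term {term!r} annotates non-universe proteins: {sorted(stray)[:5]}")

    def restricted_to(self, detected: set) -> "AnnotationMap":
        """Intersect the universe (and every term) with a detected proteome."""
        universe = self.universe & detected
        terms = {t: m & universe for t, m in self.terms.items()}
        return AnnotationMap({t: m for t, m in terms.items() if m}, universe)


ENRICHMENT_COLUMNS = ["term", "k", "K", "n", "N", "p", "adjusted", "significant"]


def hypergeometric_enrichment(
    query: set, ann: AnnotationMap, alpha: float = 0.01
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with BH FDR across terms.

    For each term, p = P[X >= k] with X ~ Hypergeom(N, K, n): N universe size,
    K term size, n query size, k overlap.  Records with BH q <= alpha are
    flagged significant.  Ordered by q then p.
    """
    query = set(query) & ann.universe
    if not query:
        raise ValueError("query does not intersect the annotation universe")
    N, n = len(ann.universe), len(query)
    rows = []
    for term, members in ann.terms.items():
        K = len(members)
        k = len(members & query)
        p = float(st.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    out["adjusted"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["adjusted"] <= alpha
    return out.sort_values(["adjusted", "p"], kind="stable").reset_index(drop=True)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p-value order)."""
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(p: np.ndarray) -> np.ndarray:
    return np.minimum(np.asarray(p, dtype=float) * len(p), 1.0)


def fisher_term_profiles(
    per_replicate_queries: list[set], ann: AnnotationMap, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-replicate one-sided Fisher enrichment with Bonferroni correction.

    For each replicate's protein set, every term is tested on the 2x2 table
    (in query vs rest) x (annotated vs not), one-sided toward enrichment; the
    per-replicate p-vector is Bonferroni-adjusted across terms and terms with
    adjusted p <= alpha are flagged.  Degenerate tables (an empty margin) are
    skipped with a flag.  Columns: replicate, term, k, K, n, N, p, adjusted,
    significant, skipped.
    """
    if not per_replicate_queries:
        raise ValueError("need at least one replicate query")
    N = len(ann.universe)
    frames = []
    for r, query in enumerate(per_replicate_queries):
        query = set(query) & ann.universe
        n = len(query)
        rows = []
        for term, members in ann.terms.items():
            K = len(members)
            k = len(members & query)
            skipped = n == 0 or n == N or K == 0 or K == N
            if skipped:
                p = np.nan
            else:
                table = [[k, K - k], [n - k, N - K - (n - k)]]
                p = float(st.fisher_exact(table, alternative="greater")[1])
            rows.append((r, term, k, K, n, N, p, skipped))
        df = pd.DataFrame(
            rows, columns=["replicate", "term", "k", "K", "n", "N", "p", "skipped"]
        )
        tested = ~df["skipped"]
        df["adjusted"] = np.nan
        df.loc[tested, "adjusted"] = bonferroni_adjust(df.loc[tested, "p"].to_numpy())
        df["significant"] = df["adjusted"] <= alpha
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def term_score_matrix(
    per_replicate_queries: list[set],
    ann: AnnotationMap,
    encoding: str = "neglog10p",
) -> pd.DataFrame:
    """Replicates x terms score matrix for the profile comparison.

    ``neglog10p`` (default) scores each cell as -log10 of the raw one-sided
    Fisher p for that replicate and term; ``indicator`` scores 1 when the term
    is represented in the replicate's query, else 0.
    """
    table = fisher_term_profiles(per_replicate_queries, ann, alpha=1.0)
    terms = list(ann.terms)
    mat = pd.DataFrame(0.0, index=range(len(per_replicate_queries)), columns=terms)
    for _, row in table.iterrows():
        if encoding == "indicator":
            mat.loc[row["replicate"], row["term"]] = float(row["k"] > 0)
        elif encoding == "neglog10p":
            p = row["p"]
            mat.loc[row["replicate"], row["term"]] = 0.0 if row["skipped"] else -np.log10(max(p, 1e-300))
        else:
            raise ValueError(f"unknown encoding {encoding!r}")
    return mat


def compare_term_profiles_lda(
    term_matrix: pd.DataFrame,
    groups: list[str],
    f_min: float = 5.0,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Two-class F comparison of per-replicate term-enrichment profiles.

    For each term the same two-group F statistic used for protein abundances
    is applied to the term's scores split by ``groups`` (exactly two distinct
    labels, >= 2 replicates each).  Perfect separation with zero within-group
    variance reports the +inf sentinel and is retained; constant columns give
    F = 0 and are retained as non-significant.  Returns the full table with a
    ``retained`` flag for F >= f_min and p <= p_max.
    """
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValueError("exactly two group labels required")
    groups = np.asarray(groups)
    rows = []
    for term in term_matrix.columns:
        col = term_matrix[term].to_numpy(dtype=float)
        f, p = two_group_f(col[groups == labels[0]], col[groups == labels[1]])
        rows.append((term, f, p, f >= f_min and p <= p_max))
    return pd.DataFrame(rows, columns=["term", "F", "p", "retained"])


# ---------------------------------------------------------------------------
# Functional modules
# ---------------------------------------------------------------------------

@dataclass
class FunctionalModule:
    term: str
    q_value: float
    members: list[str]
    profiles: pd.DataFrame = field(repr=False)  # member x condition, scaled 0-100
    direction: dict[str, str] = field(default_factory=dict)  # member -> up|down


def assign_functional_modules(
    daps: pd.DataFrame,
    avspc: pd.DataFrame,
    ann: AnnotationMap,
    alpha: float = 0.01,
) -> list[FunctionalModule]:
    """Group DAPs into functional modules via hypergeometric term enrichment.

    Modules are the terms significant (BH q <= alpha) for the DAP set; each
    lists its member DAPs with their per-condition avSpC profile scaled to
    0-100 and an up/down direction from the sign of the ln fold-change (a
    protein may belong to several modules).  ``avspc`` is a protein x
    condition table of average normalized counts.  No significant term yields
    an empty list (valid).
    """
    if daps.empty:
        raise ValueError("DAP table is empty")
    dap_ids = set(daps["protein"])
    enr = hypergeometric_enrichment(dap_ids, ann, alpha=alpha)
    direction_all = {
        p: "up" if lfc > 0 else "down"
        for p, lfc in zip(daps["protein"], daps["lnFC"])
    }
    modules = []
    for _, row in enr[enr["significant"]].iterrows():
        members = sorted(ann.terms[row["term"]] & dap_ids)
        prof = avspc.loc[[p for p in members if p in avspc.index]]
        scaled = prof.apply(lambda r: pd.Series(scale_to_0_100(r), index=prof.columns), axis=1)
        modules.append(
            FunctionalModule(
                term=row["term"],
                q_value=float(row["adjusted"]),
                members=members,
                profiles=scaled,
                direction={p: direction_all.get(p, "up") for p in members},
            )
        )
    return modules
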