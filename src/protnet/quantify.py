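"""Label-free quantification from spectral counts.

Spectral counts (SpC, the number of MS/MS spectra matched to a protein) are a
semi-quantitative proxy for protein abundance.  This module normalizes a
protein x sample count matrix by total signal, calls differentially abundant
proteins (DAPs) between pairs of conditions with a two-class linear-discriminant
criterion (which for two groups reduces to the one-way F statistic, the square
of the pooled two-sample t), computes natural-log fold changes capped at +/-5
with condition-exclusive proteins pinned to exactly +/-5, clusters DAP profiles
with Ward linkage on Euclidean distances, and computes detection overlaps
(Venn regions and the all-sample core set used for co-expression).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st

DESIGN_COLUMNS = ("condition", "batch", "replicate")

#: Saturation value for the natural-log fold change; condition-exclusive
#: proteins are assigned exactly +/-FC_CAP.
FC_CAP = 5.0


# ---------------------------------------------------------------------------
# Count matrix container
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Protein x sample spectral counts plus the sample design.

    Parameters
    ----------
    counts
        DataFrame with protein ids as index and sample ids as columns.
        Nonnegative; integer when raw, real after normalization.
    design
        DataFrame indexed by sample id with columns ``condition``, ``batch``,
        ``replicate``, covering every sample of ``counts`` exactly once.
    normalized
        Whether total-signal normalization has been applied.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate protein ids: {list(dupes)}")
        if self.counts.columns.duplicated().any():
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dupes)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing:
            raise ValueError(f"design missing columns: {missing}")
        if set(self.design.index) != set(self.counts.columns):
            extra = set(self.design.index) - set(self.counts.columns)
            absent = set(self.counts.columns) - set(self.design.index)
            raise ValueError(
                f"design/sample mismatch: design-only={sorted(extra)}, "
                f"matrix-only={sorted(absent)}"
            )
        # align design row order to column order
        self.design = self.design.loc[list(self.counts.columns)]

    @property
    def protein_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.design["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    def samples_of(self, condition: str) -> list[str]:
        sel = self.design.index[self.design["condition"] == condition]
        if len(sel) == 0:
            raise ValueError(f"condition not in design: {condition!r}")
        return list(sel)

    def subset_conditions(self, conditions: list[str]) -> "CountMatrix":
        samples = [s for c in conditions for s in self.samples_of(c)]
        return CountMatrix(
            self.counts[samples].copy(), self.design.loc[samples].copy(), self.normalized
        )


def normalize_total_signal(m: CountMatrix) -> CountMatrix:
    """Total-signal normalization: nSpC(i,j) = SpC(i,j) * mean(total) / total(j).

    Every normalized column sums to the mean raw sample total, so column totals
    are equal across samples afterwards.  Protein and sample order preserved.
    """
    if m.normalized:
        raise ValueError("matrix already normalized")
    totals = m.counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero)}")
    factors = totals.mean() / totals
    return replace(m, counts=m.counts * factors, normalized=True)


def scale_to_0_100(values) -> np.ndarray:
    """Scale a per-condition avSpC vector so its maximum maps to 100.

    An all-zero vector returns all zeros (no error).
    """
    v = np.asarray(values, dtype=float)
    top = v.max(initial=0.0)
    if top == 0:
        return np.zeros_like(v)
    return 100.0 * v / top


# ---------------------------------------------------------------------------
# Differential abundance
# ---------------------------------------------------------------------------

@dataclass
class DifferentialRecord:
    protein_id: str
    comparison: tuple[str, str]
    av_a: float
    av_b: float
    f_ratio: float
    p_value: float
    ln_fc: float
    exclusive: str = "none"  # none | a_only | b_only


def fold_change(av_a: float, av_b: float) -> float:
    """ln(av_a / av_b), clipped to [-FC_CAP, FC_CAP]; exclusives get exactly +/-FC_CAP.

    Antisymmetric under argument swap.  Both arguments zero is a contract
    violation (such proteins are dropped before testing).
    """
    if av_a < 0 or av_b < 0:
        raise ValueError("averages must be nonnegative")
    if av_a == 0 and av_b == 0:
        raise ValueError("fold change undefined for two zero averages")
    if av_b == 0:
        return FC_CAP
    if av_a == 0:
        return -FC_CAP
    return float(np.clip(np.log(av_a) - np.log(av_b), -FC_CAP, FC_CAP))


def two_group_f(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-group one-way F statistic and its p-value at df (1, n_a + n_b - 2).

    For two classes the linear-discriminant F-ratio criterion reduces to this
    statistic, which equals the square of the pooled-variance t statistic.
    Degenerate cases: zero pooled variance with equal means gives (0, 1);
    zero pooled variance with unequal means (perfect separation) gives
    (inf, 0) as a documented sentinel.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 replicates")
    df2 = na + nb - 2
    ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    delta = a.mean() - b.mean()
    if ss == 0:
        if delta == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (na * nb / (na + nb)) * delta**2 / (ss / df2)
    return float(f), float(st.f.sf(f, 1, df2))


def differential_abundance(
    m: CountMatrix, pair: tuple[str, str]
) -> list[DifferentialRecord]:
    """Per-protein two-group F test between the two conditions of ``pair``.

    Requires a normalized matrix.  Proteins with zero counts in every sample of
    both groups are dropped.  Proteins with zero counts in exactly one group
    are flagged exclusive and receive ln fold-change exactly +/-FC_CAP.
    """
    if not m.normalized:
        raise ValueError("normalize the matrix before testing")
    cond_a, cond_b = pair
    xa = m.counts[m.samples_of(cond_a)].to_numpy(dtype=float)
    xb = m.counts[m.samples_of(cond_b)].to_numpy(dtype=float)
    if xa.shape[1] < 2 or xb.shape[1] < 2:
        raise ValueError("both conditions need >= 2 replicates")

    na, nb = xa.shape[1], xb.shape[1]
    df2 = na + nb - 2
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    delta = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (na * nb / (na + nb)) * delta**2 / (ss / df2)
    f = np.where(ss == 0, np.where(delta == 0, 0.0, np.inf), f)
    p = np.where(np.isinf(f), 0.0, np.where(f == 0, 1.0, st.f.sf(np.where(np.isfinite(f), f, 1.0), 1, df2)))

    zero_a = (xa == 0).all(axis=1)
    zero_b = (xb == 0).all(axis=1)
    records = []
    for i, pid in enumerate(m.counts.index):
        if zero_a[i] and zero_b[i]:
            continue
        if zero_a[i]:
            excl, lfc = "b_only", -FC_CAP
        elif zero_b[i]:
            excl, lfc = "a_only", FC_CAP
        else:
            excl, lfc = "none", fold_change(mean_a[i], mean_b[i])
        records.append(
            DifferentialRecord(
                protein_id=pid,
                comparison=(cond_a, cond_b),
                av_a=float(mean_a[i]),
                av_b=float(mean_b[i]),
                f_ratio=float(f[i]),
                p_value=float(p[i]),
                ln_fc=float(lfc),
                exclusive=excl,
            )
        )
    return records


def select_daps(
    records: list[DifferentialRecord], f_min: float = 5.0, p_max: float = 0.01
) -> pd.DataFrame:
    """Keep records with f_ratio >= f_min and p <= p_max as a DifferentialTable.

    The stricter p <= 0.001 tier used for network-module input is obtained by
    passing ``p_max=0.001``.
    """
    kept = [r for r in records if r.f_ratio >= f_min and r.p_value <= p_max]
    return records_to_table(kept)


def records_to_table(records: list[DifferentialRecord]) -> pd.DataFrame:
    rows = [
        {
            "protein": r.protein_id,
            "comparison": f"{r.comparison[0]} vs {r.comparison[1]}",
            "avA": r.av_a,
            "avB": r.av_b,
            "F": r.f_ratio,
            "p": r.p_value,
            "lnFC": r.ln_fc,
            "exclusive": r.exclusive,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["protein", "comparison", "avA", "avB", "F", "p", "lnFC", "exclusive"]
    )


# ---------------------------------------------------------------------------
# Profile clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomerative clustering result: leaf labels plus a scipy linkage matrix."""

    labels: list[str]
    linkage: np.ndarray | None  # None for a single-leaf tree

    @property
    def heights(self) -> np.ndarray:
        if self.linkage is None:
            return np.array([])
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Serialize as a Newick string with branch lengths from merge heights."""
        if self.linkage is None:
            return f"{self.labels[0]};"
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[n + i] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
            height[n + i] = h
        return node[n + len(self.linkage) - 1] + ";"


def cluster_profiles(m: CountMatrix) -> Dendrogram:
    """Ward-linkage hierarchical clustering of protein profiles (Euclidean distance).

    Merge heights are non-decreasing (Ward linkage is reducible).  A single
    protein yields a single-leaf tree with no merges.
    """
    labels = list(m.counts.index)
    if len(labels) == 0:
        raise ValueError("no proteins to cluster")
    if len(labels) == 1:
        return Dendrogram(labels, None)
    z = sch.linkage(m.counts.to_numpy(dtype=float), method="ward", metric="euclidean")
    return Dendrogram(labels, z)


# ---------------------------------------------------------------------------
# Detection overlaps
# ---------------------------------------------------------------------------

@dataclass
class DetectionOverlap:
    """Venn region cardinalities for up to 4 detection sets, plus the core set."""

    set_names: list[str]
    regions: dict[frozenset, int] = field(default_factory=dict)
    core: set = field(default_factory=set)

    def region(self, *names: str) -> int:
        """Cardinality of the exclusive Venn region for exactly these sets."""
        return self.regions.get(frozenset(names), 0)


def detection_overlap(
    m: CountMatrix, by: str = "condition", groups: dict[str, set] | None = None
) -> DetectionOverlap:
    """Detection overlaps between sample groups and the all-sample core set.

    Detection is count > 0.  A group's detection set is the union of per-sample
    detections; the core set contains proteins detected in every individual
    sample of the whole matrix (the universe for co-expression).  ``groups``
    may supply arbitrary named protein sets instead (up to 4 for Venn regions).
    """
    if groups is None:
        groups = {}
        for cond in m.conditions if by == "condition" else sorted(set(m.design[by])):
            sel = m.design.index[m.design[by] == cond]
            detected = m.counts[list(sel)].gt(0).any(axis=1)
            groups[cond] = set(m.counts.index[detected])
    if len(groups) > 4:
        raise ValueError("Venn regions supported for at most 4 sets")
    names = list(groups)
    regions: dict[frozenset, int] = {}
    universe = set().union(*groups.values()) if groups else set()
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(groups[c] for c in combo))
            outside = set().union(*(groups[c] for c in names if c not in combo), set())
            regions[frozenset(combo)] = len(inside - outside)
    core = set(m.counts.index[m.counts.gt(0).all(axis=1)])
    out = DetectionOverlap(set_names=names, regions=regions, core=core)
    out.universe = universe  # type: ignore[attr-defined]
    return out
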