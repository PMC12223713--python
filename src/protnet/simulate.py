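"""Synthetic study generator with recorded ground truth.

Emulates the statistical shape of a label-free shotgun proteomics study of
four conditions (wild type and a retrograde-signalling mutant, each with and
without a chloroplast translation inhibitor), 9 replicates per condition drawn
from 3 acquisition batches: over-dispersed heavy-tailed spectral counts with
per-sample library-size factors and per-batch multiplicative effects, planted
differentially abundant proteins (including condition-exclusive ones), planted
co-expression blocks driven by latent monotone factors, scale-free interaction
networks with planted bridge nodes, and annotation maps with a planted
over-represented term.  Everything planted is recorded exactly in
:class:`SimTruth`, so downstream recovery tests never re-derive the truth.

The count model is negative binomial (mean/dispersion parameterization,
variance = mu + dispersion * mu^2), the standard over-dispersed choice for
spectral counts.  All generators are pure functions of their inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .quantify import CountMatrix

DEFAULT_CONDITIONS = ("Col-0", "Col-0+Lin", "gun1", "gun1+Lin")


@dataclass
class SimDesign:
    """Sample design of the simulated study."""

    n_proteins: int
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    replicates_per_condition: int = 9
    batches: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("need at least one protein")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if self.replicates_per_condition < 1 or self.batches < 1:
            raise ValueError("replicates and batches must be positive")
        if self.replicates_per_condition % self.batches != 0:
            raise ValueError(
                f"{self.replicates_per_condition} replicates cannot be allocated "
                f"evenly across {self.batches} batches"
            )

    def design_frame(self) -> pd.DataFrame:
        rows = []
        for cond in self.conditions:
            for r in range(self.replicates_per_condition):
                rows.append(
                    {
                        "sample": f"{cond}_r{r + 1}",
                        "condition": cond,
                        "batch": r % self.batches + 1,
                        "replicate": r + 1,
                    }
                )
        return pd.DataFrame(rows).set_index("sample")


@dataclass
class SimTruth:
    """Exact record of everything planted by a generator."""

    dap_ids: dict = field(default_factory=dict)  # protein -> {comparison: true lnFC}
    exclusive_ids: dict = field(default_factory=dict)  # protein -> zeroed condition
    coexpr_blocks: list = field(default_factory=list)  # list of protein sets
    hub_ids: set = field(default_factory=set)
    enriched_terms: dict = field(default_factory=dict)  # term -> planted fraction
    library_factors: dict = field(default_factory=dict)  # sample -> factor


def simulate_counts(
    design: SimDesign,
    baseline_mean: float = 20.0,
    dispersion: float = 0.2,
    effect_ln_fc: float = 2.0,
    frac_dap: float = 0.05,
    frac_exclusive: float = 0.02,
    batch_sd: float = 0.1,
    library_sd: float = 0.1,
    baseline_log_sd: float = 1.0,
    n_coexpr_blocks: int = 0,
    coexpr_block_size: int = 5,
    coexpr_noise: float = 0.0,
    batch_dropout: float = 0.0,
    effect_condition: str | None = None,
) -> tuple[CountMatrix, SimTruth]:
    """Simulate a spectral-count matrix with planted effects.

    Per-protein baseline means are log-normal around ``baseline_mean``
    (heavy-tailed abundances); counts are negative binomial with
    variance mu + dispersion*mu^2, scaled by per-sample library-size factors
    (log-normal, sd ``library_sd``) and per-protein-per-batch multiplicative
    effects (log-normal, sd ``batch_sd``).  Planted differential proteins get
    their mean multiplied by exp(+/-effect_ln_fc) in ``effect_condition``
    (default: the second condition); exclusives get hard zeros there and a
    guaranteed detection elsewhere, so the downstream +/-5 fold-change rule is
    exercised deterministically.  Co-expression blocks replace their proteins'
    counts with monotone functions of a shared latent driver drawn per
    condition.
    """
    if frac_dap + frac_exclusive > 1:
        raise ValueError("frac_dap + frac_exclusive must be <= 1")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(design.seed)
    dframe = design.design_frame()
    n_prot = design.n_proteins
    samples = list(dframe.index)
    n_samp = len(samples)
    proteins = [f"P{i + 1:05d}" for i in range(n_prot)]
    conditions = list(design.conditions)
    if effect_condition is None:
        effect_condition = conditions[1] if len(conditions) > 1 else conditions[0]
    if effect_condition not in conditions:
        raise ValueError(f"effect condition {effect_condition!r} not in design")

    # heavy-tailed per-protein baselines, mean-preserving log-normal
    base = baseline_mean * rng.lognormal(-baseline_log_sd**2 / 2, baseline_log_sd, n_prot)
    lib = rng.lognormal(-library_sd**2 / 2, library_sd, n_samp)
    batch_fx = rng.lognormal(-batch_sd**2 / 2, batch_sd, (n_prot, design.batches))

    n_dap = int(round(frac_dap * n_prot))
    n_excl = int(round(frac_exclusive * n_prot))
    perm = rng.permutation(n_prot)
    dap_idx = perm[:n_dap]
    excl_idx = perm[n_dap : n_dap + n_excl]
    signs = rng.choice([-1.0, 1.0], size=n_dap)

    mu = np.empty((n_prot, n_samp))
    cond_of = dframe["condition"].to_numpy()
    batch_of = dframe["batch"].to_numpy() - 1
    for j in range(n_samp):
        mu[:, j] = base * batch_fx[:, batch_of[j]] * lib[j]
    treated = cond_of == effect_condition
    mu[np.ix_(dap_idx, np.where(treated)[0])] *= np.exp(signs * effect_ln_fc)[:, None]
    # exclusives: floor the baseline so detection outside the zeroed condition
    # is essentially certain, then hard-zero the designated condition
    if n_excl:
        mu[excl_idx, :] = np.maximum(mu[excl_idx, :], baseline_mean)
        mu[np.ix_(excl_idx, np.where(treated)[0])] = 0.0

    size = 1.0 / dispersion
    with np.errstate(divide="ignore"):
        p = size / (size + mu)
    counts = np.zeros((n_prot, n_samp), dtype=np.int64)
    pos = mu > 0
    counts[pos] = rng.negative_binomial(size, p[pos])

    if batch_dropout > 0:
        # batch-specific detection dropout: later batches miss more proteins
        for b in range(design.batches):
            rate = batch_dropout * (b + 1) / design.batches
            cols = np.where(batch_of == b)[0]
            drop = rng.random((n_prot, len(cols))) < rate
            counts[:, cols] = np.where(drop, 0, counts[:, cols])

    if n_excl:
        # structural guarantee: every exclusive is detected in every other condition
        for cond in conditions:
            if cond == effect_condition:
                continue
            cols = np.where(cond_of == cond)[0]
            for i in excl_idx:
                if counts[i, cols].sum() == 0:
                    counts[i, cols[0]] = 1

    # planted co-expression blocks: shared latent monotone driver per condition
    blocks: list[set] = []
    if n_coexpr_blocks:
        avail = perm[n_dap + n_excl :]
        need = n_coexpr_blocks * coexpr_block_size
        if len(avail) < need:
            raise ValueError("not enough proteins left for the requested co-expression blocks")
        for b in range(n_coexpr_blocks):
            idx = avail[b * coexpr_block_size : (b + 1) * coexpr_block_size]
            gains = rng.uniform(5.0, 15.0, coexpr_block_size)
            for cond in conditions:
                cols = np.where(cond_of == cond)[0]
                driver = rng.permutation(len(cols)) + 1.0
                vals = gains[:, None] * driver[None, :]
                if coexpr_noise > 0:
                    vals = vals + rng.normal(0.0, coexpr_noise, vals.shape)
                counts[np.ix_(idx, cols)] = np.maximum(np.rint(vals), 1).astype(np.int64)
            blocks.append({proteins[i] for i in idx})

    matrix = CountMatrix(
        pd.DataFrame(counts, index=proteins, columns=samples),
        dframe.drop(columns=[], errors="ignore"),
    )

    ref = conditions[0] if effect_condition != conditions[0] else conditions[-1]
    dap_truth = {
        proteins[i]: {(ref, effect_condition): -float(s * effect_ln_fc)}
        for i, s in zip(dap_idx, signs)
    }
    truth = SimTruth(
        dap_ids=dap_truth,
        exclusive_ids={proteins[i]: effect_condition for i in excl_idx},
        coexpr_blocks=blocks,
        library_factors=dict(zip(samples, lib)),
    )
    return matrix, truth


def simulate_network(
    n_nodes: int, attach_m: int = 2, n_bridges: int = 0, seed: int = 0
) -> tuple[nx.Graph, SimTruth]:
    """Preferential-attachment interaction network, optionally with planted bridges.

    With ``n_bridges == 0`` this is a single Barabasi-Albert graph (scale-free
    degree distribution; a tree when attach_m == 1).  With bridges, two
    independently grown preferential-attachment communities of (near-)equal
    size are joined only through the bridge nodes, each of which connects to
    the highest-degree node of either community; bridge identities are recorded
    in the truth.
    """
    if attach_m < 1 or n_nodes <= attach_m:
        raise ValueError("need n_nodes > attach_m >= 1")
    if n_bridges < 0:
        raise ValueError("n_bridges must be nonnegative")
    if n_bridges > 0 and n_nodes < 10:
        raise ValueError("bridged networks need n_nodes >= 10 (degenerate communities)")
    if n_bridges == 0:
        ba = nx.barabasi_albert_graph(n_nodes, attach_m, seed=seed)
        g = nx.relabel_nodes(ba, {i: f"n{i:05d}" for i in ba})
        return g, SimTruth()

    n_left = (n_nodes - n_bridges + 1) // 2
    n_right = n_nodes - n_bridges - n_left
    if min(n_left, n_right) <= attach_m:
        raise ValueError("communities too small for attach_m")
    left = nx.relabel_nodes(
        nx.barabasi_albert_graph(n_left, attach_m, seed=seed),
        {i: f"a{i:05d}" for i in range(n_left)},
    )
    right = nx.relabel_nodes(
        nx.barabasi_albert_graph(n_right, attach_m, seed=seed + 1),
        {i: f"b{i:05d}" for i in range(n_right)},
    )
    g = nx.union(left, right)
    anchor_a = max(left.degree, key=lambda kv: (kv[1], kv[0]))[0]
    anchor_b = max(right.degree, key=lambda kv: (kv[1], kv[0]))[0]
    bridges = {f"bridge{k}" for k in range(n_bridges)}
    for b in sorted(bridges):
        g.add_edge(b, anchor_a)
        g.add_edge(b, anchor_b)
    return g, SimTruth(hub_ids=bridges)


def simulate_annotation(
    universe: set,
    n_terms: int,
    planted_term_size: int,
    dap_ids: set,
    enrichment_fraction: float,
    seed: int = 0,
) -> tuple[dict, SimTruth]:
    """Annotation map with one term planted to over-represent ``dap_ids``.

    The planted term (``T000``) draws ``enrichment_fraction`` of its members
    from ``dap_ids`` and the rest uniformly from the remaining universe; the
    other terms draw uniformly from the whole universe at the same size.
    Returns (term -> protein set, truth).
    """
    if not universe:
        raise ValueError("universe is empty")
    if planted_term_size > len(universe):
        raise ValueError("planted_term_size exceeds the universe")
    if not 0 <= enrichment_fraction <= 1:
        raise ValueError("enrichment_fraction must be a fraction")
    rng = np.random.default_rng(seed)
    uni = sorted(universe)
    daps = sorted(set(dap_ids) & universe)
    n_from_dap = min(int(round(enrichment_fraction * planted_term_size)), len(daps))
    chosen = set(rng.choice(daps, n_from_dap, replace=False)) if n_from_dap else set()
    # the remainder comes from outside dap_ids, so the planted overlap equals
    # the requested fraction exactly (at the random-expectation fraction the
    # planted term is then statistically indistinguishable from the others)
    rest_pool = sorted(set(uni) - set(daps) - chosen)
    n_rest = planted_term_size - len(chosen)
    if n_rest > len(rest_pool):
        raise ValueError("universe too small outside dap_ids for the requested term size")
    chosen |= set(rng.choice(rest_pool, n_rest, replace=False))
    terms = {"T000": chosen}
    for t in range(1, n_terms):
        terms[f"T{t:03d}"] = set(rng.choice(uni, planted_term_size, replace=False))
    return terms, SimTruth(enriched_terms={"T000": enrichment_fraction})
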