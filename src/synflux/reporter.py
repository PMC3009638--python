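"""Reporter-metabolite scoring of differential-expression p-values.

Each measured gene's p-value is converted to a z-score through the
inverse normal CDF, z_gene = Φ⁻¹(1 − p).  A metabolite's raw score is
the arithmetic mean of the z-scores of its neighboring genes — a gene
neighbors a metabolite when one of its reactions involves that
metabolite (cofactors excluded, or ATP/H₂O would connect everything).
Raw scores are corrected against the background distribution of random
gene aggregates of the same size N: z_corrected = (z_raw − m_N) / s_N.
Metabolites with high corrected scores are "reporters": points of the
network around which transcriptional change concentrates.

Also here: a greedy seeded search for co-regulated connected gene
subnetworks, and KEGG-style category summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import DEFAULT_COFACTORS, MetabolicModel, ModelError

__all__ = [
    "ExpressionDataset",
    "GeneScoreVector",
    "BackgroundDistribution",
    "DegenerateInputError",
    "gene_zscores",
    "metabolite_raw_score",
    "build_background",
    "background_correct",
    "metabolite_gene_neighborhoods",
    "reporter_metabolites",
    "gene_adjacency_graph",
    "coregulated_subnetwork_search",
    "category_summary",
    "P_CLAMP",
]

#: p-values are clamped to [P_CLAMP, 1 - P_CLAMP] before inversion so that
#: z-scores stay finite.
P_CLAMP = 1.0e-10
DEFAULT_BG_SAMPLES = 10_000


class DegenerateInputError(ModelError):
    """Gene scores are constant; background correction is undefined."""


@dataclass
class ExpressionDataset:
    """Per-gene p-values per contrast; genes may be absent (unmeasured)."""

    pvalues: pd.DataFrame  # index: gene id, columns: contrast labels

    def __post_init__(self):
        vals = self.pvalues.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if ((finite < 0) | (finite > 1)).any():
            bad = self.pvalues.index[
                ((self.pvalues < 0) | (self.pvalues > 1)).any(axis=1)
            ]
            raise ModelError(f"p-values outside [0, 1] for gene(s) {list(bad[:3])}")

    @property
    def contrasts(self) -> list[str]:
        return list(self.pvalues.columns)

    @classmethod
    def from_dict(cls, data: Mapping[str, Mapping[str, float]]) -> "ExpressionDataset":
        """``data`` maps contrast label -> {gene: p}."""
        return cls(pd.DataFrame(data))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionDataset":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        self.pvalues.round(10).to_csv(path, sep="\t", index_label="gene_id")


GeneScoreVector = dict[str, float]


def gene_zscores(data: ExpressionDataset, contrast: str) -> GeneScoreVector:
    """z = Φ⁻¹(1 − p) per measured gene; small p means large positive z."""
    if contrast not in data.pvalues.columns:
        raise ModelError(f"contrast {contrast!r} not in dataset")
    col = data.pvalues[contrast].dropna()
    p = col.to_numpy(dtype=float).clip(P_CLAMP, 1.0 - P_CLAMP)
    z = norm.ppf(1.0 - p)
    return dict(zip(col.index, map(float, z)))


def metabolite_raw_score(
    z: GeneScoreVector, neighbor_genes: Iterable[str]
) -> tuple[float, int]:
    """Arithmetic mean of the neighbor genes' z-scores, with the count used."""
    scored = [z[g] for g in neighbor_genes if g in z]
    if not scored:
        raise ModelError("no scored neighbor genes")
    return float(np.mean(scored)), len(scored)


@dataclass
class BackgroundDistribution:
    """Mean/sd of random size-N gene aggregates, per aggregate size."""

    moments: dict[int, tuple[float, float]]  # N -> (m_N, s_N)
    samples: int
    seed: int | None = None

    def __getitem__(self, n: int) -> tuple[float, float]:
        if n not in self.moments:
            raise ModelError(f"background has no aggregate size {n}")
        return self.moments[n]


def build_background(
    z: GeneScoreVector,
    sizes: Iterable[int],
    n_samples: int = DEFAULT_BG_SAMPLES,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BackgroundDistribution:
    """Sample ``n_samples`` random aggregates (with replacement from the
    scored genes) for every distinct size and record mean and sd."""

    if rng is None:
        rng = np.random.default_rng(seed)
    # canonical gene order -> sampling invariant to input ordering
    scores = np.array([z[g] for g in sorted(z)], dtype=float)
    if scores.size == 0:
        raise ModelError("no scored genes for background sampling")
    if np.ptp(scores) == 0.0:
        raise DegenerateInputError(
            "all gene z-scores identical; background sd would be zero "
            "(is every p-value the same?)"
        )
    moments: dict[int, tuple[float, float]] = {}
    for n in sorted(set(sizes)):
        draws = rng.choice(scores, size=(n_samples, n), replace=True)
        means = draws.mean(axis=1)
        m, s = float(means.mean()), float(means.std())
        if s == 0.0:
            raise DegenerateInputError(f"zero background sd at aggregate size {n}")
        moments[n] = (m, s)
    return BackgroundDistribution(moments, n_samples, seed)


def background_correct(raw: float, n: int, bg: BackgroundDistribution) -> float:
    m, s = bg[n]
    return (raw - m) / s


# ---------------------------------------------------------------------------
# Network neighborhoods


def metabolite_gene_neighborhoods(
    model: MetabolicModel,
    cofactors: Iterable[str] | None = None,
    include_external: bool = False,
) -> dict[str, frozenset[str]]:
    """Map each (non-cofactor) metabolite to the genes of its reactions."""
    lowered = {
        c.lower() for c in (DEFAULT_COFACTORS if cofactors is None else cofactors)
    }
    out: dict[str, set[str]] = {}
    for rxn in model.reactions.values():
        if rxn.gpr is None:
            continue
        genes = rxn.gpr.genes()
        for met_id in rxn.stoichiometry:
            met = model.metabolites[met_id]
            if met.external and not include_external:
                continue
            if met.cofactor or met.id.lower() in lowered or met.name.lower() in lowered:
                continue
            out.setdefault(met_id, set()).update(genes)
    return {m: frozenset(g) for m, g in out.items()}


@dataclass
class ReporterTable:
    """Ranked reporter-metabolite scores for one contrast."""

    table: pd.DataFrame  # metabolite, n_genes, z_raw, z_corrected, rank
    contrast: str
    skipped: list[str] = field(default_factory=list)

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)


def reporter_metabolites(
    model: MetabolicModel,
    data: ExpressionDataset,
    contrast: str,
    bg_samples: int = DEFAULT_BG_SAMPLES,
    seed: int | None = 0,
    cofactors: Iterable[str] | None = None,
) -> ReporterTable:
    """Full pipeline: z-scores → neighborhood means → background correction.

    Metabolites with no scored neighbor gene are skipped (listed in
    ``skipped``).  Output ordering is deterministic for a fixed seed:
    descending corrected score, ties broken by metabolite id.
    """

    z = gene_zscores(data, contrast)
    hoods = metabolite_gene_neighborhoods(model, cofactors=cofactors)
    rows = []
    skipped = []
    sizes = []
    raw_by_met: dict[str, tuple[float, int]] = {}
    for met_id in sorted(hoods):
        scored = [g for g in hoods[met_id] if g in z]
        if not scored:
            skipped.append(met_id)
            continue
        raw, n = metabolite_raw_score(z, scored)
        raw_by_met[met_id] = (raw, n)
        sizes.append(n)
    if not raw_by_met:
        raise ModelError("no metabolite has scored neighbor genes")
    bg = build_background(z, sizes, n_samples=bg_samples, seed=seed)
    for met_id, (raw, n) in raw_by_met.items():
        rows.append(
            {
                "metabolite": met_id,
                "n_genes": n,
                "z_raw": raw,
                "z_corrected": background_correct(raw, n, bg),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["z_corrected", "metabolite"], ascending=[False, True]
    )
    df["rank"] = range(1, len(df) + 1)
    return ReporterTable(df.reset_index(drop=True), contrast, skipped)


# ---------------------------------------------------------------------------
# Co-regulated subnetworks


def gene_adjacency_graph(
    model: MetabolicModel, cofactors: Iterable[str] | None = None
):
    """Genes are adjacent when their reactions share a non-cofactor
    metabolite."""
    import networkx as nx

    hoods = metabolite_gene_neighborhoods(model, cofactors=cofactors)
    g = nx.Graph()
    g.add_nodes_from(model.genes)
    for genes in hoods.values():
        members = sorted(genes)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                g.add_edge(a, b)
    return g


def _greedy_best_subnetwork(
    z: Mapping[str, float],
    graph,
    bg: BackgroundDistribution,
    size_limit: int,
) -> tuple[frozenset[str], float]:
    """Best-scoring connected set found by greedy extension from every
    top-decile start gene."""

    def corrected(total: float, n: int) -> float:
        m, s = bg[n]
        return (total / n - m) / s

    ranked = sorted((g for g in graph.nodes if g in z), key=lambda g: (-z[g], g))
    n_starts = max(1, len(ranked) // 10)
    best_set: frozenset[str] = frozenset()
    best_score = -np.inf
    for start in ranked[:n_starts]:
        members = {start}
        total = z[start]
        score = corrected(total, 1)
        frontier = {nb for nb in graph.neighbors(start) if nb in z}
        while len(members) < size_limit and frontier:
            candidate = max(
                frontier, key=lambda nb: (corrected(total + z[nb], len(members) + 1), nb)
            )
            new_score = corrected(total + z[candidate], len(members) + 1)
            if new_score <= score:
                break
            members.add(candidate)
            total += z[candidate]
            score = new_score
            frontier.discard(candidate)
            frontier |= {
                nb for nb in graph.neighbors(candidate)
                if nb in z and nb not in members
            }
        if score > best_score or (
            score == best_score and sorted(members) < sorted(best_set)
        ):
            best_score = score
            best_set = frozenset(members)
    return best_set, float(best_score)


def coregulated_subnetwork_search(
    model: MetabolicModel,
    data: ExpressionDataset,
    contrast: str,
    size_limit: int = 20,
    seed: int | None = 0,
    bg_samples: int = DEFAULT_BG_SAMPLES,
    cofactors: Iterable[str] | None = None,
    n_permutations: int = 30,
) -> tuple[frozenset[str], float]:
    """Greedy search for a connected gene set with high aggregate score.

    From each top-decile gene, repeatedly add the neighboring gene that
    maximizes the background-corrected aggregate z until the score drops
    or ``size_limit`` is reached; the best set over all starts wins.

    Because the greedy maximizes over many starts and extensions, its raw
    best score is selection-inflated even on null data.  The returned
    score is therefore calibrated against the null of the same search on
    ``n_permutations`` gene-label permutations:
    (raw − mean_perm) / sd_perm.  Seeded and deterministic.  Empty graph
    → empty set with score 0.
    """

    z = gene_zscores(data, contrast)
    graph = gene_adjacency_graph(model, cofactors=cofactors)
    scored_nodes = sorted(g for g in graph.nodes if g in z)
    if not scored_nodes:
        return frozenset(), 0.0
    rng = np.random.default_rng(seed)
    bg = build_background(
        z, range(1, min(size_limit, len(scored_nodes)) + 1),
        n_samples=bg_samples, rng=rng, seed=seed,
    )
    best_set, raw = _greedy_best_subnetwork(z, graph, bg, size_limit)
    if n_permutations <= 1:
        return best_set, raw
    values = np.array([z[g] for g in scored_nodes])
    perm_scores = []
    for _ in range(n_permutations):
        shuffled = dict(zip(scored_nodes, rng.permutation(values)))
        # same score multiset -> the background transfers unchanged
        perm_scores.append(_greedy_best_subnetwork(shuffled, graph, bg, size_limit)[1])
    mu = float(np.mean(perm_scores))
    sd = float(np.std(perm_scores))
    if sd == 0.0:
        return best_set, 0.0
    return best_set, (raw - mu) / sd


# ---------------------------------------------------------------------------
# Category summaries


def category_summary(
    genes: Iterable[str], category_map: Mapping[str, str]
) -> pd.DataFrame:
    """Count genes per functional category; percent = 100·count/total to
    two decimals; rows sorted by descending count, then category name."""
    genes = list(genes)
    # zero-count categories from the map still get a row (as in printed
    # orthology tables)
    counts: dict[str, int] = {cat: 0 for cat in category_map.values()}
    for g in genes:
        cat = category_map.get(g, "Unassigned")
        counts[cat] = counts.get(cat, 0) + 1
    total = len(genes)
    rows = [
        {
            "category": cat,
            "count": n,
            "percent": round(100.0 * n / total, 2) if total else 0.0,
        }
        for cat, n in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["category", "count", "percent"])
    if len(df):
        df = df.sort_values(["count", "category"], ascending=[False, True])
    return df.reset_index(drop=True)
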