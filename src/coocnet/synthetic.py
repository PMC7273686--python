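"""Synthetic multi-environment compositional count tables with planted structure.

The generator emulates the statistical shape of a large amplicon survey:
several environments, each with its own sample set; sparse non-negative
integer counts obtained by fixed-depth multinomial sampling of latent
relative abundances (hence genuinely compositional data); planted positive
and negative pairwise associations; hub taxa with many planted partners; and
edges shared across environments (generalists) versus environment-specific
edges (specialists).

The dependence model is a Gaussian copula over per-ESV log-abundances: for
each environment a latent correlation matrix embeds the planted latent
correlations (repaired to the nearest positive-definite matrix by eigenvalue
clipping when overconstrained), multivariate-normal fluctuations are added to
per-ESV base log-abundances and exponentiated.  Monotone dependence survives
both the exponential and rank-based measures, so a planted latent
correlation is detectable by Spearman correlation by construction.  Planted
partner ESVs share a base abundance level so the association is also visible
to the magnitude-sensitive Bray-Curtis measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ndtri

from coocnet.io_model import (
    AbundanceTable,
    TAXONOMIC_RANKS,
    UNCLASSIFIED,
    canonical_pair,
)

#: the fourteen environment categories used throughout the package
_ENVIRONMENTS = (
    "soil",
    "rhizosphere",
    "plant surface",
    "plant corpus",
    "animal surface",
    "animal corpus",
    "animal secretion",
    "animal proximal gut",
    "animal distal gut",
    "saline water",
    "non-saline water",
    "saline sediment",
    "non-saline sediment",
    "non-saline surface",
)

_DUMMY_PHYLA = (
    "Acidobacteria", "Actinobacteria", "Alphaproteobacteria", "Bacteroidia",
    "Clostridia", "Deltaproteobacteria", "Gammaproteobacteria", "Spirochaetia",
    "Sphingobacteria", "Verrucomicrobiae",
)


def default_environment_labels() -> list[str]:
    """The fourteen standard environment category labels."""
    return list(_ENVIRONMENTS)


@dataclass
class PlantedEdge:
    esv_a: str
    esv_b: str
    latent_rho: float
    environments: frozenset[str]

    def __post_init__(self) -> None:
        if not -1.0 <= self.latent_rho <= 1.0:
            raise ValueError(f"|latent correlation| > 1: {self.latent_rho}")
        if self.latent_rho == 0:
            raise ValueError("planted edge with zero latent correlation")
        self.environments = frozenset(self.environments)
        if not self.environments:
            raise ValueError("planted edge with empty environment subset")
        canonical_pair(self.esv_a, self.esv_b)  # rejects self-pairs

    @property
    def key(self) -> tuple[str, str]:
        return canonical_pair(self.esv_a, self.esv_b)

    @property
    def sign(self) -> int:
        return 1 if self.latent_rho > 0 else -1


@dataclass
class PlantedDesign:
    """Full description of a synthetic multi-environment dataset.

    Defaults give a desk-scale replica of a multi-environment survey:
    14 environments x 60 samples, 150 ESVs, depth 10,000 reads/sample,
    log-normal base abundances (mu=0, sigma=1.5 on the natural-log scale),
    within-ESV log fluctuation scale 1.0, presence probability 0.9.
    """

    n_environments: int = 14
    samples_per_environment: int = 60
    n_esvs: int = 150
    sequencing_depth: int = 10_000
    planted_edges: list[PlantedEdge] = field(default_factory=list)
    hub_spec: list[tuple[str, int]] = field(default_factory=list)
    base_mu: float = 0.0
    base_sigma: float = 1.5
    fluctuation_sigma: float = 1.0
    sparsity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for value, name in [
            (self.n_environments, "n_environments"),
            (self.samples_per_environment, "samples_per_environment"),
            (self.n_esvs, "n_esvs"),
            (self.sequencing_depth, "sequencing_depth"),
        ]:
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not 0.0 < self.sparsity <= 1.0:
            raise ValueError("sparsity must be in (0, 1]")
        for esv, degree in self.hub_spec:
            if degree >= self.n_esvs:
                raise ValueError(f"hub {esv}: target degree {degree} >= n_esvs")

    @property
    def environments(self) -> list[str]:
        return default_environment_labels()[: self.n_environments]

    def esv_labels(self) -> list[str]:
        width = len(str(self.n_esvs - 1))
        return [f"ESV{i:0{width}d}" for i in range(self.n_esvs)]


def _nearest_positive_definite(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped repair, rescaled back to unit diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= eps:
        return corr
    vals = np.clip(vals, eps, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def _expand_hubs(design: PlantedDesign) -> list[PlantedEdge]:
    """Turn hub specifications into planted edges across all environments.

    Hub partners are the lexicographically first ESVs not already planted
    with that hub; latent correlation 0.8, positive, all environments.
    """
    labels = design.esv_labels()
    envs = frozenset(design.environments)
    edges = list(design.planted_edges)
    taken = {e.key for e in edges}
    for hub, degree in design.hub_spec:
        current = sum(1 for k in taken if hub in k)
        for other in labels:
            if current >= degree:
                break
            if other == hub:
                continue
            key = canonical_pair(hub, other)
            if key in taken:
                continue
            edges.append(PlantedEdge(key[0], key[1], 0.8, envs))
            taken.add(key)
            current += 1
    return edges


def _latent_correlation(design: PlantedDesign, edges: list[PlantedEdge],
                        env: str, index: dict[str, int]) -> np.ndarray:
    corr = np.eye(design.n_esvs)
    active = [e for e in edges if env in e.environments]
    for e in active:
        i, j = index[e.esv_a], index[e.esv_b]
        corr[i, j] = corr[j, i] = e.latent_rho
    repaired = _nearest_positive_definite(corr)
    # verify the repair did not destroy any planted association
    for e in active:
        i, j = index[e.esv_a], index[e.esv_b]
        if np.sign(repaired[i, j]) != np.sign(e.latent_rho) or (
            abs(repaired[i, j]) < 0.5 * abs(e.latent_rho)
        ):
            raise ValueError(
                f"latent correlation matrix for {env!r} infeasible after "
                f"positive-definite repair; offending pair ({e.esv_a}, {e.esv_b})"
            )
    return repaired


def generate_dataset(
    design: PlantedDesign,
) -> tuple[AbundanceTable, dict[str, set[tuple[str, str, int]]]]:
    """Generate counts and ground truth for a planted design.

    Returns
    -------
    table
        The combined :class:`AbundanceTable` over all environments, with
        per-sample environment labels attached.
    truth
        Map ``environment -> set of (esv_a, esv_b, sign)`` listing every
        planted edge active in that environment (canonical pair order).
    """
    rng = np.random.default_rng(design.seed)
    labels = design.esv_labels()
    index = {e: i for i, e in enumerate(labels)}
    edges = _expand_hubs(design)
    for e in edges:
        for bad in (e.esv_a, e.esv_b):
            if bad not in index:
                raise ValueError(f"planted edge references unknown ESV {bad!r}")
    for hub, _ in design.hub_spec:
        if hub not in index:
            raise ValueError(f"hub spec references unknown ESV {hub!r}")

    # Base log-abundances.  ESVs carrying a planted association are placed in
    # the mid-to-upper abundance range (50th-85th percentile of the base
    # distribution): a taxon observed at well below one count per sample
    # cannot carry rank information at a fixed sequencing depth, while a
    # pair dominating the composition has its shared variation cancelled by
    # closure -- both would make the ground truth vacuous.  Planted partners
    # share a base level so the association is also visible to the
    # magnitude-sensitive Bray-Curtis measure.
    base = rng.normal(design.base_mu, design.base_sigma, size=design.n_esvs)
    planted_ids = {x for e in edges for x in (e.esv_a, e.esv_b)}
    planted_ids |= {h for h, _ in design.hub_spec}
    for esv in sorted(planted_ids):
        u = rng.uniform(0.50, 0.85)
        base[index[esv]] = design.base_mu + design.base_sigma * ndtri(u)
    for e in edges:
        base[index[e.esv_b]] = base[index[e.esv_a]]

    all_counts = []
    sample_ids: list[str] = []
    environment_of: dict[str, str] = {}
    truth: dict[str, set[tuple[str, str, int]]] = {}

    for env_idx, env in enumerate(design.environments):
        corr = _latent_correlation(design, edges, env, index)
        chol = np.linalg.cholesky(corr)
        z = chol @ rng.standard_normal((design.n_esvs, design.samples_per_environment))
        log_abund = base[:, None] + design.fluctuation_sigma * z
        abund = np.exp(log_abund)

        # per-environment presence mask; planted/hub ESVs always present
        present = rng.random(design.n_esvs) < design.sparsity
        for esv in planted_ids:
            present[index[esv]] = True
        abund[~present, :] = 0.0

        totals = abund.sum(axis=0, keepdims=True)
        if np.any(totals == 0):  # every ESV masked out: fall back to uniform
            abund[:, totals[0] == 0] = 1.0
            totals = abund.sum(axis=0, keepdims=True)
        rel = abund / totals
        counts = np.column_stack([
            rng.multinomial(design.sequencing_depth, rel[:, k])
            for k in range(design.samples_per_environment)
        ])
        all_counts.append(counts)
        tag = f"E{env_idx:02d}"
        for k in range(design.samples_per_environment):
            sid = f"{tag}S{k:04d}"
            sample_ids.append(sid)
            environment_of[sid] = env
        truth[env] = {
            (*e.key, e.sign) for e in edges if env in e.environments
        }

    table = AbundanceTable(
        labels, sample_ids,
        np.concatenate(all_counts, axis=1) if all_counts else
        np.zeros((design.n_esvs, 0), dtype=np.int64),
        environment_of,
    )
    return table, truth


def replica_design(seed: int = 0) -> PlantedDesign:
    """Desk-scale replica of a 14-environment survey.

    150 ESVs, 60 samples per environment, depth 10,000.  Planted structure:
    eight generalist associations spanning all environments (two of them
    mutual exclusions), one environment-specific association per
    environment, and two hub taxa with six partners each across all
    environments.
    """
    envs = default_environment_labels()
    all_envs = frozenset(envs)
    planted = []
    for k in range(8):
        rho = -0.85 if k >= 6 else 0.85
        planted.append(PlantedEdge(f"ESV{100 + 2 * k:03d}", f"ESV{101 + 2 * k:03d}",
                                   rho, all_envs))
    for i, env in enumerate(envs):
        planted.append(PlantedEdge(f"ESV{70 + 2 * i:03d}", f"ESV{71 + 2 * i:03d}",
                                   0.85, frozenset([env])))
    return PlantedDesign(
        n_environments=14,
        samples_per_environment=60,
        n_esvs=150,
        sequencing_depth=10_000,
        planted_edges=planted,
        hub_spec=[("ESV000", 6), ("ESV001", 6)],
        seed=seed,
    )


def dummy_taxonomy(esv_ids: Sequence[str], seed: int = 0) -> dict[str, tuple[str, ...]]:
    """Assign synthetic ranked lineages from a fixed dummy pool."""
    rng = np.random.default_rng(seed)
    out: dict[str, tuple[str, ...]] = {}
    for esv in esv_ids:
        phylum = _DUMMY_PHYLA[rng.integers(len(_DUMMY_PHYLA))]
        lineage = ["Bacteria", phylum, f"{phylum}_c{rng.integers(3)}",
                   f"o{rng.integers(5)}", f"f{rng.integers(8)}", f"g{rng.integers(12)}"]
        out[esv] = tuple(lineage[: len(TAXONOMIC_RANKS)]) if lineage else (UNCLASSIFIED,)
    return out
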