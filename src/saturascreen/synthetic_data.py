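"""Synthetic chronograms, site rates and alignments.

Emulates the structure of a mixed mitochondrial/nuclear fish phylogenomic
study: a ~44-taxon chronogram with a Devonian-age root (~390 Ma), fast
protein-coding partitions whose third codon positions are strongly
saturated, and slower conserved partitions.  Everything is seeded and
reproducible bit-for-bit.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .seqio import Alignment, Chronogram, PartitionScheme, StrideRange
from .subst_models import SubstitutionModel, transition_probabilities_batch

__all__ = [
    "PartitionSpec", "SimulationConfig", "simulate_chronogram",
    "draw_site_rates", "simulate_alignment", "simulate_dataset",
    "MITO_LIKE", "NUCLEAR_LIKE", "mito_like_config", "nuclear_like_config",
]

# Per-partition rate presets (substitutions/site/Ma).  The codon-position
# multipliers and Γ shapes place the fast preset's informativeness peak well
# before 145 Ma (strong third-position saturation, decay ~0.85 from peak)
# and the slow preset's peak near/after 145 Ma (decay < 0.03): peak arithmetic
# T* = 1/(4λ) gives per-position peaks of (31, 62, 14) Ma for the fast preset
# and (167, 208, 139) Ma for the slow one.
MITO_LIKE = {
    "mean_rate": 0.010,
    "codon_multipliers": (0.8, 0.4, 1.8),
    "gamma_shape": 2.0,
}
NUCLEAR_LIKE = {
    "mean_rate": 0.0015,
    "codon_multipliers": (1.0, 0.8, 1.2),
    "gamma_shape": 6.0,
}
# Conserved mitochondrial genes emulating the retained (unflagged) subsets of
# a real mitogenome: mean rates span the range implied by retained-subset
# informativeness peaks of 106-217 Ma (rate = 1/(4 * peak)).
CONSERVED_MITO_MEANS = (0.0022, 0.0017, 0.0012)

# GTR parameters used for simulation: transition-heavy exchangeabilities and
# AT-rich composition for the mito-like model, flatter for the nuclear-like.
MITO_GTR = {"freqs": (0.28, 0.29, 0.15, 0.28),
            "rates": (1.0, 8.0, 1.0, 1.0, 16.0, 1.0)}
NUCLEAR_GTR = {"freqs": (0.27, 0.23, 0.24, 0.26),
               "rates": (1.0, 4.0, 1.0, 1.0, 4.0, 1.0)}


@dataclass
class PartitionSpec:
    """One gene partition in a simulated dataset."""

    name: str
    n_sites: int
    mean_rate: float
    codon_multipliers: tuple[float, float, float] = (1.0, 1.0, 1.0)
    gamma_shape: float = 2.0

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise ValueError("partitions need at least one codon")
        if self.mean_rate <= 0 or self.gamma_shape <= 0:
            raise ValueError("rate parameters must be positive")

    @classmethod
    def from_preset(cls, name: str, n_sites: int, preset: dict):
        return cls(name, n_sites, preset["mean_rate"],
                   preset["codon_multipliers"], preset["gamma_shape"])


@dataclass
class SimulationConfig:
    n_taxa: int = 44
    root_age: float = 390.0
    birth_rate: float = 0.05
    death_rate: float = 0.025
    partitions: list[PartitionSpec] = field(default_factory=list)
    model: SubstitutionModel = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if self.root_age <= 0:
            raise ValueError("root age must be positive")
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("birth/death rates must be nonnegative")
        if self.model is None:
            self.model = SubstitutionModel.gtr(**NUCLEAR_GTR)


def mito_like_config(seed: int = 0, n_fast: int = 10, n_slow: int = 3,
                     sites_per_gene: int = 600, **kw) -> SimulationConfig:
    """A mitogenome-like dataset: mostly fast, saturated protein-coding genes
    plus a conserved minority that survives screening (as the slow codon
    subsets did in the empirical mtDNA data)."""
    parts = [PartitionSpec.from_preset(f"mtfast{i+1}", sites_per_gene, MITO_LIKE)
             for i in range(n_fast)]
    parts += [PartitionSpec(f"mtcons{i+1}", sites_per_gene,
                            CONSERVED_MITO_MEANS[i % len(CONSERVED_MITO_MEANS)],
                            NUCLEAR_LIKE["codon_multipliers"],
                            NUCLEAR_LIKE["gamma_shape"])
              for i in range(n_slow)]
    return SimulationConfig(partitions=parts, seed=seed,
                            model=SubstitutionModel.gtr(**MITO_GTR), **kw)


def nuclear_like_config(seed: int = 0, n_genes: int = 9,
                        sites_per_gene: int = 600, **kw) -> SimulationConfig:
    """A nuclear-exon-like dataset: slow genes with mild codon structure."""
    parts = [PartitionSpec.from_preset(f"nuc{i+1}", sites_per_gene,
                                       NUCLEAR_LIKE) for i in range(n_genes)]
    return SimulationConfig(partitions=parts, seed=seed,
                            model=SubstitutionModel.gtr(**NUCLEAR_GTR), **kw)


def simulate_chronogram(config: SimulationConfig,
                        max_retries: int = 100) -> Chronogram:
    """Birth-death tree conditioned on the taxon count, rescaled so the root
    age equals ``config.root_age`` exactly; ultrametric by construction."""
    rng = random.Random(config.seed)
    last_err = None
    for _ in range(max_retries):
        try:
            tree = treesim.birth_death_tree(
                birth_rate=config.birth_rate,
                death_rate=config.death_rate,
                num_extant_tips=config.n_taxa,
                rng=rng)
            break
        except Exception as e:  # process died out; resample
            last_err = e
    else:
        raise RuntimeError(f"birth-death simulation kept dying out: {last_err}")
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i}"
    # force exact ultrametry and the requested root age by resetting branch
    # lengths from (possibly slightly drifted) node depths
    for nd in tree.preorder_node_iter():
        nd._d = 0.0 if nd.parent_node is None else (
            nd.parent_node._d + (nd.edge.length or 0.0))
    height = max(lf._d for lf in tree.leaf_node_iter())
    scale = config.root_age / height
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            nd._age = 0.0
        else:
            nd._age = (height - nd._d) * scale
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = nd.parent_node._age - nd._age
    return Chronogram(tree)


def draw_site_rates(n_sites: int, mean: float, shape: float,
                    seed: int | np.random.Generator,
                    codon_multipliers: tuple[float, float, float] | None = None
                    ) -> np.ndarray:
    """I.i.d. Γ rate draws scaled to the requested mean.

    With ``codon_multipliers`` the mean varies by codon position (site i has
    position i mod 3), giving the 3-fold rate structure of protein-coding
    sequence.
    """
    if mean <= 0 or shape <= 0:
        raise ValueError("mean and shape must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    draws = rng.gamma(shape, 1.0 / shape, size=n_sites)
    rates = draws * mean
    if codon_multipliers is not None:
        mult = np.asarray(codon_multipliers, dtype=float)
        if mult.shape != (3,) or np.any(mult <= 0):
            raise ValueError("need 3 positive codon multipliers")
        rates = rates * mult[np.arange(n_sites) % 3]
    return rates


def simulate_alignment(tree: Chronogram, model: SubstitutionModel,
                       rates: np.ndarray,
                       seed: int | np.random.Generator) -> Alignment:
    """Forward CTMC simulation: root states from the stationary frequencies,
    each edge evolving site i over distance rate_i x duration."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rates = np.asarray(rates, dtype=float)
    n_sites = rates.size
    pi = model.base_frequencies
    from ._felsenstein import TreeIndex
    t = TreeIndex(tree)
    states = {t.root: rng.choice(4, size=n_sites, p=pi)}
    order = list(range(t.n_nodes - 1, -1, -1))  # preorder = reversed postorder
    for i in order:
        p = t.parent[i]
        if p < 0:
            continue
        P = transition_probabilities_batch(model, rates * t.durations[i])
        rows = P[np.arange(n_sites), states[p]]  # (n_sites, 4)
        cum = rows.cumsum(axis=1)
        u = rng.random(n_sites)
        states[i] = (u[:, None] > cum[:, :-1]).sum(axis=1)
    bases = np.array(list("ACGT"))
    taxa, mat = [], []
    for tid, label in zip(t.tip_ids, t.tip_labels):
        taxa.append(label)
        mat.append(bases[states[tid]])
    return Alignment(taxa, np.array(mat))


def simulate_dataset(config: SimulationConfig, tree: Chronogram | None = None):
    """Simulate all partitions of a dataset on one chronogram.

    Returns (tree, alignment, scheme, true_rates).  The scheme lists each
    gene's codon positions as three stride ranges, exercising the
    ``start-end\\3`` dialect the screening inputs use.
    """
    if tree is None:
        tree = simulate_chronogram(config)
    rng = np.random.default_rng((config.seed, 1))
    blocks, rate_blocks = [], []
    subsets: dict[str, list[StrideRange]] = {}
    offset = 0
    for spec in config.partitions:
        r = draw_site_rates(spec.n_sites, spec.mean_rate, spec.gamma_shape,
                            rng, spec.codon_multipliers)
        rate_blocks.append(r)
        end = offset + spec.n_sites
        subsets[spec.name] = [
            StrideRange(offset + 1 + k, end, 3) for k in range(3)]
        offset = end
    true_rates = np.concatenate(rate_blocks)
    aln = simulate_alignment(tree, config.model, true_rates, rng)
    scheme = PartitionScheme(subsets)
    return tree, aln, scheme, true_rates
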