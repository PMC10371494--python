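"""Sitewise likelihoods by Felsenstein pruning over the phylogeny.

The pruning recursion propagates per-node conditional likelihood vectors
from the leaves to the (arbitrary) root, where they are summed against the
stationary profile of the evaluating substitution matrix.  Per-node
renormalization with a log accumulator prevents underflow on deep trees.

Rate categories are integrated by equal-weight averaging of category
likelihoods; mixture components by log-sum-exp over component likelihoods
weighted by the mixture weights ("marginal" mode) or by conditioning on the
current per-site allocation ("allocated" mode, used inside Gibbs updates).
Identical site patterns are collapsed before pruning and results broadcast
back, which changes cost only, never values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from phylocv.alignment import Alignment, SYMBOL_MASKS
from phylocv.substitution import (
    Exchangeabilities,
    FrequencyProfile,
    RateMatrix,
    build_rate_matrix,
)
from phylocv.tree import Phylogeny, check_leaf_match


@dataclass
class SiteLikelihoodTable:
    """Per-site log-likelihoods, optionally with the per-component breakdown.

    ``component_log_likelihoods[n, c]`` is the site-n log-likelihood under
    component c alone (rate categories already averaged), the quantity the
    allocation Gibbs sampler conditions on.
    """

    log_likelihoods: np.ndarray
    component_log_likelihoods: np.ndarray | None = None

    @property
    def total(self) -> float:
        return float(self.log_likelihoods.sum())


def _pattern_log_likelihoods(tree: Phylogeny, leaf_masks: dict[int, np.ndarray],
                             p_matrices: np.ndarray, root_pi: np.ndarray) -> np.ndarray:
    """Prune one (component, rate-category) setting over all site patterns.

    ``p_matrices[i]`` is the transition matrix on the edge above node ``i``;
    ``leaf_masks[leaf]`` the (n_patterns, 4) conditional rows for that leaf.
    """
    partial: list[np.ndarray | None] = [None] * tree.n_nodes
    n_patterns = next(iter(leaf_masks.values())).shape[0]
    log_scale = np.zeros(n_patterns)
    for node in tree.postorder:
        kids = tree.children[node]
        if not kids:
            partial[node] = leaf_masks[node]
            continue
        prod: np.ndarray | None = None
        for child in kids:
            contrib = partial[child] @ p_matrices[child].T
            prod = contrib if prod is None else prod * contrib
        scale = prod.max(axis=1)
        safe = np.where(scale > 0.0, scale, 1.0)
        prod = prod / safe[:, np.newaxis]
        with np.errstate(divide="ignore"):
            log_scale += np.log(scale)
        partial[node] = prod
    root_like = partial[tree.root] @ root_pi
    with np.errstate(divide="ignore"):
        return np.log(root_like) + log_scale


def prune_site_likelihood(tree: Phylogeny, column: dict[str, str],
                          p_per_branch: np.ndarray,
                          root_profile: FrequencyProfile) -> float:
    """Likelihood of a single site pattern given per-branch transition matrices.

    ``column`` maps taxon name to residue symbol; missing/ambiguous symbols
    contribute a conditional of 1 on every compatible nucleotide, and an
    all-missing column therefore has likelihood exactly 1.
    """
    masks = {}
    for leaf in tree.leaf_indices:
        name = tree.names[leaf]
        symbol = column[name]
        if symbol not in SYMBOL_MASKS:
            raise ValueError(f"unknown residue symbol {symbol!r} for taxon {name!r}")
        masks[leaf] = SYMBOL_MASKS[symbol][np.newaxis, :]
    logl = _pattern_log_likelihoods(tree, masks, p_per_branch, root_profile.pi)
    return float(np.exp(logl[0]))


class LikelihoodEngine:
    """Pattern-collapsed pruning evaluator bound to one alignment and tree shape.

    Collapsing identical columns and pre-encoding leaf conditionals is done
    once; every evaluation then costs O(n_patterns) per (component, rate
    category).  The cache affects cost only — a test verifies collapsing
    on/off gives identical values.
    """

    def __init__(self, alignment: Alignment, tree: Phylogeny,
                 collapse_patterns: bool = True):
        check_leaf_match(tree, alignment)
        self.tree = tree
        self.n_sites = alignment.n_sites
        columns = alignment.sequences.T  # (n_sites, n_taxa)
        if collapse_patterns:
            unique_cols, inverse = np.unique(columns, axis=0, return_inverse=True)
        else:
            unique_cols, inverse = columns, np.arange(alignment.n_sites)
        self.pattern_index = inverse
        self.n_patterns = unique_cols.shape[0]
        row_of = {t: i for i, t in enumerate(alignment.taxon_names)}
        self.leaf_masks: dict[int, np.ndarray] = {}
        lookup = {sym: mask for sym, mask in SYMBOL_MASKS.items()}
        for leaf in tree.leaf_indices:
            row = row_of[tree.names[leaf]]
            self.leaf_masks[leaf] = np.array(
                [lookup[sym] for sym in unique_cols[:, row]]
            )

    def component_pattern_logl(self, profile: FrequencyProfile,
                               rho: Exchangeabilities | None,
                               rates: np.ndarray,
                               branch_lengths: np.ndarray) -> np.ndarray:
        """Pattern log-likelihoods under one component, averaged over rate categories."""
        q = build_rate_matrix(profile, rho if rho is not None else Exchangeabilities.equal())
        return self.pattern_logl_for_matrix(q, rates, branch_lengths)

    def pattern_logl_for_matrix(self, q: RateMatrix, rates: np.ndarray,
                                branch_lengths: np.ndarray) -> np.ndarray:
        per_cat = np.empty((len(rates), self.n_patterns))
        for k, rate in enumerate(rates):
            p = q.transition_matrices(branch_lengths * rate)
            per_cat[k] = _pattern_log_likelihoods(self.tree, self.leaf_masks,
                                                  p, q.pi)
        if len(rates) == 1:
            return per_cat[0]
        return logsumexp(per_cat, axis=0) - np.log(len(rates))

    def component_site_logl(self, model, branch_lengths: np.ndarray) -> np.ndarray:
        """(n_sites, n_components) log-likelihood table for a mixture model."""
        rates = model.gamma.rates if model.gamma is not None else np.array([1.0])
        table = np.empty((len(model.profiles), self.n_patterns))
        for c, profile in enumerate(model.profiles):
            table[c] = self.component_pattern_logl(profile, model.rho, rates,
                                                   branch_lengths)
        return table[:, self.pattern_index].T

    def site_logl(self, model, branch_lengths: np.ndarray,
                  mode: str = "marginal",
                  allocation: np.ndarray | None = None,
                  return_components: bool = False) -> SiteLikelihoodTable:
        comp = self.component_site_logl(model, branch_lengths)
        if mode == "marginal":
            if comp.shape[1] == 1:
                per_site = comp[:, 0]
            else:
                log_w = np.log(model.component_weights())
                per_site = logsumexp(comp + log_w[np.newaxis, :], axis=1)
        elif mode == "allocated":
            if allocation is None:
                raise ValueError("allocated mode requires a site allocation")
            per_site = comp[np.arange(comp.shape[0]), allocation]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return SiteLikelihoodTable(per_site, comp if return_components else None)


def sitewise_log_likelihoods(alignment: Alignment, tree: Phylogeny, model,
                             mode: str = "marginal",
                             allocation: np.ndarray | None = None,
                             collapse_patterns: bool = True) -> SiteLikelihoodTable:
    """Per-site log-likelihoods of an alignment under a (mixture) model.

    ``marginal`` mode averages over rate categories with equal weights and
    sums over mixture components with the model's weights; ``allocated``
    mode conditions each site on ``allocation[n]``.
    """
    engine = LikelihoodEngine(alignment, tree, collapse_patterns=collapse_patterns)
    z = allocation.z if hasattr(allocation, "z") else allocation
    return engine.site_logl(model, tree.lengths, mode=mode, allocation=z)
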