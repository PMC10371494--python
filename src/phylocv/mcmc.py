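"""Posterior sampling of substitution-model parameters on a fixed topology.

One MCMC cycle applies, in fixed order: a multiplier move per branch
length, an exchangeability simplex move, a gamma-shape scale move, the
mixture update (weight move for finite mixtures; allocation + profile +
concentration sweep for DP mixtures), and a profile move per component.
All Metropolis–Hastings moves satisfy detailed balance against the
posterior; proposal scales adapt during burn-in only, so the post-burn-in
kernel is fixed and stationarity is preserved.

The tree topology is held fixed throughout (user-supplied or the
simulation tree); only branch lengths are sampled.  Priors: branch lengths
iid exponential (mean 0.1 by default), frequency profiles and mixture
weights flat Dirichlet, exchangeabilities flat Dirichlet on their scaled
simplex, gamma shape exponential with mean 1, DP concentration exponential
with mean 10.  All are configurable through :class:`Priors`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from scipy.stats import dirichlet as dirichlet_dist

from phylocv.alignment import Alignment
from phylocv.likelihood import LikelihoodEngine
from phylocv.mixtures import (
    MixtureModel,
    SiteAllocation,
    dp_update,
    _draw_profile,
)
from phylocv.substitution import (
    Exchangeabilities,
    FrequencyProfile,
    GammaRates,
    PROFILE_FLOOR,
    discretize_gamma,
)
from phylocv.tree import Phylogeny


@dataclass
class Priors:
    """Prior hyper-parameters (our defaults; every one is configurable)."""

    branch_length_mean: float = 0.1
    alpha_mean: float = 1.0
    concentration_mean: float = 10.0
    profile_concentration: float = 1.0
    weight_concentration: float = 1.0


@dataclass
class ModelSpec:
    """A point in the model lattice: {F81, GTR} x {none, finite, dp} x {+/-gamma}."""

    kind: str = "single"  # single | finite | dp
    free_exchangeabilities: bool = True
    n_components: int = 1
    gamma: bool = True
    ncat: int = 4
    priors: Priors = field(default_factory=Priors)

    def __post_init__(self) -> None:
        if self.kind not in ("single", "finite", "dp"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "single" and self.n_components != 1:
            raise ValueError("single-matrix models have one component")
        if self.kind == "finite" and self.n_components < 1:
            raise ValueError("finite mixture needs at least one component")
        if self.ncat < 1:
            raise ValueError("need at least one rate category")

    @property
    def label(self) -> str:
        base = "GTR" if self.free_exchangeabilities else "F81"
        if self.kind == "finite":
            tag = "GTR" if self.free_exchangeabilities else "Poisson"
            base = f"CATf={self.n_components}-{tag}"
        elif self.kind == "dp":
            base = "CAT-GTR" if self.free_exchangeabilities else "CAT-Poisson"
        return base + ("+G" if self.gamma else "")


@dataclass
class ChainState:
    """One snapshot theta_k of every sampled parameter."""

    branch_lengths: np.ndarray
    profiles: list[FrequencyProfile]
    weights: np.ndarray | None
    rho: np.ndarray | None
    alpha: float | None
    allocation: np.ndarray | None
    concentration: float | None
    log_likelihood: float = math.nan
    log_prior: float = math.nan
    cycle: int = 0

    @property
    def log_posterior(self) -> float:
        return self.log_likelihood + self.log_prior

    def mixture_model(self, spec: ModelSpec) -> MixtureModel:
        gamma = discretize_gamma(self.alpha, spec.ncat) if spec.gamma else None
        rho = Exchangeabilities(self.rho) if self.rho is not None else None
        return MixtureModel(kind=spec.kind, profiles=list(self.profiles),
                            weights=None if self.weights is None else self.weights.copy(),
                            rho=rho, gamma=gamma, concentration=self.concentration)

    def copy(self) -> "ChainState":
        return ChainState(
            branch_lengths=self.branch_lengths.copy(),
            profiles=list(self.profiles),
            weights=None if self.weights is None else self.weights.copy(),
            rho=None if self.rho is None else self.rho.copy(),
            alpha=self.alpha,
            allocation=None if self.allocation is None else self.allocation.copy(),
            concentration=self.concentration,
            log_likelihood=self.log_likelihood,
            log_prior=self.log_prior,
            cycle=self.cycle,
        )


@dataclass
class PosteriorSampleSet:
    """K retained post-burn-in draws from a chain run on one dataset."""

    samples: list[ChainState]
    spec: ModelSpec
    provenance: dict

    @property
    def size(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# elementary Metropolis–Hastings moves (reused by the prior-recovery tests)

def multiplier_move(value: float, log_target, rng: np.random.Generator,
                    scale: float = 1.0) -> tuple[float, bool]:
    """Scale move x -> x*exp(scale*(u-1/2)); Hastings factor is the multiplier."""
    factor = math.exp(scale * (rng.random() - 0.5))
    proposal = value * factor
    log_acc = log_target(proposal) - log_target(value) + math.log(factor)
    if math.log(rng.random()) < log_acc:
        return proposal, True
    return value, False


def dirichlet_simplex_move(vec: np.ndarray, log_target, rng: np.random.Generator,
                           concentration: float = 200.0,
                           floor: float = PROFILE_FLOOR) -> tuple[np.ndarray, bool]:
    """MH step on the simplex with a Dirichlet proposal centred at the current point.

    Proposals with an entry below ``floor`` are rejected, truncating the
    stationary law to the floored simplex (the truncated mass is
    negligible for flat-ish targets).
    """
    conc = concentration * vec + 0.1
    prop = rng.dirichlet(conc)
    if np.any(prop < floor):
        return vec, False
    prop = prop / prop.sum()
    conc_rev = concentration * prop + 0.1
    log_hastings = (dirichlet_dist.logpdf(vec, conc_rev)
                    - dirichlet_dist.logpdf(prop, conc))
    log_acc = log_target(prop) - log_target(vec) + log_hastings
    if math.log(rng.random()) < log_acc:
        return prop, True
    return vec, False


# ---------------------------------------------------------------------------

_MOVE_FAMILIES = ("branch", "rho", "alpha", "weights", "profile")


class Chain:
    """A single MCMC chain bound to one alignment, tree and model spec.

    Single and finite-mixture models are sampled against the marginal
    (component-summed) likelihood; DP models condition their shared
    parameters on the current site allocation, which the DP sweep then
    refreshes.  With ``prior_only=True`` the likelihood term is dropped
    everywhere, which the prior-recovery tests exploit.
    """

    def __init__(self, alignment: Alignment | None, tree: Phylogeny,
                 spec: ModelSpec, seed: int = 0, prior_only: bool = False):
        self.spec = spec
        self.tree = tree
        self.prior_only = prior_only or alignment is None
        self.rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.engine = None if self.prior_only else LikelihoodEngine(alignment, tree)
        self.alignment = alignment
        self.n_sites = 0 if alignment is None else alignment.n_sites
        self.branch_nodes = tree.branch_nodes
        self.tuning = {"branch": 1.0, "rho": 300.0, "alpha": 1.0,
                       "weights": 300.0, "profile": 300.0}
        self.accepts = {f: 0 for f in _MOVE_FAMILIES}
        self.attempts = {f: 0 for f in _MOVE_FAMILIES}
        self._window_accepts = {f: 0 for f in _MOVE_FAMILIES}
        self._window_attempts = {f: 0 for f in _MOVE_FAMILIES}
        self._init_state()

    # -- initialization ----------------------------------------------------

    def _init_state(self) -> None:
        spec, rng = self.spec, self.rng
        pr = spec.priors
        if self.prior_only:
            bl = rng.exponential(pr.branch_length_mean, size=self.tree.n_nodes)
            bl[self.tree.root] = 0.0
        else:
            bl = self.tree.lengths.copy()
            bl[bl <= 0] = 1e-6
        n_comp = {"single": 1, "finite": spec.n_components, "dp": 1}[spec.kind]
        profiles = [_draw_profile(rng, pr.profile_concentration) for _ in range(n_comp)]
        weights = (np.full(n_comp, 1.0 / n_comp)
                   if spec.kind in ("single", "finite") else None)
        rho = rng.dirichlet(np.ones(6)) * 6.0 if spec.free_exchangeabilities else None
        alpha = float(rng.exponential(pr.alpha_mean)) + 0.05 if spec.gamma else None
        allocation = np.zeros(self.n_sites, dtype=int) if spec.kind == "dp" else None
        concentration = pr.concentration_mean if spec.kind == "dp" else None
        self.state = ChainState(branch_lengths=bl, profiles=profiles,
                                weights=weights, rho=rho, alpha=alpha,
                                allocation=allocation, concentration=concentration)
        self._refresh_likelihood_cache()
        self.state.log_prior = self._log_prior()
        if not math.isfinite(self.state.log_posterior):
            raise ArithmeticError("initial state has non-finite log posterior")

    # -- likelihood bookkeeping -------------------------------------------

    def _rates(self, alpha: float | None) -> np.ndarray:
        if not self.spec.gamma:
            return np.array([1.0])
        return discretize_gamma(alpha, self.spec.ncat).rates

    def _columns(self, bl: np.ndarray, rho: np.ndarray | None,
                 alpha: float | None,
                 profiles: list[FrequencyProfile]) -> np.ndarray:
        """(n_components, n_patterns) pattern log-likelihood matrix."""
        rates = self._rates(alpha)
        rho_obj = Exchangeabilities(rho) if rho is not None else None
        return np.stack([
            self.engine.component_pattern_logl(p, rho_obj, rates, bl)
            for p in profiles
        ])

    def _pattern_weights(self) -> np.ndarray:
        return np.bincount(self.engine.pattern_index,
                           minlength=self.engine.n_patterns).astype(float)

    def _allocated_pattern_counts(self, z: np.ndarray, n_comp: int) -> np.ndarray:
        counts = np.zeros((n_comp, self.engine.n_patterns))
        for c in range(n_comp):
            counts[c] = np.bincount(self.engine.pattern_index[z == c],
                                    minlength=self.engine.n_patterns)
        return counts

    def _total_loglik(self, columns: np.ndarray,
                      weights: np.ndarray | None) -> float:
        if self.prior_only:
            return 0.0
        if self.spec.kind == "dp":
            return float((self._alloc_counts * columns).sum())
        if columns.shape[0] == 1:
            return float(self._pat_weights @ columns[0])
        mixed = logsumexp(columns + np.log(weights)[:, np.newaxis], axis=0)
        return float(self._pat_weights @ mixed)

    def _refresh_likelihood_cache(self) -> None:
        st = self.state
        if self.prior_only:
            self._cols = None
            st.log_likelihood = 0.0
            return
        self._pat_weights = self._pattern_weights()
        if self.spec.kind == "dp":
            self._alloc_counts = self._allocated_pattern_counts(
                st.allocation, len(st.profiles))
        self._cols = self._columns(st.branch_lengths, st.rho, st.alpha, st.profiles)
        st.log_likelihood = self._total_loglik(self._cols, st.weights)

    # -- priors ------------------------------------------------------------

    def _log_prior(self) -> float:
        st, pr = self.state, self.spec.priors
        bl = st.branch_lengths[self.branch_nodes]
        lp = float(-(bl / pr.branch_length_mean).sum()
                   - len(bl) * math.log(pr.branch_length_mean))
        if st.alpha is not None:
            lp += -st.alpha / pr.alpha_mean - math.log(pr.alpha_mean)
        if st.concentration is not None:
            lp += (-st.concentration / pr.concentration_mean
                   - math.log(pr.concentration_mean))
        # flat Dirichlet terms (profiles, weights, rho) are constant when the
        # concentration hyper-parameters are 1; include them otherwise
        if pr.profile_concentration != 1.0:
            conc = np.full(4, pr.profile_concentration)
            lp += sum(dirichlet_dist.logpdf(p.pi, conc) for p in st.profiles)
        if st.weights is not None and pr.weight_concentration != 1.0 \
                and len(st.weights) > 1:
            conc = np.full(len(st.weights), pr.weight_concentration)
            lp += float(dirichlet_dist.logpdf(st.weights, conc))
        return lp

    # -- move machinery ----------------------------------------------------

    def _record(self, family: str, accepted: bool) -> None:
        self.attempts[family] += 1
        self._window_attempts[family] += 1
        if accepted:
            self.accepts[family] += 1
            self._window_accepts[family] += 1

    def _try_update(self, family: str, log_acc: float, apply) -> bool:
        if math.isnan(log_acc):
            raise ArithmeticError(f"{family} move produced NaN log-posterior")
        accepted = math.log(self.rng.random()) < log_acc
        if accepted:
            apply()
        self._record(family, accepted)
        return accepted

    def _branch_moves(self) -> None:
        st = self.state
        pr = self.spec.priors
        scale = self.tuning["branch"]
        for node in self.branch_nodes:
            old = st.branch_lengths[node]
            factor = math.exp(scale * (self.rng.random() - 0.5))
            new = old * factor
            if self.prior_only:
                new_cols, new_ll = None, 0.0
            else:
                bl = st.branch_lengths.copy()
                bl[node] = new
                new_cols = self._columns(bl, st.rho, st.alpha, st.profiles)
                new_ll = self._total_loglik(new_cols, st.weights)
            d_prior = -(new - old) / pr.branch_length_mean
            log_acc = (new_ll - st.log_likelihood) + d_prior + math.log(factor)

            def apply(node=node, new=new, new_cols=new_cols, new_ll=new_ll,
                      d_prior=d_prior):
                st.branch_lengths[node] = new
                st.log_likelihood = new_ll
                st.log_prior += d_prior
                if new_cols is not None:
                    self._cols = new_cols

            self._try_update("branch", log_acc, apply)

    def _rho_move(self) -> None:
        st = self.state
        if st.rho is None:
            return
        scale = self.tuning["rho"]
        simplex = st.rho / 6.0
        conc = scale * simplex + 0.1
        prop = self.rng.dirichlet(conc)
        if np.any(prop < PROFILE_FLOOR):
            self._record("rho", False)
            return
        prop = prop / prop.sum()
        conc_rev = scale * prop + 0.1
        log_hastings = (dirichlet_dist.logpdf(simplex, conc_rev)
                        - dirichlet_dist.logpdf(prop, conc))
        new_rho = prop * 6.0
        if self.prior_only:
            new_cols, new_ll = None, 0.0
        else:
            new_cols = self._columns(st.branch_lengths, new_rho, st.alpha, st.profiles)
            new_ll = self._total_loglik(new_cols, st.weights)
        log_acc = (new_ll - st.log_likelihood) + log_hastings

        def apply():
            st.rho = new_rho
            st.log_likelihood = new_ll
            if new_cols is not None:
                self._cols = new_cols

        self._try_update("rho", log_acc, apply)

    def _alpha_move(self) -> None:
        st = self.state
        if st.alpha is None:
            return
        pr = self.spec.priors
        scale = self.tuning["alpha"]
        factor = math.exp(scale * (self.rng.random() - 0.5))
        new_alpha = st.alpha * factor
        if self.prior_only:
            new_cols, new_ll = None, 0.0
        else:
            new_cols = self._columns(st.branch_lengths, st.rho, new_alpha, st.profiles)
            new_ll = self._total_loglik(new_cols, st.weights)
        d_prior = -(new_alpha - st.alpha) / pr.alpha_mean
        log_acc = (new_ll - st.log_likelihood) + d_prior + math.log(factor)

        def apply():
            st.alpha = new_alpha
            st.log_likelihood = new_ll
            st.log_prior += d_prior
            if new_cols is not None:
                self._cols = new_cols

        self._try_update("alpha", log_acc, apply)

    def _weight_move(self) -> None:
        st = self.state
        if st.weights is None or len(st.weights) < 2:
            return
        scale = self.tuning["weights"]
        conc = scale * st.weights + 0.1
        prop = self.rng.dirichlet(conc)
        if np.any(prop < PROFILE_FLOOR):
            self._record("weights", False)
            return
        prop = prop / prop.sum()
        conc_rev = scale * prop + 0.1
        log_hastings = (dirichlet_dist.logpdf(st.weights, conc_rev)
                        - dirichlet_dist.logpdf(prop, conc))
        new_ll = 0.0 if self.prior_only else self._total_loglik(self._cols, prop)
        log_acc = (new_ll - st.log_likelihood) + log_hastings

        def apply():
            st.weights = prop
            st.log_likelihood = new_ll

        self._try_update("weights", log_acc, apply)

    def _profile_moves(self) -> None:
        st = self.state
        scale = self.tuning["profile"]
        for c in range(len(st.profiles)):
            conc = scale * st.profiles[c].pi + 0.1
            prop = self.rng.dirichlet(conc)
            if np.any(prop < PROFILE_FLOOR):
                self._record("profile", False)
                continue
            prop = prop / prop.sum()
            conc_rev = scale * prop + 0.1
            log_hastings = (dirichlet_dist.logpdf(st.profiles[c].pi, conc_rev)
                            - dirichlet_dist.logpdf(prop, conc))
            new_profile = FrequencyProfile(prop)
            if self.prior_only:
                new_row, new_ll = None, 0.0
            else:
                new_row = self.engine.component_pattern_logl(
                    new_profile,
                    Exchangeabilities(st.rho) if st.rho is not None else None,
                    self._rates(st.alpha), st.branch_lengths)
                cols = self._cols.copy()
                cols[c] = new_row
                new_ll = self._total_loglik(cols, st.weights)
            log_acc = (new_ll - st.log_likelihood) + log_hastings

            def apply(c=c, new_profile=new_profile, new_row=new_row, new_ll=new_ll):
                st.profiles[c] = new_profile
                st.log_likelihood = new_ll
                if new_row is not None:
                    self._cols[c] = new_row

            self._try_update("profile", log_acc, apply)

    def _dp_sweep(self) -> None:
        st = self.state
        pr = self.spec.priors
        mixture = st.mixture_model(self.spec)
        alloc = SiteAllocation(st.allocation, n_components=len(st.profiles))
        result = dp_update(
            self.alignment, self.tree, (mixture, alloc), self.rng,
            engine=self.engine, branch_lengths=st.branch_lengths,
            prior_only=self.prior_only,
            profile_prior_concentration=pr.profile_concentration,
            concentration_prior=(1.0, 1.0 / pr.concentration_mean),
            profile_proposal_concentration=self.tuning["profile"],
            _return_columns=not self.prior_only,
        )
        if self.prior_only:
            new_mixture, new_alloc = result
            st.profiles = list(new_mixture.profiles)
            st.allocation = new_alloc.z
            st.concentration = new_mixture.concentration
            st.log_prior = self._log_prior()
            return
        new_mixture, new_alloc, site_columns = result
        st.profiles = list(new_mixture.profiles)
        st.weights = new_mixture.weights
        st.allocation = new_alloc.z
        st.concentration = new_mixture.concentration
        # rebuild the pattern-level caches for the new component set
        self._alloc_counts = self._allocated_pattern_counts(
            st.allocation, len(st.profiles))
        self._cols = self._columns(st.branch_lengths, st.rho, st.alpha, st.profiles)
        st.log_likelihood = self._total_loglik(self._cols, st.weights)
        st.log_prior = self._log_prior()

    def sweep(self) -> ChainState:
        """One full MCMC cycle over every move family."""
        self._branch_moves()
        self._rho_move()
        self._alpha_move()
        if self.spec.kind == "finite":
            self._weight_move()
        if self.spec.kind == "dp":
            self._dp_sweep()
        else:
            self._profile_moves()
        st = self.state
        if not math.isfinite(st.log_posterior):
            raise ArithmeticError("non-finite log posterior after sweep")
        st.cycle += 1
        return st

    def _tune(self) -> None:
        """Burn-in-only adaptation of proposal scales toward mid acceptance."""
        for family in ("branch", "alpha"):
            att = self._window_attempts[family]
            if att < 20:
                continue
            rate = self._window_accepts[family] / att
            if rate < 0.2:
                self.tuning[family] *= 0.7
            elif rate > 0.6:
                self.tuning[family] *= 1.4
        for family in ("rho", "weights", "profile"):
            att = self._window_attempts[family]
            if att < 20:
                continue
            rate = self._window_accepts[family] / att
            # Dirichlet proposals: larger concentration = smaller steps
            if rate < 0.2:
                self.tuning[family] *= 1.6
            elif rate > 0.6:
                self.tuning[family] *= 0.6
            self.tuning[family] = min(max(self.tuning[family], 10.0), 1e6)
        for family in _MOVE_FAMILIES:
            self._window_accepts[family] = 0
            self._window_attempts[family] = 0

    def acceptance_rates(self) -> dict[str, float]:
        return {f: (self.accepts[f] / self.attempts[f]) if self.attempts[f] else math.nan
                for f in _MOVE_FAMILIES}

    def run(self, cycles: int, burnin: int,
            trace_path=None) -> PosteriorSampleSet:
        if not cycles > burnin >= 0:
            raise ValueError("need cycles > burnin >= 0")
        samples: list[ChainState] = []
        trace_fh = open(trace_path, "w") if trace_path else None
        if trace_fh:
            trace_fh.write("cycle\tlog_posterior\tlog_likelihood\talpha\t"
                           "tree_length\tn_occupied\tacc_branch\tacc_profile\n")
        try:
            for cycle in range(cycles):
                st = self.sweep()
                if cycle < burnin and (cycle + 1) % 50 == 0:
                    self._tune()
                if cycle >= burnin:
                    samples.append(st.copy())
                if trace_fh:
                    rates = self.acceptance_rates()
                    alpha = st.alpha if st.alpha is not None else math.nan
                    trace_fh.write(
                        f"{cycle}\t{st.log_posterior:.6f}\t{st.log_likelihood:.6f}\t"
                        f"{alpha:.6f}\t{st.branch_lengths[self.branch_nodes].sum():.6f}\t"
                        f"{len(st.profiles)}\t{rates['branch']:.3f}\t"
                        f"{rates['profile']:.3f}\n")
        finally:
            if trace_fh:
                trace_fh.close()
        return PosteriorSampleSet(samples=samples, spec=self.spec,
                                  provenance={"cycles": cycles, "burnin": burnin})


def mcmc_sweep(chain: Chain) -> ChainState:
    """Advance a chain by one full cycle and return its state."""
    return chain.sweep()


def run_chain(alignment: Alignment, tree: Phylogeny, spec: ModelSpec,
              cycles: int = 1500, burnin: int = 500, seed: int = 0,
              trace_path=None) -> PosteriorSampleSet:
    """Run one chain on one dataset and retain every post-burn-in cycle.

    The default 1500 cycles with 500 discarded as burn-in leaves K = 1000
    retained draws.  Snapshots are not thinned.
    """
    chain = Chain(alignment, tree, spec, seed=seed)
    out = chain.run(cycles, burnin, trace_path=trace_path)
    out.provenance.update({"seed": seed, "model": spec.label,
                           "n_sites": alignment.n_sites})
    return out
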