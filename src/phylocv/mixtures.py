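"""Finite and Dirichlet-process mixtures of nucleotide frequency profiles.

Each mixture component owns one stationary-frequency profile; the six
exchangeabilities, the gamma shape and the branch lengths are shared across
components.  A "Poisson" variant has no free exchangeabilities (all equal),
i.e. a mixture of F81-type matrices.  The Dirichlet-process version lets
the data choose the number of occupied components; its site-allocation
sweep is an auxiliary-component Gibbs sampler (m auxiliary components per
site update), which stays valid even though profiles are not conjugate to
the tree likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from phylocv.likelihood import LikelihoodEngine, _pattern_log_likelihoods
from phylocv.substitution import (
    Exchangeabilities,
    FrequencyProfile,
    GammaRates,
    PROFILE_FLOOR,
    build_rate_matrix,
)


@dataclass
class MixtureModel:
    """A mixture of frequency profiles sharing one exchangeability set.

    ``kind`` is ``single`` (one matrix), ``finite`` (fixed component count)
    or ``dp`` (Dirichlet process).  ``rho=None`` marks the Poisson variants
    (all exchangeabilities equal).  For DP models ``weights`` holds the
    occupancy fractions of the current allocation, which is also how a
    posterior snapshot is scored on new data.
    """

    kind: str
    profiles: list[FrequencyProfile]
    weights: np.ndarray | None = None
    rho: Exchangeabilities | None = None
    gamma: GammaRates | None = None
    concentration: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("single", "finite", "dp"):
            raise ValueError(f"unknown mixture kind {self.kind!r}")
        if not self.profiles:
            raise ValueError("mixture needs at least one profile")
        if self.kind == "single" and len(self.profiles) != 1:
            raise ValueError("a single-matrix model has exactly one profile")
        if self.weights is None and self.kind in ("single", "finite"):
            self.weights = np.full(len(self.profiles), 1.0 / len(self.profiles))
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.profiles),):
                raise ValueError("one weight per profile required")
            if abs(self.weights.sum() - 1.0) > 1e-12:
                raise ValueError("mixture weights must sum to 1")
        if self.kind == "dp":
            if self.concentration is None or self.concentration <= 0:
                raise ValueError("DP mixture requires a positive concentration")

    @property
    def n_components(self) -> int:
        return len(self.profiles)

    def component_weights(self) -> np.ndarray:
        if self.weights is None:
            raise ValueError("mixture has no weights attached")
        return self.weights

    @property
    def rates(self) -> np.ndarray:
        return self.gamma.rates if self.gamma is not None else np.array([1.0])


@dataclass
class SiteAllocation:
    """Per-site component membership ``z`` plus the occupancy counts."""

    z: np.ndarray
    n_components: int | None = None
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=int)
        k = self.n_components if self.n_components is not None else int(self.z.max()) + 1
        self.n_components = k
        self.counts = np.bincount(self.z, minlength=k)

    @property
    def n_sites(self) -> int:
        return self.z.shape[0]


def site_mixture_log_likelihood(component_site_likelihoods, weights) -> float:
    """ln(sum_c w_c L_c) of one site, evaluated with log-sum-exp."""
    lik = np.asarray(component_site_likelihoods, dtype=float)
    w = np.asarray(weights, dtype=float)
    if lik.shape != w.shape:
        raise ValueError(
            f"{lik.shape[0]} component likelihoods but {w.shape[0]} weights"
        )
    if np.any(lik < 0):
        raise ValueError("component likelihoods must be non-negative")
    with np.errstate(divide="ignore"):
        log_terms = np.log(lik) + np.log(w)
    return float(logsumexp(log_terms))


def site_mixture_likelihood(component_site_likelihoods, weights) -> float:
    """Mixture likelihood sum_c w_c L_c of one site (log-space internally)."""
    return float(np.exp(site_mixture_log_likelihood(component_site_likelihoods,
                                                    weights)))


def _sample_categorical_log(log_probs: np.ndarray, rng: np.random.Generator) -> int:
    """Draw from an unnormalized log-probability vector (Gumbel-max)."""
    g = rng.gumbel(size=log_probs.shape)
    return int(np.argmax(log_probs + g))


def gibbs_resample_allocations(alignment, tree, mixture: MixtureModel,
                               rng: np.random.Generator,
                               component_logl: np.ndarray | None = None,
                               engine: LikelihoodEngine | None = None) -> SiteAllocation:
    """One Gibbs pass over site allocations of a finite mixture.

    Each ``z_n`` is drawn from the conditional posterior proportional to
    ``w_c p(D_n | component c)``, all sites in parallel.  The component
    likelihood table may be passed in to avoid recomputation.
    """
    if component_logl is None:
        if engine is None:
            engine = LikelihoodEngine(alignment, tree)
        component_logl = engine.component_site_logl(mixture, tree.lengths)
    log_w = np.log(mixture.component_weights())
    log_post = component_logl + log_w[np.newaxis, :]
    finite = np.isfinite(logsumexp(log_post, axis=1))
    if not finite.all():
        site = int(np.argmin(finite))
        raise ArithmeticError(
            f"all mixture components assign zero likelihood at site {site + 1}"
        )
    g = rng.gumbel(size=log_post.shape)
    z = np.argmax(log_post + g, axis=1)
    return SiteAllocation(z, n_components=mixture.n_components)


def _draw_profile(rng: np.random.Generator, concentration: float = 1.0) -> FrequencyProfile:
    return FrequencyProfile.from_values(rng.dirichlet(np.full(4, concentration)))


def _single_site_logl(engine: LikelihoodEngine, profile: FrequencyProfile,
                      rho, rates: np.ndarray, branch_lengths: np.ndarray,
                      site: int) -> float:
    """Log-likelihood of one site under one profile (rate categories averaged)."""
    pattern = engine.pattern_index[site]
    masks = {leaf: m[pattern:pattern + 1] for leaf, m in engine.leaf_masks.items()}
    q = build_rate_matrix(profile, rho if rho is not None else Exchangeabilities.equal())
    vals = np.empty(len(rates))
    for k, rate in enumerate(rates):
        p = q.transition_matrices(branch_lengths * rate)
        vals[k] = _pattern_log_likelihoods(engine.tree, masks, p, q.pi)[0]
    return float(logsumexp(vals) - np.log(len(rates)))


def _profile_move(profile: FrequencyProfile, log_target, rng: np.random.Generator,
                  proposal_concentration: float = 200.0) -> tuple[FrequencyProfile, bool]:
    """Metropolis–Hastings step on the 4-simplex with a Dirichlet proposal.

    The proposal is Dirichlet centred on the current point; proposals with
    an entry below the profile floor are rejected outright (a reflecting
    truncation that leaves the stationary law on the floored simplex).
    """
    from scipy.stats import dirichlet as dirichlet_dist

    conc = proposal_concentration * profile.pi + 0.1
    prop = rng.dirichlet(conc)
    if np.any(prop < PROFILE_FLOOR):
        return profile, False
    prop_profile = FrequencyProfile(prop / prop.sum())
    conc_rev = proposal_concentration * prop_profile.pi + 0.1
    log_hastings = (dirichlet_dist.logpdf(profile.pi, conc_rev)
                    - dirichlet_dist.logpdf(prop_profile.pi, conc))
    log_acc = log_target(prop_profile) - log_target(profile) + log_hastings
    if np.log(rng.random()) < log_acc:
        return prop_profile, True
    return profile, False


def dp_update(alignment, tree, mixture_state, rng: np.random.Generator, *,
              m_aux: int = 3,
              engine: LikelihoodEngine | None = None,
              branch_lengths: np.ndarray | None = None,
              prior_only: bool = False,
              profile_prior_concentration: float = 1.0,
              concentration_prior: tuple[float, float] = (1.0, 0.1),
              update_concentration: bool = True,
              profile_proposal_concentration: float = 200.0,
              _return_columns: bool = False):
    """One Dirichlet-process sweep: allocations, profiles, concentration.

    ``mixture_state`` is a ``(MixtureModel, SiteAllocation)`` pair.  Site
    allocations are updated sequentially with ``m_aux`` fresh auxiliary
    components drawn from the Dirichlet(1,1,1,1) base measure per site;
    emptied components are removed (their profile is recycled as the first
    auxiliary, per the auxiliary-variable scheme), so no orphan profiles
    survive.  Occupied profiles are then refreshed by a Metropolis step
    against the likelihood of their member sites, and the concentration is
    resampled by the beta-augmentation conditional.

    With ``prior_only=True`` the likelihood term is dropped and the sweep
    samples the Chinese-restaurant-process prior exactly.
    """
    mixture, alloc = mixture_state
    if mixture.kind != "dp":
        raise ValueError("dp_update requires a DP mixture")
    n_sites = alloc.n_sites
    conc = float(mixture.concentration)
    profiles = list(mixture.profiles)
    z = alloc.z.copy()
    rates = mixture.rates

    if prior_only:
        # with the likelihood term dropped the allocation scan reduces to the
        # Chinese restaurant process: the m auxiliary tables pool to mass conc
        counts_list = list(np.bincount(z, minlength=len(profiles)).astype(int))
        for n in range(n_sites):
            c = z[n]
            counts_list[c] -= 1
            if counts_list[c] == 0:
                counts_list.pop(c)
                z[z > c] -= 1
            probs = np.array(counts_list + [conc], dtype=float)
            u = rng.random() * probs.sum()
            choice = int(np.searchsorted(np.cumsum(probs), u))
            choice = min(choice, len(counts_list))
            if choice == len(counts_list):
                counts_list.append(1)
            else:
                counts_list[choice] += 1
            z[n] = choice
        profiles = [_draw_profile(rng, profile_prior_concentration)
                    for _ in counts_list]
        if update_concentration:
            conc = resample_concentration(len(profiles), n_sites, conc, rng,
                                          prior_shape=concentration_prior[0],
                                          prior_rate=concentration_prior[1])
        counts = np.array(counts_list, dtype=float)
        new_mixture = MixtureModel(kind="dp", profiles=profiles,
                                   weights=counts / counts.sum(),
                                   rho=mixture.rho, gamma=mixture.gamma,
                                   concentration=conc)
        return new_mixture, SiteAllocation(z, n_components=len(profiles))

    if engine is None:
        engine = LikelihoodEngine(alignment, tree)
    if branch_lengths is None:
        branch_lengths = tree.lengths
    # cached per-component site log-likelihood columns, kept in step with z
    columns = [engine.component_site_logl(
        replace(mixture, kind="dp", profiles=[p], weights=None), branch_lengths
    )[:, 0] for p in profiles]

    counts = np.bincount(z, minlength=len(profiles)).astype(int)

    def column_for(profile: FrequencyProfile) -> np.ndarray:
        if prior_only:
            return np.zeros(n_sites)
        one = replace(mixture, kind="dp", profiles=[profile], weights=None)
        return engine.component_site_logl(one, branch_lengths)[:, 0]

    for n in range(n_sites):
        c = z[n]
        counts[c] -= 1
        if counts[c] == 0:
            recycled = profiles.pop(c)
            columns.pop(c)
            counts = np.delete(counts, c)
            z[z > c] -= 1
            aux_profiles = [recycled] + [_draw_profile(rng, profile_prior_concentration)
                                         for _ in range(m_aux - 1)]
        else:
            aux_profiles = [_draw_profile(rng, profile_prior_concentration)
                            for _ in range(m_aux)]
        k = len(profiles)
        log_probs = np.empty(k + m_aux)
        if k:
            existing = np.array([columns[c2][n] for c2 in range(k)])
            log_probs[:k] = np.log(counts[:k]) + (0.0 if prior_only else existing)
        for a, prof in enumerate(aux_profiles):
            lik = 0.0 if prior_only else _single_site_logl(
                engine, prof, mixture.rho, rates, branch_lengths, n)
            log_probs[k + a] = np.log(conc / m_aux) + lik
        choice = _sample_categorical_log(log_probs, rng)
        if choice < k:
            z[n] = choice
            counts[choice] += 1
        else:
            new_prof = aux_profiles[choice - k]
            profiles.append(new_prof)
            columns.append(column_for(new_prof))
            counts = np.append(counts, 1)
            z[n] = k

    # refresh occupied component profiles from their conditionals
    for c in range(len(profiles)):
        members = np.flatnonzero(z == c)
        if prior_only:
            profiles[c] = _draw_profile(rng, profile_prior_concentration)
            continue

        def log_target(profile: FrequencyProfile, _members=members) -> float:
            col = column_for(profile)
            return float(col[_members].sum())  # flat Dirichlet prior adds a constant

        new_prof, accepted = _profile_move(
            profiles[c], log_target, rng,
            proposal_concentration=profile_proposal_concentration)
        if accepted:
            profiles[c] = new_prof
            columns[c] = column_for(new_prof)

    if update_concentration:
        conc = resample_concentration(len(profiles), n_sites, conc, rng,
                                      prior_shape=concentration_prior[0],
                                      prior_rate=concentration_prior[1])

    weights = counts / counts.sum()
    new_mixture = MixtureModel(kind="dp", profiles=profiles, weights=weights,
                               rho=mixture.rho, gamma=mixture.gamma,
                               concentration=conc)
    new_alloc = SiteAllocation(z, n_components=len(profiles))
    if _return_columns:
        return new_mixture, new_alloc, np.column_stack(columns)
    return new_mixture, new_alloc


def resample_concentration(occupied: int, n_sites: int, current: float,
                           rng: np.random.Generator,
                           prior_shape: float = 1.0,
                           prior_rate: float = 0.1) -> float:
    """Gibbs draw of the DP concentration given the number of occupied components.

    Beta-augmentation scheme: draw eta ~ Beta(current+1, n), then the
    concentration from the two-gamma mixture conditional under a
    Gamma(prior_shape, prior_rate) prior (the default is Exponential with
    mean 10).
    """
    if occupied < 1:
        raise ValueError("at least one occupied component required")
    a, b = prior_shape, prior_rate
    eta = rng.beta(current + 1.0, n_sites)
    rate = b - np.log(eta)
    odds = (a + occupied - 1.0) / (n_sites * rate)
    if rng.random() < odds / (1.0 + odds):
        return float(rng.gamma(a + occupied, 1.0 / rate))
    return float(rng.gamma(a + occupied - 1.0, 1.0 / rate))
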