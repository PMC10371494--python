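"""Sitewise Bayesian cross-validation of substitution models.

One replicate draws a random fifth of the alignment columns as the testing
set, fits each model by MCMC on the remaining four fifths, and scores the
held-out columns under the retained posterior draws:

    CV score = sum_n ln[(1/K) sum_k p(D_n | theta_k)]

Scores are reported relative to a reference model (GTR+G by default) on
the same splits, and the whole protocol is repeated (five times by
default) to give a mean and standard deviation per model.  Within a
replicate every model sees the same split — the paired design that makes
the difference-score arithmetic meaningful at small replicate counts.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from phylocv.alignment import Alignment
from phylocv.likelihood import LikelihoodEngine
from phylocv.mcmc import ModelSpec, PosteriorSampleSet, run_chain
from phylocv.tree import Phylogeny


@dataclass
class FoldSplit:
    """One learning/testing partition of alignment columns."""

    learning: Alignment
    testing: Alignment
    replicate_id: int
    seed: int

    def __post_init__(self) -> None:
        learn = set(self.learning.site_ids.tolist())
        test = set(self.testing.site_ids.tolist())
        if learn & test:
            raise ValueError("learning and testing columns overlap")

    @property
    def split_id(self) -> str:
        """A stable hash of the testing-column membership."""
        digest = hashlib.sha256(self.testing.site_ids.tobytes()).hexdigest()
        return digest[:12]


def testing_set_size(n_sites: int, fraction: float = 0.2) -> int:
    """Round-half-even of ``n_sites * fraction`` (the remainder convention)."""
    return round(n_sites * fraction)


def split_fold(alignment: Alignment, fraction: float = 0.2, seed: int = 0,
               replicate_id: int = 0) -> FoldSplit:
    """Draw a testing fifth of the columns uniformly without replacement."""
    n = alignment.n_sites
    if n < 5:
        raise ValueError(f"need at least 5 sites to split, got {n}")
    k = testing_set_size(n, fraction)
    rng = np.random.default_rng(seed)
    test_idx = np.sort(rng.choice(n, size=k, replace=False))
    mask = np.zeros(n, dtype=bool)
    mask[test_idx] = True
    return FoldSplit(learning=alignment.take_columns(np.flatnonzero(~mask)),
                     testing=alignment.take_columns(test_idx),
                     replicate_id=replicate_id, seed=seed)


def split_kfold(alignment: Alignment, n_folds: int = 5,
                seed: int = 0) -> list[FoldSplit]:
    """A disjoint k-fold partition (the alternative to independent draws)."""
    n = alignment.n_sites
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} sites")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    out = []
    for r, test_idx in enumerate(folds):
        mask = np.zeros(n, dtype=bool)
        mask[test_idx] = True
        out.append(FoldSplit(learning=alignment.take_columns(np.flatnonzero(~mask)),
                             testing=alignment.take_columns(np.sort(test_idx)),
                             replicate_id=r, seed=seed))
    return out


def cv_score_from_site_log_likelihoods(per_draw_logl: np.ndarray) -> float:
    """The CV score from a (K draws x n sites) site log-likelihood table.

    Implements sum_n ln[(1/K) sum_k p(D_n|theta_k)] with the inner average
    taken in probability space via log-sum-exp.
    """
    per_draw_logl = np.atleast_2d(np.asarray(per_draw_logl, dtype=float))
    k = per_draw_logl.shape[0]
    site_scores = logsumexp(per_draw_logl, axis=0) - math.log(k)
    return float(site_scores.sum())


def cv_score(testing: Alignment, samples: PosteriorSampleSet,
             tree: Phylogeny) -> float:
    """Sum over testing sites of ln[(1/K) sum_k p(D_n | theta_k)].

    Site likelihoods are evaluated in marginal mode (rate categories and
    mixture components integrated) under each retained draw; the average
    over draws is taken in probability space via log-sum-exp.
    """
    if not samples.samples:
        raise ValueError("empty posterior sample set")
    if testing.n_sites == 0:
        raise ValueError("empty testing set")
    engine = LikelihoodEngine(testing, tree)
    k = len(samples.samples)
    per_draw = np.empty((k, testing.n_sites))
    for i, st in enumerate(samples.samples):
        model = st.mixture_model(samples.spec)
        per_draw[i] = engine.site_logl(model, st.branch_lengths).log_likelihoods
    site_scores = logsumexp(per_draw, axis=0) - math.log(k)
    if not np.isfinite(site_scores).all():
        bad = int(np.flatnonzero(~np.isfinite(site_scores))[0])
        raise ArithmeticError(
            f"zero likelihood under every draw at site {testing.site_ids[bad] + 1}"
        )
    return cv_score_from_site_log_likelihoods(per_draw)


@dataclass
class CVReport:
    """Per-replicate CV scores for a set of models, with relative summaries."""

    scores: dict[str, np.ndarray]          # model label -> per-replicate scores
    reference: str
    split_ids: list[str] = field(default_factory=list)
    n_test_sites: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = {m: np.asarray(s, dtype=float) for m, s in self.scores.items()}
        if self.scores and self.reference not in self.scores:
            raise ValueError(f"reference model {self.reference!r} not scored")

    @property
    def models(self) -> list[str]:
        return list(self.scores)

    @property
    def n_replicates(self) -> int:
        return len(next(iter(self.scores.values()))) if self.scores else 0

    def deltas(self) -> dict[str, np.ndarray]:
        ref = self.scores[self.reference]
        return {m: s - ref for m, s in self.scores.items()}

    def summary(self) -> dict[str, dict[str, float]]:
        """Per model: mean/SD of the score and of the relative score."""
        out = {}
        deltas = self.deltas()
        for m, s in self.scores.items():
            d = deltas[m]
            out[m] = {
                "score_mean": float(s.mean()),
                "score_sd": float(s.std(ddof=1)) if len(s) > 1 else 0.0,
                "delta_mean": float(d.mean()),
                "delta_sd": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
            }
        return out


def relative_scores(scores: dict[str, np.ndarray], reference: str,
                    split_ids: dict[str, list[str]] | None = None
                    ) -> dict[str, dict[str, float]]:
    """Per-replicate differences to the reference, summarized as mean and SD.

    ``split_ids`` (model -> per-replicate split hashes), when given, guards
    the pairing: differencing scores computed on different splits is
    refused because the difference is only defined on shared splits.
    """
    if reference not in scores:
        raise ValueError(f"reference model {reference!r} missing from scores")
    if split_ids is not None:
        ref_ids = split_ids[reference]
        for m, ids in split_ids.items():
            if list(ids) != list(ref_ids):
                raise ValueError(
                    f"model {m!r} was scored on different splits than the reference"
                )
    ref = np.asarray(scores[reference], dtype=float)
    out = {}
    for m, s in scores.items():
        s = np.asarray(s, dtype=float)
        if s.shape != ref.shape:
            raise ValueError(f"model {m!r} has a different replicate count")
        d = s - ref
        out[m] = {
            "delta_mean": float(d.mean()),
            "delta_sd": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
            "deltas": d,
        }
    return out


def per_site_ratio(delta: float, n_sites: int) -> tuple[float, float]:
    """Per-site relative CV score and the implied fold-improvement per column.

    A relative score Delta over n sites means the average column is
    exp(Delta/n) times better explained by the model than by the reference.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    per_site = delta / n_sites
    return per_site, math.exp(per_site)


def run_protocol(alignment: Alignment, tree: Phylogeny,
                 model_specs: list[ModelSpec], replicates: int = 5,
                 seed: int = 0, cycles: int = 1500, burnin: int = 500,
                 reference: str | None = None, mode: str = "independent",
                 checkpoint_dir=None) -> CVReport:
    """The full cross-validation protocol for a set of models.

    Per replicate one fold split is shared by every model; each model is
    fit by MCMC on the learning set and scored on the testing set.  With
    ``mode="independent"`` (default) each replicate draws a fresh random
    fifth; ``mode="kfold"`` uses a disjoint 5-fold partition instead.
    Partial results are checkpointed per (model, replicate) when a
    directory is given, making long protocols resumable.
    """
    if not model_specs:
        raise ValueError("need at least one model spec")
    labels = [spec.label for spec in model_specs]
    if len(set(labels)) != len(labels):
        raise ValueError("model specs must have distinct labels")
    if reference is None:
        reference = "GTR+G" if "GTR+G" in labels else labels[0]
    if reference not in labels:
        raise ValueError(f"reference {reference!r} is not among the model specs")

    root_seq = np.random.SeedSequence(seed)
    split_seeds = root_seq.spawn(replicates)
    chain_seeds = root_seq.spawn(1)[0].generate_state(replicates * len(model_specs))

    if mode == "kfold":
        folds = split_kfold(alignment, n_folds=replicates, seed=seed)
    elif mode == "independent":
        folds = [split_fold(alignment, seed=int(ss.generate_state(1)[0] % (2**31)),
                            replicate_id=r)
                 for r, ss in enumerate(split_seeds)]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if checkpoint_dir is not None:
        checkpoint_dir = Path(checkpoint_dir)
        checkpoint_dir.mkdir(parents=True, exist_ok=True)

    scores: dict[str, np.ndarray] = {lab: np.empty(replicates) for lab in labels}
    for r, fold in enumerate(folds):
        for j, spec in enumerate(model_specs):
            lab = spec.label
            ckpt = None
            if checkpoint_dir is not None:
                safe = lab.replace("/", "_").replace("=", "")
                ckpt = checkpoint_dir / f"{safe}_rep{r}.json"
                if ckpt.exists():
                    payload = json.loads(ckpt.read_text())
                    if payload.get("split_id") == fold.split_id:
                        scores[lab][r] = payload["cv_score"]
                        continue
            chain_seed = int(chain_seeds[r * len(model_specs) + j] % (2**31))
            samples = run_chain(fold.learning, tree, spec, cycles=cycles,
                                burnin=burnin, seed=chain_seed)
            scores[lab][r] = cv_score(fold.testing, samples, tree)
            if ckpt is not None:
                ckpt.write_text(json.dumps({
                    "model": lab, "replicate": r, "cv_score": scores[lab][r],
                    "split_id": fold.split_id, "seed": chain_seed,
                }))
    return CVReport(scores=scores, reference=reference,
                    split_ids=[f.split_id for f in folds],
                    n_test_sites=[f.testing.n_sites for f in folds])
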