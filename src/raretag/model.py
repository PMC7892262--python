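"""Bayesian gene-tag association with latent per-variant pathogenicity.

The model compares a baseline hypothesis, in which every subject is a case
with a common rate tau0 ~ Beta(a0, b0), against association models in which
subjects carrying a *pathogenic configuration* of rare alleles are cases at
an elevated rate tau1 ~ Beta(a1, b1) (the penetrance).  Which of the k
candidate variants in a gene are actually pathogenic is unknown: a latent
indicator vector z in {0,1}^k with z_j | omega ~ Bernoulli(omega) and
omega ~ Beta(w_a, w_b) (omega integrated out analytically) selects them.
Given z and a mode of inheritance (MOI), subject i's configuration is

    dominant:  x_i = 1  iff  any selected variant has allele count >= 1
    recessive: x_i = 1  iff  the summed count over selected variants >= 2
               (phase-unaware compound heterozygotes qualify)

Both strata are Bernoulli samples with conjugate Beta rates, so the
evidence given z is a product of two beta-binomial marginals and the full
association evidence is the sum over all 2^k values of z.  For small k the
sum is enumerated exactly; for large k it is estimated by a stepping-stone
sampler over a power-posterior ladder.

Evidence ratios are reported as natural-log Bayes factors.  The posterior
probability of association is pp = pi*B / (pi*B + 1 - pi) for a prior
probability of association pi and the prior-weighted average Bayes factor B
across the (MOI x impact-class) model grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import betaln, logsumexp
from sklearn.base import BaseEstimator

__all__ = [
    "AssociationPriors",
    "AssociationResult",
    "RareVariantAssociation",
    "log_beta_marginal",
    "log_evidence_null",
    "log_evidence_given_z",
    "log_prior_z",
    "log_evidence_assoc_exact",
    "log_evidence_assoc_sampled",
    "overall_bf_and_pp",
    "model_posterior",
    "moi_posterior",
    "variant_posterior",
]

MOI_DOMINANT = "dominant"
MOI_RECESSIVE = "recessive"
_MOIS = (MOI_DOMINANT, MOI_RECESSIVE)

# enumeration block size: bounds the 2^k x n_carriers working array
_Z_CHUNK = 4096


@dataclass(frozen=True)
class AssociationPriors:
    """Hyperparameters of the Bayesian gene-tag comparison.

    a0, b0
        Beta prior on the baseline case rate tau0.  The default Beta(1, 9)
        reflects that tagged cases are a minority of the tested cohort.
    a1, b1
        Beta prior on the carrier case rate tau1 (the penetrance).  The
        default Beta(3, 1) encodes an expectation of high penetrance for a
        truly pathogenic configuration.
    w_a, w_b
        Beta prior on the proportion omega of candidate variants that are
        pathogenic; Beta(1, 1) is uniform.
    model_weights
        Prior weights over (moi, impact-class) models.  ``None`` means
        uniform over whichever models are fitted.  Keys are
        ``"{moi}:{impact_class}"`` strings.
    pi
        Prior probability that the gene-tag pair is associated at all.
    k_max_exact
        Largest k for which the 2^k sum over z is enumerated exactly;
        beyond it the stepping-stone sampler is used.
    """

    a0: float = 1.0
    b0: float = 9.0
    a1: float = 3.0
    b1: float = 1.0
    w_a: float = 1.0
    w_b: float = 1.0
    model_weights: Mapping[str, float] | None = None
    pi: float = 1e-3
    k_max_exact: int = 16

    def __post_init__(self) -> None:
        for name in ("a0", "b0", "a1", "b1", "w_a", "w_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be > 0")
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must lie strictly in (0, 1)")
        if self.model_weights is not None:
            total = sum(self.model_weights.values())
            if not np.isclose(total, 1.0):
                object.__setattr__(
                    self,
                    "model_weights",
                    {k: v / total for k, v in self.model_weights.items()},
                )


@dataclass
class AssociationResult:
    """Per (gene, tag) inference output."""

    gene: str
    tag: str
    log_bf_per_model: dict[str, float]
    log_bf: float
    pp: float
    moi_posterior: dict[str, float]
    variant_posteriors: np.ndarray
    n_case: int
    n_control: int
    best_model: str | None = None
    flags: list[str] = field(default_factory=list)


def _validate_beta(a: float, b: float) -> None:
    if a <= 0 or b <= 0:
        raise ValueError("Beta hyperparameters must be strictly positive")


def log_beta_marginal(n_case: int, n_control: int, a: float, b: float) -> float:
    """Log marginal likelihood of a Bernoulli sample under a Beta(a, b) rate.

    Integrating tau out of tau^n_case (1-tau)^n_control gives
    B(a + n_case, b + n_control) / B(a, b).
    """
    _validate_beta(a, b)
    if np.any(np.asarray(n_case) < 0) or np.any(np.asarray(n_control) < 0):
        raise ValueError("counts must be non-negative")
    return betaln(a + n_case, b + n_control) - betaln(a, b)


def log_evidence_null(y: np.ndarray, priors: AssociationPriors) -> float:
    """Evidence of the no-association model: one shared case rate tau0."""
    y = np.asarray(y, dtype=bool)
    if y.size == 0:
        raise ValueError("y must be nonempty")
    n1 = int(y.sum())
    return float(log_beta_marginal(n1, y.size - n1, priors.a0, priors.b0))


def log_evidence_given_z(
    y: np.ndarray, x: np.ndarray, priors: AssociationPriors
) -> float:
    """Evidence conditional on a pathogenic configuration x.

    Non-carriers (x=0) are a Bernoulli sample at rate tau0, carriers (x=1)
    at rate tau1; both rates are integrated out.
    """
    y = np.asarray(y, dtype=bool)
    x = np.asarray(x, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n1_carrier = int((y & x).sum())
    n0_carrier = int((~y & x).sum())
    n1_base = int((y & ~x).sum())
    n0_base = int((~y & ~x).sum())
    return float(
        log_beta_marginal(n1_base, n0_base, priors.a0, priors.b0)
        + log_beta_marginal(n1_carrier, n0_carrier, priors.a1, priors.b1)
    )


def log_prior_z(z: np.ndarray, k: int, priors: AssociationPriors) -> float:
    """Log prior of a pathogenicity vector with omega integrated out.

    Exchangeable in z: depends only on s = sum(z).  Sums to one over
    {0,1}^k by beta-binomial conjugacy.
    """
    z = np.asarray(z)
    if z.size != k:
        raise ValueError("len(z) must equal k")
    s = int(np.sum(z != 0))
    return float(
        betaln(priors.w_a + s, priors.w_b + k - s) - betaln(priors.w_a, priors.w_b)
    )


def _log_prior_by_count(k: int, priors: AssociationPriors) -> np.ndarray:
    s = np.arange(k + 1)
    return betaln(priors.w_a + s, priors.w_b + k - s) - betaln(priors.w_a, priors.w_b)


def _carrier_reduce(y: np.ndarray, G: np.ndarray):
    """Split subjects into rows that can ever carry (any alt allele) and the
    inert remainder, whose stratum counts are fixed for every z."""
    y = np.asarray(y, dtype=bool)
    G = np.asarray(G)
    if G.ndim != 2 or G.shape[0] != y.size:
        raise ValueError("G must be N x k aligned with y")
    carrier_rows = G.any(axis=1)
    Gc = G[carrier_rows]
    yc = y[carrier_rows]
    n1_inert = int(y[~carrier_rows].sum())
    n0_inert = int((~y[~carrier_rows]).sum())
    return yc, Gc, n1_inert, n0_inert


def _config_matrix(Z: np.ndarray, Gc: np.ndarray, moi: str) -> np.ndarray:
    """Configuration indicators for a block of z vectors.

    Z: (m, k) binary; Gc: (n_carriers, k) counts.  Returns (m, n_carriers).
    """
    if moi == MOI_DOMINANT:
        return (Z @ (Gc > 0).T.astype(np.int64)) >= 1
    if moi == MOI_RECESSIVE:
        return (Z @ Gc.T.astype(np.int64)) >= 2
    raise ValueError(f"unknown mode of inheritance: {moi!r}")


def pathogenic_configuration(G: np.ndarray, z: np.ndarray, moi: str) -> np.ndarray:
    """Per-subject pathogenic-configuration indicator x for one z and MOI."""
    G = np.asarray(G)
    z = np.asarray(z, dtype=np.int64)
    if z.size != G.shape[1]:
        raise ValueError("len(z) must equal the number of variants")
    return _config_matrix(z[None, :], G, moi)[0]


def _enumerate_terms(
    y: np.ndarray, G: np.ndarray, moi: str, priors: AssociationPriors
):
    """Yield (Z_block, per-z log joint) over all 2^k pathogenicity vectors."""
    k = G.shape[1]
    yc, Gc, n1_inert, n0_inert = _carrier_reduce(y, G)
    yc_f = yc.astype(np.int64)
    log_prior = _log_prior_by_count(k, priors)
    codes = np.arange(2**k, dtype=np.int64)
    for start in range(0, codes.size, _Z_CHUNK):
        block = codes[start : start + _Z_CHUNK]
        Z = ((block[:, None] >> np.arange(k)) & 1).astype(np.int64)
        X = _config_matrix(Z, Gc, moi)
        n1_carrier = X @ yc_f
        n_carrier = X.sum(axis=1)
        n0_carrier = n_carrier - n1_carrier
        n1_base = n1_inert + int(yc.sum()) - n1_carrier
        n0_base = n0_inert + int((~yc).sum()) - n0_carrier
        log_lik = (
            betaln(priors.a0 + n1_base, priors.b0 + n0_base)
            - betaln(priors.a0, priors.b0)
            + betaln(priors.a1 + n1_carrier, priors.b1 + n0_carrier)
            - betaln(priors.a1, priors.b1)
        )
        yield Z, log_prior[Z.sum(axis=1)] + log_lik


def log_evidence_assoc_exact(
    y: np.ndarray, G: np.ndarray, moi: str, priors: AssociationPriors
) -> float:
    """Exact association evidence: log sum over all 2^k z of prior x likelihood.

    Raises if k exceeds ``priors.k_max_exact`` — use the sampler instead.
    """
    k = np.asarray(G).shape[1]
    if k > priors.k_max_exact:
        raise ValueError(
            f"k={k} exceeds k_max_exact={priors.k_max_exact}; "
            "use log_evidence_assoc_sampled"
        )
    if k == 0:
        return log_evidence_null(y, priors)
    parts = [logsumexp(term) for _, term in _enumerate_terms(y, G, moi, priors)]
    return float(logsumexp(parts))


def variant_posterior(
    y: np.ndarray, G: np.ndarray, moi: str, priors: AssociationPriors
) -> np.ndarray:
    """Posterior inclusion probability P(z_j = 1 | y, model) per variant."""
    G = np.asarray(G)
    k = G.shape[1]
    if k == 0:
        return np.empty(0)
    if k > priors.k_max_exact:
        raise ValueError("variant_posterior requires k <= k_max_exact")
    log_num = np.full(k, -np.inf)
    log_den = -np.inf
    for Z, terms in _enumerate_terms(y, G, moi, priors):
        log_den = logsumexp([log_den, logsumexp(terms)])
        for j in range(k):
            sel = Z[:, j] == 1
            if sel.any():
                log_num[j] = logsumexp([log_num[j], logsumexp(terms[sel])])
    return np.exp(log_num - log_den)


def log_evidence_assoc_sampled(
    y: np.ndarray,
    G: np.ndarray,
    moi: str,
    priors: AssociationPriors,
    n_steps: int = 2000,
    seed: int | np.random.Generator = 0,
    n_rungs: int = 11,
    flag_tolerance: float = 1.0,
) -> tuple[float, float, bool]:
    """Stepping-stone estimate of the association evidence for large k.

    Runs a Gibbs sampler over z along a power-posterior ladder
    p_beta(z) ∝ p(z) L(z)^beta with a geometric beta schedule, and combines
    rungs with the stepping-stone identity
    log Z = sum_t log E_{beta_{t-1}}[ L^{beta_t - beta_{t-1}} ].

    Returns (log-evidence, Monte Carlo standard error, flagged).  The flag
    is set when the two half-chain estimates at any rung disagree by more
    than ``flag_tolerance`` log units.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y = np.asarray(y, dtype=bool)
    G = np.asarray(G)
    k = G.shape[1]
    if k == 0:
        return log_evidence_null(y, priors), 0.0, False

    yc, Gc, n1_inert, n0_inert = _carrier_reduce(y, G)
    n1_tot = int(y.sum())
    n0_tot = int(y.size - n1_tot)
    log_prior = _log_prior_by_count(k, priors)

    def log_lik(z: np.ndarray) -> float:
        x = _config_matrix(z[None, :], Gc, moi)[0]
        n1c = int((yc & x).sum())
        n0c = int((~yc & x).sum())
        return float(
            betaln(priors.a0 + n1_tot - n1c, priors.b0 + n0_tot - n0c)
            - betaln(priors.a0, priors.b0)
            + betaln(priors.a1 + n1c, priors.b1 + n0c)
            - betaln(priors.a1, priors.b1)
        )

    # geometric ladder: beta_0 = 0, then geometrically spaced up to 1
    betas = np.concatenate([[0.0], np.geomspace(1.0 / 2 ** (n_rungs - 2), 1.0, n_rungs - 1)])
    burn = max(20, n_steps // 10)

    z = np.zeros(k, dtype=np.int64)
    ll = log_lik(z)
    log_ratios = []
    stderrs = []
    flagged = False
    for t in range(1, len(betas)):
        b_prev, b_next = betas[t - 1], betas[t]
        samples = np.empty(n_steps)
        for it in range(burn + n_steps):
            for j in rng.permutation(k):
                z[j] ^= 1
                ll_new = log_lik(z)
                s_new = z.sum()
                s_old = s_new - 1 if z[j] == 1 else s_new + 1
                log_acc = (
                    log_prior[s_new]
                    - log_prior[s_old]
                    + b_prev * (ll_new - ll)
                )
                if np.log(rng.random()) < log_acc:
                    ll = ll_new
                else:
                    z[j] ^= 1
            if it >= burn:
                samples[it - burn] = ll
        d = b_next - b_prev
        w = d * samples
        log_mean = logsumexp(w) - np.log(n_steps)
        half = n_steps // 2
        lm1 = logsumexp(w[:half]) - np.log(half)
        lm2 = logsumexp(w[half:]) - np.log(n_steps - half)
        if abs(lm1 - lm2) > flag_tolerance:
            flagged = True
        # delta-method stderr of log-mean-exp with an effective-sample-size
        # correction from the lag-1 autocorrelation of the weights
        ew = np.exp(w - w.max())
        var = ew.var(ddof=1)
        if ew.size > 2 and var > 0:
            rho = np.corrcoef(ew[:-1], ew[1:])[0, 1]
            rho = min(max(rho, 0.0), 0.99) if np.isfinite(rho) else 0.0
            ess = n_steps * (1 - rho) / (1 + rho)
        else:
            ess = n_steps
        se = np.sqrt(var / max(ess, 2.0)) / max(ew.mean(), 1e-300)
        log_ratios.append(log_mean)
        stderrs.append(se)
    return (
        float(sum(log_ratios)),
        float(np.sqrt(np.sum(np.square(stderrs)))),
        flagged,
    )


def overall_bf_and_pp(
    per_model_log_bf: Mapping[str, float], priors: AssociationPriors
) -> tuple[float, float]:
    """Prior-weighted overall Bayes factor and posterior probability.

    B = sum_m w_m B_m (in log space); pp = pi*B / (pi*B + 1 - pi).
    """
    models = list(per_model_log_bf)
    if not models:
        raise ValueError("no models supplied")
    log_w = _log_weights(models, priors)
    log_bf = logsumexp([log_w[m] + per_model_log_bf[m] for m in models])
    # pp = 1 / (1 + exp(log(1-pi) - log(pi) - log B)), stable for huge B
    log_odds = np.log(priors.pi) - np.log1p(-priors.pi) + log_bf
    pp = float(1.0 / (1.0 + np.exp(-log_odds)))
    return float(log_bf), pp


def _log_weights(models: Sequence[str], priors: AssociationPriors) -> dict[str, float]:
    if priors.model_weights is None:
        w = {m: 1.0 / len(models) for m in models}
    else:
        missing = [m for m in models if m not in priors.model_weights]
        if missing:
            raise ValueError(f"model_weights missing entries for {missing}")
        total = sum(priors.model_weights[m] for m in models)
        w = {m: priors.model_weights[m] / total for m in models}
    return {m: np.log(v) for m, v in w.items()}


def model_posterior(
    per_model_log_bf: Mapping[str, float], priors: AssociationPriors
) -> dict[str, float]:
    """P(model | association) ∝ weight_m * BF_m, normalised over models."""
    models = list(per_model_log_bf)
    if not models:
        raise ValueError("no models supplied")
    log_w = _log_weights(models, priors)
    logs = np.array([log_w[m] + per_model_log_bf[m] for m in models])
    post = np.exp(logs - logsumexp(logs))
    return dict(zip(models, post.tolist()))


def moi_posterior(
    per_model_log_bf: Mapping[str, float], priors: AssociationPriors
) -> dict[str, float]:
    """Posterior over modes of inheritance, marginalised over impact classes."""
    post = model_posterior(per_model_log_bf, priors)
    out: dict[str, float] = {}
    for m, p in post.items():
        moi = m.split(":", 1)[0]
        out[moi] = out.get(moi, 0.0) + p
    return out


class RareVariantAssociation(BaseEstimator):
    """Gene-level Bayesian case-control association with latent pathogenicity.

    Fits the baseline-vs-association model comparison to an N x k matrix of
    alternate-allele counts ``X`` and a binary case vector ``y``, over a grid
    of (mode of inheritance) x (variant impact class) association models.

    Parameters mirror :class:`AssociationPriors`; ``random_state`` seeds the
    stepping-stone sampler used when a model's k exceeds ``k_max_exact``.

    Attributes (after ``fit``)
    --------------------------
    log_bf_per_model_ : dict mapping "moi:impact" -> natural-log Bayes factor
    log_bf_ : overall (prior-weighted) natural-log Bayes factor
    pp_ : posterior probability of association
    model_posterior_, moi_posterior_ : posterior over models / MOI
    best_model_ : highest-posterior model label
    variant_posteriors_ : per-variant P(z_j=1 | data, best model); NaN for
        variants outside the best model's impact class
    n_case_, n_control_ : stratum sizes
    flags_ : diagnostics (e.g. sampler non-convergence)
    """

    def __init__(
        self,
        a0: float = 1.0,
        b0: float = 9.0,
        a1: float = 3.0,
        b1: float = 1.0,
        w_a: float = 1.0,
        w_b: float = 1.0,
        pi: float = 1e-3,
        model_weights: Mapping[str, float] | None = None,
        moi: Sequence[str] = _MOIS,
        pool_impact_classes: bool = True,
        k_max_exact: int = 16,
        n_steps: int = 2000,
        random_state: int | None = None,
    ) -> None:
        self.a0 = a0
        self.b0 = b0
        self.a1 = a1
        self.b1 = b1
        self.w_a = w_a
        self.w_b = w_b
        self.pi = pi
        self.model_weights = model_weights
        self.moi = moi
        self.pool_impact_classes = pool_impact_classes
        self.k_max_exact = k_max_exact
        self.n_steps = n_steps
        self.random_state = random_state

    def _priors(self) -> AssociationPriors:
        return AssociationPriors(
            a0=self.a0,
            b0=self.b0,
            a1=self.a1,
            b1=self.b1,
            w_a=self.w_a,
            w_b=self.w_b,
            model_weights=self.model_weights,
            pi=self.pi,
            k_max_exact=self.k_max_exact,
        )

    def fit(self, X, y, impact_class: Sequence[str] | None = None):
        """Fit the model comparison.

        Parameters
        ----------
        X : array-like of shape (n_subjects, n_variants)
            Alternate-allele counts in {0, 1, 2}.
        y : array-like of shape (n_subjects,)
            Case (1) / control (0) labels.
        impact_class : sequence of str, optional
            Per-variant impact labels (``"high"`` / ``"moderate_deleterious"``).
            When given, each class is tested separately and, optionally,
            pooled; when omitted all variants form a single pooled class.
        """
        X = np.asarray(X)
        y = np.asarray(y).astype(bool)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (subjects x variants)")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have mismatched subject counts")
        if X.size and (np.any(X < 0) or np.any(X > 2)):
            raise ValueError("allele counts must lie in {0, 1, 2}")
        priors = self._priors()
        rng = np.random.default_rng(self.random_state)

        k = X.shape[1]
        if impact_class is None:
            class_cols: dict[str, np.ndarray] = {"pooled": np.arange(k)}
        else:
            impact_class = np.asarray(impact_class)
            if impact_class.shape[0] != k:
                raise ValueError("impact_class must have one label per variant")
            class_cols = {
                str(c): np.flatnonzero(impact_class == c)
                for c in dict.fromkeys(impact_class)
            }
            if self.pool_impact_classes and len(class_cols) > 1:
                class_cols["pooled"] = np.arange(k)

        log_null = log_evidence_null(y, priors)
        self.flags_ = []
        self.log_bf_per_model_ = {}
        self._model_cols = {}
        for moi in self.moi:
            for cname, cols in class_cols.items():
                label = f"{moi}:{cname}"
                sub = X[:, cols]
                if sub.shape[1] <= self.k_max_exact:
                    log_ev = log_evidence_assoc_exact(y, sub, moi, priors)
                else:
                    log_ev, se, flagged = log_evidence_assoc_sampled(
                        y, sub, moi, priors, n_steps=self.n_steps, seed=rng
                    )
                    if flagged:
                        self.flags_.append(f"sampler_nonconvergence:{label}")
                self.log_bf_per_model_[label] = log_ev - log_null
                self._model_cols[label] = cols

        self.log_bf_, self.pp_ = overall_bf_and_pp(self.log_bf_per_model_, priors)
        self.model_posterior_ = model_posterior(self.log_bf_per_model_, priors)
        self.moi_posterior_ = moi_posterior(self.log_bf_per_model_, priors)
        self.best_model_ = max(self.model_posterior_, key=self.model_posterior_.get)

        self.variant_posteriors_ = np.full(k, np.nan)
        best_cols = self._model_cols[self.best_model_]
        best_moi = self.best_model_.split(":", 1)[0]
        if best_cols.size and best_cols.size <= self.k_max_exact:
            self.variant_posteriors_[best_cols] = variant_posterior(
                y, X[:, best_cols], best_moi, priors
            )
        elif best_cols.size:
            warnings.warn(
                "variant posteriors unavailable: best model exceeds k_max_exact",
                stacklevel=2,
            )
        self.n_case_ = int(y.sum())
        self.n_control_ = int(y.size - y.sum())
        self.k_ = k
        return self

    def result(self, gene: str = "", tag: str = "") -> AssociationResult:
        """Package the fitted attributes as an :class:`AssociationResult`."""
        if not hasattr(self, "pp_"):
            raise AttributeError("estimator is not fitted")
        return AssociationResult(
            gene=gene,
            tag=tag,
            log_bf_per_model=dict(self.log_bf_per_model_),
            log_bf=self.log_bf_,
            pp=self.pp_,
            moi_posterior=dict(self.moi_posterior_),
            variant_posteriors=self.variant_posteriors_.copy(),
            n_case=self.n_case_,
            n_control=self.n_control_,
            best_model=self.best_model_,
            flags=list(self.flags_),
        )
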