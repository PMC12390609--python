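"""Latent-class analysis for the six binary eDNA amplification indicators.

eDNA site samples lack morphological verification, so a latent-class model
is fitted to the 6 binary indicators (3 qPCR replicates x 2 probes, coded
2 = amplification / 1 = none) to infer a proxy truth class per sample.

Model: a finite mixture over R classes. Class r has prevalence p_r and,
conditional on class membership, the indicators are independent Bernoulli
with response probability pi_jr = P(indicator j amplifies | class r):

    P(y) = sum_r p_r * prod_j pi_jr^y_j (1 - pi_jr)^(1 - y_j)

Fitting is by expectation-maximisation from multiple random starts, with
model selection over candidate R by information criteria plus multinomial
goodness-of-fit (G-squared and Pearson chi-squared over the 2^6 = 64
possible response patterns). The three-class solution is interpreted by
its response profiles as *Ae. sierrensis*, *Ae. aegypti*, and No
Detection, and each sample is assigned its modal-posterior class.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .qpcr_io import AEGYPTI, NO_DETECTION, N_INDICATORS, PatternRow, SIERRENSIS

# Response probabilities are clamped away from {0, 1} during EM so the
# log-likelihood stays finite even when a class explains an indicator
# perfectly.
_PROB_FLOOR = 1e-6

#: Labeling is refused when the best class-to-species margin is below this.
MIN_SEPARATION = 0.1


class LcaError(ValueError):
    pass


class LabelingError(LcaError):
    """The fitted classes cannot be mapped one-to-one onto species labels."""


@dataclass
class LcaModel:
    """Mixture parameters: prevalences (R,) and responses (J, R)."""

    prevalence: np.ndarray
    response: np.ndarray  # response[j, r] = P(indicator j amplifies | class r)

    def __post_init__(self) -> None:
        self.prevalence = np.asarray(self.prevalence, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.prevalence.ndim != 1 or self.response.ndim != 2:
            raise LcaError("prevalence must be 1-D and response 2-D (J x R)")
        if self.response.shape[1] != self.prevalence.shape[0]:
            raise LcaError("response column count must equal number of classes")
        if not np.isclose(self.prevalence.sum(), 1.0, atol=1e-8):
            raise LcaError("prevalences must sum to 1")
        if ((self.response < 0) | (self.response > 1)).any():
            raise LcaError("response probabilities must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return int(self.prevalence.shape[0])

    @property
    def n_indicators(self) -> int:
        return int(self.response.shape[0])

    @property
    def n_params(self) -> int:
        # (R - 1) free prevalences + J * R response probabilities
        return (self.n_classes - 1) + self.n_indicators * self.n_classes


@dataclass
class LcaFit:
    model: LcaModel
    loglik: float
    aic: float
    bic: float
    g_squared: float
    chi_squared: float
    df_fit: int
    converged: bool
    n_iterations: int
    posterior: np.ndarray  # (N, R), rows sum to 1
    n_obs: int
    sample_ids: list[str] = field(default_factory=list)
    loglik_history: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class ClassLabeling:
    """Injective map from class index to species label (R = 3)."""

    mapping: dict[int, str]
    separation_score: float


def _to_binary(patterns: Sequence[PatternRow]) -> np.ndarray:
    """(N, J) array in {0, 1}; 1 corresponds to the coded level 2."""
    if not patterns:
        raise LcaError("no patterns supplied")
    return np.array([[v - 1 for v in p.indicators] for p in patterns], dtype=float)


def pattern_probability(model: LcaModel, pattern: PatternRow | Sequence[int]) -> float:
    """Mixture probability of one coded pattern under the model."""
    indicators = pattern.indicators if isinstance(pattern, PatternRow) else pattern
    if len(indicators) != model.n_indicators:
        raise LcaError(
            f"pattern length {len(indicators)} != model indicators {model.n_indicators}"
        )
    y = np.asarray(indicators, dtype=float) - 1.0
    per_class = np.prod(
        model.response ** y[:, None] * (1.0 - model.response) ** (1.0 - y[:, None]), axis=0
    )
    return float(np.dot(model.prevalence, per_class))


def _log_pattern_matrix(y: np.ndarray, model: LcaModel) -> np.ndarray:
    """(K, R) log P(pattern_k | class r) for binary rows y."""
    logp = np.log(np.clip(model.response, _PROB_FLOOR, 1.0 - _PROB_FLOOR))
    log1m = np.log(np.clip(1.0 - model.response, _PROB_FLOOR, 1.0 - _PROB_FLOOR))
    return y @ logp + (1.0 - y) @ log1m


def _loglik_and_posterior(
    y: np.ndarray, counts: np.ndarray, model: LcaModel
) -> tuple[float, np.ndarray]:
    log_joint = _log_pattern_matrix(y, model) + np.log(model.prevalence)[None, :]
    log_mix = logsumexp(log_joint, axis=1)
    posterior = np.exp(log_joint - log_mix[:, None])
    return float(np.dot(counts, log_mix)), posterior


def _em_single(
    y: np.ndarray,
    counts: np.ndarray,
    init: LcaModel,
    max_iter: int,
    tol: float,
) -> tuple[LcaModel, float, list[float], bool, int]:
    n = counts.sum()
    model = init
    history: list[float] = []
    loglik, posterior = _loglik_and_posterior(y, counts, model)
    history.append(loglik)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        weights = posterior * counts[:, None]  # (K, R)
        class_mass = weights.sum(axis=0)
        prevalence = class_mass / n
        response = (weights.T @ y).T / class_mass[None, :]
        response = np.clip(response, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
        model = LcaModel(prevalence=prevalence / prevalence.sum(), response=response)
        new_loglik, posterior = _loglik_and_posterior(y, counts, model)
        history.append(new_loglik)
        if abs(new_loglik - loglik) < tol:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    return model, loglik, history, converged, iterations


def _random_init(rng: np.random.Generator, n_classes: int, n_indicators: int) -> LcaModel:
    prevalence = rng.dirichlet(np.ones(n_classes))
    response = rng.uniform(0.1, 0.9, size=(n_indicators, n_classes))
    return LcaModel(prevalence=prevalence, response=response)


def fit_em(
    patterns: Sequence[PatternRow],
    n_classes: int,
    n_starts: int = 20,
    max_iter: int = 5000,
    tol: float = 1e-8,
    seed: int = 0,
) -> LcaFit:
    """Fit an R-class model by EM from multiple random starts.

    The E-step computes class posteriors proportional to prevalence times
    the conditional-independence likelihood; the M-step replaces the
    prevalences with mean posteriors and each response probability with
    the posterior-weighted indicator mean. The best-likelihood start is
    returned, with goodness-of-fit computed over all 64 patterns.
    """
    if n_classes < 1:
        raise LcaError("n_classes must be >= 1")
    y_full = _to_binary(patterns)
    n_obs, n_ind = y_full.shape
    y_unique, inverse, counts = np.unique(
        y_full, axis=0, return_inverse=True, return_counts=True
    )
    counts = counts.astype(float)
    rng = np.random.default_rng(seed)
    best: tuple[LcaModel, float, list[float], bool, int] | None = None
    for _ in range(max(1, n_starts)):
        init = _random_init(rng, n_classes, n_ind)
        fit = _em_single(y_unique, counts, init, max_iter, tol)
        if best is None or fit[1] > best[1]:
            best = fit
    assert best is not None
    model, loglik, history, converged, iterations = best
    _, posterior_unique = _loglik_and_posterior(y_unique, counts, model)
    posterior = posterior_unique[inverse]
    g2, chi2, df_fit = goodness_of_fit(model, patterns)
    return LcaFit(
        model=model,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * model.n_params,
        bic=-2.0 * loglik + model.n_params * np.log(n_obs),
        g_squared=g2,
        chi_squared=chi2,
        df_fit=df_fit,
        converged=converged,
        n_iterations=iterations,
        posterior=posterior,
        n_obs=n_obs,
        sample_ids=[p.sample_id for p in patterns],
        loglik_history=history,
    )


def all_patterns(n_indicators: int = N_INDICATORS) -> list[tuple[int, ...]]:
    """All 2^J coded patterns in lexicographic order."""
    return [tuple(v) for v in itertools.product((1, 2), repeat=n_indicators)]


def goodness_of_fit(
    model_or_fit: LcaModel | LcaFit, patterns: Sequence[PatternRow]
) -> tuple[float, float, int]:
    """(G-squared, Pearson chi-squared, residual df) over all 64 cells.

    G2 = 2 * sum_{O_k > 0} O_k log(O_k / E_k) sums over observed patterns;
    chi2 = sum_{E_k > 0} (O_k - E_k)^2 / E_k over cells with positive
    expectation; df = 2^J - 1 - n_params.
    """
    model = model_or_fit.model if isinstance(model_or_fit, LcaFit) else model_or_fit
    n = len(patterns)
    observed: dict[tuple[int, ...], int] = {}
    for p in patterns:
        observed[p.indicators] = observed.get(p.indicators, 0) + 1
    g2 = 0.0
    chi2 = 0.0
    for cell in all_patterns(model.n_indicators):
        e = n * pattern_probability(model, cell)
        o = observed.get(cell, 0)
        if o > 0:
            g2 += 2.0 * o * np.log(o / e)
        if e > 0:
            chi2 += (o - e) ** 2 / e
    df_fit = 2**model.n_indicators - 1 - model.n_params
    return float(g2), float(chi2), int(df_fit)


def select_model(
    patterns: Sequence[PatternRow],
    candidates: Iterable[int] = (2, 3, 4),
    n_starts: int = 20,
    max_iter: int = 5000,
    tol: float = 1e-8,
    seed: int = 0,
) -> tuple[LcaFit, pd.DataFrame]:
    """Fit each candidate class count and choose by minimum BIC.

    Returns the chosen fit and a comparison table with all four criteria
    (AIC, BIC, G-squared, chi-squared) per candidate. When the criteria
    disagree about the best R, the table's ``attrs['criterion_choices']``
    records each criterion's winner; the choice itself is always BIC's.
    """
    candidates = sorted(set(candidates))
    if not candidates:
        raise LcaError("no candidate class counts supplied")
    fits: dict[int, LcaFit] = {}
    rows = []
    for r in candidates:
        sub_seed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % 2**31)
        fit = fit_em(patterns, r, n_starts=n_starts, max_iter=max_iter, tol=tol, seed=sub_seed)
        fits[r] = fit
        rows.append(
            {
                "n_classes": r,
                "loglik": fit.loglik,
                "n_params": fit.model.n_params,
                "aic": fit.aic,
                "bic": fit.bic,
                "g_squared": fit.g_squared,
                "chi_squared": fit.chi_squared,
                "df_fit": fit.df_fit,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows).set_index("n_classes")
    choices = {c: int(table[c].idxmin()) for c in ("aic", "bic", "g_squared", "chi_squared")}
    table.attrs["criterion_choices"] = choices
    table.attrs["criteria_agree"] = len(set(choices.values())) == 1
    return fits[choices["bic"]], table


def label_classes(fit: LcaFit, min_separation: float = MIN_SEPARATION) -> ClassLabeling:
    """Map fitted classes to species labels by their probe response profiles.

    With s_r (a_r) the mean response over the sierr (aegypti) indicators,
    the class maximising s_r - a_r is *Ae. sierrensis*, the class
    maximising a_r - s_r is *Ae. aegypti*, and the remaining class(es) are
    No Detection. The separation score is the smaller of the two winning
    margins over the runner-up; an ambiguous or weakly separated fit
    raises :class:`LabelingError` rather than guessing.
    """
    response = fit.model.response
    n_probe_reps = fit.model.n_indicators // 2
    s = response[:n_probe_reps].mean(axis=0)
    a = response[n_probe_reps:].mean(axis=0)
    d = s - a
    sierr_idx = int(np.argmax(d))
    aegy_idx = int(np.argmax(-d))
    if sierr_idx == aegy_idx:
        raise LabelingError(
            f"classes are indistinguishable: s - a = {np.round(d, 4).tolist()}"
        )

    def margin(values: np.ndarray, winner: int) -> float:
        others = np.delete(values, winner)
        return float(values[winner] - others.max())

    score = min(margin(d, sierr_idx), margin(-d, aegy_idx))
    if score < min_separation:
        raise LabelingError(
            f"separation score {score:.4f} below {min_separation}; response "
            f"profiles s = {np.round(s, 4).tolist()}, a = {np.round(a, 4).tolist()}"
        )
    mapping = {sierr_idx: SIERRENSIS, aegy_idx: AEGYPTI}
    for r in range(fit.model.n_classes):
        if r not in mapping:
            mapping[r] = NO_DETECTION
    if fit.model.n_classes == 3 and len(set(mapping.values())) != 3:
        raise LabelingError(f"labeling is not injective: {mapping}")
    return ClassLabeling(mapping=mapping, separation_score=score)


def assign_classes(
    fit: LcaFit, labeling: ClassLabeling, patterns: Sequence[PatternRow]
) -> pd.DataFrame:
    """Modal-posterior class per sample, mapped through the labeling.

    Returns a DataFrame with columns ``sample_id``, ``assigned_class`` and
    ``posterior`` (the modal class's posterior probability).
    """
    if len(patterns) != fit.posterior.shape[0]:
        raise LcaError("patterns do not match the fitted posterior matrix")
    modal = np.argmax(fit.posterior, axis=1)
    return pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in patterns],
            "assigned_class": [labeling.mapping[int(r)] for r in modal],
            "posterior": fit.posterior[np.arange(len(patterns)), modal],
        }
    )


def align_classes(model: LcaModel, truth_response: np.ndarray) -> list[int]:
    """Permutation of fitted classes best matching truth response columns.

    ``perm[j]`` is the fitted class index matched to truth class j, chosen
    to minimise the total mean absolute response difference (optimal
    assignment). Used for parameter-recovery checks where label switching
    must be undone.
    """
    from scipy.optimize import linear_sum_assignment

    r = model.n_classes
    cost = np.array(
        [
            [np.abs(model.response[:, i] - truth_response[:, j]).mean() for j in range(r)]
            for i in range(r)
        ]
    )
    fitted_idx, truth_idx = linear_sum_assignment(cost)
    perm = [0] * r
    for i, j in zip(fitted_idx, truth_idx):
        perm[j] = int(i)
    return perm
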