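"""Proportional-odds (cumulative-logit) likelihood with nested random effects.

For patient *i* in facility *j(i)* and county *c(i)* the latent linear
predictor is

    eta_i = x_i' beta + f_{j(i)} + u_{c(i)}·[u active] + phi_{c(i)}·[phi active]

and the category probabilities follow the cumulative-logit form

    P(y_i = k) = F(kappa_k - eta_i) - F(kappa_{k-1} - eta_i),

with F the logistic CDF, kappa_0 = -inf and kappa_K = +inf.  Cutpoints are
stored as (g1, positive increments) so that the ordering kappa_1 < ... <
kappa_{K-1} holds by construction.  There is no intercept: the cutpoints
absorb the location of the latent scale, which is why adding a constant to
eta and to every cutpoint leaves every probability unchanged.

Which random-effect terms enter eta is selected by ``structure``:

===============  ==========================
unstructured     u (iid county) + f
structured       phi (CAR county) + f
convolution      u + phi + f
none             f only
===============  ==========================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "CutpointSet",
    "ParameterState",
    "STRUCTURES",
    "structure_uses_u",
    "structure_uses_phi",
    "linear_predictor",
    "linear_predictor_all",
    "category_probabilities",
    "log_likelihood",
    "deviance",
]

STRUCTURES = ("none", "unstructured", "structured", "convolution")

_PROB_FLOOR = 1e-300


def structure_uses_u(structure: str) -> bool:
    return structure in ("unstructured", "convolution")


def structure_uses_phi(structure: str) -> bool:
    return structure in ("structured", "convolution")


def _check_structure(structure: str) -> None:
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}; expected one of {STRUCTURES}")


@dataclass
class CutpointSet:
    """Ordered cutpoints parameterised as a base value plus positive increments.

    ``g1`` is the first cutpoint; ``increments`` are the strictly positive
    gaps to the remaining ones, so ``kappa = g1 + cumsum([0, *increments])``.
    For the three-category study design this is (g1, g2) with
    kappa_1 = g1 and kappa_2 = g1 + g2.
    """

    g1: float
    increments: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    def __post_init__(self):
        self.increments = np.atleast_1d(np.asarray(self.increments, dtype=float))
        if np.any(self.increments <= 0):
            raise ValueError("cutpoint increments must be strictly positive")

    @property
    def kappa(self) -> np.ndarray:
        return self.g1 + np.concatenate(([0.0], np.cumsum(self.increments)))

    @property
    def n_categories(self) -> int:
        return len(self.increments) + 2

    @classmethod
    def from_kappa(cls, kappa) -> "CutpointSet":
        kappa = np.asarray(kappa, dtype=float)
        if kappa.ndim != 1 or len(kappa) < 1:
            raise ValueError("kappa must be a vector of length >= 1")
        if np.any(np.diff(kappa) <= 0):
            raise ValueError("kappa must be strictly increasing")
        return cls(g1=float(kappa[0]), increments=np.diff(kappa))


@dataclass
class ParameterState:
    """One point in parameter space: coefficients, cutpoints, random effects
    and their precisions."""

    beta: np.ndarray
    cutpoints: CutpointSet
    u: np.ndarray = None
    f: np.ndarray = None
    phi: np.ndarray = None
    tau_h: float = 1.0
    tau_v: float = 1.0
    tau_c: float = 1.0

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        for name in ("u", "f", "phi"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        for name in ("tau_h", "tau_v", "tau_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def copy(self) -> "ParameterState":
        return ParameterState(
            beta=self.beta.copy(),
            cutpoints=CutpointSet(self.cutpoints.g1, self.cutpoints.increments.copy()),
            u=None if self.u is None else self.u.copy(),
            f=None if self.f is None else self.f.copy(),
            phi=None if self.phi is None else self.phi.copy(),
            tau_h=self.tau_h,
            tau_v=self.tau_v,
            tau_c=self.tau_c,
        )


def _effect(vec, idx, n, what):
    if vec is None:
        raise ValueError(f"state has no {what} effects but the structure requires them")
    idx = np.asarray(idx, dtype=int) - 1
    if np.any(idx < 0) or np.any(idx >= len(vec)):
        raise IndexError(f"{what} index out of range for effect vector of length {len(vec)}")
    return vec[idx]


def linear_predictor(x_row, state: ParameterState, facility: int, county: int, structure: str) -> float:
    """Latent predictor for a single patient (1-based indices)."""
    eta = linear_predictor_all_raw(
        np.atleast_2d(np.asarray(x_row, dtype=float)),
        np.array([facility]),
        np.array([county]),
        state,
        structure,
    )
    return float(eta[0])


def linear_predictor_all_raw(X, facility_index, county_index, state: ParameterState, structure: str) -> np.ndarray:
    _check_structure(structure)
    eta = X @ state.beta if X.shape[1] else np.zeros(X.shape[0])
    if state.f is not None:
        eta = eta + _effect(state.f, facility_index, None, "facility")
    if structure_uses_u(structure):
        eta = eta + _effect(state.u, county_index, None, "county (u)")
    if structure_uses_phi(structure):
        eta = eta + _effect(state.phi, county_index, None, "county (phi)")
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor")
    return eta


def linear_predictor_all(dataset, state: ParameterState, structure: str) -> np.ndarray:
    """Vector of latent predictors for every patient in ``dataset``."""
    return linear_predictor_all_raw(
        dataset.X, dataset.facility_index, dataset.county_index, state, structure
    )


def category_probabilities(eta, cutpoints: CutpointSet) -> np.ndarray:
    """Category probabilities under the cumulative-logit model.

    ``eta`` may be a scalar (returns a length-K vector) or an array of
    shape (n,) (returns (n, K)).  Probabilities are computed as differences
    of numerically stable logistic CDFs and always sum to one.
    """
    eta_arr = np.atleast_1d(np.asarray(eta, dtype=float))
    kappa = cutpoints.kappa
    cum = expit(kappa[None, :] - eta_arr[:, None])  # P(y <= k), k = 1..K-1
    full = np.concatenate(
        [np.zeros((len(eta_arr), 1)), cum, np.ones((len(eta_arr), 1))], axis=1
    )
    probs = np.diff(full, axis=1)
    probs = np.clip(probs, 0.0, 1.0)
    if np.isscalar(eta) or np.asarray(eta).ndim == 0:
        return probs[0]
    return probs


def _row_log_probs(eta, y, cutpoints: CutpointSet) -> np.ndarray:
    kappa = cutpoints.kappa
    K = len(kappa) + 1
    cum = expit(kappa[None, :] - eta[:, None])
    full = np.concatenate([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))], axis=1)
    rows = np.arange(len(eta))
    p = full[rows, y] - full[rows, y - 1]
    return np.log(np.maximum(p, _PROB_FLOOR))


def log_likelihood(dataset, state: ParameterState, structure: str, use_weights: bool = False) -> float:
    """Sum over patients of the log probability of the realised category.

    ``use_weights`` multiplies each patient's contribution by its survey
    weight (a pseudo-likelihood diagnostic); the modelling default is the
    unweighted likelihood.
    """
    if dataset.n == 0:
        return 0.0
    eta = linear_predictor_all(dataset, state, structure)
    lp = _row_log_probs(eta, dataset.y, state.cutpoints)
    if use_weights and dataset.weight is not None:
        lp = lp * dataset.weight
    return float(np.sum(lp))


def deviance(dataset, state: ParameterState, structure: str) -> float:
    """Model deviance, D = -2 log-likelihood."""
    return -2.0 * log_likelihood(dataset, state, structure)
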