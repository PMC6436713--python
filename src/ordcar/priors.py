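"""Prior densities and conjugate precision updates.

Coefficients get independent normal priors whose precision depends on the
coefficient block (patient-level effects are given a slightly tighter
precision than the facility/county blocks, matching the BUGS model code the
analysis mirrors).  Unstructured county effects u and facility effects f
are iid normal with Gamma-distributed precisions; the spatially structured
county effects phi carry the intrinsic CAR prior

    log p(phi | tau_c) = -(tau_c / 2) * sum_{i~j} (phi_i - phi_j)^2 + const
                       = -(tau_c / 2) * phi' L phi + const,

where the sum runs over unordered neighbour pairs once and L is the graph
Laplacian.  The density is improper (invariant to adding a constant to
phi); identification is by the sum-to-zero constraint imposed in the
sampler.  All Gamma distributions use the shape-rate parameterisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .adjacency import AdjacencyStructure
from .likelihood import ParameterState, structure_uses_phi, structure_uses_u

__all__ = [
    "PriorSpec",
    "car_log_density",
    "log_prior_total",
    "sample_precision_conditional",
]


@dataclass
class PriorSpec:
    """Prior constants.  Defaults follow the hierarchical-model code the
    study used: block precisions (b: 0.001; s, q, m: 1e-6), first-cutpoint
    precision 0.01, Gamma(0.001, 0.001) for the cutpoint increment and the
    facility precision, and Gamma(0.5, 0.0005) for the county precisions."""

    beta_precision: dict = field(
        default_factory=lambda: {"b": 1e-3, "s": 1e-6, "q": 1e-6, "m": 1e-6}
    )
    beta_mean: float = 0.0
    g1_precision: float = 0.01
    g2_shape: float = 0.001
    g2_rate: float = 0.001
    tau_h_shape: float = 0.5
    tau_h_rate: float = 0.0005
    tau_c_shape: float = 0.5
    tau_c_rate: float = 0.0005
    tau_v_shape: float = 0.001
    tau_v_rate: float = 0.001

    def __post_init__(self):
        vals = [self.g1_precision, self.g2_shape, self.g2_rate,
                self.tau_h_shape, self.tau_h_rate, self.tau_c_shape,
                self.tau_c_rate, self.tau_v_shape, self.tau_v_rate]
        vals += list(self.beta_precision.values())
        if any(v <= 0 for v in vals):
            raise ValueError("all prior precisions, shapes and rates must be > 0")

    def beta_precisions_for(self, blocks) -> np.ndarray:
        return np.array([self.beta_precision[b] for b in blocks], dtype=float)


def _normal_logpdf(x, mean, precision):
    x = np.asarray(x, dtype=float)
    return 0.5 * np.log(precision / (2.0 * np.pi)) - 0.5 * precision * (x - mean) ** 2


def _gamma_logpdf(x, shape, rate):
    if x <= 0:
        return -np.inf
    return stats.gamma.logpdf(x, a=shape, scale=1.0 / rate)


def car_log_density(phi, adjacency: AdjacencyStructure, tau_c: float) -> float:
    """Unnormalised intrinsic-CAR log density, pairwise sum over unordered
    neighbour pairs counted once (equivalently -(tau/2) phi' L phi)."""
    phi = np.asarray(phi, dtype=float)
    if len(phi) != adjacency.n:
        raise ValueError(
            f"phi has length {len(phi)} but adjacency has {adjacency.n} counties"
        )
    if tau_c <= 0:
        raise ValueError("tau_c must be > 0")
    pos = 0
    total = 0.0
    num = np.asarray(adjacency.num)
    adj = np.asarray(adjacency.adj)
    # one pass over the flattened list; each unordered pair appears twice, so
    # halve the directed sum
    diffs = phi[np.repeat(np.arange(adjacency.n), num)] - phi[adj]
    total = float(np.sum(diffs**2)) / 2.0
    return -0.5 * tau_c * total


def pairwise_difference_sum(phi, adjacency: AdjacencyStructure) -> float:
    """Sum over unordered neighbour pairs of (phi_i - phi_j)^2."""
    phi = np.asarray(phi, dtype=float)
    num = np.asarray(adjacency.num)
    adj = np.asarray(adjacency.adj)
    diffs = phi[np.repeat(np.arange(adjacency.n), num)] - phi[adj]
    return float(np.sum(diffs**2)) / 2.0


def log_prior_total(
    state: ParameterState,
    prior: PriorSpec,
    adjacency: AdjacencyStructure = None,
    structure: str = "convolution",
    blocks=None,
) -> float:
    """Sum of all log prior terms active under ``structure``.

    Normal terms (coefficients, g1, u, f) include their normalising
    constants; Gamma terms are full log densities; the CAR term is the
    unnormalised pairwise form (its normalising constant does not involve
    phi and is dropped, as is standard for the intrinsic prior).
    """
    if blocks is None:
        blocks = ["b"] * len(state.beta)
    prec = prior.beta_precisions_for(blocks)
    total = float(np.sum(_normal_logpdf(state.beta, prior.beta_mean, prec)))
    total += float(_normal_logpdf(state.cutpoints.g1, 0.0, prior.g1_precision))
    for inc in state.cutpoints.increments:
        total += _gamma_logpdf(inc, prior.g2_shape, prior.g2_rate)
    if state.f is not None:
        total += float(np.sum(_normal_logpdf(state.f, 0.0, state.tau_v)))
        total += _gamma_logpdf(state.tau_v, prior.tau_v_shape, prior.tau_v_rate)
    if structure_uses_u(structure):
        if state.u is None:
            raise ValueError("structure uses u but state.u is None")
        total += float(np.sum(_normal_logpdf(state.u, 0.0, state.tau_h)))
        total += _gamma_logpdf(state.tau_h, prior.tau_h_shape, prior.tau_h_rate)
    if structure_uses_phi(structure):
        if state.phi is None:
            raise ValueError("structure uses phi but state.phi is None")
        if adjacency is None:
            raise ValueError("structure uses phi but no adjacency supplied")
        total += car_log_density(state.phi, adjacency, state.tau_c)
        total += _gamma_logpdf(state.tau_c, prior.tau_c_shape, prior.tau_c_rate)
    return total


def sample_precision_conditional(
    effects,
    prior_shape: float,
    prior_rate: float,
    kind: str = "iid",
    adjacency: AdjacencyStructure = None,
    rng: np.random.Generator = None,
) -> float:
    """Draw a precision from its conjugate Gamma full conditional.

    iid effects theta_1..theta_m ~ N(0, 1/tau) give

        tau | theta ~ Gamma(shape + m/2, rate + sum(theta^2)/2);

    CAR effects on a graph with n nodes and c connected components give

        tau | phi ~ Gamma(shape + (n - c)/2, rate + (1/2) sum_{i~j} (phi_i - phi_j)^2),

    the rank deficiency of the intrinsic prior removing one degree of
    freedom per component.
    """
    effects = np.asarray(effects, dtype=float)
    if effects.size == 0:
        raise ValueError("effects must be non-empty")
    if rng is None:
        rng = np.random.default_rng()
    if kind == "iid":
        shape = prior_shape + effects.size / 2.0
        rate = prior_rate + float(np.sum(effects**2)) / 2.0
    elif kind == "car":
        if adjacency is None:
            raise ValueError("kind='car' requires an adjacency structure")
        n_comp = len(adjacency.connected_components())
        shape = prior_shape + (adjacency.n - n_comp) / 2.0
        rate = prior_rate + 0.5 * pairwise_difference_sum(effects, adjacency)
    else:
        raise ValueError(f"unknown kind {kind!r}; expected 'iid' or 'car'")
    return float(rng.gamma(shape=shape, scale=1.0 / rate))


def conditional_gamma_parameters(effects, prior_shape, prior_rate, kind="iid", adjacency=None):
    """(shape, rate) of the conjugate full conditional, without drawing."""
    effects = np.asarray(effects, dtype=float)
    if kind == "iid":
        return (prior_shape + effects.size / 2.0,
                prior_rate + float(np.sum(effects**2)) / 2.0)
    n_comp = len(adjacency.connected_components())
    return (prior_shape + (adjacency.n - n_comp) / 2.0,
            prior_rate + 0.5 * pairwise_difference_sum(effects, adjacency))
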