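"""Metropolis-within-Gibbs sampler for the hierarchical spatial ordinal model.

The target is the joint posterior

    p(beta, g, u, f, phi, tau | y)  proportional to
        L(y | beta, g, u, f, phi) * p(beta) * p(g) * p(f | tau_v) p(tau_v)
        * p(u | tau_h) p(tau_h) * p_CAR(phi | tau_c) p(tau_c)

with the cumulative-logit likelihood of :mod:`ordcar.likelihood` and the
priors of :mod:`ordcar.priors`; which random-effect terms are present
follows the model structure (none / unstructured / structured /
convolution).

Update scheme per iteration:

* single-site adaptive random-walk Metropolis for every coefficient and
  for the cutpoint parameters (g1 on its natural scale, each increment on
  the log scale with the Jacobian in the acceptance ratio, which keeps the
  cutpoints ordered in every draw);
* blocked random-walk Metropolis for the facility effects f and the
  unstructured county effects u: facilities (and counties) partition the
  patients, so all sites can be proposed at once and accepted or rejected
  independently using per-group likelihood sums;
* the CAR field phi is updated by graph colour classes (greedy colouring
  of the county graph): within a class no two counties are neighbours, so
  the sites are conditionally independent and can be vectorised; after the
  sweep phi is re-centred to mean zero (the standard identification of the
  intrinsic prior);
* conjugate Gibbs draws for the precisions tau_v, tau_h, tau_c.

Proposal scales adapt by Robbins-Monro during burn-in toward 35%
acceptance and are frozen afterwards, so the post-burn-in chain has a
fixed kernel.  One master seed drives everything; per-chain streams are
spawned deterministically, and identical configuration yields bit-identical
draws.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .adjacency import AdjacencyStructure
from .datasets import OrdinalDataset
from .likelihood import (
    STRUCTURES,
    CutpointSet,
    ParameterState,
    structure_uses_phi,
    structure_uses_u,
)
from .priors import PriorSpec, pairwise_difference_sum

__all__ = ["ModelSpec", "McmcConfig", "PosteriorDraws", "run_mcmc",
           "BIVARIATE_MCMC", "MULTIVARIABLE_MCMC"]

_PROB_FLOOR = 1e-300
_TARGET_ACCEPT = 0.35


@dataclass
class ModelSpec:
    """What to fit: covariates, random-effect structure, priors."""

    structure: str = "convolution"
    covariates: list = None          # None = all columns of the dataset
    forced: list = field(default_factory=list)
    prior: PriorSpec = field(default_factory=PriorSpec)
    facility_effects: bool = True

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.covariates is not None and not set(self.forced) <= set(self.covariates):
            raise ValueError("forced covariates must be a subset of the covariate list")


@dataclass
class McmcConfig:
    """Chain settings: retained draws, burn-in, thinning, chains, seed."""

    n_draws: int = 2000
    burnin: int = 1000
    thinning: int = 1
    n_chains: int = 1
    seed: int = 0
    adapt: bool = True
    init_scale_beta: float = 0.1
    init_scale_cut: float = 0.1
    init_scale_effect: float = 0.5

    def __post_init__(self):
        if self.n_draws < 1 or self.burnin < 0 or self.thinning < 1 or self.n_chains < 1:
            raise ValueError("need n_draws >= 1, burnin >= 0, thinning >= 1, n_chains >= 1")


# settings mirroring the published screening and final fits
BIVARIATE_MCMC = McmcConfig(n_draws=1000, burnin=1000, thinning=10)
MULTIVARIABLE_MCMC = McmcConfig(n_draws=10000, burnin=1000, thinning=100)


@dataclass
class PosteriorDraws:
    """Retained MCMC samples plus everything needed to interpret them.

    ``samples`` maps parameter names (``beta``, ``kappa``, ``g``, ``u``,
    ``f``, ``phi``, ``tau_h``, ``tau_v``, ``tau_c``, ``deviance``) to
    arrays of shape (n_chains, n_draws, dim) — scalars have dim 1.
    """

    samples: dict
    param_names: dict
    structure: str
    acceptance: dict
    config: McmcConfig
    fingerprint: str = ""

    @property
    def n_chains(self) -> int:
        return next(iter(self.samples.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.samples.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains concatenated, shape (chains*draws, dim)."""
        arr = self.samples[name]
        return arr.reshape(-1, arr.shape[2])

    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        manifest = {
            "structure": self.structure,
            "acceptance": self.acceptance,
            "fingerprint": self.fingerprint,
            "config": {k: getattr(self.config, k) for k in
                       ("n_draws", "burnin", "thinning", "n_chains", "seed")},
            "param_names": self.param_names,
            "shapes": {k: list(v.shape) for k, v in self.samples.items()},
        }
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
        for name, arr in self.samples.items():
            flat = arr.reshape(-1, arr.shape[2])
            np.savetxt(os.path.join(directory, f"{name}.csv"), flat, delimiter=",")

    @classmethod
    def load(cls, directory) -> "PosteriorDraws":
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        samples = {}
        for name, shape in manifest["shapes"].items():
            flat = np.loadtxt(os.path.join(directory, f"{name}.csv"), delimiter=",", ndmin=2)
            samples[name] = flat.reshape(shape)
        cfg = McmcConfig(**manifest["config"])
        return cls(
            samples=samples,
            param_names=manifest["param_names"],
            structure=manifest["structure"],
            acceptance=manifest["acceptance"],
            config=cfg,
            fingerprint=manifest["fingerprint"],
        )


# ----------------------------------------------------------------------
# internal chain machinery


class _Chain:
    def __init__(self, dataset: OrdinalDataset, adjacency, spec: ModelSpec,
                 config: McmcConfig, rng: np.random.Generator):
        self.rng = rng
        self.spec = spec
        self.config = config
        self.structure = spec.structure
        self.use_u = structure_uses_u(self.structure)
        self.use_phi = structure_uses_phi(self.structure)
        self.use_f = spec.facility_effects
        self.prior = spec.prior

        if spec.covariates is not None:
            dataset = dataset.subset_columns(spec.covariates)
        self.data = dataset
        self.n = dataset.n
        self.p = dataset.p
        self.K = dataset.n_categories
        self.J = dataset.n_facilities
        self.M = dataset.n_counties
        self.X = dataset.X
        self.y = dataset.y
        self.fac = dataset.facility_index - 1
        self.cty = dataset.county_index - 1
        self.blocks = [dataset.block_of(c) for c in dataset.columns]
        self.beta_prec = self.prior.beta_precisions_for(self.blocks)

        self.adjacency = adjacency
        if self.use_phi:
            if adjacency is None:
                raise ValueError("spatial structure requires an adjacency structure")
            if adjacency.n != self.M and self.n > 0:
                raise ValueError("adjacency size does not match county count")
            adjacency.require_connected()
            self.W = adjacency.weight_matrix()
            self.num = np.asarray(adjacency.num, dtype=float)
            g = adjacency.to_graph()
            import networkx as nx

            colours = nx.greedy_color(g, strategy="largest_first")
            n_col = max(colours.values()) + 1
            self.colour_classes = [
                np.array([v for v, c in colours.items() if c == k], dtype=int)
                for k in range(n_col)
            ]
            self.n_components = 1

        # initial state
        self.beta = np.zeros(self.p)
        if self.n > 0:
            freq = np.array([(self.y <= k).mean() for k in range(1, self.K)])
            freq = np.clip(freq, 0.02, 0.98)
            kappa0 = np.log(freq / (1 - freq))
            for k in range(1, len(kappa0)):  # enforce ordering at init
                kappa0[k] = max(kappa0[k], kappa0[k - 1] + 0.1)
        else:
            kappa0 = np.linspace(0.0, 1.0, self.K - 1)
        self.g1 = float(kappa0[0])
        self.log_inc = np.log(np.maximum(np.diff(kappa0), 0.1)) if self.K > 2 else np.zeros(0)
        self.u = np.zeros(self.M)
        self.f = np.zeros(self.J)
        self.phi = np.zeros(self.M)
        self.tau_h = 1.0
        self.tau_v = 1.0
        self.tau_c = 1.0

        self.eta = self._eta_from_scratch()
        self.row_ll = self._row_ll(self.eta, self._kappa())

        # adaptive proposal scales
        self.s_beta = np.full(self.p, config.init_scale_beta)
        self.s_g1 = config.init_scale_cut
        self.s_inc = np.full(len(self.log_inc), config.init_scale_cut)
        self.s_f = np.full(self.J, config.init_scale_effect)
        self.s_u = np.full(self.M, config.init_scale_effect)
        self.s_phi = np.full(self.M, config.init_scale_effect)
        self.acc_counts = {}
        self.prop_counts = {}

    # -- likelihood plumbing -------------------------------------------
    def _kappa(self) -> np.ndarray:
        return self.g1 + np.concatenate(([0.0], np.cumsum(np.exp(self.log_inc))))

    def _eta_from_scratch(self) -> np.ndarray:
        eta = self.X @ self.beta if self.p else np.zeros(self.n)
        if self.use_f:
            eta = eta + self.f[self.fac]
        if self.use_u:
            eta = eta + self.u[self.cty]
        if self.use_phi:
            eta = eta + self.phi[self.cty]
        return eta

    def _row_ll(self, eta, kappa) -> np.ndarray:
        if self.n == 0:
            return np.zeros(0)
        cum = expit(kappa[None, :] - eta[:, None])
        full = np.concatenate(
            [np.zeros((self.n, 1)), cum, np.ones((self.n, 1))], axis=1
        )
        rows = np.arange(self.n)
        pr = full[rows, self.y] - full[rows, self.y - 1]
        return np.log(np.maximum(pr, _PROB_FLOOR))

    def loglik(self) -> float:
        return float(self.row_ll.sum())

    # -- bookkeeping ----------------------------------------------------
    def _tally(self, key, accepted, proposed=1):
        self.acc_counts[key] = self.acc_counts.get(key, 0) + float(np.sum(accepted))
        self.prop_counts[key] = self.prop_counts.get(key, 0) + float(np.size(accepted)) * proposed

    @staticmethod
    def _rm_step(t: int) -> float:
        return min(0.3, 2.0 / np.sqrt(t + 10.0))

    # -- update blocks --------------------------------------------------
    def update_beta(self, t, adapting):
        kappa = self._kappa()
        for j in range(self.p):
            prop = self.s_beta[j] * self.rng.standard_normal()
            eta_new = self.eta + prop * self.X[:, j]
            rows_new = self._row_ll(eta_new, kappa)
            b_new = self.beta[j] + prop
            dprior = -0.5 * self.beta_prec[j] * (
                (b_new - self.prior.beta_mean) ** 2 - (self.beta[j] - self.prior.beta_mean) ** 2
            )
            log_alpha = rows_new.sum() - self.row_ll.sum() + dprior
            accept = np.log(self.rng.uniform()) < log_alpha
            if accept:
                self.beta[j] = b_new
                self.eta = eta_new
                self.row_ll = rows_new
            if adapting:
                self.s_beta[j] = float(np.exp(
                    np.log(self.s_beta[j]) + self._rm_step(t) * (float(accept) - _TARGET_ACCEPT)
                ))
            self._tally(f"beta[{j}]", accept)

    def update_cutpoints(self, t, adapting):
        # g1 on its natural scale
        prop = self.s_g1 * self.rng.standard_normal()
        g1_new = self.g1 + prop
        kappa_new = g1_new + np.concatenate(([0.0], np.cumsum(np.exp(self.log_inc))))
        rows_new = self._row_ll(self.eta, kappa_new)
        dprior = -0.5 * self.prior.g1_precision * (g1_new**2 - self.g1**2)
        accept = np.log(self.rng.uniform()) < rows_new.sum() - self.row_ll.sum() + dprior
        if accept:
            self.g1 = g1_new
            self.row_ll = rows_new
        if adapting:
            self.s_g1 = float(np.exp(
                np.log(self.s_g1) + self._rm_step(t) * (float(accept) - _TARGET_ACCEPT)
            ))
        self._tally("g1", accept)

        # each increment on the log scale; in z = log(increment) the Gamma
        # prior plus Jacobian is shape*z - rate*e^z, evaluated in log space
        # so that the very diffuse default prior cannot overflow
        for k in range(len(self.log_inc)):
            prop = self.s_inc[k] * self.rng.standard_normal()
            z_old = self.log_inc[k]
            z_new = z_old + prop
            if abs(z_new) > 600.0:  # e^z overflows / underflows: zero density
                accept = False
            else:
                log_inc_new = self.log_inc.copy()
                log_inc_new[k] = z_new
                kappa_new = self.g1 + np.concatenate(([0.0], np.cumsum(np.exp(log_inc_new))))
                rows_new = self._row_ll(self.eta, kappa_new)
                dprior = (
                    self.prior.g2_shape * (z_new - z_old)
                    - self.prior.g2_rate * (np.exp(z_new) - np.exp(z_old))
                )
                accept = np.log(self.rng.uniform()) < rows_new.sum() - self.row_ll.sum() + dprior
            if accept:
                self.log_inc = log_inc_new
                self.row_ll = rows_new
            if adapting:
                self.s_inc[k] = float(np.exp(
                    np.log(self.s_inc[k]) + self._rm_step(t) * (float(accept) - _TARGET_ACCEPT)
                ))
            self._tally(f"g2[{k}]", accept)

    def _update_grouped(self, values, scales, group_idx, n_groups, tau, key, t, adapting):
        """Joint proposal with independent accept/reject per group; valid
        because groups partition the rows and the prior is iid."""
        kappa = self._kappa()
        prop = scales * self.rng.standard_normal(n_groups)
        values_new = values + prop
        if self.n > 0:
            eta_new = self.eta + prop[group_idx]
            rows_new = self._row_ll(eta_new, kappa)
            dll = np.bincount(group_idx, weights=rows_new - self.row_ll, minlength=n_groups)
        else:
            eta_new = self.eta
            rows_new = self.row_ll
            dll = np.zeros(n_groups)
        dprior = -0.5 * tau * (values_new**2 - values**2)
        accept = np.log(self.rng.uniform(size=n_groups)) < dll + dprior
        if np.any(accept) and self.n > 0:
            row_accept = accept[group_idx]
            self.eta = np.where(row_accept, eta_new, self.eta)
            self.row_ll = np.where(row_accept, rows_new, self.row_ll)
        values[accept] = values_new[accept]
        if adapting:
            scales *= np.exp(self._rm_step(t) * (accept.astype(float) - _TARGET_ACCEPT))
        self._tally(key, accept)

    def update_f(self, t, adapting):
        self._update_grouped(self.f, self.s_f, self.fac, self.J, self.tau_v, "f", t, adapting)

    def update_u(self, t, adapting):
        self._update_grouped(self.u, self.s_u, self.cty, self.M, self.tau_h, "u", t, adapting)

    def update_phi(self, t, adapting):
        kappa = self._kappa()
        for cls_nodes in self.colour_classes:
            neighbour_sum = np.asarray(self.W @ self.phi).ravel()
            prop = np.zeros(self.M)
            prop[cls_nodes] = self.s_phi[cls_nodes] * self.rng.standard_normal(len(cls_nodes))
            phi_new = self.phi + prop
            if self.n > 0:
                eta_new = self.eta + prop[self.cty]
                rows_new = self._row_ll(eta_new, kappa)
                dll_all = np.bincount(self.cty, weights=rows_new - self.row_ll, minlength=self.M)
            else:
                eta_new = self.eta
                rows_new = self.row_ll
                dll_all = np.zeros(self.M)
            d = prop[cls_nodes]
            j = cls_nodes
            dprior = -0.5 * self.tau_c * (
                self.num[j] * (phi_new[j] ** 2 - self.phi[j] ** 2)
                - 2.0 * d * neighbour_sum[j]
            )
            accept_cls = np.log(self.rng.uniform(size=len(j))) < dll_all[j] + dprior
            accept = np.zeros(self.M, dtype=bool)
            accept[j[accept_cls]] = True
            if np.any(accept) and self.n > 0:
                row_accept = accept[self.cty]
                self.eta = np.where(row_accept, eta_new, self.eta)
                self.row_ll = np.where(row_accept, rows_new, self.row_ll)
            self.phi[accept] = phi_new[accept]
            if adapting:
                self.s_phi[j] *= np.exp(self._rm_step(t) * (accept_cls.astype(float) - _TARGET_ACCEPT))
            self._tally("phi", accept_cls)
        # identification: re-centre the intrinsic field every sweep
        centre = float(self.phi.mean())
        if centre != 0.0:
            self.phi -= centre
            if self.n > 0:
                self.eta = self.eta - centre
                self.row_ll = self._row_ll(self.eta, kappa)

    def update_precisions(self):
        if self.use_f:
            self.tau_v = float(self.rng.gamma(
                self.prior.tau_v_shape + self.J / 2.0,
                1.0 / (self.prior.tau_v_rate + 0.5 * float(np.sum(self.f**2))),
            ))
        if self.use_u:
            self.tau_h = float(self.rng.gamma(
                self.prior.tau_h_shape + self.M / 2.0,
                1.0 / (self.prior.tau_h_rate + 0.5 * float(np.sum(self.u**2))),
            ))
        if self.use_phi:
            shape = self.prior.tau_c_shape + (self.M - self.n_components) / 2.0
            rate = self.prior.tau_c_rate + 0.5 * pairwise_difference_sum(self.phi, self.adjacency)
            self.tau_c = float(self.rng.gamma(shape, 1.0 / rate))

    def iterate(self, t, adapting):
        self.update_beta(t, adapting)
        self.update_cutpoints(t, adapting)
        if self.use_f:
            self.update_f(t, adapting)
        if self.use_u:
            self.update_u(t, adapting)
        if self.use_phi:
            self.update_phi(t, adapting)
        self.update_precisions()

    def snapshot(self) -> dict:
        kappa = self._kappa()
        out = {
            "beta": self.beta.copy(),
            "g": np.concatenate(([self.g1], np.exp(self.log_inc))),
            "kappa": kappa,
            "tau_h": np.array([self.tau_h]),
            "tau_v": np.array([self.tau_v]),
            "tau_c": np.array([self.tau_c]),
            "u": self.u.copy(),
            "f": self.f.copy(),
            "phi": self.phi.copy(),
            "deviance": np.array([-2.0 * self.loglik()]),
        }
        return out

    def acceptance_rates(self) -> dict:
        return {
            k: (self.acc_counts[k] / self.prop_counts[k]) if self.prop_counts[k] else 0.0
            for k in sorted(self.acc_counts)
        }


def _preflight(dataset: OrdinalDataset, spec: ModelSpec):
    cols = spec.covariates if spec.covariates is not None else dataset.columns
    for c in cols:
        if c not in dataset.columns:
            raise KeyError(f"covariate {c!r} not in dataset")
        if dataset.n > 0 and np.ptp(dataset.X[:, dataset.columns.index(c)]) == 0:
            raise ValueError(f"covariate {c!r} has zero variation")


def run_mcmc(
    dataset: OrdinalDataset,
    adjacency: AdjacencyStructure,
    spec: ModelSpec,
    config: McmcConfig,
) -> PosteriorDraws:
    """Run the Metropolis-within-Gibbs sampler.

    Returns retained draws of shape (n_chains, n_draws, dim) per parameter,
    recorded after ``config.burnin`` adaptation iterations and thinned by
    ``config.thinning``.  Deterministic given ``config.seed``.
    """
    if structure_uses_phi(spec.structure) and adjacency is None:
        raise ValueError("structured/convolution models need an adjacency structure")
    _preflight(dataset, spec)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    all_chains = []
    acceptance = {}
    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        chain = _Chain(dataset, adjacency, spec, config, rng)
        stored = []
        for t in range(config.burnin):
            chain.iterate(t, adapting=config.adapt)
        total = config.n_draws * config.thinning
        for t in range(total):
            chain.iterate(config.burnin + t, adapting=False)
            if (t + 1) % config.thinning == 0:
                stored.append(chain.snapshot())
        all_chains.append(stored)
        acceptance[f"chain{c}"] = chain.acceptance_rates()

    names = list(all_chains[0][0].keys())
    samples = {
        name: np.stack([
            np.stack([snap[name] for snap in chain_draws]) for chain_draws in all_chains
        ])
        for name in names
    }
    cols = spec.covariates if spec.covariates is not None else dataset.columns
    param_names = {
        "beta": list(cols),
        "g": ["g1"] + [f"g{k}" for k in range(2, dataset.n_categories)],
        "kappa": [f"kappa{k}" for k in range(1, dataset.n_categories)],
    }
    return PosteriorDraws(
        samples=samples,
        param_names=param_names,
        structure=spec.structure,
        acceptance=acceptance,
        config=config,
        fingerprint=dataset.fingerprint(),
    )
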