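"""Synthetic study generator: nested ordinal data with spatial county effects.

The real facility survey behind the analysis is not publicly deposited, so
this module generates datasets with the same statistical architecture:
counties on a connected adjacency graph, facilities allocated to counties,
patients allocated to facilities, and a three-category ordinal outcome
drawn from the proportional-odds model with known coefficients, iid county
and facility effects, and a spatially autocorrelated (intrinsic CAR)
county field.  Every generated quantity, including the realised random
effects and latent predictors, is recorded in a :class:`TruthRecord` so
that estimator-recovery studies can compare posteriors against truth.

Generation is a pure function of ``(config, truth, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .adjacency import AdjacencyStructure, generate_adjacency
from .datasets import OrdinalDataset
from .likelihood import CutpointSet, category_probabilities

__all__ = [
    "CovariateSpec",
    "SimulationConfig",
    "TruthRecord",
    "sample_car_effects",
    "generate_dataset",
    "simulate_study",
    "study_config",
]


@dataclass
class CovariateSpec:
    """Plan for one covariate.

    ``kind`` is ``"categorical"`` (integer codes with reference level 1,
    dummy-expanded to ``name_k`` columns for levels 2..L) or
    ``"continuous"`` (standardised at its own level).  ``level`` places the
    draw at patient, facility or county resolution.  ``beta`` holds the
    true log-odds coefficients: one value per non-reference level (plus one
    for the missing code, if any) for categoricals, a scalar for
    continuous covariates.
    """

    name: str
    kind: str = "continuous"
    level: str = "patient"
    block: str = "b"
    probs: tuple = None
    beta: tuple = 0.0
    missing_code: int = None
    missing_prob: float = 0.0

    def __post_init__(self):
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.level not in ("patient", "facility", "county"):
            raise ValueError(f"unknown covariate level {self.level!r}")
        if self.kind == "categorical":
            if self.probs is None:
                raise ValueError(f"categorical covariate {self.name!r} needs probs")
            expected = len(self.probs) - 1 + (1 if self.missing_code else 0)
            if len(np.atleast_1d(self.beta)) != expected:
                raise ValueError(
                    f"{self.name!r}: expected {expected} beta values, got "
                    f"{len(np.atleast_1d(self.beta))}"
                )

    @property
    def column_names(self):
        if self.kind == "continuous":
            return [self.name]
        names = [f"{self.name}_{k}" for k in range(2, len(self.probs) + 1)]
        if self.missing_code:
            names.append(f"{self.name}_{self.missing_code}")
        return names


@dataclass
class SimulationConfig:
    """Dimensions, nesting and covariate plan of a synthetic study."""

    n_counties: int = 47
    n_facilities: int = 281
    n_patients: int = 2568
    covariates: list = field(default_factory=list)
    structure: str = "convolution"
    adjacency_kind: str = "random-planar"
    county_sizes: np.ndarray = None  # relative facility allocation, default uniform
    facility_effects: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_counties < 2:
            raise ValueError("n_counties must be >= 2")
        if self.n_facilities < self.n_counties:
            raise ValueError("need at least one facility per county")
        if self.n_patients < self.n_facilities:
            raise ValueError("need at least one patient per facility")

    @property
    def column_names(self):
        out = []
        for cov in self.covariates:
            out.extend(cov.column_names)
        return out

    @property
    def blocks(self):
        out = {}
        for cov in self.covariates:
            for name in cov.column_names:
                out[name] = cov.block
        return out

    @property
    def beta(self) -> np.ndarray:
        parts = [np.atleast_1d(np.asarray(c.beta, dtype=float)) for c in self.covariates]
        return np.concatenate(parts) if parts else np.zeros(0)


@dataclass
class TruthRecord:
    """Generating values and realised random effects of one synthetic study."""

    beta_true: np.ndarray
    cutpoints_true: np.ndarray
    tau_h_true: float = 16.0
    tau_v_true: float = 11.0
    tau_c_true: float = 1.5
    u_true: np.ndarray = None
    f_true: np.ndarray = None
    phi_true: np.ndarray = None
    eta_true: np.ndarray = None
    columns: list = None
    seed: int = 0

    def __post_init__(self):
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        self.cutpoints_true = np.asarray(self.cutpoints_true, dtype=float)
        if np.any(np.diff(self.cutpoints_true) <= 0):
            raise ValueError("cutpoints_true must be strictly increasing")
        for name in ("tau_h_true", "tau_v_true", "tau_c_true"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.phi_true is not None and abs(float(np.mean(self.phi_true))) > 1e-8:
            raise ValueError("phi_true must sum to zero")

    def to_json(self, path) -> None:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        with open(path, "w") as fh:
            json.dump({k: conv(v) for k, v in self.__dict__.items()}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("beta_true", "cutpoints_true", "u_true", "f_true", "phi_true", "eta_true"):
            if d.get(k) is not None:
                d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def sample_car_effects(
    adjacency: AdjacencyStructure, tau_c: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw one realisation of the intrinsic CAR field on the sum-to-zero
    subspace.

    The intrinsic prior has precision matrix tau_c * L (L the graph
    Laplacian), which is rank-deficient; the draw is taken in the span of
    the eigenvectors with positive eigenvalue, i.e. from the proper
    distribution on the subspace orthogonal to the constant vector, and
    re-centred to mean zero at machine precision.
    """
    if tau_c <= 0:
        raise ValueError("tau_c must be > 0")
    adjacency.require_connected()
    L = adjacency.laplacian()
    eigval, eigvec = np.linalg.eigh(L)
    positive = eigval > 1e-10 * eigval.max()
    z = rng.standard_normal(int(np.sum(positive)))
    phi = eigvec[:, positive] @ (z / np.sqrt(tau_c * eigval[positive]))
    return phi - phi.mean()


def _allocate(n_items: int, n_groups: int, rng: np.random.Generator, sizes=None) -> np.ndarray:
    """1-based group index per item; every group receives at least one item."""
    if sizes is None:
        p = np.full(n_groups, 1.0 / n_groups)
    else:
        p = np.asarray(sizes, dtype=float)
        p = p / p.sum()
    counts = 1 + rng.multinomial(n_items - n_groups, p)
    return np.repeat(np.arange(1, n_groups + 1), counts)


def _draw_covariate(cov: CovariateSpec, sizes: dict, maps: dict, rng: np.random.Generator):
    """Return (columns, raw_codes) for one covariate, broadcast to patients."""
    n_units = sizes[cov.level]
    if cov.kind == "continuous":
        x = rng.standard_normal(n_units)
        x = (x - x.mean()) / x.std()  # standardised at its own level
        return {cov.name: x[maps[cov.level]]}, x[maps[cov.level]]
    levels = np.arange(1, len(cov.probs) + 1)
    codes = rng.choice(levels, size=n_units, p=np.asarray(cov.probs) / np.sum(cov.probs))
    if cov.missing_code:
        miss = rng.uniform(size=n_units) < cov.missing_prob
        codes = np.where(miss, cov.missing_code, codes)
    codes = codes[maps[cov.level]]
    cols = {}
    for k in levels[1:]:
        cols[f"{cov.name}_{k}"] = (codes == k).astype(float)
    if cov.missing_code:
        cols[f"{cov.name}_{cov.missing_code}"] = (codes == cov.missing_code).astype(float)
    return cols, codes


def generate_dataset(
    config: SimulationConfig,
    truth: TruthRecord = None,
    adjacency: AdjacencyStructure = None,
):
    """Generate one synthetic study.

    Returns ``(dataset, truth)`` where ``truth`` is completed with the
    realised random effects and latent predictors.  If ``truth`` is None a
    default record with the config's plan coefficients is built; if
    ``adjacency`` is None one is generated from the config.
    """
    rng = np.random.default_rng(config.seed)
    if adjacency is None:
        adjacency = generate_adjacency(config.n_counties, config.adjacency_kind, config.seed)
    if adjacency.n != config.n_counties:
        raise ValueError(
            f"adjacency has {adjacency.n} counties, config expects {config.n_counties}"
        )
    if truth is None:
        # default cutpoints place the marginal outcome split near the
        # surveyed 45/46/9 given the default plan's mean linear predictor
        truth = TruthRecord(
            beta_true=config.beta,
            cutpoints_true=np.array([1.0, 3.5]),
            seed=config.seed,
        )
    expected_p = len(config.column_names)
    if len(truth.beta_true) != expected_p:
        raise ValueError(
            f"truth.beta_true has length {len(truth.beta_true)} but the covariate "
            f"plan expands to {expected_p} columns ({config.column_names})"
        )

    M, J, n = config.n_counties, config.n_facilities, config.n_patients
    fac_county = _allocate(J, M, rng, config.county_sizes)  # county of each facility
    pat_facility = _allocate(n, J, rng)
    pat_county = fac_county[pat_facility - 1]

    maps = {
        "patient": np.arange(n),
        "facility": pat_facility - 1,
        "county": pat_county - 1,
    }
    sizes = {"patient": n, "facility": J, "county": M}

    columns, X_cols = [], []
    for cov in config.covariates:
        cols, _ = _draw_covariate(cov, sizes, maps, rng)
        for name, values in cols.items():
            columns.append(name)
            X_cols.append(values)
    X = np.column_stack(X_cols) if X_cols else np.zeros((n, 0))

    from .likelihood import structure_uses_phi, structure_uses_u

    u = truth.u_true
    if u is None:
        u = (
            rng.standard_normal(M) / np.sqrt(truth.tau_h_true)
            if structure_uses_u(config.structure)
            else np.zeros(M)
        )
    f = truth.f_true
    if f is None:
        f = (
            rng.standard_normal(J) / np.sqrt(truth.tau_v_true)
            if config.facility_effects
            else np.zeros(J)
        )
    phi = truth.phi_true
    if phi is None:
        phi = (
            sample_car_effects(adjacency, truth.tau_c_true, rng)
            if structure_uses_phi(config.structure)
            else np.zeros(M)
        )
    for name, vec, m in (("u_true", u, M), ("f_true", f, J), ("phi_true", phi, M)):
        if len(vec) != m:
            raise ValueError(f"{name} has length {len(vec)}, expected {m}")

    eta = X @ truth.beta_true + f[pat_facility - 1] + u[pat_county - 1] + phi[pat_county - 1]
    cutpoints = CutpointSet.from_kappa(truth.cutpoints_true)
    probs = category_probabilities(eta, cutpoints)
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-12):
        raise AssertionError("category probabilities do not sum to one")
    cum = np.cumsum(probs, axis=1)
    yu = rng.uniform(size=n)
    y = 1 + (yu[:, None] > cum[:, :-1]).sum(axis=1)

    dataset = OrdinalDataset(
        y=y,
        X=X,
        columns=columns,
        blocks=config.blocks,
        facility_index=pat_facility,
        county_index=pat_county,
        weight=None,
        n_categories=cutpoints.n_categories,
        n_facilities=J,
        n_counties=M,
    )
    completed = TruthRecord(
        beta_true=truth.beta_true,
        cutpoints_true=truth.cutpoints_true,
        tau_h_true=truth.tau_h_true,
        tau_v_true=truth.tau_v_true,
        tau_c_true=truth.tau_c_true,
        u_true=u,
        f_true=f,
        phi_true=phi - phi.mean() if np.any(phi) else phi,
        eta_true=eta,
        columns=columns,
        seed=config.seed,
    )
    return dataset, completed


def simulate_study(config: SimulationConfig, truth: TruthRecord = None):
    """Convenience wrapper returning ``(dataset, adjacency, truth)``."""
    adjacency = generate_adjacency(config.n_counties, config.adjacency_kind, config.seed)
    dataset, truth = generate_dataset(config, truth, adjacency)
    return dataset, adjacency, truth


def study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default synthetic study: the analysed survey's dimensions (47
    counties, 281 facilities, 2,568 patients) with a covariate plan spanning
    all three levels, a multi-level categorical, a missing-coded categorical
    and continuous covariates.  True coefficients are the convolution-model
    odds ratios of the published fit, on the log scale."""
    covariates = [
        CovariateSpec("age_group", "categorical", "patient", "b",
                      probs=(0.35, 0.40, 0.25), beta=(-0.142, -0.196)),
        CovariateSpec("prev_abortion", "categorical", "patient", "b",
                      probs=(0.70, 0.30), beta=(0.598,)),
        CovariateSpec("modern_fp", "categorical", "patient", "b",
                      probs=(0.50, 0.50), beta=(0.493,)),
        CovariateSpec("wanted", "categorical", "patient", "b",
                      probs=(0.40, 0.35, 0.25), beta=(0.418, 0.473, 0.10),
                      missing_code=9, missing_prob=0.08),
        CovariateSpec("public", "categorical", "facility", "m",
                      probs=(0.315, 0.685), beta=(0.957,)),
        CovariateSpec("method_count", "continuous", "facility", "s", beta=0.175),
        CovariateSpec("anc_skilled", "continuous", "county", "q", beta=-0.039),
    ]
    defaults = dict(
        n_counties=47,
        n_facilities=281,
        n_patients=2568,
        covariates=covariates,
        structure="convolution",
        adjacency_kind="random-planar",
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
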