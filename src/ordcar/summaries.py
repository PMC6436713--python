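"""Posterior summaries: odds-ratio tables, DIC, convergence diagnostics."""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .likelihood import CutpointSet, ParameterState, deviance
from .sampler import PosteriorDraws

__all__ = ["DicResult", "FitSummary", "compute_dic", "dic_from_deviance",
           "summarize", "diagnostics", "posterior_mean_state"]


@dataclass
class DicResult:
    """Deviance information criterion and its components.

    ``d_bar`` is the posterior mean deviance, ``d_at_mean`` the deviance at
    the posterior means of all parameters (random effects included — the
    "focused" plug-in), ``p_d = d_bar - d_at_mean`` the effective number of
    parameters, and ``dic = d_bar + p_d``.
    """

    d_bar: float
    d_at_mean: float

    @property
    def p_d(self) -> float:
        return self.d_bar - self.d_at_mean

    @property
    def dic(self) -> float:
        return self.d_bar + self.p_d

    def as_dict(self) -> dict:
        return {"D_bar": self.d_bar, "D_at_mean": self.d_at_mean,
                "pD": self.p_d, "DIC": self.dic}


def dic_from_deviance(deviance_draws, deviance_at_mean: float) -> DicResult:
    """DIC from a vector of per-draw deviances and a plug-in deviance."""
    deviance_draws = np.asarray(deviance_draws, dtype=float)
    if deviance_draws.size == 0:
        raise ValueError("no deviance draws")
    return DicResult(d_bar=float(deviance_draws.mean()), d_at_mean=float(deviance_at_mean))


def posterior_mean_state(draws: PosteriorDraws) -> ParameterState:
    """Parameter state at the posterior means of all stored parameters."""
    mean = {k: draws.stacked(k).mean(axis=0) for k in
            ("beta", "kappa", "u", "f", "phi", "tau_h", "tau_v", "tau_c")}
    return ParameterState(
        beta=mean["beta"],
        cutpoints=CutpointSet.from_kappa(mean["kappa"]),
        u=mean["u"],
        f=mean["f"],
        phi=mean["phi"],
        tau_h=float(mean["tau_h"][0]),
        tau_v=float(mean["tau_v"][0]),
        tau_c=float(mean["tau_c"][0]),
    )


def compute_dic(draws: PosteriorDraws, dataset, spec=None) -> DicResult:
    """DIC of a fit: mean stored deviance vs deviance at posterior means."""
    if draws.n_draws == 0:
        raise ValueError("empty draws")
    dev_draws = draws.stacked("deviance").ravel()
    state = posterior_mean_state(draws)
    structure = spec.structure if spec is not None else draws.structure
    d_at_mean = deviance(dataset, state, structure)
    return dic_from_deviance(dev_draws, d_at_mean)


@dataclass
class FitSummary:
    """Posterior coefficient table on both the log-odds and OR scales."""

    table: pd.DataFrame
    levels: tuple

    def __str__(self):
        return self.table.to_string(float_format=lambda v: f"{v:0.3f}")


def _interval_columns(levels):
    cols = []
    for lv in levels:
        lo = (1 - lv) / 2
        hi = 1 - lo
        cols.append((lv, 100 * lo, 100 * hi))
    return cols


def summarize(draws: PosteriorDraws, levels=(0.85, 0.95), parameters=None) -> FitSummary:
    """Per-coefficient posterior summary.

    For each coefficient: posterior mean/SD on the log-odds scale; the
    posterior mean and SD of the draw-wise odds ratio exp(beta); and
    equal-tailed credible intervals for the OR at each requested level
    (85% and 95% by default — the screening and reporting levels).
    Cutpoints and precisions are summarised on their natural scale.
    """
    for lv in levels:
        if not 0 < lv < 1:
            raise ValueError(f"credibility level must be in (0,1), got {lv}")
    names_map = draws.param_names
    rows = []
    wanted = parameters if parameters is not None else ["beta", "kappa", "tau_h", "tau_v", "tau_c"]
    for group in wanted:
        if group not in draws.samples:
            raise KeyError(f"unknown parameter group {group!r}")
        arr = draws.stacked(group)
        labels = names_map.get(group, [group] * arr.shape[1])
        if arr.shape[1] == 1 and group not in names_map:
            labels = [group]
        for j in range(arr.shape[1]):
            d = arr[:, j]
            row = {
                "parameter": labels[j] if j < len(labels) else f"{group}[{j}]",
                "group": group,
                "mean": d.mean(),
                "sd": d.std(ddof=1),
                "median": float(np.median(d)),
            }
            if group == "beta":
                or_draws = np.exp(d)
                row["or_mean"] = or_draws.mean()
                row["or_sd"] = or_draws.std(ddof=1)
                row["or_median"] = float(np.median(or_draws))
                for lv, lo, hi in _interval_columns(levels):
                    ql, qh = np.quantile(or_draws, [(1 - lv) / 2, 1 - (1 - lv) / 2])
                    row[f"or_{lo:g}%"] = ql
                    row[f"or_{hi:g}%"] = qh
            else:
                for lv, lo, hi in _interval_columns(levels):
                    ql, qh = np.quantile(d, [(1 - lv) / 2, 1 - (1 - lv) / 2])
                    row[f"{lo:g}%"] = ql
                    row[f"{hi:g}%"] = qh
            rows.append(row)
    return FitSummary(table=pd.DataFrame(rows), levels=tuple(levels))


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain R-hat for one parameter via arviz (rank-normalised).

    ``chains`` has shape (n_chains, n_draws).
    """
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        import arviz as az

        res = az.rhat(az.convert_to_dataset(chains[:, :, None]))
    return float(res["x"].values[0])


def _lag_autocorr(x: np.ndarray, lag: int = 1) -> float:
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return 0.0
    return float(np.dot(x[:-lag], x[lag:]) / denom)


def diagnostics(draws: PosteriorDraws, rhat_threshold: float = 1.05,
                groups=("beta", "kappa", "tau_h", "tau_v", "tau_c")) -> dict:
    """Convergence report: split-R-hat per parameter (>= 2 chains), lag-1
    autocorrelation of the retained draws, acceptance rates and a
    per-parameter converged flag."""
    report = {"parameters": {}, "acceptance": draws.acceptance,
              "rhat_threshold": rhat_threshold}
    single = draws.n_chains < 2
    if single:
        warnings.warn("single chain: split-R-hat omitted", stacklevel=2)
    for group in groups:
        if group not in draws.samples:
            continue
        arr = draws.samples[group]  # chains x draws x dim
        labels = draws.param_names.get(group, [group] * arr.shape[2])
        for j in range(arr.shape[2]):
            name = labels[j] if j < len(labels) else f"{group}[{j}]"
            entry = {
                "mean": float(arr[:, :, j].mean()),
                "lag1_autocorr": _lag_autocorr(arr[:, :, j].ravel()),
            }
            if not single:
                rhat = _split_rhat(arr[:, :, j])
                entry["rhat"] = rhat
                entry["converged"] = bool(rhat < rhat_threshold)
            report["parameters"][name] = entry
    return report
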