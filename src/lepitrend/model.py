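"""Hierarchical Bayesian GLMMs for per-night community responses.

``CommunityTrendModel`` is built from a response vector and a
:class:`~lepitrend.design.DesignSpec` (or directly from the community and
nights tables via :meth:`CommunityTrendModel.from_tables`).  Total abundance
uses a zero-inflated negative binomial likelihood; coverage-corrected
richness and biomass use a hurdle gamma.  All likelihoods use a log link;
the zero/hurdle probability is intercept-only.

The posterior combines the response likelihood with standard-normal
non-centred random effects for site, site-year, night group and
spatio-temporal cluster, penalized (random-effect) representations of the
day-of-year and duration smooths, and weakly-informative default priors:
student-t(3, centre, scale) on the intercept, flat on slopes,
half-student-t(3, 0, 2.5) on random-effect and smoothing SDs,
gamma(0.01, 0.01) on the NB/gamma shape, and a flat prior on the mixing
probability ``pi`` itself.

``fit`` runs adaptive HMC (seeded, deterministic) and returns a
``TrendResults`` object carrying posterior draws, split-R-hat diagnostics,
the design snapshot with its standardization constants, and ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from . import hmc
from .design import DesignSpec, build_design
from .diagnostics import RHAT_THRESHOLD, compute_rhat
from .distributions import HurdleGammaKernel, ZINBKernel

RANDOM_TERMS = ("site", "site_year", "night", "cluster")
FAMILIES = ("zinb", "hurdle_gamma")


class _Layout:
    """Maps named parameter blocks onto one flat unconstrained vector."""

    def __init__(self):
        self.slices: dict[str, slice] = {}
        self.size = 0

    def add(self, name: str, k: int) -> None:
        self.slices[name] = slice(self.size, self.size + k)
        self.size += k

    def __getitem__(self, name: str) -> slice:
        return self.slices[name]

    def __contains__(self, name: str) -> bool:
        return name in self.slices


def _half_t_logpdf_grad(s: float, scale: float = 2.5) -> tuple[float, float]:
    # density of half-t(3, 0, scale) at s, plus d/d log s including jacobian
    z2 = s * s / (3.0 * scale * scale)
    logp = -2.0 * np.log1p(z2) + np.log(s)
    dlogp_dlogs = -4.0 * s * s / (3.0 * scale * scale + s * s) + 1.0
    return logp, dlogp_dlogs


class CommunityTrendModel:
    """GLMM for one community response against year x elevation.

    Parameters
    ----------
    y : array
        Per-night response, aligned with the design rows.  Non-negative
        integers for ``family="zinb"``, non-negative floats for
        ``family="hurdle_gamma"``.
    design : DesignSpec
        Output of :func:`lepitrend.design.build_design`.
    family : str
        ``"zinb"`` (abundance) or ``"hurdle_gamma"`` (richness, biomass).
    zero_inflated, include_random, include_smooths, flat_priors, fixed_shape
        Structure switches used mainly for testing reduced models;
        the defaults give the full model.
    """

    def __init__(
        self,
        y,
        design: DesignSpec,
        family: str = "zinb",
        zero_inflated: bool = True,
        include_random: bool = True,
        include_smooths: bool = True,
        flat_priors: bool = False,
        fixed_shape: float | None = None,
    ):
        if family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        y = np.asarray(y, dtype=float)
        if len(y) != design.n_obs:
            raise ValueError("response and design have different lengths")
        if np.any(y < 0):
            raise ValueError("response must be non-negative")
        if family == "zinb" and np.any(y != np.floor(y)):
            raise ValueError("ZINB response must be integer-valued")
        self.y = y
        self.design = design
        self.family = family
        self.zero_inflated = zero_inflated if family == "zinb" else True
        self.include_random = include_random
        self.include_smooths = include_smooths
        self.flat_priors = flat_priors
        self.fixed_shape = fixed_shape

        # brms-style data-dependent intercept prior on the link scale
        link_y = np.log(y + (y[y > 0].min() if np.any(y > 0) else 1.0) / 2.0)
        self._icpt_centre = float(np.median(link_y))
        mad = float(np.median(np.abs(link_y - np.median(link_y))))
        self._icpt_scale = max(2.5, 2.5 * mad)

        self._kernel = ZINBKernel(y) if family == "zinb" else HurdleGammaKernel(y)

        lay = _Layout()
        lay.add("beta", design.X.shape[1])
        if include_smooths:
            lay.add("a_doy", design.B_doy.shape[1])
            lay.add("log_tau_doy", 1)
            if np.any(design.B_dur):
                lay.add("a_dur", design.B_dur.shape[1])
                lay.add("log_tau_dur", 1)
        if include_random:
            for g in RANDOM_TERMS:
                lay.add(f"z_{g}", design.group_n[g])
                lay.add(f"log_sigma_{g}", 1)
        if fixed_shape is None:
            lay.add("log_shape", 1)
        if self.zero_inflated:
            lay.add("logit_pi", 1)
        self.layout = lay

    # ------------------------------------------------------------------
    @classmethod
    def from_tables(
        cls,
        community: pd.DataFrame,
        nights: pd.DataFrame,
        response: str = "abundance",
        group: str = "all",
        **kwargs,
    ) -> "CommunityTrendModel":
        """Build the model from a tidy community table joined to nights.

        ``response`` selects the column (``abundance`` -> ZINB;
        ``richness_cc``/``biomass_mg`` -> hurdle gamma); ``group`` selects
        the community-table rows ("all" or a trait-group label).
        """
        sub = community[community["group"] == group]
        if sub.empty:
            raise ValueError(f"no community rows for group {group!r}")
        joined = sub.merge(nights, on="night_id", how="inner", validate="1:1")
        design = build_design(joined)
        family = "zinb" if response == "abundance" else "hurdle_gamma"
        y = joined[response].to_numpy()
        return cls(y, design, family=family, **kwargs)

    # ------------------------------------------------------------------
    def _initial_point(self) -> np.ndarray:
        theta = np.zeros(self.layout.size)
        theta[self.layout["beta"]][...] = 0.0
        b = theta[self.layout["beta"]]
        b[0] = self._icpt_centre
        theta[self.layout["beta"]] = b
        if "log_shape" in self.layout:
            theta[self.layout["log_shape"]] = 0.0
        if "logit_pi" in self.layout:
            frac0 = np.clip(np.mean(self.y == 0), 0.02, 0.98)
            if self.family == "zinb":
                frac0 = np.clip(frac0 / 2.0, 0.02, 0.98)
            theta[self.layout["logit_pi"]] = logit(frac0)
        return theta

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Log posterior density (up to a constant) and its gradient."""
        lay = self.layout
        d = self.design
        grad = np.zeros_like(theta)
        beta = theta[lay["beta"]]
        eta = d.X @ beta

        if self.include_smooths:
            a_doy = theta[lay["a_doy"]]
            tau_doy = float(np.exp(theta[lay["log_tau_doy"]][0]))
            eta = eta + d.B_doy @ (tau_doy * a_doy)
            if "a_dur" in lay:
                a_dur = theta[lay["a_dur"]]
                tau_dur = float(np.exp(theta[lay["log_tau_dur"]][0]))
                eta = eta + d.B_dur @ (tau_dur * a_dur)

        sigmas = {}
        if self.include_random:
            for g in RANDOM_TERMS:
                z = theta[lay[f"z_{g}"]]
                s = float(np.exp(theta[lay[f"log_sigma_{g}"]][0]))
                sigmas[g] = (z, s)
                eta = eta + s * z[d.group_idx[g]]

        if np.any(eta > 40.0):  # exp would overflow; reject
            return -np.inf, grad

        shape = self.fixed_shape if self.fixed_shape is not None else float(
            np.exp(theta[lay["log_shape"]][0])
        )
        if self.zero_inflated:
            pi = float(expit(theta[lay["logit_pi"]][0]))
        else:
            pi = 0.0

        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            ll, g_eta, g_shape, g_pi = self._kernel(eta, shape, pi)
        if not np.isfinite(ll):
            return -np.inf, grad

        logp = ll
        grad[lay["beta"]] = d.X.T @ g_eta

        if not self.flat_priors:
            x0 = beta[0] - self._icpt_centre
            s0 = self._icpt_scale
            logp += -2.0 * np.log1p(x0 * x0 / (3.0 * s0 * s0))
            grad[lay["beta"]][0] += -4.0 * x0 / (3.0 * s0 * s0 + x0 * x0)

        if self.include_smooths:
            bt = d.B_doy.T @ g_eta
            grad[lay["a_doy"]] = tau_doy * bt - a_doy
            logp += -0.5 * float(a_doy @ a_doy)
            gt = tau_doy * float(a_doy @ bt)
            if not self.flat_priors:
                lp, dg = _half_t_logpdf_grad(tau_doy)
                logp += lp
                gt += dg
            grad[lay["log_tau_doy"]] = gt
            if "a_dur" in lay:
                bt2 = d.B_dur.T @ g_eta
                grad[lay["a_dur"]] = tau_dur * bt2 - a_dur
                logp += -0.5 * float(a_dur @ a_dur)
                gt2 = tau_dur * float(a_dur @ bt2)
                if not self.flat_priors:
                    lp, dg = _half_t_logpdf_grad(tau_dur)
                    logp += lp
                    gt2 += dg
                grad[lay["log_tau_dur"]] = gt2

        if self.include_random:
            for g in RANDOM_TERMS:
                z, s = sigmas[g]
                agg = np.bincount(d.group_idx[g], weights=g_eta, minlength=d.group_n[g])
                grad[lay[f"z_{g}"]] = s * agg - z
                logp += -0.5 * float(z @ z)
                gs = s * float(z @ agg)
                if not self.flat_priors:
                    lp, dg = _half_t_logpdf_grad(s)
                    logp += lp
                    gs += dg
                grad[lay[f"log_sigma_{g}"]] = gs

        if self.fixed_shape is None:
            gsh = g_shape * shape
            if not self.flat_priors:
                logp += 0.01 * np.log(shape) - 0.01 * shape
                gsh += 0.01 - 0.01 * shape
            grad[lay["log_shape"]] = gsh

        if self.zero_inflated:
            gpi = g_pi * pi * (1.0 - pi)
            # flat prior on pi itself => logistic density on the logit scale
            logp += np.log(pi) + np.log1p(-pi)
            gpi += 1.0 - 2.0 * pi
            grad[lay["logit_pi"]] = gpi

        return float(logp), grad

    def log_posterior(self, theta: np.ndarray) -> float:
        return self.logp_grad(np.asarray(theta, dtype=float))[0]

    # ------------------------------------------------------------------
    def fit(
        self,
        chains: int = 4,
        iterations: int = 2000,
        warmup: int = 1000,
        seed: int = 0,
        target_accept: float = 0.8,
        max_leapfrog: int = 16,
        init: str = "map",
    ) -> "TrendResults":
        """Sample the posterior with adaptive HMC.

        ``iterations`` counts total iterations per chain including
        ``warmup`` (the convention of the Stan interfaces); a fixed ``seed``
        reproduces draws exactly.  ``init="map"`` starts the chains from a
        jittered posterior mode (with SDs floored away from the funnel
        neck), which makes short warmups far more effective; ``init="default"``
        starts from the data-derived heuristic point.
        """
        if warmup >= iterations:
            raise ValueError("warmup must be smaller than iterations")
        if init == "map":
            start = self.fit_map(maxiter=400)["theta"].copy()
            for name, sl in self.layout.slices.items():
                if name.startswith("log_sigma") or name.startswith("log_tau"):
                    start[sl] = np.maximum(start[sl], -2.5)
        elif init == "default":
            start = self._initial_point()
        else:
            raise ValueError("init must be 'map' or 'default'")
        draws, chain_info = hmc.sample(
            self.logp_grad,
            start,
            chains=chains,
            n_iter=iterations,
            n_warmup=warmup,
            seed=seed,
            target_accept=target_accept,
            max_leapfrog=max_leapfrog,
        )
        return TrendResults(self, draws, chain_info, seed)

    def fit_map(self, maxiter: int = 500) -> dict[str, np.ndarray | float]:
        """Posterior mode via L-BFGS (mainly for reduced-model checks)."""
        init = self._initial_point()

        def negative(theta):
            lp, g = self.logp_grad(theta)
            return -lp, -g

        res = minimize(
            negative,
            init,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": 1e-10, "ftol": 1e-14},
        )
        out = {"theta": res.x, "logp": -res.fun, "converged": bool(res.success)}
        out["beta"] = res.x[self.layout["beta"]]
        return out


@dataclass
class TrendResults:
    """Posterior draws plus diagnostics for a fitted community model."""

    model: CommunityTrendModel
    _draws: np.ndarray          # (chains, n_kept, d)
    chain_info: list
    seed: int

    # -- raw access -----------------------------------------------------
    @property
    def n_chains(self) -> int:
        return self._draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self._draws.shape[0] * self._draws.shape[1]

    def block(self, name: str) -> np.ndarray:
        """Draws of one parameter block, shape (chains, n_kept, k)."""
        return self._draws[:, :, self.model.layout[name]]

    def coef_draws(self, column: str) -> np.ndarray:
        """Flattened posterior draws of one fixed-effect coefficient."""
        j = self.model.design.x_names.index(column)
        return self.block("beta")[:, :, j].ravel()

    @property
    def beta_year(self) -> np.ndarray:
        return self.coef_draws("year_z")

    @property
    def beta_elev(self) -> np.ndarray:
        return self.coef_draws("elev_z")

    @property
    def beta_yx(self) -> np.ndarray:
        return self.coef_draws("year_z:elev_z")

    @property
    def intercept(self) -> np.ndarray:
        return self.coef_draws("intercept")

    @property
    def pi(self) -> np.ndarray:
        if "logit_pi" not in self.model.layout:
            return np.zeros(self.n_draws)
        return expit(self.block("logit_pi")[:, :, 0].ravel())

    @property
    def shape(self) -> np.ndarray:
        if self.model.fixed_shape is not None:
            return np.full(self.n_draws, self.model.fixed_shape)
        return np.exp(self.block("log_shape")[:, :, 0].ravel())

    def sigma(self, term: str) -> np.ndarray:
        return np.exp(self.block(f"log_sigma_{term}")[:, :, 0].ravel())

    # -- diagnostics ----------------------------------------------------
    def rhat(self, rank_normalize: bool = False) -> pd.Series:
        """Split-R-hat for every scalar parameter."""
        out = {}
        lay = self.model.layout
        names = self.model.design.x_names
        for name, sl in lay.slices.items():
            arr = self._draws[:, :, sl]
            for j in range(arr.shape[2]):
                label = names[j] if name == "beta" else (
                    name if arr.shape[2] == 1 else f"{name}[{j}]"
                )
                out[label] = compute_rhat(arr[:, :, j], rank_normalize)
        return pd.Series(out, name="rhat")

    @property
    def converged(self) -> bool:
        r = self.rhat()
        return bool(np.all(np.nan_to_num(r.to_numpy(), nan=np.inf) < RHAT_THRESHOLD))

    @property
    def n_divergent(self) -> int:
        return int(sum(c.n_divergent for c in self.chain_info))

    # -- summaries ------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD, 95% CI and R-hat for the headline parameters."""
        rows = []
        r = self.rhat()

        def _row(label, draws):
            lo, hi = np.percentile(draws, [2.5, 97.5])
            rows.append(
                {
                    "parameter": label,
                    "mean": float(np.mean(draws)),
                    "sd": float(np.std(draws)),
                    "ci2.5": float(lo),
                    "ci97.5": float(hi),
                    "rhat": float(r.get(label, np.nan)),
                }
            )

        for name in self.model.design.x_names:
            _row(name, self.coef_draws(name))
        if self.model.include_random:
            for g in RANDOM_TERMS:
                d = self.sigma(g)
                lo, hi = np.percentile(d, [2.5, 97.5])
                rows.append(
                    {
                        "parameter": f"sigma_{g}",
                        "mean": float(np.mean(d)),
                        "sd": float(np.std(d)),
                        "ci2.5": float(lo),
                        "ci97.5": float(hi),
                        "rhat": float(r.get(f"log_sigma_{g}", np.nan)),
                    }
                )
        shape_label = "phi" if self.model.family == "zinb" else "alpha"
        d = self.shape
        lo, hi = np.percentile(d, [2.5, 97.5])
        rows.append(
            {
                "parameter": shape_label,
                "mean": float(np.mean(d)),
                "sd": float(np.std(d)),
                "ci2.5": float(lo),
                "ci97.5": float(hi),
                "rhat": float(r.get("log_shape", np.nan)),
            }
        )
        if "logit_pi" in self.model.layout:
            d = self.pi
            lo, hi = np.percentile(d, [2.5, 97.5])
            rows.append(
                {
                    "parameter": "pi",
                    "mean": float(np.mean(d)),
                    "sd": float(np.std(d)),
                    "ci2.5": float(lo),
                    "ci97.5": float(hi),
                    "rhat": float(r.get("logit_pi", np.nan)),
                }
            )
        return pd.DataFrame(rows)

    def save(self, draws_path, sidecar_path) -> None:
        """Write draws as CSV plus a JSON sidecar (constants, seed, R-hat)."""
        import json

        names = []
        lay = self.model.layout
        xn = self.model.design.x_names
        for name, sl in lay.slices.items():
            k = sl.stop - sl.start
            if name == "beta":
                names.extend(xn)
            elif k == 1:
                names.append(name)
            else:
                names.extend(f"{name}[{j}]" for j in range(k))
        flat = self._draws.reshape(-1, self._draws.shape[2])
        df = pd.DataFrame(flat, columns=names)
        df.insert(0, "chain", np.repeat(np.arange(self.n_chains), self._draws.shape[1]))
        df.to_csv(draws_path, index=False)
        side = {
            "seed": int(self.seed),
            "family": self.model.family,
            "standardization": {
                k: list(v) for k, v in self.model.design.standardization.items()
            },
            "observed_elev_range": list(self.model.design.observed_elev_range),
            "observed_year_range": list(self.model.design.observed_year_range),
            "rhat": {k: (None if np.isnan(v) else float(v)) for k, v in self.rhat().items()},
        }
        with open(sidecar_path, "w") as fh:
            json.dump(side, fh, indent=1)
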