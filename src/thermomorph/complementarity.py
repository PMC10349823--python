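"""Rule-conformance classification and the slope-on-slope meta-regression.

A family *conforms to Bergmann's rule* when the 95% credible interval of its
body-mass temperature slope lies entirely below zero, and *to Allen's rule*
when the interval of its bill-size slope lies entirely above zero.  Families
whose intervals include zero are non-significant; among families
non-significant for both traits, those whose point estimates nevertheless
point the expected way (body slope < 0, bill slope > 0) are flagged — the
parenthetical count in the cross-tabulation.

The across-family relationship between the two sets of slopes is estimated
with an errors-in-variables meta-regression: each family's observed bill
slope is normal around θ_j = α + β·x_j with its known posterior SD, the
observed body slope is normal around the latent true slope x_j with its known
SD, and the latents share a population N(μ_body, τ²).  A negative β is the
complementarity signal: stronger bill-size gradients pair with weaker
body-size gradients.  Inference is a conjugate Gibbs sampler with
weakly-informative N(0, 1) priors on α, β, and μ_body.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConformanceRecord",
    "classify_conformance",
    "classify_families",
    "crosstab_table1",
    "SlopeMetaRegression",
    "MetaRegressionResults",
    "fit_metaregression",
]

BODY_CLASSES = ["nonsignificant", "bergmann", "positive"]
BILL_CLASSES = ["nonsignificant", "allen", "negative"]


@dataclass(frozen=True)
class ConformanceRecord:
    family: str
    body_class: str   # bergmann (negative & significant) | positive | nonsignificant
    bill_class: str   # allen (positive & significant) | negative | nonsignificant
    expected_direction_flag: bool  # both nonsignificant but pointing the expected way


def _require(est: pd.Series | dict, keys=("family", "median", "q2.5", "q97.5")) -> dict:
    d = dict(est)
    missing = [k for k in keys if k not in d]
    if missing:
        raise KeyError(f"slope estimate missing fields: {missing}")
    return d


def classify_conformance(body, bill) -> ConformanceRecord:
    """Classify one family from its body and bill slope estimates.

    ``body`` and ``bill`` are mappings/Series with ``family``, ``median``,
    ``q2.5``, ``q97.5`` (the central 95% credible interval).
    """
    b = _require(body)
    a = _require(bill)
    if b["family"] != a["family"]:
        raise ValueError(f"family mismatch: {b['family']!r} vs {a['family']!r}")
    if b["q97.5"] < 0:
        body_class = "bergmann"
    elif b["q2.5"] > 0:
        body_class = "positive"
    else:
        body_class = "nonsignificant"
    if a["q2.5"] > 0:
        bill_class = "allen"
    elif a["q97.5"] < 0:
        bill_class = "negative"
    else:
        bill_class = "nonsignificant"
    flag = (
        body_class == "nonsignificant"
        and bill_class == "nonsignificant"
        and b["median"] < 0
        and a["median"] > 0
    )
    return ConformanceRecord(
        family=str(b["family"]),
        body_class=body_class,
        bill_class=bill_class,
        expected_direction_flag=flag,
    )


def classify_families(body_slopes: pd.DataFrame, bill_slopes: pd.DataFrame) -> list[ConformanceRecord]:
    """Classify every family present in both slope tables (aligned on family)."""
    body_idx = body_slopes.set_index("family")
    bill_idx = bill_slopes.set_index("family")
    fams = [f for f in body_idx.index if f in bill_idx.index]
    out = []
    for fam in fams:
        body = body_idx.loc[fam].to_dict() | {"family": fam}
        bill = bill_idx.loc[fam].to_dict() | {"family": fam}
        out.append(classify_conformance(body, bill))
    return out


def crosstab_table1(records: list[ConformanceRecord]) -> tuple[pd.DataFrame, int]:
    """3×3 cross-tabulation of body vs bill classes, plus the flagged count.

    The flagged count is the number of families in the (nonsignificant,
    nonsignificant) cell whose point estimates nevertheless point in the
    directions both rules expect.
    """
    if not records:
        raise ValueError("no conformance records")
    table = pd.DataFrame(0, index=BODY_CLASSES, columns=BILL_CLASSES)
    flagged = 0
    for r in records:
        table.loc[r.body_class, r.bill_class] += 1
        flagged += int(r.expected_direction_flag)
    table.index.name = "body"
    table.columns.name = "bill"
    return table, flagged


# ---------------------------------------------------------------------------
# Errors-in-variables meta-regression


class SlopeMetaRegression:
    """Meta-regression of bill slopes on body slopes with known SEs.

    Parameters
    ----------
    bill_slopes, body_slopes : DataFrames with columns ``family``, ``median``,
        ``sd`` (posterior SD used as the known standard error), aligned on
        family.
    extra_tau : estimate an additional bill-side residual SD beyond the
        reported SEs.  Off by default; switched on automatically (with a
        warning) when every bill SE is zero, where the stated model is a
        degenerate delta function.
    """

    def __init__(
        self,
        bill_slopes: pd.DataFrame,
        body_slopes: pd.DataFrame,
        extra_tau: bool = False,
    ) -> None:
        bill = bill_slopes.set_index("family")
        body = body_slopes.set_index("family")
        fams = [f for f in body.index if f in bill.index]
        if len(fams) < 3:
            raise ValueError("need at least 3 families for the meta-regression")
        self.families = fams
        self.y = bill.loc[fams, "median"].to_numpy(dtype=float)
        self.sy = bill.loc[fams, "sd"].to_numpy(dtype=float)
        self.w = body.loc[fams, "median"].to_numpy(dtype=float)
        self.sw = body.loc[fams, "sd"].to_numpy(dtype=float)
        if np.any(self.sy < 0) or np.any(self.sw < 0):
            raise ValueError("standard errors must be nonnegative")
        self.extra_tau = bool(extra_tau)
        if not self.extra_tau and np.all(self.sy == 0):
            warnings.warn(
                "all bill-slope SEs are zero: estimating a residual SD "
                "(the stated measurement-error likelihood is degenerate)",
                stacklevel=2,
            )
            self.extra_tau = True
        if np.ptp(self.w) < 1e-12:
            warnings.warn(
                "body slopes are (near) constant: meta-regression slope is "
                "unidentifiable and the posterior will follow the prior",
                stacklevel=2,
            )

    def fit(
        self,
        iterations: int = 6000,
        burn_in: int = 1000,
        thin: int = 2,
        chains: int = 2,
        seed: int = 0,
        prior_sd: float = 1.0,
    ) -> "MetaRegressionResults":
        """Conjugate Gibbs sampler over (α, β, μ_body, τ², latents, [τ_extra²])."""
        if iterations <= burn_in:
            raise ValueError("iterations must exceed burn_in")
        y, sy, w, sw = self.y, self.sy, self.w, self.sw
        J = len(y)
        sy2 = sy**2
        sw2 = sw**2
        prior_prec = 1.0 / prior_sd**2
        a_tau, b_tau = 0.001, 0.001  # vague inverse-gamma on latent spread τ²

        n_draws = (iterations - burn_in) // thin
        alpha_d = np.empty((chains, n_draws))
        beta_d = np.empty((chains, n_draws))
        mu_d = np.empty((chains, n_draws))
        tau_d = np.empty((chains, n_draws))
        extra_d = np.empty((chains, n_draws))
        x_d = np.empty((chains, n_draws, J))

        for c in range(chains):
            rng = np.random.default_rng(seed + c)
            x = w.copy()
            alpha, beta = 0.0, 0.0
            mu = float(w.mean())
            tau2 = max(float(w.var()), 1e-10)
            extra2 = max(float(y.var()), 1e-10) if self.extra_tau else 0.0
            keep = 0
            for it in range(iterations):
                v = sy2 + extra2  # bill-side variance per family
                v = np.maximum(v, 1e-300)

                # (alpha, beta) | x: weighted Bayesian regression
                X = np.column_stack([np.ones(J), x])
                prec = X.T @ (X / v[:, None]) + prior_prec * np.eye(2)
                rhs = X.T @ (y / v)
                L = np.linalg.cholesky(prec)
                mean = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
                ab = mean + np.linalg.solve(L.T, rng.standard_normal(2))
                alpha, beta = float(ab[0]), float(ab[1])

                # latents x_j | rest
                prec_x = beta**2 / v + 1.0 / tau2
                rhs_x = beta * (y - alpha) / v + mu / tau2
                obs = sw2 > 0
                prec_x = prec_x + np.where(obs, 1.0 / np.where(obs, sw2, 1.0), 0.0)
                rhs_x = rhs_x + np.where(obs, w / np.where(obs, sw2, 1.0), 0.0)
                x = rhs_x / prec_x + rng.standard_normal(J) / np.sqrt(prec_x)
                x = np.where(obs, x, w)  # zero body SE pins the latent

                # mu_body | x
                prec_mu = J / tau2 + prior_prec
                mu = rng.normal((x.sum() / tau2) / prec_mu, 1.0 / np.sqrt(prec_mu))

                # tau² | x, mu
                tau2 = 1.0 / rng.gamma(
                    a_tau + 0.5 * J, 1.0 / (b_tau + 0.5 * np.sum((x - mu) ** 2))
                )

                # optional bill-side residual variance
                if self.extra_tau:
                    r = y - alpha - beta * x
                    if np.all(sy2 == 0):
                        extra2 = 1.0 / rng.gamma(
                            a_tau + 0.5 * J, 1.0 / (b_tau + 0.5 * np.sum(r**2))
                        )
                    else:
                        # non-conjugate when SEs differ: random-walk Metropolis on log extra²
                        prop = extra2 * np.exp(0.3 * rng.standard_normal())
                        ll_cur = -0.5 * np.sum(np.log(sy2 + extra2) + r**2 / (sy2 + extra2))
                        ll_prop = -0.5 * np.sum(np.log(sy2 + prop) + r**2 / (sy2 + prop))
                        # log-scale proposal: symmetric in log space; IG(a,b) prior
                        lp_cur = -(a_tau + 1) * np.log(extra2) - b_tau / extra2 + np.log(extra2)
                        lp_prop = -(a_tau + 1) * np.log(prop) - b_tau / prop + np.log(prop)
                        if np.log(rng.uniform()) < (ll_prop + lp_prop) - (ll_cur + lp_cur):
                            extra2 = prop

                if it >= burn_in and (it - burn_in) % thin == 0:
                    alpha_d[c, keep] = alpha
                    beta_d[c, keep] = beta
                    mu_d[c, keep] = mu
                    tau_d[c, keep] = np.sqrt(tau2)
                    extra_d[c, keep] = np.sqrt(extra2) if self.extra_tau else 0.0
                    x_d[c, keep] = x
                    keep += 1

        return MetaRegressionResults(
            model=self,
            alpha=alpha_d,
            beta=beta_d,
            mu_body=mu_d,
            tau=tau_d,
            extra_sd=extra_d,
            latents=x_d,
            seed=seed,
        )


@dataclass
class MetaRegressionResults:
    """Posterior draws and summaries from :class:`SlopeMetaRegression.fit`."""

    model: SlopeMetaRegression
    alpha: np.ndarray
    beta: np.ndarray
    mu_body: np.ndarray
    tau: np.ndarray
    extra_sd: np.ndarray
    latents: np.ndarray
    seed: int

    def _summ(self, draws: np.ndarray) -> dict:
        d = draws.reshape(-1)
        lo, hi = np.quantile(d, [0.025, 0.975])
        return {
            "median": float(np.median(d)),
            "sd": float(d.std(ddof=1)),
            "q2.5": float(lo),
            "q97.5": float(hi),
        }

    def params_summary(self) -> pd.DataFrame:
        rows = {
            "alpha": self._summ(self.alpha),
            "beta_metaregression": self._summ(self.beta),
            "mu_body": self._summ(self.mu_body),
            "tau_latent": self._summ(self.tau),
        }
        if self.model.extra_tau:
            rows["extra_residual_sd"] = self._summ(self.extra_sd)
        return pd.DataFrame(rows).T

    def latent_summary(self) -> pd.DataFrame:
        rows = []
        for j, fam in enumerate(self.model.families):
            s = self._summ(self.latents[:, :, j])
            s["family"] = fam
            rows.append(s)
        return pd.DataFrame(rows).set_index("family")

    @property
    def slope_median(self) -> float:
        return float(np.median(self.beta))

    def slope_ci(self) -> tuple[float, float]:
        lo, hi = np.quantile(self.beta.reshape(-1), [0.025, 0.975])
        return float(lo), float(hi)

    def summary(self) -> str:
        head = (
            f"Errors-in-variables meta-regression of bill slopes on body slopes\n"
            f"  families: {len(self.model.families)}   chains: {self.beta.shape[0]} x "
            f"{self.beta.shape[1]} draws (seed {self.seed})\n"
        )
        return head + self.params_summary().to_string(float_format=lambda v: f"{v: .5g}")

    def to_json(self) -> dict:
        return {
            "params": {k: v for k, v in self.params_summary().to_dict("index").items()},
            "n_families": len(self.model.families),
            "seed": self.seed,
        }


def fit_metaregression(
    bill_slopes: pd.DataFrame,
    body_slopes: pd.DataFrame,
    seed: int = 0,
    **fit_kwargs,
) -> MetaRegressionResults:
    """Convenience wrapper: build and fit the meta-regression in one call."""
    return SlopeMetaRegression(bill_slopes, body_slopes).fit(seed=seed, **fit_kwargs)
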