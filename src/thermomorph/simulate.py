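"""Synthetic species-level datasets with known ground truth.

The generator reproduces the statistical structure assumed by the hierarchical
models in this package, run forwards:

* a pure-birth family tree, scaled to unit height, yields Ω;
* family intercepts and body-mass temperature slopes are drawn jointly from a
  multivariate normal with across-family covariance Σ ⊗ Ω, where Σ is the 2×2
  intercept/slope covariance;
* each family's bill-size temperature slope is a linear function of its body
  slope (the across-family "complementarity" line) plus independent scatter —
  the default slope of −0.25 encodes the complementarity scenario in which
  stronger bill gradients pair with weaker body gradients;
* species ln body mass follows intercept + slope × temperature + noise;
  species ln bill size follows a quadratic allometry on ln mass, a diet
  effect, the family bill slope × temperature, and noise;
* four linear bill measurements (exposed culmen, tip-to-nares distance, bill
  width, bill depth, in mm) are back-generated from ln bill size with fixed
  positive loadings plus small lognormal noise so that the morphometric
  composite stage has realistic 4-column input.

Every draw flows from a single integer seed; the truth record stores all
hyperparameters and the per-family intercepts and slopes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .phylo import PhyloTree, PhyloCovariance, phylo_vcv, read_newick, scale_unit_height, simulate_pure_birth

__all__ = ["SimulationConfig", "SyntheticDataset", "generate_dataset", "write_fixture", "read_fixture"]

# loadings of the four linear bill measurements (mm) on ln bill size; the
# intercepts put them on realistic AVONET-like scales (exposed culmen largest,
# width/depth smaller)
_MEASUREMENT_LOADINGS = {"ec_mm": 1.0, "tnd_mm": 0.9, "bw_mm": 0.8, "bd_mm": 0.85}
_MEASUREMENT_INTERCEPTS = {"ec_mm": 3.0, "tnd_mm": 2.6, "bw_mm": 2.0, "bd_mm": 2.1}
# lognormal noise on each back-generated measurement, set so the leading
# principal component of the four (correlated) measurements carries roughly
# four fifths of their variance, as in real avian bill data
_MEASUREMENT_NOISE_SD = 0.14


@dataclass
class SimulationConfig:
    """All hyperparameters of the generative model (defaults = study conditions)."""

    n_families: int = 30
    species_per_family: int | list[int] = 30
    mu_alpha: float = 3.9          # grand ln body mass intercept (ln g)
    mu_beta_body: float = -0.005   # grand temperature slope (ln g per °C)
    sigma2_alpha: float = 0.5      # phylogenetic variance of family intercepts
    sigma2_beta: float = 1e-4      # phylogenetic variance of family slopes (SD 0.01)
    sigma_alphabeta: float = 0.0   # intercept–slope covariance
    sigma_o_body: float = 0.3      # residual SD of ln body mass
    sigma_o_bill: float = 0.15     # residual SD of ln bill size
    meta_intercept: float = 0.0    # bill-slope meta-line intercept
    meta_slope: float = -0.25      # across-family slope of bill slopes on body slopes
    eta_sd: float = 0.005          # scatter of bill slopes around the meta-line
    b1: float = 0.4                # linear allometry coefficient on ln mass
    b2: float = -0.015             # quadratic allometry coefficient
    diet_effects: tuple = (0.0, 0.10, -0.10, 0.05, -0.05)  # 5-level diet offsets
    temp_range: tuple = (-10.0, 25.0)  # °C, uniform within each family
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma2_alpha, self.sigma2_beta) < 0:
            raise ValueError("variance parameters must be nonnegative")
        cov = self.intercept_slope_cov()
        if np.linalg.eigvalsh(cov).min() < -1e-12:
            raise ValueError("intercept/slope covariance must be PSD")
        if len(self.diet_effects) != 5:
            raise ValueError("diet_effects must have length 5")
        if self.eta_sd < 0:
            raise ValueError("eta_sd must be nonnegative")
        if min(self.sigma_o_body, self.sigma_o_bill) <= 0:
            raise ValueError("residual SDs must be positive")

    def intercept_slope_cov(self) -> np.ndarray:
        return np.array(
            [
                [self.sigma2_alpha, self.sigma_alphabeta],
                [self.sigma_alphabeta, self.sigma2_beta],
            ]
        )


@dataclass
class SyntheticDataset:
    """Species table + family tree + complete generative truth."""

    species: pd.DataFrame
    tree: PhyloTree
    truth: dict

    @property
    def families(self) -> list[str]:
        return list(self.truth["families"])

    def family_vcv(self, unit_height: bool = True) -> PhyloCovariance:
        v = phylo_vcv(self.tree)
        return scale_unit_height(v) if unit_height else v


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the generative model forwards; fully reproducible per seed."""
    rng = np.random.default_rng(config.seed)
    J = config.n_families
    tree = simulate_pure_birth(J, seed=int(rng.integers(2**31)), prefix="fam")
    omega = scale_unit_height(phylo_vcv(tree))
    families = omega.labels

    # (α, β_body) across families: covariance Σ ⊗ Ω (effect-major stacking)
    sigma = config.intercept_slope_cov()
    cov = np.kron(sigma, omega.matrix)
    mean = np.concatenate([np.full(J, config.mu_alpha), np.full(J, config.mu_beta_body)])
    draw = _mvn(rng, mean, cov)
    alpha_j = dict(zip(families, draw[:J]))
    beta_body_j = dict(zip(families, draw[J:]))

    # bill slopes on the across-family meta-line plus scatter
    eta = rng.normal(0.0, config.eta_sd, size=J) if config.eta_sd > 0 else np.zeros(J)
    beta_bill_j = {
        fam: config.meta_intercept + config.meta_slope * beta_body_j[fam] + eta[k]
        for k, fam in enumerate(families)
    }

    if isinstance(config.species_per_family, int):
        n_per = {fam: config.species_per_family for fam in families}
    else:
        if len(config.species_per_family) != J:
            raise ValueError("species_per_family list must have length n_families")
        n_per = dict(zip(families, config.species_per_family))

    rows = []
    sp_counter = 0
    lo, hi = config.temp_range
    for fam in families:
        n = n_per[fam]
        temps = rng.uniform(lo, hi, size=n)
        diets = rng.integers(1, 6, size=n)
        eps_body = rng.normal(0.0, config.sigma_o_body, size=n)
        eps_bill = rng.normal(0.0, config.sigma_o_bill, size=n)
        ln_mass = alpha_j[fam] + beta_body_j[fam] * temps + eps_body
        diet_off = np.array([config.diet_effects[d - 1] for d in diets])
        ln_bill = (
            config.b1 * ln_mass
            + config.b2 * ln_mass**2
            + diet_off
            + beta_bill_j[fam] * temps
            + eps_bill
        )
        for i in range(n):
            sp_counter += 1
            rows.append(
                {
                    "species": f"sp{sp_counter:05d}",
                    "family": fam,
                    "temperature_c": temps[i],
                    "diet": int(diets[i]),
                    "ln_body_mass_g": ln_mass[i],
                    "ln_bill_size": ln_bill[i],
                }
            )
    species = pd.DataFrame(rows)

    # back-generate linear measurements (mm scale) from ln bill size
    for col, load in _MEASUREMENT_LOADINGS.items():
        noise = rng.normal(0.0, _MEASUREMENT_NOISE_SD, size=len(species))
        species[col] = np.exp(
            _MEASUREMENT_INTERCEPTS[col] + load * species["ln_bill_size"].to_numpy() + noise
        )

    truth = {
        "families": families,
        "alpha": {f: float(alpha_j[f]) for f in families},
        "beta_body": {f: float(beta_body_j[f]) for f in families},
        "beta_bill": {f: float(beta_bill_j[f]) for f in families},
        "config": _config_to_jsonable(config),
    }
    return SyntheticDataset(species=species, tree=tree, truth=truth)


def write_fixture(dataset: SyntheticDataset, path) -> dict[str, Path]:
    """Write species CSV, Newick tree, and truth JSON under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = {
        "species": path / "species.csv",
        "tree": path / "family_tree.nwk",
        "truth": path / "truth.json",
    }
    dataset.species.to_csv(out["species"], index=False)
    out["tree"].write_text(dataset.tree.to_newick() + "\n")
    out["truth"].write_text(json.dumps(dataset.truth, indent=1, sort_keys=True))
    return out


def read_fixture(path) -> SyntheticDataset:
    """Inverse of :func:`write_fixture`."""
    path = Path(path)
    species = pd.read_csv(path / "species.csv")
    tree = read_newick((path / "family_tree.nwk").read_text())
    truth = json.loads((path / "truth.json").read_text())
    return SyntheticDataset(species=species, tree=tree, truth=truth)


def _mvn(rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """MVN draw via eigendecomposition; tolerates PSD (rank-deficient) covariances."""
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    z = rng.standard_normal(len(mean))
    return mean + V @ (np.sqrt(w) * z)


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
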