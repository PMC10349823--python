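"""Drivers of apparent rule conformance: randomization tests and regressions.

Families that *appear* to conform to Bergmann's or Allen's rule may simply be
the ones where weak gradients are easiest to detect — more sampled species,
wider temperature ranges, larger bodies — or the ones whose bill evolution is
ecologically constrained (rare, specialized bill shapes).  Two procedures
probe this:

* a univariate randomization test per family trait: trait values are shuffled
  among families (category sizes fixed) to build the null distribution of
  each conformance category's mean; the reported p is the one-sided
  proportion of null means beyond the observed mean, measured toward the
  nearer extreme, with significance when the observed mean sits in the outer
  2.5% tail on either side;
* phylogenetic GLS regressions of conformance *intensity* (the slope
  magnitude, with Bergmann's strength taken as −1 × the body slope) on the
  family traits, with Pagel's λ estimated by ML and a VIF collinearity check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diagnostics import variance_inflation_factors
from .pgls import pgls_fit
from .phylo import PhyloCovariance

__all__ = [
    "TRAIT_COLUMNS",
    "build_family_traits",
    "RandomizationResult",
    "randomization_test",
    "randomization_table",
    "conformance_intensity_gls",
]

TRAIT_COLUMNS = [
    "mean_ln_body_mass",
    "mean_bill_size",
    "mean_relative_bill_size",
    "temperature_range",
    "ln_n_species",
    "mean_kernel_density",
]


def build_family_traits(
    species: pd.DataFrame,
    bill_pc1: pd.Series,
    relative_bill: pd.Series,
    family_mean_density: pd.Series,
    family_col: str = "family",
    temperature_col: str = "temperature_c",
    mass_col: str = "ln_body_mass_g",
) -> pd.DataFrame:
    """Assemble the per-family trait table used by the randomization tests.

    ``bill_pc1`` and ``relative_bill`` are per-species series aligned with
    ``species``; ``family_mean_density`` is indexed by family.  Temperature
    range is the max minus min species mean breeding temperature within the
    family; sample size enters as ln N.
    """
    df = species.copy()
    df["_bill_pc1"] = np.asarray(bill_pc1, dtype=float)
    df["_rel_bill"] = np.asarray(relative_bill, dtype=float)
    grouped = df.groupby(family_col)
    traits = pd.DataFrame(
        {
            "mean_ln_body_mass": grouped[mass_col].mean(),
            "mean_bill_size": grouped["_bill_pc1"].mean(),
            "mean_relative_bill_size": grouped["_rel_bill"].mean(),
            "temperature_range": grouped[temperature_col].max()
            - grouped[temperature_col].min(),
            "ln_n_species": np.log(grouped.size()),
        }
    )
    missing = set(traits.index) - set(family_mean_density.index)
    if missing:
        raise KeyError(f"families missing kernel densities: {sorted(missing)}")
    traits["mean_kernel_density"] = family_mean_density.reindex(traits.index)
    traits.index.name = "family"
    return traits


@dataclass(frozen=True)
class RandomizationResult:
    trait: str
    category: str
    observed_mean: float
    expected_mean: float  # average of the null category means
    p: float              # one-sided, toward the nearer extreme; ties count as beyond
    significant: bool     # observed mean in the outer 2.5% tail of the null


def randomization_test(
    traits: pd.DataFrame,
    categories: pd.Series,
    n_iter: int = 1000,
    seed: int = 0,
    trait_columns: list[str] | None = None,
) -> list[RandomizationResult]:
    """Null distributions of category trait means under label randomization.

    ``categories`` maps each family to its conformance category (e.g.
    bergmann / allen / neither).  Each iteration permutes the trait values
    among families while category sizes stay fixed; each trait is permuted
    independently (univariate tests).  Empty categories are skipped with a
    warning.  Deterministic per seed.
    """
    trait_columns = trait_columns or [c for c in TRAIT_COLUMNS if c in traits.columns]
    cats = pd.Series(np.asarray(categories), index=traits.index)
    levels = [c for c in pd.unique(cats) if (cats == c).sum() > 0]
    if len(levels) < 2:
        raise ValueError("need at least 2 nonempty categories")
    rng = np.random.default_rng(seed)
    n = len(traits)
    masks = {lev: (cats == lev).to_numpy() for lev in levels}
    results = []
    for trait in trait_columns:
        vals = traits[trait].to_numpy(dtype=float)
        # one permutation matrix per trait: (n_iter, n)
        perm = np.argsort(rng.random((n_iter, n)), axis=1)
        permuted = vals[perm]
        for lev in levels:
            mask = masks[lev]
            if mask.sum() == 0:  # pragma: no cover - filtered above
                warnings.warn(f"empty category {lev!r}; skipped", stacklevel=2)
                continue
            observed = float(vals[mask].mean())
            null_means = permuted[:, mask].mean(axis=1)
            # ties count toward "beyond" on both sides (conservative)
            p_low = float(np.mean(null_means <= observed))
            p_high = float(np.mean(null_means >= observed))
            p = min(p_low, p_high)
            results.append(
                RandomizationResult(
                    trait=trait,
                    category=str(lev),
                    observed_mean=observed,
                    expected_mean=float(null_means.mean()),
                    p=p,
                    significant=p < 0.025,
                )
            )
    return results


def randomization_table(results: list[RandomizationResult]) -> pd.DataFrame:
    """Flat table of randomization results (one row per trait × category)."""
    return pd.DataFrame(
        [
            {
                "trait": r.trait,
                "category": r.category,
                "expected_mean": r.expected_mean,
                "observed_mean": r.observed_mean,
                "p": r.p,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def conformance_intensity_gls(
    slopes: pd.Series,
    traits: pd.DataFrame,
    family_vcv: PhyloCovariance,
    rule: str = "bergmann",
    lam: float | None = None,
) -> pd.DataFrame:
    """Phylogenetic regression of rule strength on family traits.

    ``slopes`` holds per-family posterior slope medians indexed by family.
    For ``rule="bergmann"`` the response is −1 × the body slope (so larger
    values mean a stronger Bergmann effect) and the size predictor is mean
    body mass; for ``rule="allen"`` the response is the bill slope and the
    size predictor is mean bill size — body and bill size are too correlated
    to enter one model together.  Pagel's λ is estimated by ML unless fixed.
    Returns a coefficient table with a VIF column (warning above 2, error
    only at perfect collinearity).
    """
    if rule not in {"bergmann", "allen"}:
        raise ValueError("rule must be 'bergmann' or 'allen'")
    fams = [f for f in traits.index if f in slopes.index]
    if len(fams) < 10:
        raise ValueError("need at least 10 families")
    y = slopes.reindex(fams).to_numpy(dtype=float)
    if rule == "bergmann":
        y = -y
        size_col = "mean_ln_body_mass"
    else:
        size_col = "mean_bill_size"
    predictors = [
        size_col,
        "mean_relative_bill_size",
        "temperature_range",
        "ln_n_species",
        "mean_kernel_density",
    ]
    predictors = [p for p in predictors if p in traits.columns]
    Xdf = traits.loc[fams, predictors]
    constant = [p for p in predictors if np.ptp(Xdf[p].to_numpy(dtype=float)) == 0]
    if constant:
        warnings.warn(
            f"dropping constant predictors (collinear with intercept): {constant}",
            stacklevel=2,
        )
        predictors = [p for p in predictors if p not in constant]
        Xdf = Xdf[predictors]
    if np.ptp(y) > 0:
        vifs = variance_inflation_factors(Xdf)
        if np.isinf(vifs).any():
            raise np.linalg.LinAlgError("perfectly collinear predictors")
        if (vifs > 2).any():
            warnings.warn(
                f"variance inflation above 2: {vifs[vifs > 2].to_dict()}", stacklevel=2
            )
    else:
        vifs = variance_inflation_factors(Xdf)
    X = np.column_stack([np.ones(len(fams)), Xdf.to_numpy(dtype=float)])
    vcv = family_vcv.reorder(fams)
    fit = pgls_fit(y, X, vcv, lam=lam, names=["(Intercept)", *predictors])
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
        },
        index=fit.names,
    )
    table["vif"] = [np.nan] + [vifs.get(p, np.nan) for p in predictors]
    table.attrs["lambda"] = fit.lam
    table.attrs["rule"] = rule
    return table
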