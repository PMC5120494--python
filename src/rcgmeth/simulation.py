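"""Simulation harness: power/type-I studies and log-score comparisons.

Three study designs are supported:

* a single-site power study over a grid of effect sizes for one coefficient
  (typically gender), with beta values drawn either from the ratio density
  itself or from a Gumbel-copula bivariate-gamma construction;
* a multi-site study running the single-site design over a table of
  per-site parameter combinations, summarized by effect-size deciles;
* a train/test log-score comparison of the RCG model against beta
  regression and M-value regression.

The covariate matrix is drawn once per study (fixed seed) and reused across
replicates, so rejection rates are conditional on the design — mirroring a
study that keeps the real cohort covariates fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .params import RCGParams, build_design
from .inference import fit_rcg, wald_test, FitSettings
from .comparators import fit_mvalue, fit_betareg, log_score
from .samplers import (CopulaDesign, COHORT_COVARIATE_SPEC, sample_covariates,
                       sample_rcg_beta, sample_gumbel_pair, calibrate_copula)

__all__ = ["SimulationDesign", "SimulationResult", "run_power_study",
           "run_multisite_study", "run_logscore_study", "synthetic_site_table",
           "load_design"]

MODELS = ("rcg", "betareg", "mvalue")

# ML estimates at a reference CpG site of the cohort fit with five
# covariates (intercept, gender, age, bmi, smoking, depression)
REFERENCE_GAMMA = np.array([-1.099, 0.096, -0.007, -0.004, 0.003, 0.001])
REFERENCE_ALPHA = 5.84
REFERENCE_RHO = 0.93

# marginal-mean coefficient vectors of the copula construction at the same
# site (zeta_gender_m is varied to produce the requested gamma_gender)
COPULA_ZETA_M = np.array([-6.2777, np.nan, 0.0003, -0.0001, -0.0199, 0.0010])
COPULA_ZETA_U = np.array([-5.6424, -0.0731, 0.0088, 0.0016, -0.0073, -0.0014])
COPULA_ALPHA_M = 20.2
COPULA_ALPHA_U = 12.760


@dataclass(frozen=True)
class SimulationDesign:
    """Declarative description of one power/type-I study."""
    generator: str = "rcg_ratio"          # "rcg_ratio" or "gumbel_copula"
    n_subjects: int = 1118
    n_replicates: int = 2000
    test_coef: str = "gender"
    effects: tuple[float, ...] = (0.0,)   # grid for gamma_<test_coef>
    gamma: np.ndarray = field(default_factory=lambda: REFERENCE_GAMMA.copy())
    alpha: float = REFERENCE_ALPHA
    rho: float = REFERENCE_RHO
    level: float = 0.05
    seed: int = 0
    models: tuple[str, ...] = MODELS

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must lie in (0, 1)")
        if self.generator not in ("rcg_ratio", "gumbel_copula"):
            raise ValueError(f"unknown generator {self.generator!r}")
        object.__setattr__(self, "gamma", np.asarray(self.gamma, dtype=float))


@dataclass
class SimulationResult:
    design: SimulationDesign
    table: pd.DataFrame       # generator, rho, effect, model, rejections, replicates, rejection_rate, mc_se
    n_nonconverged: int = 0

    def rejection_rate(self, model: str, effect: float) -> float:
        t = self.table
        row = t[(t["model"] == model) & (np.isclose(t["effect"], effect))]
        return float(row["rejection_rate"].iloc[0])


def load_design(path) -> SimulationDesign:
    """Read a :class:`SimulationDesign` from a YAML config file.

    Keys mirror the dataclass fields; ``effects``, ``gamma`` and ``models``
    may be given as lists.
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in ("effects", "models"):
        if key in doc:
            doc[key] = tuple(doc[key])
    if "gamma" in doc:
        doc["gamma"] = np.asarray(doc["gamma"], dtype=float)
    return SimulationDesign(**doc)


def _study_covariates(design: SimulationDesign):
    cov = sample_covariates(design.n_subjects, COHORT_COVARIATE_SPEC,
                            seed=design.seed)
    X, names = build_design(cov)
    return X, names


def _generate_beta(design: SimulationDesign, X: np.ndarray, effect: float,
                   k: int, rng, copula_cache: dict) -> np.ndarray:
    gamma = design.gamma.copy()
    gamma[k] = effect
    if design.generator == "rcg_ratio":
        theta = np.exp(X @ gamma)
        return sample_rcg_beta(X.shape[0], design.alpha, design.rho, theta, rng)
    # Gumbel copula: gamma = zeta_m - zeta_u, so set zeta_m[k] = zeta_u[k] + effect
    if "rho_tilde" not in copula_cache:
        copula_cache["rho_tilde"] = calibrate_copula(
            design.rho, (COPULA_ALPHA_M, COPULA_ALPHA_U),
            seed=np.random.default_rng(design.seed).integers(2**31))
    zeta_m = COPULA_ZETA_M.copy()
    zeta_u = COPULA_ZETA_U.copy()
    zeta_m[k] = zeta_u[k] + effect
    # keep the remaining gamma entries at the design's values
    free = np.isnan(zeta_m)
    zeta_m[free] = zeta_u[free] + gamma[free]
    cd = CopulaDesign(rho_tilde=copula_cache["rho_tilde"],
                      alpha_m=COPULA_ALPHA_M, alpha_u=COPULA_ALPHA_U,
                      zeta_m=zeta_m, zeta_u=zeta_u, target_rho=design.rho)
    m, u = sample_gumbel_pair(X.shape[0], cd, X, rng)
    return m / (m + u)


def _fit_and_test(model: str, b, X, k: int, level: float,
                  settings: FitSettings):
    if model == "rcg":
        fit = fit_rcg(b, X, settings=settings)
        if not fit.converged:
            return None
        return wald_test(fit, k, level).p < level
    if model == "betareg":
        fit = fit_betareg(b, X)
        if not fit.converged:
            return None
        return fit.p[k] < level
    if model == "mvalue":
        return fit_mvalue(b, X).p[k] < level
    raise ValueError(f"unknown model {model!r}")


def run_power_study(design: SimulationDesign,
                    settings: FitSettings = FitSettings()) -> SimulationResult:
    """Estimate rejection rates of H0: gamma_k = 0 over the effect grid.

    A replicate whose RCG fit fails to converge is re-drawn once; if the
    re-draw also fails it is counted as a non-rejection and logged.
    Fully deterministic given the design (seed included).
    """
    X, names = _study_covariates(design)
    try:
        k = names.index(design.test_coef)
    except ValueError:
        raise KeyError(f"test coefficient {design.test_coef!r} not among {names}")
    ss = np.random.SeedSequence(design.seed)
    rows = []
    n_nonconv = 0
    copula_cache: dict = {}
    for effect in design.effects:
        child = np.random.default_rng(ss.spawn(1)[0])
        rej = {m: 0 for m in design.models}
        for _ in range(design.n_replicates):
            b = _generate_beta(design, X, effect, k, child, copula_cache)
            for model in design.models:
                out = _fit_and_test(model, b, X, k, design.level, settings)
                if out is None:  # one re-draw, then count as non-rejection
                    b2 = _generate_beta(design, X, effect, k, child, copula_cache)
                    out = _fit_and_test(model, b2, X, k, design.level, settings)
                    if out is None:
                        n_nonconv += 1
                        out = False
                rej[model] += bool(out)
        for model in design.models:
            phat = rej[model] / design.n_replicates
            rows.append({
                "generator": design.generator, "rho": design.rho,
                "effect": effect, "model": model, "rejections": rej[model],
                "replicates": design.n_replicates, "rejection_rate": phat,
                "mc_se": np.sqrt(phat * (1.0 - phat) / design.n_replicates),
            })
    return SimulationResult(design=design, table=pd.DataFrame(rows),
                            n_nonconverged=n_nonconv)


def synthetic_site_table(n_sites: int, seed: int = 0,
                         effect_range: tuple[float, float] = (-0.3, 0.3)) -> pd.DataFrame:
    """Synthetic per-site parameter table emulating 'real-life' combinations
    of (alpha, rho, gamma) across CpG sites.

    Shapes are log-normal around the reference site's alpha; correlations are
    beta-distributed with mean ~0.45 (the bulk of array-wide intensity
    correlations); gender effects span the given range; the remaining
    coefficients stay at the reference values.
    """
    rng = np.random.default_rng(seed)
    alpha = np.exp(rng.normal(np.log(REFERENCE_ALPHA), 0.4, size=n_sites))
    rho = np.clip(rng.beta(2.9, 3.5, size=n_sites), 0.0, 0.99)
    g_gender = rng.uniform(*effect_range, size=n_sites)
    g0 = rng.normal(-1.0, 0.5, size=n_sites)
    tbl = pd.DataFrame({
        "site": [f"syn{i:04d}" for i in range(n_sites)],
        "alpha": alpha, "rho": rho, "gamma0": g0, "gamma_gender": g_gender,
        "gamma_age": REFERENCE_GAMMA[2], "gamma_bmi": REFERENCE_GAMMA[3],
        "gamma_smoking": REFERENCE_GAMMA[4], "gamma_depression": REFERENCE_GAMMA[5],
    })
    return tbl


def run_multisite_study(site_table: pd.DataFrame, n_subjects: int = 1118,
                        n_replicates: int = 100, level: float = 0.05,
                        seed: int = 0,
                        models: tuple[str, ...] = MODELS) -> pd.DataFrame:
    """Per-site rejection rates over a parameter table, plus decile grouping.

    Returns the site table augmented with one power column per model and a
    ``decile`` column grouping sites by the tested effect.
    """
    if len(site_table) == 0:
        raise ValueError("site table is empty")
    gamma_cols = ["gamma0", "gamma_gender", "gamma_age", "gamma_bmi",
                  "gamma_smoking", "gamma_depression"]
    out = site_table.copy()
    for model in models:
        out[f"power_{model}"] = np.nan
    ss = np.random.SeedSequence(seed)
    for i, row in site_table.iterrows():
        gamma = row[gamma_cols].to_numpy(dtype=float)
        design = SimulationDesign(
            generator="rcg_ratio", n_subjects=n_subjects,
            n_replicates=n_replicates, test_coef="gender",
            effects=(float(row["gamma_gender"]),), gamma=gamma,
            alpha=float(row["alpha"]), rho=float(row["rho"]), level=level,
            seed=int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)),
            models=models)
        res = run_power_study(design)
        for model in models:
            out.loc[i, f"power_{model}"] = res.rejection_rate(
                model, float(row["gamma_gender"]))
    if len(out) >= 10:
        out["decile"] = pd.qcut(out["gamma_gender"], 10, labels=False)
    else:
        out["decile"] = 0
    return out


def run_logscore_study(
    generate,                    # callable(rng) -> (b, X) for one full cohort
    n_splits: int = 10,
    train_size: int = 750,
    test_size: int = 368,
    seed: int = 0,
    jacobian: bool = True,
    settings: FitSettings = FitSettings(),
) -> pd.DataFrame:
    """Train/test log-score comparison of the three models.

    For each split, all models are fitted on the training part and scored on
    the held-out part (mean predictive log-density for b).  Returns one row
    per split with the three scores; attaches Wilcoxon signed-rank p-values
    for the paired RCG-vs-comparator differences as ``DataFrame.attrs``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_splits):
        b, X = generate(rng)
        n = b.shape[0]
        if train_size + test_size > n:
            raise ValueError("train + test exceeds the generated sample size")
        perm = rng.permutation(n)
        tr, te = perm[:train_size], perm[train_size:train_size + test_size]
        scores = {}
        frcg = fit_rcg(b[tr], X[tr], settings=settings)
        if not frcg.converged:
            continue  # excluded pairwise
        scores["rcg"] = log_score(frcg, b[te], X[te])
        scores["betareg"] = log_score(fit_betareg(b[tr], X[tr]), b[te], X[te])
        scores["mvalue"] = log_score(fit_mvalue(b[tr], X[tr]), b[te], X[te],
                                     jacobian=jacobian)
        scores["split"] = s
        rows.append(scores)
    df = pd.DataFrame(rows)
    for other in ("betareg", "mvalue"):
        d = df["rcg"] - df[other]
        if len(d) >= 6 and np.any(d != 0):
            df.attrs[f"wilcoxon_p_rcg_vs_{other}"] = float(
                stats.wilcoxon(d).pvalue)
        else:
            df.attrs[f"wilcoxon_p_rcg_vs_{other}"] = np.nan
        df.attrs[f"mean_diff_rcg_vs_{other}"] = float(d.mean())
    return df
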