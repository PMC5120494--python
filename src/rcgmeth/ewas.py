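"""Site-wise EWAS application of the three models with FDR control.

A :class:`MethylationDataset` holds a sites-by-samples beta matrix aligned
with a per-sample covariate table.  ``run_sitewise`` fits one model per CpG
site and reports Wald tests for a chosen coefficient; ``adjust_fdr``
implements the Benjamini-Hochberg and Benjamini-Yekutieli step-up
procedures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import build_design, clamp_beta
from .inference import fit_rcg, wald_test, FitSettings
from .comparators import fit_betareg, fit_mvalue

logger = logging.getLogger("rcgmeth")

__all__ = ["MethylationDataset", "read_dataset", "run_sitewise", "adjust_fdr"]

#: default stabilizing offset added to M+U when reconstructing beta values
#: from raw intensities
DEFAULT_OFFSET = 100.0

#: refuse sites with more than this fraction of missing beta values
MAX_MISSING_FRACTION = 0.05

RESULT_COLUMNS = ["site", "coef", "estimate", "se", "z", "p",
                  "q_bh", "q_by", "converged"]


@dataclass
class MethylationDataset:
    """Aligned beta-value matrix (sites x samples) and covariate table."""

    sites: list[str]
    samples: list[str]
    betas: np.ndarray            # shape (n_sites, n_samples), values in [0, 1]
    covariates: pd.DataFrame     # indexed by sample id
    offset: float = DEFAULT_OFFSET

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.shape != (len(self.sites), len(self.samples)):
            raise ValueError("beta matrix shape does not match id lists")
        if set(self.covariates.index) != set(self.samples):
            raise ValueError("sample ids of matrix and covariates differ")
        self.covariates = self.covariates.loc[self.samples]
        finite = self.betas[np.isfinite(self.betas)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("beta values must lie in [0, 1]")
        missing = np.mean(~np.isfinite(self.betas), axis=1)
        bad = np.flatnonzero(missing > MAX_MISSING_FRACTION)
        if bad.size:
            raise ValueError(
                f"{bad.size} site(s) exceed {MAX_MISSING_FRACTION:.0%} missing "
                f"beta values (first: {self.sites[bad[0]]}); "
                "complete data are required")

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def read_dataset(
    beta_path,
    covariate_path,
    *,
    m_path=None,
    u_path=None,
    offset: float = DEFAULT_OFFSET,
    sep: str | None = None,
    max_unmatched_fraction: float = 0.2,
) -> MethylationDataset:
    """Read a beta matrix (or raw M/U intensity matrices) and covariates.

    The matrix files have CpG sites in rows and samples in columns (header =
    sample ids, first column = site ids); the covariate table has one sample
    per row.  When ``m_path``/``u_path`` are given instead of ``beta_path``,
    beta values are computed as M/(M+U+offset).  Samples missing from either
    side are dropped with a warning while below ``max_unmatched_fraction``.
    """

    def _read_matrix(path):
        df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
        bad = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
        if len(bad):
            col = bad[0]
            row = df[col].map(
                lambda v: not isinstance(v, (int, float))).idxmax()
            raise ValueError(f"non-numeric cell in {path} at row {row!r}, "
                             f"column {col!r}")
        return df

    if m_path is not None or u_path is not None:
        if m_path is None or u_path is None:
            raise ValueError("both m_path and u_path are required")
        m = _read_matrix(m_path)
        u = _read_matrix(u_path)
        if not (m.index.equals(u.index) and m.columns.equals(u.columns)):
            raise ValueError("M and U matrices must share sites and samples")
        betas = m / (m + u + offset)
    else:
        betas = _read_matrix(beta_path)
    covars = pd.read_csv(covariate_path, sep=sep, engine="python", index_col=0)
    covars.index = covars.index.astype(str)
    betas.columns = betas.columns.astype(str)

    matrix_samples = list(betas.columns)
    shared = [s for s in matrix_samples if s in set(covars.index)]
    n_unmatched = (len(set(matrix_samples) ^ set(covars.index)))
    denom = max(len(matrix_samples), len(covars))
    if len(shared) == 0 or n_unmatched / denom > max_unmatched_fraction:
        raise ValueError(
            f"{n_unmatched} unmatched sample id(s) exceed the allowed "
            f"fraction {max_unmatched_fraction:.0%}")
    if n_unmatched:
        logger.warning("dropping %d unmatched sample(s)", n_unmatched)
    betas = betas[shared]
    covars = covars.loc[shared]

    _, n_clamped = clamp_beta(betas.to_numpy())
    if n_clamped:
        logger.info("ingestion: %d beta value(s) outside (eps, 1-eps) will be "
                    "clamped at fit time", n_clamped)
    return MethylationDataset(sites=list(betas.index.astype(str)),
                              samples=shared, betas=betas.to_numpy(),
                              covariates=covars, offset=offset)


def adjust_fdr(p_values, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg (BH) or Benjamini-Yekutieli (BY) step-up
    adjusted p-values.

    BY multiplies the BH adjustment by the harmonic sum 1 + 1/2 + ... + 1/m,
    valid under arbitrary dependence.  Adjusted values are monotone in the
    order statistics and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    if method.upper() == "BY":
        ranked = ranked * np.sum(1.0 / np.arange(1, m + 1))
    elif method.upper() != "BH":
        raise ValueError("method must be 'BH' or 'BY'")
    # step-up: running minimum from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _site_row(site, model, b, X, names, k, settings) -> dict:
    row = {"site": site, "coef": names[k], "converged": True}
    try:
        if model == "rcg":
            fit = fit_rcg(b, X, settings=settings, coef_names=names)
            t = wald_test(fit, k)
            row.update(estimate=t.estimate, se=t.se, z=t.z, p=t.p,
                       converged=fit.converged)
        elif model == "betareg":
            fit = fit_betareg(b, X, names)
            row.update(estimate=fit.coef[k], se=fit.se[k], z=fit.z[k],
                       p=fit.p[k], converged=fit.converged)
        elif model == "mvalue":
            fit = fit_mvalue(b, X, names)
            row.update(estimate=fit.coef[k], se=fit.se[k], z=fit.z[k],
                       p=fit.p[k])
        else:
            raise ValueError(f"unknown model {model!r}")
    except (ValueError, np.linalg.LinAlgError, FloatingPointError) as exc:
        logger.warning("site %s failed: %s", site, exc)
        row.update(estimate=np.nan, se=np.nan, z=np.nan, p=np.nan,
                   converged=False)
    return row


def run_sitewise(
    dataset: MethylationDataset,
    model: str = "rcg",
    covariates: list[str] | None = None,
    test: str = "gender",
    settings: FitSettings = FitSettings(),
    fdr_methods: tuple[str, ...] = ("BH", "BY"),
) -> pd.DataFrame:
    """Fit one model per CpG site and test one coefficient.

    Sites are independent: the result is invariant to site order up to row
    permutation.  Per-site failures are flagged, not fatal.
    """
    X, names = build_design(dataset.covariates, covariates)
    if test not in names:
        raise KeyError(f"test coefficient {test!r} not among {names}")
    k = names.index(test)
    rows = [_site_row(site, model, dataset.betas[i], X, names, k, settings)
            for i, site in enumerate(dataset.sites)]
    out = pd.DataFrame(rows)
    if out["p"].notna().sum() == 0:
        raise RuntimeError("all sites failed to fit")
    ok = out["p"].notna()
    for meth in fdr_methods:
        col = f"q_{meth.lower()}"
        out[col] = np.nan
        out.loc[ok, col] = adjust_fdr(out.loc[ok, "p"].to_numpy(), meth)
    return out[[c for c in RESULT_COLUMNS if c in out.columns]]
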