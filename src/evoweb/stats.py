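"""Minimal regression layer for trend analysis across the z-sweep.

The sweep analysis needs three things: generalized linear models (gamma and
Poisson with log links, quasibinomial with a logit link) for the metric
regressions, an interaction model for relative generalist/specialist
persistence, and a rank-correlation trend test.  Smoothed additive fits are
deliberately out of scope; a monotone-trend certificate (Spearman) plus GLM
coefficients carries the same scientific content at this scale.

GLM estimation is delegated to statsmodels' IRLS; quasibinomial is the
binomial family with a moment (Pearson chi-square) dispersion estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = ["GlmFit", "glm_fit", "interaction_persistence_model", "spearman_trend"]

_FAMILIES = {
    ("gamma", "log"): lambda: sm.families.Gamma(sm.families.links.Log()),
    ("poisson", "log"): lambda: sm.families.Poisson(sm.families.links.Log()),
    ("quasibinomial", "logit"): lambda: sm.families.Binomial(sm.families.links.Logit()),
    ("gaussian", "identity"): lambda: sm.families.Gaussian(sm.families.links.Identity()),
}
_DEFAULT_LINKS = {"gamma": "log", "poisson": "log",
                  "quasibinomial": "logit", "gaussian": "identity"}


@dataclass
class GlmFit:
    """Result of one GLM fit."""

    family: str
    link: str
    coefficients: np.ndarray
    standard_errors: np.ndarray
    dispersion: float
    converged: bool
    n: int

    def coef_table(self, names: list[str] | None = None) -> pd.DataFrame:
        names = names or [f"b{i}" for i in range(len(self.coefficients))]
        return pd.DataFrame({"coef": self.coefficients, "se": self.standard_errors},
                            index=names)


def glm_fit(y, X, family: str, link: str | None = None, maxiter: int = 100) -> GlmFit:
    """Fit a GLM by iteratively reweighted least squares.

    ``X`` is the full design matrix (include the intercept column
    yourself).  Quasibinomial and gamma fits estimate the dispersion from
    the Pearson chi-square; Poisson fixes it at 1.  Non-convergence is
    reported through the ``converged`` flag rather than an exception.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than design columns")
    if family not in _DEFAULT_LINKS:
        raise ValueError(f"unsupported family {family!r}")
    link = link or _DEFAULT_LINKS[family]
    if (family, link) not in _FAMILIES:
        raise ValueError(f"unsupported family/link combination ({family}, {link})")
    fam = _FAMILIES[(family, link)]()
    scale = "X2" if family in ("quasibinomial", "gamma") else 1.0
    with warnings.catch_warnings():
        # Poisson on non-integer responses (mean lifespans) is intentional,
        # matching a quasi-likelihood reading of count-like data
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=fam)
        try:
            res = model.fit(maxiter=maxiter, scale=scale)
            converged = bool(getattr(res, "converged", True))
        except Exception:
            return GlmFit(family, link, np.full(X.shape[1], np.nan),
                          np.full(X.shape[1], np.nan), float("nan"), False, len(y))
    return GlmFit(
        family=family,
        link=link,
        coefficients=np.asarray(res.params, dtype=float),
        standard_errors=np.asarray(res.bse, dtype=float),
        dispersion=float(res.scale),
        converged=converged,
        n=len(y),
    )


def interaction_persistence_model(table: pd.DataFrame) -> GlmFit:
    """Poisson log-link GLM of mean lifespan on species type, z, and type x z.

    ``table`` is either long format (columns ``z``, ``type`` in
    {specialist, generalist}, ``mean_lifespan``) or a per-simulation
    metrics table with ``mean_lifespan_specialist`` / ``_generalist``
    columns, which is melted internally.  The last coefficient is the
    interaction term: a significantly non-zero value means invader
    strangeness moves specialist and generalist persistence differently.
    """
    if "type" not in table.columns:
        parts = []
        for kind in ("specialist", "generalist"):
            col = f"mean_lifespan_{kind}"
            part = table[["z", col]].rename(columns={col: "mean_lifespan"})
            part["type"] = kind
            parts.append(part)
        table = pd.concat(parts, ignore_index=True)
    table = table.dropna(subset=["mean_lifespan"])
    for kind in ("specialist", "generalist"):
        if table.loc[table["type"] == kind, "z"].nunique() < 3:
            raise ValueError(f"need both bins present for >= 3 z values ({kind} short)")
    is_gen = (table["type"] == "generalist").to_numpy(dtype=float)
    z = table["z"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(z), is_gen, z, is_gen * z])
    return glm_fit(table["mean_lifespan"].to_numpy(), X, family="poisson", link="log")


def spearman_trend(x, y, alternative: str = "greater") -> tuple[float, float]:
    """Spearman rank correlation with a one-sided p-value.

    The positive-trend certificate used across the z-sweep: rho > 0 with
    small p supports a monotone increase of y in x without assuming any
    functional form.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 5:
        raise ValueError("spearman_trend needs at least 5 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y, alternative=alternative)
    return float(rho), float(p)
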