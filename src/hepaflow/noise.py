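"""Technical-noise regression and the two-criterion transcript filter.

Across cells, the squared coefficient of variation of a transcript with
mean FPKM mu is modelled as

    CV^2 = a1 / mu + a0

so the technical-noise variance at mean mu is sigma0^2 = a0*mu^2 + a1*mu.
The constants are estimated by a gamma-family generalized linear regression
of CV^2 on 1/mu (identity link) over transcripts with mu above a floor
mu_th, chosen so that at most 5% of transcripts above it have CV^2 > 0.3.
A transcript is retained iff

  1. the normal-approximation 95% interval mu +/- z*sqrt(sigma0^2)
     excludes zero (expression surpasses noise), and
  2. its observed variance sigma^2 exceeds sigma0^2 (it varies more than
     technical noise alone explains).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .matrix import ExpressionMatrix


def estimate_moments(matrix: ExpressionMatrix, include_spikeins: bool = False) -> pd.DataFrame:
    """Per-gene mean, unbiased variance and CV^2 = sigma^2/mu^2 across cells.

    CV^2 is NaN for genes with mu = 0.  Spike-in rows are excluded unless
    ``include_spikeins``.
    """
    if matrix.n_cells < 2:
        raise ValueError("variance needs at least 2 cells")
    sub = matrix if include_spikeins else matrix.biological()
    vals = sub.values.to_numpy()
    mu = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mu > 0, var / mu**2, np.nan)
    return pd.DataFrame({"mu": mu, "var": var, "cv2": cv2}, index=sub.genes)


def select_mu_threshold(
    moments: pd.DataFrame, cv2_cut: float = 0.3, max_frac: float = 0.05
) -> float:
    """Smallest mean floor above which high-CV^2 transcripts are rare.

    Returns the smallest candidate mu_th (0 or an observed mu) such that a
    non-empty set of genes has mu > mu_th and at most ``max_frac`` of them
    have CV^2 > ``cv2_cut``.
    """
    ok = moments.dropna(subset=["cv2"])
    if ok.empty:
        raise ValueError("no gene with positive mean")
    mu = ok["mu"].to_numpy()
    cv2 = ok["cv2"].to_numpy()
    candidates = np.concatenate([[0.0], np.unique(mu)])
    for th in candidates:
        above = mu > th
        if not above.any():
            break
        frac = (cv2[above] > cv2_cut).mean()
        if frac <= max_frac:
            return float(th)
    raise ValueError(
        "no mean threshold satisfies the CV^2 fraction condition; "
        "provide more genes or relax max_frac"
    )


@dataclass
class NoiseModelResults:
    """Fitted noise constants with the threshold and CI multiplier used."""

    a0: float
    a1: float
    mu_th: float
    z: float = 1.96
    method: str = "glm-gamma-identity"
    n_genes_fit: int = 0

    def noise_variance(self, mu) -> np.ndarray | float:
        """sigma0^2 = a0*mu^2 + a1*mu, exactly."""
        mu_arr = np.asarray(mu, dtype=float)
        if np.any(mu_arr < 0):
            raise ValueError("mean must be non-negative")
        out = self.a0 * mu_arr**2 + self.a1 * mu_arr
        return float(out) if np.isscalar(mu) else out

    def summary(self) -> str:
        lines = [
            "Technical noise model  CV^2 = a1/mu + a0",
            "-" * 42,
            f"a0 (intercept)      {self.a0:12.6g}",
            f"a1 (slope, FPKM)    {self.a1:12.6g}",
            f"mu_th (fit floor)   {self.mu_th:12.6g}",
            f"z (CI multiplier)   {self.z:12.4g}",
            f"genes in fit        {self.n_genes_fit:12d}",
            f"method              {self.method:>12s}",
        ]
        return "\n".join(lines)


# Backwards-friendly alias used throughout the package.
NoiseModel = NoiseModelResults


class TechnicalNoiseModel:
    """Model object for the CV^2-vs-mean technical noise regression.

    Built from per-gene moments (or directly from an expression matrix via
    :meth:`from_matrix`); :meth:`fit` returns :class:`NoiseModelResults`.
    """

    def __init__(self, moments: pd.DataFrame, mu_th: float | None = None,
                 cv2_cut: float = 0.3, max_frac: float = 0.05, z: float = 1.96):
        self.moments = moments
        self.cv2_cut = cv2_cut
        self.max_frac = max_frac
        self.z = z
        self.mu_th = (
            select_mu_threshold(moments, cv2_cut, max_frac) if mu_th is None else mu_th
        )

    @classmethod
    def from_matrix(cls, matrix: ExpressionMatrix, **kwargs) -> "TechnicalNoiseModel":
        return cls(estimate_moments(matrix), **kwargs)

    def fit(self, trim_factor: float = 3.0) -> NoiseModelResults:
        """Fit the regression; one trimmed re-fit captures the noise floor.

        The observed CV^2 mixes technical noise with biological
        variability, so strongly differential transcripts sit far above
        the technical baseline.  After a first pass, genes whose CV^2
        exceeds ``trim_factor`` times their fitted value are set aside and
        the model is re-fitted once; on clean technical-noise data nothing
        is trimmed and the fit is unchanged.
        """
        sub = self.moments.dropna(subset=["cv2"])
        sub = sub[sub["mu"] > self.mu_th]
        if len(sub) < 10:
            raise ValueError("need at least 10 genes above mu_th to fit the noise model")
        y_all = sub["cv2"].to_numpy()
        x_all = 1.0 / sub["mu"].to_numpy()

        def _solve(y, x):
            X = sm.add_constant(x)
            try:
                if np.any(y <= 0):
                    raise ValueError("gamma family requires strictly positive CV^2")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    glm = sm.GLM(
                        y, X, family=sm.families.Gamma(link=sm.families.links.Identity())
                    )
                    res = glm.fit()
                params = res.params
                if not np.all(np.isfinite(params)):
                    raise ValueError("non-finite GLM estimates")
                return params, "glm-gamma-identity"
            except Exception:
                try:
                    return sm.OLS(y, X).fit().params, "ols-fallback"
                except Exception as exc:  # pragma: no cover - degenerate design
                    raise RuntimeError(f"noise regression failed: {exc}") from exc

        params, method = _solve(y_all, x_all)
        fitted = params[0] + params[1] * x_all
        keep = y_all <= trim_factor * np.maximum(fitted, 1e-12)
        if (~keep).any() and keep.sum() >= 10:
            params, method = _solve(y_all[keep], x_all[keep])
            sub = sub[keep]
        a0, a1 = float(params[0]), float(params[1])
        if a0 < 0 or a1 < 0:
            warnings.warn("negative noise-constant estimate clipped at 0")
            a0, a1 = max(a0, 0.0), max(a1, 0.0)
        return NoiseModelResults(
            a0=a0, a1=a1, mu_th=self.mu_th, z=self.z, method=method, n_genes_fit=len(sub)
        )


def fit_noise_model(moments: pd.DataFrame, mu_th: float, z: float = 1.96) -> NoiseModelResults:
    """Functional wrapper over :class:`TechnicalNoiseModel`."""
    return TechnicalNoiseModel(moments, mu_th=mu_th, z=z).fit()


def noise_variance(model: NoiseModelResults, mu) -> np.ndarray | float:
    return model.noise_variance(mu)


def filter_genes(moments: pd.DataFrame, model: NoiseModelResults) -> pd.DataFrame:
    """Apply the two retention criteria to every gene.

    Returns a frame indexed like ``moments`` with ``sigma0_sq``, boolean
    ``crit1`` (mu - z*sqrt(sigma0^2) > 0), ``crit2`` (sigma^2 > sigma0^2),
    ``retained`` and ``failing_criterion`` (1, 2 or 0 = retained; when both
    fail, criterion 1 is reported).
    """
    mu = moments["mu"].to_numpy(dtype=float)
    var = moments["var"].to_numpy(dtype=float)
    s0 = model.noise_variance(mu)
    crit1 = mu - model.z * np.sqrt(s0) > 0
    crit2 = var > s0
    retained = crit1 & crit2
    failing = np.where(~crit1, 1, np.where(~crit2, 2, 0))
    return pd.DataFrame(
        {
            "mu": mu,
            "var": var,
            "cv2": moments["cv2"].to_numpy(),
            "sigma0_sq": s0,
            "crit1": crit1,
            "crit2": crit2,
            "retained": retained,
            "failing_criterion": failing,
        },
        index=moments.index,
    )


def filter_matrix(matrix: ExpressionMatrix, cv2_cut: float = 0.3,
                  max_frac: float = 0.05, z: float = 1.96) -> pd.DataFrame:
    """End-to-end convenience: moments -> mu_th -> fit -> per-gene filter."""
    model = TechnicalNoiseModel.from_matrix(matrix, cv2_cut=cv2_cut, max_frac=max_frac, z=z)
    results = model.fit()
    return filter_genes(model.moments, results)
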