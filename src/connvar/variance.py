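"""Longitudinal variance decomposition: ReML random-intercept models and ICC.

For each target (a vertex, or the global mean of a metric) the repeated
measurements follow a random-intercept linear mixed model

    y = X beta + Z b + eps,   b ~ N(0, sigma_b^2 I),  eps ~ N(0, sigma_w^2 I),

whose implied covariance is compound symmetric within subjects.  Variance
components are estimated by restricted maximum likelihood, profiling the
restricted log-likelihood over the variance ratio lambda = sigma_b^2 /
sigma_w^2 on a log grid followed by bounded scalar refinement — fully
deterministic, with the non-negativity constraint handled by comparing the
interior optimum against the lambda = 0 boundary.

The decomposition yields the between-subject variance sigma_b^2 (inter-
individual variability), the within-subject variance sigma_w^2 (intra-
individual variability), their normalized strengths, the intraclass
correlation ICC = sigma_b^2 / (sigma_b^2 + sigma_w^2), its qualitative band
(slight/fair/moderate/substantial/almost perfect), and the Wald z of the
adjusted intercept ("significance strength").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

ICC_BANDS = (
    ("slight", 0.0, 0.2),
    ("fair", 0.2, 0.4),
    ("moderate", 0.4, 0.6),
    ("substantial", 0.6, 0.8),
    ("almost_perfect", 0.8, 1.0),
)

#: metadata recorded with every fit; the reliability index is the standard
#: between-over-total ratio, so high between-subject variance means high ICC
ICC_ORIENTATION = "sigma_b^2 / (sigma_b^2 + sigma_w^2)"


@dataclass
class VarianceDecomposition:
    """Estimates for one target: fixed effects, variance components, ICC."""

    beta: np.ndarray
    beta_se: np.ndarray
    beta_names: Tuple[str, ...]
    sigma_b2: float
    sigma_w2: float
    icc: float
    band: str
    intra_strength: float          # sigma_w^2 / total
    inter_strength: float          # sigma_b^2 / total (equals the ICC)
    z_intercept: float
    boundary: bool                 # sigma_b^2 pinned at zero
    n_obs: int
    n_subjects: int
    meta: dict = field(default_factory=dict)


class _ProfileREML:
    """Restricted likelihood of the random-intercept model, profiled in
    lambda = sigma_b^2 / sigma_w^2.  Sufficient statistics are precomputed so
    each lambda evaluation costs O(G p^2)."""

    def __init__(self, y: np.ndarray, X: np.ndarray,
                 groups: np.ndarray) -> None:
        self.n, self.p = X.shape
        self.X, self.y = X, y
        uniq, inv = np.unique(groups, return_inverse=True)
        self.G = uniq.size
        self.sizes = np.bincount(inv).astype(float)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # per-group column sums of X and of y
        self.sX = np.zeros((self.G, self.p))
        np.add.at(self.sX, inv, X)
        self.sy = np.bincount(inv, weights=y)

    def _gls_pieces(self, lam: float):
        c = lam / (1.0 + lam * self.sizes)          # per-group shrinkage
        XtViX = self.XtX - (self.sX * c[:, None]).T @ self.sX
        XtViy = self.Xty - self.sX.T @ (c * self.sy)
        ytViy = self.yty - float(c @ self.sy ** 2)
        return XtViX, XtViy, ytViy

    def neg2_restricted_loglik(self, lam: float) -> float:
        XtViX, XtViy, ytViy = self._gls_pieces(lam)
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e300
        beta = np.linalg.solve(XtViX, XtViy)
        q = ytViy - float(beta @ XtViy)
        if q <= 0:
            return 1e300
        df = self.n - self.p
        logdet_v = float(np.log1p(lam * self.sizes).sum())
        return df * np.log(q / df) + logdet_v + logdet_x

    def solve(self, lam: float) -> Tuple[np.ndarray, np.ndarray, float]:
        XtViX, XtViy, ytViy = self._gls_pieces(lam)
        beta = np.linalg.solve(XtViX, XtViy)
        q = ytViy - float(beta @ XtViy)
        sigma_w2 = q / (self.n - self.p)
        cov = sigma_w2 * np.linalg.inv(XtViX)
        return beta, np.sqrt(np.diag(cov)), sigma_w2


def _classify_band(icc: float) -> str:
    if icc <= 0:
        return "slight"             # printed intervals are open at 0
    for name, lo, hi in ICC_BANDS:
        if lo < icc <= hi:
            return name
    return "almost_perfect"


def reml_random_intercept(y: np.ndarray, X: np.ndarray,
                          subject_ids: Sequence,
                          beta_names: Optional[Sequence[str]] = None
                          ) -> VarianceDecomposition:
    """Fit the random-intercept model by deterministic profile ReML.

    ``X`` must be full column rank and include the intercept as its first
    column (the Wald "significance strength" refers to it).  A boundary
    solution sigma_b^2 = 0 is flagged, not an error.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    X = np.asarray(X, dtype=np.float64)
    groups = np.asarray(subject_ids)
    if X.ndim != 2 or X.shape[0] != y.size or groups.size != y.size:
        raise ValueError("y, X and subject_ids must agree on length")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in y or X")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("too few observations for the design")
    if np.unique(groups).size < 2:
        raise ValueError("need at least two subjects")

    prof = _ProfileREML(y, X, groups)

    # profile over log(lambda): coarse grid, then bounded refinement
    grid = np.concatenate([[0.0], np.logspace(-8, 4, 49)])
    crit = np.array([prof.neg2_restricted_loglik(l) for l in grid])
    k = int(np.argmin(crit))
    if k == 0:
        lam_hat = 0.0
    else:
        lo = np.log(grid[max(k - 1, 1)])
        hi = np.log(grid[min(k + 1, grid.size - 1)])
        if lo == hi:
            lam_hat = grid[k]
        else:
            res = minimize_scalar(
                lambda t: prof.neg2_restricted_loglik(np.exp(t)),
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-12})
            lam_hat = float(np.exp(res.x))
            if prof.neg2_restricted_loglik(0.0) < prof.neg2_restricted_loglik(lam_hat):
                lam_hat = 0.0

    beta, se, sigma_w2 = prof.solve(lam_hat)
    sigma_b2 = lam_hat * sigma_w2
    boundary = lam_hat < 1e-8
    if boundary:
        sigma_b2 = 0.0

    total = sigma_b2 + sigma_w2
    icc = sigma_b2 / total if total > 0 else float("nan")
    names = tuple(beta_names) if beta_names is not None else tuple(
        f"beta{i}" for i in range(p))
    z = float(beta[0] / se[0]) if se[0] > 0 else float("nan")
    return VarianceDecomposition(
        beta=beta, beta_se=se, beta_names=names,
        sigma_b2=float(sigma_b2), sigma_w2=float(sigma_w2),
        icc=float(icc), band=_classify_band(icc),
        intra_strength=float(sigma_w2 / total) if total > 0 else float("nan"),
        inter_strength=float(sigma_b2 / total) if total > 0 else float("nan"),
        z_intercept=z, boundary=boundary,
        n_obs=n, n_subjects=int(np.unique(groups).size),
        meta={"icc_orientation": ICC_ORIENTATION, "lambda": lam_hat})


def balanced_anova_components(y: np.ndarray, subject_ids: Sequence
                              ) -> Tuple[float, float]:
    """Closed-form one-way variance components for a balanced design.

    sigma_w^2 = MSW and sigma_b^2 = max(0, (MSB - MSW) / k) with k sessions
    per subject; equals the ReML solution for the intercept-only balanced
    model (when interior).  Used as an independent oracle in tests.
    """
    y = np.asarray(y, dtype=np.float64)
    df = pd.DataFrame({"y": y, "g": np.asarray(subject_ids)})
    sizes = df.groupby("g")["y"].count()
    if sizes.nunique() != 1:
        raise ValueError("design is not balanced")
    k = int(sizes.iloc[0])
    G = sizes.size
    means = df.groupby("g")["y"].mean()
    grand = y.mean()
    msb = k * ((means - grand) ** 2).sum() / (G - 1)
    msw = float(((df["y"] - df["g"].map(means)) ** 2).sum() / (G * (k - 1)))
    return max(0.0, (msb - msw) / k), msw


# ---------------------------------------------------------------------------
# model assembly over a longitudinal table
# ---------------------------------------------------------------------------

GLOBAL_COVARIATES = ("age", "sex", "meanFD")
VERTEX_COVARIATES = ("gM", "age", "sex", "meanFD", "mcBBR", "jacobian")
_CENTERED = {"age", "meanFD", "mcBBR", "gM", "jacobian"}


def _design_from_frame(df: pd.DataFrame, covariates: Sequence[str]
                       ) -> Tuple[np.ndarray, Tuple[str, ...]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for c in covariates:
        x = df[c].to_numpy(dtype=np.float64)
        if c in _CENTERED:
            x = x - x.mean()
        cols.append(x)
        names.append(c)
    return np.column_stack(cols), tuple(names)


def fit_metric_models(table: pd.DataFrame, level: str,
                      include_gm: bool = True
                      ) -> Dict[object, VarianceDecomposition]:
    """One ReML fit per target in a long-format metric table.

    ``level`` is "global" (covariates: age, sex, meanFD) or "vertex"
    (additionally the metric's global mean gM — post-hoc standardization —
    plus mcBBR and the per-vertex surface Jacobian).  Continuous covariates
    are mean-centered; sex is 0/1.  ``include_gm=False`` drops the gM
    covariate for metrics whose global mean is not meaningful (dual
    regression: the stage-2 map mean is fixed by the regression algebra).
    """
    if level not in ("global", "vertex"):
        raise ValueError("level must be 'global' or 'vertex'")
    covs = GLOBAL_COVARIATES if level == "global" else VERTEX_COVARIATES
    if level == "vertex" and not include_gm:
        covs = tuple(c for c in covs if c != "gM")
    required = {"subject", "session", "target", "value", *covs}
    missing = sorted(required - set(table.columns))
    if missing:
        raise ValueError(f"longitudinal table is missing columns: {missing}")

    out: Dict[object, VarianceDecomposition] = {}
    for target, sub in table.groupby("target", sort=True):
        X, names = _design_from_frame(sub, covs)
        out[target] = reml_random_intercept(
            sub["value"].to_numpy(), X, sub["subject"].to_numpy(),
            beta_names=names)
    return out


def icc_and_bands(d: VarianceDecomposition
                  ) -> Tuple[float, str, float, float]:
    """(ICC, band, intra_strength, inter_strength) for one decomposition."""
    total = d.sigma_b2 + d.sigma_w2
    if total <= 0:
        raise ValueError("both variance components are zero; ICC undefined")
    icc = d.sigma_b2 / total
    return icc, _classify_band(icc), d.sigma_w2 / total, d.sigma_b2 / total


def significance_strength(d: VarianceDecomposition) -> float:
    """Wald z of the adjusted intercept, reported unthresholded."""
    if not np.isfinite(d.z_intercept):
        raise ValueError("intercept standard error is zero; strength undefined")
    return d.z_intercept


def summarize_by_labels(values: np.ndarray, labels: np.ndarray,
                        threshold: float = 0.4) -> pd.DataFrame:
    """Per-label mean and percentage of values at or above ``threshold``.

    NaN entries (masked targets) are excluded from both statistics; a label
    left empty after masking is reported with n = 0.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    if values.size != labels.size:
        raise ValueError("values and labels must have the same length")
    rows = []
    for lab in np.unique(labels):
        v = values[labels == lab]
        v = v[np.isfinite(v)]
        if v.size == 0:
            rows.append(dict(label=lab, mean=np.nan, percent_high=np.nan, n=0))
        else:
            rows.append(dict(label=lab, mean=float(v.mean()),
                             percent_high=100.0 * float((v >= threshold).mean()),
                             n=int(v.size)))
    return pd.DataFrame(rows)
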