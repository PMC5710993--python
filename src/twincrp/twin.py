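"""Twin models for genetic influence on log-CRP.

Three tools: double-entry within-pair correlations by zygosity, a univariate
maximum-likelihood ACE variance decomposition fitted to complete twin pairs,
and the four-level co-twin latent genetic risk score.

The ACE model treats each twin pair as a draw from a bivariate normal with a
common mean and total variance sigma2_A + sigma2_C + sigma2_E, and within-pair
covariance sigma2_A + sigma2_C for monozygotic (MZ) pairs and
sigma2_A/2 + sigma2_C for dizygotic (DZ) pairs.  Variance components are
bounded below at zero; estimates are reported as fractions of the total
variance, with a profile-likelihood confidence interval (default) or a
family-level bootstrap for the additive-genetic fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "within_pair_correlations",
    "falconer",
    "falconer_clipped",
    "TwinACEModel",
    "ACEResults",
    "latent_genetic_score",
    "add_latent_genetic_score",
    "score_validation",
    "SCORE_LABELS",
]

SCORE_LABELS = ("lowest", "low", "high", "highest")

_CHI2_95_DF1 = float(stats.chi2.ppf(0.95, df=1))


def _pair_matrix(table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Pivot a cohort table into one row per complete pair.

    Returns a frame with columns ``x1``, ``x2``, ``zygosity``; pairs missing
    either twin's value are dropped.
    """
    wide = table.pivot_table(
        index="family_id", columns="twin_index", values=value_col, aggfunc="first"
    )
    if not {1, 2}.issubset(wide.columns):
        raise ValueError("cohort table must contain twin_index values 1 and 2")
    zyg = table.groupby("family_id")["zygosity"].first()
    pairs = pd.DataFrame({"x1": wide[1], "x2": wide[2], "zygosity": zyg}).dropna()
    return pairs


def _double_entry_corr(x1: np.ndarray, x2: np.ndarray) -> float:
    """Intraclass-style correlation entering each pair in both orders."""
    a = np.concatenate([x1, x2])
    b = np.concatenate([x2, x1])
    return float(np.corrcoef(a, b)[0, 1])


def within_pair_correlations(
    table: pd.DataFrame, value_col: str = "log_crp", min_pairs: int = 3
) -> tuple[float, float]:
    """Double-entry within-pair correlations ``(r_mz, r_dz)`` of ``value_col``.

    The double-entry estimator (each pair contributes both orderings) is
    invariant to the labelling of twin 1 vs twin 2.
    """
    pairs = _pair_matrix(table, value_col)
    out = []
    for zyg in ("MZ", "DZ"):
        grp = pairs[pairs["zygosity"] == zyg]
        if len(grp) < min_pairs:
            raise ValueError(
                f"need at least {min_pairs} complete {zyg} pairs; got {len(grp)}"
            )
        out.append(_double_entry_corr(grp["x1"].to_numpy(), grp["x2"].to_numpy()))
    return out[0], out[1]


def falconer(r_mz: float, r_dz: float) -> tuple[float, float, float]:
    """Closed-form ACE fractions from twin correlations (unclipped).

    a = 2(r_mz - r_dz), c = 2 r_dz - r_mz, e = 1 - r_mz.  Values may fall
    outside [0, 1] when the correlations are incompatible with the model;
    use :func:`falconer_clipped` for a reporting-safe variant.
    """
    if not (-1 <= r_mz <= 1 and -1 <= r_dz <= 1):
        raise ValueError("correlations must lie in [-1, 1]")
    a = 2.0 * (r_mz - r_dz)
    c = 2.0 * r_dz - r_mz
    e = 1.0 - r_mz
    return a, c, e


def falconer_clipped(r_mz: float, r_dz: float) -> tuple[float, float, float]:
    """Falconer fractions clipped to [0, 1] and renormalized to sum to 1."""
    vals = np.clip(falconer(r_mz, r_dz), 0.0, None)
    total = vals.sum()
    if total == 0:
        return 0.0, 0.0, 1.0
    vals = vals / total
    return float(vals[0]), float(vals[1]), float(vals[2])


@dataclass
class ACEResults:
    """Fitted ACE variance decomposition.

    Variance fractions ``a_frac + c_frac + e_frac = 1``; ``ci_a`` is a 95%
    interval for the additive-genetic fraction (heritability).
    """

    a_frac: float
    c_frac: float
    e_frac: float
    mean: float
    total_var: float
    minus2ll: float
    converged: bool
    n_mz_pairs: int
    n_dz_pairs: int
    ci_a: tuple[float, float]
    ci_method: str
    model: "TwinACEModel" = field(repr=False, default=None)

    @property
    def variances(self) -> tuple[float, float, float]:
        return (
            self.a_frac * self.total_var,
            self.c_frac * self.total_var,
            self.e_frac * self.total_var,
        )

    def to_dict(self) -> dict:
        return {
            "a_frac": self.a_frac,
            "c_frac": self.c_frac,
            "e_frac": self.e_frac,
            "mean": self.mean,
            "total_var": self.total_var,
            "minus2ll": self.minus2ll,
            "converged": self.converged,
            "n_mz_pairs": self.n_mz_pairs,
            "n_dz_pairs": self.n_dz_pairs,
            "ci_a": list(self.ci_a),
            "ci_method": self.ci_method,
        }

    def summary(self) -> str:
        lines = [
            "Univariate ACE twin model (maximum likelihood)",
            f"  pairs: {self.n_mz_pairs} MZ, {self.n_dz_pairs} DZ",
            f"  mean = {self.mean:.4f}, total variance = {self.total_var:.4f}",
            f"  A = {self.a_frac:.3f}  (95% CI {self.ci_a[0]:.3f}-{self.ci_a[1]:.3f},"
            f" {self.ci_method})",
            f"  C = {self.c_frac:.3f}",
            f"  E = {self.e_frac:.3f}",
            f"  -2 log L = {self.minus2ll:.2f}  converged = {self.converged}",
        ]
        return "\n".join(lines)


class TwinACEModel:
    """Maximum-likelihood univariate ACE model for paired twin outcomes.

    Parameters
    ----------
    mz, dz : ndarray of shape (n_pairs, 2)
        Outcome values for complete MZ and DZ pairs.
    """

    def __init__(self, mz: np.ndarray, dz: np.ndarray):
        mz = np.asarray(mz, dtype=float)
        dz = np.asarray(dz, dtype=float)
        for name, arr in (("mz", mz), ("dz", dz)):
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"{name} must be an (n_pairs, 2) array")
            if len(arr) < 3:
                raise ValueError(f"need at least 3 complete {name.upper()} pairs")
            if np.isnan(arr).any():
                raise ValueError(f"{name} pairs contain missing values")
        self.mz = mz
        self.dz = dz

    @classmethod
    def from_cohort(cls, table: pd.DataFrame, outcome: str = "log_crp") -> "TwinACEModel":
        """Build the model from a cohort table with complete-pair filtering."""
        pairs = _pair_matrix(table, outcome)
        mz = pairs.loc[pairs["zygosity"] == "MZ", ["x1", "x2"]].to_numpy()
        dz = pairs.loc[pairs["zygosity"] == "DZ", ["x1", "x2"]].to_numpy()
        return cls(mz, dz)

    # -- likelihood ----------------------------------------------------------

    @staticmethod
    def _group_nll(arr: np.ndarray, mu: float, v: float, c: float) -> float:
        """Negative log-likelihood of one zygosity group under a bivariate
        normal with common mean mu, variance v, covariance c."""
        det = v * v - c * c
        if det <= 0 or v <= 0:
            # large finite penalty keeps finite-difference gradients defined
            return 1e12
        d1 = arr[:, 0] - mu
        d2 = arr[:, 1] - mu
        quad = (v * (d1 * d1 + d2 * d2) - 2.0 * c * d1 * d2) / det
        n = len(arr)
        return 0.5 * (n * (2.0 * np.log(2.0 * np.pi) + np.log(det)) + quad.sum())

    def _nll(self, params: np.ndarray) -> float:
        mu, va, vc, ve = params
        v = va + vc + ve
        nll = self._group_nll(self.mz, mu, v, va + vc)
        nll += self._group_nll(self.dz, mu, v, 0.5 * va + vc)
        return nll

    def _start(self) -> np.ndarray:
        allvals = np.concatenate([self.mz.ravel(), self.dz.ravel()])
        mu0 = float(allvals.mean())
        vtot = float(allvals.var())
        r_mz = _double_entry_corr(self.mz[:, 0], self.mz[:, 1])
        r_dz = _double_entry_corr(self.dz[:, 0], self.dz[:, 1])
        a, c, e = falconer_clipped(r_mz, r_dz)
        # keep the start strictly interior
        fracs = np.clip([a, c, e], 0.02, None)
        fracs = fracs / fracs.sum()
        return np.array([mu0, *(fracs * vtot)])

    def fit(
        self,
        ci_method: str = "profile",
        n_boot: int = 200,
        seed: Optional[int] = None,
    ) -> ACEResults:
        """Fit by bounded quasi-Newton maximization of the pair likelihood.

        ``ci_method`` is ``"profile"`` (default; profile likelihood on the
        additive-genetic fraction) or ``"bootstrap"`` (family-level resampling
        with ``n_boot`` replicates).
        """
        x0 = self._start()
        bounds = [(None, None), (0.0, None), (0.0, None), (1e-10, None)]
        res = optimize.minimize(
            self._nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
        )
        mu, va, vc, ve = res.x
        total = va + vc + ve
        fracs = np.array([va, vc, ve]) / total
        minus2ll = 2.0 * res.fun

        if ci_method == "profile":
            ci = self._profile_ci_a(res.x, res.fun)
        elif ci_method == "bootstrap":
            ci = self._bootstrap_ci_a(n_boot=n_boot, seed=seed)
        else:
            raise ValueError("ci_method must be 'profile' or 'bootstrap'")

        return ACEResults(
            a_frac=float(fracs[0]),
            c_frac=float(fracs[1]),
            e_frac=float(fracs[2]),
            mean=float(mu),
            total_var=float(total),
            minus2ll=float(minus2ll),
            converged=bool(res.success),
            n_mz_pairs=len(self.mz),
            n_dz_pairs=len(self.dz),
            ci_a=ci,
            ci_method=ci_method,
            model=self,
        )

    # -- confidence intervals --------------------------------------------

    def _profile_nll_a(self, f_a: float, x_hat: np.ndarray) -> float:
        """Minimized NLL with the A fraction constrained to ``f_a``."""

        def nll(theta):
            mu, log_total, g = theta
            total = np.exp(log_total)
            va = f_a * total
            vc = g * (1.0 - f_a) * total
            ve = total - va - vc
            return self._nll(np.array([mu, va, vc, max(ve, 0.0)]))

        mu_hat, va_h, vc_h, ve_h = x_hat
        total_h = va_h + vc_h + ve_h
        g0 = vc_h / ((1.0 - f_a) * total_h) if f_a < 1 else 0.0
        g0 = float(np.clip(g0, 1e-6, 1 - 1e-6))
        res = optimize.minimize(
            nll,
            np.array([mu_hat, np.log(total_h), g0]),
            method="L-BFGS-B",
            bounds=[(None, None), (None, None), (0.0, 1.0 - 1e-9)],
            options={"maxiter": 300, "ftol": 1e-12},
        )
        return float(res.fun)

    def _profile_ci_a(self, x_hat: np.ndarray, nll_hat: float) -> tuple[float, float]:
        va, vc, ve = x_hat[1:]
        a_hat = va / (va + vc + ve)
        cutoff = nll_hat + 0.5 * _CHI2_95_DF1

        def deviance(f):
            return self._profile_nll_a(f, x_hat) - cutoff

        eps = 1e-6
        lo = 0.0
        if a_hat > eps and deviance(eps) > 0:
            lo = float(optimize.brentq(deviance, eps, a_hat, xtol=1e-5))
        hi = 1.0
        if a_hat < 1 - eps and deviance(1 - eps) > 0:
            hi = float(optimize.brentq(deviance, a_hat, 1 - eps, xtol=1e-5))
        return lo, hi

    def _bootstrap_ci_a(self, n_boot: int, seed: Optional[int]) -> tuple[float, float]:
        rng = np.random.default_rng(seed)
        a_vals = np.empty(n_boot)
        for b in range(n_boot):
            mz_b = self.mz[rng.integers(0, len(self.mz), len(self.mz))]
            dz_b = self.dz[rng.integers(0, len(self.dz), len(self.dz))]
            fit = TwinACEModel(mz_b, dz_b).fit(ci_method="profile")
            a_vals[b] = fit.a_frac
        lo, hi = np.percentile(a_vals, [2.5, 97.5])
        return float(lo), float(hi)


# -- latent genetic risk score ------------------------------------------------

_SCORE_MAP = {
    ("MZ", False): 0,  # lowest risk: MZ co-twin without high CRP
    ("DZ", False): 1,  # low risk
    ("DZ", True): 2,   # high risk
    ("MZ", True): 3,   # highest risk: MZ co-twin with high CRP
}


def latent_genetic_score(zygosity: str, cotwin_high: bool) -> int:
    """Ordinal genetic-liability code from zygosity and the co-twin's
    high-CRP status: (MZ, no) -> 0, (DZ, no) -> 1, (DZ, yes) -> 2,
    (MZ, yes) -> 3."""
    key = (str(zygosity), bool(cotwin_high))
    if key[0] not in ("MZ", "DZ"):
        raise ValueError(f"zygosity must be 'MZ' or 'DZ'; got {zygosity!r}")
    return _SCORE_MAP[key]


def add_latent_genetic_score(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Attach each twin's latent genetic score from the co-twin's flag.

    Requires the ``high_crp`` column.  Records whose co-twin is absent from
    the table (incomplete pairs, e.g. after exclusions) are dropped; the
    second return value is the number of dropped records.
    """
    if "high_crp" not in table.columns:
        raise ValueError("high_crp column required; run derive_analysis_variables first")
    out = table.copy()
    cotwin_index = 3 - out["twin_index"]
    key = pd.MultiIndex.from_arrays([out["family_id"], out["twin_index"]])
    flag = pd.Series(out["high_crp"].to_numpy(), index=key)
    cotwin_key = pd.MultiIndex.from_arrays([out["family_id"], cotwin_index])
    cotwin_flag = flag.reindex(cotwin_key).to_numpy()
    present = ~pd.isna(cotwin_flag)
    n_dropped = int((~present).sum())
    out = out.loc[present].copy()
    zyg_is_mz = (out["zygosity"] == "MZ").to_numpy()
    high = cotwin_flag[present].astype(bool)
    score = np.where(zyg_is_mz, np.where(high, 3, 0), np.where(high, 2, 1))
    out["genetic_score"] = score
    return out, n_dropped


def score_validation(table: pd.DataFrame, outcome: str = "log_crp") -> dict:
    """Regress standardized log-CRP on the 0-3 genetic score.

    Reports both conventions for the score's effect size: the fully
    standardized coefficient (the Pearson correlation) and the slope of
    standardized log-CRP per score point, together with R^2.
    """
    if "genetic_score" not in table.columns:
        raise ValueError("genetic_score column required; run add_latent_genetic_score")
    y = table[outcome].to_numpy(dtype=float)
    s = table["genetic_score"].to_numpy(dtype=float)
    y_std = (y - y.mean()) / y.std()
    r = float(np.corrcoef(y_std, s)[0, 1])
    slope = float(np.cov(y_std, s, ddof=0)[0, 1] / s.var())
    return {
        "n": len(table),
        "beta_standardized": r,
        "slope_per_level": slope,
        "r_squared": r * r,
    }
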