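"""Protein phenotype construction from repeated measurements.

Milk protein concentration is measured up to three times per animal over a
lactation (peak, mid, late). This module assesses skewness, builds per-period
natural-log phenotypes, and fits the repeated-measures mixed model

    y = X b + Z a + Z p + e,   a ~ (0, A sa2),  p ~ (0, I spe2),  e ~ (0, I se2)

by REML, where ``A`` is an animal relationship matrix (pedigree or genomic).
The aggregate phenotype for animal *i* is the additive-animal BLUP plus the
mean of that animal's residuals — a single analysis-ready value per animal,
centred near zero across the population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

PERIODS = ("peak", "mid", "late")


class SkewnessUndefinedError(ValueError):
    pass


class AggregateLogError(ValueError):
    """Raised when asked to log-transform the aggregate phenotype.

    The aggregate is centred on zero and contains a large proportion of
    negative values, so a log transform is meaningless for it.
    """


def sample_skewness(values) -> float:
    """Third-moment sample skewness: sum((x - mean)^3) / (n * s^3).

    ``s`` is the sample standard deviation with the n-1 denominator. Requires
    at least three observations and non-constant data.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"need at least 3 values, got {x.size}")
    s = x.std(ddof=1)
    if s == 0:
        raise SkewnessUndefinedError("skewness undefined for a constant vector")
    return float(np.sum((x - x.mean()) ** 3) / (x.size * s**3))


def effect_to_fold(beta_log: float, n_alleles: int = 1) -> float:
    """Convert a natural-log-scale allele effect to a fold change.

    ``exp(beta * n_alleles)`` rounded to three significant figures — e.g. a
    per-allele effect of 0.56 log-units is a 1.75x fold change per allele.
    """
    if n_alleles not in (1, 2):
        raise ValueError("n_alleles must be 1 (per allele) or 2 (between homozygotes)")
    if not np.isfinite(beta_log):
        raise ValueError("beta must be finite")
    fold = float(np.exp(beta_log * n_alleles))
    if fold == 0:
        return 0.0
    from math import floor, log10
    return round(fold, 2 - int(floor(log10(abs(fold)))))


def validate_table(tbl: pd.DataFrame) -> pd.DataFrame:
    """Check a repeated-measures table: one record per animal x period."""
    required = {"animal_id", "period", "value"}
    missing = required - set(tbl.columns)
    if missing:
        raise ValueError(f"repeated-measures table missing columns: {sorted(missing)}")
    dup = tbl.duplicated(subset=["animal_id", "period"])
    if dup.any():
        bad = tbl.loc[dup, ["animal_id", "period"]].iloc[0]
        raise ValueError(f"duplicate record for animal {bad['animal_id']} "
                         f"period {bad['period']}")
    return tbl


def prepare_log_phenotypes(tbl: pd.DataFrame,
                           periods: list[str] | None = None) -> dict[str, pd.Series]:
    """Natural-log per-period phenotype vectors, indexed by animal id.

    Refuses to transform the aggregate phenotype; raises a domain error
    naming the offending animal on non-positive values.
    """
    validate_table(tbl)
    if periods is None:
        periods = [p for p in tbl["period"].unique()]
    out: dict[str, pd.Series] = {}
    for period in periods:
        if str(period).lower() in ("agg", "aggregate"):
            raise AggregateLogError(
                "refusing to log-transform the aggregate phenotype: it is "
                "centred on zero and contains negative values")
        sub = tbl[tbl["period"] == period]
        bad = sub[sub["value"] <= 0]
        if len(bad):
            raise ValueError(
                f"non-positive concentration for animal {bad.iloc[0]['animal_id']} "
                f"in period {period}: {bad.iloc[0]['value']}")
        out[period] = pd.Series(np.log(sub["value"].to_numpy()),
                                index=sub["animal_id"].to_numpy(), name=f"log_{period}")
    return out


# ---------------------------------------------------------------------------
# Repeated-measures REML
# ---------------------------------------------------------------------------

@dataclass
class RepeatedMeasuresResults:
    """REML fit of the three-component repeated-measures model.

    ``aggregate`` holds the per-animal analysis-ready phenotype: additive
    animal BLUP plus the mean residual (optionally plus the permanent-
    environment BLUP when the model was fitted with ``include_pe_in_aggregate``).
    """

    sigma2_additive: float
    sigma2_pe: float
    sigma2_residual: float
    h2: float
    se_h2: float
    lrt: float
    lrt_p: float
    loglik: float
    fixed_effects: pd.Series
    animal_blup: pd.Series
    pe_blup: pd.Series
    residuals: pd.Series  # per record
    aggregate: pd.DataFrame  # animal_id, value, n_records
    converged: bool
    loglik_trace: list
    n_records: int
    n_animals: int

    @property
    def sigma2_total(self) -> float:
        return self.sigma2_additive + self.sigma2_pe + self.sigma2_residual

    def summary(self) -> str:
        lines = [
            "Repeated-measures REML (animal + permanent environment + residual)",
            f"  records / animals : {self.n_records} / {self.n_animals}",
            f"  sigma2_additive   : {self.sigma2_additive:.6g}",
            f"  sigma2_pe         : {self.sigma2_pe:.6g}",
            f"  sigma2_residual   : {self.sigma2_residual:.6g}",
            f"  h2                : {self.h2:.4f} (SE {self.se_h2:.4f})",
            f"  LRT (h2=0)        : {self.lrt:.4g}  p = {self.lrt_p:.3g}",
            f"  REML loglik       : {self.loglik:.6g}",
            f"  converged         : {self.converged}",
            "  fixed effects:",
        ]
        for name, val in self.fixed_effects.items():
            lines.append(f"    {name:<22s} {val: .6g}")
        return "\n".join(lines)


class RepeatedMeasuresModel:
    """REML for repeated measurements with a relationship-structured animal
    effect and an i.i.d. permanent-environment effect.

    Parameters
    ----------
    table:
        Records with columns ``animal_id``, ``period``, ``value`` plus any
        fixed-effect covariate columns named in ``fixed_effects``.
    relationship:
        Animal x animal symmetric PSD matrix (pedigree A or a GRM) indexed
        like ``animal_ids`` (a DataFrame, or an array plus ``animal_ids``).
    fixed_effects:
        Names of covariate columns fitted as fixed effects in addition to
        the collection-period factor (always included).
    include_pe:
        Drop the permanent-environment component when False (needed e.g.
        when A = I makes it unidentifiable).
    include_pe_in_aggregate:
        Whether the PE BLUP is added into the aggregate phenotype. Default
        False: the aggregate is additive BLUP + mean residual only.
    """

    def __init__(self, table: pd.DataFrame, relationship,
                 animal_ids: list[str] | None = None,
                 fixed_effects: list[str] | None = None,
                 include_pe: bool = True,
                 include_pe_in_aggregate: bool = False) -> None:
        table = validate_table(table).reset_index(drop=True)
        if isinstance(relationship, pd.DataFrame):
            animal_ids = list(relationship.index.astype(str))
            A = relationship.to_numpy(dtype=float)
        else:
            A = np.asarray(relationship, dtype=float)
            if animal_ids is None:
                raise ValueError("animal_ids required when relationship is an array")
            animal_ids = [str(a) for a in animal_ids]
        if A.shape != (len(animal_ids),) * 2 or not np.allclose(A, A.T, atol=1e-8):
            raise ValueError("relationship must be square and symmetric")
        if np.min(np.linalg.eigvalsh(A)) < -1e-6:
            raise np.linalg.LinAlgError("relationship matrix is not positive semi-definite")
        tbl_animals = set(table["animal_id"].astype(str))
        missing = tbl_animals - set(animal_ids)
        if missing:
            raise ValueError(f"animals absent from relationship: {sorted(missing)[:5]}")
        # keep only animals with records, in relationship order
        used = [a for a in animal_ids if a in tbl_animals]
        aidx = {a: k for k, a in enumerate(used)}
        sel = [animal_ids.index(a) for a in used]
        self.A = A[np.ix_(sel, sel)]
        self.animal_ids = used
        self.table = table
        self.y = table["value"].to_numpy(dtype=float)
        self.rec_animal = np.array([aidx[str(a)] for a in table["animal_id"]])
        self.fixed_effect_names = list(fixed_effects or [])
        self.include_pe = include_pe
        self.include_pe_in_aggregate = include_pe_in_aggregate
        self.X, self.x_names = self._design(table)
        self._check_rank()
        n, q = self.y.size, len(used)
        self.Z = np.zeros((n, q))
        self.Z[np.arange(n), self.rec_animal] = 1.0
        self.counts = self.Z.sum(axis=0)

    def _design(self, table: pd.DataFrame):
        cols = [np.ones(len(table))]
        names = ["intercept"]
        periods = sorted(table["period"].unique(), key=str)
        for pval in periods[1:]:  # first level is the reference
            cols.append((table["period"] == pval).to_numpy(dtype=float))
            names.append(f"period[{pval}]")
        for eff in self.fixed_effect_names:
            if eff not in table.columns:
                raise ValueError(f"fixed effect column {eff!r} not in table")
            cols.append(table[eff].to_numpy(dtype=float))
            names.append(eff)
        return np.column_stack(cols), names

    def _check_rank(self) -> None:
        r = np.linalg.matrix_rank(self.X)
        if r < self.X.shape[1]:
            # name the first column whose removal restores full rank
            for j in range(self.X.shape[1] - 1, 0, -1):
                Xr = np.delete(self.X, j, axis=1)
                if np.linalg.matrix_rank(Xr) == Xr.shape[1]:
                    raise ValueError(
                        f"fixed effect {self.x_names[j]!r} is confounded "
                        f"(design matrix rank {r} < {self.X.shape[1]})")
            raise ValueError("fixed-effect design matrix is rank deficient")

    # -- restricted log-likelihood via the q-dimensional Woodbury form ------
    def _loglik(self, sa2: float, spe2: float, se2: float):
        y, X, Z, A = self.y, self.X, self.Z, self.A
        n, p = y.size, X.shape[1]
        q = A.shape[0]
        K = sa2 * A + (spe2 if self.include_pe else 0.0) * np.eye(q)
        D = np.diag(self.counts)
        M = se2 * np.eye(q) + D @ K  # q x q; |V| = se2^(n-q) |M|... via lemma
        sign, logdet_M = np.linalg.slogdet(M / se2)
        if sign <= 0:
            return -np.inf, None
        logdet_V = n * np.log(se2) + logdet_M
        # V^-1 x = (x - Z K M^-T? ...) use V^-1 = (1/se2)[I - Z K (se2 I + D K)^-1 Z']
        KM = np.linalg.solve(M.T, K.T).T  # K @ M^-1
        def Vinv(mat):
            return (mat - Z @ (KM @ (Z.T @ mat))) / se2
        XtVinv = Vinv(X).T
        XtVinvX = XtVinv @ X
        XtVinvy = XtVinv @ y
        beta = np.linalg.solve(XtVinvX, XtVinvy)
        r = y - X @ beta
        quad = float(r @ Vinv(r))
        sign2, logdet_XVX = np.linalg.slogdet(XtVinvX)
        ll = -0.5 * (logdet_V + logdet_XVX + quad + (n - p) * np.log(2 * np.pi))
        return float(ll), (beta, r, Vinv, K)

    def fit(self, maxiter: int = 400) -> RepeatedMeasuresResults:
        y = self.y
        vy = float(np.var(y))
        if vy == 0:
            # nothing to partition: every component zero, aggregate zero
            agg = pd.DataFrame({
                "animal_id": self.animal_ids,
                "value": np.zeros(len(self.animal_ids)),
                "n_records": self.counts.astype(int),
            })
            zero_an = pd.Series(0.0, index=self.animal_ids)
            return RepeatedMeasuresResults(
                0.0, 0.0, 0.0, 0.0, float("nan"), 0.0, 0.5, 0.0,
                pd.Series({"intercept": float(y[0]) if y.size else 0.0}),
                zero_an, zero_an, pd.Series(np.zeros(y.size)), agg,
                True, [], y.size, len(self.animal_ids))

        trace: list[float] = []

        def negll(theta):
            sa2, spe2, se2 = np.exp(theta)
            if not self.include_pe:
                spe2 = 0.0
            ll, _ = self._loglik(sa2, spe2, se2)
            if np.isfinite(ll):
                trace.append(max(ll, trace[-1]) if trace else ll)
            return -ll if np.isfinite(ll) else 1e12

        k = 3 if self.include_pe else 2
        x0 = np.log(np.array([0.3, 0.1, 0.6][:3]) * vy)
        if not self.include_pe:
            x0 = x0[[0, 2]]

        def unpack(theta):
            if self.include_pe:
                return np.exp(theta)
            sa2, se2 = np.exp(theta)
            return np.array([sa2, 0.0, se2])

        def negll_k(theta):
            return negll(np.array([theta[0], theta[1], theta[2]])
                         if self.include_pe else
                         np.array([theta[0], -np.inf, theta[1]]))

        res = optimize.minimize(negll_k, x0, method="Nelder-Mead",
                                options={"maxiter": maxiter, "xatol": 1e-9,
                                         "fatol": 1e-10})
        sa2, spe2, se2 = unpack(res.x)
        ll, aux = self._loglik(sa2, spe2, se2)
        beta, r, Vinv, K = aux
        total = sa2 + spe2 + se2
        h2 = sa2 / total

        # null fit (sa2 = 0) for the boundary LRT
        def negll0(theta):
            spe2_, se2_ = (np.exp(theta[0]), np.exp(theta[1])) if self.include_pe \
                else (0.0, np.exp(theta[0]))
            ll0_, _ = self._loglik(0.0, spe2_, se2_)
            return -ll0_ if np.isfinite(ll0_) else 1e12

        x00 = np.log([0.2 * vy, 0.8 * vy]) if self.include_pe else np.log([vy])
        res0 = optimize.minimize(negll0, x00, method="Nelder-Mead",
                                 options={"maxiter": maxiter})
        ll0 = -float(res0.fun)
        lrt = max(0.0, 2.0 * (ll - ll0))
        lrt_p = 0.5 * float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 0.5

        se_h2 = self._h2_se(res.x, unpack)

        # BLUPs: a_hat = sa2 * A Z' V^-1 r ; p_hat = spe2 * Z' V^-1 r
        Vinv_r = Vinv(r)
        ZtVr = self.Z.T @ Vinv_r
        a_hat = sa2 * (self.A @ ZtVr)
        p_hat = spe2 * ZtVr
        e_hat = r - self.Z @ a_hat - self.Z @ p_hat
        mean_resid = np.bincount(self.rec_animal, weights=e_hat,
                                 minlength=len(self.animal_ids)) / self.counts
        agg_val = a_hat + mean_resid
        if self.include_pe_in_aggregate:
            agg_val = agg_val + p_hat
        agg = pd.DataFrame({
            "animal_id": self.animal_ids,
            "value": agg_val,
            "n_records": self.counts.astype(int),
        })
        return RepeatedMeasuresResults(
            sigma2_additive=float(sa2), sigma2_pe=float(spe2),
            sigma2_residual=float(se2), h2=float(h2), se_h2=se_h2,
            lrt=lrt, lrt_p=lrt_p, loglik=float(ll),
            fixed_effects=pd.Series(beta, index=self.x_names),
            animal_blup=pd.Series(a_hat, index=self.animal_ids),
            pe_blup=pd.Series(p_hat, index=self.animal_ids),
            residuals=pd.Series(e_hat),
            aggregate=agg, converged=bool(res.success),
            loglik_trace=trace, n_records=y.size, n_animals=len(self.animal_ids))

    def _h2_se(self, theta_hat, unpack) -> float:
        """Delta-method SE of h2 from the numeric Hessian on the log-variance scale."""
        def ll_of(theta):
            sa2, spe2, se2 = unpack(theta)
            ll, _ = self._loglik(sa2, spe2, se2)
            return ll

        k = len(theta_hat)
        h = 1e-4
        H = np.zeros((k, k))
        f0 = ll_of(theta_hat)
        for i in range(k):
            for j in range(i, k):
                ei = np.eye(k)[i] * h
                ej = np.eye(k)[j] * h
                fij = ll_of(theta_hat + ei + ej)
                fi = ll_of(theta_hat + ei)
                fj = ll_of(theta_hat + ej)
                H[i, j] = H[j, i] = (fij - fi - fj + f0) / h**2
        try:
            C = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return float("nan")
        v = unpack(theta_hat)
        sa2, spe2, se2 = v
        total = sa2 + spe2 + se2
        # dh2/dtheta_i with theta_i = log(sigma_i^2)
        if k == 3:
            grad = np.array([sa2 * (total - sa2), -sa2 * spe2, -sa2 * se2]) / total**2
        else:
            grad = np.array([sa2 * (total - sa2), -sa2 * se2]) / total**2
        var = float(grad @ C @ grad)
        return float(np.sqrt(var)) if var > 0 else float("nan")


def fit_repeated_measures(table: pd.DataFrame, relationship,
                          animal_ids=None, fixed_effects=None,
                          include_pe: bool = True):
    """Functional wrapper: returns (aggregate DataFrame, results object)."""
    res = RepeatedMeasuresModel(table, relationship, animal_ids,
                                fixed_effects, include_pe).fit()
    return res.aggregate, res
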