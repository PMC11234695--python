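"""Mixed-linear-model association machinery.

Implements the GCTA-style workflow used for every QTL layer: a genomic
relationship matrix (GRM) from standardized dosages, REML estimation of the
polygenic variance under ``y ~ N(Xb, sg2*G + se2*I)``, and single-variant
mixed-model association (MLMA) in which the variance components are estimated
once under the null and each variant is then tested by generalized least
squares. Leave-one-chromosome-out (LOCO) and leave-one-segment-out (LOSO)
designs are supported by excluding the tested region's variants from the GRM.

The model classes follow the Model -> fit() -> Results convention:

>>> grm = compute_grm(genotypes)
>>> vc = PolygenicModel(y, grm).fit()          # REML variance components
>>> scan = MixedAssociationScan(y, genotypes, grm).fit()   # MLMA
>>> scan.summary()
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import GenotypeMatrix, QtlSummary, maf_from_dosage


def _mean_impute(dosage: np.ndarray) -> np.ndarray:
    """Mean-impute missing (NaN) entries per variant (column)."""
    d = np.array(dosage, dtype=float)
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_r, nan_c = np.where(np.isnan(d))
    d[nan_r, nan_c] = col_mean[nan_c]
    return d


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

@dataclass
class Grm:
    """Genomic relationship matrix (VanRaden method 1 / GCTA default).

    ``matrix[i, k] = (1/m) * sum_j z_ij z_kj`` with
    ``z_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j))``.
    """

    sample_ids: list[str]
    matrix: np.ndarray
    n_variants_used: int
    excluded_region: tuple | str | None = None
    n_monomorphic_skipped: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.sample_ids),) * 2:
            raise ValueError("GRM shape inconsistent with sample ids")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        self.matrix = m

    @property
    def n(self) -> int:
        return len(self.sample_ids)


def compute_grm(g: GenotypeMatrix,
                exclude: tuple[str, int, int] | str | None = None) -> Grm:
    """Build a GRM from standardized dosages, optionally excluding a region.

    ``exclude`` may be a chromosome name (LOCO) or a ``(chrom, start, end)``
    interval in 1-based inclusive coordinates (LOSO). Monomorphic variants
    are skipped and counted; missing dosages are mean-imputed.
    """
    keep = np.ones(g.n_variants, dtype=bool)
    if exclude is not None:
        for j, v in enumerate(g.variants):
            if isinstance(exclude, str):
                if v.chrom == exclude:
                    keep[j] = False
            else:
                chrom, start, end = exclude
                if v.chrom == str(chrom) and start <= v.pos <= end:
                    keep[j] = False
    d = _mean_impute(g.dosage[:, keep])
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_mono = int((~poly).sum())
    d = d[:, poly]
    p = p[poly]
    m = d.shape[1]
    if m == 0:
        raise ValueError("no polymorphic variants available for the GRM")
    z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    mat = z @ z.T / m
    return Grm(list(g.samples), mat, m, exclude, n_mono)


def write_grm_tsv(grm: Grm, path) -> None:
    pd.DataFrame(grm.matrix, index=grm.sample_ids, columns=grm.sample_ids).to_csv(
        path, sep="\t", index_label="sample")


def read_grm_tsv(path) -> Grm:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return Grm(list(df.index.astype(str)), df.to_numpy(), n_variants_used=0)


def write_grm_gcta(grm: Grm, prefix: str) -> None:
    """GCTA binary triple: ``.grm.bin`` (float32 lower triangle, row-major),
    ``.grm.N.bin`` (variant counts), ``.grm.id`` (FID/IID)."""
    n = grm.n
    tri = np.concatenate([grm.matrix[i, : i + 1] for i in range(n)]).astype("<f4")
    tri.tofile(prefix + ".grm.bin")
    np.full(tri.shape, grm.n_variants_used, dtype="<f4").tofile(prefix + ".grm.N.bin")
    with open(prefix + ".grm.id", "w") as fh:
        for s in grm.sample_ids:
            fh.write(f"{s}\t{s}\n")


def read_grm_gcta(prefix: str) -> Grm:
    ids = [line.split()[1] for line in open(prefix + ".grm.id")]
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype="<f4")
    mat = np.zeros((n, n))
    k = 0
    for i in range(n):
        mat[i, : i + 1] = tri[k: k + i + 1]
        k += i + 1
    mat = mat + np.tril(mat, -1).T
    nvar = int(np.fromfile(prefix + ".grm.N.bin", dtype="<f4")[0])
    return Grm(ids, mat, nvar)


# ---------------------------------------------------------------------------
# REML variance components (two components: G and I)
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponentsResults:
    """REML fit of ``y ~ N(Xb, sg2*G + se2*I)``.

    ``h2`` is sg2/(sg2+se2); ``lrt_p`` tests H0: sg2 = 0 against the 50:50
    mixture of a point mass at zero and chi-square(1), the usual reference
    for a variance component on the boundary.
    """

    sigma2_g: float
    sigma2_e: float
    h2: float
    se_h2: float
    lrt: float
    lrt_p: float
    loglik: float
    loglik_null: float
    n: int
    converged: bool = True
    method: str = "profile+curvature"

    @property
    def sigma2_total(self) -> float:
        return self.sigma2_g + self.sigma2_e

    def summary(self) -> str:
        lines = [
            "REML variance components (GRM + residual)",
            f"  n                : {self.n}",
            f"  sigma2_g         : {self.sigma2_g:.6g}",
            f"  sigma2_e         : {self.sigma2_e:.6g}",
            f"  h2               : {self.h2:.4f} (SE {self.se_h2:.4f})",
            f"  LRT (h2=0)       : {self.lrt:.4g}  p = {self.lrt_p:.3g}",
            f"  REML loglik      : {self.loglik:.6g}",
            f"  converged        : {self.converged}",
        ]
        return "\n".join(lines)


class PolygenicModel:
    """REML for a single genomic variance component plus residual.

    Uses the eigendecomposition of the GRM so each likelihood evaluation is
    O(n): rotate ``y`` and ``X`` by the eigenvectors, profile the total
    variance out, and maximise the restricted likelihood over ``h2`` by
    bounded 1-D search; the SE comes from the numeric curvature at the
    optimum.
    """

    def __init__(self, y: np.ndarray, grm: Grm,
                 covariates: np.ndarray | None = None) -> None:
        y = np.asarray(y, dtype=float).reshape(-1)
        if y.size != grm.n:
            raise ValueError("phenotype length does not match GRM dimension")
        if np.var(y) == 0:
            raise ValueError("phenotype has no variance")
        X = np.ones((y.size, 1))
        if covariates is not None:
            C = np.atleast_2d(np.asarray(covariates, dtype=float))
            if C.shape[0] != y.size:
                C = C.T
            X = np.column_stack([X, C])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
        self.y = y
        self.X = X
        self.grm = grm
        # eigendecomposition done once
        d, U = np.linalg.eigh(grm.matrix)
        self._d = np.clip(d, 0.0, None)
        self._U = U
        self._ys = U.T @ y
        self._Xs = U.T @ X

    def _restricted_loglik(self, h2: float) -> float:
        d, ys, Xs = self._d, self._ys, self._Xs
        n, p = ys.size, Xs.shape[1]
        delta = h2 * d + (1.0 - h2)
        if np.any(delta <= 0):
            return -np.inf
        w = 1.0 / delta
        XtWX = Xs.T @ (Xs * w[:, None])
        XtWy = Xs.T @ (ys * w)
        beta = np.linalg.solve(XtWX, XtWy)
        r = ys - Xs @ beta
        q = float(r @ (r * w))
        s2 = q / (n - p)
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        ll = -0.5 * ((n - p) * np.log(s2) + np.sum(np.log(delta))
                     + logdet_xwx + (n - p))
        return float(ll)

    def fit(self) -> VarianceComponentsResults:
        eps = 1e-6
        # coarse grid then bounded refinement: the profile can be multi-modal
        grid = np.linspace(0.0, 1.0 - eps, 21)
        ll_grid = np.array([self._restricted_loglik(h) for h in grid])
        h0 = grid[int(np.argmax(ll_grid))]
        lo, hi = max(0.0, h0 - 0.06), min(1.0 - eps, h0 + 0.06)
        res = optimize.minimize_scalar(lambda h: -self._restricted_loglik(h),
                                       bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-8})
        h2 = float(res.x)
        ll = -float(res.fun)
        ll0 = self._restricted_loglik(0.0)
        if ll0 >= ll:  # boundary optimum
            h2, ll = 0.0, ll0
        # profiled total variance at the optimum
        delta = h2 * self._d + (1.0 - h2)
        w = 1.0 / delta
        XtWX = self._Xs.T @ (self._Xs * w[:, None])
        beta = np.linalg.solve(XtWX, self._Xs.T @ (self._ys * w))
        r = self._ys - self._Xs @ beta
        s2 = float(r @ (r * w)) / (self._ys.size - self._Xs.shape[1])
        # SE via numeric curvature of the profile restricted likelihood
        step = 1e-4
        hm = min(max(h2, step), 1 - eps - step)
        d2 = (self._restricted_loglik(hm + step) - 2 * self._restricted_loglik(hm)
              + self._restricted_loglik(hm - step)) / step**2
        se_h2 = float(1.0 / np.sqrt(-d2)) if d2 < 0 else float("nan")
        lrt = max(0.0, 2.0 * (ll - ll0))
        lrt_p = 0.5 * float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 0.5
        return VarianceComponentsResults(
            sigma2_g=h2 * s2, sigma2_e=(1 - h2) * s2, h2=h2, se_h2=se_h2,
            lrt=lrt, lrt_p=lrt_p, loglik=ll, loglik_null=ll0,
            n=self._ys.size, converged=bool(getattr(res, "success", True)),
        )


def reml_variance_components(y, grm: Grm, covariates=None) -> VarianceComponentsResults:
    """Functional wrapper around :class:`PolygenicModel`."""
    return PolygenicModel(y, grm, covariates).fit()


# ---------------------------------------------------------------------------
# MLMA
# ---------------------------------------------------------------------------

@dataclass
class MlmaResult:
    """A QtlSummary plus scan metadata."""

    summary_table: QtlSummary
    phenotype: str
    covariate_names: list[str]
    grm_mode: str
    variance_components: VarianceComponentsResults
    threshold: float | None = None

    @property
    def table(self) -> pd.DataFrame:
        return self.summary_table.table

    def significant(self, threshold: float | None = None) -> pd.DataFrame:
        thr = threshold if threshold is not None else self.threshold
        if thr is None:
            raise ValueError("no significance threshold supplied")
        t = self.summary_table.tested()
        return t[t["p"] < thr]

    def summary(self) -> str:
        t = self.summary_table.tested()
        lines = [
            f"MLMA scan: phenotype={self.phenotype!r} grm_mode={self.grm_mode}"
            f" covariates={self.covariate_names}",
            f"  variants tested  : {len(t)} of {len(self.summary_table)}",
            f"  null h2          : {self.variance_components.h2:.4f}",
        ]
        if len(t):
            top = self.summary_table.top_variant()
            lines.append(f"  top variant      : {top['id']} at {top['chrom']}:{int(top['pos'])}"
                         f"  beta={top['beta']:.4g} (SE {top['se']:.3g})  p={top['p']:.3g}")
        if self.threshold is not None:
            lines.append(f"  threshold        : {self.threshold:.3g}"
                         f"  ({len(self.significant())} significant)")
        return "\n".join(lines)


class MixedAssociationScan:
    """Single-variant mixed-model association (GCTA MLMA style).

    Variance components are estimated once under the null model (no variant),
    then every variant is tested by GLS under ``V = sg2*G + se2*I``. Beta is
    reported per copy of the alt allele; the Wald p-value uses the standard
    normal reference. Monomorphic variants keep a row flagged
    ``"monomorphic"`` rather than being dropped.
    """

    def __init__(self, y: np.ndarray, genotypes: GenotypeMatrix, grm: Grm,
                 covariates: np.ndarray | None = None,
                 covariate_names: list[str] | None = None,
                 phenotype_name: str = "phenotype",
                 grm_mode: str = "full") -> None:
        if genotypes.n_samples != grm.n:
            raise ValueError("genotype and GRM sample dimensions differ")
        y = np.asarray(y, dtype=float).reshape(-1)
        if y.size != grm.n:
            raise ValueError("phenotype length does not match GRM dimension")
        self.y = y
        self.g = genotypes
        self.grm = grm
        self.covariates = covariates
        self.covariate_names = covariate_names or (
            [] if covariates is None else
            [f"cov{i}" for i in range(np.atleast_2d(covariates).shape[-1])])
        self.phenotype_name = phenotype_name
        self.grm_mode = grm_mode

    def fit(self, threshold: float | None = None) -> MlmaResult:
        null = PolygenicModel(self.y, self.grm, self.covariates)
        vc = null.fit()
        d, U = null._d, null._U
        delta = vc.h2 * d + (1.0 - vc.h2)
        sw = 1.0 / np.sqrt(delta)
        Xw = null._Xs * sw[:, None]
        yw = null._ys * sw
        # weighted projection onto the covariate complement
        Qx, _ = np.linalg.qr(Xw)
        y_t = yw - Qx @ (Qx.T @ yw)
        dos = _mean_impute(self.g.dosage)
        n_nonmiss = np.sum(~np.isnan(self.g.dosage), axis=0)
        Gw = (U.T @ dos) * sw[:, None]
        G_t = Gw - Qx @ (Qx.T @ Gw)
        xx = np.einsum("ij,ij->j", G_t, G_t)
        xy = G_t.T @ yw
        s2 = vc.sigma2_total
        mono = dos.std(axis=0) == 0
        # variants (numerically) collinear with the covariates carry no
        # testable residual dosage variation
        xw_norm = np.einsum("ij,ij->j", Gw, Gw)
        collinear = ~mono & (xx <= 1e-8 * np.maximum(xw_norm, 1e-300))
        drop = mono | collinear
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(drop, np.nan, xy / xx)
            se = np.where(drop, np.nan, np.sqrt(s2 / xx))
        zstat = beta / se
        p = 2.0 * stats.norm.sf(np.abs(zstat))
        p = np.clip(p, np.nextafter(0, 1), 1.0)
        rows = pd.DataFrame({
            "id": [v.id for v in self.g.variants],
            "chrom": [v.chrom for v in self.g.variants],
            "pos": [v.pos for v in self.g.variants],
            "ref": [v.ref for v in self.g.variants],
            "alt": [v.alt for v in self.g.variants],
            "maf": [maf_from_dosage(self.g.dosage[:, j]) for j in range(self.g.n_variants)],
            "n": n_nonmiss,
            "beta": beta,
            "se": se,
            "p": np.where(drop, np.nan, p),
            "status": np.select([mono, collinear], ["monomorphic", "collinear"],
                                default="ok"),
        })
        return MlmaResult(QtlSummary(rows, name=self.phenotype_name),
                          self.phenotype_name, list(self.covariate_names),
                          self.grm_mode, vc, threshold)


def mlma(y, genotypes: GenotypeMatrix, grm: Grm, covariates=None,
         threshold: float | None = None, phenotype_name: str = "phenotype",
         grm_mode: str = "full") -> MlmaResult:
    """Functional wrapper around :class:`MixedAssociationScan`."""
    return MixedAssociationScan(y, genotypes, grm, covariates,
                                phenotype_name=phenotype_name,
                                grm_mode=grm_mode).fit(threshold)


def conditional_scan(y, genotypes: GenotypeMatrix, grm: Grm, covariates=None,
                     condition_on: str = "", phenotype_name: str = "phenotype",
                     grm_mode: str = "full") -> MlmaResult:
    """MLMA with the dosage of ``condition_on`` appended to the covariates.

    The conditioning variant itself is reported as NA (status
    ``"conditioned"``) since its effect is absorbed by the covariate.
    """
    j = genotypes.variant_index(condition_on)  # KeyError if absent
    cond = _mean_impute(genotypes.dosage[:, [j]])
    if covariates is None:
        cov = cond
        names = [f"dosage[{condition_on}]"]
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(y):
            C = C.T
        cov = np.column_stack([C, cond])
        names = [f"cov{i}" for i in range(C.shape[1])] + [f"dosage[{condition_on}]"]
    res = MixedAssociationScan(y, genotypes, grm, cov, names,
                               phenotype_name, grm_mode).fit()
    t = res.table
    cond_row = t["id"] == condition_on
    t.loc[cond_row, ["beta", "se", "p"]] = np.nan
    t.loc[cond_row, "status"] = "conditioned"
    return res


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold ``alpha / m`` (full precision).

    Use :func:`format_threshold` for the conventional 2-significant-figure
    presentation.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def format_threshold(value: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (e.g. 0.05/631896 -> 7.9e-8)."""
    if value == 0:
        return 0.0
    from math import floor, log10
    k = sig - 1 - floor(log10(abs(value)))
    return round(value, k)
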