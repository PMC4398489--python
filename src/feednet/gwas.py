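"""Pedigree-aware single-SNP association testing.

The association model per SNP k and trait y is the animal model

    y_i = X_i phi + Z_k g + u_i + e_i

with fixed effects phi, additive SNP covariate Z in {-1, 0, +1}, a polygenic
effect u ~ N(0, A sigma2_u) whose covariance is the pedigree numerator
relationship matrix A, and residual e ~ N(0, I sigma2_e).  Significance is a
likelihood-ratio test (1 df) of the model with versus without the SNP
covariate, using maximum likelihood (LRTs on fixed effects require ML; REML
likelihoods are not comparable across fixed-effect structures).

Computation follows the standard eigendecomposition trick: with
A = U D U' the rotation y* = U'y, X* = U'X diagonalises the covariance,
V* = sigma2_e (lambda D + I) where lambda = sigma2_u / sigma2_e.  The null
model per trait profiles the likelihood over lambda once; each SNP test then
reduces to a weighted least-squares fit in the rotated basis with lambda held
fixed (an exact per-SNP re-optimisation mode is available behind a flag).

Standard errors of fixed effects use the degree-of-freedom corrected residual
variance from the weighted fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Pedigree",
    "build_nrm",
    "PedigreeMixedLM",
    "PedigreeMixedLMResults",
    "SnpTest",
    "fit_null_model",
    "test_snp",
    "test_two_snp",
    "test_interaction",
    "run_gwas",
    "default_trait_fixed_effects",
]

UNKNOWN_PARENT = "0"

#: Fixed-effect factors per trait class used in the source design: efficiency
#: ratios get birth year and season, intake/gain traits birth year only,
#: metabolites the sampling year and measurement day.
def default_trait_fixed_effects(traits) -> dict[str, list[str]]:
    from .traits import METABOLITE_TRAITS

    config = {}
    for t in traits:
        if t in ("RFI", "FCR"):
            config[t] = ["birth_year", "season"]
        elif t in ("dEI", "ADG"):
            config[t] = ["birth_year"]
        elif t in METABOLITE_TRAITS:
            config[t] = ["sampling_year", "measurement_day"]
        else:
            config[t] = ["birth_year"]
    return config


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, unknown reference)."""


class Pedigree:
    """Three-column pedigree (animal, sire, dam); "0" marks unknown parents.

    Animals are topologically ordered at construction (parents before
    offspring); a cycle raises :class:`PedigreeError`.
    """

    def __init__(self, records: pd.DataFrame):
        df = records.copy()
        for col in ("animal", "sire", "dam"):
            if col not in df.columns:
                raise PedigreeError(f"pedigree missing column {col!r}")
            df[col] = df[col].astype(str)
        if df["animal"].duplicated().any():
            dup = df.loc[df["animal"].duplicated(), "animal"].iloc[0]
            raise PedigreeError(f"duplicated animal id {dup!r}")
        known = set(df["animal"])
        for col in ("sire", "dam"):
            bad = set(df[col]) - known - {UNKNOWN_PARENT}
            if bad:
                raise PedigreeError(
                    f"{col} ids not present as animals: {sorted(bad)[:5]}"
                )
        self.df = self._toposort(df)
        self.animals = pd.Index(self.df["animal"])

    @staticmethod
    def _toposort(df: pd.DataFrame) -> pd.DataFrame:
        order: list[int] = []
        state = dict.fromkeys(df["animal"], 0)  # 0 new, 1 visiting, 2 done
        parents = {
            a: (s, d)
            for a, s, d in zip(df["animal"], df["sire"], df["dam"])
        }
        pos = {a: i for i, a in enumerate(df["animal"])}

        def visit(a: str) -> None:
            stack = [(a, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    state[node] = 2
                    order.append(pos[node])
                    continue
                if state[node] == 2:
                    continue
                if state[node] == 1:
                    raise PedigreeError(f"pedigree cycle involving {node!r}")
                state[node] = 1
                stack.append((node, True))
                for p in parents[node]:
                    if p != UNKNOWN_PARENT and state[p] != 2:
                        if state[p] == 1:
                            raise PedigreeError(f"pedigree cycle involving {p!r}")
                        stack.append((p, False))

        for a in df["animal"]:
            if state[a] != 2:
                visit(a)
        return df.iloc[order].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def relationship_matrix(self) -> pd.DataFrame:
        """Numerator relationship matrix A by the tabular method.

        Founders get diagonal 1; for animal i with parents s, d:
        a(i,j) = (a(s,j) + a(d,j)) / 2 for previously processed j, and
        a(i,i) = 1 + a(s,d)/2 (inbreeding from related parents).  An unknown
        parent contributes zero relationship.
        """
        n = len(self.df)
        idx = {a: i for i, a in enumerate(self.df["animal"])}
        A = np.zeros((n, n))
        sires = self.df["sire"].to_numpy()
        dams = self.df["dam"].to_numpy()
        for i in range(n):
            s = idx.get(sires[i], -1) if sires[i] != UNKNOWN_PARENT else -1
            d = idx.get(dams[i], -1) if dams[i] != UNKNOWN_PARENT else -1
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
            A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
        return pd.DataFrame(A, index=self.animals, columns=self.animals)


def build_nrm(pedigree: Pedigree) -> pd.DataFrame:
    """Numerator relationship matrix of a pedigree (tabular method)."""
    return pedigree.relationship_matrix()


# ---------------------------------------------------------------------------
# mixed model


@dataclass
class PedigreeMixedLMResults:
    """ML fit of y = X phi + u + e with u ~ N(0, A sigma2_u)."""

    params: pd.Series
    bse: pd.Series
    sigma2_u: float
    sigma2_e: float
    lambda_: float
    llf: float
    nobs: int
    model: "PedigreeMixedLM"
    converged: bool = True
    flags: list = field(default_factory=list)

    @property
    def heritability(self) -> float:
        """Narrow-sense h2 implied by the variance components."""
        tot = self.sigma2_u + self.sigma2_e
        return self.sigma2_u / tot if tot > 0 else np.nan

    def summary(self) -> str:
        lines = [
            "Pedigree mixed linear model (ML)",
            f"  n obs:        {self.nobs}",
            f"  logLik:       {self.llf:.4f}",
            f"  sigma2_u:     {self.sigma2_u:.6g}",
            f"  sigma2_e:     {self.sigma2_e:.6g}",
            f"  lambda (u/e): {self.lambda_:.6g}",
            f"  h2:           {self.heritability:.4f}",
            "  fixed effects:",
        ]
        for name, est, se in zip(self.params.index, self.params, self.bse):
            lines.append(f"    {name:<20} {est: .6g}  (SE {se:.3g})")
        if self.flags:
            lines.append(f"  flags: {', '.join(self.flags)}")
        return "\n".join(lines)


class PedigreeMixedLM:
    """Animal model with a pedigree polygenic effect, fitted by ML.

    Parameters
    ----------
    endog : (n,) array
        Trait values of the phenotyped animals.
    exog : (n, p) DataFrame or array
        Fixed-effect design (should include an intercept column).
    relationship : (n, n) array
        Phenotyped-animal submatrix of the numerator relationship matrix.
    """

    LAMBDA_MAX = 1e4

    def __init__(self, endog, exog, relationship, exog_names=None, eig=None):
        y = np.asarray(endog, float)
        if isinstance(exog, pd.DataFrame):
            exog_names = list(exog.columns)
            X = exog.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, float)
            if X.ndim == 1:
                X = X[:, None]
            if exog_names is None:
                exog_names = [f"x{i}" for i in range(X.shape[1])]
        A = np.asarray(relationship, float)
        n = len(y)
        if X.shape[0] != n or A.shape != (n, n):
            raise ValueError("inconsistent dimensions of endog/exog/relationship")
        if np.ptp(y) == 0:
            raise ValueError("zero-variance trait")
        self.endog = y
        self.exog = X
        self.exog_names = exog_names
        self.nobs = n
        if eig is not None:
            d, U = eig  # precomputed decomposition of A, reusable across fits
        else:
            try:
                d, U = np.linalg.eigh(A)
            except np.linalg.LinAlgError as err:  # pragma: no cover
                raise np.linalg.LinAlgError(
                    "eigendecomposition of the relationship matrix failed; "
                    "consider adding a ridge of 1e-8 to its diagonal"
                ) from err
        if d.min() < -1e-8 * max(1.0, d.max()):
            raise np.linalg.LinAlgError(
                "relationship submatrix is not positive semi-definite; "
                "consider adding a ridge of 1e-8 to its diagonal"
            )
        self._identity_like = bool(np.allclose(A, np.eye(n), atol=1e-12))
        self.eigenvalues = np.clip(d, 0.0, None)
        self.eigenvectors = U
        self._yt = U.T @ y
        self._Xt = U.T @ X

    # -- profile likelihood machinery ------------------------------------

    def _wls(self, Xt: np.ndarray, lam: float):
        """Weighted LS in the rotated basis at variance ratio lam."""
        w = 1.0 / (lam * self.eigenvalues + 1.0)
        Xw = Xt * w[:, None]
        xtx = Xt.T @ Xw
        xty = Xw.T @ self._yt
        beta, *_ = np.linalg.lstsq(xtx, xty, rcond=None)
        resid = self._yt - Xt @ beta
        rss = float(resid @ (w * resid))
        return beta, rss, xtx, w

    def _profile_llf(self, lam: float, Xt: np.ndarray) -> float:
        n = self.nobs
        _, rss, _, _ = self._wls(Xt, lam)
        sigma2 = rss / n
        logdet = float(np.log(lam * self.eigenvalues + 1.0).sum())
        return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)

    def _optimize_lambda(self, Xt: np.ndarray) -> float:
        if self._identity_like:
            # A = I: sigma2_u and sigma2_e are not separately identifiable
            return 0.0
        neg = lambda t: -self._profile_llf(np.expm1(t), Xt)  # t = log(1+lam)
        res = optimize.minimize_scalar(
            neg, bounds=(0.0, np.log1p(self.LAMBDA_MAX)), method="bounded",
            options={"xatol": 1e-8},
        )
        lam = float(np.expm1(res.x))
        # boundary check against lam = 0 exactly
        if self._profile_llf(0.0, Xt) >= self._profile_llf(lam, Xt):
            lam = 0.0
        return lam

    def fit(self, lambda_=None) -> PedigreeMixedLMResults:
        """Fit by ML; optionally hold the variance ratio fixed at ``lambda_``."""
        Xt = self._Xt
        lam = self._optimize_lambda(Xt) if lambda_ is None else float(lambda_)
        beta, rss, xtx, w = self._wls(Xt, lam)
        n, p = self.nobs, Xt.shape[1]
        sigma2_e = rss / n
        llf = self._profile_llf(lam, Xt)
        dof = max(n - p, 1)
        cov = np.linalg.pinv(xtx) * (rss / dof)
        flags = []
        if self._identity_like and lambda_ is None:
            flags.append("variance split unidentifiable (A = I); lambda fixed at 0")
        return PedigreeMixedLMResults(
            params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=self.exog_names),
            sigma2_u=lam * sigma2_e,
            sigma2_e=sigma2_e,
            lambda_=lam,
            llf=llf,
            nobs=n,
            model=self,
            flags=flags,
        )

    def fit_with_covariates(
        self, covariates: np.ndarray, names: list[str], lambda_: float,
        reoptimize: bool = False,
    ) -> PedigreeMixedLMResults:
        """Fit with extra covariate columns appended to the fixed design.

        ``lambda_`` is the null model's variance ratio; with
        ``reoptimize=True`` the ratio is re-estimated for the extended model
        (exact mode).
        """
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        Ct = self.eigenvectors.T @ C
        Xt = np.hstack([self._Xt, Ct])
        lam = self._optimize_lambda(Xt) if reoptimize else float(lambda_)
        beta, rss, xtx, w = self._wls(Xt, lam)
        n, p = self.nobs, Xt.shape[1]
        sigma2_e = rss / n
        llf = self._profile_llf(lam, Xt)
        dof = max(n - p, 1)
        cov = np.linalg.pinv(xtx) * (rss / dof)
        all_names = self.exog_names + names
        return PedigreeMixedLMResults(
            params=pd.Series(beta, index=all_names),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=all_names),
            sigma2_u=lam * sigma2_e,
            sigma2_e=sigma2_e,
            lambda_=lam,
            llf=llf,
            nobs=n,
            model=self,
        )


def fit_null_model(trait, fixed_effects, relationship) -> PedigreeMixedLMResults:
    """Fit the no-SNP animal model for one trait (variance components + llf)."""
    return PedigreeMixedLM(trait, fixed_effects, relationship).fit()


@dataclass
class SnpTest:
    """One SNP-trait association row."""

    effect: float
    se: float
    lrt: float
    p_value: float
    testable: bool = True
    flag: str = ""
    fit: PedigreeMixedLMResults | None = None


def _prepare_snp(snp: np.ndarray) -> tuple[np.ndarray, str]:
    """Mean-impute missing codes; report monomorphism."""
    snp = np.asarray(snp, float).copy()
    obs = np.isfinite(snp)
    if not obs.any():
        return snp, "all_missing"
    if np.ptp(snp[obs]) == 0:
        return snp, "monomorphic"
    snp[~obs] = snp[obs].mean()
    return snp, ""


def _collinear(null: PedigreeMixedLMResults, cols: np.ndarray) -> bool:
    Xt = null.model._Xt
    C = np.asarray(cols, float)
    if C.ndim == 1:
        C = C[:, None]
    Ct = null.model.eigenvectors.T @ C
    full = np.hstack([Xt, Ct])
    return np.linalg.matrix_rank(full) < full.shape[1]


def test_snp(
    null: PedigreeMixedLMResults, snp, name: str = "snp", reoptimize: bool = False
) -> SnpTest:
    """LRT of the single-SNP model against the null (chi-square, 1 df)."""
    snp, flag = _prepare_snp(snp)
    if flag:
        return SnpTest(np.nan, np.nan, 0.0, 1.0, testable=False, flag=flag)
    if _collinear(null, snp):
        return SnpTest(np.nan, np.nan, 0.0, 1.0, testable=False, flag="collinear")
    full = null.model.fit_with_covariates(
        snp, [name], lambda_=null.lambda_, reoptimize=reoptimize
    )
    lrt = max(2.0 * (full.llf - null.llf), 0.0)
    p = float(stats.chi2.sf(lrt, df=1))
    return SnpTest(
        effect=float(full.params[name]),
        se=float(full.bse[name]),
        lrt=lrt,
        p_value=p,
        fit=full,
    )


def test_two_snp(
    null: PedigreeMixedLMResults, snp_a, snp_b, names=("snpA", "snpB"),
    reoptimize: bool = False,
) -> tuple[SnpTest, SnpTest, PedigreeMixedLMResults]:
    """Joint fit of two additive SNP covariates; per-SNP effects and SEs.

    Each SNP's LRT compares the 2-SNP model against the model with that SNP
    dropped (1 df), i.e. its marginal contribution given the other locus.
    """
    a, flag_a = _prepare_snp(snp_a)
    b, flag_b = _prepare_snp(snp_b)
    if flag_a or flag_b:
        bad = SnpTest(np.nan, np.nan, 0.0, 1.0, testable=False,
                      flag=flag_a or flag_b)
        return bad, bad, None
    pair = np.column_stack([a, b])
    if _collinear(null, pair):
        bad = SnpTest(np.nan, np.nan, 0.0, 1.0, testable=False, flag="collinear")
        return bad, bad, None
    full = null.model.fit_with_covariates(
        pair, list(names), lambda_=null.lambda_, reoptimize=reoptimize
    )
    single_b = null.model.fit_with_covariates(
        b, [names[1]], lambda_=null.lambda_, reoptimize=reoptimize
    )
    single_a = null.model.fit_with_covariates(
        a, [names[0]], lambda_=null.lambda_, reoptimize=reoptimize
    )
    lrt_a = max(2.0 * (full.llf - single_b.llf), 0.0)
    lrt_b = max(2.0 * (full.llf - single_a.llf), 0.0)
    res_a = SnpTest(float(full.params[names[0]]), float(full.bse[names[0]]),
                    lrt_a, float(stats.chi2.sf(lrt_a, df=1)), fit=full)
    res_b = SnpTest(float(full.params[names[1]]), float(full.bse[names[1]]),
                    lrt_b, float(stats.chi2.sf(lrt_b, df=1)), fit=full)
    return res_a, res_b, full


def test_interaction(
    null: PedigreeMixedLMResults, snp_a, snp_b, reoptimize: bool = False
) -> SnpTest:
    """Epistasis LRT: {A + B + AxB} against {A + B}, chi-square 1 df.

    The interaction covariate is the elementwise product of the two additive
    codes.  The variance ratio is re-estimated under the two-SNP base model
    (not taken from the no-SNP null): gene-dropped genotypes are themselves
    family-structured, so major additive QTL inflate the no-SNP polygenic
    estimate and would misweight the interaction contrast.
    """
    a, flag_a = _prepare_snp(snp_a)
    b, flag_b = _prepare_snp(snp_b)
    if flag_a or flag_b:
        return SnpTest(np.nan, np.nan, 0.0, 1.0, testable=False,
                       flag=flag_a or flag_b)
    ab = a * b
    if np.ptp(ab) == 0:
        return SnpTest(np.nan, np.nan, 0.0, 1.0, testable=False,
                       flag="degenerate_product")
    pair = np.column_stack([a, b])
    trio = np.column_stack([a, b, ab])
    if _collinear(null, trio):
        return SnpTest(np.nan, np.nan, 0.0, 1.0, testable=False, flag="collinear")
    base = null.model.fit_with_covariates(
        pair, ["snpA", "snpB"], lambda_=null.lambda_, reoptimize=True
    )
    full = null.model.fit_with_covariates(
        trio, ["snpA", "snpB", "snpAxB"], lambda_=base.lambda_,
        reoptimize=reoptimize,
    )
    lrt = max(2.0 * (full.llf - base.llf), 0.0)
    return SnpTest(
        effect=float(full.params["snpAxB"]),
        se=float(full.bse["snpAxB"]),
        lrt=lrt,
        p_value=float(stats.chi2.sf(lrt, df=1)),
        fit=full,
    )


# ---------------------------------------------------------------------------
# genome-wide scan


def build_fixed_design(pheno: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    """Intercept + treatment-coded dummies for the named categorical factors."""
    X = pd.DataFrame({"Intercept": 1.0}, index=pheno.index)
    for f in factors:
        if f not in pheno.columns:
            raise KeyError(f"fixed-effect factor {f!r} missing from phenotype table")
        dummies = pd.get_dummies(
            pheno[f].astype("category"), prefix=f, drop_first=True, dtype=float
        )
        X = pd.concat([X, dummies], axis=1)
    return X


def run_gwas(
    pheno: pd.DataFrame,
    genotypes,
    trait_config: dict[str, list[str]],
    relationship: pd.DataFrame,
    traits: list[str] | None = None,
    reoptimize: bool = False,
) -> pd.DataFrame:
    """Single-SNP association scan for every (SNP, trait) pair.

    Parameters
    ----------
    pheno : DataFrame
        Indexed by animal id; trait columns plus fixed-effect factor columns.
    genotypes : GenotypeMatrix
        Post-QC genotypes; animals are matched to ``pheno`` by id.
    trait_config : dict
        Trait -> list of fixed-effect factor column names.
    relationship : DataFrame
        Numerator relationship matrix covering at least the phenotyped
        animals (full-pedigree matrix accepted; the phenotyped submatrix is
        taken per trait).

    Returns a tidy frame (snp, trait, effect, se, lrt, p, testable, flag).
    """
    if traits is None:
        traits = list(trait_config)
    missing = [t for t in traits if t not in trait_config]
    if missing:
        raise KeyError(f"traits missing from trait_config: {missing}")
    rows = []
    sample_index = pd.Index(genotypes.sample_ids.astype(str))
    for trait in traits:
        y = pheno[trait]
        keep = y.notna()
        ids = pd.Index(pheno.index[keep].astype(str))
        ids = ids[ids.isin(sample_index)]
        sub = pheno.loc[pheno.index.astype(str).isin(ids)]
        X = build_fixed_design(sub, trait_config[trait])
        A_sub = relationship.loc[ids, ids].to_numpy()
        model = PedigreeMixedLM(sub[trait].to_numpy(), X, A_sub)
        null = model.fit()
        rowsel = genotypes.sample_ids.get_indexer(ids)
        codes = genotypes.codes[rowsel]
        for j, snp_id in enumerate(genotypes.snp_ids):
            res = test_snp(null, codes[:, j], name=str(snp_id),
                           reoptimize=reoptimize)
            rows.append(
                (snp_id, trait, res.effect, res.se, res.lrt, res.p_value,
                 res.testable, res.flag)
            )
    return pd.DataFrame(
        rows, columns=["snp", "trait", "effect", "se", "lrt", "p", "testable", "flag"]
    )
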