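"""Linear models of health outcomes on ilr coordinates plus covariates.

The composition enters the regression as a single multi-column term (the
D-1 ilr coordinates), alongside sociodemographic covariates (sex, age,
deprivation decile), fitted by ordinary least squares.  Because any two
ilr bases span the same column space, fitted values, predictions, the
ANOVA table and all substitution differences are invariant to the basis
choice — only the individual ilr coefficients change.

Significance of each term is assessed with Type II (marginality) tests:
each term is tested after all others, with the ilr block treated as one
(D-1)-df term.  Both the F statistic and the equivalent Wald chi-squared
(chi2 = F * df under OLS) are reported; F is primary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
import scipy.stats
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import het_breuschpagan, linear_reset
from statsmodels.stats.outliers_influence import OLSInfluence

from .composition import (
    Composition,
    CompositionError,
    DEFAULT_PARTS,
    IlrTransformer,
    SequentialBinaryPartition,
)

__all__ = [
    "IlrLinearModel",
    "DiagnosticsReport",
    "fit_outcome_model",
    "OUTCOMES",
]

logger = logging.getLogger(__name__)

#: Outcomes analysed in the reference pipeline.  ``vo2peak_adj`` is peak
#: oxygen uptake with zBMI as an additional covariate, fractionating out
#: the contribution of fatness to fitness.
OUTCOMES: dict[str, dict] = {
    "zbmi": {"covariates": ("sex", "age", "imd_decile")},
    "whtr_pct": {"covariates": ("sex", "age", "imd_decile")},
    "vo2peak": {"covariates": ("sex", "age", "imd_decile")},
    "vo2peak_adj": {"column": "vo2peak",
                    "covariates": ("sex", "age", "imd_decile", "zbmi")},
}

DEFAULT_CATEGORICAL = ("sex", "imd_decile")


class RankDeficiencyError(ValueError):
    """The design matrix is not full rank; names the offending columns."""


@dataclass(frozen=True)
class DiagnosticsReport:
    """Regression diagnostics mirroring the usual OLS assumption checks.

    Flags use fixed, documented thresholds: p < 0.01 for the linearity
    (RESET), normality (Jarque-Bera) and heteroscedasticity
    (Breusch-Pagan) tests, and a Bonferroni-corrected p < 0.05 for the
    externally studentised residual outlier test.  High-leverage points
    are reported (leverage > 3p/n) but do not by themselves fail a flag.
    """

    n_obs: int
    r_squared: float
    resid_mean: float
    resid_std: float
    reset_stat: float
    reset_pvalue: float
    jarque_bera_stat: float
    jarque_bera_pvalue: float
    breusch_pagan_stat: float
    breusch_pagan_pvalue: float
    max_abs_student_resid: float
    outlier_bonf_pvalue: float
    outlier_indices: tuple[int, ...]
    high_leverage_indices: tuple[int, ...]
    leverage_threshold: float

    ALPHA = 0.01

    @property
    def linearity_ok(self) -> bool:
        return self.reset_pvalue >= self.ALPHA

    @property
    def normality_ok(self) -> bool:
        return self.jarque_bera_pvalue >= self.ALPHA

    @property
    def homoscedasticity_ok(self) -> bool:
        return self.breusch_pagan_pvalue >= self.ALPHA

    @property
    def no_outliers(self) -> bool:
        return len(self.outlier_indices) == 0

    @property
    def all_ok(self) -> bool:
        return (self.linearity_ok and self.normality_ok
                and self.homoscedasticity_ok and self.no_outliers)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["outlier_indices"] = list(self.outlier_indices)
        d["high_leverage_indices"] = list(self.high_leverage_indices)
        d.update(linearity_ok=self.linearity_ok, normality_ok=self.normality_ok,
                 homoscedasticity_ok=self.homoscedasticity_ok,
                 no_outliers=self.no_outliers, all_ok=self.all_ok)
        return d


class IlrLinearModel(BaseEstimator, RegressorMixin):
    """OLS regression of an outcome on ilr coordinates and covariates.

    Parameters
    ----------
    parts : sequence of str
        Names of the composition columns in ``X`` (durations in minutes).
    covariates : sequence of str
        Names of covariate columns in ``X``.  Those listed in
        ``categorical`` enter as unordered factors (reference level =
        lowest observed value); the rest enter linearly.
    categorical : sequence of str
        Covariates treated as factors.  The deprivation decile is
        categorical by construction: a single slope would force a linear
        deprivation gradient the data need not follow.
    sbp : SequentialBinaryPartition, optional
        ilr basis; pivot balances over ``parts`` by default.  All
        predictions are basis-invariant.
    zero_policy, zero_delta
        Forwarded to :class:`~codasub.composition.IlrTransformer`.

    Attributes
    ----------
    results_ : statsmodels RegressionResults
    basis_ : the SBP actually used
    coef_, intercept_ : full coefficient vector split sklearn-style
    ilr_coef_ : the D-1 coefficients of the ilr block
    anova_ : Type II ANOVA table (computed lazily via :meth:`anova`)
    """

    def __init__(self, parts: Sequence[str] = DEFAULT_PARTS,
                 covariates: Sequence[str] = ("sex", "age", "imd_decile"),
                 categorical: Sequence[str] = DEFAULT_CATEGORICAL,
                 sbp: SequentialBinaryPartition | None = None,
                 zero_policy: str = "error", zero_delta: float = 0.5):
        self.parts = parts
        self.covariates = covariates
        self.categorical = categorical
        self.sbp = sbp
        self.zero_policy = zero_policy
        self.zero_delta = zero_delta

    # -- fitting ----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y) -> "IlrLinearModel":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with part and covariate columns")
        y = np.asarray(pd.Series(y).to_numpy(), dtype=float)
        if y.shape[0] != len(X):
            raise ValueError("X and y have different lengths")

        missing_cols = [c for c in (*self.parts, *self.covariates)
                        if c not in X.columns]
        if missing_cols:
            raise KeyError(f"X is missing required columns: {missing_cols}")

        keep = np.isfinite(y)
        for c in (*self.covariates, *self.parts):
            keep &= X[c].notna().to_numpy()
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropping %d record(s) with missing outcome/covariates",
                        n_dropped)
        X = X.loc[keep].reset_index(drop=True)
        y = y[keep]
        self.n_dropped_ = n_dropped

        self._ilr = IlrTransformer(parts=tuple(self.parts), sbp=self.sbp,
                                   zero_policy=self.zero_policy,
                                   zero_delta=self.zero_delta).fit(X)
        self.basis_ = self._ilr.basis_
        Z = self._ilr.transform(X)

        data = {"ilr": Z}
        terms = ["ilr"]
        for c in self.covariates:
            data[c] = np.asarray(X[c])
            terms.append(f"C({c})" if c in self.categorical else c)
        formula = "~ " + " + ".join(terms)
        design = patsy.dmatrix(formula, data, return_type="dataframe")
        self.design_info_ = design.design_info

        self._check_rank(design)
        ols = sm.OLS(y, design)
        # anova_lm needs the patsy design info, which sm.OLS drops when
        # not built through the formula API
        ols.data.design_info = self.design_info_
        self.results_ = ols.fit()
        self._train_X_ = X
        self._train_y_ = y
        self._design_col_means_ = design.to_numpy().mean(axis=0)

        names = list(design.columns)
        params = self.results_.params.to_numpy()
        self.feature_names_ = names
        self.intercept_ = float(params[0])
        self.coef_ = params[1:]
        sl = self.design_info_.slice("ilr")
        self.ilr_coef_ = params[sl]
        self.resid_df_ = float(self.results_.df_resid)
        self.sigma2_ = float(self.results_.mse_resid)
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _check_rank(design: pd.DataFrame) -> None:
        M = design.to_numpy()
        rank = np.linalg.matrix_rank(M)
        if rank < M.shape[1]:
            # identify columns in the null space for the error message
            _, s, vt = np.linalg.svd(M, full_matrices=False)
            null = vt[s < s[0] * 1e-10 * max(M.shape)] if s.size else vt[-1:]
            involved = sorted({design.columns[j]
                               for v in np.atleast_2d(null)
                               for j in np.nonzero(np.abs(v) > 1e-6)[0]})
            raise RankDeficiencyError(
                f"design matrix is rank deficient (rank {rank} < {M.shape[1]}); "
                f"collinear columns: {involved}"
            )

    # -- prediction -------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "results_"):
            raise RuntimeError("model is not fitted")

    def _design_for(self, X: pd.DataFrame) -> np.ndarray:
        Z = self._ilr.transform(X)
        data = {"ilr": Z}
        for c in self.covariates:
            data[c] = np.asarray(X[c])
        try:
            return patsy.build_design_matrices([self.design_info_], data)[0]
        except patsy.PatsyError as exc:  # e.g. unseen factor level
            raise ValueError(f"cannot build design matrix for new data: {exc}") from exc

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Linear predictor for rows carrying parts and covariates."""
        self._check_fitted()
        M = np.asarray(self._design_for(X))
        return M @ self.results_.params.to_numpy()

    def profile_row(self, comp: Composition | np.ndarray,
                    profile: Mapping[str, float] | None = None) -> np.ndarray:
        """Design row for one composition at a covariate profile.

        The default profile sets every covariate column to its training
        design-matrix mean: numeric covariates at the sample mean and
        factor dummies at observed proportions.  An explicit ``profile``
        maps covariate names to values and builds the row through the
        fitted design info (unknown factor levels raise).
        """
        self._check_fitted()
        z = self._ilr.transform(np.atleast_2d(
            comp.values if isinstance(comp, Composition) else np.asarray(comp, float)))
        if profile is None:
            row = self._design_col_means_.copy()
        else:
            missing = [c for c in self.covariates if c not in profile]
            if missing:
                raise ValueError(f"profile is missing covariates: {missing}")
            data = {"ilr": z}
            for c in self.covariates:
                data[c] = np.asarray([profile[c]])
            try:
                row = np.asarray(
                    patsy.build_design_matrices([self.design_info_], data)[0]
                )[0]
            except patsy.PatsyError as exc:
                raise ValueError(f"invalid covariate profile: {exc}") from exc
        row[self.design_info_.slice("ilr")] = z[0]
        return row

    def predict_composition(self, comp: Composition | np.ndarray,
                            profile: Mapping[str, float] | None = None) -> float:
        """Predicted outcome for one composition at a covariate profile.

        Differences between two compositions at the same profile do not
        depend on the profile (the model has no interactions), so the
        default mean profile is only a convention for absolute levels.
        """
        row = self.profile_row(comp, profile)
        return float(row @ self.results_.params.to_numpy())

    # -- inference --------------------------------------------------------

    def anova(self) -> pd.DataFrame:
        """Type II (marginality) ANOVA: each term after all others.

        Returns one row per model term with ``sum_sq``, ``df``, ``F``,
        ``p_F`` and the Wald equivalents ``chisq`` (= F * df) and
        ``p_chisq``.  The ilr block appears as a single (D-1)-df term.
        """
        self._check_fitted()
        tab = anova_lm(self.results_, typ=2)
        tab = tab.rename(columns={"sum_sq": "sum_sq", "F": "F", "PR(>F)": "p_F"})
        tab = tab[tab.index != "Residual"].copy()
        resid = anova_lm(self.results_, typ=2).loc["Residual"]
        tab["chisq"] = tab["F"] * tab["df"]
        tab["p_chisq"] = scipy.stats.chi2.sf(tab["chisq"], tab["df"])
        tab.attrs["resid_sum_sq"] = float(resid["sum_sq"])
        tab.attrs["resid_df"] = float(resid["df"])
        self.anova_ = tab
        return tab

    def term_test(self, term: str) -> pd.Series:
        """Marginality test for one named term (e.g. ``"ilr"``, ``"age"``)."""
        tab = self.anova()
        for label in tab.index:
            if label == term or label == f"C({term})":
                return tab.loc[label]
        raise KeyError(f"term {term!r} not in model; terms: {list(tab.index)}")

    def diagnostics(self) -> DiagnosticsReport:
        """Assumption checks: linearity, normality, homoscedasticity, outliers."""
        self._check_fitted()
        res = self.results_
        resid = res.resid
        exog = np.asarray(res.model.exog)

        reset = linear_reset(res, power=2, use_f=True)
        jb_stat, jb_p, _, _ = sm.stats.jarque_bera(resid)
        bp_stat, bp_p, _, _ = het_breuschpagan(resid, exog)

        infl = OLSInfluence(res)
        student = infl.resid_studentized_external
        # leverage-one points (e.g. a singleton factor level) have an
        # undefined externally studentised residual; they cannot be tested
        student = np.where(np.isfinite(student), student, 0.0)
        n, p = exog.shape
        # Bonferroni outlier test on the max |studentised| residual
        abs_max = float(np.max(np.abs(student)))
        bonf_p = float(min(1.0, n * 2.0 * scipy.stats.t.sf(abs_max, res.df_resid - 1)))
        raw_p = n * 2.0 * scipy.stats.t.sf(np.abs(student), res.df_resid - 1)
        outliers = tuple(int(i) for i in np.nonzero(raw_p < 0.05)[0])
        lev_thr = 3.0 * p / n
        high_lev = tuple(int(i) for i in np.nonzero(infl.hat_matrix_diag > lev_thr)[0])

        return DiagnosticsReport(
            n_obs=int(res.nobs), r_squared=float(res.rsquared),
            resid_mean=float(np.mean(resid)), resid_std=float(np.std(resid, ddof=1)),
            reset_stat=float(reset.statistic), reset_pvalue=float(reset.pvalue),
            jarque_bera_stat=float(jb_stat), jarque_bera_pvalue=float(jb_p),
            breusch_pagan_stat=float(bp_stat), breusch_pagan_pvalue=float(bp_p),
            max_abs_student_resid=abs_max, outlier_bonf_pvalue=bonf_p,
            outlier_indices=outliers, high_leverage_indices=high_lev,
            leverage_threshold=lev_thr,
        )

    def coef_table(self) -> pd.DataFrame:
        self._check_fitted()
        res = self.results_
        return pd.DataFrame({
            "coef": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues,
        })


def fit_outcome_model(records: pd.DataFrame, outcome: str,
                      covariates: Sequence[str] | None = None,
                      sbp: SequentialBinaryPartition | None = None,
                      parts: Sequence[str] = DEFAULT_PARTS,
                      **kwargs) -> IlrLinearModel:
    """Fit the standard outcome model from a participant table.

    ``outcome`` is either a column name or one of the named analyses in
    :data:`OUTCOMES` (``"vo2peak_adj"`` adds zBMI as a covariate).
    """
    spec = OUTCOMES.get(outcome, {})
    column = spec.get("column", outcome)
    if covariates is None:
        covariates = spec.get("covariates", ("sex", "age", "imd_decile"))
    if column not in records.columns:
        raise KeyError(f"outcome column {column!r} not found")
    model = IlrLinearModel(parts=parts, covariates=tuple(covariates),
                           sbp=sbp, **kwargs)
    return model.fit(records, records[column])
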