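"""Multinomial (baseline-category logit) models of TIB category.

The outcome is the three-level TIB category with UTIB as the reference;
exponentiated coefficients are relative risk ratios (RRR) — the factor by
which one unit of a predictor multiplies the odds of being STIB or RTIB
*relative to UTIB*.  Two covariate sets are used:

* Model I  — age, sex (female vs male reference), average daily nap length,
  SPPB total score; used with the tertile exposures (average CPM, % of wear
  time at 2303–4999 cpm, % at >= 5000 cpm), lowest tertile as reference.
* Model II — Model I plus % of wear time at >= 5000 cpm; used with the
  binary highly-sedentary exposure.

Estimation is Newton-type maximum likelihood (gradient tolerance 1e-8, at
most 100 iterations) via :class:`statsmodels.api.MNLogit`.  Confidence
intervals for RRRs are Wald intervals ``exp(coef ± 1.96 SE)`` with standard
errors from the observed information; the overall p-value of an exposure is
a likelihood-ratio test of its block.  Predicted category probabilities are
softmax transforms of the linear predictors with covariates held at cohort
means (continuous) and modes (categorical); their confidence intervals, and
those of probability contrasts between exposure levels, use the delta
method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exposures import tertile_assign

__all__ = [
    "ModelSpec",
    "TibMultinomialModel",
    "TibMultinomialResults",
    "FitError",
    "fit_multinomial",
]

OUTCOMES = ("UTIB", "STIB", "RTIB")
TERTILE_EXPOSURES = ("avg_cpm", "pct_mid", "pct_high")
MODEL_I_COVARIATES = ("age", "sex_female", "avg_nap_minutes", "sppb_total")


class FitError(RuntimeError):
    """The multinomial fit is infeasible or failed to converge."""


@dataclass(frozen=True)
class ModelSpec:
    """Which exposure and covariate set to fit.

    exposure : "avg_cpm" | "pct_mid" | "pct_high" (tertile exposures) or
               "highly_sedentary" (binary)
    model    : "I" or "II"; Model II (additional adjustment for pct_high)
               is only used with the highly_sedentary exposure.
    """

    exposure: str
    model: str = "I"

    def __post_init__(self) -> None:
        if self.exposure not in TERTILE_EXPOSURES + ("highly_sedentary",):
            raise ValueError(f"unknown exposure {self.exposure!r}")
        if self.model not in ("I", "II"):
            raise ValueError("model must be 'I' or 'II'")
        if self.model == "II" and self.exposure != "highly_sedentary":
            raise ValueError("Model II is only used with the highly_sedentary exposure")
        if self.model == "I" and self.exposure == "highly_sedentary":
            pass  # permitted, but the adjusted analysis uses Model II

    @property
    def exposure_terms(self) -> tuple[str, ...]:
        if self.exposure == "highly_sedentary":
            return ("highly_sedentary",)
        return (f"{self.exposure}_middle", f"{self.exposure}_high")

    @property
    def covariate_terms(self) -> tuple[str, ...]:
        cov = MODEL_I_COVARIATES
        if self.model == "II":
            cov = cov + ("pct_high",)
        return cov


class TibMultinomialModel:
    """Three-category baseline-logit model of TIB category.

    Construct either from a raw design (``endog`` category labels plus an
    exog DataFrame that already includes a constant) or, for the standard
    analyses, with :meth:`from_dataframe` from an analysis table.
    """

    def __init__(
        self,
        endog: pd.Series | np.ndarray,
        exog: pd.DataFrame,
        exposure_terms: tuple[str, ...] = (),
        spec: ModelSpec | None = None,
        outcomes: tuple[str, ...] = OUTCOMES,
    ):
        # outcomes[0] is the reference; a 2-level tuple gives the binary
        # degenerate model (identical to logistic regression)
        self.outcomes = tuple(outcomes)
        y = pd.Categorical(endog, categories=list(self.outcomes))
        if y.isna().any():
            raise ValueError(f"endog contains values outside {self.outcomes}")
        counts = pd.Series(y).value_counts()
        empty = [c for c in self.outcomes if counts.get(c, 0) == 0]
        if empty:
            raise FitError(f"empty outcome category: {', '.join(empty)}")
        self.endog = y
        self.exog = exog.astype(float)
        if not (self.exog.std(axis=0) == 0).sum() == 1:
            raise ValueError("exog must contain exactly one constant column")
        rank = np.linalg.matrix_rank(self.exog.to_numpy())
        if rank < self.exog.shape[1]:
            raise FitError("collinear design columns")
        self.exposure_terms = tuple(exposure_terms)
        self.spec = spec
        self._sm_model = sm.MNLogit(np.asarray(y.codes), self.exog.to_numpy())

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, spec: ModelSpec) -> "TibMultinomialModel":
        """Build the design for a Model I/II analysis from an analysis table.

        Expects the columns written by the processing pipeline:
        ``tib_category``, the exposure column, ``age``, ``sex`` (or
        ``sex_female``), ``avg_nap_minutes``, ``sppb_total``, ``pct_high``.
        Tertile exposures are cut here with lowest tertile as reference.
        """
        df = table.copy()
        if "sex_female" not in df.columns:
            df["sex_female"] = (df["sex"] == "female").astype(float)
        design = pd.DataFrame(index=df.index)
        design["const"] = 1.0
        if spec.exposure == "highly_sedentary":
            design["highly_sedentary"] = df["highly_sedentary"].astype(float)
        else:
            tert = tertile_assign(df[spec.exposure].to_numpy())
            design[f"{spec.exposure}_middle"] = [
                1.0 if t == "middle" else 0.0 for t in tert
            ]
            design[f"{spec.exposure}_high"] = [
                1.0 if t == "high" else 0.0 for t in tert
            ]
        for term in spec.covariate_terms:
            design[term] = df[term].astype(float)
        return cls(
            df["tib_category"], design, exposure_terms=spec.exposure_terms, spec=spec
        )

    # -- estimation ---------------------------------------------------------

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> "TibMultinomialResults":
        res = self._sm_model.fit(method="newton", tol=tol, maxiter=maxiter, disp=0)
        if not res.mle_retvals.get("converged", False):
            raise FitError(
                "Newton iteration did not converge; check for perfect "
                f"separation among {list(self.exog.columns)}"
            )
        if not np.all(np.isfinite(np.asarray(res.bse))):
            big = self.exog.columns[
                ~np.all(np.isfinite(np.asarray(res.bse)), axis=1)
            ]
            raise FitError(f"non-finite standard error for term(s) {list(big)}")
        lr = None
        if self.exposure_terms:
            keep = [c for c in self.exog.columns if c not in self.exposure_terms]
            restricted = sm.MNLogit(
                np.asarray(self.endog.codes), self.exog[keep].to_numpy()
            ).fit(method="newton", tol=tol, maxiter=maxiter, disp=0)
            stat = 2.0 * (res.llf - restricted.llf)
            df_lr = len(self.exposure_terms) * (len(self.outcomes) - 1)
            lr = (float(stat), df_lr, float(stats.chi2.sf(stat, df_lr)))
        return TibMultinomialResults(self, res, lr)


class TibMultinomialResults:
    """Fitted coefficients, RRRs with Wald CIs, and probability machinery."""

    def __init__(self, model: TibMultinomialModel, sm_results, lr_test):
        self.model = model
        self._res = sm_results
        #: (stat, df, p) of the likelihood-ratio test of the exposure block
        self.lr_test = lr_test
        self.terms = list(model.exog.columns)
        self.nonref_outcomes = list(model.outcomes[1:])
        # statsmodels params: (n_terms, n_outcomes-1), columns ordered by code
        self.params = pd.DataFrame(
            np.asarray(sm_results.params),
            index=self.terms,
            columns=self.nonref_outcomes,
        )
        self.bse = pd.DataFrame(
            np.asarray(sm_results.bse), index=self.terms, columns=self.nonref_outcomes
        )
        self.llf = float(sm_results.llf)
        self.nobs = int(sm_results.nobs)

    # -- coefficient-scale results ------------------------------------------

    @property
    def rrr(self) -> pd.DataFrame:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald CI bounds for the RRRs, as a (term, outcome)-indexed frame."""
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        out = pd.concat(
            {"lower": lo, "upper": hi}, axis=1
        ).swaplevel(axis=1).sort_index(axis=1)
        return out

    @property
    def pvalues(self) -> pd.DataFrame:
        z = self.params / self.bse
        return pd.DataFrame(
            2 * stats.norm.sf(np.abs(z)), index=self.terms,
            columns=self.nonref_outcomes,
        )

    def rrr_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Tidy RRR table: one row per (outcome, term)."""
        z = stats.norm.ppf(1 - alpha / 2)
        rows = []
        for outcome in self.nonref_outcomes:
            for term in self.terms:
                if term == "const":
                    continue
                b = self.params.loc[term, outcome]
                se = self.bse.loc[term, outcome]
                rows.append(
                    {
                        "outcome": outcome,
                        "term": term,
                        "rrr": np.exp(b),
                        "ci_lower": np.exp(b - z * se),
                        "ci_upper": np.exp(b + z * se),
                        "p_value": self.pvalues.loc[term, outcome],
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        spec = self.model.spec
        head = [
            "Multinomial logit of TIB category (reference: UTIB)",
            f"n = {self.nobs}, log-likelihood = {self.llf:.3f}",
        ]
        if spec is not None:
            head.insert(1, f"Exposure: {spec.exposure}   Covariates: Model {spec.model}")
        if self.lr_test is not None:
            stat, df, p = self.lr_test
            head.append(
                f"Exposure LR test: chi2({df}) = {stat:.3f}, p = {p:.4f}"
            )
        tab = self.rrr_table()
        body = tab.to_string(
            index=False,
            formatters={
                "rrr": "{:.3f}".format,
                "ci_lower": "{:.3f}".format,
                "ci_upper": "{:.3f}".format,
                "p_value": "{:.4f}".format,
            },
        )
        return "\n".join(head) + "\n\n" + body

    # -- probability-scale results ------------------------------------------

    def _flat_cov(self) -> np.ndarray:
        return np.asarray(self._res.cov_params())

    def _flatten(self, grad: np.ndarray) -> np.ndarray:
        # cov_params orders parameters equation-major (all terms of STIB,
        # then all terms of RTIB) == Fortran ravel of the (term, outcome) grid
        return grad.ravel(order="F")

    def _reference_row(self) -> pd.Series:
        """Covariates at cohort means; binary dummies at means as well.

        With ``at='mode'`` semantics for categorical covariates use
        :meth:`predicted_probabilities`'s ``categorical`` switch.
        """
        return self.model.exog.mean(axis=0)

    def _design_point(
        self, at_level: object, categorical: str = "mode"
    ) -> np.ndarray:
        exog = self.model.exog
        x = exog.mean(axis=0)
        if categorical == "mode":
            for col in exog.columns:
                vals = exog[col].unique()
                if set(np.unique(vals)).issubset({0.0, 1.0}) and col != "const":
                    x[col] = exog[col].mode().iloc[0]
        spec = self.model.spec
        if at_level is None:
            return x.to_numpy()
        if spec is None:
            raise ValueError(
                "exposure levels need a ModelSpec; use from_dataframe"
            )
        if spec.exposure == "highly_sedentary":
            if at_level not in (0, 1, True, False):
                raise ValueError(f"exposure level must be 0/1, got {at_level!r}")
            x["highly_sedentary"] = float(at_level)
        else:
            if at_level not in ("low", "middle", "high"):
                raise ValueError(
                    f"exposure level must be low/middle/high, got {at_level!r}"
                )
            x[f"{spec.exposure}_middle"] = 1.0 if at_level == "middle" else 0.0
            x[f"{spec.exposure}_high"] = 1.0 if at_level == "high" else 0.0
        return x.to_numpy()

    def _probs_and_grad(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Category probabilities at x, and their gradients wrt flat params."""
        beta = self.params.to_numpy()              # (K, J-1)
        eta = np.concatenate([[0.0], x @ beta])    # (J,)
        eta -= eta.max()
        p = np.exp(eta)
        p /= p.sum()
        K, Jm1 = beta.shape
        n_out = len(self.model.outcomes)
        grads = np.empty((n_out, K * Jm1))
        for c in range(n_out):
            g = np.empty((K, Jm1))
            for j in range(Jm1):
                g[:, j] = p[c] * ((1.0 if c == j + 1 else 0.0) - p[j + 1]) * x
            grads[c] = self._flatten(g)
        return p, grads

    def predicted_probabilities(
        self,
        at: object = None,
        alpha: float = 0.05,
        categorical: str = "mode",
    ) -> pd.DataFrame:
        """P(UTIB), P(STIB), P(RTIB) at an exposure level, with delta CIs.

        ``at`` is an exposure level (``"low"/"middle"/"high"`` for tertile
        exposures, 0/1 for highly_sedentary) or None for the covariate-mean
        design point.  Continuous covariates sit at their means; binary
        covariates at their modes (``categorical="mean"`` uses means).
        """
        x = self._design_point(at, categorical=categorical)
        p, grads = self._probs_and_grad(x)
        V = self._flat_cov()
        se = np.sqrt(np.einsum("ij,jk,ik->i", grads, V, grads))
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "probability": p,
                "se": se,
                "ci_lower": p - z * se,
                "ci_upper": p + z * se,
            },
            index=list(self.model.outcomes),
        )

    def probability_contrast(
        self,
        level_a: object,
        level_b: object,
        alpha: float = 0.05,
        categorical: str = "mode",
    ) -> pd.DataFrame:
        """P(category | level_a) − P(category | level_b) with delta CIs."""
        xa = self._design_point(level_a, categorical=categorical)
        xb = self._design_point(level_b, categorical=categorical)
        pa, ga = self._probs_and_grad(xa)
        pb, gb = self._probs_and_grad(xb)
        diff = pa - pb
        g = ga - gb
        V = self._flat_cov()
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", g, V, g), 0.0))
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "contrast": diff,
                "se": se,
                "ci_lower": diff - z * se,
                "ci_upper": diff + z * se,
            },
            index=list(self.model.outcomes),
        )


def fit_multinomial(table: pd.DataFrame, spec: ModelSpec) -> TibMultinomialResults:
    """Convenience wrapper: build the Model I/II design and fit it."""
    return TibMultinomialModel.from_dataframe(table, spec).fit()
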