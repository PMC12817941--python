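"""Trend-moderated per-gene linear models and factorial contrasts.

Each gene's log2 CPM profile is modelled by ordinary least squares on a
cell-means design: one coefficient per (cell line, dose) cell of the
factorial layout, so every contrast of interest is an explicit linear
combination of cell means.  Per-gene residual variances ``s2_g`` (with
shared residual degrees of freedom ``d_g``) are then shrunk toward a
mean-expression trend by empirical Bayes:

* the trend ``s2_0(A)`` is a locally weighted regression of the (bias
  corrected) log residual variances on mean log2 CPM;
* the prior degrees of freedom ``d_0`` come from moment matching — the
  variance of the log variances in excess of the chi-square sampling
  variance ``trigamma(d_g/2)`` is inverted through the trigamma function;
* the posterior variance is ``(d_0 * s2_0 + d_g * s2_g) / (d_0 + d_g)``.

The moderated t-statistic for a contrast ``c`` is ``c'beta_hat`` over its
model-based standard error with the posterior variance, on ``d_0 + d_g``
degrees of freedom.  The contrasts named after the study design are:

* ``response(line, dose)`` — treatment vs mock within a cell line ("IFN
  response");
* ``effect(pert, ctrl, dose)`` — a perturbed line's response minus the
  control line's response (the contrast of contrasts: "KD effect" /
  "OE effect");
* ``baseline(pert, ctrl)`` — mock vs mock between lines.

Both raw p-values (the operative discovery threshold in this workflow) and
Benjamini-Hochberg adjusted p-values are always reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .counts import DOSES, DesignError, NormalizedExpression, SampleDesign

__all__ = [
    "DesignMatrix",
    "build_design",
    "ModeratedLinearModel",
    "ModeratedFitResults",
    "ContrastResult",
    "trigamma_inverse",
]


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on the monotone map)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


@dataclass(frozen=True)
class DesignMatrix:
    """Cell-means design: samples x (line, dose) indicator columns."""

    matrix: pd.DataFrame
    cells: list[tuple[str, str]]

    @property
    def coef_names(self) -> list[str]:
        return list(self.matrix.columns)

    def _coef_index(self, line: str, dose: str) -> int:
        name = f"{line}:{dose}"
        try:
            return self.coef_names.index(name)
        except ValueError:
            raise DesignError(
                f"no design cell {name!r}; available: {self.coef_names}"
            ) from None

    def response_contrast(self, line: str, dose: str) -> np.ndarray:
        """(line, dose) - (line, mock): the within-line treatment response."""
        if dose == "mock":
            raise DesignError("response contrast needs a non-mock dose")
        c = np.zeros(len(self.coef_names))
        c[self._coef_index(line, dose)] = 1.0
        c[self._coef_index(line, "mock")] = -1.0
        return c

    def effect_contrast(self, pert_line: str, control_line: str, dose: str) -> np.ndarray:
        """Perturbed line's response minus the control line's response."""
        return self.response_contrast(pert_line, dose) - self.response_contrast(control_line, dose)

    def baseline_contrast(self, pert_line: str, control_line: str) -> np.ndarray:
        """(pert, mock) - (ctrl, mock): expression difference before treatment."""
        c = np.zeros(len(self.coef_names))
        c[self._coef_index(pert_line, "mock")] = 1.0
        c[self._coef_index(control_line, "mock")] = -1.0
        return c


def build_design(d: SampleDesign) -> DesignMatrix:
    """Cell-means design matrix for one experiment's samples.

    One indicator column per (perturbation, dose) cell, named
    ``"{perturbation}:{dose}"``, in deterministic (sorted line, dose) order.
    """
    t = d.table
    if t["experiment"].nunique() > 1:
        raise DesignError(
            "build_design expects samples from a single experiment; "
            f"got {sorted(t['experiment'].unique())}"
        )
    lines = sorted(t["perturbation"].unique())
    doses = [d for d in DOSES if (t["dose"] == d).any()]
    cells = [(line, dose) for line in lines for dose in doses]
    present = set(zip(t["perturbation"], t["dose"]))
    missing = [c for c in cells if c not in present]
    if missing:
        raise DesignError(f"empty design cell(s): {missing}")
    cols = {}
    for line, dose in cells:
        cols[f"{line}:{dose}"] = (
            ((t["perturbation"] == line) & (t["dose"] == dose)).astype(float).to_numpy()
        )
    mat = pd.DataFrame(cols, index=t["sample_id"].to_numpy())
    if np.linalg.matrix_rank(mat.to_numpy()) < mat.shape[1]:
        raise DesignError("design matrix is rank deficient")
    return DesignMatrix(mat, cells)


def moderate_variances(
    s2: np.ndarray, df: float, amean: np.ndarray, trend_span: float = 0.5
) -> tuple[np.ndarray, float, np.ndarray]:
    """Empirical-Bayes variance moderation toward a mean-expression trend.

    Given per-gene residual variances ``s2`` on shared residual df, fits a
    lowess trend of the bias-corrected log variances on ``amean``, estimates
    the prior degrees of freedom ``d0`` by trigamma moment matching of the
    excess log-variance dispersion, and returns
    ``(s2_prior, d0, s2_posterior)`` with
    ``s2_posterior = (d0 * s2_prior + df * s2) / (d0 + df)`` (the trend
    itself when ``d0`` is infinite).
    """
    s2 = np.asarray(s2, float)
    amean = np.asarray(amean, float)
    d = float(df)
    ok = s2 > 0
    if not ok.any():
        # fully degenerate input (every gene fits exactly): nothing to learn,
        # leave the variances alone
        return s2.copy(), 0.0, s2.copy()
    # bias-corrected log variance: E[e] = log(sigma^2) for chi-square s2
    e = np.log(s2[ok]) - special.digamma(d / 2) + np.log(d / 2)
    a_ok = amean[ok]
    order = np.argsort(a_ok, kind="stable")
    fitted = lowess(e[order], a_ok[order], frac=trend_span, return_sorted=False)
    # map the trend back to every gene (including s2 == 0 genes)
    trend = np.interp(amean, a_ok[order], fitted)
    evar = float(np.var(e - trend[ok], ddof=1))
    excess = evar - float(special.polygamma(1, d / 2))
    if excess > 0:
        d0 = 2.0 * trigamma_inverse(excess)
        s20 = np.exp(trend + special.digamma(d0 / 2) - np.log(d0 / 2))
        s2_post = (d0 * s20 + d * s2) / (d0 + d)
    else:
        d0 = np.inf
        s20 = np.exp(trend)
        s2_post = s20.copy()
    return s20, float(d0), s2_post


@dataclass(frozen=True)
class ContrastResult:
    """Per-gene statistics for one named contrast."""

    name: str
    table: pd.DataFrame  # columns: log2fc, t, p_raw, p_adj

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def p_raw(self) -> pd.Series:
        return self.table["p_raw"]

    @property
    def p_adj(self) -> pd.Series:
        return self.table["p_adj"]

    def significant(self, alpha: float = 0.05, adjusted: bool = False) -> pd.Index:
        col = "p_adj" if adjusted else "p_raw"
        return self.table.index[self.table[col] < alpha]


class ModeratedLinearModel:
    """Per-gene cell-means linear model with trend-based variance moderation.

    Parameters
    ----------
    expr
        :class:`~lncperturb.counts.NormalizedExpression` or a log2 CPM
        DataFrame (genes x samples).
    design
        :class:`DesignMatrix` whose rows match the expression columns.
    """

    def __init__(self, expr: NormalizedExpression | pd.DataFrame, design: DesignMatrix):
        e = expr.log_cpm if isinstance(expr, NormalizedExpression) else expr
        if list(e.columns) != list(design.matrix.index):
            # align if same set, otherwise fail
            try:
                e = e[list(design.matrix.index)]
            except KeyError:
                raise DesignError("expression columns do not match design rows") from None
        self.exprs = e
        self.design = design
        n, p = design.matrix.shape
        if n - p <= 0:
            raise DesignError(f"no residual degrees of freedom (n={n}, p={p})")

    @classmethod
    def from_design_sheet(
        cls,
        expr: NormalizedExpression | pd.DataFrame,
        d: SampleDesign,
        experiment: str | None = None,
    ) -> "ModeratedLinearModel":
        """Build the model for one experiment's samples from the design sheet."""
        t = d.table
        if experiment is not None:
            t = t[t["experiment"] == experiment]
            if t.empty:
                raise DesignError(f"no samples for experiment {experiment!r}")
        sub = SampleDesign(t.reset_index(drop=True))
        dm = build_design(sub)
        e = expr.log_cpm if isinstance(expr, NormalizedExpression) else expr
        return cls(e[list(dm.matrix.index)], dm)

    def fit(self, trend_span: float = 0.5, min_genes_for_moderation: int = 10) -> "ModeratedFitResults":
        """OLS per gene, then empirical-Bayes moderation of the variances."""
        X = self.design.matrix.to_numpy(float)
        Y = self.exprs.to_numpy(float)  # genes x samples
        n, p = X.shape
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = Y @ X @ xtx_inv  # genes x p
        resid = Y - beta @ X.T
        d_resid = n - p
        s2 = np.einsum("ij,ij->i", resid, resid) / d_resid
        amean = Y.mean(axis=1)
        res = ModeratedFitResults(
            model=self,
            coefficients=pd.DataFrame(beta, index=self.exprs.index, columns=self.design.coef_names),
            residual_var=pd.Series(s2, index=self.exprs.index, name="s2"),
            df_residual=d_resid,
            amean=pd.Series(amean, index=self.exprs.index, name="amean"),
            xtx_inv=xtx_inv,
        )
        res._moderate(trend_span, min_genes_for_moderation)
        return res


@dataclass
class ModeratedFitResults:
    """Fitted cell means plus moderated variances; contrast evaluation lives here."""

    model: ModeratedLinearModel
    coefficients: pd.DataFrame
    residual_var: pd.Series
    df_residual: int
    amean: pd.Series
    xtx_inv: np.ndarray
    s2_prior: pd.Series | None = None
    df_prior: float | None = None
    s2_post: pd.Series | None = None
    moderated: bool = field(default=False)

    # -- moderation -------------------------------------------------------
    def _moderate(self, trend_span: float, min_genes: int) -> None:
        s2 = self.residual_var.to_numpy(float)
        d = float(self.df_residual)
        n_genes = s2.size
        if n_genes < min_genes:
            import warnings

            warnings.warn(
                f"only {n_genes} genes: variance moderation refused, using ordinary t",
                stacklevel=3,
            )
            self.s2_prior = self.residual_var.copy()
            self.df_prior = 0.0
            self.s2_post = self.residual_var.copy()
            self.moderated = False
            return
        s20, d0, s2_post = moderate_variances(
            s2, d, self.amean.to_numpy(float), trend_span=trend_span
        )
        self.s2_prior = pd.Series(s20, index=self.residual_var.index, name="s2_prior")
        self.df_prior = float(d0)
        self.s2_post = pd.Series(s2_post, index=self.residual_var.index, name="s2_post")
        self.moderated = True

    @property
    def df_total(self) -> float:
        return float(self.df_prior + self.df_residual)

    # -- contrasts --------------------------------------------------------
    def contrast(self, c: np.ndarray, name: str) -> ContrastResult:
        """Moderated t-test of the contrast ``c`` across all genes."""
        c = np.asarray(c, float)
        if c.shape != (self.coefficients.shape[1],):
            raise DesignError(
                f"contrast length {c.shape} does not match {self.coefficients.shape[1]} coefficients"
            )
        if not np.any(c):
            raise DesignError("zero contrast vector")
        log2fc = self.coefficients.to_numpy(float) @ c
        unscaled_se = float(np.sqrt(c @ self.xtx_inv @ c))
        se = np.sqrt(self.s2_post.to_numpy(float)) * unscaled_se
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, log2fc / se, 0.0)
        df = min(self.df_total, 1e6)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.clip(p, 0.0, 1.0)
        p_adj = multipletests(p, method="fdr_bh")[1]
        table = pd.DataFrame(
            {"log2fc": log2fc, "t": t, "p_raw": p, "p_adj": p_adj},
            index=self.coefficients.index,
        )
        return ContrastResult(name, table)

    def response(self, line: str, dose: str) -> ContrastResult:
        """Within-line IFN response: (line, dose) vs (line, mock)."""
        return self.contrast(
            self.model.design.response_contrast(line, dose), f"response:{line}:{dose}"
        )

    def effect(self, pert_line: str, control_line: str, dose: str) -> ContrastResult:
        """Contrast of contrasts: perturbed response minus control response."""
        return self.contrast(
            self.model.design.effect_contrast(pert_line, control_line, dose),
            f"effect:{pert_line}:{dose}",
        )

    def baseline(self, pert_line: str, control_line: str) -> ContrastResult:
        """Mock-vs-mock expression difference between two lines."""
        return self.contrast(
            self.model.design.baseline_contrast(pert_line, control_line),
            f"baseline:{pert_line}",
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "Moderated linear model (cell means, trend empirical Bayes)",
            f"  genes:                {self.coefficients.shape[0]}",
            f"  samples:              {self.model.design.matrix.shape[0]}",
            f"  coefficients (cells): {', '.join(self.coefficients.columns)}",
            f"  residual df per gene: {self.df_residual}",
            f"  prior df (d0):        {self.df_prior:.3g}",
            f"  total df:             {self.df_total:.3g}",
            f"  median s2 / s2_post:  {self.residual_var.median():.4g} / {self.s2_post.median():.4g}",
        ]
        return "\n".join(lines)
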