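"""Association analysis: does the genetic score predict serum vitamin D?

The analysis cohort carries serum 25(OH)D3 (Z-scored before modelling), a
supplementation indicator and daily dose, BMI, age, sex, MS case/control
status, and the Z-scored genetic risk score.  Four pieces reproduce the
analysis pipeline:

* an age/sex-adjusted predictor screen with Benjamini–Hochberg FDR;
* the multivariable model  vd_z ~ grs_z + age + sex + bmi + supplementing +
  ms_status, fitted on the whole cohort and within supplementation strata;
* the adjusted-R² gain from adding the score to the covariate-only model;
* per-variant 2x3 chi-square tests of genotype distribution between cases
  and controls.

The statsmodels-style entry point is :class:`VitaminDGrsModel`, whose
``fit()`` returns a :class:`VitaminDGrsResults` with tidy tables, a text
``summary()``, and a stratified scatter plot.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .score import zscore

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sample_id", "vd_level", "supplementing", "dose", "bmi", "age", "sex", "ms_status")
STRATA = ("all", "non_supplementers", "supplementers")
BASE_COVARIATES = ("age", "sex", "bmi", "supplementing", "ms_status")
DEFAULT_SCREEN = ("supplementing", "log_dose", "bmi", "age", "ms_status")


class SingularDesignError(ValueError):
    """The design matrix is rank deficient (collinear or constant terms)."""


class CohortTable:
    """Validated per-sample phenotype/covariate table.

    Wraps a DataFrame with columns sample_id, vd_level (serum 25(OH)D3,
    nmol/L), supplementing (bool), dose (IU/day, 0 for non-supplementers),
    bmi, age, sex ('F'/'M' or 0/1), ms_status (bool), and optionally grs_z.
    Adds vd_z (cohort-wide Z-score of vd_level) and log_dose = log(1 + dose).
    """

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table lacks column(s) {missing}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id in cohort table (e.g. {dup!r})")
        dosed = df["dose"].fillna(0) > 0
        if (dosed & ~df["supplementing"].astype(bool)).any():
            raise ValueError("dose > 0 for a sample marked not supplementing")
        df["supplementing"] = df["supplementing"].astype(bool)
        df["ms_status"] = df["ms_status"].astype(bool)
        if df["sex"].dtype == object:
            df["sex"] = (df["sex"].astype(str).str.upper().str[0] == "F").astype(int)
        df["log_dose"] = np.log1p(df["dose"].fillna(0).astype(float))
        if "vd_z" not in df.columns:
            df["vd_z"] = zscore(df["vd_level"]).to_numpy()
        self.frame = df

    @classmethod
    def from_tsv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path, sep="\t"))

    def with_scores(self, scores) -> "CohortTable":
        """Join a :class:`~vdgrs.score.ScoreResult` (or Series) as grs_z."""
        z = scores.z if hasattr(scores, "z") else pd.Series(scores)
        df = self.frame.copy()
        df["grs_z"] = df["sample_id"].map(z)
        n_lost = int(df["grs_z"].isna().sum())
        if n_lost:
            logger.info("score join: %d samples without a GRS", n_lost)
        return CohortTable(df)

    def __len__(self) -> int:
        return len(self.frame)


class R2Delta(NamedTuple):
    r2_base: float
    r2_full: float
    delta: float


def _design(df: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    X = df[list(terms)].astype(float)
    return sm.add_constant(X, has_constant="add")


def fit_linear_model(
    cohort: CohortTable | pd.DataFrame,
    response: str,
    terms: Sequence[str],
    *,
    stratum: str = "all",
):
    """OLS of ``response`` on ``terms`` (plus intercept), complete cases.

    Returns ``(table, fitted)``: a tidy DataFrame (term, stratum, estimate,
    se, p, n, covariates) excluding the intercept, and the statsmodels
    results object for diagnostics (R², residuals, ...).
    """
    df = cohort.frame if isinstance(cohort, CohortTable) else cohort
    cols = [response, *terms]
    data = df[cols].apply(pd.to_numeric, errors="coerce")
    complete = data.dropna()
    n_dropped = len(data) - len(complete)
    if n_dropped:
        logger.info("complete-case analysis: excluded %d of %d samples", n_dropped, len(data))
    if len(complete) < len(terms) + 2:
        raise ValueError(f"too few complete cases ({len(complete)}) for {len(terms)} terms")
    X = _design(complete, terms)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        const = [c for c in terms if complete[c].nunique() <= 1]
        raise SingularDesignError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"constant/collinear terms: {const or 'correlated covariates'}"
        )
    fit = sm.OLS(complete[response].astype(float), X).fit()
    rows = [
        {
            "term": t,
            "stratum": stratum,
            "estimate": fit.params[t],
            "se": fit.bse[t],
            "p": fit.pvalues[t],
            "n": int(fit.nobs),
            "covariates": ",".join(c for c in terms if c != t),
        }
        for t in terms
    ]
    return pd.DataFrame(rows), fit


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def screen_predictors(
    cohort: CohortTable,
    candidates: Sequence[str] = DEFAULT_SCREEN,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Age/sex-adjusted single-predictor screen with BH-FDR.

    Each candidate is fitted as ``vd_z ~ candidate + age + sex`` (adjusters
    already in the candidate set are not duplicated); candidate-term p-values
    are BH-adjusted across the screen and flagged at FDR < ``alpha``.
    """
    rows = []
    for cand in candidates:
        adjusters = [a for a in ("age", "sex") if a != cand]
        table, _ = fit_linear_model(cohort, "vd_z", [cand, *adjusters])
        rows.append(table[table["term"] == cand].iloc[0])
    out = pd.DataFrame(rows).reset_index(drop=True)
    out["q"] = bh_adjust(out["p"])
    out["pass_fdr"] = out["q"] < alpha
    return out


def grs_association(cohort: CohortTable, covariates: Sequence[str] = BASE_COVARIATES) -> pd.DataFrame:
    """Multivariable GRS models: whole cohort and supplementation strata.

    Whole cohort: vd_z ~ grs_z + age + sex + bmi + supplementing + ms_status.
    Within each stratum the supplementing indicator is constant and dropped;
    ms_status is retained (and dropped automatically when constant, e.g. a
    controls-only cohort).  Empty strata are skipped with a warning.
    """
    frames = []
    df = cohort.frame
    for stratum in STRATA:
        if stratum == "all":
            sub = df
        elif stratum == "supplementers":
            sub = df[df["supplementing"]]
        else:
            sub = df[~df["supplementing"]]
        if len(sub) == 0:
            logger.warning("stratum %s is empty; skipped", stratum)
            continue
        terms = ["grs_z", *covariates]
        if stratum != "all":
            terms = [t for t in terms if t != "supplementing"]
        terms = [t for t in terms if sub[t].nunique() > 1]  # drop constants
        try:
            table, _ = fit_linear_model(sub, "vd_z", terms, stratum=stratum)
        except ValueError as exc:
            logger.warning("stratum %s skipped: %s", stratum, exc)
            continue
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def adjusted_r2_delta(cohort: CohortTable, covariates: Sequence[str] = BASE_COVARIATES) -> R2Delta:
    """Adjusted R² of the covariate-only model, the +GRS model, and the gain."""
    _, base = fit_linear_model(cohort, "vd_z", list(covariates))
    _, full = fit_linear_model(cohort, "vd_z", ["grs_z", *covariates])
    return R2Delta(float(base.rsquared_adj), float(full.rsquared_adj), float(full.rsquared_adj - base.rsquared_adj))


def genotype_distribution_test(case_counts, control_counts) -> float | pd.Series:
    """Chi-square homogeneity test of genotype counts between cases and controls.

    Inputs are genotype counts (n0, n1, n2 effect-allele copies) for each
    group: length-3 sequences for one variant (returns a float p-value) or
    mappings/DataFrames keyed by variant (returns a Series).  Genotype
    columns with zero total are collapsed, reducing the degrees of freedom.
    """
    if isinstance(case_counts, (pd.DataFrame, dict)):
        case_df = pd.DataFrame(case_counts).T if isinstance(case_counts, dict) else case_counts
        ctrl_df = pd.DataFrame(control_counts).T if isinstance(control_counts, dict) else control_counts
        return pd.Series(
            {rid: genotype_distribution_test(case_df.loc[rid], ctrl_df.loc[rid]) for rid in case_df.index},
            name="p",
        )
    table = np.asarray([case_counts, control_counts], dtype=float)
    if table.shape != (2, 3) or np.any(table < 0):
        raise ValueError("expected non-negative 2x3 genotype count tables")
    if table.sum() == 0:
        raise ValueError("genotype distribution test undefined for all-zero counts")
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2 or np.any(table.sum(axis=1) == 0):
        return 1.0  # a single genotype column (or an empty group) cannot differ
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


# ---------------------------------------------------------------------------
# model / results objects


class VitaminDGrsModel:
    """GRS → serum vitamin D association model for one cohort.

    Parameters
    ----------
    cohort : CohortTable or DataFrame
        Phenotypes with a populated ``grs_z`` column (see
        :meth:`from_components` to join scores yourself).
    covariates : sequence of str
        Adjustment set for the multivariable model; defaults to age, sex,
        BMI, supplementation and MS status.
    """

    def __init__(self, cohort, covariates: Sequence[str] = BASE_COVARIATES):
        self.cohort = cohort if isinstance(cohort, CohortTable) else CohortTable(cohort)
        if "grs_z" not in self.cohort.frame.columns:
            raise ValueError("cohort has no grs_z column; join scores first (from_components)")
        self.covariates = tuple(covariates)

    @classmethod
    def from_components(cls, phenotypes, scores, covariates: Sequence[str] = BASE_COVARIATES):
        """Build from a phenotype table plus a ScoreResult / grs_z Series."""
        table = phenotypes if isinstance(phenotypes, CohortTable) else CohortTable(phenotypes)
        return cls(table.with_scores(scores), covariates)

    def fit(self, screen: bool = True, screen_candidates: Sequence[str] = DEFAULT_SCREEN):
        assoc = grs_association(self.cohort, self.covariates)
        r2 = adjusted_r2_delta(self.cohort, self.covariates)
        screen_table = screen_predictors(self.cohort, screen_candidates) if screen else None
        return VitaminDGrsResults(self, assoc, r2, screen_table)


@dataclass
class VitaminDGrsResults:
    """Fitted association results: tidy tables, summary, and plotting."""

    model: VitaminDGrsModel
    associations: pd.DataFrame
    r2: R2Delta
    screen: pd.DataFrame | None = None

    def grs_estimate(self, stratum: str = "all") -> pd.Series:
        t = self.associations
        return t[(t["term"] == "grs_z") & (t["stratum"] == stratum)].iloc[0]

    def summary(self) -> str:
        lines = ["Vitamin D GRS association", "=" * 60]
        for stratum in STRATA:
            sub = self.associations[self.associations["stratum"] == stratum]
            if sub.empty:
                continue
            lines.append(f"\n[{stratum}]  n = {int(sub['n'].iloc[0])}")
            lines.append(f"{'term':<14}{'estimate':>10}{'se':>9}{'p':>12}")
            for _, r in sub.iterrows():
                lines.append(f"{r['term']:<14}{r['estimate']:>10.4f}{r['se']:>9.4f}{r['p']:>12.3g}")
        lines.append(
            f"\nadjusted R²: base {self.r2.r2_base:.3f} → with GRS {self.r2.r2_full:.3f}"
            f" (Δ = {self.r2.delta:.3f})"
        )
        if self.screen is not None:
            lines.append("\npredictor screen (age/sex-adjusted, BH-FDR):")
            lines.append(f"{'term':<14}{'estimate':>10}{'p':>12}{'q':>12}  FDR<5%")
            for _, r in self.screen.iterrows():
                flag = "yes" if r["pass_fdr"] else "no"
                lines.append(f"{r['term']:<14}{r['estimate']:>10.4f}{r['p']:>12.3g}{r['q']:>12.3g}  {flag}")
        return "\n".join(lines)

    def plot_stratified(self, ax_pair=None):
        """Scatter of covariate-adjusted vd_z against grs_z per stratum.

        Vitamin D is residualized on the non-GRS covariates within each
        stratum (partial regression), then plotted against the score with
        the stratum's fitted line.
        """
        import matplotlib.pyplot as plt

        if ax_pair is None:
            fig, ax_pair = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        else:
            fig = ax_pair[0].figure
        df = self.model.cohort.frame
        for ax, (label, mask) in zip(
            ax_pair,
            [("non-supplementers", ~df["supplementing"]), ("supplementers", df["supplementing"])],
        ):
            sub = df[mask].dropna(subset=["vd_z", "grs_z"])
            if sub.empty:
                ax.set_title(f"{label} (empty)")
                continue
            covs = [c for c in self.model.covariates if c != "supplementing" and sub[c].nunique() > 1]
            if covs:
                _, cov_fit = fit_linear_model(sub, "vd_z", covs)
                resid = cov_fit.resid
            else:
                resid = sub["vd_z"] - sub["vd_z"].mean()
            ax.scatter(sub.loc[resid.index, "grs_z"], resid, s=8, alpha=0.5)
            slope, intercept = np.polyfit(sub.loc[resid.index, "grs_z"], resid, 1)
            xs = np.linspace(sub["grs_z"].min(), sub["grs_z"].max(), 20)
            ax.plot(xs, intercept + slope * xs, color="crimson")
            ax.set_title(label)
            ax.set_xlabel("GRS (Z-score)")
        ax_pair[0].set_ylabel("adjusted serum vD (Z-score)")
        fig.tight_layout()
        return fig

    def to_tsv(self, path) -> None:
        self.associations.to_csv(path, sep="\t", index=False)
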