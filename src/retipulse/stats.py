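"""Mixed-effects group comparison of log pulse-amplitude summaries.

Observations are vessel x force-level summaries (mean/max log amplitude
or amplitude slope), repeated within eyes across induced-IOP levels and
within participants across eyes. The model is a linear mixed-effects
regression with fixed effects for study group, age, sex, induced IOP and
POAG status, and random intercepts for participant and eye-within-
participant (the eye intercept absorbs laterality and the IOP repeats).
Group contrasts are Wald z-tests evaluated against a Bonferroni-
corrected alpha (0.05 / 5 = 0.01 for the five comparisons against a
reference group).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = [
    "LmmFit",
    "GroupComparison",
    "fit_lmm",
    "pairwise_contrasts",
    "bonferroni_alpha",
    "qq_points",
]



@dataclass
class LmmFit:
    """A fitted mixed model plus the bookkeeping contrasts need."""

    result: object  # statsmodels MixedLMResults
    response: str
    vessel_label: str
    reference: str
    group_levels: list[str]
    group_means: pd.DataFrame  # observed per-group mean/sd/n of the response
    simplified: bool  # True when the random structure was reduced to eye-only

    @property
    def residuals(self) -> np.ndarray:
        return np.asarray(self.result.resid)

    def group_coefficient(self, group: str) -> str | None:
        """Name of the fixed-effect parameter for ``group`` vs the reference."""
        if group == self.reference:
            return None
        return f"C(group_id, Treatment('{self.reference}'))[T.{group}]"


def fit_lmm(
    table: pd.DataFrame,
    response: str = "mean_logamp",
    vessel_label: str = "vein",
    reference: str = "N1_N1",
) -> LmmFit:
    """Fit the mixed model for one response and vessel class.

    Fixed effects: study group (treatment-coded against ``reference``),
    age, sex, induced IOP and POAG. Random effects: participant
    intercept plus eye-within-participant intercept. A singular or
    non-converging fit is retried with the simplified structure (random
    intercept for eye only) and flagged.
    """
    data = table[table["vessel_label"] == vessel_label].copy()
    data = data.dropna(subset=[response])
    groups_present = sorted(data["group_id"].unique())
    if len(groups_present) < 2:
        raise ValueError("group comparison needs at least two groups present")
    if reference not in groups_present:
        raise ValueError(f"reference group {reference!r} absent from the data")

    # drop degenerate covariates (constant within the analysed subset)
    terms = [f"C(group_id, Treatment('{reference}'))"]
    if data["age"].nunique() > 1:
        terms.append("age")
    if data["sex"].nunique() > 1:
        terms.append("C(sex)")
    if data["induced_iop"].nunique() > 1:
        terms.append("induced_iop")
    if data["poag"].nunique() > 1:
        terms.append("C(poag)")
    formula = f"{response} ~ " + " + ".join(terms)
    observed = (
        data.groupby("group_id")[response]
        .agg(["mean", "std", "count"])
        .rename(columns={"mean": "marginal_mean", "std": "sd", "count": "n"})
        .reset_index()
    )

    multi_eye = data.groupby("participant_id")["eye_id"].nunique().max() > 1

    def _try(structure: str):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if structure == "full":
                model = smf.mixedlm(
                    formula,
                    data,
                    groups=data["participant_id"],
                    re_formula="1",
                    vc_formula={"eye": "0 + C(eye_id)"},
                )
            elif structure == "eye":
                model = smf.mixedlm(formula, data, groups=data["eye_id"])
            else:  # no random effects left: ordinary least squares
                return smf.ols(formula, data).fit()
            for method in ("lbfgs", "powell"):
                try:
                    result = model.fit(reml=True, method=method)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                ok = result.converged and np.all(
                    np.isfinite(result.bse.iloc[: len(groups_present)])
                )
                if ok:
                    return result
            return None

    # the eye-within-participant component is only identifiable when some
    # participant contributes both eyes; otherwise start from the eye model
    structures = ["full", "eye", "ols"] if multi_eye else ["eye", "ols"]
    result = None
    simplified = False
    for structure in structures:
        result = _try(structure)
        if result is not None:
            simplified = structure != structures[0]
            if simplified:
                logger.warning(
                    "mixed model singular or non-converged; using %s structure",
                    structure,
                )
            break

    return LmmFit(
        result=result,
        response=response,
        vessel_label=vessel_label,
        reference=reference,
        group_levels=groups_present,
        group_means=observed,
        simplified=simplified,
    )


@dataclass
class GroupComparison:
    """One Wald contrast between two study groups."""

    response: str
    vessel_label: str
    group_a: str
    group_b: str
    estimate: float
    se: float
    p_value: float
    significant: bool
    alpha: float


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-comparison alpha for ``m`` comparisons (family alpha / m)."""
    if m < 1:
        raise ValueError("number of comparisons must be at least 1")
    if not 0.0 < family_alpha < 1.0:
        raise ValueError("family alpha must lie in (0, 1)")
    return family_alpha / m


def pairwise_contrasts(
    fit: LmmFit,
    reference: str | None = None,
    family_alpha: float = 0.05,
    m: int | None = None,
) -> list[GroupComparison]:
    """Wald z contrasts of each group against the reference.

    With six study groups this yields the five per-reference comparisons;
    each is judged against the Bonferroni-corrected alpha
    (``family_alpha / m``, m defaulting to the number of contrasts).
    Groups absent from the fit are skipped.
    """
    reference = reference or fit.reference
    if reference != fit.reference:
        raise ValueError("contrast reference must match the fitted treatment coding")
    others = [g for g in fit.group_levels if g != reference]
    m = m if m is not None else len(others)
    alpha = bonferroni_alpha(family_alpha, m)
    params = fit.result.params
    bse = fit.result.bse
    out = []
    for g in others:
        name = fit.group_coefficient(g)
        if name not in params.index:
            logger.info("group %s absent from fit; contrast skipped", g)
            continue
        est = float(params[name])
        se = float(bse[name])
        z = est / se if se > 0 else np.inf * np.sign(est)
        p = float(2.0 * sps.norm.sf(abs(z)))
        out.append(
            GroupComparison(
                response=fit.response,
                vessel_label=fit.vessel_label,
                group_a=g,
                group_b=reference,
                estimate=est,
                se=se,
                p_value=p,
                significant=bool(p < alpha),
                alpha=alpha,
            )
        )
    return out


def contrasts_to_table(contrasts: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in contrasts])


def qq_points(residuals: np.ndarray, plot_path=None) -> tuple[np.ndarray, np.ndarray, bool]:
    """Normal quantile-quantile pairs for a residual vector.

    Returns ``(theoretical, sample, degenerate)``: ordered residuals
    paired with standard-normal quantiles at plotting positions
    ``(i - 0.5) / n``; ``degenerate`` flags a constant residual vector
    (flat line, no normality information).
    """
    r = np.sort(np.asarray(residuals, dtype=float))
    n = r.size
    if n < 3:
        raise ValueError("q-q diagnostics need at least three residuals")
    theo = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    degenerate = bool(np.ptp(r) == 0.0)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        ax.plot(theo, r, "o", ms=3)
        lim = [min(theo.min(), r.min()), max(theo.max(), r.max())]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel("theoretical quantiles")
        ax.set_ylabel("sample quantiles")
        fig.savefig(plot_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return theo, r, degenerate
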