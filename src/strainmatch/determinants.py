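"""Determinants of engraftment efficiency.

Assembles one row per true (donor, recipient) pairing carrying the
engraftment efficiency together with the candidate explanatory covariates
(donor and recipient alpha-diversity, mean donor-recipient species and
functional beta-diversity, Prevotella/Bacteroides ratios, donor batch size)
and provides the statistics used on it: Pearson correlation with a linear
fit, Kruskal-Wallis/ANOVA omnibus tests with Dunn/Tukey post-hocs, and
linear mixed models with donor and recipient random intercepts compared by
likelihood-ratio test.

Mixed models are fitted with statsmodels' MixedLM; the two crossed random
intercepts are expressed as variance components over a single trivial
grouping, and the likelihood-ratio test compares maximum-likelihood (not
REML) fits because the competing models differ in their fixed effects.
Fixed-effect confidence intervals are Wald intervals (the fitter does not
profile), tagged as such in the output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .metrics import bray_curtis, jaccard_binary, pb_ratio, shannon_index
from .matching import baseline_sample_map

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = [
    "donor_id",
    "recipient_id",
    "efficiency",
    "donor_alpha_mean",
    "recipient_alpha_baseline",
    "bc_species_mean",
    "jaccard_species_mean",
    "bc_functional_mean",
    "donor_pb_mean",
    "recipient_pb",
    "batch_size",
]


def build_covariate_table(
    efficiency_records: pd.DataFrame,
    abundance: pd.DataFrame,
    functional: pd.DataFrame | None,
    roster: pd.DataFrame,
    reference,
) -> pd.DataFrame:
    """One covariate row per true (donor, recipient) pairing.

    Donor-level covariates are arithmetic means over the donor's samples;
    donor-recipient dissimilarities are averaged over donor samples against
    the recipient's baseline sample (not computed on mean profiles).  Rows
    whose functional profiles are unavailable carry NaN in
    ``bc_functional_mean``.
    """
    from .evaluation import as_reference

    ref = as_reference(reference)
    species_cols = [c for c in abundance.columns if c != "UNKNOWN"]
    baselines = baseline_sample_map(roster)
    donor_rows = roster[roster["role"] == "donor"]
    donor_samples = donor_rows.groupby("subject_id")["sample_id"].apply(list)

    eff = efficiency_records.set_index(["donor", "recipient"])["efficiency"]
    rows = []
    for recipient, donors in sorted(ref.items()):
        base = baselines.get(recipient)
        if base is None or base not in abundance.index:
            raise ValueError(
                f"recipient {recipient} lacks a baseline abundance profile"
            )
        base_prof = abundance.loc[base, species_cols]
        r_alpha = shannon_index(base_prof.to_numpy())
        r_pb = pb_ratio(base_prof)
        for donor in sorted(donors):
            samples = donor_samples.get(donor)
            if not samples:
                raise ValueError(f"donor {donor} has no samples in roster")
            missing = [s for s in samples if s not in abundance.index]
            if missing:
                raise ValueError(
                    f"donor samples missing from abundance table: {missing}"
                )
            profs = [abundance.loc[s, species_cols] for s in samples]
            d_alpha = float(
                np.mean([shannon_index(p.to_numpy()) for p in profs])
            )
            d_pb = float(np.mean([pb_ratio(p) for p in profs]))
            bc = float(
                np.mean(
                    [bray_curtis(p.to_numpy(), base_prof.to_numpy()) for p in profs]
                )
            )
            jc = float(
                np.mean(
                    [
                        jaccard_binary(p.to_numpy(), base_prof.to_numpy())
                        for p in profs
                    ]
                )
            )
            bc_func = float("nan")
            if functional is not None and base in functional.index:
                fps = [s for s in samples if s in functional.index]
                if fps:
                    fb = functional.loc[base].to_numpy()
                    bc_func = float(
                        np.mean(
                            [
                                bray_curtis(functional.loc[s].to_numpy(), fb)
                                for s in fps
                            ]
                        )
                    )
            rows.append(
                {
                    "donor_id": donor,
                    "recipient_id": recipient,
                    "efficiency": float(eff.get((donor, recipient), np.nan)),
                    "donor_alpha_mean": d_alpha,
                    "recipient_alpha_baseline": r_alpha,
                    "bc_species_mean": bc,
                    "jaccard_species_mean": jc,
                    "bc_functional_mean": bc_func,
                    "donor_pb_mean": d_pb,
                    "recipient_pb": r_pb,
                    "batch_size": len(donors),
                }
            )
    table = pd.DataFrame(rows, columns=COVARIATE_COLUMNS)
    return table.sort_values(["recipient_id", "donor_id"], ignore_index=True)


# ---------------------------------------------------------------------------
# Mixed models
# ---------------------------------------------------------------------------


@dataclass
class MixedModelSpec:
    """Fixed-effect structure of an efficiency mixed model.

    ``interactions`` lists pairs of fixed-effect names; random intercepts
    for donor and recipient identity are always included.
    """

    fixed_effects: list[str]
    interactions: list[tuple[str, str]] = field(default_factory=list)
    response: str = "efficiency"

    def __post_init__(self) -> None:
        for a, b in self.interactions:
            if a not in self.fixed_effects or b not in self.fixed_effects:
                raise ValueError(
                    f"interaction ({a}, {b}) references absent fixed effect"
                )

    def formula(self) -> str:
        terms = list(self.fixed_effects) + [
            f"{a}:{b}" for a, b in self.interactions
        ]
        rhs = " + ".join(terms) if terms else "1"
        return f"{self.response} ~ {rhs}"

    def covariates(self) -> list[str]:
        return list(self.fixed_effects)


@dataclass
class ModelFit:
    """Fitted mixed model: per-effect estimates with Wald CIs and p-values."""

    effects: pd.DataFrame  # effect, estimate, ci_low, ci_high, p_value
    log_likelihood: float
    n_obs: int
    converged: bool
    singular: bool
    method: str  # "REML" or "ML"
    ci_method: str = "wald"


def _fit_lmm(
    data: pd.DataFrame, formula: str, reml: bool
) -> tuple[ModelFit, object]:
    df = data.copy()
    df["_group"] = 1
    vc = {
        "donor": "0 + C(donor_id)",
        "recipient": "0 + C(recipient_id)",
    }
    model = smf.mixedlm(
        formula, df, groups="_group", vc_formula=vc, re_formula="0"
    )
    singular = False
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for optimiser in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                candidate = model.fit(reml=reml, method=optimiser)
            except (np.linalg.LinAlgError, ValueError):
                continue
            res = candidate
            if candidate.converged and np.isfinite(
                np.asarray(candidate.bse_fe, dtype=float)
            ).all():
                break
        if res is None:
            raise RuntimeError("mixed-model fit failed with every optimiser")
    vcs = np.asarray(res.vcomp, dtype=float)
    if (vcs < 1e-8).any():
        singular = True
        logger.warning("singular random-effect fit (a variance component ~ 0)")
    fe_names = res.model.exog_names
    ci = res.conf_int().loc[fe_names]
    effects = pd.DataFrame(
        {
            "effect": fe_names,
            "estimate": res.params[fe_names].to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
            "p_value": res.pvalues[fe_names].to_numpy(),
        }
    )
    fit = ModelFit(
        effects=effects,
        log_likelihood=float(res.llf),
        n_obs=int(res.nobs),
        converged=bool(res.converged),
        singular=singular,
        method="REML" if reml else "ML",
    )
    return fit, res


def _complete_cases(
    table: pd.DataFrame, spec: MixedModelSpec
) -> pd.DataFrame:
    cols = [spec.response] + spec.covariates()
    data = table.replace([np.inf, -np.inf], np.nan)
    kept = data.dropna(subset=cols)
    dropped = len(table) - len(kept)
    if dropped:
        logger.info(
            "dropped %d incomplete rows for model %s", dropped, spec.formula()
        )
    return kept


def _without(spec: MixedModelSpec, drop: list[str]) -> MixedModelSpec:
    return MixedModelSpec(
        fixed_effects=[c for c in spec.fixed_effects if c not in drop],
        interactions=[
            (a, b)
            for a, b in spec.interactions
            if a not in drop and b not in drop
        ],
        response=spec.response,
    )


def fit_mixed_models(
    table: pd.DataFrame,
    spec_full: MixedModelSpec,
    spec_reduced: MixedModelSpec,
    standardise: bool = False,
    reml: bool = True,
) -> tuple[ModelFit, ModelFit, float]:
    """Fit full and reduced mixed models and compare them by LRT.

    Both models use donor and recipient random intercepts.  Reported
    estimates come from the ``reml`` fits; the likelihood-ratio test always
    compares maximum-likelihood fits of the two fixed-effect structures on
    the union complete-case rows.  Returns (full fit, reduced fit, LRT p).
    """
    cols = sorted(set(spec_full.covariates()) | set(spec_reduced.covariates()))
    union_spec = MixedModelSpec(fixed_effects=cols, response=spec_full.response)
    data = _complete_cases(table, union_spec)
    constant = [c for c in cols if data[c].nunique() <= 1]
    if constant:
        logger.warning(
            "zero-variance covariates dropped from both models: %s", constant
        )
        spec_full = _without(spec_full, constant)
        spec_reduced = _without(spec_reduced, constant)
        cols = [c for c in cols if c not in constant]
    if data["donor_id"].nunique() < 2 or data["recipient_id"].nunique() < 2:
        raise ValueError("need >= 2 donors and >= 2 recipients for random effects")
    if standardise:
        data = data.copy()
        for c in cols:
            sd = data[c].std()
            if sd > 0:
                data[c] = (data[c] - data[c].mean()) / sd

    full_fit, full_res = _fit_lmm(data, spec_full.formula(), reml)
    red_fit, red_res = _fit_lmm(data, spec_reduced.formula(), reml)

    if reml:
        full_ml, full_ml_res = _fit_lmm(data, spec_full.formula(), False)
        red_ml, red_ml_res = _fit_lmm(data, spec_reduced.formula(), False)
    else:
        full_ml, full_ml_res = full_fit, full_res
        red_ml, red_ml_res = red_fit, red_res
    df_diff = len(full_ml_res.model.exog_names) - len(
        red_ml_res.model.exog_names
    )
    if df_diff == 0:
        lrt_p = 1.0
    else:
        lr = 2.0 * (full_ml.log_likelihood - red_ml.log_likelihood)
        lrt_p = float(stats.chi2.sf(max(lr, 0.0), df=abs(df_diff)))
    return full_fit, red_fit, lrt_p


def full_model_spec(include_batch_size: bool = True) -> MixedModelSpec:
    """The full efficiency model: all covariates plus the donor-recipient
    alpha-diversity and P/B-ratio interactions."""
    fixed = [
        "donor_alpha_mean",
        "recipient_alpha_baseline",
        "bc_species_mean",
        "jaccard_species_mean",
        "bc_functional_mean",
        "donor_pb_mean",
        "recipient_pb",
    ]
    if include_batch_size:
        fixed.append("batch_size")
    return MixedModelSpec(
        fixed_effects=fixed,
        interactions=[
            ("donor_alpha_mean", "recipient_alpha_baseline"),
            ("donor_pb_mean", "recipient_pb"),
        ],
    )


def reduced_model_spec(include_batch_size: bool = True) -> MixedModelSpec:
    """The reduced model: same covariates, no interactions."""
    spec = full_model_spec(include_batch_size)
    return MixedModelSpec(fixed_effects=spec.fixed_effects, interactions=[])


def category_difference_covariates(
    table: pd.DataFrame,
    functional: pd.DataFrame,
    roster: pd.DataFrame,
) -> pd.DataFrame:
    """Per-pairing mean donor-minus-recipient functional category differences.

    For each pairing in the covariate table, each COG category contributes a
    ``cat_<category>`` column holding mean(donor samples) minus the recipient
    baseline renormalised relative abundance.  Pairings lacking functional
    profiles on either side are omitted.
    """
    baselines = baseline_sample_map(roster)
    donor_rows = roster[roster["role"] == "donor"]
    donor_samples = donor_rows.groupby("subject_id")["sample_id"].apply(list)

    cats = list(functional.columns)
    rows = []
    for _, row in table.iterrows():
        base = baselines.get(row["recipient_id"])
        samples = [
            s
            for s in donor_samples.get(row["donor_id"], [])
            if s in functional.index
        ]
        if base is None or base not in functional.index or not samples:
            continue
        diff = functional.loc[samples].mean(axis=0) - functional.loc[base]
        rec = {f"cat_{c}": diff[c] for c in cats}
        rec.update(
            donor_id=row["donor_id"],
            recipient_id=row["recipient_id"],
            efficiency=row["efficiency"],
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def per_category_difference_model(
    table: pd.DataFrame,
    functional: pd.DataFrame,
    roster: pd.DataFrame,
) -> ModelFit:
    """Mixed model of efficiency on per-category functional differences.

    Fixed effects are the :func:`category_difference_covariates` columns;
    donor and recipient IDs are random intercepts.  Categories absent
    everywhere (zero difference variance) are dropped with a warning.
    """
    data = category_difference_covariates(table, functional, roster)
    if data.empty:
        raise ValueError("no pairings with complete functional profiles")
    cats = list(functional.columns)
    keep = []
    for c in cats:
        col = f"cat_{c}"
        if data[col].abs().max() < 1e-12:
            logger.warning("category %s absent everywhere; dropped", c)
        else:
            keep.append(col)
    # Category differences sum to zero across the full profile, so one
    # category must serve as the reference to keep the design full rank
    # (prefer the unannotated NA bucket).
    if len(keep) == len(cats) >= 2:
        reference = "cat_NA" if "cat_NA" in keep else keep[-1]
        keep.remove(reference)
        logger.info("category %s used as reference (dropped)", reference)
    spec = MixedModelSpec(fixed_effects=keep)
    data = _complete_cases(data, spec)
    fit, _ = _fit_lmm(data, spec.formula(), reml=True)
    return fit


# ---------------------------------------------------------------------------
# Correlations and group tests
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    slope: float
    intercept: float
    n: int


def correlation_with_fit(x, y) -> CorrelationResult:
    """Pearson correlation with the companion least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    lin = stats.linregress(x, y)
    return CorrelationResult(
        r=float(r),
        r_squared=float(r) ** 2,
        p_value=float(p),
        slope=float(lin.slope),
        intercept=float(lin.intercept),
        n=int(x.size),
    )


@dataclass
class GroupTestResult:
    method: str
    statistic: float
    p_value: float
    posthoc: pd.DataFrame  # group_a, group_b, statistic, p_adjusted
    adjustment: str


def _dunn_posthoc(
    groups: dict[str, np.ndarray], adjustment: str = "holm"
) -> pd.DataFrame:
    """Dunn's z-test on mean ranks with tie correction."""
    names = list(groups)
    values = np.concatenate([groups[g] for g in names])
    sizes = {g: len(groups[g]) for g in names}
    n = len(values)
    ranks = stats.rankdata(values)
    mean_rank = {}
    start = 0
    for g in names:
        mean_rank[g] = ranks[start : start + sizes[g]].mean()
        start += sizes[g]
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_rank[a] - mean_rank[b]) / se
            rows.append((a, b, float(z), 2.0 * stats.norm.sf(abs(z))))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_raw"])
    out["p_adjusted"] = multipletests(out["p_raw"], method=adjustment)[1]
    return out.drop(columns="p_raw")


def group_tests(
    values_by_group: dict[str, np.ndarray],
    method: str = "kruskal",
    adjustment: str = "holm",
) -> GroupTestResult:
    """Omnibus group comparison with pairwise post-hocs.

    ``method="kruskal"`` runs Kruskal-Wallis with Dunn's post-hoc
    (p-values adjusted by ``adjustment``, Holm by default);
    ``method="anova"`` runs one-way ANOVA with Tukey's HSD (whose
    studentised-range family correction is inherent).
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("empty group")
    names = list(groups)
    arrays = [groups[g] for g in names]
    if method == "kruskal":
        stat, p = stats.kruskal(*arrays)
        posthoc = _dunn_posthoc(groups, adjustment)
        return GroupTestResult("kruskal-wallis", float(stat), float(p), posthoc, adjustment)
    if method == "anova":
        stat, p = stats.f_oneway(*arrays)
        hsd = stats.tukey_hsd(*arrays)
        rows = []
        for i, a in enumerate(names):
            for j in range(i + 1, len(names)):
                rows.append(
                    (a, names[j], float(hsd.statistic[i, j]), float(hsd.pvalue[i, j]))
                )
        posthoc = pd.DataFrame(
            rows, columns=["group_a", "group_b", "statistic", "p_adjusted"]
        )
        return GroupTestResult("anova", float(stat), float(p), posthoc, "tukey-hsd")
    raise ValueError(f"unknown method: {method}")


def wilcoxon_rank_sum(a, b, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test."""
    res = stats.mannwhitneyu(
        np.asarray(a, float),
        np.asarray(b, float),
        alternative="two-sided",
        method=method,
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class AlphaThresholdSummary:
    cut: float
    frac_zero_below: float
    frac_zero_above: float
    n_below: int
    n_above: int


def alpha_threshold_summary(
    table: pd.DataFrame, cut: float = 2.5
) -> AlphaThresholdSummary:
    """Fraction of zero-efficiency pairings below vs at/above a donor
    alpha-diversity cut (an apparent minimal-diversity threshold)."""
    if table.empty:
        raise ValueError("empty covariate table")
    below = table[table["donor_alpha_mean"] < cut]
    above = table[table["donor_alpha_mean"] >= cut]
    frac = lambda t: float((t["efficiency"] == 0).mean()) if len(t) else 0.0
    return AlphaThresholdSummary(
        cut=cut,
        frac_zero_below=frac(below),
        frac_zero_above=frac(above),
        n_below=len(below),
        n_above=len(above),
    )
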