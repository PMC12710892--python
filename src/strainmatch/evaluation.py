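"""Donor-pool prediction, threshold optimisation, recall and efficiency.

The number of distinct donor-matching species strains in each FMT recipient
predicts the recipient's donor pool: every donor with at least one surviving
strain match is a predicted pool member.  Predictions are scored against the
reference pairings over all (donor, evaluable recipient) pairs, and the
normalised-distance threshold theta is selected by sweeping a grid
(default 0.001-3.000 in steps of 0.001) and maximising the F1 score.

Per-donor recall is the proportion of a donor's true recipients that were
predicted; engraftment efficiency is, for each true (donor, recipient)
pairing, the percentage of the donor's distinct profiled species strains
(pooled across the donor's samples) that survive as engrafted matches in
that recipient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .matching import baseline_sample_map, symmetric_distances

logger = logging.getLogger(__name__)

Reference = dict[str, set[str]]


@dataclass
class ConfusionSummary:
    """Confusion counts and scores over (donor, recipient) pairs at one theta."""

    theta: float
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f1: float


@dataclass
class ProportionTestResult:
    """Two-sample equal-proportions chi-square test (continuity corrected)."""

    successes: tuple[int, int]
    totals: tuple[int, int]
    proportions: tuple[float, float]
    statistic: float
    p_value: float


def as_reference(reference) -> Reference:
    """Normalise a reference pairing table to {recipient: {donors}}."""
    if isinstance(reference, pd.DataFrame):
        return {
            r: set(g["donor"]) for r, g in reference.groupby("recipient")
        }
    return {r: set(ds) for r, ds in reference.items()}


def predict_pairings(matches: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Distinct-species surviving match counts per (recipient, donor).

    The predicted donor pool of a recipient is every donor with count >= 1.
    Recipients with no surviving matches do not appear (empty prediction).
    """
    if matches.empty:
        return {}
    surviving = matches[matches["surviving"]]
    prediction: dict[str, dict[str, int]] = {}
    counts = surviving.groupby(["recipient_subject", "donor_subject"])[
        "species"
    ].nunique()
    for (recipient, donor), n in counts.items():
        prediction.setdefault(recipient, {})[donor] = int(n)
    return prediction


def score_against_reference(
    prediction: dict[str, dict[str, int]],
    reference,
    donors: list[str],
    theta: float = float("nan"),
) -> ConfusionSummary:
    """Classify every (donor, evaluable recipient) pair as TP/FP/TN/FN.

    The evaluation universe is donors x reference recipients.  Precision,
    recall and F1 use the 0/0 -> 0 convention, penalising empty predictions.

    Raises
    ------
    ValueError
        If a predicted recipient is absent from the reference.
    """
    ref = as_reference(reference)
    unknown = set(prediction) - set(ref)
    if unknown:
        raise ValueError(
            f"predicted recipients absent from reference: {sorted(unknown)}"
        )
    tp = fp = tn = fn = 0
    for recipient, true_donors in ref.items():
        predicted = {
            d for d, n in prediction.get(recipient, {}).items() if n >= 1
        }
        for donor in donors:
            in_pred, in_true = donor in predicted, donor in true_donors
            if in_pred and in_true:
                tp += 1
            elif in_pred:
                fp += 1
            elif in_true:
                fn += 1
            else:
                tn += 1
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return ConfusionSummary(theta, tp, fp, tn, fn, precision, recall, f1)


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------


@dataclass
class SweepInputs:
    """Precomputed donor-vs-recipient distance arrays for fast sweeping.

    For every (species, donor sample, recipient post sample) pair present in
    the distance table we store the post-sample distance and the distance of
    the same donor sample to the recipient's own baseline (inf when the
    species has no baseline strain), so candidate calling and baseline
    subtraction at any theta reduce to two comparisons.
    """

    donors: list[str]
    recipients: list[str]  # evaluable FMT recipients (baseline + post present)
    n_species: int
    fmt_d_post: np.ndarray
    fmt_d_base: np.ndarray
    fmt_donor_idx: np.ndarray
    fmt_recipient_idx: np.ndarray
    fmt_key: np.ndarray  # donor_idx * n_species + species_idx
    pl_d_post: np.ndarray
    pl_d_base: np.ndarray
    pl_key: np.ndarray


def _pair_arrays(
    sym: pd.DataFrame,
    donor_subject: dict[str, str],
    post_subject: dict[str, str],
    baselines: dict[str, str],
) -> pd.DataFrame:
    pairs = sym[
        sym["sample_a"].isin(donor_subject) & sym["sample_b"].isin(post_subject)
    ].copy()
    pairs["donor_subject"] = pairs["sample_a"].map(donor_subject)
    pairs["recipient_subject"] = pairs["sample_b"].map(post_subject)
    pairs = pairs[pairs["recipient_subject"].isin(baselines)]
    lookup = sym.set_index(["species", "sample_a", "sample_b"])["normalised"]
    keys = pd.MultiIndex.from_arrays(
        [
            pairs["species"],
            pairs["sample_a"],
            pairs["recipient_subject"].map(baselines),
        ]
    )
    d_base = lookup.reindex(keys).to_numpy()
    pairs["d_base"] = np.where(np.isnan(d_base), np.inf, d_base)
    return pairs


def build_sweep_inputs(
    distances: pd.DataFrame, roster: pd.DataFrame
) -> SweepInputs:
    """Assemble the arrays used by :func:`threshold_sweep`."""
    sym = symmetric_distances(distances)
    donor_rows = roster[roster["role"] == "donor"]
    donor_subject = dict(zip(donor_rows["sample_id"], donor_rows["subject_id"]))
    donors = sorted(set(donor_subject.values()))
    baselines = baseline_sample_map(roster)

    def _posts(role: str) -> dict[str, str]:
        rows = roster[(roster["role"] == role) & (roster["timepoint"] == "post")]
        return dict(zip(rows["sample_id"], rows["subject_id"]))

    fmt_posts = _posts("fmt_recipient")
    recipients = sorted(
        {subj for subj in fmt_posts.values() if subj in baselines}
    )
    dropped = set(fmt_posts.values()) - set(recipients)
    if dropped:
        logger.warning(
            "FMT recipients without baseline excluded from evaluation: %s",
            sorted(dropped),
        )

    species = sorted(distances["species"].unique())
    sp_idx = {s: i for i, s in enumerate(species)}
    d_idx = {d: i for i, d in enumerate(donors)}
    r_idx = {r: i for i, r in enumerate(recipients)}

    fmt_pairs = _pair_arrays(sym, donor_subject, fmt_posts, baselines)
    fmt_pairs = fmt_pairs[fmt_pairs["recipient_subject"].isin(r_idx)]
    pl_pairs = _pair_arrays(
        sym, donor_subject, _posts("placebo_recipient"), baselines
    )

    def _key(frame: pd.DataFrame) -> np.ndarray:
        return (
            frame["donor_subject"].map(d_idx).to_numpy(dtype=np.int64)
            * len(species)
            + frame["species"].map(sp_idx).to_numpy(dtype=np.int64)
        )

    return SweepInputs(
        donors=donors,
        recipients=recipients,
        n_species=len(species),
        fmt_d_post=fmt_pairs["normalised"].to_numpy(),
        fmt_d_base=fmt_pairs["d_base"].to_numpy(),
        fmt_donor_idx=fmt_pairs["donor_subject"].map(d_idx).to_numpy(np.int64),
        fmt_recipient_idx=fmt_pairs["recipient_subject"]
        .map(r_idx)
        .to_numpy(np.int64),
        fmt_key=_key(fmt_pairs),
        pl_d_post=pl_pairs["normalised"].to_numpy(),
        pl_d_base=pl_pairs["d_base"].to_numpy(),
        pl_key=_key(pl_pairs),
    )


def default_theta_grid() -> np.ndarray:
    """Default sweep grid: 0.001 to 3.000 in steps of 0.001."""
    return np.round(np.arange(1, 3001) * 0.001, 3)


def threshold_sweep(
    distances: pd.DataFrame,
    roster: pd.DataFrame,
    reference,
    theta_grid: np.ndarray | None = None,
    use_placebo_subtraction: bool = False,
    placebo_background: str = "per_theta",
    fixed_background_theta: float = 0.2,
    inclusive: bool = True,
) -> tuple[pd.DataFrame, ConfusionSummary]:
    """Score pairing predictions over a threshold grid and pick the optimum.

    At every theta the full pipeline is recomputed: candidate matching,
    baseline subtraction (whose flags are theta-dependent), optional placebo
    subtraction, donor-pool prediction, and confusion scoring against the
    reference.  The optimum maximises F1, ties broken by the smallest theta.

    ``placebo_background`` selects whether the placebo background set is
    recomputed at every theta (``"per_theta"``) or frozen at
    ``fixed_background_theta`` (``"fixed"``).
    """
    if theta_grid is None:
        theta_grid = default_theta_grid()
    theta_grid = np.asarray(theta_grid, dtype=float)
    if theta_grid.size == 0:
        raise ValueError("empty theta grid")
    if (theta_grid <= 0).any():
        raise ValueError("theta grid must be strictly positive")
    theta_grid = np.sort(theta_grid)
    if placebo_background not in ("per_theta", "fixed"):
        raise ValueError("placebo_background must be 'per_theta' or 'fixed'")

    inputs = build_sweep_inputs(distances, roster)
    ref = as_reference(reference)
    unknown = set(inputs.recipients) - set(ref)
    if unknown:
        raise ValueError(
            f"evaluable recipients absent from reference: {sorted(unknown)}"
        )
    R, D = len(inputs.recipients), len(inputs.donors)
    ref_mat = np.zeros((R, D), dtype=bool)
    for i, r in enumerate(inputs.recipients):
        for j, d in enumerate(inputs.donors):
            ref_mat[i, j] = d in ref[r]

    def _surv(d_post, d_base, theta):
        if inclusive:
            return (d_post <= theta) & ~(d_base <= theta)
        return (d_post < theta) & ~(d_base < theta)

    fixed_bg = None
    if use_placebo_subtraction and placebo_background == "fixed":
        fixed_bg = np.unique(
            inputs.pl_key[
                _surv(inputs.pl_d_post, inputs.pl_d_base, fixed_background_theta)
            ]
        )

    rows = []
    for theta in theta_grid:
        surv = _surv(inputs.fmt_d_post, inputs.fmt_d_base, theta)
        if use_placebo_subtraction:
            bg = (
                fixed_bg
                if fixed_bg is not None
                else np.unique(
                    inputs.pl_key[
                        _surv(inputs.pl_d_post, inputs.pl_d_base, theta)
                    ]
                )
            )
            if bg.size:
                surv = surv & ~np.isin(inputs.fmt_key, bg)
        pred = np.zeros((R, D), dtype=bool)
        pred[inputs.fmt_recipient_idx[surv], inputs.fmt_donor_idx[surv]] = True
        tp = int((pred & ref_mat).sum())
        fp = int((pred & ~ref_mat).sum())
        fn = int((~pred & ref_mat).sum())
        tn = int((~pred & ~ref_mat).sum())
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        rows.append((theta, tp, fp, tn, fn, precision, recall, f1))

    sweep = pd.DataFrame(
        rows,
        columns=["theta", "tp", "fp", "tn", "fn", "precision", "recall", "f1"],
    )
    best = sweep.iloc[int(np.argmax(sweep["f1"].to_numpy()))]
    optimum = ConfusionSummary(
        theta=float(best["theta"]),
        tp=int(best["tp"]),
        fp=int(best["fp"]),
        tn=int(best["tn"]),
        fn=int(best["fn"]),
        precision=float(best["precision"]),
        recall=float(best["recall"]),
        f1=float(best["f1"]),
    )
    return sweep, optimum


# ---------------------------------------------------------------------------
# Recall, efficiency, novel-fraction comparison
# ---------------------------------------------------------------------------


def donor_recall(
    prediction: dict[str, dict[str, int]], reference
) -> dict[str, float]:
    """Per-donor proportion of true recipients correctly predicted.

    Donors with no true recipients have undefined recall and are excluded
    (logged).
    """
    ref = as_reference(reference)
    donors = sorted({d for ds in ref.values() for d in ds})
    recalls = {}
    for donor in donors:
        true_recipients = [r for r, ds in ref.items() if donor in ds]
        if not true_recipients:
            logger.info("donor %s has no true recipients; recall undefined", donor)
            continue
        tp = sum(
            1
            for r in true_recipients
            if prediction.get(r, {}).get(donor, 0) >= 1
        )
        recalls[donor] = tp / len(true_recipients)
    return recalls


def donor_strain_counts(
    alignments, roster: pd.DataFrame
) -> dict[str, int]:
    """Distinct species with a profiled strain in >=1 of each donor's samples."""
    donor_rows = roster[roster["role"] == "donor"]
    samples_of = donor_rows.groupby("subject_id")["sample_id"].apply(set)
    counts = {}
    for donor, samples in samples_of.items():
        n = sum(
            1
            for sp, recs in alignments.items()
            if samples & set(recs)
        )
        counts[donor] = n
    return counts


def engraftment_efficiency(
    matches: pd.DataFrame,
    alignments,
    reference,
    roster: pd.DataFrame,
) -> pd.DataFrame:
    """Engraftment efficiency per true (donor, recipient) pairing, in percent.

    Efficiency = 100 x (distinct species with a surviving match in the
    recipient) / (distinct species with a profiled strain in any of the
    donor's samples).  Donors with zero profiled strains are excluded
    (logged).
    """
    ref = as_reference(reference)
    denominators = donor_strain_counts(alignments, roster)
    surviving = matches[matches["surviving"]] if len(matches) else matches
    engrafted: dict[tuple[str, str], int] = {}
    if len(surviving):
        counts = surviving.groupby(["donor_subject", "recipient_subject"])[
            "species"
        ].nunique()
        engrafted = {k: int(v) for k, v in counts.items()}
    rows = []
    for recipient, donors in sorted(ref.items()):
        for donor in sorted(donors):
            n_strains = denominators.get(donor, 0)
            if n_strains == 0:
                logger.warning(
                    "donor %s has no profiled strains; efficiency undefined",
                    donor,
                )
                continue
            n_eng = min(engrafted.get((donor, recipient), 0), n_strains)
            rows.append(
                (donor, recipient, n_strains, n_eng, 100.0 * n_eng / n_strains)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "donor",
            "recipient",
            "n_donor_strains",
            "n_engrafted",
            "efficiency",
        ],
    )


def proportion_test(
    successes_a: int, total_a: int, successes_b: int, total_b: int
) -> ProportionTestResult:
    """Two-sample equal-proportions test with continuity correction.

    The chi-square test on the 2x2 table with Yates continuity correction,
    equivalent to R's ``prop.test`` for two samples; two-sided p-value.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    table = [
        [successes_a, total_a - successes_a],
        [successes_b, total_b - successes_b],
    ]
    res = chi2_contingency(table, correction=True)
    return ProportionTestResult(
        successes=(successes_a, successes_b),
        totals=(total_a, total_b),
        proportions=(successes_a / total_a, successes_b / total_b),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def novel_fraction_comparison(
    matches_a: pd.DataFrame, matches_b: pd.DataFrame
) -> ProportionTestResult:
    """Compare the novel-strain fractions of two cohorts' surviving matches.

    Counts distinct (recipient, species) engrafted strains per cohort, with
    the novel/replacement class taken from the match classification.
    """

    def _counts(matches: pd.DataFrame) -> tuple[int, int]:
        surviving = matches[
            matches["surviving"] & (matches["match_class"] != "unclassified")
        ]
        pairs = surviving.drop_duplicates(
            ["recipient_subject", "species"]
        )
        return int((pairs["match_class"] == "novel").sum()), len(pairs)

    novel_a, total_a = _counts(matches_a)
    novel_b, total_b = _counts(matches_b)
    return proportion_test(novel_a, total_a, novel_b, total_b)
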