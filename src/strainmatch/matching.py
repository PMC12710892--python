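"""Strain-match calling with baseline and placebo subtraction.

A donor strain is matched to a recipient when the per-species
median-normalised JC69 distance between a donor sample consensus and the
recipient's post-treatment consensus is at or below a threshold theta.
Two subtractions then remove matches that cannot be attributed to
engraftment:

* baseline subtraction — the same donor strain also matches the recipient's
  own baseline sample, so the strain was already present before treatment
  (recipient origin);
* placebo subtraction — the (donor, species) strain also survives in a
  placebo recipient, so its presence is ambiguous background rather than
  FMT engraftment.

Surviving matches are classified as *novel* (species absent from the
recipient's baseline taxonomic profile) or *replacement* (species present at
baseline but the strain replaced by the donor's).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MATCH_COLUMNS = [
    "species",
    "donor_subject",
    "donor_sample",
    "recipient_subject",
    "recipient_post_sample",
    "normalised_distance",
    "flag_baseline_origin",
    "flag_placebo_background",
    "surviving",
    "match_class",
]

RECIPIENT_ROLES = ("fmt_recipient", "placebo_recipient")


def symmetric_distances(distances: pd.DataFrame) -> pd.DataFrame:
    """Materialise both orientations of the unordered distance table."""
    flipped = distances.rename(
        columns={"sample_a": "sample_b", "sample_b": "sample_a"}
    )
    return pd.concat([distances, flipped], ignore_index=True)


def baseline_sample_map(roster: pd.DataFrame) -> dict[str, str]:
    """Map each recipient subject to its baseline sample id."""
    rows = roster[
        roster["role"].isin(RECIPIENT_ROLES)
        & (roster["timepoint"] == "baseline")
    ]
    return dict(zip(rows["subject_id"], rows["sample_id"]))


def _empty_match_table() -> pd.DataFrame:
    return pd.DataFrame(columns=MATCH_COLUMNS)


def call_candidate_matches(
    distances: pd.DataFrame,
    roster: pd.DataFrame,
    theta: float,
    recipient_role: str = "fmt_recipient",
    inclusive: bool = True,
) -> pd.DataFrame:
    """Candidate strain matches: donor sample vs recipient post sample.

    One record per (species, donor sample, recipient post sample) whose
    normalised distance is <= theta (or strictly < theta when
    ``inclusive=False``).  Saturated (infinite) distances never match.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    sym = symmetric_distances(distances)
    donor_rows = roster[roster["role"] == "donor"]
    post_rows = roster[
        (roster["role"] == recipient_role) & (roster["timepoint"] == "post")
    ]
    donor_subject = dict(zip(donor_rows["sample_id"], donor_rows["subject_id"]))
    post_subject = dict(zip(post_rows["sample_id"], post_rows["subject_id"]))

    cand = sym[
        sym["sample_a"].isin(donor_subject) & sym["sample_b"].isin(post_subject)
    ]
    keep = (
        cand["normalised"] <= theta if inclusive else cand["normalised"] < theta
    )
    cand = cand.loc[keep]
    out = pd.DataFrame(
        {
            "species": cand["species"].to_numpy(),
            "donor_subject": cand["sample_a"].map(donor_subject).to_numpy(),
            "donor_sample": cand["sample_a"].to_numpy(),
            "recipient_subject": cand["sample_b"].map(post_subject).to_numpy(),
            "recipient_post_sample": cand["sample_b"].to_numpy(),
            "normalised_distance": cand["normalised"].to_numpy(),
        }
    )
    out["flag_baseline_origin"] = False
    out["flag_placebo_background"] = False
    out["surviving"] = True
    out["match_class"] = "unclassified"
    return out.sort_values(
        ["species", "donor_sample", "recipient_post_sample"], ignore_index=True
    )


def apply_baseline_subtraction(
    matches: pd.DataFrame,
    distances: pd.DataFrame,
    roster: pd.DataFrame,
    theta: float,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Flag matches whose donor strain is already in the recipient baseline.

    A match is flagged when the same donor sample also matches (distance
    <= theta) the recipient's own baseline sample for that species.  Species
    with no baseline strain profile are never flagged.  Recipients lacking a
    baseline sample altogether cannot be evaluated: their matches are
    dropped and logged.
    """
    if matches.empty:
        return matches.copy()
    baselines = baseline_sample_map(roster)
    no_baseline = set(matches["recipient_subject"]) - set(baselines)
    out = matches.copy()
    if no_baseline:
        logger.warning(
            "recipients without baseline sample excluded from matching: %s",
            sorted(no_baseline),
        )
        out = out[~out["recipient_subject"].isin(no_baseline)].copy()
    if out.empty:
        return out.reset_index(drop=True)

    sym = symmetric_distances(distances)
    lookup = sym.set_index(["species", "sample_a", "sample_b"])["normalised"]
    out["_baseline_sample"] = out["recipient_subject"].map(baselines)
    keys = pd.MultiIndex.from_arrays(
        [out["species"], out["donor_sample"], out["_baseline_sample"]]
    )
    d_base = lookup.reindex(keys).to_numpy()
    d_base = np.where(np.isnan(d_base), np.inf, d_base)
    flagged = d_base <= theta if inclusive else d_base < theta
    out["flag_baseline_origin"] = flagged
    out["surviving"] = ~out["flag_baseline_origin"] & ~out[
        "flag_placebo_background"
    ]
    return out.drop(columns="_baseline_sample").reset_index(drop=True)


def apply_placebo_subtraction(
    matches: pd.DataFrame, placebo_matches: pd.DataFrame
) -> pd.DataFrame:
    """Flag FMT matches whose (donor, species) survives in any placebo.

    The placebo match table must have been produced by the identical
    candidate-calling and baseline-subtraction procedure on placebo
    recipients.  Granularity is (donor subject, species): all of a donor's
    samples are pooled, mirroring the pooled efficiency definition.
    Idempotent: reapplying with the same background changes nothing.
    """
    out = matches.copy()
    if out.empty:
        return out
    surviving = placebo_matches[placebo_matches["surviving"]] if len(
        placebo_matches
    ) else placebo_matches
    background = (
        set(zip(surviving["donor_subject"], surviving["species"]))
        if len(surviving)
        else set()
    )
    keys = list(zip(out["donor_subject"], out["species"]))
    out["flag_placebo_background"] = out["flag_placebo_background"].to_numpy() | (
        np.array([k in background for k in keys])
        if background
        else np.zeros(len(out), dtype=bool)
    )
    out["surviving"] = ~out["flag_baseline_origin"] & ~out[
        "flag_placebo_background"
    ]
    return out


def classify_novel_or_replacement(
    matches: pd.DataFrame,
    abundance: pd.DataFrame,
    roster: pd.DataFrame,
) -> pd.DataFrame:
    """Classify surviving matches as novel or replacement strains.

    A surviving match is a *replacement* when the species has positive
    relative abundance in the recipient's baseline sample, *novel* when its
    baseline abundance is zero.  Species absent from the abundance table stay
    unclassified (logged).
    """
    out = matches.copy()
    if out.empty:
        return out
    baselines = baseline_sample_map(roster)
    classes = []
    missing_species = set()
    for _, row in out.iterrows():
        if not row["surviving"]:
            classes.append("unclassified")
            continue
        sp = row["species"]
        base = baselines.get(row["recipient_subject"])
        if sp not in abundance.columns or base is None or base not in abundance.index:
            missing_species.add(sp)
            classes.append("unclassified")
            continue
        classes.append(
            "replacement" if abundance.loc[base, sp] > 0 else "novel"
        )
    if missing_species:
        logger.warning(
            "species missing from abundance table left unclassified: %s",
            sorted(missing_species),
        )
    out["match_class"] = classes
    return out


def call_matches(
    distances: pd.DataFrame,
    roster: pd.DataFrame,
    theta: float,
    abundance: pd.DataFrame | None = None,
    placebo_subtraction: bool = True,
    inclusive: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full matching pipeline at a single threshold.

    Returns ``(fmt_matches, placebo_matches)``, both baseline-subtracted;
    the FMT table is additionally placebo-subtracted when requested, and
    classified when an abundance table is supplied.
    """
    placebo = call_candidate_matches(
        distances, roster, theta, "placebo_recipient", inclusive
    )
    placebo = apply_baseline_subtraction(
        placebo, distances, roster, theta, inclusive
    )
    fmt = call_candidate_matches(
        distances, roster, theta, "fmt_recipient", inclusive
    )
    fmt = apply_baseline_subtraction(fmt, distances, roster, theta, inclusive)
    if placebo_subtraction:
        fmt = apply_placebo_subtraction(fmt, placebo)
    if abundance is not None:
        fmt = classify_novel_or_replacement(fmt, abundance, roster)
    return fmt, placebo


def match_count_matrix(matches: pd.DataFrame, roster: pd.DataFrame) -> pd.DataFrame:
    """Distinct-species surviving match counts, recipients x donors.

    Heatmap-ready layout: one row per FMT recipient, one column per donor.
    """
    donors = sorted(roster.loc[roster["role"] == "donor", "subject_id"].unique())
    recipients = sorted(
        roster.loc[roster["role"] == "fmt_recipient", "subject_id"].unique()
    )
    mat = pd.DataFrame(0, index=recipients, columns=donors)
    surviving = matches[matches["surviving"]] if len(matches) else matches
    if len(surviving):
        counts = (
            surviving.groupby(["recipient_subject", "donor_subject"])["species"]
            .nunique()
            .reset_index()
        )
        for _, row in counts.iterrows():
            mat.loc[row["recipient_subject"], row["donor_subject"]] = row[
                "species"
            ]
    mat.index.name = "recipient"
    return mat
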