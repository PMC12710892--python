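"""Pairwise JC69 strain distances and per-species median normalisation.

Dominant-strain profilers emit, per species, one aligned consensus sequence
per sample.  Strain relatedness between two samples is summarised by the
Jukes-Cantor (JC69) distance between their consensus sequences; because
species differ widely in intrinsic strain diversity, each species' distances
are normalised by the median of all its pairwise distances before any
thresholding.  The normalised distance is the quantity on which strain
matches are called downstream.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Per-species alignments: {species: {sample_id: aligned sequence}}.
StrainAlignmentSet = Mapping[str, Mapping[str, str]]

#: JC69 saturates at p = 3/4; beyond it the distance is undefined.
SATURATION_P = 0.75

_RESOLVED = frozenset(b"ACGT")


def jc69_distance(seq_a: str, seq_b: str) -> tuple[float, float]:
    """JC69 distance between two aligned sequences.

    Sites where either sequence is not a resolved base (A/C/G/T) are
    excluded (pairwise deletion).  Returns ``(p_mismatch, raw_jc69)`` where
    ``p_mismatch`` is the mismatch proportion over jointly resolved sites and
    ``raw_jc69 = -(3/4) ln(1 - (4/3) p)`` in substitutions per site.
    Saturated pairs (p >= 3/4) get ``raw_jc69 = inf``.

    Raises
    ------
    ValueError
        If the sequences differ in length or share no resolved site.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned sequences differ in length: {len(seq_a)} vs {len(seq_b)}"
        )
    a = np.frombuffer(seq_a.upper().encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode("ascii"), dtype=np.uint8)
    valid_a = np.isin(a, np.frombuffer(b"ACGT", dtype=np.uint8))
    valid_b = np.isin(b, np.frombuffer(b"ACGT", dtype=np.uint8))
    joint = valid_a & valid_b
    n_sites = int(joint.sum())
    if n_sites == 0:
        raise ValueError("no jointly resolved sites between sequences")
    p = float((a[joint] != b[joint]).sum()) / n_sites
    return p, jc69_from_p(p)


def jc69_from_p(p: float) -> float:
    """Closed-form JC69 transform of a mismatch proportion."""
    if p >= SATURATION_P:
        return math.inf
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def _encode(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    mat = np.frombuffer(
        "".join(s.upper() for s in seqs).encode("ascii"), dtype=np.uint8
    ).reshape(len(seqs), -1)
    valid = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
    return mat, valid


def pairwise_species_distances(alignments: StrainAlignmentSet) -> pd.DataFrame:
    """All unordered pairwise JC69 distances, per species.

    Returns a long-format table with columns ``species, sample_a, sample_b,
    p_mismatch, raw_jc69`` (unordered pairs stored once, ``sample_a <
    sample_b``).  Species with fewer than two samples contribute no rows;
    pairs with zero jointly resolved sites are omitted.  Both situations are
    logged.

    Raises
    ------
    ValueError
        If sequences within a species differ in length.
    """
    rows: list[tuple] = []
    for species in sorted(alignments):
        records = alignments[species]
        samples = sorted(records)
        if len(samples) < 2:
            logger.warning(
                "species %s has %d sample(s); no pairs", species, len(samples)
            )
            continue
        lengths = {len(records[s]) for s in samples}
        if len(lengths) > 1:
            offender = ", ".join(f"{s}:{len(records[s])}" for s in samples)
            raise ValueError(
                f"alignment length mismatch in species {species} ({offender})"
            )
        mat, valid = _encode([records[s] for s in samples])
        n = len(samples)
        for i in range(n):
            joint = valid[i] & valid[i + 1 :]
            n_sites = joint.sum(axis=1)
            mism = ((mat[i] != mat[i + 1 :]) & joint).sum(axis=1)
            for k, j in enumerate(range(i + 1, n)):
                if n_sites[k] == 0:
                    logger.warning(
                        "species %s: no jointly resolved sites for %s vs %s; "
                        "pair omitted",
                        species,
                        samples[i],
                        samples[j],
                    )
                    continue
                p = mism[k] / n_sites[k]
                rows.append(
                    (species, samples[i], samples[j], float(p), jc69_from_p(p))
                )
    table = pd.DataFrame(
        rows, columns=["species", "sample_a", "sample_b", "p_mismatch", "raw_jc69"]
    )
    return table.sort_values(
        ["species", "sample_a", "sample_b"], ignore_index=True
    )


def normalise_by_species_median(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each species' raw JC69 distances by that species' median.

    The median is taken over all finite pairwise raw distances of the
    species.  Saturated pairs stay ``inf``.  A species whose median is zero
    (all compared strains identical) is flagged in the log and its zero raw
    distances map to normalised 0, so identical strains remain matchable.
    """
    out = table.copy()
    normalised = np.full(len(out), np.inf)
    for species, idx in out.groupby("species").groups.items():
        raw = out.loc[idx, "raw_jc69"].to_numpy()
        finite = np.isfinite(raw)
        if not finite.any():
            logger.warning("species %s: all pairs saturated; left inf", species)
            continue
        med = float(np.median(raw[finite]))
        if med == 0.0:
            logger.warning(
                "species %s: zero median raw distance; zero raws -> 0", species
            )
            normalised[out.index.get_indexer(idx)] = np.where(
                raw == 0.0, 0.0, np.inf
            )
        else:
            normalised[out.index.get_indexer(idx)] = raw / med
    out["normalised"] = normalised
    return out


def distance_density_split(
    table: pd.DataFrame, roster: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Split normalised distances into intra- and inter-subject classes.

    A pair is intra-subject when both samples belong to the same subject.
    Donor batch samples are excluded from both classes since a batch pools
    several donors and is ambiguous as an intra- or inter-subject comparison.

    Parameters
    ----------
    roster
        Sample metadata with columns ``sample_id, subject_id, role``.

    Returns
    -------
    (intra, inter) : arrays of normalised distances.
    """
    known = set(roster["sample_id"])
    missing = (set(table["sample_a"]) | set(table["sample_b"])) - known
    if missing:
        raise ValueError(f"samples missing from roster: {sorted(missing)}")
    subject = roster.set_index("sample_id")["subject_id"]
    role = roster.set_index("sample_id")["role"]
    batch = (role.reindex(table["sample_a"]).to_numpy() == "donor_batch") | (
        role.reindex(table["sample_b"]).to_numpy() == "donor_batch"
    )
    keep = table.loc[~batch]
    same = (
        subject.reindex(keep["sample_a"]).to_numpy()
        == subject.reindex(keep["sample_b"]).to_numpy()
    )
    values = keep["normalised"].to_numpy()
    return values[same], values[~same]
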