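"""Readers and writers for the pipeline's plain-text formats.

All tables are tab-delimited UTF-8 with a header row; ``inf`` and ``NA``
sentinels are spelled literally.  Alignments are plain FASTA, one file per
species, one aligned record per sample (wrapped lines and lowercase residues
tolerated; residues are uppercased on read).  Writers stable-sort their rows
so outputs are diffable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .synthetic import TruthSet

logger = logging.getLogger(__name__)

ROSTER_COLUMNS = ["sample_id", "subject_id", "role", "timepoint", "read_count"]
ROLES = {"donor", "donor_batch", "fmt_recipient", "placebo_recipient"}


class InputFormatError(ValueError):
    """Raised when an input file violates the declared dialect."""


def read_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    missing = set(ROSTER_COLUMNS) - set(table.columns)
    if missing:
        raise InputFormatError(
            f"{path}: missing metadata columns {sorted(missing)}"
        )
    dupes = table["sample_id"][table["sample_id"].duplicated()]
    if len(dupes):
        raise InputFormatError(
            f"{path}: duplicate sample_id(s) {sorted(set(dupes))}"
        )
    bad_roles = set(table["role"]) - ROLES
    if bad_roles:
        raise InputFormatError(f"{path}: unknown role(s) {sorted(bad_roles)}")
    return table[ROSTER_COLUMNS]


def read_alignments(directory: str | Path) -> dict[str, dict[str, str]]:
    """Read per-species FASTA alignments from a directory.

    The species name is the file stem.  Raises on duplicate sample ids or
    unequal sequence lengths within a file, naming the offender.
    """
    directory = Path(directory)
    alignments: dict[str, dict[str, str]] = {}
    for path in sorted(directory.glob("*.fasta")):
        species = path.stem
        records: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise InputFormatError(
                    f"{path}: duplicate sample id {rec.id}"
                )
            records[rec.id] = str(rec.seq).upper()
        lengths = {len(s) for s in records.values()}
        if len(lengths) > 1:
            raise InputFormatError(
                f"{path}: unequal aligned lengths {sorted(lengths)}"
            )
        if records:
            alignments[species] = records
        else:
            logger.warning("%s: empty alignment file skipped", path)
    return alignments


def read_abundance(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(
        path, sep="\t", index_col="sample_id", float_precision="round_trip"
    )
    if table.index.duplicated().any():
        raise InputFormatError(f"{path}: duplicate sample_id rows")
    if (table.drop(columns=["UNKNOWN"], errors="ignore") < 0).any().any():
        raise InputFormatError(f"{path}: negative abundances")
    return table


def read_cog(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False
    )
    required = {"sample_id", "gene_id", "category"}
    missing = required - set(table.columns)
    if missing:
        raise InputFormatError(f"{path}: missing columns {sorted(missing)}")
    return table[["sample_id", "gene_id", "category"]]


def read_reference_pairings(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    missing = {"recipient", "donor"} - set(table.columns)
    if missing:
        raise InputFormatError(f"{path}: missing columns {sorted(missing)}")
    return table[["recipient", "donor"]]


def read_truth(path: str | Path) -> TruthSet:
    with open(path) as fh:
        return TruthSet.from_json_dict(json.load(fh))


def write_distances(table: pd.DataFrame, path: str | Path) -> None:
    out = table.sort_values(
        ["species", "sample_a", "sample_b"], ignore_index=True
    )
    out.to_csv(path, sep="\t", index=False)


def read_distances(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"species", "sample_a", "sample_b", "p_mismatch", "raw_jc69"}
    missing = required - set(table.columns)
    if missing:
        raise InputFormatError(f"{path}: missing columns {sorted(missing)}")
    return table


def write_matches(table: pd.DataFrame, path: str | Path) -> None:
    out = table.sort_values(
        ["species", "donor_sample", "recipient_post_sample"],
        ignore_index=True,
    )
    out.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)
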