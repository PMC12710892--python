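"""Synthetic multi-donor FMT cohort generator with ground truth.

Emulates the data shape produced by dominant-strain profiling of a
multi-donor faecal microbiota transplantation (FMT) trial: a sample roster
(donors with repeated donation samples, FMT and placebo recipients at
baseline and one post-treatment timepoint), per-species consensus-sequence
alignments, a species relative-abundance table, a gene-to-COG-category
annotation table, and a ground-truth record of donor pools and engraftment
events.

The strain model is deliberately simple but reproduces the one feature the
downstream analysis depends on: a bimodal distribution of per-species
normalised DNA distances.  Each species has a pool of lineages diverged from
a common root at per-site rate ``d_inter``; every subject carrying the
species holds one lineage, and each sample's consensus is its subject's
lineage sequence plus fresh per-site noise at rate ``d_intra``.  With
``d_intra << d_inter`` intra-lineage pairs form a low mode far below the
median while inter-lineage pairs form a mode near 1 after median
normalisation.

Engraftment ground truth: each FMT recipient receives a pool of donors; for
every species carried by a pool donor, the donor's strain engrafts with the
donor's efficiency probability, replacing (or adding to) the recipient's
post-treatment profile.  Placebo recipients always retain their own baseline
lineages.  Strain detection per (sample, species) is a Bernoulli thinning
whose probability may depend on the sample's read depth, emulating
depth-limited strain profiling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: 23 defined COG functional-category letters; unannotated genes map to NA.
COG_CATEGORIES = tuple("JKLDVTMNUOCGEFHIPQRSABZ")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class CohortConfigError(ValueError):
    """Raised for an internally inconsistent cohort configuration."""


def logistic_detection(
    read_count: np.ndarray,
    midpoint_log10: float = 5.5,
    slope: float = 2.5,
) -> np.ndarray:
    """Detection probability as a logistic function of log10 read depth.

    Defaults give ~0.78 detection at 1M reads and ~0.95 at 8M reads, i.e. an
    average around 0.9 over the default depth range, reflecting the observed
    depth-dependence of strain-profiling yield.
    """
    x = slope * (np.log10(np.asarray(read_count, dtype=float)) - midpoint_log10)
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class CohortConfig:
    """Study-design parameters for a synthetic FMT cohort.

    Defaults describe a cohort with 9 donors and fixed pools of 4 donors per
    recipient, ~36 profiled species at ~25% per-subject prevalence (so a
    sample carries ~8 profiled strains on average, range roughly 1-17),
    per-donor engraftment efficiencies spread over 0-15%, and well-separated
    intra/inter strain-distance modes (``d_intra=5e-4`` vs ``d_inter=0.02``).

    ``donor_efficiency`` may be a mapping donor_id->probability, a single
    float applied to every donor, or None for the default 0-0.15 spread.
    ``detection_rate`` may be a float (depth-independent), a callable mapping
    read counts to probabilities, or None for :func:`logistic_detection`.
    """

    n_donors: int = 9
    donor_samples_range: tuple[int, int] = (2, 3)
    n_fmt_recipients: int = 12
    n_placebo_recipients: int = 6
    pool_size_range: tuple[int, int] = (4, 4)
    n_species: int = 36
    marker_length: int = 1000
    d_intra: float = 0.0005
    d_inter: float = 0.02
    n_lineages_per_species: int | None = None
    p_shared_lineage: float = 0.05
    species_prevalence: float = 0.25
    donor_efficiency: Mapping[str, float] | float | None = None
    detection_rate: float | Callable[[np.ndarray], np.ndarray] | None = None
    read_depth_range: tuple[int, int] = (1_000_000, 8_000_000)
    include_donor_batch: bool = False
    genes_per_sample: int = 200
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.p_shared_lineage <= 1.0:
            raise CohortConfigError("p_shared_lineage must be in [0, 1]")
        if not 0.0 <= self.species_prevalence <= 1.0:
            raise CohortConfigError("species_prevalence must be in [0, 1]")
        if not 0.0 <= self.d_intra < self.d_inter <= 1.0:
            raise CohortConfigError("require 0 <= d_intra < d_inter <= 1")
        if self.marker_length <= 0:
            raise CohortConfigError("marker_length must be positive")
        lo, hi = self.pool_size_range
        if not 1 <= lo <= hi:
            raise CohortConfigError("pool_size_range must be a valid interval")
        if hi > self.n_donors:
            raise CohortConfigError(
                f"pool_size_range upper bound {hi} exceeds n_donors "
                f"{self.n_donors}"
            )
        lo, hi = self.donor_samples_range
        if not 1 <= lo <= hi:
            raise CohortConfigError("donor_samples_range must be >= 1")
        if isinstance(self.donor_efficiency, float):
            effs: Sequence[float] = [self.donor_efficiency]
        elif self.donor_efficiency is None:
            effs = []
        else:
            effs = list(self.donor_efficiency.values())
        if any(not 0.0 <= e <= 1.0 for e in effs):
            raise CohortConfigError("donor efficiencies must be in [0, 1]")
        if isinstance(self.detection_rate, float) and not (
            0.0 <= self.detection_rate <= 1.0
        ):
            raise CohortConfigError("constant detection_rate must be in [0, 1]")

    def donor_ids(self) -> list[str]:
        return [f"D{i + 1:02d}" for i in range(self.n_donors)]

    def efficiency_map(self) -> dict[str, float]:
        donors = self.donor_ids()
        if self.donor_efficiency is None:
            values = np.linspace(0.0, 0.15, len(donors))
            return dict(zip(donors, values.tolist()))
        if isinstance(self.donor_efficiency, float):
            return {d: self.donor_efficiency for d in donors}
        missing = set(donors) - set(self.donor_efficiency)
        if missing:
            raise CohortConfigError(
                f"donor_efficiency missing donors: {sorted(missing)}"
            )
        return {d: float(self.donor_efficiency[d]) for d in donors}

    def detection_fn(self) -> Callable[[np.ndarray], np.ndarray]:
        if self.detection_rate is None:
            return logistic_detection
        if callable(self.detection_rate):
            return self.detection_rate
        p = float(self.detection_rate)
        return lambda reads: np.full(np.shape(reads), p)


@dataclass
class TruthSet:
    """Ground truth recorded alongside a generated cohort."""

    true_pairings: dict[str, set[str]]
    engraftment_events: list[tuple[str, str, str]]  # (donor, recipient, species)
    lineage_assignment: dict[tuple[str, str], int]  # (subject, species) -> id

    def to_json_dict(self) -> dict:
        return {
            "true_pairings": {
                r: sorted(ds) for r, ds in sorted(self.true_pairings.items())
            },
            "engraftment_events": [list(e) for e in sorted(self.engraftment_events)],
            "lineage_assignment": {
                f"{subj}|{sp}": lid
                for (subj, sp), lid in sorted(self.lineage_assignment.items())
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "TruthSet":
        return cls(
            true_pairings={r: set(ds) for r, ds in d["true_pairings"].items()},
            engraftment_events=[tuple(e) for e in d["engraftment_events"]],
            lineage_assignment={
                tuple(k.split("|", 1)): v
                for k, v in d["lineage_assignment"].items()
            },
        )


@dataclass
class Cohort:
    """A fully generated synthetic cohort and its ground truth."""

    config: CohortConfig
    roster: pd.DataFrame
    alignments: dict[str, dict[str, str]]
    abundance: pd.DataFrame
    cog: pd.DataFrame
    truth: TruthSet


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with probability ``rate``."""
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n)) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode("ascii")


def _species_names(n: int) -> list[str]:
    """Synthetic species names; the first genera are labelled Prevotella and
    Bacteroides so genus-ratio covariates are computable downstream."""
    names = []
    for i in range(n):
        if i < 3:
            names.append(f"Prevotella_sp{i + 1:02d}")
        elif i < 6:
            names.append(f"Bacteroides_sp{i + 1:02d}")
        else:
            names.append(f"Genus{i + 1:02d}_sp{i + 1:02d}")
    return names


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a complete synthetic cohort; deterministic given the seed."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_design, rng_lineage, rng_assign, rng_engraft, rng_detect, rng_abund, rng_cog = (
        np.random.default_rng(s) for s in streams
    )

    donors = config.donor_ids()
    fmt = [f"R{i + 1:02d}" for i in range(config.n_fmt_recipients)]
    placebo = [f"P{i + 1:02d}" for i in range(config.n_placebo_recipients)]
    subjects = donors + fmt + placebo
    species = _species_names(config.n_species)
    efficiency = config.efficiency_map()
    detect = config.detection_fn()

    # --- roster -----------------------------------------------------------
    rows = []
    lo, hi = config.read_depth_range
    log_lo, log_hi = np.log(lo), np.log(hi)

    def _depth() -> int:
        return int(np.exp(rng_design.uniform(log_lo, log_hi)))

    ds_lo, ds_hi = config.donor_samples_range
    for d in donors:
        n_samp = int(rng_design.integers(ds_lo, ds_hi + 1))
        for k in range(n_samp):
            rows.append((f"{d}_S{k + 1}", d, "donor", "donation", _depth()))
    for r in fmt:
        rows.append((f"{r}_BL", r, "fmt_recipient", "baseline", _depth()))
        rows.append((f"{r}_W8", r, "fmt_recipient", "post", _depth()))
    for p in placebo:
        rows.append((f"{p}_BL", p, "placebo_recipient", "baseline", _depth()))
        rows.append((f"{p}_W8", p, "placebo_recipient", "post", _depth()))
    if config.include_donor_batch:
        rows.append(("BATCH_S1", "BATCH", "donor_batch", "donation", _depth()))
    roster = pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "role", "timepoint", "read_count"]
    )

    # --- carriage and lineage assignment ---------------------------------
    carriage = rng_assign.random((len(subjects), len(species))) < (
        config.species_prevalence
    )
    # a stool sample is never sterile: guarantee >= 1 carried species
    for i in range(len(subjects)):
        if not carriage[i].any():
            carriage[i, int(rng_assign.integers(len(species)))] = True
    subj_index = {s: i for i, s in enumerate(subjects)}

    lineage_assignment: dict[tuple[str, str], int] = {}
    lineage_of: dict[str, dict[str, int]] = {sp: {} for sp in species}
    n_lineages: dict[str, int] = {}
    for j, sp in enumerate(species):
        next_id = 0
        assigned: list[tuple[str, int]] = []
        for s in subjects:
            if not carriage[subj_index[s], j]:
                continue
            if assigned and rng_assign.random() < config.p_shared_lineage:
                lid = assigned[int(rng_assign.integers(len(assigned)))][1]
            elif (
                config.n_lineages_per_species is not None
                and next_id >= config.n_lineages_per_species
            ):
                lid = int(rng_assign.integers(config.n_lineages_per_species))
            else:
                lid = next_id
                next_id += 1
            lineage_of[sp][s] = lid
            lineage_assignment[(s, sp)] = lid
            assigned.append((s, lid))
        n_lineages[sp] = next_id

    # Lineage sequences: common root per species, diverged at d_inter.
    lineage_seq: dict[str, dict[int, np.ndarray]] = {}
    for sp in species:
        root = rng_lineage.integers(0, 4, size=config.marker_length)
        lineage_seq[sp] = {
            lid: _mutate(root, config.d_inter, rng_lineage)
            for lid in range(max(n_lineages[sp], 1))
        }

    # --- donor pools and engraftment events ------------------------------
    pool_lo, pool_hi = config.pool_size_range
    true_pairings: dict[str, set[str]] = {}
    for r in fmt:
        size = int(rng_engraft.integers(pool_lo, pool_hi + 1))
        pool = rng_engraft.choice(donors, size=size, replace=False)
        true_pairings[r] = set(pool.tolist())

    events: list[tuple[str, str, str]] = []
    engrafted_from: dict[str, dict[str, str]] = {r: {} for r in fmt}
    for r in fmt:
        for j, sp in enumerate(species):
            claimants = [
                d
                for d in donors
                if d in true_pairings[r]
                and carriage[subj_index[d], j]
                and rng_engraft.random() < efficiency[d]
            ]
            if not claimants:
                continue
            winner = claimants[int(rng_engraft.integers(len(claimants)))]
            events.append((winner, r, sp))
            engrafted_from[r][sp] = winner

    # --- consensus sequences with detection dropout ----------------------
    depth = roster.set_index("sample_id")["read_count"]
    alignments: dict[str, dict[str, str]] = {sp: {} for sp in species}

    def _emit_seq(sp: str, sample: str, source_lineage: int) -> None:
        p_det = float(np.asarray(detect(np.array([depth[sample]])))[0])
        if rng_detect.random() >= p_det:
            return
        seq = _mutate(lineage_seq[sp][source_lineage], config.d_intra, rng_detect)
        alignments[sp][sample] = _to_str(seq)

    sample_rows = roster[roster["role"] != "donor_batch"]
    for _, row in sample_rows.iterrows():
        sample, subj, role, timepoint = (
            row["sample_id"],
            row["subject_id"],
            row["role"],
            row["timepoint"],
        )
        for sp in species:
            own = lineage_of[sp].get(subj)
            if role == "fmt_recipient" and timepoint == "post":
                donor = engrafted_from[subj].get(sp)
                if donor is not None:
                    _emit_seq(sp, sample, lineage_of[sp][donor])
                elif own is not None:
                    _emit_seq(sp, sample, own)
            elif own is not None:
                _emit_seq(sp, sample, own)
    if config.include_donor_batch:
        # A batch sample pools donor material: use each donor lineage present.
        for sp in species:
            carriers = [d for d in donors if d in lineage_of[sp]]
            if carriers:
                d = carriers[int(rng_detect.integers(len(carriers)))]
                _emit_seq(sp, "BATCH_S1", lineage_of[sp][d])
    alignments = {sp: recs for sp, recs in alignments.items() if recs}

    # --- species relative abundances --------------------------------------
    abund_rows = {}
    for _, row in sample_rows.iterrows():
        sample, subj, role, timepoint = (
            row["sample_id"],
            row["subject_id"],
            row["role"],
            row["timepoint"],
        )
        carried = {sp for sp in species if subj in lineage_of[sp]}
        if role == "fmt_recipient" and timepoint == "post":
            carried |= set(engrafted_from[subj])
        vec = np.zeros(len(species))
        if carried:
            unknown = rng_abund.uniform(0.02, 0.2)
            weights = rng_abund.dirichlet(np.ones(len(carried)))
            for w, sp in zip(weights, sorted(carried)):
                vec[species.index(sp)] = w * (1.0 - unknown)
        abund_rows[sample] = vec
    abundance = pd.DataFrame.from_dict(
        abund_rows, orient="index", columns=species
    )
    abundance["UNKNOWN"] = 1.0 - abundance.sum(axis=1)
    abundance.index.name = "sample_id"

    # --- COG annotations ---------------------------------------------------
    cog_rows = []
    n_cat = len(COG_CATEGORIES)
    for subj in subjects:
        profile = rng_cog.dirichlet(np.full(n_cat, 2.0))
        for sample in roster.loc[
            roster["subject_id"] == subj, "sample_id"
        ]:
            n_genes = int(rng_cog.poisson(config.genes_per_sample))
            cats = rng_cog.choice(n_cat, size=n_genes, p=profile)
            for g in range(n_genes):
                gene = f"{sample}_g{g + 1}"
                if rng_cog.random() < 0.10:
                    cog_rows.append((sample, gene, "NA"))
                    continue
                cog_rows.append((sample, gene, COG_CATEGORIES[cats[g]]))
                if rng_cog.random() < 0.08:
                    other = (cats[g] + 1 + rng_cog.integers(n_cat - 1)) % n_cat
                    cog_rows.append((sample, gene, COG_CATEGORIES[other]))
    cog = pd.DataFrame(cog_rows, columns=["sample_id", "gene_id", "category"])

    truth = TruthSet(
        true_pairings=true_pairings,
        engraftment_events=events,
        lineage_assignment=lineage_assignment,
    )
    return Cohort(
        config=config,
        roster=roster,
        alignments=alignments,
        abundance=abundance,
        cog=cog,
        truth=truth,
    )


def emit_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort to disk in the pipeline's input formats.

    Produces ``metadata.tsv``, ``abundance.tsv``, ``cog.tsv``, ``truth.json``,
    ``reference_pairings.tsv`` and one aligned FASTA per species under
    ``alignments/``.  Species with no detected strains are omitted (logged).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aln_dir = directory / "alignments"
    aln_dir.mkdir(exist_ok=True)

    paths = {
        "metadata": directory / "metadata.tsv",
        "abundance": directory / "abundance.tsv",
        "cog": directory / "cog.tsv",
        "truth": directory / "truth.json",
        "reference_pairings": directory / "reference_pairings.tsv",
        "alignments_dir": aln_dir,
    }
    cohort.roster.to_csv(paths["metadata"], sep="\t", index=False)
    cohort.abundance.to_csv(paths["abundance"], sep="\t")
    cohort.cog.to_csv(paths["cog"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth.to_json_dict(), fh, indent=1, sort_keys=True)
    ref_rows = [
        {"recipient": r, "donor": d}
        for r, ds in sorted(cohort.truth.true_pairings.items())
        for d in sorted(ds)
    ]
    pd.DataFrame(ref_rows, columns=["recipient", "donor"]).to_csv(
        paths["reference_pairings"], sep="\t", index=False
    )
    for sp in sorted(cohort.alignments):
        records = cohort.alignments[sp]
        if not records:
            logger.info("species %s has no detected strains; file omitted", sp)
            continue
        seqs = [
            SeqRecord(Seq(records[s]), id=s, description="")
            for s in sorted(records)
        ]
        SeqIO.write(seqs, aln_dir / f"{sp}.fasta", "fasta")
    return paths
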