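"""Seeded simulation of phased multi-locus diploid data with known species.

The generator emulates the statistical structure that the conspecificity
analysis assumes in RAD-seq data from several diploid species:

* each species has a private allele pool per locus (a fixed number of
  distinct haplotypes derived from a species backbone sequence);
* species backbones diverge independently from a common ancestral sequence
  (a star phylogeny) by private substitutions, at an expected per-site rate
  ``divergence_rate`` per species;
* within-species haplotypes add private substitutions at an expected
  per-site rate ``polymorphism_rate`` (heterozygosity arises because each
  individual draws its two alleles uniformly, with replacement, from its
  species pool);
* optional introgression: with per-individual per-locus probability
  ``introgression_rho``, an individual of the designated sister pair
  (species 0 and 1) carries one allele drawn from the sister's pool —
  exactly the cross-pool heterozygote that merges haploweb pools;
* missingness: with probability ``missing_rate`` an individual is absent
  from a locus (missingness overrides introgression).

Mutations are substitutions only, uniform across sites, with the target
base drawn uniformly from the three alternatives; the same site may be hit
twice.  All randomness flows from a single :class:`numpy.random.Generator`
with a documented draw order (per locus: ancestral sequence, then species
backbones, then pool haplotypes, then per individual: allele indices,
introgression, missingness), so identical config + seed reproduce the
dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .alleles_io import AlleleRecord, Dataset, Locus
from .errors import ValidationError

BASES = np.frombuffer(b"ACGT", dtype="S1")

#: individuals given 95% missingness in the study-shaped preset
STUDY_HIGH_MISSING = ("s2_i0", "s3_i0")


@dataclass
class SimulationConfig:
    """Parameters of one simulated dataset.

    ``inds_per_species`` may be a single integer or a per-species list.
    Rates are per site (``divergence_rate``, ``polymorphism_rate``) or per
    individual-locus (``introgression_rho``, ``missing_rate``).
    ``missing_overrides`` maps individual ids to their own missing rate,
    used to plant high-missingness libraries.
    """

    n_species: int
    inds_per_species: int | list[int]
    n_loci: int
    locus_length: int
    divergence_rate: float = 0.03
    polymorphism_rate: float = 0.005
    pool_size: int = 3
    introgression_rho: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    missing_overrides: dict[str, float] = field(default_factory=dict)

    def species_sizes(self) -> list[int]:
        if isinstance(self.inds_per_species, int):
            return [self.inds_per_species] * self.n_species
        return list(self.inds_per_species)

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValidationError("n_species must be >= 1")
        sizes = self.species_sizes()
        if len(sizes) != self.n_species:
            raise ValidationError(
                "inds_per_species list length must equal n_species"
            )
        if any(s < 1 for s in sizes):
            raise ValidationError("inds_per_species entries must be >= 1")
        if self.n_loci < 0:
            raise ValidationError("n_loci must be >= 0")
        if self.locus_length < 1:
            raise ValidationError("locus_length must be >= 1")
        if self.divergence_rate < 0 or self.polymorphism_rate < 0:
            raise ValidationError("mutation rates must be >= 0")
        if self.pool_size < 1:
            raise ValidationError("pool_size must be >= 1")
        if not 0 <= self.introgression_rho <= 1:
            raise ValidationError("introgression_rho must be in [0, 1]")
        if self.introgression_rho > 0 and self.n_species < 2:
            raise ValidationError("introgression requires n_species >= 2")
        if not 0 <= self.missing_rate <= 1:
            raise ValidationError("missing_rate must be in [0, 1]")
        for ind, m in self.missing_overrides.items():
            if not 0 <= m <= 1:
                raise ValidationError(
                    f"missing override for {ind} must be in [0, 1]"
                )

    def individual_ids(self) -> list[tuple[str, int]]:
        """(individual_id, species index) pairs, species-major order."""
        out = []
        for s, size in enumerate(self.species_sizes()):
            for i in range(size):
                out.append((f"s{s}_i{i}", s))
        return out


@dataclass
class TruthTable:
    """Ground truth of a simulation, for recovery tests."""

    species_of: dict[str, int]
    introgressed_events: list[tuple[str, str]]  # (individual_id, locus_id)
    missing_events: list[tuple[str, str]]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Apply Poisson(rate * len) substitutions at uniform sites."""
    seq = seq.copy()
    n_mut = rng.poisson(rate * len(seq))
    for _ in range(n_mut):
        site = int(rng.integers(len(seq)))
        current = seq[site]
        alternatives = BASES[BASES != current]
        seq[site] = alternatives[int(rng.integers(3))]
    return seq


def simulate_dataset(config: SimulationConfig) -> tuple[Dataset, TruthTable]:
    """Generate a phased diploid multi-species dataset plus its truth table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    individuals = config.individual_ids()
    species_of = {ind: s for ind, s in individuals}
    introgressed: list[tuple[str, str]] = []
    missing: list[tuple[str, str]] = []
    loci: list[Locus] = []

    for locus_idx in range(config.n_loci):
        locus_id = f"L{locus_idx}"
        ancestral = BASES[rng.integers(0, 4, size=config.locus_length)]
        pools: list[list[str]] = []
        for s in range(config.n_species):
            backbone = _mutate(rng, ancestral, config.divergence_rate)
            pool = [
                _mutate(rng, backbone, config.polymorphism_rate)
                .tobytes()
                .decode("ascii")
                for _ in range(config.pool_size)
            ]
            pools.append(pool)

        records: list[AlleleRecord] = []
        for ind, s in individuals:
            draws = rng.integers(0, config.pool_size, size=2)
            alleles = [pools[s][int(d)] for d in draws]
            introgression_here = False
            if config.introgression_rho > 0 and s in (0, 1):
                if rng.random() < config.introgression_rho:
                    sister = 1 - s
                    pick = int(rng.integers(config.pool_size))
                    alleles[1] = pools[sister][pick]
                    introgression_here = True
            m = config.missing_overrides.get(ind, config.missing_rate)
            if m > 0 and rng.random() < m:
                missing.append((ind, locus_id))
                continue  # absent: overrides introgression
            if introgression_here:
                introgressed.append((ind, locus_id))
            records.append(AlleleRecord(ind, 0, alleles[0]))
            records.append(AlleleRecord(ind, 1, alleles[1]))
        loci.append(
            Locus(locus_id=locus_id, records=records, length=config.locus_length)
        )

    dataset = Dataset(loci=loci, individuals=[ind for ind, _ in individuals])
    dataset.validate()
    return dataset, TruthTable(species_of, introgressed, missing)


def study_preset_config(seed: int) -> SimulationConfig:
    """Config approximating the study's shape: 13 diploid individuals in 7
    species (sizes 3,2,2,2,2,1,1), 500 loci of 120 bp, moderate divergence,
    10% missingness globally, and two designated individuals (one each in
    species 2 and 3) with 95% missingness — stand-ins for libraries with
    very little data."""
    return SimulationConfig(
        n_species=7,
        inds_per_species=[3, 2, 2, 2, 2, 1, 1],
        n_loci=500,
        locus_length=120,
        divergence_rate=0.03,
        polymorphism_rate=0.005,
        pool_size=3,
        introgression_rho=0.0,
        missing_rate=0.1,
        seed=seed,
        missing_overrides={ind: 0.95 for ind in STUDY_HIGH_MISSING},
    )


def emulate_study_design(seed: int) -> tuple[Dataset, TruthTable]:
    """Simulate a dataset with the study-shaped preset (see
    :func:`study_preset_config`)."""
    return simulate_dataset(study_preset_config(seed))


def write_truth_tsv(truth: TruthTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("individual\tspecies\n")
        for ind, s in truth.species_of.items():
            fh.write(f"{ind}\t{s}\n")


def read_truth_tsv(path: str | Path) -> dict[str, str]:
    """Read an individual→species-label truth table."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("individual"):
            raise ValidationError(f"{path}: expected 'individual<TAB>species' header")
        for line in fh:
            if line.strip():
                ind, label = line.rstrip("\n").split("\t")
                out[ind] = label
    return out


def write_events_tsv(
    events: list[tuple[str, str]], path: str | Path, kind: str
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"individual\tlocus\t{kind}\n")
        for ind, locus in events:
            fh.write(f"{ind}\t{locus}\t1\n")


def config_as_dict(config: SimulationConfig) -> dict:
    return asdict(config)
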