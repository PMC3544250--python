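"""Backcross-genetics simulator: meiosis, crossing, and SSR genotyping.

Simulates BC\\ :sub:`n`\\ F\\ :sub:`1` populations from a donor x recipient
cross.  A diploid genome is represented per chromosome as two haplotypes,
each an ordered list of ancestry segments (recipient vs donor) tiling the
chromosome on 0-based half-open bp intervals.  Meiosis draws crossover counts
from a Poisson distribution with mean equal to the chromosome map length in
Morgans (Haldane model, no interference) and crossover positions uniformly
in physical coordinates, i.e. a globally linear cM/Mb map.

Genotyping a plant at a marker yields the codominant SSR call used in
marker-assisted backcrossing:

* ``A`` - homozygous for the recipient (recurrent parent) allele,
* ``B`` - homozygous for the donor allele,
* ``H`` - heterozygous,
* ``-`` - missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import IntegrityError, PanelValidationError
from .marker_panel import MarkerPanel

RECIPIENT = "recipient"
DONOR = "donor"
MISSING = "-"

#: Genome-wide average map density used by default, in centimorgan per megabase.
DEFAULT_CM_PER_MB = 4.0


@dataclass(frozen=True)
class AncestrySegment:
    """Maximal run of one parental origin; 0-based half-open [start_bp, end_bp)."""

    start_bp: int
    end_bp: int
    origin: str

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise IntegrityError(
                f"empty ancestry segment [{self.start_bp}, {self.end_bp})"
            )
        if self.origin not in (RECIPIENT, DONOR):
            raise IntegrityError(f"unknown origin {self.origin!r}")

    def __len__(self) -> int:
        return self.end_bp - self.start_bp


Haplotype = tuple[AncestrySegment, ...]


@dataclass(frozen=True)
class GeneticMap:
    """Linear physical-to-genetic map over the 12 chromosomes.

    Parameters
    ----------
    chromosome_lengths_bp
        chromosome -> physical length in bp.
    cm_per_mb
        global conversion rate, or per-chromosome mapping.  Map length of a
        chromosome in Morgans is ``length_bp * cm_per_mb / 1e8``.
    """

    chromosome_lengths_bp: Mapping[int, int]
    cm_per_mb: float | Mapping[int, float] = DEFAULT_CM_PER_MB

    def rate(self, chromosome: int) -> float:
        if isinstance(self.cm_per_mb, Mapping):
            return float(self.cm_per_mb[chromosome])
        return float(self.cm_per_mb)

    def morgans(self, chromosome: int) -> float:
        return self.chromosome_lengths_bp[chromosome] * self.rate(chromosome) / 1e8

    def chromosomes(self) -> list[int]:
        return sorted(self.chromosome_lengths_bp)


def haldane_recomb_fraction(distance_morgans: float) -> float:
    """Haldane map function r = (1 - exp(-2d)) / 2 for d in Morgans."""
    if distance_morgans < 0:
        raise ValueError("map distance must be non-negative")
    return 0.5 * (1.0 - math.exp(-2.0 * distance_morgans))


@dataclass
class PlantGenome:
    """A diploid genome: per chromosome, two segment-tiled haplotypes."""

    plant_id: str
    haplotypes: dict[int, tuple[Haplotype, Haplotype]]

    @classmethod
    def founder(
        cls, plant_id: str, origin: str, chromosome_lengths_bp: Mapping[int, int]
    ) -> "PlantGenome":
        """Fully homozygous founder of a single parental origin."""
        haps = {
            chrom: (
                (AncestrySegment(0, length, origin),),
                (AncestrySegment(0, length, origin),),
            )
            for chrom, length in chromosome_lengths_bp.items()
        }
        return cls(plant_id, haps)

    def chromosome_length(self, chromosome: int) -> int:
        return self.haplotypes[chromosome][0][-1].end_bp

    def validate(self) -> None:
        """Check the tiling invariants; raise :class:`IntegrityError` on violation."""
        for chrom, pair in self.haplotypes.items():
            for hap in pair:
                if not hap:
                    raise IntegrityError(f"{self.plant_id} chr{chrom}: empty haplotype")
                if hap[0].start_bp != 0:
                    raise IntegrityError(
                        f"{self.plant_id} chr{chrom}: tiling does not start at 0"
                    )
                for prev, cur in zip(hap, hap[1:]):
                    if cur.start_bp != prev.end_bp:
                        raise IntegrityError(
                            f"{self.plant_id} chr{chrom}: gap or overlap at {cur.start_bp}"
                        )
                    if cur.origin == prev.origin:
                        raise IntegrityError(
                            f"{self.plant_id} chr{chrom}: non-maximal segments at "
                            f"{cur.start_bp}"
                        )

    def origin_at(self, chromosome: int, pos0: int) -> tuple[str, str]:
        """Parental origin of both haplotypes at a 0-based position."""
        result = []
        for hap in self.haplotypes[chromosome]:
            for seg in hap:
                if seg.start_bp <= pos0 < seg.end_bp:
                    result.append(seg.origin)
                    break
            else:
                raise IntegrityError(
                    f"{self.plant_id} chr{chromosome}: position {pos0} uncovered"
                )
        return tuple(result)  # type: ignore[return-value]


def _merge(segments: Iterable[AncestrySegment]) -> Haplotype:
    """Re-normalize a segment run to a maximal tiling."""
    merged: list[AncestrySegment] = []
    for seg in segments:
        if merged and merged[-1].origin == seg.origin:
            merged[-1] = AncestrySegment(merged[-1].start_bp, seg.end_bp, seg.origin)
        else:
            merged.append(seg)
    return tuple(merged)


def _copy_interval(hap: Haplotype, start: int, end: int) -> list[AncestrySegment]:
    out = []
    for seg in hap:
        lo = max(seg.start_bp, start)
        hi = min(seg.end_bp, end)
        if lo < hi:
            out.append(AncestrySegment(lo, hi, seg.origin))
    return out

def simulate_gamete(
    parent: PlantGenome, genetic_map: GeneticMap, rng: np.random.Generator
) -> dict[int, Haplotype]:
    """Simulate one meiotic product (a single haplotype per chromosome).

    Per chromosome, in ascending chromosome order, the draws are: the starting
    parental haplotype (fair coin), the crossover count (Poisson with mean =
    map length in Morgans), then the crossover positions (uniform in bp).
    The gamete alternates between the two parental haplotypes at crossovers.
    """
    gamete: dict[int, Haplotype] = {}
    for chrom in sorted(parent.haplotypes):
        length = parent.chromosome_length(chrom)
        current = int(rng.integers(2))
        n_xo = int(rng.poisson(genetic_map.morgans(chrom)))
        cuts = np.sort(rng.integers(1, length, size=n_xo)) if n_xo else np.array([], int)
        breaks = [0, *[int(c) for c in np.unique(cuts)], length]
        pieces: list[AncestrySegment] = []
        for start, end in zip(breaks, breaks[1:]):
            pieces.extend(
                _copy_interval(parent.haplotypes[chrom][current], start, end)
            )
            current = 1 - current
        gamete[chrom] = _merge(pieces)
    return gamete


def cross(
    mother: PlantGenome,
    father: PlantGenome,
    n_progeny: int,
    genetic_map: GeneticMap,
    rng: np.random.Generator,
    id_prefix: str = "P",
) -> list[PlantGenome]:
    """Cross two plants; each progeny unites one gamete from each parent.

    Progeny identifiers are ``{id_prefix}{i:04d}`` and, like the genomes
    themselves, are deterministic given the generator state.
    """
    if n_progeny <= 0:
        raise ValueError("n_progeny must be positive")
    progeny = []
    for i in range(n_progeny):
        maternal = simulate_gamete(mother, genetic_map, rng)
        paternal = simulate_gamete(father, genetic_map, rng)
        haps = {chrom: (maternal[chrom], paternal[chrom]) for chrom in maternal}
        progeny.append(PlantGenome(f"{id_prefix}{i:04d}", haps))
    return progeny


@dataclass
class GenotypeMatrix:
    """Plants x markers of categorical calls A/B/H/``-`` (missing).

    Backed by a pandas DataFrame of strings with plant ids as the index and
    marker names as columns.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise IntegrityError("duplicate plant ids in genotype matrix")
        valid = {"A", "B", "H", MISSING}
        bad = set(np.unique(self.frame.to_numpy(dtype=str))) - valid
        if bad:
            raise IntegrityError(f"invalid genotype calls: {sorted(bad)}")

    @property
    def plant_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def marker_names(self) -> list[str]:
        return list(self.frame.columns)

    def call(self, plant_id: str, marker: str) -> str:
        return str(self.frame.at[plant_id, marker])

    def calls_for(self, plant_id: str) -> pd.Series:
        return self.frame.loc[plant_id]

    def subset_plants(self, plant_ids: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.frame.loc[list(plant_ids)].copy())

    def subset_markers(self, markers: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.frame.loc[:, list(markers)].copy())

    def write(self, path: str | Path, sep: str = ",") -> None:
        self.frame.to_csv(path, sep=sep, index_label="plant_id")

    @classmethod
    def read(cls, path: str | Path) -> "GenotypeMatrix":
        frame = pd.read_csv(path, sep=None, engine="python", dtype=str)
        if "plant_id" not in frame.columns:
            raise IntegrityError("genotype matrix file must have a plant_id column")
        return cls(frame.set_index("plant_id"))


def genotype_plants(
    plants: Sequence[PlantGenome],
    panel: MarkerPanel,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Score every plant at every panel marker as A, B, H or missing.

    The 1-based marker coordinate is converted to the simulator's 0-based
    system here, exactly once.  With ``missing_rate > 0`` each call is
    independently dropped with that probability (requires ``rng``).
    """
    if missing_rate and rng is None:
        raise ValueError("missing_rate > 0 requires an rng")
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be a probability")
    for m in panel:
        for plant in plants[:1]:
            if m.position_bp > plant.chromosome_length(m.chromosome):
                raise PanelValidationError(
                    f"marker {m.name} beyond chromosome {m.chromosome} length"
                )
    names = panel.names
    rows = np.empty((len(plants), len(names)), dtype=object)
    for i, plant in enumerate(plants):
        for j, marker in enumerate(panel):
            a, b = plant.origin_at(marker.chromosome, marker.position_bp - 1)
            if a == b:
                rows[i, j] = "A" if a == RECIPIENT else "B"
            else:
                rows[i, j] = "H"
    if missing_rate:
        mask = rng.random(rows.shape) < missing_rate
        rows[mask] = MISSING
    frame = pd.DataFrame(rows, index=[p.plant_id for p in plants], columns=names)
    return GenotypeMatrix(frame)


def true_rpg(plant: PlantGenome) -> float:
    """Ground-truth recurrent-parent-genome percentage, bp-weighted.

    Counts recipient allele-bp over both haplotypes, so heterozygous
    intervals contribute half; in [0, 100].
    """
    recipient_bp = 0
    total_bp = 0
    for chrom, pair in plant.haplotypes.items():
        for hap in pair:
            for seg in hap:
                total_bp += len(seg)
                if seg.origin == RECIPIENT:
                    recipient_bp += len(seg)
    return 100.0 * recipient_bp / total_bp


def unselected_backcross_population(
    n_plants: int,
    n_backcrosses: int,
    genetic_map: GeneticMap,
    rng: np.random.Generator,
    id_prefix: str | None = None,
) -> list[PlantGenome]:
    """Simulate independent unselected BC\\ :sub:`n`\\ F\\ :sub:`1` plants.

    Each plant descends through its own chain of single-plant backcrosses of
    the F1 to the recipient; the expected recurrent genome fraction after
    n backcrosses is ``1 - 2**-(n+1)``.
    """
    if n_backcrosses < 1:
        raise ValueError("n_backcrosses must be >= 1")
    lengths = genetic_map.chromosome_lengths_bp
    recipient = PlantGenome.founder("recipient", RECIPIENT, lengths)
    donor = PlantGenome.founder("donor", DONOR, lengths)
    prefix = id_prefix or f"BC{n_backcrosses}F1_"
    plants = []
    for i in range(n_plants):
        individual = cross(donor, recipient, 1, genetic_map, rng, id_prefix="F1_")[0]
        for _ in range(n_backcrosses):
            individual = cross(individual, recipient, 1, genetic_map, rng)[0]
        individual.plant_id = f"{prefix}{i:04d}"
        plants.append(individual)
    return plants


def write_truth_sidecar(plants: Sequence[PlantGenome], path: str | Path) -> None:
    """Write the ``plant_id,true_rpg_percent`` oracle table for a population."""
    pd.DataFrame(
        {
            "plant_id": [p.plant_id for p in plants],
            "true_rpg_percent": [true_rpg(p) for p in plants],
        }
    ).to_csv(path, index=False)


__all__ = [
    "AncestrySegment",
    "GeneticMap",
    "GenotypeMatrix",
    "PlantGenome",
    "DEFAULT_CM_PER_MB",
    "RECIPIENT",
    "DONOR",
    "MISSING",
    "haldane_recomb_fraction",
    "simulate_gamete",
    "cross",
    "genotype_plants",
    "true_rpg",
    "unselected_backcross_population",
    "write_truth_sidecar",
]
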