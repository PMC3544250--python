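"""Packaged fixtures: the Saltol-region marker table, a synthetic 89-marker
background panel, and a toy genotype matrix.

The Saltol-region panel transcribes the published marker table for the
FL478 -> BT7 introgression programme (chromosome 1; foreground markers
RM493 and RM3412b, flanking markers for recombinant selection).  Two markers
are published without SSR coordinates (AP3206f, RM3412b); their ``position_bp``
is taken from the printed megabase value, the others use their SSR start.

The background panel is synthetic (the study's genome-wide panel is not
published): 89 polymorphic markers spread deterministically over the 12
chromosomes, at least four per chromosome, allocation proportional to
chromosome length, with the Saltol window on chromosome 1 excluded so the
background set stays unlinked to the target locus.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Mapping

from .backcross_sim import GenotypeMatrix
from .marker_panel import (
    DEFAULT_CHROMOSOME_LENGTHS_BP,
    Marker,
    MarkerPanel,
    load_marker_panel,
)

#: Window on chromosome 1 (bp) reserved for the target region; background
#: markers are kept outside it.
SALTOL_WINDOW_BP: tuple[int, int] = (10_500_000, 16_500_000)


def _data_path(name: str) -> Path:
    return Path(resources.files("mabckit").joinpath("data", name))  # type: ignore[arg-type]


def table1_panel() -> MarkerPanel:
    """The packaged Saltol-region marker panel (foreground + flank roles)."""
    return load_marker_panel(_data_path("saltol_region_markers.tsv"))


def background_panel() -> MarkerPanel:
    """The packaged fixed 89-marker synthetic background panel."""
    return load_marker_panel(_data_path("background89.tsv"))


def default_panel() -> MarkerPanel:
    """Saltol-region panel merged with the 89-marker background panel."""
    return table1_panel().merged(background_panel())


def toy_matrix() -> GenotypeMatrix:
    """A 4-plant x 6-marker matrix used as a hand-checkable selection oracle."""
    return GenotypeMatrix.read(_data_path("toy_matrix.csv"))


def build_background_panel(
    n_markers: int = 89,
    chromosome_lengths: Mapping[int, int] | None = None,
    min_per_chromosome: int = 4,
    exclude_chr1_window: tuple[int, int] = SALTOL_WINDOW_BP,
) -> MarkerPanel:
    """Deterministically construct the synthetic background panel.

    Markers are allocated to chromosomes proportionally to physical length
    (largest-remainder rounding, floor of ``min_per_chromosome``) and placed
    evenly along each chromosome.  On chromosome 1 the placement skips the
    excluded target window by spacing markers over the complement and shifting
    coordinates past the window.
    """
    lengths = dict(chromosome_lengths or DEFAULT_CHROMOSOME_LENGTHS_BP)
    chroms = sorted(lengths)
    if n_markers < min_per_chromosome * len(chroms):
        raise ValueError("n_markers too small for the per-chromosome minimum")
    total = sum(lengths.values())
    quota = {c: n_markers * lengths[c] / total for c in chroms}
    counts = {c: max(min_per_chromosome, int(quota[c])) for c in chroms}
    # largest-remainder top-up / trim to hit n_markers exactly
    while sum(counts.values()) < n_markers:
        c = max(chroms, key=lambda c: (quota[c] - counts[c], -c))
        counts[c] += 1
    while sum(counts.values()) > n_markers:
        c = min(
            (c for c in chroms if counts[c] > min_per_chromosome),
            key=lambda c: (quota[c] - counts[c], -c),
        )
        counts[c] -= 1

    markers = []
    for chrom in chroms:
        n = counts[chrom]
        if chrom == 1:
            lo, hi = exclude_chr1_window
            usable = lengths[chrom] - (hi - lo)
        else:
            usable = lengths[chrom]
        for j in range(1, n + 1):
            pos = round(usable * j / (n + 1))
            if chrom == 1 and pos >= exclude_chr1_window[0]:
                pos += exclude_chr1_window[1] - exclude_chr1_window[0]
            markers.append(
                Marker(
                    name=f"SBG{chrom:02d}_{j:02d}",
                    chromosome=chrom,
                    position_bp=max(1, pos),
                    position_mb=round(pos / 1e6, 1),
                    role="background",
                    polymorphic=True,
                )
            )
    return MarkerPanel(markers, lengths)


__all__ = [
    "SALTOL_WINDOW_BP",
    "table1_panel",
    "background_panel",
    "default_panel",
    "toy_matrix",
    "build_background_panel",
]
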