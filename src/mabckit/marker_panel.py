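"""SSR marker panels: loading, validation and polymorphism bookkeeping.

A panel is an ordered collection of microsatellite (SSR) markers with physical
coordinates on the 12 rice chromosomes.  Markers carry a selection *role*:

``foreground``
    tightly linked to the target locus (here the *Saltol* QTL on chromosome 1);
    plants must be heterozygous at these markers to carry the donor allele.
``flank``
    flanking the target region; used for recombinant selection against
    linkage drag.
``background``
    genome-wide markers unlinked to the target, used to select for recurrent
    parent genome.

Coordinates follow the convention of published SSR tables: marker positions
and SSR spans are 1-based inclusive base-pair coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import FormatError, PanelValidationError

logger = logging.getLogger(__name__)

ROLES = ("foreground", "flank", "background")

#: Default pseudo-chromosome lengths (bp) for the 12 rice chromosomes.
#: Round megabase values of the order of the japonica reference assembly;
#: chromosome 1 is the Saltol carrier and the longest.
DEFAULT_CHROMOSOME_LENGTHS_BP: dict[int, int] = {
    1: 45_000_000,
    2: 36_000_000,
    3: 37_000_000,
    4: 36_000_000,
    5: 30_000_000,
    6: 32_000_000,
    7: 30_000_000,
    8: 29_000_000,
    9: 23_000_000,
    10: 24_000_000,
    11: 29_000_000,
    12: 28_000_000,
}

PANEL_COLUMNS = [
    "name",
    "chromosome",
    "position_bp",
    "position_mb",
    "forward_primer",
    "reverse_primer",
    "motif",
    "n_repeats",
    "ssr_start",
    "ssr_end",
    "role",
    "polymorphic",
]

_REQUIRED_COLUMNS = ("name", "chromosome", "position_bp")


@dataclass(frozen=True)
class Marker:
    """A single SSR locus.

    Optional descriptive fields (primers, motif, repeat structure) may be
    absent (``None``); absence is distinct from zero.
    """

    name: str
    chromosome: int
    position_bp: int
    position_mb: float | None = None
    forward_primer: str | None = None
    reverse_primer: str | None = None
    motif: str | None = None
    n_repeats: int | None = None
    ssr_start_bp: int | None = None
    ssr_end_bp: int | None = None
    role: str = "background"
    polymorphic: bool = True

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PanelValidationError(
                f"marker {self.name}: unknown role {self.role!r} (expected one of {ROLES})"
            )
        if not 1 <= self.chromosome <= 12:
            raise PanelValidationError(
                f"marker {self.name}: chromosome {self.chromosome} outside 1-12"
            )
        if self.position_bp < 1:
            raise PanelValidationError(
                f"marker {self.name}: position_bp must be a positive 1-based coordinate"
            )
        if (
            self.ssr_start_bp is not None
            and self.ssr_end_bp is not None
            and self.ssr_start_bp > self.ssr_end_bp
        ):
            raise PanelValidationError(
                f"marker {self.name}: SSR start {self.ssr_start_bp} > end {self.ssr_end_bp}"
            )
        if self.role == "foreground" and self.chromosome != 1:
            raise PanelValidationError(
                f"marker {self.name}: foreground markers must lie on the Saltol "
                f"carrier chromosome 1, not chromosome {self.chromosome}"
            )


@dataclass(frozen=True)
class SSRSpanReport:
    """Internal-consistency audit of a marker's printed repeat structure."""

    marker: str
    applicable: bool
    implied_repeats: Fraction | None = None
    printed_repeats: int | None = None
    consistent: bool | None = None


@dataclass
class MarkerPanel:
    """An ordered, name-unique collection of markers plus chromosome lengths.

    Markers are kept sorted by (chromosome, position_bp).  Construction
    validates uniqueness and that each marker lies within its chromosome.
    """

    markers: list[Marker]
    chromosome_lengths_bp: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROMOSOME_LENGTHS_BP)
    )

    def __post_init__(self) -> None:
        self.markers = sorted(self.markers, key=lambda m: (m.chromosome, m.position_bp))
        seen: set[str] = set()
        for m in self.markers:
            if m.name in seen:
                raise PanelValidationError(f"duplicate marker name: {m.name}")
            seen.add(m.name)
            length = self.chromosome_lengths_bp.get(m.chromosome)
            if length is None:
                raise PanelValidationError(
                    f"marker {m.name}: no configured length for chromosome {m.chromosome}"
                )
            if m.position_bp > length:
                raise PanelValidationError(
                    f"marker {m.name}: position {m.position_bp} beyond chromosome "
                    f"{m.chromosome} length {length}"
                )

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    def get(self, name: str) -> Marker:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(m.name == name for m in self.markers)

    def by_role(self, role: str) -> list[Marker]:
        return [m for m in self.markers if m.role == role]

    def subset(self, names: Iterable[str]) -> "MarkerPanel":
        wanted = set(names)
        missing = wanted - set(self.names)
        if missing:
            raise KeyError(f"markers not in panel: {sorted(missing)}")
        return MarkerPanel(
            [m for m in self.markers if m.name in wanted], self.chromosome_lengths_bp
        )

    def merged(self, other: "MarkerPanel") -> "MarkerPanel":
        return MarkerPanel(
            list(self.markers) + list(other.markers), self.chromosome_lengths_bp
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.markers:
            rows.append(
                {
                    "name": m.name,
                    "chromosome": m.chromosome,
                    "position_bp": m.position_bp,
                    "position_mb": m.position_mb,
                    "forward_primer": m.forward_primer,
                    "reverse_primer": m.reverse_primer,
                    "motif": m.motif,
                    "n_repeats": m.n_repeats,
                    "ssr_start": m.ssr_start_bp,
                    "ssr_end": m.ssr_end_bp,
                    "role": m.role,
                    "polymorphic": m.polymorphic,
                }
            )
        return pd.DataFrame(rows, columns=PANEL_COLUMNS)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        frame = self.to_frame()
        frame["n_repeats"] = frame["n_repeats"].astype("Int64")
        frame["ssr_start"] = frame["ssr_start"].astype("Int64")
        frame["ssr_end"] = frame["ssr_end"].astype("Int64")
        frame.to_csv(path, sep=sep, index=False)

    def validation_report(self, min_per_chromosome: int = 4) -> str:
        """Per-chromosome polymorphic-marker counts against the coverage guideline.

        Background selection needs at least ``min_per_chromosome`` polymorphic
        markers on every chromosome; shortfalls are reported, not raised.
        """
        lines = [
            f"marker panel: {len(self.markers)} markers "
            f"({sum(m.polymorphic for m in self.markers)} polymorphic)"
        ]
        for chrom in sorted(self.chromosome_lengths_bp):
            n_poly = sum(
                1 for m in self.markers if m.chromosome == chrom and m.polymorphic
            )
            flag = "" if n_poly >= min_per_chromosome else (
                f"  ** below guideline of {min_per_chromosome}"
            )
            lines.append(f"chromosome {chrom:>2}: {n_poly:>3} polymorphic markers{flag}")
        return "\n".join(lines)


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def _opt_int(value) -> int | None:
    s = _opt_str(value)
    return None if s is None else int(float(s))


def _opt_float(value) -> float | None:
    s = _opt_str(value)
    return None if s is None else float(s)


def load_marker_panel(
    path: str | Path,
    chromosome_lengths: Mapping[int, int] | None = None,
) -> MarkerPanel:
    """Load a marker panel from a tab- or comma-separated table.

    Required columns: ``name``, ``chromosome``, ``position_bp``.  All other
    columns are optional; blank cells become absent fields (``None``), never
    zero.  ``role`` defaults to ``background`` and ``polymorphic`` to true.

    Raises
    ------
    FormatError
        if a required column is missing.
    PanelValidationError
        on duplicate names or out-of-range coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep=None, engine="python", dtype=str)
    for col in _REQUIRED_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"{path.name}: required column {col!r} is missing")
    if table.empty:
        logger.warning("%s: panel file has a header but no markers", path.name)
    markers = []
    for _, row in table.iterrows():
        polymorphic_raw = _opt_str(row.get("polymorphic"))
        markers.append(
            Marker(
                name=str(row["name"]).strip(),
                chromosome=int(row["chromosome"]),
                position_bp=int(float(row["position_bp"])),
                position_mb=_opt_float(row.get("position_mb")),
                forward_primer=_opt_str(row.get("forward_primer")),
                reverse_primer=_opt_str(row.get("reverse_primer")),
                motif=_opt_str(row.get("motif")),
                n_repeats=_opt_int(row.get("n_repeats")),
                ssr_start_bp=_opt_int(row.get("ssr_start")),
                ssr_end_bp=_opt_int(row.get("ssr_end")),
                role=_opt_str(row.get("role")) or "background",
                polymorphic=(
                    True
                    if polymorphic_raw is None
                    else polymorphic_raw.lower() in ("1", "true", "yes")
                ),
            )
        )
    lengths = dict(chromosome_lengths or DEFAULT_CHROMOSOME_LENGTHS_BP)
    return MarkerPanel(markers, lengths)


def check_ssr_span(marker: Marker) -> SSRSpanReport:
    """Audit a marker's SSR span against its printed motif and repeat count.

    ``implied_repeats = (ssr_end - ssr_start + 1) / len(motif)`` on 1-based
    inclusive coordinates; the report is *consistent* when the implied count
    equals the printed one.  If any of motif, repeat count, or span is absent
    the check is not applicable (no error).
    """
    if (
        marker.motif is None
        or marker.n_repeats is None
        or marker.ssr_start_bp is None
        or marker.ssr_end_bp is None
    ):
        return SSRSpanReport(marker=marker.name, applicable=False)
    implied = Fraction(marker.ssr_end_bp - marker.ssr_start_bp + 1, len(marker.motif))
    return SSRSpanReport(
        marker=marker.name,
        applicable=True,
        implied_repeats=implied,
        printed_repeats=marker.n_repeats,
        consistent=implied == marker.n_repeats,
    )


def polymorphism_rate(n_polymorphic: int, n_screened: int) -> float:
    """Percentage of screened markers that are polymorphic, half-up to 1 d.p.

    E.g. 89 polymorphic of 477 screened -> 18.7.
    """
    if n_screened <= 0:
        raise ValueError("n_screened must be positive")
    if not 0 <= n_polymorphic <= n_screened:
        raise ValueError("n_polymorphic must lie in [0, n_screened]")
    rate = Decimal(100 * n_polymorphic) / Decimal(n_screened)
    return float(rate.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def audit_panel_spans(panel: MarkerPanel) -> list[SSRSpanReport]:
    """Run :func:`check_ssr_span` over every marker of a panel."""
    return [check_ssr_span(m) for m in panel.markers]


__all__ = [
    "Marker",
    "MarkerPanel",
    "SSRSpanReport",
    "DEFAULT_CHROMOSOME_LENGTHS_BP",
    "load_marker_panel",
    "check_ssr_span",
    "audit_panel_spans",
    "polymorphism_rate",
]
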