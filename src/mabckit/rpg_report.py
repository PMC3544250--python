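"""Recurrent-parent-genome statistics and reporting.

Implements the marker-based recovery statistics used in marker-assisted
backcrossing:

* ``%A`` — percentage of non-missing markers homozygous for the recipient
  allele: ``100 * n_A / (n_A + n_B + n_H)``.
* ``%R`` — percent recipient *alleles*, counting heterozygotes at half
  weight: ``100 * (n_A + 0.5 * n_H) / (n_A + n_B + n_H)``.

Markers already fixed for the recipient allele in an earlier generation (and
therefore no longer screened) are carried in a *fixed ledger* and counted as
``A`` so percentages remain comparable across generations.

Also provides the population %R histogram, GGT-style graphical genotypes
(text and matplotlib renderings), Duncan's multiple-range test for the
agronomic comparison table, and a small salinity yield-loss utility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .backcross_sim import MISSING, GenotypeMatrix
from .marker_panel import MarkerPanel

# Glyphs for text graphical genotypes.
GLYPH_RECIPIENT = "."
GLYPH_DONOR = "#"
GLYPH_HET = "+"
GLYPH_UNKNOWN = "?"
GLYPH_TICK = "|"


@dataclass(frozen=True)
class RPGSummary:
    """Per-plant recurrent-parent-genome summary over a marker set."""

    plant_id: str
    n_A: int
    n_B: int
    n_H: int
    n_missing: int

    @property
    def n_scored(self) -> int:
        return self.n_A + self.n_B + self.n_H

    @property
    def percent_A(self) -> float:
        return 100.0 * self.n_A / self.n_scored

    @property
    def percent_R(self) -> float:
        return 100.0 * (self.n_A + 0.5 * self.n_H) / self.n_scored


def compute_rpg(
    calls: Sequence[str] | pd.Series,
    fixed_ledger: int = 0,
    plant_id: str = "",
) -> RPGSummary:
    """Summarize one plant's calls into %A / %R.

    ``fixed_ledger`` markers (fixed-for-recipient, no longer screened) are
    counted as ``A``.  Missing calls are excluded from denominators.

    Raises
    ------
    ValueError
        if every call is missing and the ledger is empty (undefined result).
    """
    if fixed_ledger < 0:
        raise ValueError("fixed_ledger must be non-negative")
    values = list(calls)
    n_a = values.count("A") + fixed_ledger
    n_b = values.count("B")
    n_h = values.count("H")
    n_missing = values.count(MISSING)
    if n_a + n_b + n_h == 0:
        raise ValueError(
            f"plant {plant_id or '?'}: all calls missing and no fixed markers; "
            "%A/%R undefined"
        )
    return RPGSummary(plant_id=plant_id, n_A=n_a, n_B=n_b, n_H=n_h, n_missing=n_missing)


def rpg_table(
    matrix: GenotypeMatrix,
    markers: Sequence[str] | None = None,
    fixed_ledger: int = 0,
) -> pd.DataFrame:
    """Per-plant RPG summary table (one row per plant) over a marker subset."""
    sub = matrix if markers is None else matrix.subset_markers(markers)
    rows = []
    for pid in sub.plant_ids:
        s = compute_rpg(sub.calls_for(pid), fixed_ledger=fixed_ledger, plant_id=pid)
        rows.append(
            {
                "plant_id": pid,
                "n_A": s.n_A,
                "n_H": s.n_H,
                "n_B": s.n_B,
                "n_missing": s.n_missing,
                "percent_A": s.percent_A,
                "percent_R": s.percent_R,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RPGHistogram:
    """Binned population distribution of per-plant %R."""

    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    n_plants: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def rpg_histogram(
    summaries: Sequence[RPGSummary], bin_width: float = 2.5
) -> RPGHistogram:
    """Histogram of %R with right-open bins; the last bin is closed at 100.

    Bin edges start at the largest multiple of ``bin_width`` not exceeding the
    smallest observed value and run to 100, so counts always conserve the
    number of plants.
    """
    if not summaries:
        raise ValueError("no RPG summaries to bin")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.array([s.percent_R for s in summaries])
    lo = math.floor(values.min() / bin_width) * bin_width
    if lo >= 100.0:  # a population entirely at full recovery still needs a bin
        lo = 100.0 - bin_width
    n_bins = max(1, math.ceil((100.0 - lo) / bin_width - 1e-9))
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], 100.0)
    counts, _ = np.histogram(values, bins=edges)
    return RPGHistogram(
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
        n_plants=len(summaries),
    )


def plot_rpg_histogram(hist: RPGHistogram, ax=None):
    """Bar rendering of the %R frequency distribution."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    lefts = np.array(hist.bin_edges[:-1])
    widths = np.diff(hist.bin_edges)
    ax.bar(lefts, hist.counts, width=widths, align="edge", edgecolor="black",
           color="0.7")
    ax.set_xlabel("recurrent parent genome (%R)")
    ax.set_ylabel("number of plants")
    return ax


# ---------------------------------------------------------------------------
# graphical genotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromosomePaint:
    """Interval classification of one chromosome for one plant.

    ``positions`` are the bp coordinates of the informative (non-missing)
    markers; ``classes`` has one glyph per interval between consecutive
    markers plus the two chromosome ends (``len(positions) + 1`` entries, or a
    single entry when no marker is informative).
    """

    chromosome: int
    length_bp: int
    positions: tuple[int, ...]
    classes: tuple[str, ...]


@dataclass(frozen=True)
class GraphicalGenotype:
    plant_id: str
    paints: tuple[ChromosomePaint, ...]


def _classify(left: str | None, right: str | None) -> str:
    flanks = [c for c in (left, right) if c is not None]
    if not flanks:
        return GLYPH_UNKNOWN
    if "B" in flanks:
        return GLYPH_DONOR
    if "H" in flanks:
        return GLYPH_HET
    return GLYPH_RECIPIENT


def graphical_genotype(
    matrix: GenotypeMatrix, panel: MarkerPanel, plant_id: str
) -> GraphicalGenotype:
    """Classify inter-marker intervals of one plant for chromosome-bar plots.

    Within a chromosome, each interval between adjacent informative markers is
    coloured from its two flanking calls: both ``A`` -> recipient; any ``B``
    -> donor; otherwise (any ``H``) -> heterozygous introgression.  The
    chromosome ends take the class of their single nearest marker.  Missing
    calls are uninformative and drop out of the flanking logic; a chromosome
    with no informative marker is rendered as unknown.
    """
    if plant_id not in matrix.plant_ids:
        raise KeyError(f"plant {plant_id} not in genotype matrix")
    calls = matrix.calls_for(plant_id)
    paints = []
    for chrom in sorted(panel.chromosome_lengths_bp):
        markers = [m for m in panel if m.chromosome == chrom and m.name in calls.index]
        informative = [(m.position_bp, calls[m.name]) for m in markers
                       if calls[m.name] != MISSING]
        length = panel.chromosome_lengths_bp[chrom]
        if not informative:
            paints.append(
                ChromosomePaint(chrom, length, (), (GLYPH_UNKNOWN,))
            )
            continue
        positions = tuple(p for p, _ in informative)
        cls = [_classify(None, informative[0][1])]
        for (p0, c0), (p1, c1) in zip(informative, informative[1:]):
            cls.append(_classify(c0, c1))
        cls.append(_classify(informative[-1][1], None))
        paints.append(ChromosomePaint(chrom, length, positions, tuple(cls)))
    return GraphicalGenotype(plant_id=plant_id, paints=tuple(paints))


def render_text(gg: GraphicalGenotype, width: int = 72) -> str:
    """Fixed-width text bars: ``.`` recipient, ``#`` donor, ``+`` het, ``|`` tick.

    Interval glyph-run lengths are proportional to physical span with a
    one-character minimum, so every interval survives rendering and
    :func:`parse_text` recovers the classification exactly.
    """
    lines = [f"plant {gg.plant_id}"]
    for paint in gg.paints:
        bounds = [0, *paint.positions, paint.length_bp]
        spans = [max(1, b - a) for a, b in zip(bounds, bounds[1:])]
        total = sum(spans)
        runs = [max(1, round(width * s / total)) for s in spans]
        bar = GLYPH_TICK.join(c * r for c, r in zip(paint.classes, runs))
        lines.append(f"chr{paint.chromosome:02d} {GLYPH_TICK}{bar}{GLYPH_TICK}")
    return "\n".join(lines)


def parse_text(rendering: str) -> dict[int, tuple[str, ...]]:
    """Recover per-chromosome interval classes from a text rendering."""
    out: dict[int, tuple[str, ...]] = {}
    for line in rendering.splitlines():
        if not line.startswith("chr"):
            continue
        label, bar = line.split(" ", 1)
        chrom = int(label[3:])
        segments = bar.strip().strip(GLYPH_TICK).split(GLYPH_TICK)
        out[chrom] = tuple(seg[0] for seg in segments)
    return out


def plot_graphical_genotype(gg: GraphicalGenotype, ax=None):
    """Chromosome-bar figure: white recipient, black donor, hatched het."""
    import matplotlib.pyplot as plt

    face = {
        GLYPH_RECIPIENT: dict(facecolor="white"),
        GLYPH_DONOR: dict(facecolor="black"),
        GLYPH_HET: dict(facecolor="white", hatch="////"),
        GLYPH_UNKNOWN: dict(facecolor="0.8"),
    }
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    for i, paint in enumerate(gg.paints):
        bounds = [0, *paint.positions, paint.length_bp]
        mids = list(zip(bounds, bounds[1:]))
        for (a, b), cls in zip(mids, paint.classes):
            if b > a:
                ax.broken_barh(
                    [(a / 1e6, (b - a) / 1e6)], (i - 0.35, 0.7),
                    edgecolor="black", linewidth=0.4, **face[cls],
                )
        for p in paint.positions:
            ax.plot([p / 1e6, p / 1e6], [i - 0.45, i + 0.45], color="black",
                    linewidth=0.5)
    ax.set_yticks(range(len(gg.paints)))
    ax.set_yticklabels([f"chr{p.chromosome}" for p in gg.paints])
    ax.invert_yaxis()
    ax.set_xlabel("position (Mb)")
    ax.set_title(f"graphical genotype: {gg.plant_id}")
    return ax


# ---------------------------------------------------------------------------
# Duncan's multiple-range test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuncanResult:
    """Ordered-means multiple-range comparison with a letter display.

    ``letters`` maps each group to its letter string; groups sharing a letter
    are not significantly different at ``alpha``.  Letters are named in order
    of first appearance over the input group order (the convention of
    agronomic comparison tables, where the first row is 'a').
    """

    means: Mapping[str, float]
    n_per_group: Mapping[str, int]
    letters: Mapping[str, str]
    lsd: float
    alpha: float
    mse: float
    df_error: int
    least_significant_ranges: Mapping[int, float]

    def summary(self) -> str:
        lines = [
            f"Duncan's multiple-range test (alpha = {self.alpha})",
            f"error MS = {self.mse:.5g} on {self.df_error} df; "
            f"LSD({self.alpha}) = {self.lsd:.3f}",
            "",
            f"{'group':<16}{'n':>4}{'mean':>10}  letters",
        ]
        for g in self.means:
            lines.append(
                f"{g:<16}{self.n_per_group[g]:>4}{self.means[g]:>10.2f}  "
                f"{self.letters[g]}"
            )
        return "\n".join(lines)


def duncan_mrt(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> DuncanResult:
    """Duncan's multiple-range test after a one-way ANOVA.

    The pooled error mean square feeds least significant ranges
    ``R_p = q(1 - alpha_p; p, df) * sqrt(MSE / n_h)`` with Duncan's protection
    level ``alpha_p = 1 - (1 - alpha)^(p - 1)`` over the span ``p`` of each
    ordered-means comparison (``n_h`` the harmonic mean group size).  Groups
    inside a non-significant stretch share a letter.  ``lsd`` is the pairwise
    least significant difference ``t(1 - alpha/2, df) * sqrt(2 MSE / n_h)``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    data = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    k = len(data)
    n_total = sum(v.size for v in data.values())
    df_error = n_total - k
    sse = sum(float(((v - v.mean()) ** 2).sum()) for v in data.values())
    mse = sse / df_error
    n_h = k / sum(1.0 / v.size for v in data.values())
    se = math.sqrt(mse / n_h)
    lsd = stats.t.ppf(1 - alpha / 2, df_error) * math.sqrt(2 * mse / n_h) if mse else 0.0

    ranges: dict[int, float] = {}
    for p in range(2, k + 1):
        if mse == 0.0:
            ranges[p] = 0.0
        else:
            alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
            ranges[p] = float(
                stats.studentized_range.ppf(1 - alpha_p, p, df_error) * se
            )

    order = sorted(data, key=lambda g: -data[g].mean())
    means_sorted = [data[g].mean() for g in order]
    # Non-significant stretches over the ordered means: from each start i the
    # stretch reaches the furthest j whose range test fails to separate it
    # (shielding: a non-significant wide range protects everything inside it).
    candidates = []
    for i in range(k):
        j_max = i
        for j in range(i + 1, k):
            if means_sorted[i] - means_sorted[j] <= ranges[j - i + 1]:
                j_max = j
        candidates.append((i, j_max))
    intervals = [
        (a, b)
        for a, b in candidates
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in candidates)
    ]
    # letters per sorted position
    letters_sorted: dict[int, list[int]] = {i: [] for i in range(k)}
    for idx, (a, b) in enumerate(intervals):
        for i in range(a, b + 1):
            letters_sorted[i].append(idx)
    # rename interval letters in order of first appearance over the input order
    remap: dict[int, str] = {}
    next_letter = 0
    letters: dict[str, str] = {}
    sorted_pos = {g: order.index(g) for g in groups}
    for g in groups:
        ids = letters_sorted[sorted_pos[g]]
        for iid in ids:
            if iid not in remap:
                remap[iid] = chr(ord("a") + next_letter)
                next_letter += 1
        letters[g] = "".join(sorted(remap[iid] for iid in ids))
    return DuncanResult(
        means={g: float(data[g].mean()) for g in groups},
        n_per_group={g: int(data[g].size) for g in groups},
        letters=letters,
        lsd=float(lsd),
        alpha=alpha,
        mse=float(mse),
        df_error=df_error,
        least_significant_ranges=ranges,
    )


def salinity_yield_loss(
    ec_ds_per_m: float, threshold: float = 3.0, slope: float = 12.0
) -> float:
    """Percent rice yield reduction under soil salinity ``ec_ds_per_m`` (dS/m).

    Linear threshold model: no loss up to the tolerance threshold, then
    ``slope`` percent per dS/m, clamped to 100.
    """
    if ec_ds_per_m < 0:
        raise ValueError("electrical conductivity must be non-negative")
    return float(min(100.0, max(0.0, slope * (ec_ds_per_m - threshold))))


__all__ = [
    "RPGSummary",
    "RPGHistogram",
    "ChromosomePaint",
    "GraphicalGenotype",
    "DuncanResult",
    "compute_rpg",
    "rpg_table",
    "rpg_histogram",
    "plot_rpg_histogram",
    "graphical_genotype",
    "render_text",
    "parse_text",
    "plot_graphical_genotype",
    "duncan_mrt",
    "salinity_yield_loss",
]
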