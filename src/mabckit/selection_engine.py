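"""Three-tier marker-assisted backcross selection and the campaign driver.

Each backcross generation is screened in three tiers:

1. **Foreground selection** — keep plants heterozygous at every marker
   tightly linked to the target locus (the donor allele must be present).
2. **Recombinant selection** — among those, keep plants homozygous recipient
   at the generation's flanking marker, i.e. carrying a crossover between the
   target locus and the flank, trimming linkage drag.
3. **Background selection** — rank the survivors by recurrent-parent-genome
   recovery (%R over the genome-wide background markers) and advance the top
   plants as parents of the next backcross.

Background markers observed fixed (homozygous recipient) in all advanced
plants of a generation are dropped from later screening and carried in a
*fixed ledger*, still counted as recipient-homozygous in later %A/%R so the
percentages stay comparable across generations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .backcross_sim import (
    DEFAULT_CM_PER_MB,
    RECIPIENT,
    DONOR,
    GeneticMap,
    GenotypeMatrix,
    PlantGenome,
    cross,
    genotype_plants,
    true_rpg,
)
from .exceptions import CampaignHalt, ConfigurationError
from .marker_panel import MarkerPanel
from .rpg_report import RPGSummary, compute_rpg, rpg_table

logger = logging.getLogger(__name__)

DEFAULT_FOREGROUND = ("RM493", "RM3412b")
#: Flanking-marker schedule: distal flank in BC1, nearest proximal flank in
#: BC2/BC3; the required call is recipient-homozygous (A).
DEFAULT_FLANK_SCHEDULE: dict[int, dict[str, str]] = {
    1: {"RM10825": "A"},
    2: {"RM10694": "A"},
    3: {"RM10694": "A"},
}


@dataclass
class SelectionRoles:
    """Which markers drive each selection tier."""

    foreground_markers: tuple[str, ...] = DEFAULT_FOREGROUND
    flank_markers_by_generation: Mapping[int, Mapping[str, str]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_FLANK_SCHEDULE.items()}
    )
    background_markers: tuple[str, ...] = ()

    def validate(self, panel: MarkerPanel) -> None:
        overlap = set(self.foreground_markers) & set(self.background_markers)
        if overlap:
            raise ConfigurationError(
                f"markers cannot be both foreground and background: {sorted(overlap)}"
            )
        known = set(panel.names)
        for name in (
            *self.foreground_markers,
            *self.background_markers,
            *(m for sched in self.flank_markers_by_generation.values() for m in sched),
        ):
            if name not in known:
                raise ConfigurationError(f"marker {name!r} not in panel")


@dataclass
class CampaignConfig:
    """Reproducibility contract for a full backcross campaign."""

    seed: int
    n_generations: int = 3
    pop_size: int = 300
    n_parents_advanced: int = 2
    cm_per_mb: float = DEFAULT_CM_PER_MB
    missing_rate: float = 0.0
    roles: SelectionRoles | None = None
    panel: MarkerPanel | None = None

    def __post_init__(self) -> None:
        if self.pop_size < self.n_parents_advanced or self.n_parents_advanced < 1:
            raise ConfigurationError(
                "require pop_size >= n_parents_advanced >= 1"
            )
        if self.panel is None:
            self.panel = datasets.default_panel()
        if self.roles is None:
            self.roles = SelectionRoles(
                background_markers=tuple(
                    m.name for m in self.panel.by_role("background")
                )
            )
        self.roles.validate(self.panel)


def load_campaign_config(path: str | Path, seed: int | None = None) -> CampaignConfig:
    """Build a campaign configuration from a YAML key-value file.

    Recognized keys: ``generations``, ``pop_size``, ``n_advanced``, ``seed``,
    ``cm_per_mb``, ``missing_rate``, ``foreground`` (list),
    ``flank_schedule`` (generation -> {marker: call}), ``panel`` (path; the
    packaged panels are used when omitted).  An explicit ``seed`` argument
    overrides the file.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    panel = None
    if raw.get("panel"):
        from .marker_panel import load_marker_panel

        panel = load_marker_panel(raw["panel"])
    else:
        panel = datasets.default_panel()
    roles = SelectionRoles(
        foreground_markers=tuple(raw.get("foreground", DEFAULT_FOREGROUND)),
        flank_markers_by_generation={
            int(g): dict(v)
            for g, v in raw.get("flank_schedule", DEFAULT_FLANK_SCHEDULE).items()
        },
        background_markers=tuple(
            raw.get(
                "background",
                [m.name for m in panel.by_role("background")],
            )
        ),
    )
    cfg_seed = seed if seed is not None else raw.get("seed")
    if cfg_seed is None:
        raise ConfigurationError("a seed is required (config key 'seed' or --seed)")
    return CampaignConfig(
        seed=int(cfg_seed),
        n_generations=int(raw.get("generations", 3)),
        pop_size=int(raw.get("pop_size", 300)),
        n_parents_advanced=int(raw.get("n_advanced", 2)),
        cm_per_mb=float(raw.get("cm_per_mb", DEFAULT_CM_PER_MB)),
        missing_rate=float(raw.get("missing_rate", 0.0)),
        roles=roles,
        panel=panel,
    )


# ---------------------------------------------------------------------------
# selection tiers (pure filters over a genotype matrix)
# ---------------------------------------------------------------------------

def foreground_select(
    matrix: GenotypeMatrix, foreground_markers: Sequence[str]
) -> list[str]:
    """Plants heterozygous (H) at *every* foreground marker; missing disqualifies."""
    for name in foreground_markers:
        if name not in matrix.marker_names:
            raise ConfigurationError(f"foreground marker {name!r} absent from matrix")
    sub = matrix.frame[list(foreground_markers)]
    keep = (sub == "H").all(axis=1)
    return list(sub.index[keep])


def recombinant_select(
    matrix: GenotypeMatrix, flank_requirements: Mapping[str, str]
) -> list[str]:
    """Plants whose call equals the required call at every flanking marker.

    The caller passes the foreground-selected subset; this is a pure filter.
    An empty requirement (no flank configured for a generation) keeps all.
    """
    for name in flank_requirements:
        if name not in matrix.marker_names:
            raise ConfigurationError(f"flank marker {name!r} absent from matrix")
    keep = pd.Series(True, index=matrix.frame.index)
    for name, call in flank_requirements.items():
        keep &= matrix.frame[name] == call
    return list(matrix.frame.index[keep])


def rank_by_rpg(
    matrix: GenotypeMatrix,
    background_markers: Sequence[str],
    fixed_ledger: int = 0,
) -> pd.DataFrame:
    """Plants ranked by descending %R over the background markers.

    Missing calls are excluded per plant; ``fixed_ledger`` markers count as A.
    Ties break by descending %A, then ascending plant id.
    """
    table = rpg_table(matrix, markers=list(background_markers), fixed_ledger=fixed_ledger)
    table = table.sort_values(
        by=["percent_R", "percent_A", "plant_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return table


def background_select(
    matrix: GenotypeMatrix,
    background_markers: Sequence[str],
    k: int,
    fixed_ledger: int = 0,
) -> list[str]:
    """Top-``k`` plant ids by %R (see :func:`rank_by_rpg`).

    An empty candidate set yields an empty result with a warning, and asking
    for more plants than exist returns all of them.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not matrix.plant_ids:
        logger.warning("background selection on an empty candidate set")
        return []
    ranking = rank_by_rpg(matrix, background_markers, fixed_ledger)
    if k > len(ranking):
        logger.warning(
            "requested %d plants but only %d candidates; returning all", k, len(ranking)
        )
    return list(ranking["plant_id"].head(k))


def drop_fixed_markers(
    matrix: GenotypeMatrix,
    selected_ids: Sequence[str],
    background_markers: Sequence[str],
) -> tuple[list[str], list[str]]:
    """Split background markers into (still-screened, fixed-for-recipient).

    A marker is fixed when its call is A in every selected plant; missing
    calls are uninformative, not evidence of fixation.  Fixed markers leave
    the screening list but are counted as A in later %A/%R via the ledger.
    """
    if not selected_ids:
        raise ValueError("selected_ids must be non-empty")
    sub = matrix.frame.loc[list(selected_ids), list(background_markers)]
    fixed = [
        name for name in background_markers if (sub[name] == "A").all()
    ]
    remaining = [name for name in background_markers if name not in fixed]
    return remaining, fixed


# ---------------------------------------------------------------------------
# campaign driver
# ---------------------------------------------------------------------------

@dataclass
class GenerationRecord:
    """Audit record of one backcross generation."""

    generation: int
    n_population: int
    foreground_ids: list[str]
    recombinant_ids: list[str]
    ranking: pd.DataFrame
    advanced_ids: list[str]
    screened_background: list[str]
    newly_fixed: list[str]
    fixed_ledger: int
    matrix: GenotypeMatrix
    true_rpg_by_id: dict[str, float]


@dataclass
class SelectionTrace:
    """Full audit log and final report of a campaign run."""

    config_summary: dict
    generations: list[GenerationRecord]
    final_summaries: list[RPGSummary]

    def summary(self) -> str:
        lines = ["marker-assisted backcross campaign", ""]
        for key, value in self.config_summary.items():
            lines.append(f"  {key}: {value}")
        lines.append("")
        for rec in self.generations:
            lines.append(
                f"BC{rec.generation}F1: {rec.n_population} plants -> "
                f"{len(rec.foreground_ids)} foreground -> "
                f"{len(rec.recombinant_ids)} recombinant -> "
                f"advanced {rec.advanced_ids} "
                f"(screened {len(rec.screened_background)} background markers, "
                f"{rec.fixed_ledger} fixed)"
            )
        lines.append("")
        lines.append("final selected plants:")
        for s in self.final_summaries:
            lines.append(
                f"  {s.plant_id}: %A = {s.percent_A:.1f}, %R = {s.percent_R:.1f} "
                f"(A/H/B = {s.n_A}/{s.n_H}/{s.n_B})"
            )
        return "\n".join(lines)

    def write(self, outdir: str | Path) -> None:
        """Serialize per-generation tables, matrices and the text summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for rec in self.generations:
            tag = f"bc{rec.generation}"
            rec.matrix.write(outdir / f"{tag}_genotypes.csv")
            rec.ranking.to_csv(outdir / f"{tag}_ranking.csv", index=False)
            pd.DataFrame(
                {
                    "plant_id": list(rec.true_rpg_by_id),
                    "true_rpg_percent": list(rec.true_rpg_by_id.values()),
                }
            ).to_csv(outdir / f"{tag}_true_rpg.csv", index=False)
            stages = pd.DataFrame(
                {
                    "stage": ["foreground", "recombinant", "advanced"],
                    "plant_ids": [
                        ";".join(rec.foreground_ids),
                        ";".join(rec.recombinant_ids),
                        ";".join(rec.advanced_ids),
                    ],
                }
            )
            stages.to_csv(outdir / f"{tag}_stages.csv", index=False)
        (outdir / "summary.txt").write_text(self.summary() + "\n")


def run_campaign(config: CampaignConfig) -> SelectionTrace:
    """Run the full F1 -> BC1F1 -> ... -> BC``n``F1 selection campaign.

    Every generation crosses each advanced parent to the recipient
    (``pop_size`` progeny per parent), genotypes the population at the
    foreground + flank + currently screened background markers, applies the
    three selection tiers, and advances the top ``n_parents_advanced``
    plants.  Fully reproducible from the seed.

    Raises
    ------
    CampaignHalt
        when any tier leaves zero survivors, naming the generation and tier.
    """
    panel = config.panel
    roles = config.roles
    rng = np.random.default_rng(config.seed)
    gmap = GeneticMap(panel.chromosome_lengths_bp, config.cm_per_mb)

    recipient = PlantGenome.founder("recipient", RECIPIENT, panel.chromosome_lengths_bp)
    donor = PlantGenome.founder("donor", DONOR, panel.chromosome_lengths_bp)
    f1 = cross(donor, recipient, 1, gmap, rng, id_prefix="F1_")[0]

    parents = [f1]
    screened = list(roles.background_markers)
    fixed_ledger: list[str] = []
    records: list[GenerationRecord] = []
    final_summaries: list[RPGSummary] = []

    for gen in range(1, config.n_generations + 1):
        progeny: list[PlantGenome] = []
        for p_idx, parent in enumerate(parents):
            progeny.extend(
                cross(
                    parent,
                    recipient,
                    config.pop_size,
                    gmap,
                    rng,
                    id_prefix=f"BC{gen}_{p_idx}_",
                )
            )
        flank_req = dict(roles.flank_markers_by_generation.get(gen, {}))
        marker_names = [
            *roles.foreground_markers,
            *(m for m in flank_req if m not in roles.foreground_markers),
            *screened,
        ]
        matrix = genotype_plants(
            progeny, panel.subset(marker_names), config.missing_rate,
            rng if config.missing_rate else None,
        )
        truth = {p.plant_id: true_rpg(p) for p in progeny}

        fg_ids = foreground_select(matrix, roles.foreground_markers)
        if not fg_ids:
            raise CampaignHalt(gen, "foreground")
        rc_ids = recombinant_select(matrix.subset_plants(fg_ids), flank_req)
        if not rc_ids:
            raise CampaignHalt(gen, "recombinant")
        candidates = matrix.subset_plants(rc_ids)
        ranking = rank_by_rpg(candidates, screened, fixed_ledger=len(fixed_ledger))
        advanced = list(ranking["plant_id"].head(config.n_parents_advanced))
        if not advanced:
            raise CampaignHalt(gen, "background")

        screened, newly_fixed = drop_fixed_markers(matrix, advanced, screened)
        fixed_ledger.extend(newly_fixed)

        by_id = {p.plant_id: p for p in progeny}
        records.append(
            GenerationRecord(
                generation=gen,
                n_population=len(progeny),
                foreground_ids=fg_ids,
                recombinant_ids=rc_ids,
                ranking=ranking,
                advanced_ids=advanced,
                screened_background=list(screened),
                newly_fixed=newly_fixed,
                fixed_ledger=len(fixed_ledger),
                matrix=matrix,
                true_rpg_by_id=truth,
            )
        )
        parents = [by_id[i] for i in advanced]

    last = records[-1]
    # Final report over the background panel the last generation was ranked
    # on: screened markers as called, plus the ledger fixed for the recipient.
    ranked_markers = [
        m for m in roles.background_markers
        if m in last.matrix.marker_names and m not in fixed_ledger
    ]
    for pid in last.advanced_ids:
        final_summaries.append(
            compute_rpg(
                last.matrix.subset_markers(ranked_markers).calls_for(pid),
                fixed_ledger=len(fixed_ledger),
                plant_id=pid,
            )
        )

    config_summary = {
        "seed": config.seed,
        "generations": config.n_generations,
        "pop_size": config.pop_size,
        "n_parents_advanced": config.n_parents_advanced,
        "cm_per_mb": config.cm_per_mb,
        "missing_rate": config.missing_rate,
        "foreground": list(roles.foreground_markers),
        "flank_schedule": {
            g: dict(v) for g, v in roles.flank_markers_by_generation.items()
        },
        "n_background_markers": len(roles.background_markers),
    }
    return SelectionTrace(
        config_summary=config_summary,
        generations=records,
        final_summaries=final_summaries,
    )


__all__ = [
    "SelectionRoles",
    "CampaignConfig",
    "GenerationRecord",
    "SelectionTrace",
    "DEFAULT_FOREGROUND",
    "DEFAULT_FLANK_SCHEDULE",
    "load_campaign_config",
    "foreground_select",
    "recombinant_select",
    "rank_by_rpg",
    "background_select",
    "drop_fixed_markers",
    "run_campaign",
]
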