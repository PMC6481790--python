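"""Life-stage demographics from diver length estimates.

Divers record the estimated average total length of the turtles on a
segment; straight carapace length (SCL) is taken as 0.8 x that observed
length. Stages are pure SCL bins, left-closed and right-open, with the
adult class closed below (adults are >= the subadult upper cutoff):

===========  ==============  ==============
stage        green (cm SCL)  hawksbill
===========  ==============  ==============
new recruit  < 35            < 35
juvenile     [35, 65)        [35, 58)
subadult     [65, 80)        [58, 72)
adult        >= 80           >= 72
===========  ==============  ==============

Early records with unassigned species (~1-2% of turtles) are reassigned per
site in proportion to the site's multi-year identified species mix, either
deterministically (largest-remainder apportionment, the default) or by
seeded per-turtle draws. Stage summaries are restricted to site/species
combinations with at least 20 observed turtles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SegmentObservation, Species, segments_to_frame, frame_to_segments

__all__ = [
    "STAGES",
    "SCL_FACTOR",
    "MIN_OBSERVATIONS",
    "StageBins",
    "StageProportions",
    "DEFAULT_BINS",
    "to_scl",
    "classify_stage",
    "reassign_unidentified",
    "stage_proportions",
    "stage_proportion_table",
]

STAGES = ("new_recruit", "juvenile", "subadult", "adult")

#: SCL = observed total length x this factor
SCL_FACTOR = 0.8

#: minimum turtles per site and species for demographic characterization
MIN_OBSERVATIONS = 20


@dataclass(frozen=True)
class StageBins:
    """Upper SCL cutoffs (cm) of the first three stages for one species."""

    species: Species
    new_recruit_max: float
    juvenile_max: float
    subadult_max: float

    def __post_init__(self) -> None:
        if not self.new_recruit_max < self.juvenile_max < self.subadult_max:
            raise ValueError("stage cutoffs must be strictly increasing")


DEFAULT_BINS = {
    Species.GREEN: StageBins(Species.GREEN, 35.0, 65.0, 80.0),
    Species.HAWKSBILL: StageBins(Species.HAWKSBILL, 35.0, 58.0, 72.0),
}


def to_scl(observed_length_cm: float) -> float:
    """Straight carapace length from the diver's total-length estimate."""
    if not observed_length_cm > 0:
        raise ValueError(f"observed length must be positive, got {observed_length_cm}")
    return SCL_FACTOR * observed_length_cm


def classify_stage(scl_cm: float, species: Species, bins: StageBins | None = None) -> str:
    """Assign a life stage from SCL; bins are [lower, upper), adults closed below."""
    species = Species(species)
    if species is Species.UNIDENTIFIED:
        raise ValueError("unidentified species must be reassigned before staging")
    b = bins if bins is not None else DEFAULT_BINS[species]
    if not scl_cm > 0:
        raise ValueError(f"SCL must be positive, got {scl_cm}")
    if scl_cm < b.new_recruit_max:
        return "new_recruit"
    if scl_cm < b.juvenile_max:
        return "juvenile"
    if scl_cm < b.subadult_max:
        return "subadult"
    return "adult"


def _largest_remainder(total: int, proportions: np.ndarray) -> np.ndarray:
    """Apportion ``total`` integer units to categories by proportion; ties in
    the fractional remainders resolve toward earlier (higher-share) categories."""
    raw = total * proportions
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    # stable argsort: among equal remainders the earlier category wins
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def reassign_unidentified(
    records: Sequence[SegmentObservation],
    mode: str = "deterministic",
    seed: int | None = None,
) -> list[SegmentObservation]:
    """Replace 'unidentified' species labels using each site's multi-year
    identified species proportions.

    deterministic mode apportions each site's unidentified turtles by
    largest remainder (ties toward green, the majority species overall);
    stochastic mode draws a label per turtle. Total turtle count per site is
    conserved; count-0 placeholder rows are left untouched.
    """
    if mode not in ("deterministic", "stochastic"):
        raise ValueError(f"mode must be 'deterministic' or 'stochastic', got {mode!r}")
    df = segments_to_frame(records)
    out = df.copy()
    rng = np.random.default_rng(seed)
    unid = df[(df.species == Species.UNIDENTIFIED.value) & (df["count"] > 0)]
    for site, site_unid in unid.groupby("site_id"):
        ident = df[
            (df.site_id == site)
            & (df.species.isin([Species.GREEN.value, Species.HAWKSBILL.value]))
            & (df["count"] > 0)
        ]
        n_green = int(ident.loc[ident.species == Species.GREEN.value, "count"].sum())
        n_hawk = int(ident.loc[ident.species == Species.HAWKSBILL.value, "count"].sum())
        if n_green + n_hawk == 0:
            raise ValueError(
                f"site {site!r} has only unidentified turtles; species proportions undefined"
            )
        p_green = n_green / (n_green + n_hawk)
        total_unid = int(site_unid["count"].sum())
        if mode == "deterministic":
            greens = int(_largest_remainder(total_unid, np.array([p_green, 1 - p_green]))[0])
        else:
            greens = int(rng.binomial(total_unid, p_green))
        # walk the site's unidentified rows, allocating greens first
        remaining_green = greens
        for idx, row in site_unid.iterrows():
            c = int(row["count"])
            g = min(c, remaining_green)
            remaining_green -= g
            h = c - g
            if g and h:
                # split the row: relabel in place as green, append a hawksbill row
                out.loc[idx, ["species", "count"]] = [Species.GREEN.value, g]
                extra = out.loc[[idx]].copy()
                extra["species"] = Species.HAWKSBILL.value
                extra["count"] = h
                out = pd.concat([out, extra], ignore_index=True)
            elif g:
                out.loc[idx, ["species", "count"]] = [Species.GREEN.value, g]
            else:
                out.loc[idx, "species"] = Species.HAWKSBILL.value
    return frame_to_segments(out)


@dataclass(frozen=True)
class StageProportions:
    """Stage composition of one species at one site."""

    site_id: str
    species: Species
    n_turtles: int
    proportions: dict[str, float]

    def __post_init__(self) -> None:
        if self.n_turtles < MIN_OBSERVATIONS:
            raise ValueError(
                f"site {self.site_id}: {self.n_turtles} {self.species.value} turtles "
                f"is below the {MIN_OBSERVATIONS}-observation inclusion rule"
            )
        if abs(sum(self.proportions.values()) - 1.0) > 1e-12:
            raise ValueError("stage proportions must sum to 1")


def stage_proportions(
    records: Sequence[SegmentObservation],
    site_id: str,
    species: Species,
    bins: StageBins | None = None,
) -> StageProportions:
    """Count-weighted stage proportions for one site and species.

    A segment row with count c and one recorded mean length contributes c
    turtles at that length. Rows with a count but no length are excluded
    from demographics (they still count for density elsewhere).
    """
    species = Species(species)
    if species is Species.UNIDENTIFIED:
        raise ValueError("reassign unidentified records before computing stage proportions")
    df = segments_to_frame(records)
    sub = df[
        (df.site_id == site_id)
        & (df.species == species.value)
        & (df["count"] > 0)
        & df.mean_length_cm.notna()
    ]
    n = int(sub["count"].sum())
    if n < MIN_OBSERVATIONS:
        raise ValueError(
            f"site {site_id!r}: {n} staged {species.value} turtles "
            f"(inclusion rule requires >= {MIN_OBSERVATIONS})"
        )
    tallies = dict.fromkeys(STAGES, 0)
    for length, count in zip(sub.mean_length_cm, sub["count"]):
        tallies[classify_stage(to_scl(float(length)), species, bins)] += int(count)
    return StageProportions(
        site_id=site_id,
        species=species,
        n_turtles=n,
        proportions={s: tallies[s] / n for s in STAGES},
    )


def stage_proportion_table(
    records: Sequence[SegmentObservation],
    bins: dict[Species, StageBins] | None = None,
) -> pd.DataFrame:
    """Stage proportions for every site/species meeting the inclusion rule."""
    bins = bins or DEFAULT_BINS
    df = segments_to_frame(records)
    rows = []
    for (site, sp), _ in df[df["count"] > 0].groupby(["site_id", "species"]):
        species = Species(sp)
        if species is Species.UNIDENTIFIED:
            continue
        try:
            props = stage_proportions(records, site, species, bins[species])
        except ValueError:
            continue  # below inclusion threshold
        rows.append(
            {"site_id": site, "species": species.value, "n_turtles": props.n_turtles,
             **props.proportions}
        )
    return pd.DataFrame(rows, columns=["site_id", "species", "n_turtles", *STAGES])
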