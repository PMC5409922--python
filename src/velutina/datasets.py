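"""Packaged study data for the Andernos-les-Bains invasion (2007-2014).

The yearly nest tallies, the terrain constants, and the habitat breakdown of
the hornet nests are shipped here as plain Python tables so every analysis in
the package can run without external files.

The habitat fixture is record-level.  The source reports only marginal totals
(overall natural/man-made counts, genus totals, per-stage natural/man-made
splits); the per-cell stage x structure x genus decomposition used to expand
those totals into individual synthetic records is chosen to match every
reported marginal exactly, but the cell values themselves are not data.
"""
from __future__ import annotations

from datetime import date

from .nest_records import NestRecord, Stage, YearlyCounts

__all__ = [
    "STUDY_YEARS",
    "table1_counts",
    "habitat_records",
    "DETECTED_COLONIES",
]

STUDY_YEARS = tuple(range(2007, 2015))

# year, total, primary, secondary, unclassified, active-primary destroyed,
# active-secondary destroyed, active-unclassified destroyed.
# Stage was not recorded in 2007-2008; the active-destroyed counts for those
# years (1 of 4, 12 of 27) come from the narrative, not the printed table.
_TABLE1 = (
    (2007, 4, 0, 0, 4, 0, 0, 1),
    (2008, 27, 0, 0, 27, 0, 0, 12),
    (2009, 83, 38, 45, 0, 18, 14, 0),
    (2010, 61, 25, 36, 0, 4, 18, 0),
    (2011, 77, 26, 51, 0, 11, 22, 0),
    (2012, 94, 34, 60, 0, 16, 34, 0),
    (2013, 90, 29, 61, 0, 24, 39, 0),
    (2014, 111, 12, 99, 0, 0, 79, 0),
)

#: Printed detected-colonies row, for cross-checks and reports.
DETECTED_COLONIES = {2007: 4, 2008: 27, 2009: 63, 2010: 40, 2011: 62,
                     2012: 76, 2013: 85, 2014: 99}


def table1_counts() -> list[YearlyCounts]:
    """The yearly nest tallies of the study, as :class:`YearlyCounts`."""
    return [
        YearlyCounts(
            year=y, n_detected_total=tot, n_primary=p, n_secondary=s,
            n_unclassified=u, n_active_primary_destroyed=ap,
            n_active_secondary_destroyed=asd, n_active_unclassified_destroyed=au,
        )
        for (y, tot, p, s, u, ap, asd, au) in _TABLE1
    ]


# (stage, structure description, count) for the 201 structure-recorded nests
# of 2007-2009 and 2014, plus (stage, None, count) for the 24 without a
# recorded structure (225 nests in total).  Marginals matched exactly:
#   natural 135 / man-made 66 of 201; trees 126 (incl. 4 plain "tree" and
#   1 tree stump); buildings 56; manhole covers 3; oak 81, pine 20, plane 5,
#   poplar 3, alder/cedar/locust 2 each, birch/tulip/acacia/lime/sweetgum/fir
#   1 each; secondary: 136 recorded, 106 natural of which 100 trees;
#   primary: 39 recorded, 30 man-made.
# The distribution of genera over stages is synthetic (not reported).
_HABITAT = (
    # secondary nests, 136 with structure: 100 genus trees, 6 other natural,
    # 30 man-made
    (Stage.SECONDARY, "oak tree", 65),
    (Stage.SECONDARY, "pine tree", 15),
    (Stage.SECONDARY, "plane tree", 5),
    (Stage.SECONDARY, "poplar tree", 3),
    (Stage.SECONDARY, "alder tree", 2),
    (Stage.SECONDARY, "cedar tree", 2),
    (Stage.SECONDARY, "locust tree", 2),
    (Stage.SECONDARY, "birch tree", 1),
    (Stage.SECONDARY, "tulip tree", 1),
    (Stage.SECONDARY, "acacia tree", 1),
    (Stage.SECONDARY, "lime tree", 1),
    (Stage.SECONDARY, "sweetgum tree", 1),
    (Stage.SECONDARY, "fir tree", 1),
    (Stage.SECONDARY, "bank", 1),
    (Stage.SECONDARY, "magnolia bush", 1),
    (Stage.SECONDARY, "hedge", 1),
    (Stage.SECONDARY, "bamboo", 1),
    (Stage.SECONDARY, "bush", 2),
    (Stage.SECONDARY, "building", 24),
    (Stage.SECONDARY, "manhole cover", 3),
    (Stage.SECONDARY, "ventilation grill", 1),
    (Stage.SECONDARY, "road sign", 1),
    (Stage.SECONDARY, "electricity pylon", 1),
    (Stage.SECONDARY, None, 8),
    # primary nests, 39 with structure: 9 natural (7 trees incl. stump), 30
    # man-made
    (Stage.PRIMARY, "oak tree", 3),
    (Stage.PRIMARY, "pine tree", 1),
    (Stage.PRIMARY, "tree", 2),
    (Stage.PRIMARY, "tree stump", 1),
    (Stage.PRIMARY, "bush", 2),
    (Stage.PRIMARY, "building", 26),
    (Stage.PRIMARY, "birdhouse", 1),
    (Stage.PRIMARY, "other man-made", 3),
    (Stage.PRIMARY, None, 11),
    # 2007-2008 nests of unrecorded stage, 26 with structure: 20 natural (19
    # trees, incl. the 3 oak + 1 pine of the first year), 6 man-made
    (Stage.UNKNOWN, "oak tree", 13),
    (Stage.UNKNOWN, "pine tree", 4),
    (Stage.UNKNOWN, "tree", 2),
    (Stage.UNKNOWN, "bush", 1),
    (Stage.UNKNOWN, "building", 6),
    (Stage.UNKNOWN, None, 5),
)

_HABITAT_YEAR = {Stage.SECONDARY: 2014, Stage.PRIMARY: 2009, Stage.UNKNOWN: 2008}


def habitat_records() -> list[NestRecord]:
    """The 225 nests of the habitat analysis, as records.

    Dates are nominal placeholders (habitat summaries never read them); 201
    records carry a structure description, 24 do not.
    """
    out: list[NestRecord] = []
    for stage, structure, n in _HABITAT:
        year = _HABITAT_YEAR[stage]
        for _ in range(n):
            out.append(
                NestRecord.build(
                    year=year,
                    date_found=date(year, 9, 1),
                    date_destroyed=date(year, 9, 2),
                    stage=stage,
                    structure_text=structure,
                )
            )
    return out
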