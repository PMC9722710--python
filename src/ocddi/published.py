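"""Published reference values used by the ``check`` command and the tests.

These are the values printed in the source cost analysis (its results table
and headline incremental figures); they are compared against freshly
computed model output, never substituted for it.  Dollar values are checked
at 0.1% relative tolerance (the printed inputs are themselves rounded);
whole-number event counts must match exactly.

Column keys are ``(strategy name, rate variant)`` in the shipped base-case
naming.
"""

from __future__ import annotations

REL_TOL_COST = 1e-3

S1 = "OC alone"
S2 = "OC + enzyme inducer"
S3 = "OC + enzyme neutral"

#: The seven results-table columns in published order.
COLUMNS = [
    (S1, "point"),
    (S2, "point"),
    (S2, "low"),
    (S2, "high"),
    (S3, "point"),
    (S3, "low"),
    (S3, "high"),
]

#: Displayed (integer) event counts per column.
COUNTS = {
    "birth": (1, 11, 9, 14, 8, 7, 9),
    "induced_abortion": (1, 8, 7, 10, 6, 5, 6),
    "spontaneous_abortion": (0, 3, 3, 4, 2, 2, 3),
    "ectopic_pregnancy": (0, 0, 0, 0, 0, 0, 0),
    "total_up": (3, 23, 19, 28, 16, 14, 18),
}

#: Cost cells as (median, min, max) per column.
COSTS = {
    "birth_unadjusted": (
        (19090, 7767, 42245),
        (144903, 58955, 320660),
        (119942, 48799, 265422),
        (175966, 71593, 389398),
        (101155, 41155, 223847),
        (88599, 36047, 196062),
        (113686, 46254, 251577),
    ),
    "birth_adjusted": (
        (8293, 3375, 18353),
        (62948, 25618, 139310),
        (52105, 21205, 115312),
        (76442, 31109, 169173),
        (43943, 17883, 97250),
        (38489, 15664, 85179),
        (49387, 20099, 109297),
    ),
    "induced_abortion_unadjusted": (
        (986, 630, 4438),
        (7481, 4783, 33687),
        (6192, 3959, 27884),
        (9084, 5808, 40908),
        (5222, 3339, 23516),
        (4574, 2924, 20597),
        (5869, 3752, 26429),
    ),
    "spontaneous_abortion_unadjusted": (
        (514, 275, 1647),
        (3900, 2091, 12503),
        (3228, 1731, 10349),
        (4736, 2539, 15183),
        (2722, 1460, 8728),
        (2384, 1278, 7645),
        (3060, 1640, 9809),
    ),
    "ectopic_pregnancy_unadjusted": (
        (92, 43, 239),
        (702, 323, 1813),
        (581, 267, 1500),
        (852, 392, 2201),
        (490, 225, 1265),
        (429, 197, 1108),
        (551, 253, 1422),
    ),
    "total_unadjusted": (
        (20682, 8715, 48569),
        (156986, 66151, 368662),
        (129943, 54756, 305155),
        (190638, 80332, 447690),
        (109589, 46179, 257357),
        (95986, 40447, 225412),
        (123165, 51900, 289238),
    ),
    "total_adjusted": (
        (9885, 4323, 24677),
        (75031, 32814, 187312),
        (62106, 27162, 155045),
        (91115, 39849, 227465),
        (52378, 22907, 130760),
        (45876, 20064, 114529),
        (58866, 25745, 146958),
    ),
}

#: Headline incremental figures: delta UP and cost deltas (median, min, max).
INCREMENTALS = {
    (S2, S1): {
        "delta_up": 20,
        "unadjusted": (136304, 46041, 399121),
        "adjusted": (65146, 22839, 202788),
    },
    (S2, S3): {
        "delta_up": 7,
        "unadjusted": (47397, 14309, 158452),
        "adjusted": (22653, 7098, 80507),
    },
}

#: Typical-use scenario: typical / perfect rates and the reported fold-change.
SCENARIO1 = {"typical": 7.2, "perfect": 0.3, "fold_change": 3.8}
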