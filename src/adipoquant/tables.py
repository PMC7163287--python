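"""Published summary statistics of the reference osteoporosis cohort.

128 female subjects with osteoporotic hip BMD, stratified by 10-year major
osteoporotic fracture probability (FRAX): LOW (<10), MOD (10-20), HIGH (>20).
These printed per-group summaries seed the synthetic cohort generator and are
re-used for internal-consistency arithmetic (CV% = 100*SD/mean,
range = max - min).

Weight means are not printed in the source table; they are back-computed from
the printed SD and CV cells (mean = 100*SD/CV) and flagged as derived.
"""

from __future__ import annotations

GROUPS = ("LOW", "MOD", "HIGH")

GROUP_SIZES = {"LOW": 42, "MOD": 52, "HIGH": 34}

#: printed per-group summary cells: variable -> group -> dict of cells.
#: Units: height m, weight kg, age years, FRAX % 10-year probability.
REFERENCE_DEMOGRAPHICS = {
    "height": {
        "LOW": dict(mean=1.659, sd=0.080, min=1.54, max=1.89, cv_pct=4.9),
        "MOD": dict(mean=1.656, sd=0.082, min=1.48, max=1.88, cv_pct=5.1),
        "HIGH": dict(mean=1.658, sd=0.067, min=1.60, max=1.89, cv_pct=4.1),
    },
    "weight": {  # means derived from CV cells (not printed)
        "LOW": dict(mean=60.0, sd=12.0, min=42.0, max=94.0, cv_pct=20.0),
        "MOD": dict(mean=57.1, sd=12.0, min=45.0, max=93.0, cv_pct=21.0),
        "HIGH": dict(mean=57.1, sd=9.7, min=44.0, max=98.0, cv_pct=17.0),
    },
    "age": {
        "LOW": dict(mean=57.0, sd=6.9, min=41.0, max=72.0, cv_pct=12.0),
        "MOD": dict(mean=62.0, sd=6.9, min=49.0, max=79.0, cv_pct=11.0),
        "HIGH": dict(mean=64.0, sd=5.8, min=54.0, max=78.0, cv_pct=9.1),
    },
    "frax": {
        "LOW": dict(mean=7.6, sd=1.9, min=2.8, max=10.0, cv_pct=25.0,
                    range=7.2),
        "MOD": dict(mean=14.0, sd=2.7, min=11.0, max=19.0, cv_pct=19.0,
                    range=8.0),
        "HIGH": dict(mean=25.0, sd=6.3, min=20.0, max=50.0, cv_pct=25.0,
                    range=30.0),
    },
}


def recompute_cv_pct(variable: str, group: str) -> float:
    """CV% recomputed from the printed mean and SD cells."""
    cell = REFERENCE_DEMOGRAPHICS[variable][group]
    return 100.0 * cell["sd"] / cell["mean"]


def recompute_range(variable: str, group: str) -> float:
    """Range recomputed from the printed min and max cells."""
    cell = REFERENCE_DEMOGRAPHICS[variable][group]
    return cell["max"] - cell["min"]


def total_cohort_size() -> int:
    """Sum of the printed per-group sample sizes."""
    return sum(GROUP_SIZES.values())
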