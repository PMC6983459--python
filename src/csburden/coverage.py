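"""Case/control exome coverage harmonization.

Differential sequencing coverage between cohorts manufactures spurious
burden signal: a site well covered in cases but poorly in controls can
only yield case carriers.  Harmonization removes ("prunes") every
coding site at which the fraction of adequately covered subjects
differs between the cohorts by more than a threshold — by default more
than 10 percentage points, read as a strict inequality on the absolute
difference, so a difference of exactly 0.10 is retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError, InputFormatError

#: Default read depth at which a subject counts as adequately covered.
#: The pruning rule itself consumes pre-computed fractions; this only
#: matters when raw depth matrices are supplied.
DEFAULT_MIN_DEPTH = 10

#: Default pruning threshold: strict |frac_cases - frac_controls| > 0.10.
DEFAULT_MAX_ABS_DIFF = 0.10


@dataclass(frozen=True)
class CoverageSite:
    """Per-site adequate-coverage fractions in the two cohorts."""

    chrom: str
    pos: int
    frac_cases: float
    frac_controls: float

    def __post_init__(self) -> None:
        for label, frac in (("cases", self.frac_cases), ("controls", self.frac_controls)):
            if not 0.0 <= frac <= 1.0:
                raise InputFormatError(
                    f"{self.chrom}:{self.pos}: coverage fraction {frac} "
                    f"({label}) outside [0, 1]"
                )

    @property
    def site_id(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class HarmonizationResult:
    """Partition of input sites into retained and excluded sets."""

    retained: frozenset[tuple[str, int]]
    excluded: frozenset[tuple[str, int]]

    @property
    def excluded_fraction(self) -> float:
        total = len(self.retained) + len(self.excluded)
        return len(self.excluded) / total if total else 0.0


def adequate_fraction(depths: Sequence[float], min_depth: int = DEFAULT_MIN_DEPTH) -> float:
    """Fraction of subjects with read depth >= ``min_depth`` at a site."""
    if len(depths) == 0:
        raise InputFormatError("adequate_fraction needs at least one subject")
    return sum(1 for d in depths if d >= min_depth) / len(depths)


def harmonize(
    sites: Iterable[CoverageSite], max_abs_diff: float = DEFAULT_MAX_ABS_DIFF
) -> HarmonizationResult:
    """Prune sites whose coverage fractions differ by more than the threshold.

    A site is excluded iff ``|frac_cases - frac_controls| > max_abs_diff``
    (strictly greater; the threshold is in absolute percentage points,
    not a ratio).  The result partitions the input.
    """
    if not 0.0 <= max_abs_diff <= 1.0:
        raise ConfigurationError(f"max_abs_diff {max_abs_diff} outside [0, 1]")
    retained, excluded = set(), set()
    for site in sites:
        if abs(site.frac_cases - site.frac_controls) > max_abs_diff:
            excluded.add(site.site_id)
        else:
            retained.add(site.site_id)
    return HarmonizationResult(frozenset(retained), frozenset(excluded))


def read_coverage_tsv(path: str | Path) -> list[CoverageSite]:
    """Read a ``chrom pos frac_cases frac_controls`` table."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip", dtype={"chrom": str}, comment="#")
    missing = {"chrom", "pos", "frac_cases", "frac_controls"} - set(df.columns)
    if missing:
        raise InputFormatError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        CoverageSite(str(r.chrom), int(r.pos), float(r.frac_cases), float(r.frac_controls))
        for r in df.itertuples(index=False)
    ]


def write_coverage_tsv(sites: Iterable[CoverageSite], path: str | Path) -> None:
    pd.DataFrame(
        [(s.chrom, s.pos, s.frac_cases, s.frac_controls) for s in sites],
        columns=["chrom", "pos", "frac_cases", "frac_controls"],
        # %.17g preserves doubles exactly across a write/read cycle
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_excluded_bed(result: HarmonizationResult, path: str | Path) -> None:
    """Write excluded sites as BED (0-based half-open single-base intervals)."""
    rows = sorted(result.excluded)
    with open(path, "w") as fh:
        for chrom, pos in rows:
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\n")
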