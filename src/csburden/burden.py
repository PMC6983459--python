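"""Subject-level collapsing burden tests on case-control carrier tables.

The collapsing method (CAST-style) reduces a gene's qualifying variants
to one indicator per subject — carrier of at least one qualifying
variant, or not — and tests the resulting 2x2 table::

                 carrier   non-carrier
        cases       a        n1 - a
        controls    c        n2 - c

Statistics are one-sided with the enrichment-in-cases alternative:

* ``fisher_one_sided`` — the exact hypergeometric upper tail
  P(A >= a) at fixed margins;
* ``chisq_one_sided`` — half the two-sided 1-df Pearson chi-square
  p-value when the case carrier fraction exceeds the control fraction,
  and one minus that half otherwise (no continuity correction unless
  requested);
* ``odds_ratio`` — the cross-product ratio with a Woolf (log-OR)
  95% confidence interval, undefined whenever a zero cell degenerates
  the cross-product.

``stratified_burden`` assembles the full report: a Total row, a
low-CADD group with Frameshift / Splicing / Missense sub-rows, and the
damaging-missense (D-mis, CADD >= 20) group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from scipy.stats import chi2, hypergeom

from .errors import ConfigurationError, InputFormatError
from .variants import (
    DEFAULT_CADD_THRESHOLD,
    AnnotatedVariant,
    Classification,
    classify,
)


@dataclass(frozen=True)
class CollapsedCounts:
    """The 2x2 carrier table every burden statistic consumes."""

    a: int  # carriers among cases
    n1: int  # case cohort size
    c: int  # carriers among controls
    n2: int  # control cohort size

    def __post_init__(self) -> None:
        if not (0 <= self.a <= self.n1 and 0 <= self.c <= self.n2):
            raise InputFormatError(
                f"invalid carrier table a={self.a}/{self.n1}, c={self.c}/{self.n2}"
            )

    @property
    def b(self) -> int:
        return self.n1 - self.a

    @property
    def d(self) -> int:
        return self.n2 - self.c

    def transpose_cohorts(self) -> "CollapsedCounts":
        return CollapsedCounts(self.c, self.n2, self.a, self.n1)


@dataclass(frozen=True)
class StratumDefinition:
    """A named predicate selecting qualifying variants for one row."""

    name: str
    predicate: Callable[[AnnotatedVariant, Classification], bool]
    indent: bool = False  # sub-row in the rendered table


@dataclass
class BurdenRow:
    """One stratum's collapsed counts and association statistics."""

    stratum: str
    n_variants: int
    counts: CollapsedCounts
    odds_ratio: float | None
    ci95: tuple[float, float] | None
    p_value: float | None
    test: str
    indent: bool = False


def fisher_one_sided(counts: CollapsedCounts) -> float:
    """Exact one-sided Fisher p-value, enrichment-in-cases alternative.

    The p-value is the hypergeometric upper tail P(A >= a) with the
    observed margins (total carriers K = a + c drawn into a case cohort
    of size n1 out of N = n1 + n2 subjects).  Always in (0, 1].
    """
    N = counts.n1 + counts.n2
    K = counts.a + counts.c
    return float(hypergeom.sf(counts.a - 1, N, K, counts.n1))


def chisq_one_sided(
    counts: CollapsedCounts, continuity_correction: bool = False
) -> float:
    """One-sided 1-df Pearson chi-square p-value for case enrichment.

    Half the two-sided p when the observed case carrier fraction
    exceeds the control fraction; 1 minus that half otherwise.  A table
    with no carriers at all carries no information: p = 1 with a
    warning rather than an exception.
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    N = counts.n1 + counts.n2
    if (a + c) == 0 or (b + d) == 0:
        warnings.warn(
            "degenerate carrier table (zero margin); chi-square p set to 1",
            stacklevel=2,
        )
        return 1.0
    diff = abs(a * d - c * b)
    if continuity_correction:
        diff = max(diff - N / 2.0, 0.0)
    stat = N * diff**2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p_two = float(chi2.sf(stat, df=1))
    if counts.a / counts.n1 > counts.c / counts.n2:
        return p_two / 2.0
    return 1.0 - p_two / 2.0


def odds_ratio(
    counts: CollapsedCounts, z: float = 1.959963984540054
) -> tuple[float | None, tuple[float, float] | None]:
    """Cross-product odds ratio with a Woolf 95% confidence interval.

    OR = (a * d) / (c * b) on the carrier/non-carrier table.  When any
    cell is zero the estimate is degenerate and both the OR and the CI
    are returned as ``None`` (reports render an en dash), never as
    infinity.
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    if min(a, b, c, d) == 0:
        return None, None
    or_ = (a * d) / (c * b)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_) - z * se)
    hi = math.exp(math.log(or_) + z * se)
    return or_, (lo, hi)


def collapse_carriers(
    variants: Sequence[AnnotatedVariant],
    genotypes: Mapping[str, Iterable[str]],
    cases: Iterable[str],
    controls: Iterable[str],
) -> CollapsedCounts:
    """Collapse qualifying variants to subject-level carrier counts.

    A subject carrying any number (>= 1) of the qualifying variants
    counts once.  Cohort sizes are the full case/control rosters, not
    just genotyped carriers.

    Raises
    ------
    InputFormatError
        If a subject appears in the genotype matrix but in neither
        cohort, or in both.
    """
    case_set, control_set = set(cases), set(controls)
    overlap = case_set & control_set
    if overlap:
        raise InputFormatError(f"subjects in both cohorts: {sorted(overlap)[:5]}")
    qualifying = {v.variant_id for v in variants}
    a = c = 0
    for subject, carried in genotypes.items():
        carried_set = set(carried)
        unknown_cohort = subject not in case_set and subject not in control_set
        if unknown_cohort:
            raise InputFormatError(f"genotyped subject {subject!r} in no cohort")
        if carried_set & qualifying:
            if subject in case_set:
                a += 1
            else:
                c += 1
    return CollapsedCounts(a, len(case_set), c, len(control_set))


def allele_counts(
    variants: Sequence[AnnotatedVariant],
    genotypes: Mapping[str, Iterable[str]],
    cases: Iterable[str],
    controls: Iterable[str],
) -> tuple[int, int]:
    """Qualifying variant alleles per cohort (one per carrier per variant).

    Under singleton carriage this equals the number of variant records
    observed in each cohort; a recurrent variant is tallied once per
    carrier.  This is the tally burden tables print as the variant
    inventory, and the numerator of the allele-based counting mode.
    """
    case_set, control_set = set(cases), set(controls)
    qualifying = {v.variant_id for v in variants}
    n_case = n_control = 0
    for subject, carried in genotypes.items():
        k = len(set(carried) & qualifying)
        if subject in case_set:
            n_case += k
        elif subject in control_set:
            n_control += k
        else:
            raise InputFormatError(f"genotyped subject {subject!r} in no cohort")
    return n_case, n_control


def default_strata(
    cadd_threshold: float = DEFAULT_CADD_THRESHOLD,
) -> list[StratumDefinition]:
    """The standard stratification of a burden table.

    Total; the below-threshold group with Frameshift, Splicing and
    Missense sub-rows; and the damaging-missense group (missense with
    CADD at or above the threshold) with its Missense sub-row.
    Loss-of-function consequences carry no missense CADD stratum and
    sit in the below-threshold group.
    """
    t = cadd_threshold

    def dmis(v: AnnotatedVariant, cl: Classification) -> bool:
        return v.consequence == "missense" and v.cadd is not None and v.cadd >= t

    def low(v: AnnotatedVariant, cl: Classification) -> bool:
        return not dmis(v, cl)

    return [
        StratumDefinition("Total", lambda v, cl: True),
        StratumDefinition(f"CADD score < {t:g}", low),
        StratumDefinition(
            "Frameshift", lambda v, cl: v.consequence == "frameshift", indent=True
        ),
        StratumDefinition(
            "Splicing", lambda v, cl: v.consequence == "splice_site", indent=True
        ),
        StratumDefinition(
            "Missense (< threshold)",
            lambda v, cl: v.consequence == "missense" and not dmis(v, cl),
            indent=True,
        ),
        StratumDefinition(f"CADD score >= {t:g}", dmis),
        StratumDefinition("Missense (>= threshold)", dmis, indent=True),
    ]


def stratified_burden(
    variants: Sequence[AnnotatedVariant],
    genotypes: Mapping[str, Iterable[str]],
    cases: Iterable[str],
    controls: Iterable[str],
    strata: Sequence[StratumDefinition] | None = None,
    cadd_threshold: float = DEFAULT_CADD_THRESHOLD,
    test: str = "fisher",
    continuity_correction: bool = False,
    min_expected_for_chisq: float = 5.0,
) -> list[BurdenRow]:
    """Collapse and test every stratum of a qualifying-variant set.

    ``variants`` must already be novelty-filtered, QC-passed and
    coverage-pruned.  ``n_variants`` per row counts qualifying variant
    alleles (one per carrier per variant), so a recurrent variant
    contributes once per carrier.  The exact Fisher test is always used
    when any expected cell of a stratum's table falls below
    ``min_expected_for_chisq``; otherwise the configured ``test``
    applies.  An empty stratum yields a row with zero variants and an
    undefined p-value.
    """
    if test not in ("fisher", "chisq"):
        raise ConfigurationError(f"unknown test {test!r}")
    if strata is None:
        strata = default_strata(cadd_threshold)
    classifications = {v.variant_id: classify(v, cadd_threshold) for v in variants}
    case_set, control_set = set(cases), set(controls)

    rows = []
    for stratum in strata:
        selected = [
            v for v in variants if stratum.predicate(v, classifications[v.variant_id])
        ]
        n_case_alleles, n_control_alleles = allele_counts(
            selected, genotypes, case_set, control_set
        )
        counts = collapse_carriers(selected, genotypes, case_set, control_set)
        if not selected:
            rows.append(
                BurdenRow(stratum.name, 0, counts, None, None, None, "none", stratum.indent)
            )
            continue
        or_, ci = odds_ratio(counts)
        chosen = test
        if _min_expected(counts) < min_expected_for_chisq:
            chosen = "fisher"
        if chosen == "fisher":
            p = fisher_one_sided(counts)
            test_name = "fisher_one_sided"
        else:
            p = chisq_one_sided(counts, continuity_correction)
            test_name = "chisq_one_sided"
        rows.append(
            BurdenRow(
                stratum.name,
                n_case_alleles + n_control_alleles,
                counts,
                or_,
                ci,
                p,
                test_name,
                stratum.indent,
            )
        )
    return rows


def _min_expected(counts: CollapsedCounts) -> float:
    N = counts.n1 + counts.n2
    if N == 0:
        return 0.0
    margins_r = (counts.a + counts.c, counts.b + counts.d)
    margins_c = (counts.n1, counts.n2)
    return min(r * c / N for r in margins_r for c in margins_c)


# ---------------------------------------------------------------------------
# Rendering

_DASH = "–"  # en dash, as burden tables print for degenerate ORs


def format_row(row: BurdenRow) -> dict[str, str]:
    """Render one row at report precision (OR 1 decimal, P 2 decimals)."""
    if row.odds_ratio is None:
        or_str, ci_str = _DASH, ""
    else:
        lo, hi = row.ci95
        or_str = f"{row.odds_ratio:.1f}"
        ci_str = f"({lo:.1f}–{hi:.1f})"
    p_str = f"{row.p_value:.2f}" if row.p_value is not None else _DASH
    return {
        "stratum": ("  " if row.indent else "") + row.stratum,
        "n_variants": str(row.n_variants),
        "cases": str(row.counts.a),
        "controls": str(row.counts.c),
        "OR (95% CI)": f"{or_str} {ci_str}".strip(),
        "P value": p_str,
    }


def render_table(rows: Sequence[BurdenRow]) -> str:
    """Fixed-width text replica of the stratified burden table."""
    header = ["Stratum", "Variants", "Cases", "Controls", "OR (95% CI)", "P value"]
    body = [
        [
            f["stratum"], f["n_variants"], f["cases"], f["controls"],
            f["OR (95% CI)"], f["P value"],
        ]
        for f in map(format_row, rows)
    ]
    widths = [max(len(h), *(len(r[i]) for r in body)) if body else len(h)
              for i, h in enumerate(header)]
    def fmt(cells: list[str]) -> str:
        return "  ".join(c.ljust(w) for c, w in zip(cells, widths)).rstrip()
    lines = [fmt(header), fmt(["-" * w for w in widths])]
    lines.extend(fmt(r) for r in body)
    return "\n".join(lines)


def rows_to_records(rows: Sequence[BurdenRow]) -> list[dict]:
    """JSON-ready record per row (unrounded statistics)."""
    return [
        {
            "stratum": r.stratum,
            "n_variants": r.n_variants,
            "case_carriers": r.counts.a,
            "n_cases": r.counts.n1,
            "control_carriers": r.counts.c,
            "n_controls": r.counts.n2,
            "odds_ratio": r.odds_ratio,
            "ci95_low": r.ci95[0] if r.ci95 else None,
            "ci95_high": r.ci95[1] if r.ci95 else None,
            "p_value": r.p_value,
            "test": r.test,
        }
        for r in rows
    ]
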