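"""End-to-end orchestration of the burden and family analyses.

Stage order for the case-control arm: coverage harmonization ->
QC/novelty filtering -> classification -> stratified collapsing burden
tests.  The family arm runs dominant cosegregation filtering, candidate
ranking, and optional ACMG evidence combination.  Reports embed the
fully resolved configuration so every under-specified default (depth
threshold, test recipe, sidedness) is auditable, and are deterministic
given identical inputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import burden as bd
from . import coverage as cov
from .acmg import combine_evidence
from .errors import ConfigurationError, InputFormatError
from .pedigree import Pedigree, dominant_candidates, rank_candidates, read_ped
from .variants import (
    DEFAULT_CADD_THRESHOLD,
    DEFAULT_NOVELTY_RESOURCES,
    AnnotatedVariant,
    filter_qualifying,
    read_variants_tsv,
    read_variants_vcf,
)


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run; serialized into reports."""

    gene: str = "FBN1"
    novelty_resources: tuple[str, ...] = DEFAULT_NOVELTY_RESOURCES
    cadd_threshold: float = DEFAULT_CADD_THRESHOLD
    max_abs_diff: float = cov.DEFAULT_MAX_ABS_DIFF
    min_depth: int = cov.DEFAULT_MIN_DEPTH
    test: str = "fisher"
    continuity_correction: bool = False
    counting: str = "subject"
    tolerated_unaffected_carriers: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.test not in ("fisher", "chisq"):
            raise ConfigurationError(f"unknown test {self.test!r}")
        if self.counting not in ("subject", "allele"):
            raise ConfigurationError(f"unknown counting mode {self.counting!r}")
        self.novelty_resources = tuple(self.novelty_resources)


def run_burden_data(
    variants: Sequence[AnnotatedVariant],
    genotypes: Mapping[str, set[str]],
    cases: Sequence[str],
    controls: Sequence[str],
    coverage_sites: Sequence[cov.CoverageSite] = (),
    config: RunConfig | None = None,
) -> dict:
    """Run the full case-control burden analysis on in-memory inputs."""
    config = config or RunConfig()
    harmonization = cov.harmonize(coverage_sites, config.max_abs_diff)
    qualifying = filter_qualifying(
        variants,
        gene=config.gene,
        novelty_resources=config.novelty_resources,
        excluded_sites=harmonization.excluded,
    )
    rows = bd.stratified_burden(
        qualifying,
        genotypes,
        cases,
        controls,
        cadd_threshold=config.cadd_threshold,
        test=config.test,
        continuity_correction=config.continuity_correction,
    )
    return {
        "config": asdict(config),
        "harmonization": {
            "n_sites": len(harmonization.retained) + len(harmonization.excluded),
            "n_excluded": len(harmonization.excluded),
            "excluded_fraction": harmonization.excluded_fraction,
        },
        "n_qualifying_variants": len(qualifying),
        "rows": bd.rows_to_records(rows),
        "table": bd.render_table(rows),
    }


def run_burden(
    variants_path: str | Path,
    samples_path: str | Path,
    coverage_path: str | Path | None = None,
    genotypes_path: str | Path | None = None,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """File-based wrapper around :func:`run_burden_data`.

    ``variants_path`` may be a VCF (genotypes come from sample columns)
    or a flat TSV (then ``genotypes_path`` must supply a
    subject/variant_id carrier table).  ``samples_path`` assigns every
    subject to the case or control cohort.
    """
    config = config or RunConfig()
    variants_path = Path(variants_path)
    if variants_path.suffix in (".vcf", ".gz"):
        variants, genotypes = read_variants_vcf(variants_path)
    else:
        variants = read_variants_tsv(variants_path)
        if genotypes_path is None:
            raise ConfigurationError(
                "TSV variant input needs a --genotypes carrier table"
            )
        genotypes = _read_genotypes_tsv(genotypes_path)
    cases, controls = _read_samples_tsv(samples_path)
    for subject in cases + controls:
        genotypes.setdefault(subject, set())
    sites = cov.read_coverage_tsv(coverage_path) if coverage_path else []
    report = run_burden_data(variants, genotypes, cases, controls, sites, config)
    if out_dir is not None:
        _write_burden_report(report, Path(out_dir))
    return report


def run_family(
    ped: Pedigree | str | Path,
    variants: Sequence[AnnotatedVariant] | str | Path,
    family_genotypes_path: str | Path | None = None,
    evidence: Mapping[str, Sequence[str]] | None = None,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Dominant cosegregation screen plus optional ACMG combination.

    ``evidence`` maps variant ids to manually assigned ACMG code lists;
    matching candidates get a pathogenicity class in the report.
    """
    config = config or RunConfig()
    if not isinstance(ped, Pedigree):
        pedigrees = read_ped(ped)
        if family_genotypes_path is not None:
            _attach_family_genotypes(pedigrees, family_genotypes_path)
        ped = pedigrees[0]
    if not isinstance(variants, (list, tuple)):
        variants = read_variants_tsv(variants)
    verdicts = dominant_candidates(
        ped, variants, config.tolerated_unaffected_carriers
    )
    ranked = rank_candidates(verdicts, variants, config.cadd_threshold)
    candidates = []
    for verdict in ranked:
        entry = {
            "variant_id": verdict.variant_id,
            "cosegregates": verdict.cosegregates,
            "informative_members": verdict.informative_members,
            "violations": list(verdict.violations),
        }
        if evidence and verdict.variant_id in evidence:
            cls, rule = combine_evidence(evidence[verdict.variant_id])
            entry["acmg_class"] = cls
            entry["acmg_rule"] = rule
        candidates.append(entry)
    report = {
        "config": asdict(config),
        "family": ped.family_id,
        "candidates": candidates,
        "cosegregating": [
            v.variant_id for v in ranked if v.cosegregates
        ],
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "family_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    return report


# ---------------------------------------------------------------------------
# IO helpers


def _read_samples_tsv(path: str | Path) -> tuple[list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip", comment="#")
    missing = {"sample", "cohort"} - set(df.columns)
    if missing:
        raise InputFormatError(f"{path}: missing column(s) {sorted(missing)}")
    cases = [str(r.sample) for r in df.itertuples(index=False) if r.cohort == "case"]
    controls = [
        str(r.sample) for r in df.itertuples(index=False) if r.cohort == "control"
    ]
    bad = set(df.cohort) - {"case", "control"}
    if bad:
        raise InputFormatError(f"{path}: unknown cohort label(s) {sorted(bad)}")
    return cases, controls


def _read_genotypes_tsv(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip", comment="#")
    missing = {"subject", "variant_id"} - set(df.columns)
    if missing:
        raise InputFormatError(f"{path}: missing column(s) {sorted(missing)}")
    genotypes: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        genotypes.setdefault(str(r.subject), set()).add(str(r.variant_id))
    return genotypes


def _attach_family_genotypes(pedigrees: list[Pedigree], path: str | Path) -> None:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip", comment="#")
    missing = {"family", "member", "variant_id", "state"} - set(df.columns)
    if missing:
        raise InputFormatError(f"{path}: missing column(s) {sorted(missing)}")
    by_family = {p.family_id: p for p in pedigrees}
    for r in df.itertuples(index=False):
        ped = by_family.get(str(r.family))
        if ped is None:
            raise InputFormatError(f"{path}: unknown family {r.family!r}")
        ped.genotypes.setdefault(str(r.member), {})[str(r.variant_id)] = str(r.state)


def _write_burden_report(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "burden_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    (out_dir / "burden_table.txt").write_text(report["table"] + "\n")
    pd.DataFrame(report["rows"]).to_csv(out_dir / "burden_rows.tsv", sep="\t", index=False)
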