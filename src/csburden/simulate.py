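"""Synthetic study-input generator and the packaged reference dataset.

Two entry points:

* :func:`simulate_cohort` draws a complete synthetic case-control study
  — cohort rosters, singleton heterozygous qualifying variants with a
  planted carrier-enrichment odds ratio, a coverage matrix with an
  exact fraction of case/control-imbalanced sites, per-resource
  frequency leakage, and a three-generation dominant pedigree with one
  planted cosegregating loss-of-function variant — deterministically
  from a seed.

* :func:`fbn1_fixture` returns the deterministic packaged dataset whose
  qualifying-variant inventory reproduces the published FBN1
  congenital-scoliosis burden table exactly (30 novel variants, 16
  case / 14 control carriers, 11 damaging-missense: 8 case / 3
  control) and whose case damaging-missense records carry the
  published positions, CADD scores and domains.  Control-cohort and
  low-CADD records are synthetic placeholders constrained only by the
  printed marginal counts, since they are not individually published.

The generator's default parameters are the study's own conditions:
574 cases versus 828 controls, a control qualifying-carrier rate of
14/828, about 1 in 15 qualifying variants being loss-of-function, and
4.8% of coding sites coverage-imbalanced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import CoverageSite, write_coverage_tsv
from .errors import ConfigurationError, InputFormatError
from .pedigree import Pedigree, PedigreeMember, write_ped
from .variants import (
    DEFAULT_NOVELTY_RESOURCES,
    AnnotatedVariant,
    DomainMap,
    write_variants_tsv,
)

#: FBN1 protein NP_000129.3 residue count.
FBN1_PROTEIN_LENGTH = 2871

_DATA = resources.files("csburden.data")


def fbn1_domain_map() -> DomainMap:
    """The packaged FBN1 domain map (synthetic interval boundaries)."""
    import io

    text = (_DATA / "fbn1_domains.tsv").read_text()
    return DomainMap.from_tsv(io.StringIO(text), FBN1_PROTEIN_LENGTH)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic case-control study.

    Defaults mirror the emulated study design: cohort sizes 574/828, a
    control carrier rate of 14/828 for qualifying variants, singleton
    heterozygous carriage, two-component CADD mixture straddling the
    damaging threshold of 20, and 4.8% coverage-imbalanced sites.
    """

    n_cases: int = 574
    n_controls: int = 828
    n_sites: int = 1000
    carrier_rate_controls: float = 14 / 828
    planted_or: float = 1.0
    frac_imbalanced_sites: float = 0.048
    #: P(variant is loss-of-function) — the emulated inventory has 2/30.
    lgd_rate: float = 2 / 30
    #: (mean, sd) of the below/above-threshold CADD components and the
    #: weight of the damaging component (11/30 in the emulated inventory).
    cadd_low: tuple[float, float] = (13.0, 3.5)
    cadd_high: tuple[float, float] = (27.0, 4.0)
    cadd_high_weight: float = 11 / 30
    #: Probability a simulated variant leaks into one frequency resource
    #: (and is therefore removed by the novelty filter).
    novelty_leak_rate: float = 0.1
    #: Number of case variants carried by two subjects instead of one.
    n_recurrent_case_variants: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigurationError("cohort sizes must be >= 1")
        if self.planted_or <= 0:
            raise ConfigurationError("planted odds ratio must be > 0")
        for name in (
            "carrier_rate_controls",
            "frac_imbalanced_sites",
            "lgd_rate",
            "cadd_high_weight",
            "novelty_leak_rate",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{name} = {val} outside [0, 1]")
        if self.case_carrier_rate >= 1.0:
            raise ConfigurationError(
                "planted odds ratio drives the case carrier probability to >= 1"
            )

    @property
    def case_carrier_rate(self) -> float:
        """Case carrier probability implied by the planted odds ratio.

        p1 solves p1/(1-p1) = OR * p0/(1-p0) for p0 the control rate.
        """
        p0 = self.carrier_rate_controls
        odds1 = self.planted_or * p0 / (1.0 - p0)
        return odds1 / (1.0 + odds1)


@dataclass
class SyntheticDataset:
    """A complete, internally consistent set of pipeline inputs."""

    variants: list[AnnotatedVariant]
    genotypes: dict[str, set[str]]
    cases: list[str]
    controls: list[str]
    coverage: list[CoverageSite]
    pedigrees: list[Pedigree]
    family_variants: list[AnnotatedVariant]
    truth: dict


_GENE_START = 48_700_000  # synthetic coding-site grid origin (chrom 15 scale)


def simulate_cohort(config: SimulationConfig) -> SyntheticDataset:
    """Draw one synthetic study dataset; deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    cases = [f"CS{i + 1:04d}" for i in range(config.n_cases)]
    controls = [f"CT{i + 1:04d}" for i in range(config.n_controls)]

    # --- coverage: exactly the configured number of imbalanced sites
    n_sites = config.n_sites
    positions = _GENE_START + 3 * np.arange(n_sites)
    n_imbalanced = int(round(config.frac_imbalanced_sites * n_sites))
    imbalanced_idx = set(
        rng.choice(n_sites, size=n_imbalanced, replace=False).tolist()
    )
    coverage = []
    for i, pos in enumerate(positions):
        base = float(rng.uniform(0.90, 0.995))
        if i in imbalanced_idx:
            diff = float(rng.uniform(0.12, 0.30))
            frac_controls = max(base - diff, 0.0)
        else:
            diff = float(rng.uniform(0.0, 0.08)) * (1 if rng.random() < 0.5 else -1)
            frac_controls = float(np.clip(base - diff, 0.0, 1.0))
        coverage.append(CoverageSite("15", int(pos), base, frac_controls))

    # --- carriers at the planted odds ratio
    p0 = config.carrier_rate_controls
    p1 = config.case_carrier_rate
    case_carriers = [s for s in cases if rng.random() < p1]
    control_carriers = [s for s in controls if rng.random() < p0]

    # one singleton variant per carrier, placed at coverage-balanced sites
    balanced_idx = [i for i in range(n_sites) if i not in imbalanced_idx]
    n_recurrent = min(config.n_recurrent_case_variants, len(case_carriers) // 2)
    n_case_variants = len(case_carriers) - n_recurrent
    n_variants = n_case_variants + len(control_carriers)
    if n_variants > len(balanced_idx):
        raise ConfigurationError(
            f"{n_variants} variants need distinct balanced sites but only "
            f"{len(balanced_idx)} exist; raise n_sites"
        )
    site_idx = rng.choice(len(balanced_idx), size=n_variants, replace=False)
    variant_sites = [int(positions[balanced_idx[i]]) for i in site_idx]

    variants: list[AnnotatedVariant] = []
    genotypes: dict[str, set[str]] = {s: set() for s in cases + controls}

    carrier_groups: list[list[str]] = []
    pool = list(case_carriers)
    for _ in range(n_recurrent):
        carrier_groups.append([pool.pop(0), pool.pop(0)])
    carrier_groups.extend([s] for s in pool)
    carrier_groups.extend([s] for s in control_carriers)

    bases = "ACGT"
    for pos, carriers in zip(variant_sites, carrier_groups):
        if rng.random() < config.lgd_rate:
            consequence = "frameshift" if rng.random() < 0.5 else "splice_site"
            cadd = None
            ppos = None
        else:
            consequence = "missense"
            if rng.random() < config.cadd_high_weight:
                mean, sd = config.cadd_high
            else:
                mean, sd = config.cadd_low
            cadd = float(np.clip(rng.normal(mean, sd), 0.1, 60.0))
            ppos = int(rng.integers(1, FBN1_PROTEIN_LENGTH + 1))
        ref = bases[rng.integers(4)]
        alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
        if consequence == "frameshift":
            alt = ref + bases[rng.integers(4)]  # 1-bp insertion
        freq: dict[str, float] = {}
        if rng.random() < config.novelty_leak_rate:
            resource = DEFAULT_NOVELTY_RESOURCES[
                int(rng.integers(len(DEFAULT_NOVELTY_RESOURCES)))
            ]
            freq[resource] = float(10 ** rng.uniform(-5.5, -3.5))
        variant = AnnotatedVariant(
            chrom="15",
            pos=pos,
            ref=ref,
            alt=alt,
            gene="FBN1",
            consequence=consequence,
            protein_pos=ppos,
            cadd=cadd,
            freq=freq,
        )
        variants.append(variant)
        for subject in carriers:
            genotypes[subject].add(variant.variant_id)

    pedigree, family_variants = _planted_pedigree()

    truth = {
        "seed": config.seed,
        "planted_or": config.planted_or,
        "carrier_rate_controls": p0,
        "case_carrier_rate": p1,
        "n_case_carriers": len(case_carriers),
        "n_control_carriers": len(control_carriers),
        "n_variants": len(variants),
        "n_leaked": sum(1 for v in variants if v.freq),
        "n_imbalanced_sites": n_imbalanced,
        "planted_family_variant": family_variants[0].variant_id,
        "config": asdict(config),
    }
    return SyntheticDataset(
        variants=variants,
        genotypes=genotypes,
        cases=cases,
        controls=controls,
        coverage=coverage,
        pedigrees=[pedigree],
        family_variants=family_variants,
        truth=truth,
    )


def dominant_family_fixture() -> tuple[Pedigree, list[AnnotatedVariant]]:
    """A three-generation family segregating a dominant nonsense variant.

    Public alias of the pedigree the generator plants into every
    synthetic dataset: affected proband (III-1) and affected mother
    (II-2) are heterozygous carriers of an FBN1 p.Trp883Ter nonsense
    variant, genotyped unaffected relatives are non-carriers, and a
    decoy missense variant violates segregation.
    """
    return _planted_pedigree()


def _planted_pedigree() -> tuple[Pedigree, list[AnnotatedVariant]]:
    """A three-generation family segregating one dominant nonsense variant.

    Generation I is ungenotyped; the affected mother (II-2) and proband
    (III-1) are heterozygous carriers, unaffected genotyped relatives
    are non-carriers.  A decoy missense variant shared by the proband
    and an unaffected member is included so the filter has something to
    reject.
    """
    planted = AnnotatedVariant(
        chrom="15",
        pos=48_786_000,  # synthetic placement within the gene region
        ref="C",
        alt="T",
        gene="FBN1",
        consequence="nonsense",
        cdna_change="c.2649G>A",
        protein_change="p.Trp883Ter",
        protein_pos=883,
        cadd=42.0,
        freq={},
    )
    decoy = AnnotatedVariant(
        chrom="15",
        pos=48_760_000,
        ref="G",
        alt="A",
        gene="FBN1",
        consequence="missense",
        protein_pos=1500,
        cadd=25.0,
        freq={},
    )
    members = [
        PedigreeMember("I-1", None, None, "1", affected=False),
        PedigreeMember("I-2", None, None, "2", affected=False),
        PedigreeMember("II-1", None, None, "1", affected=False),
        PedigreeMember("II-2", "I-1", "I-2", "2", affected=True),
        PedigreeMember("III-1", "II-1", "II-2", "1", affected=True),
        PedigreeMember("III-2", "II-1", "II-2", "2", affected=False),
    ]
    genotypes = {
        "II-1": {planted.variant_id: "ref", decoy.variant_id: "het"},
        "II-2": {planted.variant_id: "het", decoy.variant_id: "ref"},
        "III-1": {planted.variant_id: "het", decoy.variant_id: "het"},
        "III-2": {planted.variant_id: "ref", decoy.variant_id: "ref"},
    }
    ped = Pedigree("FAM1", members, genotypes, proband_id="III-1")
    return ped, [planted, decoy]


# ---------------------------------------------------------------------------
# Packaged reference dataset


def _synthetic_singletons(
    spec: list[tuple[str, int, str, str, str, float | None, int | None]],
) -> tuple[list[AnnotatedVariant], dict[str, set[str]]]:
    variants, genotypes = [], {}
    for subject, pos, ref, alt, consequence, cadd, ppos in spec:
        v = AnnotatedVariant(
            chrom="15",
            pos=pos,
            ref=ref,
            alt=alt,
            gene="FBN1",
            consequence=consequence,
            protein_pos=ppos,
            cadd=cadd,
            freq={},
        )
        variants.append(v)
        genotypes.setdefault(subject, set()).add(v.variant_id)
    return variants, genotypes


def fbn1_fixture() -> SyntheticDataset:
    """The deterministic packaged FBN1 case-control dataset.

    The eight case damaging-missense carrier records come from the
    published candidate-variant table (positions, CADD scores, domains,
    the gnomAD entry of the recurrent p.Leu871Phe).  Everything the
    source tables do not itemize — the three control damaging-missense
    carriers, the below-threshold missense records, the frameshift and
    splicing records, and the coverage matrix — is synthetic, built
    only to match the published marginal counts: 30 novel qualifying
    variants; 16 case and 14 control carriers; 19 below-threshold
    (8 case / 11 control alleles); 11 damaging-missense
    (8 case / 3 control alleles).
    """
    import io

    from .variants import _read_tsv_hash_safe

    text = (_DATA / "fbn1_dmis_case_variants.tsv").read_text()
    df = _read_tsv_hash_safe(io.StringIO(text))
    df["chrom"] = df["chrom"].astype(str)

    variants: list[AnnotatedVariant] = []
    genotypes: dict[str, set[str]] = {}
    seen: dict[str, AnnotatedVariant] = {}
    case_carriers: list[str] = []
    for r in df.itertuples(index=False):
        vid = f"{r.chrom}:{int(r.pos)}:{r.ref}>{r.alt}"
        if vid not in seen:
            freq = {}
            if pd.notna(r.af_gnomAD):
                freq["gnomAD"] = float(r.af_gnomAD)
            v = AnnotatedVariant(
                chrom=str(r.chrom),
                pos=int(r.pos),
                ref=str(r.ref),
                alt=str(r.alt),
                gene="FBN1",
                consequence="missense",
                cdna_change=str(r.cdna_change),
                protein_change=str(r.protein_change),
                protein_pos=int(r.protein_pos),
                cadd=float(r.cadd),
                freq=freq,
            )
            seen[vid] = v
            variants.append(v)
        genotypes.setdefault(str(r.subject_id), set()).add(vid)
        case_carriers.append(str(r.subject_id))

    # Synthetic remainder of the inventory (marginal counts published,
    # individual records not): case side gets 1 splicing + 7 low-CADD
    # missense singletons; control side 3 damaging-missense + 1
    # frameshift + 10 low-CADD missense singletons.
    case_extra = [
        ("CS0101", 48_750_001, "C", "A", "splice_site", None, None),
        ("CS0102", 48_750_011, "G", "A", "missense", 12.4, 210),
        ("CS0103", 48_750_021, "T", "C", "missense", 15.1, 640),
        ("CS0104", 48_750_031, "A", "G", "missense", 9.8, 1012),
        ("CS0105", 48_750_041, "C", "T", "missense", 17.6, 1433),
        ("CS0106", 48_750_051, "G", "C", "missense", 11.2, 1788),
        ("CS0107", 48_750_061, "T", "A", "missense", 14.9, 2033),
        ("CS0108", 48_750_071, "A", "C", "missense", 18.3, 2504),
    ]
    control_extra = [
        ("CT0201", 48_751_001, "G", "GT", "frameshift", None, None),
        ("CT0202", 48_751_011, "C", "T", "missense", 22.1, 311),
        ("CT0203", 48_751_021, "G", "A", "missense", 25.7, 755),
        ("CT0204", 48_751_031, "T", "G", "missense", 21.4, 1899),
        ("CT0205", 48_751_041, "A", "T", "missense", 8.7, 402),
        ("CT0206", 48_751_051, "C", "G", "missense", 10.5, 877),
        ("CT0207", 48_751_061, "G", "T", "missense", 13.8, 1201),
        ("CT0208", 48_751_071, "T", "C", "missense", 16.2, 1544),
        ("CT0209", 48_751_081, "A", "G", "missense", 7.9, 1677),
        ("CT0210", 48_751_091, "C", "A", "missense", 12.8, 1902),
        ("CT0211", 48_751_101, "G", "C", "missense", 19.5, 2101),
        ("CT0212", 48_751_111, "T", "A", "missense", 15.6, 2388),
        ("CT0213", 48_751_121, "A", "C", "missense", 11.9, 2600),
        ("CT0214", 48_751_131, "C", "T", "missense", 18.9, 2750),
    ]
    extra_variants, extra_genotypes = _synthetic_singletons(case_extra + control_extra)
    variants.extend(extra_variants)
    for subject, vids in extra_genotypes.items():
        genotypes.setdefault(subject, set()).update(vids)

    carrier_cases = sorted(set(case_carriers)) + [s for s, *_ in case_extra]
    carrier_controls = [s for s, *_ in control_extra]
    cases = sorted(set(carrier_cases)) + [f"CS9{i:03d}" for i in range(574 - 16)]
    controls = carrier_controls + [f"CT9{i:03d}" for i in range(828 - 14)]
    for subject in cases + controls:
        genotypes.setdefault(subject, set())

    # Coverage: every variant site balanced; 48 of 1000 filler sites
    # imbalanced, echoing the emulated study's exclusion scale.
    variant_positions = {v.pos for v in variants}
    coverage = [CoverageSite("15", p, 0.98, 0.97) for p in sorted(variant_positions)]
    n_filler = 1000 - len(coverage)
    filler = 0
    pos = _GENE_START
    while filler < n_filler:
        if pos not in variant_positions:
            if filler < 48:
                coverage.append(CoverageSite("15", pos, 0.95, 0.80))
            else:
                coverage.append(CoverageSite("15", pos, 0.96, 0.95))
            filler += 1
        pos += 7

    pedigree, family_variants = _planted_pedigree()
    truth = {
        "n_variants_total": 30,
        "case_carriers": 16,
        "control_carriers": 14,
        "dmis_case_alleles": 8,
        "dmis_control_alleles": 3,
        "recurrent_variant": "15:48787384:T>G",
        "recurrent_case_subjects": ["XH73", "XH579"],
    }
    return SyntheticDataset(
        variants=variants,
        genotypes=genotypes,
        cases=cases,
        controls=controls,
        coverage=coverage,
        pedigrees=[pedigree],
        family_variants=family_variants,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Fixture writing


def _vcf_text(dataset: SyntheticDataset) -> str:
    samples = dataset.cases + dataset.controls
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=15>",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">',
        '##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD score">',
        '##INFO=<ID=PPOS,Number=1,Type=Integer,Description="Protein residue">',
        '##INFO=<ID=CDNA,Number=1,Type=String,Description="HGVS c. change">',
        '##INFO=<ID=PCHANGE,Number=1,Type=String,Description="HGVS p. change">',
    ]
    resources_seen = sorted({r for v in dataset.variants for r in v.freq})
    for resource in resources_seen:
        lines.append(
            f'##INFO=<ID=AF_{resource},Number=1,Type=Float,'
            f'Description="Allele frequency in {resource}">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for v in sorted(dataset.variants, key=lambda v: (v.chrom, v.pos, v.alt)):
        info = [f"GENE={v.gene}", f"CSQ={v.consequence}"]
        if v.cadd is not None:
            info.append(f"CADD={v.cadd:.6g}")
        if v.protein_pos is not None:
            info.append(f"PPOS={v.protein_pos}")
        if v.cdna_change:
            info.append(f"CDNA={v.cdna_change}")
        if v.protein_change:
            info.append(f"PCHANGE={v.protein_change}")
        for resource, af in sorted(v.freq.items()):
            info.append(f"AF_{resource}={af:.6g}")
        gts = [
            "0/1" if v.variant_id in dataset.genotypes.get(s, ()) else "0/0"
            for s in samples
        ]
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
            + ";".join(info)
            + "\tGT\t"
            + "\t".join(gts)
        )
    return "\n".join(lines) + "\n"


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> dict[str, str]:
    """Write the dataset as pipeline-readable files; return a manifest.

    Files: cohort VCF (GT-only het calls), flat variant TSV, coverage
    TSV, sample-to-cohort TSV, pedigree PED, family genotype TSV,
    per-resource allele-frequency TSVs, and a truth JSON recording the
    planted parameters.  The manifest maps each file name to its
    SHA-256 checksum.
    """
    directory = Path(directory)
    if not directory.exists():
        raise InputFormatError(f"output directory {directory} does not exist")

    files: dict[str, str] = {}

    def _write(name: str, text: str) -> None:
        path = directory / name
        path.write_text(text)
        files[name] = hashlib.sha256(text.encode()).hexdigest()

    _write("cohort.vcf", _vcf_text(dataset))

    import io

    buf = io.StringIO()
    write_variants_tsv(dataset.variants, buf)
    _write("variants.tsv", buf.getvalue())

    buf = io.StringIO()
    write_coverage_tsv(dataset.coverage, buf)
    _write("coverage.tsv", buf.getvalue())

    samples = pd.DataFrame(
        [(s, "case") for s in dataset.cases] + [(s, "control") for s in dataset.controls],
        columns=["sample", "cohort"],
    )
    _write("samples.tsv", samples.to_csv(sep="\t", index=False))

    buf = io.StringIO()
    write_ped(dataset.pedigrees, buf)
    _write("family.ped", buf.getvalue())

    fam_rows = []
    for ped in dataset.pedigrees:
        for member, gmap in sorted(ped.genotypes.items()):
            for vid, state in sorted(gmap.items()):
                fam_rows.append((ped.family_id, member, vid, state))
    _write(
        "family_genotypes.tsv",
        pd.DataFrame(
            fam_rows, columns=["family", "member", "variant_id", "state"]
        ).to_csv(sep="\t", index=False),
    )

    buf = io.StringIO()
    write_variants_tsv(dataset.family_variants, buf)
    _write("family_variants.tsv", buf.getvalue())

    by_resource: dict[str, list[tuple[str, float]]] = {}
    for v in dataset.variants:
        for resource, af in v.freq.items():
            by_resource.setdefault(resource, []).append((v.variant_id, af))
    for resource, rows in sorted(by_resource.items()):
        _write(
            f"af_{resource}.tsv",
            pd.DataFrame(rows, columns=["variant_id", "af"]).to_csv(
                sep="\t", index=False
            ),
        )

    _write("truth.json", json.dumps(dataset.truth, indent=2, sort_keys=True) + "\n")
    (directory / "manifest.json").write_text(
        json.dumps(files, indent=2, sort_keys=True) + "\n"
    )
    return files
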