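"""Annotated-variant data model and qualifying-variant classification.

A variant enters the burden analysis as an :class:`AnnotatedVariant`:
genomic coordinates (1-based, GRCh37-style), a functional consequence
taken verbatim from the annotation source, a pre-computed CADD
deleteriousness score, and per-resource population allele frequencies.
CADD is consumed as an annotation, never computed here; a score of 20
corresponds roughly to the top 1% most deleterious substitutions.

Three rules turn annotations into analysis categories:

* **novelty** — a variant is novel iff it is absent from every resource
  in a configured list (presence decides, not frequency: an entry at
  allele frequency 0 still disqualifies);
* **classification** — loss-of-function consequences (nonsense,
  frameshift, splice-site, in-frame indel) cluster into a single
  likely-gene-disrupting (LGD) class; missense variants split into
  damaging (D-mis, CADD >= threshold, inclusive) and non-damaging;
* **domain annotation** — a protein residue maps to the unique domain
  interval containing it, or to ``"inter-domain"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, InputFormatError

#: Consequence vocabulary accepted by the classifier.
CONSEQUENCES = frozenset(
    {
        "nonsense",
        "frameshift",
        "splice_site",
        "inframe_indel",
        "missense",
        "synonymous",
        "other",
    }
)

#: Consequences clustered into the likely-gene-disrupting (LGD) class.
LGD_CONSEQUENCES = frozenset({"nonsense", "frameshift", "splice_site", "inframe_indel"})

#: Frequency resources the novelty filter knows about.
KNOWN_RESOURCES = ("1KG", "ESP", "ExAC", "dbSNP", "UMD_FBN1", "gnomAD")

#: Resources consulted by the default novelty filter.  gnomAD is
#: annotated but deliberately not consulted: the reference inventory
#: this package ships contains a variant present in gnomAD at AF 4e-6
#: that nonetheless counts as novel.
DEFAULT_NOVELTY_RESOURCES = ("1KG", "ESP", "ExAC", "dbSNP", "UMD_FBN1")

#: Default D-mis cutoff, inclusive.
DEFAULT_CADD_THRESHOLD = 20.0


class MutationClass(Enum):
    """Collapsed mutation class used to form burden strata."""

    LGD = "LGD"
    MISSENSE_DMIS = "MISSENSE_DMIS"
    MISSENSE_NON_DMIS = "MISSENSE_NON_DMIS"
    OTHER = "OTHER"


@dataclass(frozen=True)
class Classification:
    """A mutation class together with the raw consequence it came from.

    The raw consequence is retained because burden tables stratify
    sub-rows by it (Frameshift / Splicing / Missense) even though all
    loss-of-function consequences share the LGD class.
    """

    mclass: MutationClass
    consequence: str

    @property
    def is_lgd(self) -> bool:
        return self.mclass is MutationClass.LGD

    @property
    def is_dmis(self) -> bool:
        return self.mclass is MutationClass.MISSENSE_DMIS


@dataclass
class AnnotatedVariant:
    """One annotated variant record.

    Parameters
    ----------
    chrom, pos, ref, alt
        Genomic coordinates (1-based) and allele strings.
    gene
        Gene symbol the variant is assigned to.
    consequence
        One of :data:`CONSEQUENCES`.
    cdna_change, protein_change
        HGVS ``c.`` / ``p.`` strings, informational only.
    protein_pos
        1-based residue index; required for missense and nonsense
        variants (used for domain annotation and truncation distance).
    cadd
        Pre-computed CADD score, ``None`` when unscored.
    freq
        Resource name -> allele frequency.  An absent key means the
        variant is not present in that resource.
    qc_pass
        Whether the record passed upstream genotype-quality filters.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    cdna_change: str | None = None
    protein_change: str | None = None
    protein_pos: int | None = None
    cadd: float | None = None
    freq: dict[str, float] = field(default_factory=dict)
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputFormatError(f"{self.chrom}:{self.pos}: position must be >= 1")
        if self.consequence not in CONSEQUENCES:
            raise InputFormatError(
                f"{self.variant_id}: unknown consequence {self.consequence!r}"
            )
        if self.cadd is not None and self.cadd < 0:
            raise InputFormatError(f"{self.variant_id}: negative CADD score")
        for resource, af in self.freq.items():
            if not 0.0 <= af <= 1.0:
                raise InputFormatError(
                    f"{self.variant_id}: allele frequency {af} in {resource} "
                    "outside [0, 1]"
                )
        if self.consequence in ("missense", "nonsense") and self.protein_pos is None:
            # Try to recover the residue index from the HGVS p. string.
            recovered = _protein_pos_from_hgvs(self.protein_change)
            if recovered is None:
                raise InputFormatError(
                    f"{self.variant_id}: {self.consequence} variant needs a "
                    "protein position"
                )
            self.protein_pos = recovered
        if self.protein_pos is not None and self.protein_pos < 1:
            raise InputFormatError(f"{self.variant_id}: protein position must be >= 1")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


_HGVS_P_RE = re.compile(r"p\.\(?[A-Za-z]{1,3}(\d+)")


def _read_tsv_hash_safe(path_or_text) -> pd.DataFrame:
    """Read a TSV skipping full-line ``#`` comments only.

    Unlike ``pd.read_csv(..., comment='#')`` this keeps ``#`` characters
    appearing inside field values intact.
    """
    import io

    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        text = Path(path_or_text).read_text()
    kept = "\n".join(
        line for line in text.splitlines() if not line.lstrip().startswith("#")
    )
    return pd.read_csv(io.StringIO(kept), sep="\t", float_precision="round_trip")


def _protein_pos_from_hgvs(protein_change: str | None) -> int | None:
    """Extract the residue integer from an HGVS ``p.`` string, if any.

    This is deliberately minimal — no full HGVS grammar, just the
    leading residue index (``p.Trp883Ter`` -> 883).
    """
    if not protein_change:
        return None
    m = _HGVS_P_RE.search(protein_change)
    return int(m.group(1)) if m else None


def is_novel(
    variant: AnnotatedVariant,
    novelty_resources: Sequence[str] = DEFAULT_NOVELTY_RESOURCES,
    known_resources: Sequence[str] = KNOWN_RESOURCES,
) -> bool:
    """Return True iff the variant is absent from every listed resource.

    Presence decides, not frequency: a record present at allele
    frequency 0 in a listed resource is *not* novel.  Resources not in
    ``novelty_resources`` (for example gnomAD under the default list)
    are ignored even when the variant has an entry there.

    Raises
    ------
    ConfigurationError
        If ``novelty_resources`` is empty or names a resource outside
        ``known_resources``.
    """
    if not novelty_resources:
        raise ConfigurationError("novelty resource list must not be empty")
    unknown = set(novelty_resources) - set(known_resources)
    if unknown:
        raise ConfigurationError(
            f"unknown novelty resource(s): {sorted(unknown)}; "
            f"known: {list(known_resources)}"
        )
    return all(resource not in variant.freq for resource in novelty_resources)


def classify(
    variant: AnnotatedVariant, cadd_threshold: float = DEFAULT_CADD_THRESHOLD
) -> Classification:
    """Assign the collapsed mutation class of a variant.

    Nonsense, frameshift, splice-site and in-frame indel consequences
    cluster into LGD.  Missense variants are D-mis when their CADD
    score is at or above ``cadd_threshold`` (the boundary is inclusive:
    a score of exactly 20 is D-mis under the default cutoff).

    Raises
    ------
    ConfigurationError
        If a missense variant carries no CADD score — silently treating
        an unscored variant as non-damaging would bias the burden test.
    """
    cons = variant.consequence
    if cons in LGD_CONSEQUENCES:
        return Classification(MutationClass.LGD, cons)
    if cons == "missense":
        if variant.cadd is None:
            raise ConfigurationError(
                f"{variant.variant_id}: missense variant without a CADD score "
                "cannot be stratified (unscored)"
            )
        if variant.cadd >= cadd_threshold:
            return Classification(MutationClass.MISSENSE_DMIS, cons)
        return Classification(MutationClass.MISSENSE_NON_DMIS, cons)
    return Classification(MutationClass.OTHER, cons)


@dataclass(frozen=True)
class DomainMap:
    """Ordered protein-domain intervals, 1-based inclusive."""

    intervals: tuple[tuple[int, int, str], ...]
    protein_length: int

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end, name in self.intervals:
            if start < 1 or end > self.protein_length or start > end:
                raise InputFormatError(
                    f"domain {name!r} interval [{start}, {end}] outside "
                    f"[1, {self.protein_length}]"
                )
            if start <= prev_end:
                raise InputFormatError(
                    f"domain {name!r} overlaps or is out of order at {start}"
                )
            prev_end = end

    @classmethod
    def from_tsv(cls, path: str | Path, protein_length: int) -> "DomainMap":
        """Read a ``start<TAB>end<TAB>name`` table (header required).

        Full-line ``#`` comments are allowed; domain names themselves
        may contain ``#`` (e.g. "cbEGF-like #32"), so only whole lines
        are treated as comments.
        """
        df = _read_tsv_hash_safe(path)
        missing = {"start", "end", "name"} - set(df.columns)
        if missing:
            raise InputFormatError(f"{path}: missing column(s) {sorted(missing)}")
        ivals = tuple(
            (int(r.start), int(r.end), str(r.name_))
            for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
        )
        return cls(tuple(sorted(ivals)), protein_length)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.intervals, columns=["start", "end", "name"]).to_csv(
            path, sep="\t", index=False
        )


def annotate_domain(protein_pos: int, domain_map: DomainMap) -> str:
    """Name the domain containing a residue, or ``"inter-domain"``.

    Raises
    ------
    InputFormatError
        If the residue lies outside ``[1, protein_length]``.
    """
    if not 1 <= protein_pos <= domain_map.protein_length:
        raise InputFormatError(
            f"residue {protein_pos} outside [1, {domain_map.protein_length}]"
        )
    for start, end, name in domain_map.intervals:
        if start <= protein_pos <= end:
            return name
    return "inter-domain"


def truncation_distance(protein_length: int, stop_codon: int) -> int:
    """Residues from a premature stop to the C-terminus, inclusive.

    A stop at the last residue is 1 residue from the end; a stop at
    residue 1 of an L-residue protein is L residues from the end.
    """
    if not 1 <= stop_codon <= protein_length:
        raise InputFormatError(
            f"stop codon {stop_codon} outside [1, {protein_length}]"
        )
    return protein_length - stop_codon + 1


# ---------------------------------------------------------------------------
# Readers


def read_variants_tsv(path: str | Path) -> list[AnnotatedVariant]:
    """Read a flat annotated-variant table.

    Required columns: chrom, pos, ref, alt, gene, consequence.
    Optional: cdna_change, protein_change, protein_pos, cadd, qc_pass,
    and one ``af_<resource>`` column per frequency resource (empty cell
    = variant absent from that resource).
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip", dtype={"chrom": str}, comment="#")
    required = {"chrom", "pos", "ref", "alt", "gene", "consequence"}
    missing = required - set(df.columns)
    if missing:
        raise InputFormatError(f"{path}: missing column(s) {sorted(missing)}")
    af_cols = {c: c[3:] for c in df.columns if c.startswith("af_")}
    variants = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        freq = {}
        for col, resource in af_cols.items():
            val = rec[col]
            if pd.notna(val):
                freq[resource] = float(val)

        def _opt(key, cast):
            val = rec.get(key)
            return cast(val) if val is not None and pd.notna(val) else None

        variants.append(
            AnnotatedVariant(
                chrom=str(rec["chrom"]),
                pos=int(rec["pos"]),
                ref=str(rec["ref"]),
                alt=str(rec["alt"]),
                gene=str(rec["gene"]),
                consequence=str(rec["consequence"]),
                cdna_change=_opt("cdna_change", str),
                protein_change=_opt("protein_change", str),
                protein_pos=_opt("protein_pos", int),
                cadd=_opt("cadd", float),
                freq=freq,
                qc_pass=str(rec.get("qc_pass", True)).lower() not in ("false", "0"),
            )
        )
    return variants


def write_variants_tsv(variants: Iterable[AnnotatedVariant], path: str | Path) -> None:
    """Write the flat table :func:`read_variants_tsv` reads (round-trip safe)."""
    rows = []
    resources: list[str] = []
    for v in variants:
        row = {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "consequence": v.consequence,
            "cdna_change": v.cdna_change,
            "protein_change": v.protein_change,
            "protein_pos": v.protein_pos,
            "cadd": v.cadd,
            "qc_pass": v.qc_pass,
        }
        for resource, af in v.freq.items():
            row[f"af_{resource}"] = af
            if resource not in resources:
                resources.append(resource)
        rows.append(row)
    cols = [
        "chrom", "pos", "ref", "alt", "gene", "consequence", "cdna_change",
        "protein_change", "protein_pos", "cadd", "qc_pass",
    ] + [f"af_{r}" for r in resources]
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_variants_vcf(
    path: str | Path,
) -> tuple[list[AnnotatedVariant], dict[str, set[str]]]:
    """Read variants and per-sample carrier sets from a VCF.

    Annotations are taken from INFO keys ``GENE``, ``CSQ`` (consequence),
    ``CADD``, ``PPOS`` (protein position), ``CDNA``, ``PCHANGE`` and one
    ``AF_<resource>`` key per frequency resource.  Any sample whose
    genotype contains at least one alternate allele is recorded as a
    carrier of that variant.

    Returns
    -------
    (variants, genotypes)
        ``genotypes`` maps sample id -> set of carried variant ids and
        contains every sample in the VCF header (possibly empty sets).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    genotypes: dict[str, set[str]] = {s: set() for s in samples}
    variants: list[AnnotatedVariant] = []
    for rec in vcf:
        freq = {}
        for resource in KNOWN_RESOURCES:
            af = rec.INFO.get(f"AF_{resource}")
            if af is not None:
                freq[resource] = float(af)
        ppos = rec.INFO.get("PPOS")
        cadd = rec.INFO.get("CADD")
        variant = AnnotatedVariant(
            chrom=rec.CHROM,
            pos=rec.POS,
            ref=rec.REF,
            alt=rec.ALT[0] if rec.ALT else ".",
            gene=rec.INFO.get("GENE", "."),
            consequence=rec.INFO.get("CSQ", "other"),
            cdna_change=rec.INFO.get("CDNA"),
            protein_change=rec.INFO.get("PCHANGE"),
            protein_pos=int(ppos) if ppos is not None else None,
            cadd=float(cadd) if cadd is not None else None,
            freq=freq,
            qc_pass=rec.FILTER is None,  # PASS / '.' both mean unfiltered
        )
        variants.append(variant)
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        for sample, gt_type in zip(samples, rec.gt_types):
            if gt_type in (1, 3):
                genotypes[sample].add(variant.variant_id)
    return variants, genotypes


def filter_qualifying(
    variants: Sequence[AnnotatedVariant],
    gene: str | None = None,
    novelty_resources: Sequence[str] = DEFAULT_NOVELTY_RESOURCES,
    excluded_sites: frozenset[tuple[str, int]] | set[tuple[str, int]] = frozenset(),
) -> list[AnnotatedVariant]:
    """Apply the qualifying-variant filters in pipeline order.

    Keeps variants that (1) pass QC, (2) lie in ``gene`` when given,
    (3) do not fall on a coverage-pruned site, and (4) are novel with
    respect to ``novelty_resources``.
    """
    out = []
    for v in variants:
        if not v.qc_pass:
            continue
        if gene is not None and v.gene != gene:
            continue
        if v.site in excluded_sites:
            continue
        if not is_novel(v, novelty_resources):
            continue
        out.append(v)
    return out


def variants_by_class(
    variants: Sequence[AnnotatedVariant],
    cadd_threshold: float = DEFAULT_CADD_THRESHOLD,
) -> Mapping[str, Classification]:
    """Classify a batch, keyed by variant id."""
    return {v.variant_id: classify(v, cadd_threshold) for v in variants}
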