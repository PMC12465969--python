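"""Core record types shared across the pipeline.

All coordinates are stored 0-based half-open internally; VCF positions
(1-based) are converted on ingest.  Mutation classes are strand-collapsed
to the pyrimidine strand, with C>T at CpG dinucleotides split out as its
own class (``CpG>TpG``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

MUTATION_CLASSES = ("C>A", "C>G", "C>T", "CpG>TpG", "T>A", "T>C", "T>G")

#: primary region categories, in lookup priority order on the X contig
REGION_CATEGORIES = ("AUTOSOME", "PAR", "X_UNIQUE")

#: region labels usable as rate-estimation strata
REGION_LABELS = ("AUTOSOME", "PAR", "X_UNIQUE", "CGI", "HMR_CGI", "NONHMR_CGI")

#: filter-cascade rule codes, stable across versions
RULE_CODES = (
    "GT_PATTERN",
    "PARENT_ALT_READS",
    "GQ",
    "DEPTH",
    "ALLELE_BALANCE",
    "NOT_SNV",
    "READ_CHECK",
    "MISSING_EVIDENCE",
)


@dataclass(frozen=True)
class TrioRecord:
    """One parent-offspring trio.

    Ages are ages of the parents at conception of the offspring, in
    years.  ``mean_depth`` maps individual role ('offspring', 'sire',
    'dam') to genome-wide mean autosomal sequencing depth (the ``indDP``
    of the depth filter).
    """

    trio_id: str
    offspring_id: str
    sire_id: str
    dam_id: str
    offspring_sex: str  # 'M' or 'F'
    paternal_age_years: float
    maternal_age_years: float
    breed: str = "unknown"
    size_class: str = "intermediate"  # 'small' | 'intermediate' | 'large'
    mean_depth: dict = field(default_factory=lambda: {"offspring": 40.0, "sire": 40.0, "dam": 40.0})
    litter_id: str = ""
    pedigree_id: str = ""

    def __post_init__(self):
        if self.offspring_sex not in ("M", "F"):
            raise ValueError(f"offspring_sex must be 'M' or 'F', got {self.offspring_sex!r}")
        for name, age in (
            ("paternal_age_years", self.paternal_age_years),
            ("maternal_age_years", self.maternal_age_years),
        ):
            if not (age > 0 and age == age and age != float("inf")):
                raise ValueError(f"{name} must be strictly positive and finite, got {age}")
        for who, d in self.mean_depth.items():
            if not d > 0:
                raise ValueError(f"mean depth for {who} must be > 0, got {d}")


@dataclass
class CandidateSite:
    """One variant site's per-sample genotype evidence within a trio.

    ``pos`` is 0-based internally.  ``gt``, ``gq``, ``dp`` and ``ad`` map
    sample role ('offspring', 'sire', 'dam') to the respective VCF
    fields; ``ad`` holds (ref_depth, alt_depth) pairs.  ``context3`` is
    the reference triplet centred on the site (bases at pos-1..pos+1).
    """

    contig: str
    pos: int
    ref: str
    alt: str
    gt: dict
    gq: dict
    dp: dict
    ad: dict
    context3: str = "NNN"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and \
            self.ref in "ACGT" and self.alt in "ACGT"


@dataclass
class DNMCall:
    """An accepted de novo single-nucleotide mutation."""

    trio_id: str
    contig: str
    pos: int
    ref: str
    alt: str
    mutation_class: str
    region: str = "AUTOSOME"  # primary category
    in_cgi: bool = False
    in_hmr_cgi: bool = False
    phase: str = "unphased"  # 'paternal' | 'maternal' | 'unphased'
    shared_group_id: str | None = None

    def __post_init__(self):
        if self.mutation_class not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation class {self.mutation_class!r}")
        if self.phase not in ("paternal", "maternal", "unphased"):
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass
class CallableProfile:
    """Per-trio callable-site and callable-size accounting.

    ``callable_sites`` counts genome positions (bp) passing the
    callability criteria per region category.  ``callable_size`` is the
    rate denominator after ploidy scaling: x2 everywhere except the
    X-unique region of a male offspring, where x1.
    """

    trio_id: str
    callable_sites: dict
    callable_size: dict
    callable_fraction: float

    def __post_init__(self):
        if not 0.0 <= self.callable_fraction <= 1.0:
            raise ValueError(f"callable_fraction outside [0, 1]: {self.callable_fraction}")


@dataclass
class FilterVerdict:
    """Outcome of the DNM filter cascade at one candidate site."""

    site_id: str
    passed: bool
    failed_rules: list

    def __post_init__(self):
        if self.passed != (len(self.failed_rules) == 0):
            raise ValueError("pass flag inconsistent with failed-rule list")
        for code in self.failed_rules:
            if code not in RULE_CODES:
                raise ValueError(f"unknown rule code {code!r}")
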