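"""Trio DNM filter cascade, read-level post-check, and callable accounting.

The cascade mirrors standard trio-based DNM calling practice: an
offspring heterozygote absent from both homozygous-reference parents,
with at most one alternate-allele read across the parents, offspring
GQ >= 40, per-sample depth at least 12 and within (0.5x, 2x) of that
individual's genome-wide mean depth, and offspring allele balance
strictly inside (0.25, 0.75).  For sites in the X-unique region of a
male offspring the depth thresholds are halved and the allele balance
must instead exceed 0.75 (hemizygous X); PAR sites are treated as
autosomal.  Only single-nucleotide variants are eligible.
"""

from __future__ import annotations

from dataclasses import dataclass

from canidnm.records import CallableProfile, CandidateSite, FilterVerdict, TrioRecord

ROLES = ("offspring", "sire", "dam")


@dataclass(frozen=True)
class FilterThresholds:
    """Central thresholds of the cascade (defaults are the study values)."""

    min_gq: int = 40
    min_dp: int = 12
    dp_mean_low: float = 0.5
    dp_mean_high: float = 2.0
    ab_low: float = 0.25
    ab_high: float = 0.75
    max_parent_alt_reads: int = 1
    gq_all_samples: bool = False  # GQ rule on parents too, if True
    min_trio_mean_depth: float = 24.0  # cohort-level trio exclusion


DEFAULT_THRESHOLDS = FilterThresholds()


def _is_male_x_unique(site: CandidateSite, trio: TrioRecord, region_map) -> bool:
    if region_map is None or trio.offspring_sex != "M":
        return False
    return region_map.primary_category(site.contig, site.pos) == "X_UNIQUE"


def apply_dnm_filters(
    site: CandidateSite,
    trio: TrioRecord,
    region_map=None,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
) -> FilterVerdict:
    """Evaluate the DNM filter cascade at one candidate site.

    Returns a :class:`FilterVerdict` whose ``failed_rules`` lists every
    violated rule (the verdict is order-independent).  Missing genotype
    evidence fails closed with rule ``MISSING_EVIDENCE``.
    """
    t = thresholds
    site_id = f"{site.contig}:{site.pos}:{site.ref}>{site.alt}"
    for role in ROLES:
        if (
            role not in site.gt
            or role not in site.dp
            or role not in site.ad
            or site.ad[role] is None
            or role not in site.gq
        ):
            return FilterVerdict(site_id, False, ["MISSING_EVIDENCE"])

    failed = []
    male_x = _is_male_x_unique(site, trio, region_map)
    halve = 0.5 if male_x else 1.0

    # 1. genotype pattern: offspring het 0/1, both parents hom-ref 0/0
    if not (
        sorted(site.gt["offspring"]) == [0, 1]
        and site.gt["sire"] == (0, 0)
        and site.gt["dam"] == (0, 0)
    ):
        failed.append("GT_PATTERN")

    # 2. at most one alternate read across both parents
    parent_alt = site.ad["sire"][1] + site.ad["dam"][1]
    if parent_alt > t.max_parent_alt_reads:
        failed.append("PARENT_ALT_READS")

    # 3. genotype quality
    gq_roles = ROLES if t.gq_all_samples else ("offspring",)
    if any(site.gq[r] < t.min_gq for r in gq_roles):
        failed.append("GQ")

    # 4. depth: DP >= 12 and 0.5*indDP < DP < 2*indDP, halved on male X-unique
    for role in ROLES:
        dp, ind = site.dp[role], trio.mean_depth[role]
        if not (
            dp >= t.min_dp * halve
            and dp > t.dp_mean_low * ind * halve
            and dp < t.dp_mean_high * ind * halve
        ):
            failed.append("DEPTH")
            break

    # 5. offspring allele balance
    ref_d, alt_d = site.ad["offspring"]
    total = ref_d + alt_d
    ab = alt_d / total if total > 0 else 0.0
    if male_x:
        if not ab > t.ab_high:
            failed.append("ALLELE_BALANCE")
    elif not (t.ab_low < ab < t.ab_high):
        failed.append("ALLELE_BALANCE")

    # 6. SNV only
    if not site.is_snv:
        failed.append("NOT_SNV")

    return FilterVerdict(site_id, not failed, failed)


def read_check(
    offspring_reads,
    sire_reads,
    dam_reads,
    ref: str,
    alt: str,
    ab_low: float = 0.25,
    ab_high: float = 0.75,
    max_incorrect: int = 1,
) -> bool:
    """Read-level post-check of an accepted DNM candidate.

    ``*_reads`` are per-read base calls at the site.  An "incorrect"
    read is a parental read differing from the reference allele, or an
    offspring read carrying neither the reference nor the DNM alternate.
    The candidate fails when more than ``max_incorrect`` such reads are
    seen, or when the offspring read-level allele balance falls outside
    [``ab_low``, ``ab_high``].  A site with no offspring reads fails
    closed.
    """
    offspring_reads = list(offspring_reads)
    if not offspring_reads:
        return False
    incorrect = sum(1 for b in sire_reads if b != ref)
    incorrect += sum(1 for b in dam_reads if b != ref)
    incorrect += sum(1 for b in offspring_reads if b not in (ref, alt))
    if incorrect > max_incorrect:
        return False
    ab = sum(1 for b in offspring_reads if b == alt) / len(offspring_reads)
    return ab_low <= ab <= ab_high


def site_is_callable(
    parent_gts: dict,
    depths: dict,
    trio: TrioRecord,
    primary_category: str = "AUTOSOME",
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Whether a genome position could have yielded a DNM call.

    Callable means: both parents homozygous reference and every trio
    member passes the same depth rules as DNM calling (halved on the
    X-unique region of a male offspring).
    """
    t = thresholds
    if parent_gts.get("sire") != (0, 0) or parent_gts.get("dam") != (0, 0):
        return False
    halve = 0.5 if (primary_category == "X_UNIQUE" and trio.offspring_sex == "M") else 1.0
    for role in ROLES:
        dp, ind = depths[role], trio.mean_depth[role]
        if not (
            dp >= t.min_dp * halve
            and dp > t.dp_mean_low * ind * halve
            and dp < t.dp_mean_high * ind * halve
        ):
            return False
    return True


def count_callable_sites(sites, trio: TrioRecord, region_map, thresholds=DEFAULT_THRESHOLDS) -> dict:
    """Tally callable sites per region label from per-site evidence.

    ``sites`` yields (contig, pos, parent_gts, depths) tuples.  Returns
    counts for the primary categories plus CGI / HMR_CGI / NONHMR_CGI
    overlays.
    """
    counts = {
        label: 0
        for label in ("AUTOSOME", "PAR", "X_UNIQUE", "CGI", "HMR_CGI", "NONHMR_CGI")
    }
    for contig, pos, parent_gts, depths in sites:
        primary, in_cgi, in_hmr = region_map.region_flags(contig, pos)
        if not site_is_callable(parent_gts, depths, trio, primary, thresholds):
            continue
        counts[primary] += 1
        if in_cgi:
            counts["CGI"] += 1
            counts["HMR_CGI" if in_hmr else "NONHMR_CGI"] += 1
    return counts


def compute_callable_profile(
    callable_sites: dict,
    trio: TrioRecord,
    genome_size: int | None = None,
) -> CallableProfile:
    """Scale per-region callable sites into callable sizes.

    Every region contributes two callable haplotypes per site except the
    X-unique region, where a male offspring carries a single X: the
    scaling factor is 1 for males and 2 for females.  ``genome_size``
    (bp, haploid) yields the callable fraction; when omitted the
    fraction is computed over the sites supplied.
    """
    male = trio.offspring_sex == "M"
    sizes = {}
    for label, n in callable_sites.items():
        if n < 0:
            raise ValueError(f"negative callable-site count for {label}")
        factor = 1 if (label == "X_UNIQUE" and male) else 2
        sizes[label] = factor * n
    primary_total = sum(
        callable_sites.get(lbl, 0) for lbl in ("AUTOSOME", "PAR", "X_UNIQUE")
    )
    denom = genome_size if genome_size else max(primary_total, 1)
    return CallableProfile(
        trio_id=trio.trio_id,
        callable_sites=dict(callable_sites),
        callable_size=sizes,
        callable_fraction=min(primary_total / denom, 1.0),
    )


def exclude_low_depth_trios(trios, thresholds: FilterThresholds = DEFAULT_THRESHOLDS):
    """Drop trios with any individual mean depth below the cohort gate (24x)."""
    return [
        t for t in trios if min(t.mean_depth.values()) >= thresholds.min_trio_mean_depth
    ]
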