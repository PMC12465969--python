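"""Synthetic trio cohorts with the statistical structure of a real
multi-breed dog pedigree study.

The generator emulates, at the level the downstream analyses consume:

* trios with breeds, size classes, parental ages at conception, and
  per-individual mean sequencing depths;
* per-parent phased DNM counts that are Poisson with identity-scale
  age-linear means, (b0 + b1 * age) * G_haploid;
* a 7-class mutational spectrum and strand-consistent triplet contexts;
* uniform genomic placement with a configurable fold-oversampling of
  hypomethylated CpG islands (the recombination-mutagenesis signal);
* early embryonic mutations duplicated across littermates (the
  sibling-sharing signal), split evenly between parental origins;
* per-site genotype evidence (GT/GQ/DP/AD) with negative-binomial depth
  and binomial allele-balance noise, writable as VCF;
* paired phylogenies whose branch-length ratio shifts on one branch at
  a configurable loss time.

Defaults are the study conditions: 390 trios, paternal/maternal age
slopes 3.25e-10 and 9.64e-11 mutations/bp/year, a cohort rate of
4.89e-9/bp/generation with 75.05% of phased mutations paternal, a
2.34-fold hypomethylated-CGI enrichment over a 30.68-Mb span, and a
0.45% sibling pair-shared fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from canidnm.records import MUTATION_CLASSES, TrioRecord
from canidnm.regions import GenomeRegionMap
from canidnm.phylo import _as_tree, node_ages

# class -> (triplet context, ref, alt) consistent with the classifier
_CLASS_TEMPLATES = {
    "C>A": ("ACA", "C", "A"),
    "C>G": ("ACA", "C", "G"),
    "C>T": ("ACA", "C", "T"),
    "CpG>TpG": ("ACG", "C", "T"),
    "T>A": ("ATA", "T", "A"),
    "T>C": ("ATA", "T", "C"),
    "T>G": ("ATA", "T", "G"),
}

#: representative 7-class spectrum (transition-rich, CpG-heavy, as in
#: carnivore germline spectra); configurable per cohort
DEFAULT_SPECTRUM = {
    "C>A": 0.08,
    "C>G": 0.09,
    "C>T": 0.26,
    "CpG>TpG": 0.19,
    "T>A": 0.07,
    "T>C": 0.25,
    "T>G": 0.06,
}

DEFAULT_TIME_TREE = (
    "((((dog:6.0,african_wild_dog:6.0):6.0,fox:12.0):33.0,bear:45.0):9.0,cat:54.0);"
)


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic trio cohort.

    Slopes and intercepts are identity-scale regression parameters of
    the per-parent phased mutation rate (mutations per haploid bp);
    intercepts left as ``None`` are solved so that the cohort rate at
    the mean parental ages equals ``target_rate`` with paternal share
    ``target_paternal_fraction``.
    """

    n_trios: int = 390
    seed: int = 0
    # age model (identity scale, per haploid bp)
    paternal_slope: float = 3.25e-10
    maternal_slope: float = 9.64e-11
    paternal_intercept: float | None = None
    maternal_intercept: float | None = None
    target_rate: float = 4.89e-9  # per bp per generation (diploid denominator)
    target_paternal_fraction: float = 0.7505
    # age distributions (truncated normal, years)
    age_mean: float = 5.0
    age_sd: float = 2.2
    age_bounds: tuple = (1.0, 12.0)
    # genome / callability
    callable_fraction_mean: float = 0.9652
    callable_fraction_sd: float = 0.002
    # regional enrichment
    hmr_fold: float = 2.34
    # sharing and phasing
    shared_fraction: float = 0.0045  # target full-sib pair-shared fraction
    phasing_fraction: float = 0.3111
    mean_litter_size: float = 2.4
    # sequencing depth model
    depth_mean: float = 43.3
    depth_sd: float = 4.0
    depth_dispersion: float = 8.0  # negative-binomial size for per-site DP
    min_mean_depth: float = 30.0
    # optional per-size-class paternal slopes; the class intercept is
    # re-solved so the paternal rate at the mean age is unchanged
    # (slower-but-earlier vs faster-but-later accumulation)
    paternal_slope_by_class: dict | None = None
    # breed structure
    breeds: tuple = (
        ("pug", "small"),
        ("bichon_frise", "small"),
        ("border_collie", "intermediate"),
        ("finnish_lapphund", "intermediate"),
        ("german_shepherd", "large"),
        ("great_dane", "large"),
    )
    spectrum: dict = field(default_factory=lambda: dict(DEFAULT_SPECTRUM))

    def __post_init__(self):
        if self.n_trios < 1:
            raise ValueError("n_trios must be >= 1")
        total = sum(self.spectrum.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"spectrum probabilities sum to {total}, not 1")
        if set(self.spectrum) - set(MUTATION_CLASSES):
            raise ValueError("spectrum contains unknown classes")
        if self.hmr_fold < 1:
            raise ValueError("hmr_fold must be >= 1")
        for name in ("paternal_slope", "maternal_slope", "target_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.paternal_intercept is None:
            r_p = 2.0 * self.target_rate * self.target_paternal_fraction
            self.paternal_intercept = r_p - self.paternal_slope * self.age_mean
        if self.maternal_intercept is None:
            r_m = 2.0 * self.target_rate * (1.0 - self.target_paternal_fraction)
            self.maternal_intercept = r_m - self.maternal_slope * self.age_mean
        lo = min(self.age_bounds)
        for b0, b1, who in (
            (self.paternal_intercept, self.paternal_slope, "paternal"),
            (self.maternal_intercept, self.maternal_slope, "maternal"),
        ):
            if b0 + b1 * lo < 0:
                raise ValueError(f"negative implied Poisson mean for {who} model")

    def parent_rate(self, sex: str, age, size_class: str | None = None) -> np.ndarray:
        """Phased per-haploid-bp mutation rate at a parental age."""
        if sex == "paternal":
            b0, b1 = self.paternal_intercept, self.paternal_slope
            if self.paternal_slope_by_class and size_class in self.paternal_slope_by_class:
                b1 = self.paternal_slope_by_class[size_class]
                b0 = (
                    self.paternal_intercept
                    + self.paternal_slope * self.age_mean
                    - b1 * self.age_mean
                )
            return b0 + b1 * np.asarray(age)
        return self.maternal_intercept + self.maternal_slope * np.asarray(age)


def default_region_map(
    autosome_bp: int = 2_280_000_000,
    x_bp: int = 124_000_000,
    par_bp: int = 6_800_000,
    hmr_cgi_bp: int = 30_682_000,
    nonhmr_cgi_bp: int = 36_819_000,
    n_islands: int = 2000,
) -> GenomeRegionMap:
    """Synthetic genome with the study's regional geometry.

    Two autosomes plus an X whose tip is the PAR; CpG islands sit on the
    first autosome as ``n_islands`` regularly spaced blocks, each split
    into a hypomethylated and a methylated half.  Island blocks are far
    coarser than real CGIs; only their total spans matter downstream.
    """
    a1 = autosome_bp * 6 // 10
    a2 = autosome_bp - a1
    hmr_len = hmr_cgi_bp // n_islands
    non_len = nonhmr_cgi_bp // n_islands
    spacing = a1 // (n_islands + 1)
    if spacing <= hmr_len + non_len:
        raise ValueError("islands overlap: reduce n_islands or spans")
    cgi, hmr = [], []
    for i in range(n_islands):
        s = (i + 1) * spacing
        hmr.append((s, s + hmr_len))
        cgi.append((s, s + hmr_len + non_len))
    return GenomeRegionMap(
        contigs={"A1": a1, "A2": a2, "X": x_bp},
        intervals={
            "PAR": {"X": np.array([(0, par_bp)])},
            "X_UNIQUE": {"X": np.array([(par_bp, x_bp)])},
            "CGI": {"A1": np.array(cgi)},
            "HMR_CGI": {"A1": np.array(hmr)},
        },
        x_contig="X",
    )


@dataclass
class SimulatedCohort:
    """A generated cohort: trios, truth DNM table, callable accounting."""

    config: SimulationConfig
    trios: list
    dnms: pd.DataFrame
    callable_sites: dict  # trio_id -> {region label -> sites}
    region_map: GenomeRegionMap
    seed: int

    @property
    def trio_index(self) -> dict:
        return {t.trio_id: t for t in self.trios}


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _place_positions(rng, n, region_map, fold):
    """Autosomal placement with HMR-CGI oversampled by ``fold``.

    Sampling is uniform within the chosen stratum; the HMR stratum is
    chosen with probability fold*f / (1 - f + fold*f) where f is the
    HMR fraction of the autosome, so the expected HMR share of
    mutations is that closed form.
    """
    hmr_iv = region_map.intervals["HMR_CGI"]["A1"]
    hmr_span = int((hmr_iv[:, 1] - hmr_iv[:, 0]).sum())
    auto_span = region_map.span("AUTOSOME")
    f = hmr_span / auto_span
    p_hmr = fold * f / (1.0 - f + fold * f)
    in_hmr = rng.random(n) < p_hmr
    contigs = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    # HMR placement: uniform over concatenated island space
    k = int(in_hmr.sum())
    if k:
        offsets = np.concatenate([[0], np.cumsum(hmr_iv[:, 1] - hmr_iv[:, 0])])
        u = rng.integers(0, offsets[-1], size=k)
        idx = np.searchsorted(offsets, u, side="right") - 1
        pos[in_hmr] = hmr_iv[idx, 0] + (u - offsets[idx])
        contigs[in_hmr] = "A1"
    # non-HMR: rejection-sample uniform autosome positions outside HMR
    m = n - k
    if m:
        a1 = region_map.contigs["A1"]
        a2 = region_map.contigs["A2"]
        got = 0
        cs, ps = [], []
        while got < m:
            draw = rng.integers(0, a1 + a2, size=(m - got) * 2 + 8)
            c = np.where(draw < a1, "A1", "A2")
            p = np.where(draw < a1, draw, draw - a1)
            keep = np.ones(len(draw), dtype=bool)
            on_a1 = c == "A1"
            if on_a1.any():
                i = np.searchsorted(hmr_iv[:, 0], p[on_a1], side="right") - 1
                inside = (i >= 0) & (p[on_a1] < hmr_iv[np.clip(i, 0, None), 1])
                keep[on_a1] = ~inside
            cs.append(c[keep])
            ps.append(p[keep])
            got += int(keep.sum())
        cs = np.concatenate(cs)[:m]
        ps = np.concatenate(ps)[:m]
        contigs[~in_hmr] = cs
        pos[~in_hmr] = ps
    return contigs, pos


def simulate_cohort(config: SimulationConfig, region_map: GenomeRegionMap | None = None) -> SimulatedCohort:
    """Generate a full synthetic cohort under the configured model.

    Returns trios, the truth DNM table (with true phase, observed
    phase, class, region flags, and shared-group ids), and per-trio
    callable-site counts per region.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if region_map is None:
        region_map = default_region_map()
    auto_span = region_map.span("AUTOSOME")

    # --- litters and trios ------------------------------------------------
    trios = []
    litters = []  # list of lists of trio indices
    i = 0
    ped = 0
    while i < cfg.n_trios:
        size = min(1 + rng.poisson(cfg.mean_litter_size - 1.0), cfg.n_trios - i)
        breed, size_class = cfg.breeds[ped % len(cfg.breeds)]
        pat_age = float(_truncated_normal(rng, cfg.age_mean, cfg.age_sd, *cfg.age_bounds, size=1)[0])
        mat_age = float(_truncated_normal(rng, cfg.age_mean, cfg.age_sd, *cfg.age_bounds, size=1)[0])
        sire, dam = f"SIRE{ped:04d}", f"DAM{ped:04d}"
        members = []
        for j in range(size):
            tid = f"TRIO{i:04d}"
            depths = {
                role: float(
                    np.clip(rng.normal(cfg.depth_mean, cfg.depth_sd), cfg.min_mean_depth, None)
                )
                for role in ("offspring", "sire", "dam")
            }
            trios.append(
                TrioRecord(
                    trio_id=tid,
                    offspring_id=f"OFF{i:04d}",
                    sire_id=sire,
                    dam_id=dam,
                    offspring_sex="M" if rng.random() < 0.5 else "F",
                    paternal_age_years=pat_age,
                    maternal_age_years=mat_age,
                    breed=breed,
                    size_class=size_class,
                    mean_depth=depths,
                    litter_id=f"LIT{ped:04d}",
                    pedigree_id=f"PED{ped:04d}",
                )
            )
            members.append(i)
            i += 1
        litters.append(members)
        ped += 1

    # --- callable accounting ---------------------------------------------
    fracs = _truncated_normal(
        rng, cfg.callable_fraction_mean, cfg.callable_fraction_sd, 0.5, 1.0, cfg.n_trios
    )
    callable_sites = {}
    for t, frac in zip(trios, fracs):
        callable_sites[t.trio_id] = {
            label: int(round(frac * region_map.span(label)))
            for label in ("AUTOSOME", "PAR", "X_UNIQUE", "CGI", "HMR_CGI", "NONHMR_CGI")
        }

    # --- mutation counts ---------------------------------------------------
    # per-offspring early fraction 2s/(1+s) makes the pair-based shared
    # fraction (shared / union over a sib pair) equal s in expectation
    e_frac = 2.0 * cfg.shared_fraction / (1.0 + cfg.shared_fraction)
    classes = list(cfg.spectrum)
    class_p = np.array([cfg.spectrum[c] for c in classes])

    rows = []
    group_counter = 0
    for litter in litters:
        first = trios[litter[0]]
        G = callable_sites[first.trio_id]["AUTOSOME"]  # haploid callable bp
        mu_p = cfg.parent_rate("paternal", first.paternal_age_years, first.size_class) * G
        mu_m = cfg.parent_rate("maternal", first.maternal_age_years) * G
        m_tot = mu_p + mu_m
        n_early = rng.poisson(e_frac * m_tot)
        early = []
        for _ in range(n_early):
            mclass = classes[rng.choice(len(classes), p=class_p)]
            contig, pos = _place_positions(rng, 1, region_map, cfg.hmr_fold)
            phase = "paternal" if rng.random() < 0.5 else "maternal"
            group_counter += 1
            gid = f"G{group_counter:05d}" if len(litter) > 1 else None
            early.append((contig[0], int(pos[0]), mclass, phase, gid))
        for idx in litter:
            trio = trios[idx]
            Gi = callable_sites[trio.trio_id]["AUTOSOME"]
            mup = cfg.parent_rate("paternal", trio.paternal_age_years, trio.size_class) * Gi
            mum = cfg.parent_rate("maternal", trio.maternal_age_years) * Gi
            n_pat = rng.poisson(max(mup - e_frac * m_tot / 2.0, 0.0))
            n_mat = rng.poisson(max(mum - e_frac * m_tot / 2.0, 0.0))
            n_late = n_pat + n_mat
            contigs, poss = _place_positions(rng, n_late, region_map, cfg.hmr_fold)
            cls_idx = rng.choice(len(classes), size=n_late, p=class_p)
            phases = ["paternal"] * n_pat + ["maternal"] * n_mat
            site_list = [
                (contigs[k], int(poss[k]), classes[cls_idx[k]], phases[k], None)
                for k in range(n_late)
            ] + early
            for contig, pos, mclass, phase, gid in site_list:
                ctx, ref, alt = _CLASS_TEMPLATES[mclass]
                _, in_cgi, in_hmr = region_map.region_flags(contig, pos)
                observed_phase = phase if rng.random() < cfg.phasing_fraction else "unphased"
                rows.append(
                    (
                        trio.trio_id,
                        trio.offspring_id,
                        contig,
                        pos,
                        ref,
                        alt,
                        ctx,
                        mclass,
                        "AUTOSOME",
                        in_cgi,
                        in_hmr,
                        phase,
                        observed_phase,
                        gid,
                        gid is not None,
                    )
                )
    dnms = pd.DataFrame(
        rows,
        columns=[
            "trio_id",
            "offspring_id",
            "contig",
            "pos",
            "ref",
            "alt",
            "context3",
            "mutation_class",
            "region",
            "in_cgi",
            "in_hmr_cgi",
            "true_phase",
            "phase",
            "shared_group_id",
            "is_early",
        ],
    )
    dnms["is_early"] = dnms["shared_group_id"].notna()
    return SimulatedCohort(
        config=cfg,
        trios=trios,
        dnms=dnms,
        callable_sites=callable_sites,
        region_map=region_map,
        seed=cfg.seed,
    )


# ---------------------------------------------------------------------------
# per-site genotype evidence and VCF emission

def simulate_site_evidence(
    cohort: SimulatedCohort,
    seed: int,
    noise: bool = True,
    n_negative_per_trio: int = 0,
    parent_error_rate: float = 0.0,
):
    """Generate GT/GQ/DP/AD evidence for the cohort's true DNM sites.

    With ``noise`` enabled, per-site depth is negative-binomial around
    each individual's mean depth and heterozygote allele depths are
    Binomial(DP, 0.5); parents carry alternate reads at
    ``parent_error_rate`` per read.  With ``noise`` off, depths equal
    the individual means, allele depths split evenly, and parents carry
    zero alternate reads, so the filter cascade recovers truth exactly.
    ``n_negative_per_trio`` adds inherited-heterozygote (parent 0/1)
    sites that a correct filter must reject.

    Returns a DataFrame with one row per (trio, site): trio_id, the
    evidence fields, and ``truth`` in {'dnm', 'inherited'}.
    """
    from canidnm.records import CandidateSite

    rng = np.random.default_rng(seed)
    cfg = cohort.config
    trio_index = cohort.trio_index
    out = []

    def draw_dp(mean):
        if not noise:
            return int(round(mean))
        p = cfg.depth_dispersion / (cfg.depth_dispersion + mean)
        return int(rng.negative_binomial(cfg.depth_dispersion, p))

    def het_ad(dp):
        alt = rng.binomial(dp, 0.5) if noise else dp // 2
        return (dp - alt, alt)

    def homref_ad(dp):
        alt = rng.binomial(dp, parent_error_rate) if (noise and parent_error_rate) else 0
        return (dp - alt, alt)

    for row in cohort.dnms.itertuples(index=False):
        trio = trio_index[row.trio_id]
        dps = {role: draw_dp(trio.mean_depth[role]) for role in ("offspring", "sire", "dam")}
        site = CandidateSite(
            contig=row.contig,
            pos=row.pos,
            ref=row.ref,
            alt=row.alt,
            gt={"offspring": (0, 1), "sire": (0, 0), "dam": (0, 0)},
            gq={"offspring": 99, "sire": 99, "dam": 99},
            dp=dps,
            ad={
                "offspring": het_ad(dps["offspring"]),
                "sire": homref_ad(dps["sire"]),
                "dam": homref_ad(dps["dam"]),
            },
            context3=row.context3,
        )
        out.append((row.trio_id, site, "dnm"))

    if n_negative_per_trio:
        for trio in cohort.trios:
            for _ in range(n_negative_per_trio):
                pos = int(rng.integers(1, cohort.region_map.contigs["A2"] - 1))
                dps = {
                    role: draw_dp(trio.mean_depth[role])
                    for role in ("offspring", "sire", "dam")
                }
                site = CandidateSite(
                    contig="A2",
                    pos=pos,
                    ref="C",
                    alt="T",
                    gt={"offspring": (0, 1), "sire": (0, 1), "dam": (0, 0)},
                    gq={"offspring": 99, "sire": 99, "dam": 99},
                    dp=dps,
                    ad={
                        "offspring": het_ad(dps["offspring"]),
                        "sire": het_ad(dps["sire"]),
                        "dam": homref_ad(dps["dam"]),
                    },
                    context3="ACT",
                )
                out.append((trio.trio_id, site, "inherited"))
    return out


def write_trio_vcf(path, trio: TrioRecord, sites, contigs: dict) -> None:
    """Write CandidateSite evidence for one trio as a plain-text VCF 4.2.

    Sample columns are offspring, sire, dam.  The reference triplet is
    carried in INFO/CTX so a round trip preserves mutation-class
    context.  Output is byte-deterministic for identical inputs.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CTX,Number=1,Type=String,Description="Reference triplet centred on site">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
    ]
    for name, length in sorted(contigs.items()):
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        f"{trio.offspring_id}\t{trio.sire_id}\t{trio.dam_id}"
    )
    for site in sorted(sites, key=lambda s: (s.contig, s.pos)):
        cols = [
            site.contig,
            str(site.pos + 1),  # back to 1-based
            ".",
            site.ref,
            site.alt,
            ".",
            "PASS",
            f"CTX={site.context3}",
            "GT:GQ:DP:AD",
        ]
        for role in ("offspring", "sire", "dam"):
            gt = "/".join(map(str, site.gt[role]))
            ad = ",".join(map(str, site.ad[role]))
            cols.append(f"{gt}:{site.gq[role]}:{site.dp[role]}:{ad}")
        lines.append("\t".join(cols))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_trio_vcf(path):
    """Read a trio VCF into CandidateSite records via cyvcf2.

    Sample order must be offspring, sire, dam (as written by
    :func:`write_trio_vcf`).  Multi-allelic records are decomposed into
    bi-allelic candidates, one per alternate allele.
    """
    from cyvcf2 import VCF

    from canidnm.records import CandidateSite

    roles = ("offspring", "sire", "dam")
    sites = []
    vcf = VCF(str(path))
    for var in vcf:
        gts = var.genotypes  # [[a, b, phased], ...]
        gqs = var.gt_quals
        dps = var.format("DP")[:, 0] if var.format("DP") is not None else None
        ads = var.format("AD")
        ctx = var.INFO.get("CTX") or "NNN"
        for alt_i, alt in enumerate(var.ALT, start=1):
            gt, gq, dp, ad = {}, {}, {}, {}
            for si, role in enumerate(roles):
                a, b = gts[si][0], gts[si][1]
                gt[role] = tuple(1 if x == alt_i else 0 for x in (a, b))
                gq[role] = int(gqs[si])
                dp[role] = int(dps[si]) if dps is not None else 0
                if ads is not None:
                    ad[role] = (int(ads[si][0]), int(ads[si][alt_i]))
                else:
                    ad[role] = None
            sites.append(
                CandidateSite(
                    contig=var.CHROM,
                    pos=var.POS - 1,
                    ref=var.REF,
                    alt=alt,
                    gt=gt,
                    gq=gq,
                    dp=dp,
                    ad=ad,
                    context3=ctx,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# phased marker tracks (crossover truth)

def simulate_marker_track(
    chrom_length: int,
    n_markers: int,
    n_crossovers: int,
    seed: int,
    origin_error_rate: float = 0.0,
):
    """Informative-marker track with known crossover positions.

    Markers are uniform over the chromosome; grandparental origin
    alternates at each of ``n_crossovers`` uniform crossover points.
    ``origin_error_rate`` flips individual marker labels (phasing
    noise).  Returns (positions, origins, true_crossovers).
    """
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.integers(0, chrom_length, size=n_markers))
    crossovers = np.sort(rng.integers(0, chrom_length, size=n_crossovers))
    origins = np.searchsorted(crossovers, positions, side="right") % 2
    if origin_error_rate > 0:
        flips = rng.random(n_markers) < origin_error_rate
        origins = np.where(flips, 1 - origins, origins)
    return positions, origins, crossovers


# ---------------------------------------------------------------------------
# paired phylogenies with a rate-ratio shift

def simulate_ratioed_phylogeny(
    species_tree_with_ages,
    r0: float,
    r1: float,
    loss_time: float | None,
    noise_sd: float,
    seed: int,
    transition_clade=("dog", "african_wild_dog", "fox"),
    subst_rate: float = 2e-3,
):
    """Paired (autosome, HMR-CGI) trees with a ratio shift at a loss time.

    Per branch, the autosomal length is branch duration x
    ``subst_rate``; the HMR length is the autosomal length times r1 for
    branches entirely inside the post-loss clade, r0 for branches
    outside it, and the time-weighted mixture of the two on the
    transition branch (loss at its oldest point gives exactly r1).
    Independent multiplicative log-normal noise of sd ``noise_sd`` is
    applied to every branch of each tree.  ``loss_time=None`` means the
    loss never happened (every ratio r0).
    """
    rng = np.random.default_rng(seed)
    tree = _as_tree(species_tree_with_ages)
    ages = node_ages(tree)
    transition = frozenset(transition_clade)
    if transition not in ages:
        raise ValueError(f"transition clade {sorted(transition)} not in tree")
    t_young, t_old = ages[transition]
    if loss_time is not None and not (t_young <= loss_time <= t_old):
        raise ValueError(
            f"loss_time {loss_time} outside transition branch span [{t_young}, {t_old}]"
        )

    def ratio_for(clade):
        if loss_time is None:
            return r0
        if clade == transition:
            w = (loss_time - t_young) / (t_old - t_young)
            return w * r1 + (1.0 - w) * r0
        if clade < transition:
            return r1  # post-loss lineage
        return r0

    auto = _as_tree(tree.as_string(schema="newick"))
    hmr = _as_tree(tree.as_string(schema="newick"))
    for src, dst_auto, dst_hmr in zip(
        tree.preorder_node_iter(), auto.preorder_node_iter(), hmr.preorder_node_iter()
    ):
        if src.parent_node is None:
            continue
        clade = frozenset(lf.taxon.label for lf in src.leaf_iter())
        duration = ages[clade][1] - ages[clade][0]
        base = duration * subst_rate
        noise_a = rng.lognormal(0.0, noise_sd) if noise_sd > 0 else 1.0
        noise_h = rng.lognormal(0.0, noise_sd) if noise_sd > 0 else 1.0
        dst_auto.edge.length = base * noise_a
        dst_hmr.edge.length = base * ratio_for(clade) * noise_h
    return auto, hmr
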